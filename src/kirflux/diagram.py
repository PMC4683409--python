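"""Construction and validation of the eleven-state permeation diagram.

The Kir2.1 pore is modelled as a single-file selectivity filter with four
binding sites (S1..S4, extracellular to intracellular), each occupied by an
ion or a water molecule, plus one lumped, voltage-independent K+ site in the
wide pore (cytoplasmic pore and central cavity).  Ions may not occupy
adjacent filter sites, the ion-empty filter is excluded, and the wide-pore
site may not be occupied while S4 holds an ion.  These rules yield exactly
seven filter configurations and eleven pore states.

The transition topology (which pairs of states interconvert, the rate-label
assignment and the per-edge ion/water stoichiometry) is shipped as a
declarative, human-readable model file (``data/kir2p1.model``) so that it
can be audited directly; :func:`build_diagram` parses, cross-checks and
freezes it into a :class:`PermeationDiagram`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

ION = "i"
WATER = "w"

#: free rate-constant labels, in conventional order
FREE_LABELS = tuple(f"k{i}" for i in range(1, 11))


class DiagramError(ValueError):
    """Raised when a model specification violates a structural invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SFConfiguration:
    """Occupancy of the four selectivity-filter sites, S1..S4."""

    sites: tuple[str, str, str, str]

    def __post_init__(self) -> None:
        if len(self.sites) != 4 or any(s not in (ION, WATER) for s in self.sites):
            raise DiagramError(f"invalid SF pattern {self.sites!r}")
        for a, b in zip(self.sites, self.sites[1:]):
            if a == ION and b == ION:
                raise DiagramError(
                    f"adjacent ions in SF pattern {'-'.join(self.sites)}")
        if ION not in self.sites:
            raise DiagramError("ion-empty SF configuration is excluded")

    @classmethod
    def from_string(cls, text: str) -> "SFConfiguration":
        """Parse ``i-w-i-w`` style patterns."""
        return cls(tuple(text.replace("-", "")))  # type: ignore[arg-type]

    @property
    def n_ions(self) -> int:
        return self.sites.count(ION)

    def __str__(self) -> str:
        return "-".join(self.sites)


def enumerate_sf_configurations() -> list[SFConfiguration]:
    """All admissible filter configurations (brute force; exactly 7)."""
    out = []
    for combo in itertools.product((ION, WATER), repeat=4):
        try:
            out.append(SFConfiguration(combo))
        except DiagramError:
            continue
    return out


@dataclass(frozen=True)
class PoreState:
    """One state of the pore: filter configuration plus wide-pore occupancy."""

    index: int
    sf: SFConfiguration
    wide_pore_occupied: bool

    def __post_init__(self) -> None:
        if self.wide_pore_occupied and self.sf.sites[3] == ION:
            raise DiagramError(
                f"state {self.index}: wide-pore ion below an S4 ion is excluded")

    @property
    def n_ions(self) -> int:
        return self.sf.n_ions + int(self.wide_pore_occupied)


@dataclass(frozen=True)
class TransitionEdge:
    """A directed transition with its rate label and stoichiometry.

    ``ion_transfer`` / ``water_transfer`` count particles moved across the
    extracellular reference plane (positive = efflux).  ``kplus_dependence``
    marks bimolecular edges whose rate scales linearly with [K+] on the
    named side.  Edges with ``derived=True`` carry a dependent rate fixed by
    thermodynamic cycle closure rather than a free parameter.
    """

    from_state: int
    to_state: int
    rate_label: str
    z: float | None
    kplus_dependence: str  # "none" | "intracellular" | "extracellular"
    ion_transfer: int
    water_transfer: int
    direction_sense: str  # "binding" | "release" | "efflux" | "influx"
    derived: bool = False

    @property
    def key(self) -> tuple[int, int]:
        return (self.from_state, self.to_state)


@dataclass
class StructureReport:
    states: int
    directed_rates: int
    undirected_transitions: int
    simple_cycles: int
    conducting_cycles: int

    def as_dict(self) -> dict[str, int]:
        return dict(self.__dict__)


@dataclass
class PermeationDiagram:
    """Validated eleven-state diagram (states, directed edges, named cycles)."""

    states: dict[int, PoreState]
    edges: dict[tuple[int, int], TransitionEdge]
    named_cycles: dict[str, tuple[int, ...]]
    checksum: dict[str, int] = field(default_factory=dict)

    # -- basic views --------------------------------------------------------

    def undirected_edges(self) -> list[frozenset[int]]:
        return sorted({frozenset(k) for k in self.edges},
                      key=lambda s: tuple(sorted(s)))

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.states)
        g.add_edges_from(tuple(sorted(s)) for s in {frozenset(k) for k in self.edges})
        return g

    def reverse(self, edge: TransitionEdge) -> TransitionEdge:
        return self.edges[(edge.to_state, edge.from_state)]

    def derived_edges(self) -> list[TransitionEdge]:
        return [e for e in self.edges.values() if e.derived]

    def free_edges(self) -> list[TransitionEdge]:
        return [e for e in self.edges.values() if not e.derived]

    # -- stoichiometry ------------------------------------------------------

    def cycle_stoichiometry(self, cycle: Sequence[int]) -> tuple[int, int]:
        """Net (ions, waters) transferred per completion of ``cycle``.

        The cycle is given as a state sequence; the edge closing it back to
        the first state is implied.
        """
        n_ion = n_water = 0
        for u, v in zip(cycle, tuple(cycle[1:]) + (cycle[0],)):
            try:
                e = self.edges[(u, v)]
            except KeyError:
                raise DiagramError(f"no transition {u} -> {v}") from None
            n_ion += e.ion_transfer
            n_water += e.water_transfer
        return n_ion, n_water

    # -- structural counts --------------------------------------------------

    def simple_cycles(self) -> list[tuple[int, ...]]:
        """All simple cycles of the undirected skeleton (length >= 3)."""
        return [tuple(c) for c in nx.simple_cycles(self.graph())]

    def conducting_cycle_count(self) -> int:
        return sum(1 for c in self.simple_cycles()
                   if self.cycle_stoichiometry(c)[0] != 0)


# ---------------------------------------------------------------------------
# model-file parsing
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Raw, unvalidated content of a declarative model file."""

    states: list[tuple[int, str, bool]]
    edges: list[dict]
    named_cycles: dict[str, tuple[int, ...]]
    checksum: dict[str, int]


def _default_model_text() -> str:
    return (resources.files("kirflux") / "data" / "kir2p1.model").read_text()


def parse_model(text: str) -> ModelSpec:
    states: list[tuple[int, str, bool]] = []
    edges: list[dict] = []
    cycles: dict[str, tuple[int, ...]] = {}
    checksum: dict[str, int] = {}
    section = None
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            section = line.strip("[]")
            continue
        tok = line.split()
        if section == "states":
            states.append((int(tok[0]), tok[1], bool(int(tok[2]))))
        elif section == "edges":
            edges.append(dict(
                from_state=int(tok[0]), to_state=int(tok[1]), rate_label=tok[2],
                z=None if tok[3] == "dep" else float(tok[3]),
                kplus={"in": "intracellular", "out": "extracellular",
                       "none": "none"}[tok[4]],
                ion_transfer=int(tok[5]), water_transfer=int(tok[6]),
                direction_sense=tok[7]))
        elif section == "cycles":
            cycles[tok[0]] = tuple(int(s) for s in tok[1].split(","))
        elif section == "checksum":
            checksum[tok[0]] = int(tok[1])
    return ModelSpec(states, edges, cycles, checksum)


def load_model(path: str | Path | None = None) -> ModelSpec:
    """Read a model file; the packaged Kir2.1 transcription by default."""
    text = _default_model_text() if path is None else Path(path).read_text()
    return parse_model(text)


def write_model(diagram: PermeationDiagram, path: str | Path) -> None:
    """Round-trip writer: serialise a diagram back to the text format."""
    lines = ["# kirflux model file", "", "[states]"]
    for i, st in sorted(diagram.states.items()):
        lines.append(f"{i}\t{st.sf}\t{int(st.wide_pore_occupied)}")
    lines += ["", "[edges]"]
    sense_to_tok = {"intracellular": "in", "extracellular": "out", "none": "none"}
    for e in diagram.edges.values():
        z = "dep" if e.derived else f"{e.z:g}"
        lines.append("\t".join(map(str, (
            e.from_state, e.to_state, e.rate_label, z,
            sense_to_tok[e.kplus_dependence],
            e.ion_transfer, e.water_transfer, e.direction_sense))))
    lines += ["", "[cycles]"]
    for name, seq in diagram.named_cycles.items():
        lines.append(f"{name}\t{','.join(map(str, seq))}")
    lines += ["", "[checksum]"]
    rep = structure_report(diagram)
    for key, val in rep.as_dict().items():
        lines.append(f"{key}\t{val}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# construction and validation
# ---------------------------------------------------------------------------

def build_diagram(spec: ModelSpec | None = None) -> PermeationDiagram:
    """Build and validate a :class:`PermeationDiagram` from a model spec.

    Raises :class:`DiagramError` if the spec violates the occupancy rules,
    lacks a reverse for any edge, mis-labels the degenerate intracellular
    binding steps, or cannot be made thermodynamically consistent (the
    derived-rate edges must close every independent loop exactly once).
    """
    if spec is None:
        spec = load_model()

    states: dict[int, PoreState] = {}
    for idx, sf_text, wp in spec.states:
        if idx in states:
            raise DiagramError(f"duplicate state index {idx}")
        states[idx] = PoreState(idx, SFConfiguration.from_string(sf_text), wp)

    edges: dict[tuple[int, int], TransitionEdge] = {}
    for e in spec.edges:
        edge = TransitionEdge(derived=e["rate_label"] not in FREE_LABELS,
                              from_state=e["from_state"], to_state=e["to_state"],
                              rate_label=e["rate_label"], z=e["z"],
                              kplus_dependence=e["kplus"],
                              ion_transfer=e["ion_transfer"],
                              water_transfer=e["water_transfer"],
                              direction_sense=e["direction_sense"])
        if edge.key in edges:
            raise DiagramError(f"duplicate edge {edge.key}")
        if edge.from_state not in states or edge.to_state not in states:
            raise DiagramError(f"edge {edge.key} references unknown state")
        edges[edge.key] = edge

    diagram = PermeationDiagram(states, edges, dict(spec.named_cycles),
                                dict(spec.checksum))
    _validate_reversibility(diagram)
    _validate_stoichiometry(diagram)
    _validate_derived_structure(diagram)
    _validate_named_cycles(diagram)
    return diagram


def _validate_reversibility(diagram: PermeationDiagram) -> None:
    for key in diagram.edges:
        if (key[1], key[0]) not in diagram.edges:
            raise DiagramError(f"edge {key} has no reverse edge")


def _validate_stoichiometry(diagram: PermeationDiagram) -> None:
    for e in diagram.edges.values():
        r = diagram.reverse(e)
        if r.ion_transfer != -e.ion_transfer or r.water_transfer != -e.water_transfer:
            raise DiagramError(f"edge {e.key}: reverse stoichiometry mismatch")
    # intracellular binding degeneracy: the k1 transitions load the wide pore
    for u, v in ((1, 2), (5, 6), (10, 11)):
        if (u, v) in diagram.edges and diagram.edges[(u, v)].rate_label != "k1":
            raise DiagramError(f"transition {u}->{v} must carry label k1")


def _validate_derived_structure(diagram: PermeationDiagram) -> None:
    """Derived-rate edges must form a cotree: removing their undirected
    edges must leave a spanning tree, so each derived rate closes exactly
    one independent loop and detailed balance has a unique solution."""
    g = diagram.graph()
    if not nx.is_connected(g):
        raise DiagramError("diagram is not connected")
    derived_und = {frozenset(e.key) for e in diagram.derived_edges()}
    n_loops = g.number_of_edges() - g.number_of_nodes() + 1
    if len(derived_und) != n_loops:
        raise DiagramError(
            f"{len(derived_und)} derived transitions for {n_loops} independent loops")
    tree = nx.Graph(g)
    tree.remove_edges_from(tuple(s) for s in derived_und)
    if not nx.is_tree(tree):
        raise DiagramError("derived transitions do not form a cotree")
    for s in derived_und:
        u, v = tuple(s)
        if not (diagram.edges[(u, v)].derived ^ diagram.edges[(v, u)].derived):
            raise DiagramError(
                f"exactly one direction of {u}-{v} may carry a derived rate")


def _validate_named_cycles(diagram: PermeationDiagram) -> None:
    for name, seq in diagram.named_cycles.items():
        diagram.cycle_stoichiometry(seq)  # raises if an edge is missing


def structure_report(diagram: PermeationDiagram) -> StructureReport:
    cycles = diagram.simple_cycles()
    return StructureReport(
        states=len(diagram.states),
        directed_rates=len(diagram.edges),
        undirected_transitions=len(diagram.undirected_edges()),
        simple_cycles=len(cycles),
        conducting_cycles=sum(1 for c in cycles
                              if diagram.cycle_stoichiometry(c)[0] != 0),
    )


def validate_structure(diagram: PermeationDiagram,
                       expected: Mapping[str, int] | None = None) -> StructureReport:
    """Structural report; raises :class:`DiagramError` on a count mismatch.

    ``expected`` defaults to the checksum block of the model file the
    diagram was built from (empty for ad-hoc diagrams, in which case the
    report is returned unchecked).
    """
    report = structure_report(diagram)
    expected = dict(diagram.checksum) if expected is None else dict(expected)
    for key, want in expected.items():
        got = report.as_dict().get(key)
        if got != want:
            raise DiagramError(f"structural invariant {key}: expected {want}, got {got}")
    return report


def kir2p1_diagram() -> PermeationDiagram:
    """The packaged, validated Kir2.1 eleven-state diagram."""
    return build_diagram(load_model())
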