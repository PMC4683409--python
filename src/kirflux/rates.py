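"""Rate constants: voltage dependence and thermodynamic closure.

Every transition rate follows the single-barrier Eyring form

    k(V) = k0 * exp(z * F * V / (R * T))

where ``k0`` is the rate at 0 mV and ``z`` the electrical distance (the
fraction of the membrane field the moving charge crosses).  Bimolecular
edges (K+ binding from bulk) additionally scale linearly with [K+] on the
relevant side, so their ``k0`` is in 1/(M s); all others are in 1/s.

The diagram has seven independent loops.  One directed rate per loop (the
dependent rates, e.g. k32 for the 3->2 transition) is not a free parameter:
its k0 is fixed by detailed balance (equal forward/backward rate products
around the loop at 0 mV and symmetric [K+]) and its z by the loop charge
balance (the z's around a loop must sum to the net charge the loop moves
across the membrane).  With both closures every one of the 59 cycles is
exactly reversible at equilibrium, at any symmetric [K+].
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np

from .constants import Condition, PhysicalConstants
from .diagram import (FREE_LABELS, DiagramError, PermeationDiagram,
                      TransitionEdge)

#: electrical distances of the free rate constants (dimensionless)
Z_TABLE: dict[str, float] = {
    "k1": 0.0, "k2": 0.0, "k3": 0.2, "k4": -0.2, "k5": 0.3,
    "k6": 0.2, "k7": 0.2, "k8": -0.2, "k9": 0.1, "k10": -0.1,
}


@dataclass
class RateParameterSet:
    """The ten free rate constants with their electrical distances.

    ``k0`` maps each label to its 0-mV value (1/s, or 1/(M s) for the
    bimolecular binding label k1).  ``free_mask`` marks which labels an
    optimiser may vary; it does not affect rate evaluation.
    """

    k0: dict[str, float]
    z: dict[str, float] = field(default_factory=lambda: dict(Z_TABLE))
    free_mask: dict[str, bool] = field(
        default_factory=lambda: {k: True for k in FREE_LABELS})

    def __post_init__(self) -> None:
        missing = [k for k in FREE_LABELS if k not in self.k0]
        if missing:
            raise ValueError(f"missing rate constants: {missing}")
        bad = [k for k, v in self.k0.items() if not v > 0]
        if bad:
            raise ValueError(f"rate constants must be positive: {bad}")

    def copy(self) -> "RateParameterSet":
        return RateParameterSet(dict(self.k0), dict(self.z), dict(self.free_mask))

    def with_updates(self, updates: Mapping[str, float]) -> "RateParameterSet":
        new = self.copy()
        new.k0.update(updates)
        return new

    def free_labels(self) -> list[str]:
        return [k for k in FREE_LABELS if self.free_mask.get(k, False)]

    # -- serialisation ------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"k0": self.k0, "z": self.z, "free_mask": self.free_mask}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RateParameterSet":
        d = json.loads(Path(path).read_text())
        return cls(k0=d["k0"], z=d.get("z", dict(Z_TABLE)),
                   free_mask=d.get("free_mask", {k: True for k in FREE_LABELS}))

    @classmethod
    def _from_package(cls, name: str) -> "RateParameterSet":
        d = json.loads((resources.files("kirflux") / "data" / name).read_text())
        return cls(k0=d["k0"], z=d.get("z", dict(Z_TABLE)),
                   free_mask=d.get("free_mask", {k: True for k in FREE_LABELS}))

    @classmethod
    def wild_type(cls) -> "RateParameterSet":
        """Packaged wild-type-like reference set (synthetic ground truth)."""
        return cls._from_package("params_wt.json")

    @classmethod
    def mutant(cls) -> "RateParameterSet":
        """Packaged mutant-like reference set; differs from the wild type
        only in the wide-pore rates k1, k2, k5, k7, k8."""
        return cls._from_package("params_mutant.json")


def rate_at_voltage(params: RateParameterSet, label: str, V_m: float,
                    consts: PhysicalConstants = PhysicalConstants()) -> float:
    """Evaluate k(V) = k0 exp(z F V / R T) for a free rate label."""
    if label not in params.k0:
        raise KeyError(f"unknown rate label {label!r}")
    return params.k0[label] * math.exp(
        params.z[label] * consts.F * V_m / (consts.R * consts.T))


# ---------------------------------------------------------------------------
# thermodynamic closure of the dependent rates
# ---------------------------------------------------------------------------

def _fundamental_cycle(diagram: PermeationDiagram,
                       derived_edge: TransitionEdge) -> list[tuple[int, int]]:
    """Directed fundamental loop closed by ``derived_edge``.

    The loop runs through the derived edge u->v and back from v to u along
    the spanning tree that remains when all derived-carrying undirected
    edges are removed.  Loops are topology-fixed, so they are cached on the
    diagram.
    """
    cache = getattr(diagram, "_loop_cache", None)
    if cache is None:
        cache = {}
        tree = diagram.graph()
        tree.remove_edges_from(tuple(frozenset(e.key))
                               for e in diagram.derived_edges())
        for de in diagram.derived_edges():
            path = nx.shortest_path(tree, de.to_state, de.from_state)
            cache[de.key] = [de.key] + list(zip(path, path[1:]))
        object.__setattr__(diagram, "_loop_cache", cache)
    return cache[derived_edge.key]


def resolve_dependent_rates(diagram: PermeationDiagram, params: RateParameterSet,
                            ) -> dict[tuple[int, int], tuple[float, float]]:
    """k0 and z of each dependent edge, from loop closure.

    For the loop (derived edge plus tree path) the product of 0-mV rates in
    the loop direction must equal the product against it, and the signed sum
    of z's must equal the net ionic charge the loop transports.  Each loop
    contains exactly one derived edge, so both solve directly.
    """
    out: dict[tuple[int, int], tuple[float, float]] = {}
    for de in diagram.derived_edges():
        loop = _fundamental_cycle(diagram, de)
        n_ion = sum(diagram.edges[k].ion_transfer for k in loop)
        log_k0 = 0.0
        z = float(n_ion)
        n_in = n_out = 0
        for u, v in loop:
            fwd, bwd = diagram.edges[(u, v)], diagram.edges[(v, u)]
            n_in += _conc_sign(fwd, bwd, "intracellular")
            n_out += _conc_sign(fwd, bwd, "extracellular")
            if (u, v) != de.key:
                log_k0 -= math.log(params.k0[fwd.rate_label])
                z -= fwd.z  # type: ignore[operator]
            log_k0 += math.log(params.k0[bwd.rate_label])
            z += bwd.z  # type: ignore[operator]
        if n_in != n_ion or n_out != -n_ion:
            raise DiagramError(
                f"loop through {de.key}: concentration factors do not balance "
                f"the transported charge (n_ion={n_ion}, in={n_in}, out={n_out})")
        out[de.key] = (math.exp(log_k0), z)
    return out


def _conc_sign(fwd: TransitionEdge, bwd: TransitionEdge, side: str) -> int:
    s = 0
    if fwd.kplus_dependence == side:
        s += 1
    if bwd.kplus_dependence == side:
        s -= 1
    return s


class TableRateEvaluator:
    """Condition-independent rates given directly as a table.

    Used for toy diagrams (closed-form checks) where rates are arbitrary
    numbers rather than the voltage/concentration-scaled model rates.
    """

    def __init__(self, diagram: PermeationDiagram,
                 rates: Mapping[tuple[int, int], float]):
        self.diagram = diagram
        self._rates = dict(rates)

    def rate(self, u: int, v: int, condition=None) -> float:
        return self._rates[(u, v)]

    def rate_matrix(self, condition=None) -> tuple[np.ndarray, list[int]]:
        order = sorted(self.diagram.states)
        pos = {s: i for i, s in enumerate(order)}
        K = np.zeros((len(order), len(order)))
        for (u, v), k in self._rates.items():
            K[pos[u], pos[v]] = k
        return K, order


class RateEvaluator:
    """Evaluates the full 34-rate set at arbitrary conditions.

    Dependent-rate closure is recomputed whenever the free parameters
    change; voltage and concentration scaling are applied per condition.
    """

    def __init__(self, diagram: PermeationDiagram, params: RateParameterSet,
                 consts: PhysicalConstants = PhysicalConstants()):
        self.diagram = diagram
        self.params = params
        self.consts = consts
        dep = resolve_dependent_rates(diagram, params)
        self._k0: dict[tuple[int, int], float] = {}
        self._z: dict[tuple[int, int], float] = {}
        for key, e in diagram.edges.items():
            if e.derived:
                self._k0[key], self._z[key] = dep[key]
            else:
                self._k0[key] = params.k0[e.rate_label]
                self._z[key] = params.z[e.rate_label]

    def k0(self, u: int, v: int) -> float:
        return self._k0[(u, v)]

    def z(self, u: int, v: int) -> float:
        return self._z[(u, v)]

    def rate(self, u: int, v: int, condition: Condition) -> float:
        e = self.diagram.edges[(u, v)]
        k = self._k0[(u, v)] * math.exp(
            self._z[(u, v)] * self.consts.F * condition.V_m
            / (self.consts.R * self.consts.T))
        if e.kplus_dependence == "intracellular":
            k *= condition.K_in
        elif e.kplus_dependence == "extracellular":
            k *= condition.K_out
        return k

    def rate_matrix(self, condition: Condition) -> tuple[np.ndarray, list[int]]:
        """(K, index_order): K[a, b] = rate from state order[a] to order[b]."""
        order = sorted(self.diagram.states)
        pos = {s: i for i, s in enumerate(order)}
        K = np.zeros((len(order), len(order)))
        for (u, v) in self.diagram.edges:
            K[pos[u], pos[v]] = self.rate(u, v, condition)
        return K, order
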