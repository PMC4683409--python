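"""Exact steady state and cycle-flux decomposition of the diagram.

At steady state the net ion flux through the pore decomposes exactly into
fluxes around the simple cycles of the diagram (Hill's diagram method).
Each cycle ``i`` carries a fixed water:ion stoichiometry -- its cyclic
coupling ratio ``ccr_i = n_water / n_ion`` -- so the macroscopic water-ion
coupling ratio is the flux-weighted mean

    CR_wi = sum_i (J_i / J_total) * ccr_i

where ``J_i`` is the ionic flux carried by cycle i and ``J_total`` the net
ionic flux.  Cycle fluxes are evaluated with the matrix-tree (spanning
tree / converging forest) formulation:

    J_cycle = (Pi+ - Pi-) * Sigma_cycle / Sigma

with ``Pi+``/``Pi-`` the rate products around the cycle in its two
orientations, ``Sigma_cycle`` the determinant counting all forests that
converge onto the cycle, and ``Sigma`` the sum of rooted spanning-tree
weights over all states.  This is exact (no stochastic simulation) and is
cross-checked in the test suite against the master-equation cut flux.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .constants import Condition, PhysicalConstants
from .diagram import PermeationDiagram
from .rates import RateEvaluator, RateParameterSet


@dataclass
class CycleRecord:
    """One simple cycle with its stoichiometry and (optionally) its flux.

    ``J`` is the net cycle flux in completions per second (signed, positive
    in the stored orientation); the ionic flux the cycle carries is
    ``n_ion * J``.  ``ccr`` is undefined (None) for non-conducting cycles
    (``n_ion == 0``).
    """

    cycle_id: str
    state_sequence: tuple[int, ...]
    n_ion: int
    n_water: int
    J: float | None = None

    @property
    def conducting(self) -> bool:
        return self.n_ion != 0

    @property
    def ccr(self) -> float | None:
        if self.n_ion == 0:
            return None
        return abs(self.n_water / self.n_ion)

    @property
    def ion_flux(self) -> float:
        if self.J is None:
            raise ValueError("fluxes not computed for this record")
        return self.n_ion * self.J


@dataclass
class CycleDecomposition:
    """All cycle records at one condition, plus the macroscopic fluxes."""

    condition: Condition | None
    records: list[CycleRecord]
    J_total: float  # net ion flux, ions/s (efflux positive)
    J_water: float  # net water flux, molecules/s

    def record(self, cycle_id: str) -> CycleRecord:
        for r in self.records:
            if r.cycle_id == cycle_id:
                return r
        raise KeyError(cycle_id)

    def contributions(self) -> dict[str, float]:
        """Relative ionic-flux contribution of each conducting cycle."""
        if self.J_total == 0:
            raise ValueError("contributions undefined at zero total flux")
        return {r.cycle_id: r.ion_flux / self.J_total
                for r in self.records if r.conducting}

    def to_frame(self):
        import pandas as pd
        jt = self.J_total
        rows = [{
            "cycle_id": r.cycle_id,
            "states": "-".join(map(str, r.state_sequence)),
            "n_ion": r.n_ion, "n_water": r.n_water, "ccr": r.ccr,
            "J": r.J, "ion_flux": r.n_ion * (r.J or 0.0),
            "contribution": (r.n_ion * (r.J or 0.0) / jt) if jt else np.nan,
        } for r in self.records]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cycle enumeration
# ---------------------------------------------------------------------------

def _canonical(diagram: PermeationDiagram,
               cycle: Sequence[int]) -> tuple[tuple[int, ...], int, int]:
    """Canonical orientation/rotation of a cycle with its stoichiometry.

    Orientation: net ion efflux positive; for non-conducting cycles net
    water efflux positive; fully neutral cycles take the lexicographically
    smaller direction.  Rotation: start at the smallest state index.
    """
    seq = tuple(cycle)
    n_ion, n_water = diagram.cycle_stoichiometry(seq)
    rev = tuple(reversed(seq))
    flip = (n_ion < 0) or (n_ion == 0 and n_water < 0)
    if n_ion == 0 and n_water == 0:
        flip = _rotate_min(rev) < _rotate_min(seq)
    if flip:
        seq, n_ion, n_water = rev, -n_ion, -n_water
    return _rotate_min(seq), n_ion, n_water


def _rotate_min(seq: tuple[int, ...]) -> tuple[int, ...]:
    i = seq.index(min(seq))
    return seq[i:] + seq[:i]


def _cycle_key(seq: Sequence[int]) -> frozenset[frozenset[int]]:
    return frozenset(frozenset((u, v))
                     for u, v in zip(seq, tuple(seq[1:]) + (seq[0],)))


def _unnamed_ids(n: int) -> list[str]:
    letters = string.ascii_lowercase
    out = list(letters)
    for a in letters:
        out += [a + b for b in letters]
    return out[:n]


def enumerate_cycles(diagram: PermeationDiagram) -> list[CycleRecord]:
    """All simple cycles of the undirected skeleton, fluxes unset.

    The five cycles named in the model file keep their letters; the
    remaining cycles receive deterministic ids (``f``, ``g``, ... in order
    of increasing length, then state sequence).  Stoichiometry is obtained
    by summing the per-edge transfer fields along the canonical
    orientation and is therefore a pure property of the topology.
    """
    named = {_cycle_key(seq): name for name, seq in diagram.named_cycles.items()}
    canon = [_canonical(diagram, c) for c in diagram.simple_cycles()]
    canon.sort(key=lambda t: (len(t[0]), t[0]))
    records: list[CycleRecord] = []
    ids = iter(x for x in _unnamed_ids(1000)
               if x not in diagram.named_cycles)
    for seq, n_ion, n_water in canon:
        name = named.get(_cycle_key(seq))
        if name is not None:
            seq2, n2, w2 = _canonical(diagram, diagram.named_cycles[name])
            records.append(CycleRecord(name, seq2, n2, w2))
        else:
            records.append(CycleRecord(next(ids), seq, n_ion, n_water))
    # named first (a, b, c, ...), then the rest in structural order
    records.sort(key=lambda r: (r.cycle_id not in diagram.named_cycles,
                                len(r.cycle_id), r.cycle_id))
    return records


# ---------------------------------------------------------------------------
# steady state (master-equation oracle)
# ---------------------------------------------------------------------------

def steady_state(diagram: PermeationDiagram, params: RateParameterSet | None,
                 condition: Condition | None = None,
                 consts: PhysicalConstants = PhysicalConstants(),
                 evaluator=None) -> dict[int, float]:
    """Stationary state probabilities from the master equation.

    Solves pi^T Q = 0 with sum(pi) = 1 by least squares on the augmented
    system; raises if the diagram is not irreducible or the balance
    residual exceeds 1e-10 (relative).
    """
    ev = evaluator or RateEvaluator(diagram, params, consts)
    K, order = ev.rate_matrix(condition)
    scale = K.max()
    Q = (K - np.diag(K.sum(axis=1))) / scale
    A = np.vstack([Q.T, np.ones(len(order))])
    b = np.zeros(len(order) + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    for _ in range(3):  # iterative refinement against ill-conditioning
        delta, *_ = np.linalg.lstsq(A, b - A @ pi, rcond=None)
        pi = pi + delta
    if np.any(pi < -1e-9):
        raise ArithmeticError("negative stationary probability: diagram "
                              "not irreducible at this condition")
    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()
    # balance residual per state, relative to the largest state throughput
    inflow, outflow = K.T @ pi, pi * K.sum(axis=1)
    rel = np.abs(inflow - outflow) / max((inflow + outflow).max(), 1e-300)
    if rel.max() > 1e-10:
        raise ArithmeticError("master-equation balance not satisfied")
    return {s: float(p) for s, p in zip(order, pi)}


def cut_fluxes(diagram: PermeationDiagram, params: RateParameterSet | None,
               condition: Condition | None = None,
               consts: PhysicalConstants = PhysicalConstants(),
               evaluator=None,
               pi: dict[int, float] | None = None) -> tuple[float, float]:
    """Net (ion, water) flux in particles/s across the extracellular plane.

    Independent of the cycle algebra; serves as its oracle.
    """
    ev = evaluator or RateEvaluator(diagram, params, consts)
    if pi is None:
        pi = steady_state(diagram, params, condition, consts, evaluator=ev)
    j_ion = j_water = 0.0
    for (u, v), e in diagram.edges.items():
        if e.ion_transfer or e.water_transfer:
            w = pi[u] * ev.rate(u, v, condition)
            j_ion += e.ion_transfer * w
            j_water += e.water_transfer * w
    return j_ion, j_water


# ---------------------------------------------------------------------------
# exact cycle-flux decomposition (matrix-tree formulation)
# ---------------------------------------------------------------------------

def decompose(diagram: PermeationDiagram, params: RateParameterSet | None,
              condition: Condition | None = None,
              consts: PhysicalConstants = PhysicalConstants(),
              evaluator=None,
              records: list[CycleRecord] | None = None) -> CycleDecomposition:
    """Net cycle fluxes for every simple cycle at one condition.

    Records are returned sorted by descending \\|ionic flux\\| (named
    letters keep their ids).  ``J_total`` is the sum of per-cycle ionic
    fluxes and agrees with the master-equation cut flux to numerical
    precision.
    """
    ev = evaluator or RateEvaluator(diagram, params, consts)
    if records is None:
        records = enumerate_cycles(diagram)
    K, order = ev.rate_matrix(condition)
    pos = {s: i for i, s in enumerate(order)}
    n = len(order)

    # scale to keep determinants in floating range
    logs = np.log(K[K > 0])
    s = math.exp(float(np.mean(logs)))
    Ks = K / s
    L = np.diag(Ks.sum(axis=1)) - Ks  # out-degree Laplacian

    # Sigma: total rooted spanning-tree weight (all roots)
    idx = np.arange(n)
    sigma = math.fsum(
        float(np.linalg.det(L[np.ix_(idx != j, idx != j)])) for j in range(n))
    if sigma <= 0:
        raise ArithmeticError("diagram not strongly connected")

    out: list[CycleRecord] = []
    J_total = 0.0
    J_water = 0.0
    for rec in records:
        seq = rec.state_sequence
        edges = list(zip(seq, tuple(seq[1:]) + (seq[0],)))
        lnp = math.fsum(math.log(Ks[pos[u], pos[v]]) for u, v in edges)
        lnm = math.fsum(math.log(Ks[pos[v], pos[u]]) for u, v in edges)
        diff = math.exp(lnp) * (-math.expm1(lnm - lnp))
        keep = np.array([s_ not in seq for s_ in order])
        sigma_c = float(np.linalg.det(L[np.ix_(keep, keep)])) if keep.any() else 1.0
        J = diff * sigma_c / sigma * s
        out.append(replace(rec, J=J))
        J_total += rec.n_ion * J
        J_water += rec.n_water * J

    named = set(diagram.named_cycles)
    out.sort(key=lambda r: (-abs(r.n_ion * (r.J or 0.0)),
                            r.cycle_id not in named, r.cycle_id))
    return CycleDecomposition(condition=condition, records=out,
                              J_total=J_total, J_water=J_water)


def coupling_ratio(decomp: CycleDecomposition) -> float:
    """Flux-weighted water-ion coupling ratio CR_wi.

    Undefined at equilibrium (zero total flux); raises ValueError there
    rather than returning a number.
    """
    if decomp.J_total == 0:
        raise ValueError("CR_wi undefined: total flux is zero (equilibrium)")
    return math.fsum((r.ion_flux / decomp.J_total) * r.ccr
                     for r in decomp.records if r.conducting)
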