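"""Measurable quantities derived from the permeation model.

Units follow electrophysiological convention: membrane potential in mV at
the interface level (volts internally), single-channel current in pA
(outward positive, inward negative), conductance in pS, streaming
potentials in mV, osmolality differences in Osm/kg.

The streaming potential generated by an osmotic gradient across a
single-file pore is

    V_stream = -CR_wi * v_w * d_pi / (z * F),      d_pi = R * T * c_osm

where ``CR_wi`` is the water-ion coupling ratio, ``v_w`` the molar volume
of water and ``c_osm`` the osmotic concentration difference (osmolality
times water density).  The same relation converts a measured
V_stream-vs-osmolality regression slope back into a coupling ratio;
:func:`predict_vstream` and :func:`slope_to_cr` are exact inverses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .constants import Condition, PhysicalConstants, ELEMENTARY_CHARGE
from .cycles import (CycleDecomposition, coupling_ratio, cut_fluxes,
                     decompose, enumerate_cycles)
from .diagram import PermeationDiagram
from .rates import RateEvaluator, RateParameterSet


@dataclass
class IVCurve:
    """Single-channel current-voltage relation at fixed [K+]."""

    points: list[tuple[float, float]]  # (V_m in mV, current in pA)
    K_in: float
    K_out: float

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        a = np.asarray(self.points, float)
        return a[:, 0], a[:, 1]


@dataclass
class ConductanceCurve:
    """Chord conductance versus symmetric [K+] at a stated potential."""

    points: list[tuple[float, float]]  # ([K+] in mM, conductance in pS)
    V_mV: float


# ---------------------------------------------------------------------------
# currents and conductance
# ---------------------------------------------------------------------------

def predict_current(diagram: PermeationDiagram, params: RateParameterSet,
                    condition: Condition,
                    consts: PhysicalConstants = PhysicalConstants(),
                    evaluator: RateEvaluator | None = None) -> float:
    """Single-channel current in pA (outward positive, inward negative)."""
    j_ion, _ = cut_fluxes(diagram, params, condition, consts,
                          evaluator=evaluator)
    return consts.z_ion * ELEMENTARY_CHARGE * j_ion * 1e12


def iv_curve(diagram: PermeationDiagram, params: RateParameterSet,
             K_mM: float, voltages_mV: np.ndarray | list[float],
             consts: PhysicalConstants = PhysicalConstants()) -> IVCurve:
    ev = RateEvaluator(diagram, params, consts)
    pts = [(float(v), predict_current(
        diagram, params, Condition.symmetric(v, K_mM), consts, evaluator=ev))
        for v in voltages_mV]
    return IVCurve(points=pts, K_in=K_mM * 1e-3, K_out=K_mM * 1e-3)


def chord_conductance(diagram: PermeationDiagram, params: RateParameterSet,
                      K_mM: float, V_mV: float,
                      consts: PhysicalConstants = PhysicalConstants(),
                      V_rev_mV: float = 0.0) -> float:
    """Chord conductance i/(V - V_rev) in pS at symmetric [K+]."""
    if V_mV == V_rev_mV:
        raise ValueError("chord conductance undefined at the reversal potential")
    i = predict_current(diagram, params, Condition.symmetric(V_mV, K_mM), consts)
    return i / (V_mV - V_rev_mV) * 1e3  # pA/mV -> pS


def conductance_curve(diagram: PermeationDiagram, params: RateParameterSet,
                      K_mM_list, V_mV: float = -100.0,
                      consts: PhysicalConstants = PhysicalConstants(),
                      ) -> ConductanceCurve:
    pts = [(float(k), chord_conductance(diagram, params, k, V_mV, consts))
           for k in K_mM_list]
    return ConductanceCurve(points=pts, V_mV=V_mV)


# ---------------------------------------------------------------------------
# streaming potential <-> coupling ratio (exact inverses)
# ---------------------------------------------------------------------------

def osmotic_pressure(delta_osm: float,
                     consts: PhysicalConstants = PhysicalConstants()) -> float:
    """Osmotic pressure (Pa) of an osmolality difference in Osm/kg.

    Uses the van 't Hoff relation with the osmolar concentration
    delta_osm * rho_w (Osm/kg water approximated as osmol per litre).
    """
    c_osm = delta_osm * consts.rho_w * 1e3  # osmol/m^3
    return consts.R * consts.T * c_osm


def predict_vstream(cr_wi: float, delta_osm: float,
                    consts: PhysicalConstants = PhysicalConstants()) -> float:
    """Streaming potential in mV; negative for water efflux carrying K+."""
    d_pi = osmotic_pressure(delta_osm, consts)
    return -cr_wi * consts.v_w * d_pi / (consts.z_ion * consts.F) * 1e3


def slope_to_cr(slope_mV_per_osm: float,
                consts: PhysicalConstants = PhysicalConstants()) -> float:
    """Coupling ratio from a V_stream-vs-osmolality slope (mV per Osm/kg)."""
    per_unit = -predict_vstream(1.0, 1.0, consts)  # mV per (CR * Osm/kg)
    return abs(slope_mV_per_osm) / per_unit


def coupling_ratio_curve(diagram: PermeationDiagram, params: RateParameterSet,
                         K_mM_list, V_eval_mV: float = -1.0,
                         consts: PhysicalConstants = PhysicalConstants(),
                         ) -> list[tuple[float, float]]:
    """Model CR_wi at each symmetric [K+], evaluated near the reversal
    potential (the operating point of the streaming measurement)."""
    ev = RateEvaluator(diagram, params, consts)
    recs = enumerate_cycles(diagram)
    out = []
    for k in K_mM_list:
        dec = decompose(diagram, params, Condition.symmetric(V_eval_mV, k),
                        consts, evaluator=ev, records=recs)
        out.append((float(k), coupling_ratio(dec)))
    return out


# ---------------------------------------------------------------------------
# cycle contributions
# ---------------------------------------------------------------------------

def cycle_contribution_surface(diagram: PermeationDiagram,
                               params: RateParameterSet,
                               voltages_mV, K_mM_list,
                               consts: PhysicalConstants = PhysicalConstants()):
    """Per-cycle flux contributions and chord conductances on a (V, [K+]) grid.

    Returns a tidy DataFrame with one row per (V, [K+], cycle); the
    ``contribution`` column sums to 1 over cycles at each grid point and
    the per-cycle conductances sum to the total chord conductance.
    """
    import pandas as pd
    ev = RateEvaluator(diagram, params, consts)
    recs = enumerate_cycles(diagram)
    rows = []
    for k in K_mM_list:
        for v in voltages_mV:
            if v == 0:
                continue
            cond = Condition.symmetric(v, k)
            dec = decompose(diagram, params, cond, consts,
                            evaluator=ev, records=recs)
            for r in dec.records:
                if not r.conducting:
                    continue
                i_cyc = consts.z_ion * ELEMENTARY_CHARGE * r.ion_flux * 1e12
                rows.append({
                    "V_mV": v, "K_mM": k, "cycle_id": r.cycle_id,
                    "ccr": r.ccr, "J": r.J,
                    "contribution": r.ion_flux / dec.J_total,
                    "conductance_pS": i_cyc / v * 1e3,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Michaelis-Menten conductance fit
# ---------------------------------------------------------------------------

def fit_michaelis_menten(curve: ConductanceCurve,
                         anchor_gmax: bool = False) -> tuple[float, float]:
    """Least-squares (g_max, K_M) of g = g_max [K+] / ([K+] + K_M).

    With ``anchor_gmax`` the maximum is fixed so the fit passes through the
    highest-concentration point (the convention of anchoring at 300 mM).
    """
    k = np.array([p[0] for p in curve.points], float)
    g = np.array([p[1] for p in curve.points], float)
    if len(k) < 3:
        raise ValueError("need at least three concentrations")
    if anchor_gmax:
        kmax, gmax_pt = k[np.argmax(k)], g[np.argmax(k)]

        def model(x, km):
            return gmax_pt * (kmax + km) / kmax * x / (x + km)

        popt, _ = curve_fit(model, k, g, p0=[np.median(k)], maxfev=10000)
        km = float(popt[0])
        return gmax_pt * (kmax + km) / kmax, km

    def model(x, gmax, km):
        return gmax * x / (x + km)

    popt, _ = curve_fit(model, k, g, p0=[g.max(), np.median(k)], maxfev=10000)
    return float(popt[0]), float(popt[1])
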