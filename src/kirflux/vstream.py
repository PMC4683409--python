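"""Reduction of osmotic-pulse ramp recordings to coupling ratios.

The experiment applies a train of voltage ramps (-20 to +20 mV at 1 mV/ms)
to an inside-out patch: six sweeps under the isotonic condition, six under
a hyper-osmotic pulse (sorbitol removed from the intracellular side, so
water flows outward), and six after returning to isotonic.  The coupled
water-K+ efflux shifts the reversal potential negative during the pulse;
V_stream is that shift, corrected for the liquid-junction potential of the
reference electrode between the normal- and hyper-osmotic solutions.
Regressing V_stream against the osmolality step and converting the slope
with the streaming-potential relation yields the water-ion coupling ratio.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .constants import PhysicalConstants
from .observables import slope_to_cr

ISO = "iso"
HYPER = "hyper"

#: measured junction potentials (mV) of the 3 M KCl reference electrode
#: between the normal- and hyper-osmotic solutions, as (value, SE),
#: keyed by ([K+] in mM, sorbitol molarity)
DEFAULT_JUNCTION_TABLE: dict[tuple[float, float], tuple[float, float]] = {
    (15, 0.5): (-0.22, 0.199), (15, 1.0): (-0.14, 0.084), (15, 1.5): (-0.03, 0.038),
    (50, 0.5): (-0.06, 0.022), (50, 1.0): (-0.12, 0.028), (50, 1.5): (0.13, 0.054),
    (150, 0.5): (-0.12, 0.012), (150, 1.0): (-0.22, 0.043), (150, 1.5): (-0.17, 0.057),
}


@dataclass
class JunctionTable:
    """Liquid-junction potentials by ([K+] mM, sorbitol M)."""

    entries: dict[tuple[float, float], tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_JUNCTION_TABLE))

    def potential(self, K_mM: float, sorbitol_M: float) -> float:
        key = min(self.entries, key=lambda k: (abs(k[0] - K_mM),
                                               abs(k[1] - sorbitol_M)))
        if abs(key[0] - K_mM) > 1e-6 or abs(key[1] - sorbitol_M) > 1e-6:
            raise KeyError(f"no junction entry for {K_mM} mM / {sorbitol_M} M")
        return self.entries[key][0]

    @classmethod
    def from_json(cls, path: str | Path) -> "JunctionTable":
        raw = json.loads(Path(path).read_text())
        return cls({(float(k.split("/")[0]), float(k.split("/")[1])):
                    tuple(v) for k, v in raw.items()})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {f"{k[0]:g}/{k[1]:g}": list(v) for k, v in self.entries.items()},
            indent=1))


@dataclass
class RampSweep:
    """One ramp set: a positive-going and a negative-going branch."""

    t_s: np.ndarray
    V_mV: np.ndarray
    I_pA: np.ndarray
    phase: str = ISO  # iso | hyper

    def branches(self) -> tuple[slice, slice]:
        """Index ranges of the positive- and negative-going branches."""
        turn = int(np.argmax(self.V_mV))
        return slice(0, turn + 1), slice(turn, len(self.V_mV))


@dataclass
class RampTrain:
    """A full osmotic-pulse protocol: iso / hyper / iso sweep blocks."""

    sweeps: list[RampSweep]
    K_mM: float
    delta_osm: float  # Osm/kg during the hyper phase
    sorbitol_M: float | None = None  # for the junction-table lookup
    meta: dict = field(default_factory=dict)

    def phases(self) -> list[str]:
        return [s.phase for s in self.sweeps]


@dataclass
class VStreamResult:
    """Per-train reduction: reversal potentials and the V_stream step."""

    K_mM: float
    delta_osm: float
    vrev_per_sweep: list[tuple[float, float]]  # (positive, negative) branch
    phases: list[str]
    vstream_raw: float
    junction_mV: float
    vstream: float  # junction-corrected, mV
    recovered: bool

    def vrev_means(self) -> list[float]:
        return [0.5 * (p + n) for p, n in self.vrev_per_sweep]


# ---------------------------------------------------------------------------
# reversal-potential extraction
# ---------------------------------------------------------------------------

def _zero_crossing(v: np.ndarray, i: np.ndarray) -> float:
    """Zero crossing by linear interpolation between bracketing samples.

    No smoothing is applied; traces are synthetic or already filtered.
    """
    s = np.sign(i)
    idx = np.nonzero(np.diff(s) != 0)[0]
    if len(idx) == 0:
        raise ValueError("current does not cross zero within the ramp span")
    # noise creates spurious sign changes scattered symmetrically around
    # the true crossing; the median sign change is an unbiased choice
    j = idx[len(idx) // 2]
    di = i[j + 1] - i[j]
    if di == 0:
        return float(v[j])
    return float(v[j] - i[j] * (v[j + 1] - v[j]) / di)


def extract_vrev(sweep: RampSweep,
                 branch_tolerance_mV: float = 0.5) -> tuple[float, float, bool]:
    """Reversal potential of the positive and negative ramp branches.

    Returns (V_rev_positive, V_rev_negative, consistent); ``consistent`` is
    False when the branches disagree by more than ``branch_tolerance_mV``.
    """
    pos, neg = sweep.branches()
    vp = _zero_crossing(sweep.V_mV[pos], sweep.I_pA[pos])
    vn = _zero_crossing(sweep.V_mV[neg], sweep.I_pA[neg])
    return vp, vn, abs(vp - vn) <= branch_tolerance_mV


# ---------------------------------------------------------------------------
# V_stream from a ramp train
# ---------------------------------------------------------------------------

def compute_vstream(train: RampTrain,
                    junction: JunctionTable | None = None,
                    n_edge: int = 3,
                    recovery_tolerance_mV: float = 0.3) -> VStreamResult:
    """V_stream = V_rev(first hyper sweeps) - V_rev(last preceding iso
    sweeps), junction-corrected.

    ``n_edge`` sweeps on each side of the osmotic step are averaged.
    Recovery of the post-pulse baseline is checked against
    ``recovery_tolerance_mV`` and reported, not enforced.
    """
    junction = junction or JunctionTable()
    phases = train.phases()
    vrevs = [extract_vrev(s)[:2] for s in train.sweeps]
    means = [0.5 * (p + n) for p, n in vrevs]

    hyper_idx = [i for i, ph in enumerate(phases) if ph == HYPER]
    if not hyper_idx:
        raise ValueError("train contains no hyper-osmotic sweeps")
    first_h = hyper_idx[0]
    pre_iso = [i for i in range(first_h) if phases[i] == ISO]
    post_iso = [i for i in range(hyper_idx[-1] + 1, len(phases))
                if phases[i] == ISO]
    if not pre_iso:
        raise ValueError("no isotonic sweeps precede the osmotic pulse")

    base = float(np.mean([means[i] for i in pre_iso[-n_edge:]]))
    pulse = float(np.mean([means[i] for i in hyper_idx[:n_edge]]))
    raw = pulse - base

    sorb = train.sorbitol_M if train.sorbitol_M is not None else train.delta_osm
    if train.delta_osm == 0:
        jp = 0.0
    else:
        jp = junction.potential(train.K_mM, sorb)
    corrected = raw - jp

    recovered = True
    if post_iso:
        back = float(np.mean([means[i] for i in post_iso[:n_edge]]))
        recovered = abs(back - base) <= recovery_tolerance_mV

    return VStreamResult(K_mM=train.K_mM, delta_osm=train.delta_osm,
                         vrev_per_sweep=vrevs, phases=phases,
                         vstream_raw=raw, junction_mV=jp, vstream=corrected,
                         recovered=recovered)


# ---------------------------------------------------------------------------
# regression across osmolality levels and slope comparison
# ---------------------------------------------------------------------------

def regress_vstream(results: list[VStreamResult],
                    consts: PhysicalConstants = PhysicalConstants(),
                    fit_intercept: bool = True):
    """OLS of V_stream on delta-osmolality; returns (slope, SE, CR_wi).

    Needs at least two distinct osmolality levels; replicates are allowed.
    The slope is in mV per Osm/kg and is converted to the coupling ratio
    with the streaming-potential relation.
    """
    x = np.array([r.delta_osm for r in results], float)
    y = np.array([r.vstream for r in results], float)
    if len(np.unique(x)) < 2:
        raise ValueError("slope not identifiable from a single osmolality level")
    X = sm.add_constant(x) if fit_intercept else x[:, None]
    fit = sm.OLS(y, X).fit()
    slope = float(fit.params[-1])
    se = float(fit.bse[-1])
    return slope, se, slope_to_cr(slope, consts)


def compare_slopes(group_a: list[VStreamResult],
                   group_b: list[VStreamResult]):
    """Analysis of covariance on slope equality of two V_stream-dOsm lines.

    Returns (t statistic of the interaction term, p-value).  Identical
    groups give t = 0, p = 1 by symmetry of the null.
    """
    frames = []
    for label, grp in (("A", group_a), ("B", group_b)):
        for r in grp:
            frames.append({"dosm": r.delta_osm, "vstream": r.vstream,
                           "group": label})
    df = pd.DataFrame(frames)
    for label in ("A", "B"):
        if df[df.group == label]["dosm"].nunique() < 2:
            raise ValueError("slope not identifiable within a group")
    fit = smf.ols("vstream ~ dosm * group", data=df).fit()
    t = float(fit.tvalues["dosm:group[T.B]"])
    p = float(fit.pvalues["dosm:group[T.B]"])
    return t, p


# ---------------------------------------------------------------------------
# trace I/O: CSV per sweep + JSON schedule sidecar
# ---------------------------------------------------------------------------

def write_train(train: RampTrain, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(train.sweeps):
        pd.DataFrame({"time_s": s.t_s, "V_mV": s.V_mV, "I_pA": s.I_pA}).to_csv(
            directory / f"sweep_{i:02d}.csv", index=False)
    sidecar = {"K_mM": train.K_mM, "delta_osm": train.delta_osm,
               "sorbitol_M": train.sorbitol_M, "phases": train.phases(),
               "meta": train.meta}
    (directory / "schedule.json").write_text(json.dumps(sidecar, indent=1))


def read_train(directory: str | Path) -> RampTrain:
    directory = Path(directory)
    sidecar = json.loads((directory / "schedule.json").read_text())
    sweeps = []
    for i, phase in enumerate(sidecar["phases"]):
        df = pd.read_csv(directory / f"sweep_{i:02d}.csv")
        sweeps.append(RampSweep(df["time_s"].to_numpy(),
                                df["V_mV"].to_numpy(),
                                df["I_pA"].to_numpy(), phase=phase))
    return RampTrain(sweeps=sweeps, K_mM=sidecar["K_mM"],
                     delta_osm=sidecar["delta_osm"],
                     sorbitol_M=sidecar.get("sorbitol_M"),
                     meta=sidecar.get("meta", {}))
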