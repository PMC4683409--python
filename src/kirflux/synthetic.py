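"""Synthetic-data generators: every input the pipeline consumes.

The generators emulate the study designs: single-channel i-V curves at
symmetric [K+] between 15 and 300 mM, CR-[K+] points with Gaussian noise
at the magnitudes of the reported standard errors, and osmotic-pulse ramp
trains (6 isotonic + 6 hyper-osmotic + 6 isotonic sweeps, -20..+20 mV at
1 mV/ms) from which reversal-potential shifts are extracted.  All outputs
are pure functions of (spec, seed).

Ramp traces are sampled at 10 kHz with band-limited (1-kHz low-pass)
Gaussian current noise, matching the recording/filter rates of the
protocol; noise is independent between sweeps and there is no drift.  During the hyper-osmotic phase the
patch conductance is scaled up (sorbitol removal lowers the resistance of
the long cytoplasmic pore); the scaling leaves the zero crossing, and
hence V_rev, unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import Condition, PhysicalConstants
from .cycles import coupling_ratio, decompose, enumerate_cycles
from .diagram import PermeationDiagram, kir2p1_diagram
from .fitting import FitDataset
from .observables import predict_current, predict_vstream, coupling_ratio_curve
from .rates import RateEvaluator, RateParameterSet
from .vstream import HYPER, ISO, JunctionTable, RampSweep, RampTrain

#: per-[K+] standard errors of the reported coupling ratios (wild type /
#: mutant), used as generator noise magnitudes
CR_SE_WT = {15: 0.15, 50: 0.03, 150: 0.04}
CR_SE_MUT = {15: 0.07, 50: 0.04, 150: 0.15}


@dataclass
class GeneratorSpec:
    """Ground truth plus design of the synthetic experiments.

    Defaults follow the study conditions: symmetric [K+] in
    {15, 50, 150, 300} mM, voltages -100..+100 mV, osmotic steps
    {0.5, 1.0, 1.5} Osm/kg, 3-6 replicates.
    """

    truth: RateParameterSet
    seed: int
    K_mM: tuple[float, ...] = (15.0, 50.0, 150.0, 300.0)
    voltages_mV: tuple[float, ...] = tuple(range(-100, 101, 20))
    delta_osm: tuple[float, ...] = (0.5, 1.0, 1.5)
    cr_K_mM: tuple[float, ...] = (15.0, 50.0, 150.0)
    iv_noise_rel: float = 0.02      # relative SD of current points
    iv_noise_floor_pA: float = 0.02  # additive SD floor
    cr_se: dict[float, float] = field(default_factory=lambda: dict(CR_SE_WT))
    replicates: int = 4
    # ramp-train design
    n_sweeps: tuple[int, int, int] = (6, 6, 6)  # iso / hyper / iso
    ramp_mV: tuple[float, float] = (-20.0, 20.0)
    ramp_rate_mV_per_ms: float = 1.0
    sample_hz: float = 10000.0
    filter_hz: float = 1000.0
    patch_g_nS: float = 2.0
    trace_noise_pA: float = 0.5
    hyper_g_scale: float = 1.3
    cr_eval_mV: float = -1.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for stochastic output")
        if self.iv_noise_rel < 0 or self.trace_noise_pA < 0:
            raise ValueError("noise magnitudes must be non-negative")


def _truth_record(spec: GeneratorSpec) -> dict:
    return {"k0": dict(spec.truth.k0), "seed": spec.seed}


# ---------------------------------------------------------------------------
# i-V and CR datasets
# ---------------------------------------------------------------------------

def make_iv_dataset(spec: GeneratorSpec,
                    diagram: PermeationDiagram | None = None,
                    consts: PhysicalConstants = PhysicalConstants()) -> FitDataset:
    """Noisy single-channel i-V points on the model-predicted curves."""
    diagram = diagram or kir2p1_diagram()
    rng = np.random.default_rng(spec.seed)
    ev = RateEvaluator(diagram, spec.truth, consts)
    pts = []
    for k in spec.K_mM:
        for v in spec.voltages_mV:
            i = predict_current(diagram, spec.truth,
                                Condition.symmetric(v, k), consts, evaluator=ev)
            se = abs(i) * spec.iv_noise_rel + spec.iv_noise_floor_pA
            pts.append((float(v), float(k), i + rng.normal(0.0, se), se))
    return FitDataset(iv_points=pts, cr_points=[], provenance="synthetic",
                      truth=_truth_record(spec))


def make_cr_dataset(spec: GeneratorSpec,
                    diagram: PermeationDiagram | None = None,
                    consts: PhysicalConstants = PhysicalConstants()) -> FitDataset:
    """Noisy CR_wi-[K+] points from the model's cycle-flux decomposition."""
    diagram = diagram or kir2p1_diagram()
    rng = np.random.default_rng(spec.seed + 1)
    curve = coupling_ratio_curve(diagram, spec.truth, spec.cr_K_mM,
                                 V_eval_mV=spec.cr_eval_mV, consts=consts)
    pts = []
    for k, cr in curve:
        se = spec.cr_se.get(k, 0.05)
        # recorded SE keeps the dataset invariant (SE > 0) even for
        # noiseless generation
        pts.append((float(k), cr + rng.normal(0.0, se), max(se, 1e-12)))
    return FitDataset(iv_points=[], cr_points=pts, provenance="synthetic",
                      truth=_truth_record(spec))


def make_fit_dataset(spec: GeneratorSpec,
                     diagram: PermeationDiagram | None = None,
                     consts: PhysicalConstants = PhysicalConstants()) -> FitDataset:
    """Combined i-V + CR dataset (the optimiser's input)."""
    iv = make_iv_dataset(spec, diagram, consts)
    cr = make_cr_dataset(spec, diagram, consts)
    return FitDataset(iv_points=iv.iv_points, cr_points=cr.cr_points,
                      provenance="synthetic", truth=_truth_record(spec))


# ---------------------------------------------------------------------------
# osmotic-pulse ramp trains
# ---------------------------------------------------------------------------

def make_ramp_train(spec: GeneratorSpec, K_mM: float, delta_osm: float,
                    diagram: PermeationDiagram | None = None,
                    consts: PhysicalConstants = PhysicalConstants(),
                    junction: JunctionTable | None = None,
                    replicate: int = 0) -> RampTrain:
    """One synthetic osmotic-pulse ramp train.

    Isotonic sweeps reverse at 0 mV (symmetric [K+]); hyper-osmotic sweeps
    are shifted by the streaming potential of the truth coupling ratio
    plus the junction-table offset (which the analysis stage corrects
    away).  The measured raw V_rev therefore embeds exactly the artefacts
    the reduction pipeline is expected to remove.
    """
    diagram = diagram or kir2p1_diagram()
    junction = junction or JunctionTable()
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, int(K_mM * 1000),
                                int(delta_osm * 1000), replicate]))

    cr_truth = _truth_cr(spec, diagram, K_mM, consts)
    v_stream = predict_vstream(cr_truth, delta_osm, consts)
    jp = junction.potential(K_mM, delta_osm) if delta_osm else 0.0

    v0, v1 = spec.ramp_mV
    dt_ms = 1e3 / spec.sample_hz
    step = spec.ramp_rate_mV_per_ms * dt_ms
    up = np.arange(v0, v1 + step / 2, step)
    down = up[::-1][1:]
    v_ramp = np.concatenate([up, down])
    t = np.arange(len(v_ramp)) * dt_ms * 1e-3

    sweeps = []
    n_iso1, n_hyper, n_iso2 = spec.n_sweeps
    for phase, count in ((ISO, n_iso1), (HYPER, n_hyper), (ISO, n_iso2)):
        for _ in range(count):
            if phase == HYPER:
                vrev = v_stream + jp
                g = spec.patch_g_nS * spec.hyper_g_scale
            else:
                vrev = 0.0
                g = spec.patch_g_nS
            i = g * (v_ramp - vrev)  # nS * mV = pA
            i = i + _filtered_noise(rng, len(i), spec)
            sweeps.append(RampSweep(t.copy(), v_ramp.copy(), i, phase=phase))
    return RampTrain(sweeps=sweeps, K_mM=K_mM, delta_osm=delta_osm,
                     sorbitol_M=delta_osm if delta_osm else None,
                     meta={"cr_truth": cr_truth, "v_stream_truth": v_stream,
                           "junction_mV": jp, "seed": spec.seed,
                           "replicate": replicate})


def _filtered_noise(rng: np.random.Generator, n: int,
                    spec: GeneratorSpec) -> np.ndarray:
    """Band-limited recording noise: white noise low-pass filtered at
    ``filter_hz`` (boxcar), with SD ``trace_noise_pA`` after filtering."""
    if spec.trace_noise_pA == 0:
        return np.zeros(n)
    width = max(int(round(spec.sample_hz / spec.filter_hz)), 1)
    white = rng.normal(0.0, spec.trace_noise_pA * math.sqrt(width), n + width)
    kernel = np.full(width, 1.0 / width)
    return np.convolve(white, kernel, mode="valid")[:n]


def _truth_cr(spec: GeneratorSpec, diagram: PermeationDiagram, K_mM: float,
              consts: PhysicalConstants) -> float:
    dec = decompose(diagram, spec.truth,
                    Condition.symmetric(spec.cr_eval_mV, K_mM), consts,
                    records=enumerate_cycles(diagram))
    return coupling_ratio(dec)


def make_vstream_study(spec: GeneratorSpec, K_mM: float,
                       diagram: PermeationDiagram | None = None,
                       consts: PhysicalConstants = PhysicalConstants(),
                       junction: JunctionTable | None = None) -> list[RampTrain]:
    """Replicated trains over all osmotic steps at one [K+]."""
    diagram = diagram or kir2p1_diagram()
    out = []
    for dosm in spec.delta_osm:
        for rep in range(spec.replicates):
            out.append(make_ramp_train(spec, K_mM, dosm, diagram, consts,
                                       junction, replicate=rep))
    return out
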