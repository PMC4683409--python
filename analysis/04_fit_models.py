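#!/usr/bin/env python
"""Mutant model selection and direction-of-effect study.

Fits the mutant synthetic dataset with 4, 5 and 10 free rate constants
(the remaining rates fixed at wild-type values), compares the variants by
AIC, and reports whether the winning fit reproduces the wide-pore sign
pattern (k1 up, k2 down, k5 down, k7 down) and the inwardly rectifying
i-V.  Writes results/fits.json.
"""

import json
from pathlib import Path

from kirflux import (FitDataset, GeneratorSpec, RateParameterSet, fit,
                     kir2p1_diagram, make_fit_dataset,
                     qualitative_mutant_check, select_model)
from kirflux.fitting import FitResult

BASE = Path(__file__).resolve().parents[1] / "results"
SEED = 20240902


def main() -> None:
    diagram = kir2p1_diagram()
    wt = RateParameterSet.wild_type()
    mut = RateParameterSet.mutant()
    spec = GeneratorSpec(truth=mut, seed=SEED,
                         voltages_mV=(-100, -75, -50, -25, 25, 50, 75, 100))
    dataset = make_fit_dataset(spec, diagram)

    fits = []
    for variant, maxiter in (("mut4", 800), ("mut5", 800), ("mut10", 1600)):
        res = fit(diagram, dataset, wt, variant=variant, weights=(10.0,),
                  restarts=1, seed=SEED, maxiter=maxiter)
        fits.append(res)
        print(f"{variant:>6}: k = {res.n_free:2d}  SSE = {res.sse:9.2f}"
              f"  AIC = {res.aic:8.2f}")

    best = select_model(fits)
    print(f"\nAIC selects the {best.variant} model "
          f"({best.n_free} free rate constants)")

    wt_ref = FitResult(params=wt, objective=0.0, weight=1.0, n_free=10,
                       n_points=best.n_points, sse=0.0, lnL=0.0, aic=0.0,
                       variant="wt")
    report = qualitative_mutant_check(diagram, wt_ref, best)
    print("fitted direction of effects:", report["changes"])
    print(f"wide-pore K+ affinity (k1/k2): {report['wide_pore_affinity']}"
          " (binding and release rates are identified only through their"
          " ratio when the binding step equilibrates)")
    print("identifiable pattern (affinity up, k5 down, k7 down) reproduced:",
          report["matches_identifiable_pattern"])
    print(f"rectification index i(+100)/|i(-100)|: "
          f"wt {report['rectification_wt']:.2f}, "
          f"mutant {report['rectification_mut']:.2f}")

    BASE.mkdir(exist_ok=True)
    payload = {"fits": [f.summary() for f in fits],
               "selected": best.variant, "qualitative": report,
               "seed": SEED}
    (BASE / "fits.json").write_text(json.dumps(payload, indent=1))
    print(f"wrote {BASE / 'fits.json'}")


if __name__ == "__main__":
    main()
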