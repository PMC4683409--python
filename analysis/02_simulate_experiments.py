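#!/usr/bin/env python
"""Generate the synthetic experiment suite from the calibrated truths.

Emulates the three experimental designs with the wild-type-like and
mutant-like reference parameter sets: i-V curves at symmetric [K+],
CR-[K+] points, and osmotic-pulse ramp trains at 15/50/150 mM with
0.5/1.0/1.5 Osm/kg steps.  Everything is written under
results/synthetic/<variant>/.
"""

from pathlib import Path

from kirflux import (GeneratorSpec, RateParameterSet, make_fit_dataset,
                     make_vstream_study)
from kirflux.vstream import write_train

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
SEED = 20240901


def main() -> None:
    for variant, truth in (("wt", RateParameterSet.wild_type()),
                           ("mutant", RateParameterSet.mutant())):
        spec = GeneratorSpec(truth=truth, seed=SEED)
        base = OUT / variant
        ds = make_fit_dataset(spec)
        ds.to_csv(base / "dataset")
        n_tr = 0
        for k in (15.0, 50.0, 150.0):
            for train in make_vstream_study(spec, k):
                write_train(train, base / "traces" /
                            f"k{k:g}_dosm{train.delta_osm:g}_"
                            f"r{train.meta['replicate']}")
                n_tr += 1
        print(f"{variant}: {len(ds.iv_points)} i-V points, "
              f"{len(ds.cr_points)} CR points, {n_tr} ramp trains -> {base}")


if __name__ == "__main__":
    main()
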