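# kirflux

Permeation kinetics of the inward-rectifier potassium channel Kir2.1,
analysed with an eleven-state discrete-state Markov model and exact
cycle-flux algebra.

## The scientific problem

K⁺ ions and water molecules move in single file through the narrow
selectivity filter of a K⁺ channel, so every conduction pathway couples
ion flux to water flux with a fixed stoichiometry.  Measuring the
streaming potential V_stream — the shift of the reversal potential when
an osmotic gradient drives water through the open pore — therefore
reports the **water–ion coupling ratio** CR_w–i, the number of water
molecules co-transported per ion, and through it the ion occupancy of
the filter.  For Kir2.1, CR_w–i is near one at high symmetric [K⁺]
(alternating ion–water–ion–water file) and rises toward three as [K⁺]
falls (fewer ions in the file).  A charge-reversing mutation in the
cytoplasmic pore (the low-affinity polyamine site) raises CR_w–i at all
[K⁺] and converts the single-channel i–V into a strongly inward
rectifier — evidence that the cytoplasmic pore controls the permeation
mode inside the selectivity filter.

This package implements the full analysis chain for that study design:

* **diagram** – an eleven-state permeation model: four filter sites
  (ion/water, no adjacent ions, never ion-empty → 7 configurations) plus
  a lumped wide-pore K⁺ site (doubling minus three excluded states).
  The topology ships as an auditable text model file with 34 directed
  rates, voltage dependence k(V) = k⁰·exp(zFV/RT), and dependent rates
  (e.g. k32) closed by thermodynamic reversibility.
* **cycle flux** – exact steady state and decomposition of the net flux
  onto the 59 simple cycles (matrix-tree / spanning-forest weights; 39
  cycles conduct).  Each cycle has a fixed cyclic coupling ratio
  (cycle a: 1 water/ion, c: 2, d and e: 3), and
  CR_w–i = Σ (J_i/J_total)·ccr_i.
* **observables** – single-channel currents and chord conductance,
  streaming potentials V_stream = −CR·v_w·Δπ/(zF), slope↔CR conversion,
  Michaelis–Menten conductance fits, per-cycle conductance surfaces.
* **vstream pipeline** – reversal potentials from ±20 mV ramp trains,
  junction-potential correction, V_stream–ΔOsm regression, ANCOVA slope
  comparison between channels.
* **fitting** – weighted Nelder–Mead optimisation of the ten rate
  constants against i–V and CR–[K⁺] data; mutant variants with 4/5/10
  free rates and AIC model selection.
* **synthetic data** – seeded generators for every input (i–V points,
  CR points, osmotic-pulse ramp trains) from calibrated ground-truth
  parameter sets, so the whole chain is testable end-to-end.

## Worked example

```python
from kirflux import (Condition, RateParameterSet, coupling_ratio,
                     decompose, kir2p1_diagram, predict_current,
                     slope_to_cr, validate_structure)

diagram = kir2p1_diagram()
print(validate_structure(diagram).as_dict())
# {'states': 11, 'directed_rates': 34, 'undirected_transitions': 17,
#  'simple_cycles': 59, 'conducting_cycles': 39}

wt = RateParameterSet.wild_type()
i = predict_current(diagram, wt, Condition.symmetric(-100, 150))
print(f"{i:.2f} pA")                      # -2.82 pA  (chord ~28 pS)

dec = decompose(diagram, wt, Condition.symmetric(-1.0, 150))
print(f"{coupling_ratio(dec):.2f}")       # 1.41 waters per ion at 150 mM

print(f"{slope_to_cr(-0.63):.3f}")        # 1.371 — CR from the measured
                                          # V_stream slope at 150 mM
```

The first call checks the diagram transcription (eleven states, 34
rates, 59 cycles, 39 of which conduct).  The current call evaluates the
exact steady state at −100 mV, symmetric 150 mM K⁺.  The decomposition
splits that flux over the cycles; its flux-weighted coupling ratio near
the reversal potential is the quantity the streaming-potential
experiment measures, and `slope_to_cr` converts a measured
V_stream-vs-osmolality slope (mV per Osm/kg) into the same ratio.

Numbered drivers under `analysis/` run the full study on synthetic
data: `01_validate_diagram.py` (structure), `02_simulate_experiments.py`
(datasets and ramp trains), `03_streaming_potentials.py` (V_stream
reduction and ANCOVA), `04_fit_models.py` (mutant AIC selection and the
direction-of-effect report), `05_cycle_contributions.py` (per-cycle
conductance surfaces).  Outputs land in `results/`.  A thin CLI wraps
the same stages: `kirflux validate | simulate | analyze | fit |
decompose | report`.

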