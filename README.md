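# gutstem

Quantitative toolkit for stem-cell dynamics and morphometry of the killifish
(*Nothobranchius furzeri*) intestinal epithelium.

The killifish gut has no crypts: cycling cells sit in interfold regions
(IFRs) at the base of mucosal folds and differentiated cells ride the fold
flanks like conveyor belts until they are shed at the apex.  Slow-cycling
intestinal stem cells (ISCs) are detected as label-retaining cells with a
dual-pulse protocol — BrdU twice 2 h apart, a 6-day chase, one EdU pulse,
harvest a day later — because every division halves the incorporated label:
fast-cycling progenitors dilute BrdU away while ISCs keep it.  This package
implements the full analysis stack around that experiment, plus the
biomechanical and growth measurements that frame it:

* **`gutstem.simulate`** — an agent-based forward simulator of fold/IFR
  turnover with pulse labeling, label dilution, conveyor migration and apical
  apoptosis, emitting digitized "section tables" (ordered per-cell
  DAPI/BrdU/EdU/PCNA records) and an event log.
* **`gutstem.labels`** — the four-way BrdU/EdU cell classification
  (BrdU-only = quiescent ISC, double = cycling ISC, EdU-only = cycling
  non-LRC), ISC cluster calling under the gap rule (two or more ISC-class
  cells separated by at most 10 intervening DAPI nuclei), cluster-size
  statistics and zone-occupancy profiles.
* **`gutstem.cycle`** — ISC cycle-time estimation: the dual-label closed form
  Ts = Ti·S/L, Tc = Ti·P/L for short-interval designs, and a simulation-based
  grid inversion (with bootstrap SE) for the 6-day chase where the closed
  form is invalid.
* **`gutstem.brillouin`** — Brillouin light-scattering spectra: synthesis and
  nonlinear least-squares fitting of the Stokes/anti-Stokes Lorentzian
  doublet with a Rayleigh tail, and the mechanical loss tangent
  tan δ = Γb/νb with regional comparisons.
* **`gutstem.growth`** — von Bertalanffy growth fits
  L(t) = L∞(1 − e^(−k(t−t0))), the adult→old gut/body decoupling test,
  mucosal surface area π·d·l·M, and the statistical battery
  (KS normality gate, ANOVA+Tukey, Kruskal–Wallis+Dunn, paired/Welch t).
* **`gutstem.io` / `gutstem.pipeline` / `gutstem.cli`** — TSV/JSON dialects
  with validating readers, an end-to-end seeded pipeline with a run manifest,
  and the `gutstem` command-line interface.

See `docs/methods.md` for the model, its assumptions, and every default.

## Worked example

Simulate an adult-like and an old-like cohort, run the whole pipeline, and
compare ISC cycle times:

```bash
gutstem run-all --seed 5 --out results/demo
```

which prints (numbers from this exact command):

```
adult: Tc = 52.8 h (SE 2.1 h), 117 clusters
old: Tc = 93.7 h (SE 10.5 h), 246 clusters
```

Each cohort is three simulated animals drawn with inter-individual
cycle-time variability around the scenario means of 54 h (adult) and 76 h
(old); `Tc` is the ISC total cycle time recovered by grid inversion of the
label-class fractions, `SE` the bootstrap-over-sections standard error, and
the cluster counts are ISC clusters called under the ≤10-nuclei gap rule.
The adult estimate sits on its truth; this particular old cohort drew
slow-cycling animals and lands high, which its five-fold larger SE
advertises — the aging signal (old slower than adult) is the robust
readout, recovered in ≥95% of seeded cohort pairs in the test suite.
`results/demo/summary.json` holds the per-cohort class counts, cluster-size
means, zone profiles and both cycle-time estimates; `manifest.json` records
the config, seed and output digests so the run can be reproduced
byte-for-byte.

The same stages are available individually (`gutstem simulate`, `classify`,
`clusters`, `profile`, `cycletime`, `brillouin synth|fit|compare`,
`growth fit|decouple|area`), and everything is importable as a library:

```python
from gutstem import SimConfig, simulate, render_sections, classify, call_clusters

res = simulate(SimConfig(tc_isc=54.0), seed=1)
table = render_sections(res, n_sections=3, units_per_section=5, seed=1)
calls = call_clusters(classify(table))
print(calls[["unit_id", "first_index", "last_index", "isc_count"]].head())
```

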