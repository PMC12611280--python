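# Methods

## The system being modelled

The killifish (*Nothobranchius furzeri*) intestinal mucosa has no crypts.  It
is organised in fold units: a proliferative interfold region (IFR) at the base
of each fold — the functional analogue of the mammalian crypt — and two fold
flanks that behave as conveyor belts.  Cycling cells (PCNA-positive) are
confined to the IFR; differentiated, senescent cells cover the flanks and are
shed by apoptosis at the fold apex.  Slow-cycling intestinal stem cells (ISCs)
intermingle with fast-cycling transient-amplifying (TA) progenitors inside the
IFR.

The central experiment the package reproduces computationally is dual-pulse
label-retention: BrdU is injected twice 2 h apart, a 6-day chase follows, EdU
is injected, and tissue is harvested one day later (BrdU windows at 0 h and
2 h, EdU at 146 h, harvest at 170 h).  Cells in S phase during a pulse window
incorporate that label fully; every division halves both label contents.
Fast-cycling TA cells dilute BrdU below detectability during the chase while
slow-cycling ISCs retain it, so at harvest BrdU-only cells are read as
quiescent ISCs, BrdU+EdU cells as cycling ISCs, EdU-only cells as cycling
non-LRCs, and the rest as unlabeled.

## The turnover simulator (`gutstem.simulate`)

Fixed-timestep (0.5 h) agent simulation.  Each cell carries a unit id, a
position (−1 = IFR pool; 0..n_fold−1 along one of two flanks), a state (ISC,
TA, differentiated), a cycle phase with a Gamma-distributed duration
(CV 0.15 per phase; G1 takes 70% and G2/M 30% of the non-S remainder of the
cycle; S takes `ts_frac` = 0.3 of the cycle), label contents in [0, 1], and a
division counter.

Rules per step:

* Cycling cells (always in the IFR pool) advance their phase clock.  A cell
  whose S phase overlaps a pulse window (step-quantised; windows of the same
  analogue merge) sets that label content to 1.
* At division both products carry half the mother's label contents.  ISCs
  divide asymmetrically by default (ISC → ISC + TA), keeping the ISC count
  per IFR constant; a symmetric-expansion probability is available.
* A TA cell that has completed `d_max` = 4 divisions differentiates, leaves
  the pool, and is pushed onto a randomly chosen flank at position 0; every
  push shifts the column apically, and a cell pushed past the apex is removed
  as apoptotic.  Divisions, differentiations and apoptoses are logged.
* Burn-in of 10 TA cycle times before the schedule's t = 0 establishes
  steady-state conveyor occupancy.

Default geometry: 20 fold units, 24 initial IFR cells of which 5 are ISCs,
45 positions per flank.  At the adult parameters the steady-state IFR pool is
~38 cells (5 ISCs + ~33 TAs) and each flank turns over in ~60 h (adult) to
~85 h (old, through the reduced differentiation influx alone).

Key kinetic parameters (hours unless noted): `tc_isc` 54 (adult) / 76 (old) /
40 (adolescent) — the age scenarios differ only in this value; `tc_ta` 24;
`pulse_window` 1 (analogue bioavailability per injection; the protocol does
not state one); `dilution_threshold` 1/16 — a label is scored positive while
its content is ≥ 1/16, i.e. retained through four halvings and lost at five.
With `d_max` = 4 a directly-labeled TA founder's descendants end at exactly
the detection boundary while the descendants of a labeled ISC's daughter
(one extra halving) fall below it, which is what makes TA lineages lose BrdU
during the chase while ISCs keep it.

Animals within a cohort are not clones: `simulate_cohort` draws one lognormal
multiplier per animal (CV `cv_between_animal` = 0.15) applied to both cycle
times, emulating inter-individual variation in turnover rate of the magnitude
that published cycle-time estimates display between animals.

Section rendering mimics scoring a stained section: per observed unit the IFR
pool is emitted first in randomised order (the pool has no modelled internal
geometry), then the two flanks base-to-apex; zones are IFR, lower/upper fold
half, with the top 10% of positions tagged APEX.  In cluster studies each
section observes 5 units at 60 cells per unit (roughly half of a unit's ~130
cells), standing in for the partial sampling of a thin physical section, and
the cluster-size comparison scores one section per animal — the study's
actual per-animal histology workload, with serial sections as the control;
cycle-time experiments observe every IFR cell, since they characterise
estimator error rather than a histology workflow.

What the generator does not emulate: 2-D/3-D tissue geometry and mechanics,
niche signalling, secretory lineages, staining artefacts, or segmentation
error.  Passing tests therefore validate the quantitative machinery under the
stated turnover model, not the image-analysis steps upstream of it.

## Cluster calling and positional statistics (`gutstem.labels`)

An ISC cluster is two or more ISC-class cells in which consecutive members
are separated by at most `max_gap` = 10 intervening DAPI-positive nuclei;
"no more than 10" is read inclusively (a gap of exactly 10 still joins).
Clusters are called by a single left-to-right chain pass per fold unit and
never span unit boundaries (IFRs are anatomically separate); unordered input
is an error rather than being silently sorted.  Two cluster-size readouts are
reported side by side, because both circulate in the literature: the span
(all DAPI cells from first to last member) and the double-positive member
count, alongside the ISC member count.  A cluster's zone is that of its
centroid member (the open choice documented here; any-member or first-member
definitions change little).  Group comparisons summarise per animal first,
then test between groups — paired two-tailed t-test when a paired design is
requested or the animal sets coincide, Welch's t otherwise.

## Cycle-time estimation (`gutstem.cycle`)

**Closed form.**  With every evaluated cell proliferating (true of the IFR),
P evaluated cells, S second-pulse-labeled cells, L first-pulse-only cells and
inter-pulse interval Ti:

    Ts = Ti · S / L        Tc = Ts · P / S = Ti · P / L

This is the standard dual-label scheme and is valid only while Ti is short
relative to Ts; the estimator emits a validity flag when the leaving fraction
D/(D+L) exceeds 0.5.  Under the 6-day label-retention schedule the closed
form is structurally invalid (nearly all first-pulse cells have left S), so:

**Simulation-based inversion.**  Forward-simulate the epithelium over a grid
of candidate ISC cycle times (default 24–150 h in 2 h steps), with TA cycle
time, S-phase fraction, phase CV and dilution threshold fixed at template
values, and compare the simulated (BrdU-only, double, EdU-only) fraction
vector among IFR cells with the observed one by inverse-variance-weighted
squared distance — the component variances are estimated from
section-to-section scatter, because label-class fractions of sibling cells
are correlated (lineages differentiate in bursts) and the components are far
from equally noisy.  The minimiser is refined by quadratic interpolation
over the three grid points around the minimum.  A flat objective (relative
range < 1%) flags the estimate unreliable.  The SE is the SD of the
estimator over bootstrap resamples of sections (default 200); a bagged point
estimate (median of the bootstrap-replicate minimisers) is available for
multimodal objectives.

Numerical choices that matter.  With one replicate per grid point the
simulations share a seed (common random numbers), so a reference curve
computed with the same seed and template reproduces the observed fractions
exactly at an on-grid truth (the self-consistency check).  For cohort
estimation the reference averages several independent replicates per grid
point (default 4 in the frozen study designs) rather than smoothing along
the grid: the curve is genuinely non-smooth — cohorts near Tc = 73 h show a
phase-locking resonance where first-pulse-labeled ISCs re-enter S at the
second pulse — and grid-smoothing flattens that structure.  A reference
curve may be reused across cohorts that share the template, which is
ordinary reference-table practice in simulation-based inference.

**Identifiable range.**  The design cannot distinguish slow cycling near
126 h from 54 h: labeling probability (S-phase coverage of the pulse) and
label retention (divisions during the chase) nearly cancel, leaving only the
TA-pool share of the IFR — the noisiest component — to separate them.
Cohort-level estimates are therefore computed over 24–120 h
(`studies.IDENTIFIABLE_MAX_TC`); the full default grid remains available,
with the estimator's flags and bootstrap SE exposing the ambiguity when a
cohort straddles the two basins.

`bootstrap_se` for per-section estimates multiplies the SD of resampled means
by √(n/(n−1)); the corrected value converges to the classical s/√n (for two
sections {a, b}: |a−b|/2).

Validated behaviour (recomputed by the test suite): median absolute relative
error of the inverted cycle time below 10% at truths of 40–100 h under the
30-section design, and correct adult/old ordering in ≥95% of cohort pairs
when the old cycle time is 1.4× the adult one.

## Brillouin spectra (`gutstem.brillouin`)

Spectra are 512 channels mapped linearly over a 24 GHz span with the centre
channel at 0 GHz.  The model is a Stokes/anti-Stokes pair of FWHM-
parameterised Lorentzians sharing shift νb, width Γb and amplitude (physical
symmetry halves the parameter count), an exponential Rayleigh tail
B·exp(−|f|/τ), and a flat offset.  Fitting is nonlinear least squares; the
Rayleigh tail is pre-estimated from two near-centre bands and the shift is
seeded from the highest-prominence local maximum outside a ±1.5 GHz central
exclusion window, so a strong elastic tail cannot masquerade as the doublet.
Non-convergence is reported, never silently replaced.  The readout of
comparative interest is the mechanical loss tangent tan δ = Γb/νb, which is
independent of density and refractive index (neither is known for gut
tissue) and invariant to count scaling by construction.  Regional comparisons
(anterior bulb AI vs middle MI vs posterior PI) average spectra per animal
and use paired two-tailed t-tests.

## Growth and morphometry (`gutstem.growth`)

Body and gut lengths follow the von Bertalanffy growth function
L(t) = L∞(1 − e^(−k(t−t0))), fitted by least squares with L∞ initialised at
1.1× the largest observation and k from a log-linearised regression.
Adult→old decoupling is declared when body length change is non-negative
while the gut measure decreases significantly (Welch two-tailed t, α = 0.05).
Mucosal surface area is the smooth cylinder times the fold amplification
factor: area = π·d·l·M, with M a user input (≥1; smaller values warn).

The statistical battery mirrors the study's protocol: Kolmogorov–Smirnov
normality pre-check against a fitted normal (Lilliefors) branching to
one-way ANOVA + Tukey HSD (normal) or Kruskal–Wallis + Dunn's post-hoc
(non-normal; rank z-statistics with tie correction, Bonferroni-adjusted —
implemented here because no installed package provides Dunn's test), plus
paired and Welch t-tests.

## Problem sizes and design choices

Validation experiments use deliberately moderate sizes chosen to give stable
statistics on a single CPU: recovery cohorts of 3 animals × 30 fold units
(30 sections × ~110 IFR cells), paired-comparison cohorts of one
fully-observed animal × 60 units, cluster-study cohorts of 3 animals × 15
units, 100 replicates for rate-based checks, and a 64-point inversion grid.
The measured cycle times of the study (54 h adult, 76.6 h old) are used as
the scenario parameters; the published point estimates themselves cannot be
recomputed without the original section images, so validation rests on
parameter recovery and on reproducing the direction and null results of the
age comparisons on synthetic data.

## Known limitations

* The IFR is a well-mixed pool; intra-IFR geometry and any spatial structure
  of ISC niches are not modelled, so cluster statistics inside the IFR
  reflect random mixing plus the gap rule.
* Label-retaining cells appear on folds only through slowly-shed differentiated
  cells; the old scenario retains more of them (the modelled basis of the
  positional shift), and a residual old-vs-adult difference of about one ISC
  per cluster remains an intrinsic property of dilution-based retention
  models — the cluster-size null holds under the study's paired test design,
  not as an exact equality.
* The closed-form estimator is reported for the 6-day schedule only with its
  validity flag set; the inversion estimator is the method of record there.
* Nuisance parameters are fixed during inversion; misspecified TA kinetics
  bias the estimate (the reference-curve template should match the cohort's
  assumed TA cycle time).
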