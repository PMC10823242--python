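# Methods

## Model structure and assumptions

The package models vernalization-induced silencing of *FLC* as two
pathways acting in parallel on a population of alleles.

**Allele states.** Each allele is non-nucleated (U), H3K27me3-nucleated
(N) or spread (S). Because the measured quantities (ChIP enrichment,
RNA) are population averages over many cells, the digital per-allele
switch is represented by deterministic fractions f_U, f_N, f_S rather
than a stochastic per-allele simulation; f_U + f_N + f_S = 1 is
preserved exactly by construction of the flux terms and is verified to
integrator tolerance at run time. Switching is irreversible
(U → N → S), encoding the stability of the Polycomb silenced state over
the timescales modelled.

**Nucleation.** U → N proceeds at k_nuc0 · V · η(T) inside cold. V is a
cold-memory factor standing in for slow VIN3-like accumulation,
modelled as a saturating first-order ramp (fixed point 1 in cold) with
fast decay (v_decay = 10/day) on return to warmth. The saturating form,
rather than an unbounded linear ramp, gives the constant-cold regime a
well-defined plateau in which f_U decays as a single exponential — the
closed form used by the tests. η(T) = exp(−((T − 5 °C)/15 °C)²) is a
broad temperature-efficiency optimum: nucleation is most efficient near
constant-cold temperature and somewhat weaker at the extremes of the
strongly fluctuating regime. Its width is deliberately large so that
H3K27me3 accumulation differs only mildly (≲ 15 %) between CC, FM and
FS — with the FS deficit retained as a known, documented property of
the model that the experiments did not reproduce.

**Spreading.** N → S proceeds at k_spread · g(t), where g is relative
cell-cycle activity: g_warm = 1, g_cold = 0.1. Spreading therefore
happens mostly during post-cold growth, converting essentially all
nucleated alleles to the spread state within ~2–3 weeks
(k_spread = 0.2/day), while still allowing slow conversion in cold.

**Transcription and antisense repression.** Per-state transcription
rates β_U = 10, β_N = 3, β_S = 0.3 events/day implement the graded
hierarchy (active ≫ nucleated ≫ spread). The antisense pathway enters
implicitly as a repression factor r(t) multiplying initiation in U and
N only — the spread state is treated as already maximally repressed by
chromatin. r combines:

* a slow component a_slow, first-order relaxation toward a_slow_max
  = 0.7 at k_on = 0.25/day below T_cold = 15 °C, decaying at
  k_off = 1/day above it (T_cold must exceed every cold-regime
  temperature, including the 12 °C FS daytime, or the slow component
  would see-saw in FS);
* a fast step a_fast = 0.25 below freezing (T_fast = 0 °C); and
* a graded term a_grad · exp(−T/T_scale) (a_grad = 0.15, T_scale =
  3 °C) active below 15 °C. The exponential (Arrhenius-like) shape is
  the one convex temperature dependence that lets repression both
  oscillate with the daily cycle in regimes that never reach freezing
  and preserve the ordering of daily means, FS ≤ FM ≤ CC, that a linear
  dependence would invert (the FM daily mean temperature exceeds CC's).

Repression combines additively and clamps to [0, 1]; during FS freezing
nights r reaches 0 (full transcriptional shutdown). COOLAIR-defective
lines pin r = 1; constitutive (ntl8-D3-like) lines pin a_slow at its
maximum in all temperatures while leaving nucleation cold-gated.

**Histone marks.** H3K36me3 is deposited per transcription event
(α36 = 0.02/event in both regions) with a Pol II dwell-time multiplier
1 + δ·φ(T), δ = 1.2, where φ ramps linearly from 0 at 12 °C to 1 at
0 °C: slower elongation in cold widens the window for cotranscriptional
deposition. The 12 °C onset places the FS daytime segment outside the
slowdown, which is what lets two weeks of FS remove nearly as much
nucleation-region H3K36me3 as six weeks of CC. Removal is first-order
at γ36 = 0.2/day (≈ 3.5-day half-life, within reported H3K36
methylation lifetimes). Deposition is limited by free capacity
(cap − K36 − K27)₊ with cap = 1.3 > 1, implementing partial coexistence
of the two marks on a nucleosome: a nucleated region carrying K27 = 0.9
can still hold up to 0.4 of K36. H3K27me3 relaxes quickly
(k27_relax = 5/day) to per-state targets — U: (0, 0); N: (0.9, 0);
S: (0.9, 0.9) for (nucleation region, gene body).

**mRNA.** A single unspliced-proxy pool with production Σ f·τ and decay
λ_m = 2/day. Spliced-RNA stability effects are deliberately out of
scope.

**Initial condition.** The pre-cold equilibrium has V = 0, a_slow = 0,
fractions (1 − f_N0 − f_S0, f_N0, f_S0) with f_N0 = 0.05, f_S0 = 0, and
marks/mRNA at their warm fixed points (closed-form balance of
deposition and removal). f_N0 is the fraction of alleles already
Polycomb-silenced before cold; keeping it small is what makes the
H3K27me3 fold change on vernalization much larger than the H3K36me3
fold change. COOLAIR-defective lines start from 0.4 × f_N0, encoding
their lower pre-cold H3K27me3.

## Temperature schedules

Time is in days; within-day profiles are parameterized in hours.
Protocol presets place a cold phase (CC: constant 5 °C; FM: 3–9 °C
cycle; FS: −1–12 °C cycle) between constant-22 °C warm phases (14 d
pre-cold, 28 d post-cold by default). Phase intervals are half-open, so
temperature is single-valued at boundaries. Square-wave cycles spend
the night fraction of each day at the minimum; the canonical protocol
uses 0.625 (15 h night / 9 h day), a late-autumn photoperiod — the
actual cabinet dwell fractions are not published, so this is a package
calibration choice, made once alongside the dwell-onset temperature so
that the default simulations reproduce the full set of reported
qualitative signatures simultaneously. Timepoint labels follow the
field convention: NV (end of pre-cold), kWT0 (after k weeks of cold),
kWTm (m days post-cold).

## Numerical integration

LSODA (stiff-capable, adaptive; rtol 1e-8, atol 1e-10) restarted at
every temperature discontinuity — phase boundaries and square-wave
edges — so the solver never steps across a jump in the forcing;
sinusoid segments additionally cap the step at period/8. Agreement with
a dt = 1e-4 d fixed-step Euler integration is verified to < 1e-3
relative error on a discontinuity-rich test schedule. Conservation of
allele fractions is checked (tolerance 1e-6) on every simulate call.

## Synthetic data generator

`generate_dataset` emulates ChIP-qPCR-style relative-enrichment time
courses: for each (genotype, condition, quantity, region, timepoint)
cell it draws n_reps = 3 replicates as mean-one lognormal multiplicative
perturbations (default cv = 0.25; the paper-style figures show roughly
this replicate scatter) of the noiseless population-averaged
observable, at the standard grid NV, 2WT0, 6WT0, 6WT10, 6WT20.
Replicate substreams are derived by SHA-256 hashing of the master seed
plus the cell coordinates, so extending a dataset never perturbs
existing draws. What the generator does **not** emulate: ChIP
efficiency and input-normalization mechanics, primer-level spatial
structure within a region, between-batch effects, or replicate
correlation — so passing recovery tests demonstrate identifiability
under idealized multiplicative noise, not robustness to the systematic
errors of real ChIP data.

## Fitting

Weighted least squares on replicate means; weights 1/SEM² (cells with
≥ 2 replicates; SEM floored at 2 % of the cell mean to avoid infinite
weights), a per-(quantity, region) scale factor profiled in closed form
before the nonlinear step (ChIP units are arbitrary, so only curve
shape informs the parameters), and bounded L-BFGS-B on a unit box from
multiple reproducible uniform starts. Multi-start local optimization was
chosen over MCMC because the aim is qualitative capture and parameter
recovery, not posterior inference; the spread of per-start optima near
the best loss is reported as a stability diagnostic, not a confidence
interval. Simulation failures during optimization return a penalty
value (1e12) instead of raising. The transcription hierarchy
β_U > β_N > β_S is preserved under fitting either by validation
(invalid candidates are penalized) or structurally via the virtual
ratio parameters `beta_N_frac`, `beta_S_frac` ∈ (0, 1).

The default recovery experiment (2 genotypes × CC, 5 timepoints, 3
replicates, cv = 0.1, 3 free parameters, 10 starts) runs in about two
minutes on one core; problem sizes in the tests (3-week schedules,
1–2 free parameters, few starts) were chosen to keep individual checks
in the seconds range.

## Design choices where the substance was open

* Additive-with-clamp combination of slow and fast antisense
  components (the alternative, multiplicative combination, cannot reach
  full shutdown while the slow component is sub-maximal).
* The slow antisense component is a first-order accumulator; only the
  existence of a slower-timescale increase is established, not its
  functional form.
* Pol II slowdown applies to both regions by default
  (`dwell_body_enabled`); per-region disabling is available since the
  observation motivating it is 5′-biased.
* K27 relaxation is fast but finite (5/day) rather than instantaneous,
  keeping the system a plain ODE.
* Post-cold antisense relaxation k_off = 1/day: unconstrained by the
  data modelled here; chosen fast so post-cold behaviour is dominated
  by the chromatin pathway.
* ntl8-D3 is constitutive antisense only — ectopic VIN3 does not
  nucleate in the model, matching the absence of warm H3K27me3 gain.

## Known limitations

* No nucleosome-resolution spreading, no explicit VIN3/VRN5/NTL8
  protein dynamics, no COOLAIR RNA variable or isoform structure, no
  gene-loop variable: these enter only through their effective
  parameters.
* The model intentionally predicts weaker H3K27me3 nucleation under FS
  than CC (via η(T)); the experimental data showed no difference. The
  package asserts this as a model property, not as a data property.
* Default parameters are a calibration that reproduces the reported
  qualitative signatures; none is a measured constant, and quantitative
  conclusions should be drawn only after fitting to real data.
* The deterministic-fraction formulation cannot represent cell-to-cell
  variability or allele-autonomous bistability beyond its mean-field
  consequences.
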