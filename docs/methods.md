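# Methods

This note documents the models implemented in `pdarkit`, the defaults and
numerical choices behind them, what the synthetic generators do and do not
emulate, and the design decisions taken where the problem left them open.

## Death metrics and signal-to-count conversion

Lethal fraction (LF), fractional viability (FV), relative viability (RV) and
the growth-rate metric (GR) are computed directly from live/dead counts.
Counts are real-valued throughout — they derive from fluorescence, not from
counting discrete cells. Zero-denominator metrics (empty population for
LF/FV, untreated count of zero for RV, untreated population static at T0 for
GR) are returned as NaN and propagate through every downstream table; they
are never silently dropped. Hard precondition violations (negative counts;
non-positive counts for GR, whose log-ratio form requires them) raise
`ValueError` instead.

Plate-reader assays measure a dead-cell fluorescence signal plus two lysis
anchors: a total-cell count at T0 (parallel lysed plate) and at endpoint.
Dead counts are the signal scaled by `total_end / lysed_signal_end`. The
total population at interior times is not measured; it is interpolated
**geometrically** (log-linearly) between the two anchors, consistent with
exponential growth, which is the package's own choice — linear interpolation
is available via `interpolation="linear"`. The conversion is exact at both
anchors and invariant to rescaling all fluorescence values by a common
factor. If the dead count ever exceeds the interpolated total, live counts
are clamped at zero and a warning is emitted rather than failing the run.

## LED death kinetics

LF kinetics are fit to the lag-exponential death curve
`LF(t) = LF0 + (LFP − LF0)(1 − e^(−DR(t−DO)))` for `t ≥ DO`. Before onset
the curve is held **constant at LF0**: evaluating the raw formula at
`t < DO` would dip below the baseline, contradicting the lag
interpretation. The fit is bounded least squares (`scipy.optimize.
least_squares`) with `0 ≤ LF0 ≤ LFP ≤ 1` (enforced by parameterizing the
rise `LFP − LF0 ≥ 0`), `DR ∈ (10⁻⁶, 50] /h`, `DO ∈ [0, t_max]`. Because DO
makes the objective multi-modal, the fit is multi-started: onset candidates
are the three observed times of steepest finite-difference LF slope plus the
quartiles of the time window; DR is seeded from the steepest slope divided
by the observed rise. The lowest SSE wins; ties break to the smallest DO.
Tolerances are 1e-8 on parameters and cost, capped at 10⁴ function
evaluations.

Derived quantities:

* **LF50** — earliest time at which LF reaches half its maximum observed
  value, where "maximum observed" is the larger of the measured maximum and
  the fitted curve evaluated at the horizon (default 72 h, or the last
  observation if later). Located by bisection to 1e-6 h. Missing when the
  curve never rises above baseline.
* **AUC** — the analytic integral
  `LF0·T + (LFP−LF0)[(T−DO) − (1−e^(−DR(T−DO)))/DR]` for `T > DO`, else
  `LF0·T`. The integration window is a per-dataset choice; the drivers
  default to the last shared timepoint (72 h in the synthetic panels).

## GRADE

The forward model treats the death fraction DR as the fraction of the total
population `C0·2^(t/τ)` that is dead at assay end. FV therefore depends only
on DR (`FV = 1 − DR` exactly), while GR carries the proliferation
information; the grid lookup effectively reads DR off FV and τ off GR. The
default grid is 500 × 500 with τ log-spaced on [8, 200] h and DR linear on
[0, 0.999]; the ranges and spacing are package choices (only the grid size
is prescribed by the method). Matching minimizes Euclidean distance after
dividing each axis by its grid range, since GR spans ≈ [−1, 1] while FV
spans [0, 1]. Ties break deterministically to the smallest DR index, then
the smallest τ index. The untreated doubling time is a required input; GR
inside the grid uses the same C0 and t as the observation's assay.
Continuous optimization over (τ, DR) is deliberately out of scope — the
method is defined as a lookup over simulated pairs.

## PDS score

Per genotype, the LED AUC of the treated condition minus the untreated
same-genotype AUC removes baseline death. Negative differences are floored
at 0 and flagged (`negative-baseline`): in score space a treated well cannot
be less dead than untreated. Knockout dependencies `1 − AUC_KO/AUC_WT` are
**not** clamped — sensitization (KO dies more) yields a negative
contribution, flagged `sensitization`. WT AUCs ≤ 10⁻⁶ are non-scorable.

The lethality gate is `max observed LF ≥ 0.16` (strict `< 0.16` is
non-lethal), roughly double untreated background death; the apoptotic call
is a ≥ 50% (inclusive) reduction of max LF in the BAX/BAK DKO versus WT.
Scores are normalized by the raw score of the reference condition — default
triptolide at 1 μM — computed on the same dataset, so `PDS(reference) = 1`
identically and all scores are invariant to rescaling every AUC by a common
factor. The reference is configurable; a dataset lacking it requires an
explicit `reference_raw`.

## PD-like classifier

Coordinates are the three KO/WT ratios of baseline-subtracted AUCs;
non-lethal pairs and pairs with vanishing WT AUC are excluded before
classification. The neighborhood statistic is the mean pairwise Euclidean
distance among member points (lethal doses of the validated degraders). Two
conventions were genuinely open and are fixed as follows:

* **Tail.** Small linkage ratios are significant — a degrader-like compound
  barely expands the neighborhood — so the p-value is the left-tail rank
  with add-one smoothing, `p = (1 + #{null ≤ r}) / (1 + N_null)`, keeping
  p > 0.
* **Null size.** The false expansion inserts negative controls one *lethal
  dose* at a time, so the null has one ratio per negative drug-dose, not
  per drug. This matters quantitatively: with only 11 null ratios the
  smoothed p floor is 1/12 ≈ 0.083 and no call could survive BH at
  α = 0.05. The synthetic benchmark library uses the 11-drug negative
  panel at 4 lethal doses each (44 null ratios, p floor 1/45).
* **Threshold.** α defaults to 0.05 (configurable); PD-like iff the BH
  q-value is strictly below α.

## Decay, EU and coupling fits

Protein courses normalized to their highest observed signal are fit to
`a·e^(bt) + c·e^(dt)` with `a, c ≥ 0` and `b, d ≤ 0` (pure decay), from two
starts (near-single-exponential, and split fast/slow). The half-life is the
first **downward** crossing of half the fitted curve's own maximum —
bracketed on a dense grid, refined by bisection — which guards against
non-monotonic two-term fits; crossings beyond the observed window are
extrapolated from the fit, and a curve that never reaches half-maximum gets
an infinite, flagged half-life. On single-exponential data this reduces to
`ln 2 / λ` (verified to 1e-3 h).

EU-incorporation loss is fit by a 4-parameter Hill curve in time; its t½ is
where the fitted curve crosses the absolute fraction 0.5 (missing if the
ceiling stays below 0.5). Dose-response curves use the standard 4-parameter
logistic on log₁₀ dose, whose response at EC50 is (top+bottom)/2 by
construction; flat responses are flagged unidentifiable.

The decay-death coupling is summarized two ways on (t½, LF50) pairs:
ordinary least squares (slope, intercept, Pearson r) and the best-fit
shifted identity `LF50 = t½ + c`, whose least-squares offset is
`c = mean(LF50 − t½)` — the mean lag between protein loss and death onset.

## Synthetic generators

The generators emulate the statistical structure of the assays, not their
biology:

* **Trajectories.** Total population `C0·2^(t/doubling)` with default
  C0 = 2000 cells and a 24 h doubling time; LF follows an LED truth whose
  plateau is attenuated per genotype by a factor in [0, 1] (1 = no
  protection, 0 = complete). Drugs that arrest proliferation freeze the
  total at onset (doubling → ∞), reflecting the rapid arrest transcriptional
  inhibitors cause. Measurement noise is multiplicative lognormal on counts
  (sd 0.02 by default, fluorescence-like); a companion generator adds
  Gaussian noise directly to LF for fitter-recovery benchmarks. Default
  sampling is every 2 h over 72 h (37 points).
* **Panels.** Each configured (drug, dose) plus an untreated condition is
  simulated for WT and the three KO backgrounds. The untreated truth has a
  max LF near 0.08 — half the 0.16 lethality gate, consistent with the
  gate being "double background death".
* **Decay courses.** Pol IIA/IIO intensities decay exponentially with
  configured half-lives; the EU-negative fraction is a logistic centered on
  the IIO half-life; death onset is `DO = t½(IIA) + lag` with an 11 h
  default lag. The death rate in these courses defaults to 6 /h — apoptotic
  death after a long lag is abrupt — so the half-death time LF50 sits only
  `ln2/6 ≈ 0.12 h` after onset and the recovered lag matches the configured
  lag closely; LF is sampled every 0.5 h to resolve the steep rise.
* **Screens.** 1,000 genes × 4 guides + 142 non-targeting controls by
  default; per-guide baseline abundances lognormal (sd 0.5), per-sample
  library depths lognormal (sd 0.2) to exercise normalization, counts
  negative-binomial with dispersion 0.1 around a 500-reads/guide coverage.
  Effect genes multiply their guides' expected abundance in the dead sample
  by a configured fold change.

Noiseless generator output is exactly invertible by the corresponding
fitters (recovery to 1e-6), which is how the fitters are validated. What
the generators do **not** emulate: pipetting/edge effects and drift in
plate-reader signals, apoptotic corpse decay distorting dead-cell counts at
late times, guide-specific knockout efficiency, PCR jackpotting, or any
mechanistic transcription/decay coupling. Passing tests therefore
demonstrate correctness of the estimators under the stated noise models,
not robustness to every artifact of real data.

## Screen statistics

Median-of-ratios normalization follows the standard construction: per-guide
geometric-mean reference over samples (guides with any zero excluded from
the reference), per-sample size factor = median ratio to the reference.
Note a formal consequence: normalized counts are defined only up to the
overall scale of the experiment (scaling *all* samples by k scales
normalized counts by k), but per-sample depth distortions cancel exactly,
which is what the downstream log-ratios consume. Guide fold changes are
plain normalized-count log₂ ratios with pseudocount 0.5 — a deliberate
simplification of dispersion-shrunk differential-count estimates, adequate
here because guide scores are immediately standardized against 142
non-targeting controls. The contrast (e.g. dead vs live) is a required
configuration item, not a default. The bootstrap null resamples
guide-level z-scores (with replacement, pooled across all targeting guides)
in sets matching each gene's guide count, takes medians, and computes
two-sided add-one-smoothed p-values; one shared null per guide multiplicity
makes B = 10,000 cheap. BH correction uses `statsmodels`; hits are genes
with q strictly below 0.1, signed by the gene median z. The bottom-2%
count filter removes guides strictly below the 2nd percentile of mean
normalized counts, so fully tied libraries lose nothing.

## Problem sizes and determinism

All stochastic components take explicit seeds (`numpy.random.default_rng`)
and are reproducible bit-for-bit. The validation harness uses 100-seed
replicates for LED recovery and classifier performance, 20 replicates of
1,000-gene screens at B = 10,000 for type-I control, and a single 50 × 50
grid for the GRADE round trip — sizes chosen so the whole suite reruns in
seconds while keeping Monte-Carlo error well below the decision margins.

## Known limitations

* LED assumes a single death wave; biphasic death (e.g. mixed mechanisms
  across a population) is fit by its dominant component.
* The GRADE forward model has rate-constant proliferation and a single
  terminal death fraction; time-varying rates are out of scope.
* PDS depends on the reference condition being scorable in each dataset;
  cross-cell-line comparisons re-run the scoring per line with that line's
  reference rather than modelling line effects.
* The classifier's geometry is fixed at the three knockout axes and
  Euclidean distance; correlated axes are not whitened.
* Screen p-values treat guides as exchangeable across genes; gene-length or
  chromatin covariates are not modelled.
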