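# Methods

This note documents the models, the defaults and the reasoning behind the
design choices, in the order the pipeline runs them.

## Zeitgeber time

Each donor's death instant is taken as a naive local datetime plus an IANA
time-zone id; conversion to UTC (including daylight saving) is delegated to
the system tz database. Sunrise at the death place is computed with the
NOAA low-accuracy solar equations (geometric mean longitude/anomaly,
equation of center, apparent longitude, corrected obliquity; equation of
time in minutes), using the standard refraction zenith of 90.833° plus a
horizon-dip term of 1.76′·√(elevation in m). The dip is the conventional
way to let elevation advance sunrise; published descriptions of this
analysis say elevation is adjusted for without giving a formula, so the dip
correction is a documented choice, not a reconstruction. The sunrise
estimate is iterated three times (declination and equation of time
re-evaluated at the current estimate), giving sub-second self-consistency;
agreement with an independently coded PSA ephemeris (Blanco-Muriel 2001)
bisection oracle is ≲ 5 s over a 20-place battery spanning ±64° latitude
and all seasons (tested bound: 2 min).

ZT is `t` hours after the previous sunrise when `t < 18`, else the negative
offset to the next sunrise, giving a half-open window [−6, 18). Because
sunrise-to-sunrise is not exactly 24 h, deaths within the seasonal drift
(< ~2 min) of the `t = 18` boundary can land marginally below −6 on the
negative branch; these are clamped to −6. Latitudes beyond ±66° are
rejected (no polar handling).

## Preprocessing

CPM, the detection filter (CPM > 1 in ≥ 50% of subjects — boundary
inclusive, reading the filter as the standard "50% or more" idiom), chrY
and unmapped-gene removal, and log2(CPM + offset) with offset 1 (the common
convention; the offset is recorded in provenance and configurable). Stage
flags (`counts → cpm → log2 → adjusted`) make order violations raise
immediately.

Site correction is the parametric empirical-Bayes location/scale model
(ComBat): per-gene standardization against the batch-design fit (pooled
variance with 1/N normalization), per-batch means/variances of the
standardized data shrunk across genes toward a normal / inverse-gamma
prior by the usual moment-matched coupled iteration (convergence 1e-4),
then removal and restoration of grand mean and pooled scale. No covariates
are modelled (none are documented for the original site correction; a flag
could add them later). The implementation reproduces the Bioconductor
reference to ~1e-14 on two-site test matrices (cross-checked by test
against `sva::ComBat` via Rscript). Consequences worth knowing:

* EB removes the *systematic* batch offset but intentionally leaves the
  per-gene batch-mean sampling noise (it borrows strength across genes);
  the non-EB fallback (`empirical_bayes=False`) zeroes observed batch means
  exactly and preserves per-gene grand means to 1e-6 in balanced designs —
  the EB route preserves them only approximately.
* A single batch is a no-op copy (the EB machinery degenerates there).
* A batch-balanced rhythm survives correction essentially unchanged
  (tested: R² shift < 0.05).

## Fixed-period regression

On the cos/sin basis the "nonlinear" sinusoid fit is ordinary least
squares: `y = m + a·cos(ωt) + b·sin(ωt)`, amplitude √(a²+b²), acrophase
`atan2(b, a)/ω` wrapped to [0, period). R² = 1 − SSE/SST; constant genes
get amplitude 0 and R² = 0 by convention. Preconditions: ≥ 6 observations
and ≥ 3 distinct ZT values (the studies of interest have ≥ 46).

The empirical p-value randomizes the TOD labels: p = (1 + k)/(n_perm + 1)
with k the count of null R² ≥ observed (ties count against significance;
the pseudo-count avoids p = 0). Default n_perm = 1000. Within a
transcriptome scan one shared set of label permutations serves all genes —
permuting the expression vector against a fixed time basis is equivalent to
permuting the ZT labels, the p-values of independent genes remain
conditionally independent, and the whole scan vectorizes to
`(G × N) · (N × 2)` products per permutation. Everything is deterministic
in the master seed. Significance defaults: p < 0.01 for a single large
cohort, p < 0.05 for the smaller two-cohort comparisons. A
Benjamini–Hochberg q column is emitted for convenience but no decision in
the pipeline uses it.

Bootstrap stability resamples subjects with replacement (default 100
resamples; 25 in the fast acceptance runs), refits including the
permutation null, and reports the per-gene fraction of resamples with
p < α. Resamples with fewer than 6 distinct subjects are redrawn.

## Lomb–Scargle

Scargle's tau-shifted periodogram (scipy implementation) on mean-centered
data, Horne-normalized by the sample variance, scanned over periods 8–28 h
on a frequency grid of spacing 1/(oversample · span) with oversample 8.
The per-gene p-value is the single-frequency exponential tail raised to an
effective number of independent frequencies M ≈ span · (f_hi − f_lo).
The scan bounds deliberately sit away from 12 h and 24 h because periods
pile up at scan boundaries; with a 24 h TOD range, true 24 h rhythms are at
the edge of what one cycle can establish — a design limitation inherited
from the data design, not solved here. Power at any fixed frequency equals
half the regression sum of squares of a no-intercept cos/sin fit to the
centered data (tested identity), so the periodogram is the period-scanning
counterpart of the fixed-period fit.

## Even-grid binning and the eigenvalue/pencil decomposition

Pencil analysis needs even sampling, so each gene is first averaged onto
integer hours ZT −5..42 (48 points): samples are replicated at ±24 h (and
+48 h, so that the trailing bins' kernel windows are fully populated and
the binned series is exactly 24 h periodic for a symmetric kernel), then
each hour takes a Gaussian-kernel weighted average (σ = 1 h). The kernel is
a documented choice — the original description says only "weighted
averages". The kernel window is truncated at ±6σ; weights beyond 3σ are
negligible, the wide cutoff merely guarantees positive bin weights even
when a clustered TOD distribution leaves multi-hour gaps at n = 46 (an
empty bin raises an error advising a wider kernel).

The binned, mean-centered series is decomposed by the matrix-pencil
method: Hankel matrix with pencil parameter L = N/2 − 1, SVD truncation of
the signal subspace at singular values < sv_tol × largest (default 1e-3;
for noiseless synthetic signals 1e-9 is the appropriate setting and is
what the exactness checks use), poles from the shift-invariance
eigenproblem on the truncated right singular vectors, residues by least
squares on the pole basis, conjugate pairs merged into real damped
cosines. Periods are 2πΔ/|arg z| with Δ = 1 h (∞ below an arg tolerance of
1e-9 — a zero-frequency trend), decay ln|z|/Δ per hour. The top 4
components by amplitude are reported, *without p-values* — this route
identifies components, not significant rhythms, and flags far more genes
than the regression route; that asymmetry is intrinsic. Bands: 12 h for
11 ≤ P < 13, 24 h for 20 ≤ P < 26, noise for finite P < 9 or P > 30
(periods the hourly binning of a 24 h design cannot support), other
otherwise (including ∞). On noiseless two-component signals with periods
≥ 1 h apart the decomposition recovers periods to ~1e-11 h and amplitudes
to ~1e-9 % (200-instance check; nearly coincident periods are not
resolvable from 48 points and are excluded from the draw by the ≥ 1 h
separation).

## Differential rhythmicity

ΔR² = R²_A − R²_B per gene; the null reassigns the pooled subjects to two
groups of the original sizes (the natural exchangeable null for cohort
membership). The p-value is **one-sided for the observed sign** with the
same pseudo-count. Because the side is chosen by the data, the null
rejection rate at nominal α is ~2α; the classification compensates by
requiring the gene to also be rhythmic in the relevant cohort. Classes:
`lost` (rhythmic in A, significant ΔR² > 0), `gained` (mirror), `shared`
(rhythmic in both, no significant difference), `neither`. Swapping the
cohorts maps lost ↔ gained exactly.

RRHO ranks both lists by −log10(p) (ties broken by gene id for
determinism) and, at each pair of rank cutoffs (multiples of `step`,
default n/100), computes the upper hypergeometric tail of the observed
overlap; the grid holds −log10 of those tails. One-sided enrichment only —
rhythmicity p-values carry no sign.

Peak-time populations: a 12 h fit peaks at acrophase mod 12 and again 12 h
later; genes split into ME (morning/evening) vs AN (afternoon/night) at
the midpoints (ZT 5.5 / 11.5, half-open) between the two empirically
described cluster centers ZT 2.5 and 8.5.

## Synthetic studies

The generator emulates the study design: ~13,914 genes × 104 subjects
(single-cohort default), 46 + 46 two-cohort designs, two collection sites
in equal proportions with real coordinates (Pittsburgh / Manhattan), death
dates spread over a year, and TODs drawn from a two-mode von Mises mixture
(modes ZT 4 and 14, κ = 1.5) as a stand-in for the uneven death-time
distributions of real cohorts — the real density is not published, so this
law is explicitly not a reconstruction; a uniform law and point masses are
available for calibration tests. Death datetimes are placed exactly `zt`
hours after the computed sunrise of the assigned site/date, so the
Zeitgeber stage round-trips the planted value to ~1e-10 h.

Expression is `baseline + Σ A·cos(2π(zt − φ)/T) + N(0, σ)` on the log2
scale. Defaults: baseline ~ N(5, 1.5²); 6% of genes carry a 12 h
component, 6% a 24 h one, 2% both; 12 h acrophases are drawn bimodally
around ZT 2.5 / 8.5 (sd 0.75 h) to mimic the two phase populations; 24 h
acrophases uniform. The single-cohort preset uses amplitude = noise sd = 1
(expected R² ≈ 1/3, the upper range of what such fits attain in practice).
The two-cohort preset plants 10% loss, 5% gain and 5% six-hour phase-shift
effects at amplitude 1.25 — deliberately high SNR, so that loss/gain
classification measures the method rather than borderline power at n = 46.
Count-level simulation (negative binomial → CPM) is not modelled: the
pipeline operates on log2 data and the preprocessing stages are tested on
their own arithmetic; library-size artifacts, dropout and count overdispersion
are therefore outside what passing tests demonstrate about real data.

## Problem sizes of the standard checks

Oracle equivalence: 100 random genes at n = 60. Null calibration: 2,000
white-noise genes at n = 46, 500 permutations. Pencil exactness: 200
noiseless instances. Solar battery: 20 place/date pairs. Recovery: 1,000
genes × 104 subjects (single cohort, amplitude = noise) and 1,000 genes ×
46 + 46 (two cohorts), 500 permutations; bootstrap stability on the
1,000-gene preset with 25 resamples (the stable fraction over ~90
significant genes; at a few dozen significant genes the fraction is
dominated by counting granularity). Full-run determinism on the 300-gene
smoke preset.

## Known limitations

* True 24 h rhythm detection from a 24 h TOD range is boundary-limited in
  the period-agnostic scans (inherited design constraint).
* The pencil route inherits the binning's periodic extension: the binned
  series is forced 24 h periodic, which concentrates poles near 24 h
  harmonics and contributes to the large RC counts; results are
  descriptive, not inferential.
* ComBat without covariates can absorb rhythm signal if sites are strongly
  imbalanced in TOD; the generator keeps sites TOD-balanced, as the
  original design did.
* No FDR control is applied to replication-logic decisions (raw p cutoffs,
  matching the original analyses); the q column is informational.
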