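# Methods

This note documents the models, estimators and numerical choices behind
`isotrace`, what the synthetic-data generator does and does not emulate,
and the package's known limitations.

## Scope and assumptions

The pipeline targets continuous-feeding ¹³C tracer experiments measured
by centroided MS1 LC–MS, in which an untargeted analysis of the
unlabeled control samples has already produced (a) a metabolite
annotation table (id, name, formula, adduct, m/z, RT, annotation
confidence, feature id) and (b) a feature table (m/z, apex RT, RT
boundaries, per-sample heights). Both are inputs; annotation itself and
untargeted peak detection of the unlabeled samples are out of scope.
Runs are assumed RT-aligned (single-batch acquisition). Only singly
charged species and carbon-free adducts are supported, so the carbon
count of the neutral formula fixes the isotopologue count at C + 1.
Supported adducts: [M+H]⁺, [M+Na]⁺, [M+NH₄]⁺, [M−H]⁻, [M+Cl]⁻,
[M−H−H₂O]⁻ (water loss then deprotonation; a row with any other adduct
is rejected at parse time with a log message).

Retention time is seconds in every module; the kinetics module works in
hours and conversions happen only at its boundary. The ¹³C–¹²C mass
difference is fixed at 1.003355 Da — at the 25 ppm extraction tolerance
the difference between this constant and the exact value is
inconsequential, and using one constant makes the series-spacing
contract exact.

## Extraction model

**m/z tolerance.** 0.01 Da below m/z 400, else 25 ppm, applied as a hard
closed interval. No taper: a centroid is either inside the window or
not.

**EIC grid.** Every scan inside the RT window contributes a point;
scans with no matching centroid contribute an explicit zero, so all
isotopologue channels of one run share a grid.

**Noise and baseline.** Per channel, noise is the median of the nonzero
intensities after discarding the top decile (which contains the peaks),
and the baseline is the 10th percentile of the full trace. These are
deliberately simple, robust, and configurable
(`ExtractionConfig.noise_top_decile`, `baseline_quantile`). A channel
whose baseline-subtracted maximum is below 3 × noise is discarded
before peak detection.

**Peak detection.** The baseline-subtracted trace is smoothed with a
Gaussian kernel of σ = 1 scan interval (configurable) and passed to a
Mexican-hat continuous-wavelet-transform ridge detector
(`scipy.signal.find_peaks_cwt`) with wavelet widths spanning the
expected chromatographic σ range (peak widths 5–30 s FWHM). Apexes are
refined to the local maximum of the smoothed trace, and boundaries walk
out from the apex to the nearest local minimum, stopping early once the
trace decays below 0.5 % of the apex height (a pure Gaussian never
reaches exactly zero in floating point, and without the stop the bounds
of a noiseless peak would run to the window edges). Candidates whose
boundary-to-boundary width falls outside [5 s, 45 s] are discarded as
noise ridges. This detector is a behavioral variant of the widely used
wavelet-based chromatographic peak pickers; it is not a line-for-line
reimplementation of any of them.

**Peak–peak correlation (PPC).** Shape similarity between a candidate
peak and the reference (unlabeled) peak of the same metabolite: both
peaks are aligned on their apexes, resampled by linear interpolation
onto a shared grid covering the union of their apex-centred boundary
windows (zero-filled outside each peak's own bounds), and scored by the
Pearson correlation of the resampled vectors. Degenerate (constant)
shapes score 0 and are flagged rather than propagating an undefined
correlation. Candidates with PPC < 0.6 are dropped. Apex alignment
before correlating is a design choice: the score then measures shape,
not co-elution; co-elution is enforced separately by apex clustering.

**Grouping.** Surviving apexes across all isotopologue channels of a
metabolite are clustered by complete-linkage hierarchical clustering of
apex RT, cutting the tree at 3 s. Complete linkage is chosen because
the 3 s cut then *guarantees* the maximum pairwise apex spread inside a
group is ≤ 3 s, which is asserted on every output. The group whose
mean apex RT is nearest the reference RT wins; exact ties go to the
group with the tallest peak. Within the winning group the tallest
member supplies the final apex and boundaries, so highly labeled
metabolites are anchored by their most intense isotopologue rather
than M0.

## Quantification and correction

**Intensity.** Sum of the three scans centred on the apex, on the raw
(unsmoothed) EIC. Channels with no surviving candidate are extracted
mandatorily at the group apex; a flag records this. Apexes at the grid
edge sum the available scans and are flagged.

**Natural-abundance correction.** With natural ¹³C abundance
p₁₃ = 0.0107 (configurable) and tracer purity P (default 1.0), the
measurement model is y = A·x where column j of A is the isotope pattern
of a species with j tracer-labeled carbons: Binomial(C − j, p₁₃) over
the unlabeled carbons, convolved with Binomial(j, P) over the label
positions when P < 1. The correction solves the non-negative least
squares problem min ‖A·x − y‖₂, x ≥ 0, and normalizes x to the MID.
NNLS rather than direct matrix inversion keeps corrected intensities
physical when the measurement is noisy. Only carbon is corrected: at
high resolving power the isotopologues of H/N/O are resolved away from
the ¹³C series, and resolution-dependent multi-element correction is
out of scope.

**Contamination.** In the unlabeled controls, a non-M0 isotopologue
whose corrected fraction exceeds 0.02 in strictly more than 50 % of
samples is deemed contaminated (e.g. a co-eluting species inside the
m/z window); its level is estimated as the mean fraction across the
unlabeled samples, assumed equal in labeled samples, and subtracted
from the labeled-sample fractions (clamped at zero). The subtracted
mass is returned to M0 so the MID still sums to 1 — plain subtraction
would leave the vector unnormalized, and renormalizing via M0 is the
choice that leaves the labeled, uncontaminated fractions untouched;
output metadata flags it. A metabolite whose M0 intensity is zero in
strictly more than 50 % of unlabeled samples is treated as absent and
its labeled-sample fractions are zeroed entirely. One pass of the full
protocol is a fixed point: after subtraction the re-estimated
contamination is zero, so a second pass changes nothing.

**Labeling call.** An isotopologue (except M0) is labeled when its
fraction exceeds 0.02 in strictly more than 50 % of a group's labeled
samples; a metabolite is labeled when any of its non-M0 isotopologues
is. Both thresholds are configurable.

## Kinetics

Labeling extent LE = 1 − L(M0) depends only on the unlabeled fraction,
not on how labeled mass distributes among M1…MC. An all-zero MID gives
a *missing* LE, never 0 — zero means "measured and unlabeled".

The first-order model LE(t) = a·e^(−kt) − a (a < 0) is fitted by
nonlinear least squares (`scipy.optimize.curve_fit`) on the
replicate-mean LE per time point (means rather than medians for least
squares efficiency; configurable upstream by what is passed in).
Initialization: a₀ = −max(LE); k₀ from a log-linear regression of
1 − LE/plateau on t; bounds a ∈ (−1, 0), k ∈ [0, ∞). At least three
distinct time points are required. R is the Pearson correlation of
observed versus fitted LE — the quantity reported as the fit-quality
"R-value" — and fits with R ≤ 0.8 are flagged unreliable. An
all-zero time course is reported non-converged rather than fitted.

Pathway summaries use the median labeling rate and the mean labeling
extent over member metabolites. `normalize_to_tracer` divides
per-sample fractions by the same sample's tracer reference fraction
(e.g. fully labeled glucose M+6), returning missing values where the
reference is zero. `relative_error` and `consistency_share` implement
the signed relative LE error against an independent quantification and
the share of metabolites within |30 %|.

## Statistics

Profile clustering uses 1 − Pearson correlation as the distance between
metabolite LE time profiles. "ward" linkage follows the classical Ward
convention of applying the Lance–Williams update to the raw correlation
distances (implemented by feeding √d to scipy's Ward, whose merge
sequence then matches; heights differ but memberships agree);
"complete" linkage is also exposed. Default cut: 3 clusters.
Zero-variance profiles cannot enter a correlation and are assigned
afterwards to the nearest cluster centroid, with a log flag.

Correlation networks: all pairwise Pearson correlations of per-sample
LE at one time point, two-sided p-values from the exact t-transform
with n − 2 degrees of freedom, Benjamini–Hochberg adjustment over all
pairs within one comparison, edges kept at adjusted p < 0.05.
Zero-variance metabolites are excluded and reported.

Enrichment: p = P(X ≥ k) for X ~ Hypergeometric(N, K, n). The caller
chooses the background universe: all labeled metabolites for
within-experiment cluster analyses, or the full pathway-database
universe for cross-condition comparisons.

False-positive rates re-run the entire pipeline on unlabeled samples
only: an isotopologue whose fraction exceeds 2 % in *any one* sample is
a false positive (isotopologue level); the metabolite level counts
metabolites called labeled by the strict-majority rule among all
extracted metabolites.

## Synthetic data

The generator emulates what the pipeline assumes: Gaussian
chromatographic peaks (default σ = 3 s on a 0.5 s scan grid, i.e. FWHM
≈ 7 s, inside the 5–30 s detector band), isotopologue envelopes at the
exact theoretical m/z, MIDs that follow the first-order model with
natural abundance convolved in through the same binomial matrix the
correction inverts, a within-channel noise floor (exponential
amplitudes at the planted m/z), random chemical-noise centroids across
the m/z range, log-normal abundance scatter between replicates
(default CV 10 %), per-run apex jitter (0.3 s), co-eluting decoy
interferences, and constant planted isotope contamination. The default
design is the continuous-feeding layout of an in vivo tracer study:
time points 0, 1, 3, 6, 12 and 24 h, 10 replicates per point, plus an
unlabeled control group. Labeled mass placement defaults to the fully
labeled isotopologue ("full" mode, the steady-state pattern of a
uniformly labeled tracer); "spread" mode distributes it binomially at
the per-carbon enrichment that reproduces the same LE, exercising
intermediate isotopologues.

What it does **not** emulate: peak tailing/fronting, RT drift across
batches, detector saturation, correlated chemical noise, isotope fine
structure, or profile-mode spectra. Passing the end-to-end tests
therefore demonstrates the pipeline's internal consistency and its
behavior under the stated noise model — not performance on any
particular instrument's data.

Scenario sizes used by the test suite and `scripts/acceptance.py` — a
50-metabolite roster (20 % of it deliberately unlabeled) over the full
6 × 10 design for end-to-end recovery, a 10-metabolite unlabeled-only
design for the false-positive protocol, and a 100-case (a, k) grid for
kinetic recovery — were chosen as the smallest sizes at which the
estimates of recall, precision and rate error are stable across seeds.

## Known limitations

- Isomers sharing m/z and RT are emitted as separate targets and
  cross-tagged `shared_signal_with`; their signals are not
  deconvolved.
- Only ¹³C tracers; the mass difference and element count are isolated
  in `targets` for future tracers, but no other tracer is implemented.
- No multi-charge species, ion mobility, or MS2.
- Correction assumes isotopologues of other elements are resolved
  away; on low-resolution data M+1 will be over-corrected.
- The wavelet detector is tuned for well-formed single peaks within
  the configured width band; heavily fused peaks resolve only if their
  apexes separate by more than the cluster cut.
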