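# isotrace

Metabolome-wide ¹³C stable-isotope tracing from LC–MS runs.

`isotrace` is for metabolomics researchers who run continuous-feeding
tracer experiments (e.g. [U-¹³C]-glucose) and want to quantify *which*
metabolites incorporate the tracer, *how much*, and *how fast* — across
hundreds of annotated metabolites at once, not a hand-picked panel.
Untargeted peak detection and annotation of the **unlabeled** control
samples define where each metabolite elutes; `isotrace` then performs
**targeted** extraction of every possible ¹³C-isotopologue in the
labeled samples, corrects the measured intensities for natural isotope
abundance and isotope contamination, and reports mass isotopomer
distributions (MIDs), labeling extents and first-order labeling rates,
together with the downstream statistics tracer studies need (profile
clustering, correlation networks, pathway enrichment, false-positive
evaluation).

## Method

For a metabolite with formula containing *C* carbons, the isotopologue
M*i* (i = 0…C) carries *i* heavy carbons; its theoretical m/z is the
adduct-shifted monoisotopic mass plus *i* × 1.003355 Da. The workflow:

1. **Targets** — from each annotation, compute the M0…MC m/z series and
   select the reference ("target") chromatographic peak of M0 — apex RT,
   boundaries and shape — from the unlabeled run where it is tallest.
2. **Extraction** — in every labeled run, extract each isotopologue's
   ion chromatogram over the reference RT window widened by 15 s on each
   side (m/z tolerance 25 ppm, or 0.01 Da below 400 Da). Traces whose
   maximum signal-to-noise ratio is below 3 are discarded; the rest are
   Gaussian-smoothed and passed to a Mexican-hat wavelet peak detector
   constrained to 5–30 s peak widths. Each candidate peak is scored
   against the reference shape by a peak–peak correlation (PPC, an
   apex-aligned resampled Pearson correlation) and kept at PPC ≥ 0.6.
   Apexes are clustered (complete linkage, 3 s cut — so co-grouped
   apexes never spread more than 3 s) and the group nearest the
   reference RT is selected; its boundaries follow its tallest member,
   so a highly labeled metabolite is anchored by its most intense
   isotopologue even when M0 sits in the noise.
3. **Quantification** — each isotopologue's intensity is the sum of the
   three scans around the apex (undetected channels are extracted
   mandatorily at the group apex). Measured intensities *y* are
   deconvolved against the natural-abundance binomial convolution
   matrix *A* by non-negative least squares,

       min ‖A·x − y‖₂  subject to  x ≥ 0,

   and the MID is x/Σx. Isotope contamination is estimated from the
   unlabeled controls (a non-M0 fraction > 0.02 in a strict majority of
   samples) and subtracted; metabolites whose M0 is absent from most
   unlabeled samples are zeroed. A metabolite is *labeled* when some
   non-M0 isotopologue exceeds a 2 % fraction in a strict majority of
   labeled samples.
4. **Kinetics** — the labeling extent LE = 1 − L(M0) is fitted against
   labeling time with the first-order model LE(t) = a·e^(−kt) − a
   (a < 0), giving the labeling rate k (h⁻¹) and plateau −a; R is the
   Pearson correlation of observed versus fitted LE, with R ≤ 0.8
   flagged unreliable.
5. **Statistics** — hierarchical clustering of LE time profiles on
   correlation distance; all-pairs Pearson correlation networks on
   final-time-point LE with Benjamini–Hochberg control at FDR 0.05;
   hypergeometric pathway enrichment; and a false-positive-rate
   protocol that re-runs the whole pipeline on unlabeled samples.

A ground-truthed synthetic-data generator (`isotrace.synthetic_data`)
renders complete centroided MS1 runs — Gaussian isotopologue peak
clusters, kinetic MID truth, noise floor, interferences, planted
contamination — so every stage is testable end to end without any
external data.

## Worked example

```python
from isotrace import synthetic_data as syn
from isotrace.pipeline import run_pipeline
from isotrace.kinetics import fit_all, mid_table_to_le

# a 0/1/3/6/12/24 h tracer time course, 8 metabolites, 3 replicates
spec = syn.timecourse_scenario(n_metabolites=8, seed=3, replicates=3)
manifest = syn.generate_scenario(spec)
runs = syn.render_runs(manifest, spec)

groups = dict(zip(manifest.runs.run_id, manifest.runs.group))
mid_table, targets = run_pipeline(
    runs, groups, syn.scenario_annotations(spec), syn.scenario_features(spec))

le = mid_table_to_le(mid_table, {f"t{t:g}h": t for t in spec.time_points_h})
fits = fit_all(le.dropna(subset=["le"]))
print(syn.evaluate_recovery(mid_table, manifest, fits=fits)["recall"])
print(fits[fits.reliable][["metabolite_id", "k", "r"]].head(3))
```

Output:

```
1.0
  metabolite_id         k    r
2         M0003  0.139571  1.0
3         M0004  0.202071  1.0
4         M0005  0.421799  1.0
```

`recall = 1.0` says every metabolite planted as tracer-labeled was
called labeled by the 2 %-in-a-strict-majority rule. Each fitted `k` is
the apparent first-order labeling rate in h⁻¹, and `r` the correlation
between observed and fitted labeling extents; the planted rates for
these three metabolites were 0.1394, 0.2018 and 0.4217 h⁻¹, so the
pipeline recovers them to a fraction of a percent. (The unreliable
rows filtered out here are the scenario's deliberately unlabeled
control metabolites, whose labeling rate is not identifiable.)

The same workflow is available from the shell (`isotrace simulate`,
`isotrace extract`, `isotrace kinetics`, `isotrace network`,
`isotrace enrich`, `isotrace fpr`); see `isotrace --help`.

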