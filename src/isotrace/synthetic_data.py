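"""Ground-truthed synthetic LC–MS tracer experiments.

Generates labeled/unlabeled centroided MS1 runs with the statistical
structure the pipeline assumes: per-metabolite Gaussian chromatographic
peak clusters whose isotopologues sit exactly one ¹³C–¹²C mass
difference apart, mass isotopomer distributions that follow first-order
labeling kinetics, natural ¹³C abundance convolved in, plus a
configurable noise floor, baseline centroids, co-eluting interferences
and planted isotope contamination.  Every run is accompanied by a truth
manifest (true MIDs, true labeling extents, true kinetic parameters,
planted peak positions), so recall, precision, quantification error and
rate recovery can be scored exactly.

The default experimental design mirrors a continuous-feeding tracer
study: time points 0, 1, 3, 6, 12 and 24 h with 10 replicates per
point, plus an unlabeled control group.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .kinetics import first_order_labeling
from .quantify import natural_abundance_matrix
from .raw_io import AnnotationRecord, FeatureRecord, RawRun, Scan, write_mzml
from .targets import isotopologue_mz_series, parse_formula

DEFAULT_TIME_POINTS_H = (0.0, 1.0, 3.0, 6.0, 12.0, 24.0)
DEFAULT_REPLICATES = 10
DEFAULT_SCAN_INTERVAL_S = 0.5
DEFAULT_PEAK_SIGMA_S = 3.0

#: Small pool of common-metabolite formulas used by the scenario builders.
FORMULA_POOL: tuple[tuple[str, str], ...] = (
    ("glucose", "C6H12O6"),
    ("pyruvate", "C3H4O3"),
    ("lactate", "C3H6O3"),
    ("citrate", "C6H8O7"),
    ("succinate", "C4H6O4"),
    ("malate", "C4H6O5"),
    ("fumarate", "C4H4O4"),
    ("alpha-ketoglutarate", "C5H6O5"),
    ("alanine", "C3H7NO2"),
    ("serine", "C3H7NO3"),
    ("aspartate", "C4H7NO4"),
    ("glutamate", "C5H9NO4"),
    ("glutamine", "C5H10N2O3"),
    ("glycine", "C2H5NO2"),
    ("proline", "C5H9NO2"),
    ("ribose-5-phosphate", "C5H11O8P"),
    ("glucose-6-phosphate", "C6H13O9P"),
    ("glycerol-3-phosphate", "C3H9O6P"),
    ("inosine", "C10H12N4O5"),
    ("hypoxanthine", "C5H4N4O"),
    ("uridine", "C9H12N2O6"),
    ("adenosine", "C10H13N5O4"),
    ("nicotinamide", "C6H6N2O"),
    ("pantothenate", "C9H17NO5"),
    ("taurine", "C2H7NO3S"),
)


@dataclass(frozen=True)
class MetaboliteSpec:
    metabolite_id: str
    name: str
    formula: str
    adduct: str
    rt: float                      # seconds, apex of the chromatographic peak
    peak_sigma: float = DEFAULT_PEAK_SIGMA_S
    base_intensity: float = 2e5    # apex-equivalent total ion abundance
    a: float = -0.8                # kinetic plateau parameter (a < 0)
    k: float = 0.3                 # labeling rate, h⁻¹ (0 = never labeled)


@dataclass(frozen=True)
class NoiseModel:
    baseline_level: float = 50.0   # scale of the noise floor in each channel
    cv: float = 0.10               # log-normal CV on per-run metabolite abundance
    additive_floor: float = 20.0   # additive Gaussian noise on planted centroids
    channel_noise_prob: float = 0.4  # per-scan chance of a noise-floor centroid
    baseline_peaks_per_scan: int = 20  # random chemical-noise centroids per scan

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(baseline_level=0.0, cv=0.0, additive_floor=0.0,
                   channel_noise_prob=0.0, baseline_peaks_per_scan=0)


@dataclass(frozen=True)
class Interference:
    """A co-eluting decoy centroid peak not tied to any metabolite."""

    mz: float
    rt: float
    sigma: float = DEFAULT_PEAK_SIGMA_S
    height: float = 1e5


@dataclass
class ScenarioSpec:
    metabolites: list[MetaboliteSpec]
    time_points_h: tuple[float, ...] = DEFAULT_TIME_POINTS_H
    replicates: int = DEFAULT_REPLICATES
    unlabeled_replicates: int = DEFAULT_REPLICATES
    noise: NoiseModel = field(default_factory=NoiseModel)
    contaminants: dict[str, dict[int, float]] = field(default_factory=dict)
    interferences: list[Interference] = field(default_factory=list)
    scan_interval: float = DEFAULT_SCAN_INTERVAL_S
    rt_jitter_sd: float = 0.3      # per-run apex jitter, seconds
    label_mode: str = "full"       # "full" | "spread"
    p13: float = 0.0107
    seed: int = 0

    def __post_init__(self) -> None:
        for m in self.metabolites:
            if m.a >= 0:
                raise ValueError(f"{m.metabolite_id}: a must be < 0")
            if m.k < 0:
                raise ValueError(f"{m.metabolite_id}: k must be >= 0")
        if self.replicates < 1 or self.unlabeled_replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class TruthManifest:
    """Everything the generator planted, for exact downstream scoring."""

    metabolites: pd.DataFrame  # id, formula, adduct, C, rt, a, k, labeled
    runs: pd.DataFrame         # run_id, group, t_hours, replicate
    mids: pd.DataFrame         # long: metabolite_id, run_id, isotopologue_index,
                               #       true_fraction (pre-natural-abundance), true_le
    apexes: pd.DataFrame       # metabolite_id, run_id, apex_rt (after jitter)


# ---------------------------------------------------------------------------
# Truth generation
# ---------------------------------------------------------------------------

def _true_mid(m: MetaboliteSpec, t_hours: float, carbon: int, mode: str) -> np.ndarray:
    """Pre-natural-abundance MID at one time point.

    LE comes from the first-order model; labeled mass goes entirely to the
    fully labeled isotopologue ("full" mode, uniform-tracer steady state)
    or is spread binomially over M1…MC at the per-carbon enrichment that
    reproduces the same LE ("spread" mode).
    """
    le = 0.0 if m.k == 0 else float(first_order_labeling(np.array([t_hours]), m.a, m.k)[0])
    le = float(np.clip(le, 0.0, 1.0))
    mid = np.zeros(carbon + 1)
    mid[0] = 1.0 - le
    if le == 0 or carbon == 0:
        mid[0] = 1.0
        return mid
    if mode == "full":
        mid[carbon] = le
    elif mode == "spread":
        from scipy.stats import binom

        # per-carbon enrichment e with 1 − (1 − e)^C = LE
        e = 1.0 - (1.0 - le) ** (1.0 / carbon)
        pmf = binom.pmf(np.arange(carbon + 1), carbon, e)
        mid = pmf.copy()
        mid[0] = 1.0 - le  # exact by construction; guard rounding
    else:
        raise ValueError(f"unknown label_mode {mode!r}")
    return mid / mid.sum()


def generate_scenario(spec: ScenarioSpec) -> TruthManifest:
    """Lay out runs and compute the planted truth for every metabolite."""
    rng = np.random.default_rng(spec.seed)
    met_rows, run_rows, mid_rows, apex_rows = [], [], [], []

    comps = {m.metabolite_id: parse_formula(m.formula) for m in spec.metabolites}
    for m in spec.metabolites:
        met_rows.append({
            "metabolite_id": m.metabolite_id, "name": m.name, "formula": m.formula,
            "adduct": m.adduct, "carbon_count": comps[m.metabolite_id].carbon_count,
            "rt": m.rt, "peak_sigma": m.peak_sigma, "base_intensity": m.base_intensity,
            "a": m.a, "k": m.k, "labeled": m.k > 0,
        })

    groups: list[tuple[str, float, int, bool]] = [
        ("unlabeled", 0.0, spec.unlabeled_replicates, False)
    ]
    for t in spec.time_points_h:
        groups.append((f"t{t:g}h", t, spec.replicates, True))

    for group, t_hours, n_rep, labeled in groups:
        for rep in range(1, n_rep + 1):
            run_id = f"{group}_r{rep:02d}"
            run_rows.append({"run_id": run_id, "group": group,
                             "t_hours": t_hours, "replicate": rep})
            for m in spec.metabolites:
                c = comps[m.metabolite_id].carbon_count
                mid = (_true_mid(m, t_hours, c, spec.label_mode)
                       if labeled else _true_mid(m, 0.0, c, spec.label_mode))
                le = 1.0 - mid[0]
                jitter = rng.normal(0.0, spec.rt_jitter_sd) if spec.rt_jitter_sd > 0 else 0.0
                apex_rows.append({"metabolite_id": m.metabolite_id, "run_id": run_id,
                                  "apex_rt": m.rt + jitter})
                for i, frac in enumerate(mid):
                    mid_rows.append({
                        "metabolite_id": m.metabolite_id, "run_id": run_id,
                        "isotopologue_index": i, "true_fraction": float(frac),
                        "true_le": float(le),
                    })
    return TruthManifest(
        metabolites=pd.DataFrame(met_rows),
        runs=pd.DataFrame(run_rows),
        mids=pd.DataFrame(mid_rows),
        apexes=pd.DataFrame(apex_rows),
    )


# ---------------------------------------------------------------------------
# Run rendering
# ---------------------------------------------------------------------------

def render_runs(
    manifest: TruthManifest,
    spec: ScenarioSpec,
    out_dir: str | None = None,
) -> dict[str, RawRun]:
    """Render every planted run as a centroided MS1 RawRun.

    Each isotopologue becomes a Gaussian chromatographic peak at its
    theoretical m/z whose apex height is the metabolite's (noisy) total
    abundance times its measured — natural-abundance-convolved — MID
    fraction.  Planted isotope contamination adds constant extra signal at
    the configured isotopologue in every run.  Deterministic under a fixed
    seed; when ``out_dir`` is given each run is also written as mzML.
    """
    rng = np.random.default_rng(spec.seed + 1)
    comps = {m.metabolite_id: parse_formula(m.formula) for m in spec.metabolites}
    series = {
        m.metabolite_id: isotopologue_mz_series(comps[m.metabolite_id], m.adduct)
        for m in spec.metabolites
    }
    na_mats = {
        m.metabolite_id: natural_abundance_matrix(
            comps[m.metabolite_id].carbon_count, p13=spec.p13)
        for m in spec.metabolites
    }
    polarity = "negative" if spec.metabolites[0].adduct.endswith("-") else "positive"

    rt_lo = min(m.rt for m in spec.metabolites) - 60.0
    rt_hi = max(m.rt for m in spec.metabolites) + 60.0
    grid = np.arange(max(rt_lo, 0.0), rt_hi, spec.scan_interval)
    mz_lo = min(s[0] for s in series.values()) - 50.0
    mz_hi = max(s[-1] for s in series.values()) + 50.0

    mid_lookup = manifest.mids.set_index(
        ["metabolite_id", "run_id", "isotopologue_index"])["true_fraction"]
    apex_lookup = manifest.apexes.set_index(["metabolite_id", "run_id"])["apex_rt"]

    runs: dict[str, RawRun] = {}
    for run_row in manifest.runs.itertuples(index=False):
        run_id = run_row.run_id
        # centroid store: parallel arrays of (scan index, m/z, intensity)
        idx_parts: list[np.ndarray] = []
        mz_parts: list[np.ndarray] = []
        int_parts: list[np.ndarray] = []

        def plant(mz: float, apex_rt: float, sigma: float, height: float) -> None:
            if height <= 0:
                return
            i0 = int(np.searchsorted(grid, apex_rt - 5 * sigma))
            i1 = min(int(np.searchsorted(grid, apex_rt + 5 * sigma)), len(grid))
            if i1 <= i0:
                return
            j = np.arange(i0, i1)
            y = height * np.exp(-((grid[j] - apex_rt) ** 2) / (2 * sigma**2))
            if spec.noise.additive_floor > 0:
                y = y + rng.normal(0.0, spec.noise.additive_floor, len(j))
            keep = y > 0
            idx_parts.append(j[keep])
            mz_parts.append(np.full(int(keep.sum()), mz))
            int_parts.append(y[keep])

        for m in spec.metabolites:
            c = comps[m.metabolite_id].carbon_count
            true_mid = np.array([
                mid_lookup[(m.metabolite_id, run_id, i)] for i in range(c + 1)
            ])
            measured = na_mats[m.metabolite_id] @ true_mid
            abundance = m.base_intensity
            if spec.noise.cv > 0:
                sigma_ln = np.sqrt(np.log(1.0 + spec.noise.cv**2))
                abundance *= rng.lognormal(-sigma_ln**2 / 2, sigma_ln)
            apex_rt = float(apex_lookup[(m.metabolite_id, run_id)])
            contam = spec.contaminants.get(m.metabolite_id, {})
            for i, mz in enumerate(series[m.metabolite_id]):
                height = abundance * measured[i] + abundance * contam.get(i, 0.0)
                plant(float(mz), apex_rt, m.peak_sigma, height)
                # noise floor in this channel across the whole run
                if spec.noise.channel_noise_prob > 0 and spec.noise.baseline_level > 0:
                    hits = np.flatnonzero(
                        rng.random(len(grid)) < spec.noise.channel_noise_prob)
                    idx_parts.append(hits)
                    mz_parts.append(np.full(len(hits), float(mz)))
                    int_parts.append(rng.exponential(spec.noise.baseline_level, len(hits)))

        for intf in spec.interferences:
            plant(intf.mz, intf.rt, intf.sigma, intf.height)

        if spec.noise.baseline_peaks_per_scan > 0:
            n = spec.noise.baseline_peaks_per_scan
            total = n * len(grid)
            idx_parts.append(np.repeat(np.arange(len(grid)), n))
            mz_parts.append(rng.uniform(mz_lo, mz_hi, total))
            int_parts.append(rng.exponential(max(spec.noise.baseline_level, 1.0), total))

        if idx_parts:
            idx_all = np.concatenate(idx_parts)
            mz_all = np.concatenate(mz_parts)
            int_all = np.concatenate(int_parts)
            order = np.lexsort((mz_all, idx_all))
            idx_all, mz_all, int_all = idx_all[order], mz_all[order], int_all[order]
            bounds = np.searchsorted(idx_all, np.arange(len(grid) + 1))
        else:
            idx_all = np.array([], dtype=int)
            mz_all = int_all = np.array([])
            bounds = np.zeros(len(grid) + 1, dtype=int)
        scans = [
            Scan(rt=float(rt), mz=mz_all[bounds[j]:bounds[j + 1]],
                 intensity=int_all[bounds[j]:bounds[j + 1]])
            for j, rt in enumerate(grid)
        ]
        run = RawRun(run_id=run_id, polarity=polarity, scans=scans)
        runs[run_id] = run
        if out_dir is not None:
            import os

            write_mzml(run, os.path.join(out_dir, f"{run_id}.mzML"))
    return runs


# ---------------------------------------------------------------------------
# Pipeline input tables from truth
# ---------------------------------------------------------------------------

def scenario_annotations(spec: ScenarioSpec) -> list[AnnotationRecord]:
    """Annotation table the pipeline would receive for this scenario."""
    records = []
    for i, m in enumerate(spec.metabolites, start=1):
        comp = parse_formula(m.formula)
        mz0 = float(isotopologue_mz_series(comp, m.adduct)[0])
        records.append(AnnotationRecord(
            metabolite_id=m.metabolite_id, name=m.name, formula=m.formula,
            adduct=m.adduct, mz=mz0, rt=m.rt, msi_level=1,
            feature_id=f"F{i:04d}",
        ))
    return records


def scenario_features(spec: ScenarioSpec) -> list[FeatureRecord]:
    """Feature table (as untargeted detection of the unlabeled runs would give)."""
    records = []
    for i, m in enumerate(spec.metabolites, start=1):
        comp = parse_formula(m.formula)
        mz0 = float(isotopologue_mz_series(comp, m.adduct)[0])
        half = 4.0 * m.peak_sigma
        records.append(FeatureRecord(
            feature_id=f"F{i:04d}", mz=mz0, rt_apex=m.rt,
            rt_min=m.rt - half, rt_max=m.rt + half,
        ))
    return records


# ---------------------------------------------------------------------------
# Scenario builders
# ---------------------------------------------------------------------------

def _build_roster(
    n_metabolites: int,
    rng: np.random.Generator,
    unlabeled_fraction: float = 0.0,
    rt_start: float = 120.0,
    rt_spacing: float = 25.0,
) -> list[MetaboliteSpec]:
    roster = []
    n_unlabeled = int(round(unlabeled_fraction * n_metabolites))
    for i in range(n_metabolites):
        name, formula = FORMULA_POOL[i % len(FORMULA_POOL)]
        k = 0.0 if i < n_unlabeled else float(rng.uniform(0.05, 1.0))
        a = float(-rng.uniform(0.3, 0.95))
        roster.append(MetaboliteSpec(
            metabolite_id=f"M{i + 1:04d}",
            name=f"{name}#{i // len(FORMULA_POOL) + 1}",
            formula=formula,
            adduct="[M-H]-",
            rt=rt_start + i * rt_spacing,
            base_intensity=float(rng.uniform(1e5, 8e5)),
            a=a,
            k=k,
        ))
    # shuffle which metabolite is unlabeled so RT order carries no signal
    rng.shuffle(roster)
    return [replace(m, rt=rt_start + j * rt_spacing) for j, m in enumerate(roster)]


def timecourse_scenario(
    n_metabolites: int = 50,
    seed: int = 1,
    noise: NoiseModel | None = None,
    unlabeled_fraction: float = 0.2,
    replicates: int = DEFAULT_REPLICATES,
    time_points_h: tuple[float, ...] = DEFAULT_TIME_POINTS_H,
    label_mode: str = "full",
) -> ScenarioSpec:
    """Continuous-feeding time-course design with a mixed roster."""
    rng = np.random.default_rng(seed)
    roster = _build_roster(n_metabolites, rng, unlabeled_fraction=unlabeled_fraction)
    return ScenarioSpec(
        metabolites=roster,
        time_points_h=time_points_h,
        replicates=replicates,
        unlabeled_replicates=replicates,
        noise=NoiseModel() if noise is None else noise,
        label_mode=label_mode,
        seed=seed,
    )


def unlabeled_scenario(
    n_metabolites: int = 20,
    seed: int = 1,
    noise: NoiseModel | None = None,
    contaminants: dict[str, dict[int, float]] | None = None,
    replicates: int = DEFAULT_REPLICATES,
) -> ScenarioSpec:
    """Unlabeled-only design (k = 0 everywhere) for the FPR protocol."""
    rng = np.random.default_rng(seed)
    roster = _build_roster(n_metabolites, rng, unlabeled_fraction=1.0)
    return ScenarioSpec(
        metabolites=roster,
        time_points_h=(24.0,),  # "labeled" runs exist but carry no label
        replicates=replicates,
        unlabeled_replicates=replicates,
        noise=NoiseModel.noiseless() if noise is None else noise,
        contaminants={} if contaminants is None else contaminants,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

def evaluate_recovery(
    mid_table: pd.DataFrame,
    manifest: TruthManifest,
    fits: pd.DataFrame | None = None,
    threshold: float = 0.02,
) -> dict:
    """Score pipeline output against the planted truth.

    Returns labeled-metabolite recall and precision (calls made on the
    final-time-point group by the strict-majority rule), the RMSE of the
    corrected isotopologue fractions against the pre-natural-abundance
    truth over all labeled runs, and — when kinetic ``fits`` are given —
    the per-metabolite relative rate error |k̂ − k| / k.
    """
    from .quantify import MID as _MID
    from .quantify import call_labeled as _call

    truth_mets = manifest.metabolites.set_index("metabolite_id")
    missing = set(mid_table["metabolite_id"]) - set(truth_mets.index)
    if missing:
        raise ValueError(f"pipeline output contains unknown metabolites: {sorted(missing)}")

    labeled_groups = manifest.runs.loc[manifest.runs["t_hours"] > 0, "group"]
    final_group = manifest.runs.loc[
        manifest.runs["t_hours"] == manifest.runs["t_hours"].max(), "group"].iloc[0] \
        if len(labeled_groups) else None

    calls: dict[str, bool] = {}
    if final_group is not None:
        sub = mid_table[mid_table["group"] == final_group]
        for met, per_met in sub.groupby("metabolite_id"):
            mids = {}
            for run, per_run in per_met.groupby("run_id"):
                fr = per_run.sort_values("isotopologue_index")["labeled_fraction"].to_numpy()
                mids[run] = _MID(fr, all_zero=bool(fr.sum() == 0))
            calls[str(met)], _ = _call(mids, threshold=threshold)

    truly = {m: bool(truth_mets.loc[m, "labeled"]) for m in calls}
    tp = sum(1 for m, c in calls.items() if c and truly[m])
    fp = sum(1 for m, c in calls.items() if c and not truly[m])
    fn = sum(1 for m, c in calls.items() if not c and truly[m])
    recall = tp / (tp + fn) if (tp + fn) else float("nan")
    precision = tp / (tp + fp) if (tp + fp) else float("nan")

    # MID RMSE over labeled runs
    labeled_run_ids = set(manifest.runs.loc[manifest.runs["t_hours"] > 0, "run_id"])
    obs = mid_table[mid_table["run_id"].isin(labeled_run_ids)]
    merged = obs.merge(
        manifest.mids,
        on=["metabolite_id", "run_id", "isotopologue_index"],
        how="inner",
    )
    nonzero = merged.groupby(["metabolite_id", "run_id"])["labeled_fraction"].transform("sum") > 0
    resid = merged.loc[nonzero, "labeled_fraction"] - merged.loc[nonzero, "true_fraction"]
    mid_rmse = float(np.sqrt(np.mean(resid**2))) if len(resid) else float("nan")

    out = {
        "recall": recall, "precision": precision, "mid_rmse": mid_rmse,
        "n_called": int(sum(calls.values())), "n_truly_labeled": int(sum(truly.values())),
    }
    if fits is not None and len(fits):
        merged_k = fits.merge(
            truth_mets.reset_index()[["metabolite_id", "k"]].rename(columns={"k": "k_true"}),
            on="metabolite_id",
        )
        merged_k = merged_k[merged_k["k_true"] > 0]
        rel = (merged_k["k"] - merged_k["k_true"]).abs() / merged_k["k_true"]
        out["k_relative_error_median"] = float(rel.median()) if len(rel) else float("nan")
        out["k_recovery_table"] = merged_k.assign(k_rel_err=rel)
    return out
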