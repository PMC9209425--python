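"""Labeling-extent and labeling-rate quantification.

The labeling extent of a metabolite is LE = 1 − L_M0, the fraction of
its pool carrying at least one tracer carbon.  Under continuous tracer
feeding LE follows first-order kinetics,

    LE(t) = a·e^(−k·t) − a,   a < 0,

so LE rises from 0 at t = 0 to the plateau −a with apparent first-order
rate constant k (h⁻¹), the incorporation rate of the tracer.  Fit
quality R is the Pearson correlation between observed and fitted LE;
fits with R ≤ 0.8 are flagged unreliable.

Time is in hours throughout this module; conversion from the seconds
used elsewhere happens at the caller's boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import pearsonr

from .quantify import MID

logger = logging.getLogger("isotrace")

R_MIN_RELIABLE = 0.8


@dataclass
class TimeCourse:
    metabolite_id: str
    t: np.ndarray  # hours
    le: np.ndarray  # replicate-mean LE per time point

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.le = np.asarray(self.le, dtype=float)
        if np.any(self.t < 0) or np.any(np.diff(self.t) <= 0):
            raise ValueError("time points must be non-negative and strictly increasing")
        if self.t.shape != self.le.shape:
            raise ValueError("t and LE must have equal length")


@dataclass
class KineticFit:
    metabolite_id: str
    a: float  # a < 0; plateau is −a
    k: float  # h⁻¹
    r: float  # Pearson correlation of observed vs fitted LE
    converged: bool
    reliable: bool = False

    @property
    def plateau(self) -> float:
        return -self.a


def first_order_labeling(t: np.ndarray, a: float, k: float) -> np.ndarray:
    """LE(t) = a·e^(−k·t) − a."""
    return a * np.exp(-k * np.asarray(t, dtype=float)) - a


def labeling_extent(mid: MID) -> float:
    """LE = 1 − L_M0; undefined (NaN) for an all-zero MID."""
    return mid.labeling_extent()


def fit_labeling_rate(tc: TimeCourse, r_min: float = R_MIN_RELIABLE) -> KineticFit:
    """Fit the first-order labeling model to one metabolite's time course.

    Nonlinear least squares with a ∈ (−1, 0), k ≥ 0.  Initialization:
    a₀ = −max(LE); k₀ from a log-linear regression of 1 − LE/plateau
    against t.  Requires ≥ 3 distinct time points.
    """
    if len(np.unique(tc.t)) < 3:
        raise ValueError(f"{tc.metabolite_id}: need >=3 distinct time points")
    le = tc.le
    if np.all(le <= 0) or np.ptp(le) == 0:
        # No labeling signal: non-identifiable.
        return KineticFit(tc.metabolite_id, a=-0.0, k=0.0, r=0.0, converged=False)

    plateau0 = max(float(le.max()), 1e-6)
    a0 = -min(plateau0, 0.999)
    k0 = _k_init(tc.t, le, plateau0)
    try:
        popt, _ = curve_fit(
            first_order_labeling, tc.t, le,
            p0=[a0, k0],
            bounds=([-1.0, 0.0], [-1e-12, np.inf]),
            maxfev=10000,
        )
    except RuntimeError:
        return KineticFit(tc.metabolite_id, a=a0, k=k0, r=0.0, converged=False)
    a, k = float(popt[0]), float(popt[1])
    fitted = first_order_labeling(tc.t, a, k)
    if np.ptp(fitted) == 0 or np.ptp(le) == 0:
        r = 0.0
    else:
        r = float(pearsonr(le, fitted).statistic)
    return KineticFit(tc.metabolite_id, a=a, k=k, r=r, converged=True,
                      reliable=r > r_min)


def _k_init(t: np.ndarray, le: np.ndarray, plateau: float) -> float:
    """Log-linear starting value: ln(1 − LE/plateau) = −k·t."""
    frac = 1.0 - le / (plateau * 1.05)
    mask = (frac > 1e-6) & (t > 0)
    if mask.sum() < 2:
        return 0.1
    slope = np.polyfit(t[mask], np.log(frac[mask]), 1)[0]
    return float(np.clip(-slope, 1e-3, 100.0))


def fit_all(
    le_table: pd.DataFrame, r_min: float = R_MIN_RELIABLE
) -> pd.DataFrame:
    """Fit every metabolite in a long LE table.

    ``le_table`` needs columns (metabolite_id, t_hours, le); replicates at
    the same time point are averaged before fitting.  Returns one row per
    metabolite with (a, k, r, converged, reliable).
    """
    rows = []
    for met, sub in le_table.groupby("metabolite_id", sort=True):
        mean_le = sub.groupby("t_hours")["le"].mean()
        try:
            fit = fit_labeling_rate(
                TimeCourse(str(met), mean_le.index.to_numpy(), mean_le.to_numpy()),
                r_min=r_min,
            )
        except ValueError:
            continue
        rows.append({
            "metabolite_id": str(met), "a": fit.a, "k": fit.k, "r": fit.r,
            "converged": fit.converged, "reliable": fit.reliable,
        })
    return pd.DataFrame(rows)


def summarize_pathway(
    fits: pd.DataFrame,
    le_by_metabolite: pd.Series | dict,
    pathway_map: dict[str, list[str]],
) -> pd.DataFrame:
    """Pathway-level kinetics: median k and mean LE over member metabolites."""
    le = pd.Series(le_by_metabolite, dtype=float)
    k = fits.set_index("metabolite_id")["k"] if len(fits) else pd.Series(dtype=float)
    rows = []
    for pathway, members in pathway_map.items():
        ks = k.reindex(members).dropna()
        les = le.reindex(members).dropna()
        if ks.empty and les.empty:
            continue
        rows.append({
            "pathway_id": pathway,
            "n_members": int(max(len(ks), len(les))),
            "k_median": float(ks.median()) if len(ks) else float("nan"),
            "le_mean": float(les.mean()) if len(les) else float("nan"),
        })
    return pd.DataFrame(rows)


def normalize_to_tracer(
    fractions: pd.Series, tracer_fraction: pd.Series
) -> pd.Series:
    """Divide per-sample labeled fractions by the same-sample tracer fraction.

    Used to express downstream labeling relative to tracer uptake, e.g.
    normalizing to the fully labeled (M+6) fraction of glucose.  Samples
    whose reference fraction is zero or missing come back as NaN and are
    logged.
    """
    ref = tracer_fraction.reindex(fractions.index)
    bad = ref.isna() | (ref <= 0)
    if bad.any():
        logger.warning("normalize_to_tracer: %d sample(s) with zero/missing "
                       "reference fraction set to missing", int(bad.sum()))
    out = fractions / ref.where(~bad)
    return out


def relative_error(le_test: float, le_reference: float) -> float:
    """Signed relative error (test − reference) / reference."""
    if le_reference == 0:
        return float("nan")
    return (le_test - le_reference) / le_reference


def consistency_share(
    le_test: np.ndarray, le_reference: np.ndarray, max_rel_err: float = 0.3
) -> float:
    """Share of metabolites whose |relative error| is within ``max_rel_err``.

    Metabolites with a zero reference LE are excluded from the summary.
    """
    t = np.asarray(le_test, dtype=float)
    r = np.asarray(le_reference, dtype=float)
    mask = r != 0
    if not mask.any():
        return float("nan")
    rel = (t[mask] - r[mask]) / r[mask]
    return float(np.mean(np.abs(rel) <= max_rel_err))


def mid_table_to_le(mid_table: pd.DataFrame, t_hours_by_group: dict[str, float]) -> pd.DataFrame:
    """Turn the long MID table into a long LE table (metabolite, run, t, LE).

    LE per metabolite/run is 1 − the M0 labeled fraction; metabolites whose
    MID is all zero in a run are reported as missing (NaN), not 0.
    """
    rows = []
    for (met, run), sub in mid_table.groupby(["metabolite_id", "run_id"], sort=True):
        group = sub["group"].iloc[0]
        if group not in t_hours_by_group:
            continue
        fr = sub.sort_values("isotopologue_index")["labeled_fraction"].to_numpy()
        le = float("nan") if fr.sum() == 0 else 1.0 - float(fr[0])
        rows.append({
            "metabolite_id": str(met), "run_id": str(run), "group": group,
            "t_hours": float(t_hours_by_group[group]), "le": le,
        })
    return pd.DataFrame(rows)
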