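"""Correction and quantification (workflow step 3).

Each isotopologue peak is quantified as the sum of the three scans
around the group apex; isotopologues without a detected peak are
extracted mandatorily at the theoretical m/z over the group apex.
Measured intensities are then deconvolved against the natural ¹³C
isotope pattern by non-negative least squares to give corrected
intensities and the mass isotopomer distribution (MID).  Finally,
isotope contamination estimated from the unlabeled control samples is
subtracted, and metabolites/isotopologues are called labeled by the
>2 %-in-a-strict-majority-of-samples rule.

Only carbon correction is implemented, under the high-resolution
assumption that isotopologues of other elements are chromatographically
or spectrally resolved away.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import binom

from .extraction import IsotopologueGroup, SampleExtraction
from .raw_io import EIC
from .targets import IsotopologueTarget

#: Natural abundance of ¹³C.
P13C_DEFAULT = 0.0107
#: Labeled fraction above which an isotopologue counts toward labeling /
#: contamination calls.
LABEL_FRACTION_THRESHOLD = 0.02
#: Strict majority of samples required for a call.
MAJORITY = 0.5


@dataclass
class IsotopologueQuant:
    """Raw 3-scan-sum intensities of one metabolite in one run."""

    metabolite_id: str
    run_id: str
    intensities: np.ndarray  # length C+1
    mandatory_flags: np.ndarray  # bool, length C+1
    edge_flags: np.ndarray  # bool, length C+1

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if np.any(self.intensities < 0):
            raise ValueError(f"{self.metabolite_id}/{self.run_id}: negative intensity")


@dataclass
class MID:
    """Mass isotopomer distribution: fractions of M0…MC, summing to 1.

    An all-zero MID (flagged) represents a metabolite zeroed out because
    it was absent or yielded no signal.
    """

    fractions: np.ndarray
    all_zero: bool = False

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.all_zero:
            return
        s = self.fractions.sum()
        if not np.isclose(s, 1.0, atol=1e-9):
            raise ValueError(f"MID fractions sum to {s!r}, expected 1")
        if np.any(self.fractions < -1e-12) or np.any(self.fractions > 1 + 1e-12):
            raise ValueError("MID fractions outside [0, 1]")

    def labeling_extent(self) -> float:
        if self.all_zero:
            return float("nan")
        return 1.0 - float(self.fractions[0])


@dataclass
class ContaminationProfile:
    """Per-metabolite isotope-contamination estimate from unlabeled samples."""

    levels: dict[str, np.ndarray] = field(default_factory=dict)
    absent_in_unlabeled: dict[str, bool] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Intensity extraction
# ---------------------------------------------------------------------------

def apex_intensity(
    eic: EIC, group: IsotopologueGroup, index: int
) -> tuple[float, bool, bool]:
    """3-scan apex-sum intensity of one isotopologue channel.

    Returns (intensity, mandatory_flag, edge_flag).  If the isotopologue
    has a detected peak in the group its own apex is used; otherwise the
    channel is extracted mandatorily at the group apex.  At a grid edge
    the available scans are summed and flagged.
    """
    if len(eic) == 0:
        return 0.0, True, False
    member = group.members.get(index)
    if member is not None:
        apex_rt = member.apex_rt
        mandatory = False
    else:
        apex_rt = group.group_apex_rt
        mandatory = True
        if not np.isfinite(apex_rt):
            return 0.0, True, False
    apex = int(np.argmin(np.abs(eic.rt - apex_rt)))
    lo, hi = apex - 1, apex + 2
    edge = lo < 0 or hi > len(eic)
    lo = max(lo, 0)
    value = float(eic.intensity[lo:hi].sum())
    return value, mandatory, edge


def quantify_group(
    target: IsotopologueTarget,
    group: IsotopologueGroup,
    eics: list[EIC],
    run_id: str,
) -> IsotopologueQuant:
    """Quantify all isotopologues of one metabolite in one run."""
    n = target.n_isotopologues
    intens = np.zeros(n)
    mand = np.zeros(n, dtype=bool)
    edge = np.zeros(n, dtype=bool)
    for i in range(n):
        intens[i], mand[i], edge[i] = apex_intensity(eics[i], group, i)
    return IsotopologueQuant(
        metabolite_id=target.metabolite_id, run_id=run_id,
        intensities=intens, mandatory_flags=mand, edge_flags=edge,
    )


# ---------------------------------------------------------------------------
# Natural-abundance correction
# ---------------------------------------------------------------------------

def natural_abundance_matrix(
    carbon_count: int, p13: float = P13C_DEFAULT, purity: float = 1.0
) -> np.ndarray:
    """(C+1)×(C+1) convolution matrix mapping true label counts to measured ones.

    Column j is the isotope pattern of a species with j tracer-labeled
    carbons: the binomial distribution of extra mass from natural ¹³C among
    the C−j unlabeled carbons, convolved (when tracer purity < 1) with the
    binomial number of the j label positions that actually carry ¹³C.
    Columns sum to 1.
    """
    if not 0 <= p13 < 1:
        raise ValueError("p13 must be in [0, 1)")
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    c = carbon_count
    a = np.zeros((c + 1, c + 1))
    for j in range(c + 1):
        nat = binom.pmf(np.arange(c - j + 1), c - j, p13)
        if purity < 1.0 and j > 0:
            lab = binom.pmf(np.arange(j + 1), j, purity)
            col = np.convolve(lab, nat)
        else:
            col = np.zeros(c + 1)
            col[j: j + len(nat)] = nat
        a[: len(col), j] = col[: c + 1]
    return a


def correct_natural_abundance(
    raw: IsotopologueQuant | np.ndarray,
    p13: float = P13C_DEFAULT,
    purity: float = 1.0,
) -> tuple[np.ndarray, MID]:
    """Deconvolve natural ¹³C abundance from measured intensities.

    Solves min ‖A·x − raw‖₂ subject to x ≥ 0 and normalizes x to the MID.
    An all-zero input gives an all-zero, flagged MID.
    """
    y = raw.intensities if isinstance(raw, IsotopologueQuant) else np.asarray(raw, float)
    c = len(y) - 1
    a = natural_abundance_matrix(c, p13=p13, purity=purity)
    x, _ = nnls(a, y)
    total = x.sum()
    if total <= 0:
        return x, MID(np.zeros(c + 1), all_zero=True)
    return x, MID(x / total)


# ---------------------------------------------------------------------------
# Contamination estimation and correction
# ---------------------------------------------------------------------------

def estimate_contamination(
    unlabeled_mids: dict[str, dict[str, MID]],
    unlabeled_quants: dict[str, dict[str, IsotopologueQuant]] | None = None,
    threshold: float = LABEL_FRACTION_THRESHOLD,
    majority: float = MAJORITY,
) -> ContaminationProfile:
    """Estimate per-isotopologue isotope contamination from unlabeled runs.

    ``unlabeled_mids`` maps metabolite_id → run_id → MID.  An isotopologue
    (except M0) is contaminated when its labeled fraction exceeds the
    threshold in strictly more than ``majority`` of the unlabeled samples;
    its level is the mean fraction over those runs.  A metabolite whose M0
    raw intensity is zero in strictly more than half of the unlabeled
    samples is flagged absent.
    """
    profile = ContaminationProfile()
    for met, per_run in unlabeled_mids.items():
        mids = list(per_run.values())
        if not mids:
            continue
        n_runs = len(mids)
        length = len(mids[0].fractions)
        fractions = np.vstack([m.fractions for m in mids])
        levels = np.zeros(length)
        for i in range(1, length):
            n_exceed = int(np.sum(fractions[:, i] > threshold))
            if n_exceed > majority * n_runs:
                levels[i] = float(fractions[:, i].mean())
        profile.levels[met] = levels
        absent = False
        if unlabeled_quants is not None and met in unlabeled_quants:
            m0 = np.array([q.intensities[0] for q in unlabeled_quants[met].values()])
            absent = int(np.sum(m0 == 0)) > majority * len(m0)
        profile.absent_in_unlabeled[met] = absent
    return profile


def apply_contamination_correction(
    mid: MID, metabolite_id: str, profile: ContaminationProfile
) -> MID:
    """Subtract estimated contamination from a labeled-sample MID.

    Contaminated fractions are reduced by the estimated level (clamped at
    zero); the subtracted mass is returned to M0 so the MID still sums
    to 1.  Metabolites absent from the unlabeled samples are zeroed out
    entirely.  The operation is idempotent for the absent case and clamps
    rather than oscillates otherwise.
    """
    if profile.absent_in_unlabeled.get(metabolite_id, False):
        return MID(np.zeros_like(mid.fractions), all_zero=True)
    if mid.all_zero:
        return mid
    levels = profile.levels.get(metabolite_id)
    if levels is None or not np.any(levels > 0):
        return mid
    frac = mid.fractions.copy()
    removed = 0.0
    for i in np.flatnonzero(levels > 0):
        take = min(frac[i], levels[i])
        frac[i] -= take
        removed += take
    frac[0] += removed
    return MID(frac)


# ---------------------------------------------------------------------------
# Labeled-metabolite calling
# ---------------------------------------------------------------------------

def call_labeled(
    mids: dict[str, MID],
    threshold: float = LABEL_FRACTION_THRESHOLD,
    majority: float = MAJORITY,
) -> tuple[bool, np.ndarray]:
    """Call a metabolite labeled from the MIDs of one labeled group.

    ``mids`` maps run_id → MID.  An isotopologue (except M0) is labeled
    when its fraction exceeds the threshold in strictly more than
    ``majority`` of the runs; the metabolite is labeled when at least one
    non-M0 isotopologue is.
    Returns (metabolite_labeled, per-isotopologue bool flags).
    """
    values = list(mids.values())
    if not values:
        raise ValueError("no MIDs supplied")
    n_runs = len(values)
    length = len(values[0].fractions)
    fractions = np.vstack([m.fractions for m in values])
    flags = np.zeros(length, dtype=bool)
    for i in range(1, length):
        flags[i] = int(np.sum(fractions[:, i] > threshold)) > majority * n_runs
    return bool(flags.any()), flags


# ---------------------------------------------------------------------------
# Pipeline orchestration: extraction results -> MID table
# ---------------------------------------------------------------------------

def quantify_samples(
    extractions: dict[str, SampleExtraction],
    targets: list[IsotopologueTarget],
    groups_by_run: dict[str, str],
    unlabeled_group: str = "unlabeled",
    p13: float = P13C_DEFAULT,
    purity: float = 1.0,
    correct_contamination: bool = True,
    threshold: float = LABEL_FRACTION_THRESHOLD,
    majority: float = MAJORITY,
) -> pd.DataFrame:
    """Run step 3 over all extracted samples and build the long MID table.

    ``groups_by_run`` maps run_id → experimental group; runs in
    ``unlabeled_group`` drive the contamination estimate, which is then
    applied to every labeled run when ``correct_contamination`` is on.
    """
    target_by_id = {t.metabolite_id: t for t in targets}
    quants: dict[str, dict[str, IsotopologueQuant]] = {}
    mids: dict[str, dict[str, MID]] = {}
    totals: dict[str, dict[str, float]] = {}
    for run_id, extr in extractions.items():
        for met, group in extr.groups.items():
            target = target_by_id[met]
            q = quantify_group(target, group, extr.eics[met], run_id)
            x, mid = correct_natural_abundance(q, p13=p13, purity=purity)
            quants.setdefault(met, {})[run_id] = q
            mids.setdefault(met, {})[run_id] = mid
            totals.setdefault(met, {})[run_id] = float(x.sum())

    unlabeled_runs = [r for r, g in groups_by_run.items() if g == unlabeled_group]
    profile = ContaminationProfile()
    if correct_contamination and unlabeled_runs:
        unl_mids = {
            met: {r: m for r, m in per_run.items() if r in set(unlabeled_runs)}
            for met, per_run in mids.items()
        }
        unl_quants = {
            met: {r: q for r, q in per_run.items() if r in set(unlabeled_runs)}
            for met, per_run in quants.items()
        }
        profile = estimate_contamination(
            unl_mids, unl_quants, threshold=threshold, majority=majority
        )

    rows = []
    for met, per_run in mids.items():
        levels_known = met in profile.levels
        for run_id, mid in per_run.items():
            out = mid
            if correct_contamination and levels_known and groups_by_run.get(run_id) != unlabeled_group:
                out = apply_contamination_correction(mid, met, profile)
            total = totals[met][run_id]
            for i, frac in enumerate(out.fractions):
                rows.append({
                    "metabolite_id": met,
                    "isotopologue_index": i,
                    "run_id": run_id,
                    "group": groups_by_run.get(run_id, ""),
                    "corrected_intensity": 0.0 if out.all_zero else float(frac * total),
                    "labeled_fraction": float(frac),
                })
    return pd.DataFrame(rows)
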