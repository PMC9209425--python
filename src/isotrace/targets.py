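"""Isotopologue target-list generation (workflow step 1).

For every annotated metabolite the theoretical m/z of all possible
¹³C-isotopologues (M0…MC, C = carbons of the neutral molecule) is
computed from the elemental formula and adduct, and a reference
"target EIC" — retention time plus chromatographic peak shape of the
monoisotopic ion — is selected from the unlabeled control samples.
The labeled-sample extraction stage is anchored on these targets.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
from pyteomics import mass as _pt_mass

from .raw_io import (
    ADDUCT_SHIFTS,
    EIC,
    AnnotationRecord,
    FeatureRecord,
    RawRun,
    extract_eic,
    normalize_adduct,
)

logger = logging.getLogger("isotrace")

#: ¹³C–¹²C mass difference, Da.  Fixed: isotopologue series are spaced by
#: exactly this value, which holds at the 25 ppm extraction tolerance.
C13_MASS_DIFF = 1.003355


class FormulaError(ValueError):
    """Raised when an elemental formula cannot be parsed."""


class AdductError(ValueError):
    """Raised for unknown adducts or adduct/polarity mismatches."""


@dataclass(frozen=True)
class ElementalComposition:
    """Element → count map of a neutral molecule."""

    counts: tuple[tuple[str, int], ...]

    @property
    def carbon_count(self) -> int:
        return dict(self.counts).get("C", 0)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)


@dataclass
class IsotopologueTarget:
    """One metabolite's full M0…MC target set with its reference peak."""

    metabolite_id: str
    formula: str
    adduct: str
    carbon_count: int
    mz_series: np.ndarray  # Da, length C+1
    target_rt: float  # seconds, apex of the reference peak
    target_rt_bounds: tuple[float, float]  # seconds
    target_shape: EIC  # reference M0 peak from the best unlabeled run
    source_run_id: str
    shared_signal_with: list[str] = field(default_factory=list)

    @property
    def n_isotopologues(self) -> int:
        return len(self.mz_series)


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
_KNOWN_ELEMENTS = set(_pt_mass.nist_mass.keys())


def parse_formula(formula: str) -> ElementalComposition:
    """Parse a Hill-notation elemental formula (no charges or brackets).

    >>> parse_formula("C6H12O6").as_dict()
    {'C': 6, 'H': 12, 'O': 6}
    """
    formula = formula.strip()
    if not formula:
        raise FormulaError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(formula):
        m = _FORMULA_TOKEN.match(formula, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(f"cannot parse {formula!r} at position {pos}")
        element, digits = m.groups()
        if element not in _KNOWN_ELEMENTS:
            raise FormulaError(f"unknown element {element!r} at position {pos} in {formula!r}")
        n = int(digits) if digits else 1
        if n < 1:
            raise FormulaError(f"count {n} for {element!r} in {formula!r}")
        counts[element] = counts.get(element, 0) + n
        pos = m.end()
    return ElementalComposition(counts=tuple(sorted(counts.items())))


def monoisotopic_mass(comp: ElementalComposition) -> float:
    """Monoisotopic (most abundant isotope) mass of the neutral molecule, Da."""
    return float(_pt_mass.calculate_mass(composition=_pt_mass.Composition(comp.as_dict())))


def isotopologue_mz_series(
    comp: ElementalComposition, adduct: str, polarity: str | None = None
) -> np.ndarray:
    """Theoretical m/z of M0…MC for a singly charged adduct ion.

    M0 is the monoisotopic neutral mass shifted by the adduct; Mi adds
    i × 1.003355 Da.  The carbon count is that of the NEUTRAL metabolite:
    only carbon-free adducts are in the vocabulary, so adduct carbons
    never enter the series.
    """
    adduct = normalize_adduct(adduct)
    if adduct not in ADDUCT_SHIFTS:
        raise AdductError(f"unsupported adduct {adduct!r}")
    shift, adduct_pol = ADDUCT_SHIFTS[adduct]
    if polarity is not None and polarity != adduct_pol:
        raise AdductError(f"adduct {adduct!r} is {adduct_pol} but run polarity is {polarity}")
    m0 = monoisotopic_mass(comp) + shift
    c = comp.carbon_count
    return m0 + C13_MASS_DIFF * np.arange(c + 1)


def build_target_list(
    annotations: list[AnnotationRecord],
    features: list[FeatureRecord],
    unlabeled_runs: list[RawRun],
) -> list[IsotopologueTarget]:
    """Select each metabolite's reference peak and attach its m/z series.

    The M0 EIC is extracted from every unlabeled run over the feature's RT
    bounds; the run with the highest apex supplies the reference shape, RT
    and bounds (ties broken by lexicographic run id).  Metabolites whose M0
    is absent from all unlabeled runs are dropped and logged.  Annotations
    sharing m/z (within tolerance) and overlapping RT bounds are emitted as
    separate targets but cross-tagged as shared-signal isomers.
    """
    feature_by_id = {f.feature_id: f for f in features}
    targets: list[IsotopologueTarget] = []
    for ann in annotations:
        if ann.feature_id not in feature_by_id:
            raise KeyError(
                f"annotation {ann.metabolite_id!r}: feature {ann.feature_id!r} not in feature table"
            )
        feat = feature_by_id[ann.feature_id]
        comp = parse_formula(ann.formula)
        series = isotopologue_mz_series(comp, ann.adduct)
        best: tuple[float, str, EIC] | None = None
        for run in sorted(unlabeled_runs, key=lambda r: r.run_id):
            eic = extract_eic(run, float(series[0]), (feat.rt_min, feat.rt_max))
            apex = float(eic.intensity.max()) if len(eic) else 0.0
            if apex > 0 and (best is None or apex > best[0]):
                best = (apex, run.run_id, eic)
        if best is None:
            logger.warning(
                "metabolite %s: M0 EIC empty in all unlabeled runs; dropped", ann.metabolite_id
            )
            continue
        _, run_id, shape = best
        apex_rt = float(shape.rt[int(np.argmax(shape.intensity))])
        targets.append(
            IsotopologueTarget(
                metabolite_id=ann.metabolite_id,
                formula=ann.formula,
                adduct=ann.adduct,
                carbon_count=comp.carbon_count,
                mz_series=series,
                target_rt=apex_rt,
                target_rt_bounds=(feat.rt_min, feat.rt_max),
                target_shape=shape,
                source_run_id=run_id,
            )
        )
    _tag_shared_signal(targets)
    return targets


def _tag_shared_signal(targets: list[IsotopologueTarget]) -> None:
    """Cross-tag isomer targets whose M0 windows and RT bounds overlap."""
    from .raw_io import mz_tolerance

    for i, a in enumerate(targets):
        for b in targets[i + 1:]:
            mz_close = abs(a.mz_series[0] - b.mz_series[0]) <= mz_tolerance(float(a.mz_series[0]))
            rt_overlap = (a.target_rt_bounds[0] <= b.target_rt_bounds[1]
                          and b.target_rt_bounds[0] <= a.target_rt_bounds[1])
            if mz_close and rt_overlap:
                a.shared_signal_with.append(b.metabolite_id)
                b.shared_signal_with.append(a.metabolite_id)


def targets_to_frame(targets: list[IsotopologueTarget]):
    """Serialize a target list to a DataFrame, one row per isotopologue."""
    import pandas as pd

    rows = []
    for t in targets:
        for i, mz in enumerate(t.mz_series):
            rows.append({
                "metabolite_id": t.metabolite_id,
                "isotopologue_index": i,
                "mz": float(mz),
                "target_rt": t.target_rt,
                "rt_min": t.target_rt_bounds[0],
                "rt_max": t.target_rt_bounds[1],
                "source_run_id": t.source_run_id,
                "shared_signal": ";".join(t.shared_signal_with),
            })
    return pd.DataFrame(rows)
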