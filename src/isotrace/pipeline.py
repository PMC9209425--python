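"""End-to-end orchestration: raw runs + annotations → MID table.

Ties the three workflow steps together: target-list generation from the
unlabeled control runs, targeted isotopologue extraction in every run,
and correction/quantification down to the long-format MID table.
"""

from __future__ import annotations

import pandas as pd

from .extraction import ExtractionConfig, extract_sample
from .quantify import (
    LABEL_FRACTION_THRESHOLD,
    MAJORITY,
    P13C_DEFAULT,
    quantify_samples,
)
from .raw_io import AnnotationRecord, FeatureRecord, RawRun
from .targets import IsotopologueTarget, build_target_list


def run_pipeline(
    runs: dict[str, RawRun],
    groups_by_run: dict[str, str],
    annotations: list[AnnotationRecord],
    features: list[FeatureRecord],
    unlabeled_group: str = "unlabeled",
    config: ExtractionConfig = ExtractionConfig(),
    p13: float = P13C_DEFAULT,
    purity: float = 1.0,
    correct_contamination: bool = True,
    threshold: float = LABEL_FRACTION_THRESHOLD,
    majority: float = MAJORITY,
) -> tuple[pd.DataFrame, list[IsotopologueTarget]]:
    """Run the full workflow and return (MID table, target list).

    ``runs`` maps run_id → RawRun and ``groups_by_run`` assigns each run
    to an experimental group; the runs in ``unlabeled_group`` both anchor
    the target list and drive contamination estimation.
    """
    unlabeled = [runs[r] for r, g in groups_by_run.items() if g == unlabeled_group]
    if not unlabeled:
        raise ValueError(f"no runs in unlabeled group {unlabeled_group!r}")
    targets = build_target_list(annotations, features, unlabeled)
    extractions = {
        run_id: extract_sample(run, targets, config) for run_id, run in sorted(runs.items())
    }
    mid_table = quantify_samples(
        extractions, targets, groups_by_run,
        unlabeled_group=unlabeled_group, p13=p13, purity=purity,
        correct_contamination=correct_contamination,
        threshold=threshold, majority=majority,
    )
    return mid_table, targets
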