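"""Shared fixtures: small ground-truthed scenarios run end to end once."""

from __future__ import annotations

import numpy as np
import pytest

from isotrace import synthetic_data as syn
from isotrace.pipeline import run_pipeline


@pytest.fixture(scope="session")
def small_scenario():
    """Mixed 8-metabolite time course with realistic noise, 3 replicates."""
    spec = syn.timecourse_scenario(
        n_metabolites=8, seed=3, replicates=3,
        time_points_h=(0.0, 1.0, 3.0, 6.0, 12.0, 24.0),
    )
    manifest = syn.generate_scenario(spec)
    runs = syn.render_runs(manifest, spec)
    return spec, manifest, runs


@pytest.fixture(scope="session")
def small_pipeline(small_scenario):
    spec, manifest, runs = small_scenario
    groups = dict(zip(manifest.runs.run_id, manifest.runs.group))
    mid_table, targets = run_pipeline(
        runs, groups,
        syn.scenario_annotations(spec),
        syn.scenario_features(spec),
    )
    return spec, manifest, runs, mid_table, targets


@pytest.fixture(scope="session")
def unlabeled_contaminated():
    """Noise-free unlabeled-only design with one planted contaminant (M1 at 5%)."""
    spec = syn.unlabeled_scenario(
        n_metabolites=10, seed=7, replicates=4,
        contaminants={"M0003": {1: 0.05}},
    )
    manifest = syn.generate_scenario(spec)
    runs = syn.render_runs(manifest, spec)
    return spec, manifest, runs


def pipeline_mids_by_group(mid_table, group):
    """Collect run→MID maps per metabolite for one experimental group."""
    from isotrace.quantify import MID

    sub = mid_table[mid_table["group"] == group]
    out: dict[str, dict[str, MID]] = {}
    for (met, run), per in sub.groupby(["metabolite_id", "run_id"]):
        fr = per.sort_values("isotopologue_index")["labeled_fraction"].to_numpy()
        out.setdefault(str(met), {})[str(run)] = MID(fr, all_zero=bool(fr.sum() == 0))
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
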