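"""Peak detection, peak-shape correlation and isotopologue grouping."""

import numpy as np
import pytest
from scipy.stats import pearsonr

from isotrace.extraction import (
    PeakCandidate,
    detect_isotopologue_peaks,
    group_and_select,
    ppc_score,
)
from isotrace.raw_io import EIC
from isotrace.targets import IsotopologueTarget


def gaussian_eic(apex_rt=60.0, sigma=3.0, height=5000.0, noise_level=0.0,
                 span=60.0, dt=0.5, seed=0, mz=200.0):
    rng = np.random.default_rng(seed)
    rt = np.arange(apex_rt - span, apex_rt + span, dt)
    y = height * np.exp(-((rt - apex_rt) ** 2) / (2 * sigma**2))
    if noise_level > 0:
        y = y + rng.exponential(noise_level, len(rt))
    return EIC(mz_center=mz, mz_tol=0.01, rt=rt, intensity=y, run_id="r")


def make_target(rt=60.0, sigma=3.0):
    shape = gaussian_eic(apex_rt=rt, sigma=sigma, span=12.0)
    return IsotopologueTarget(
        metabolite_id="m", formula="C6H12O6", adduct="[M-H]-", carbon_count=6,
        mz_series=np.arange(7) * 1.003355 + 179.0561,
        target_rt=rt, target_rt_bounds=(rt - 12, rt + 12),
        target_shape=shape, source_run_id="u1",
    )


class TestDetect:
    def test_single_gaussian_recovered(self):
        eic = gaussian_eic(height=5000.0, noise_level=100.0, seed=1)
        cands = detect_isotopologue_peaks(eic)
        assert len(cands) == 1
        assert cands[0].apex_rt == pytest.approx(60.0, abs=0.5)
        lo, hi = cands[0].rt_bounds
        assert lo < 60.0 < hi

    def test_pure_noise_rejected_by_snr(self):
        rng = np.random.default_rng(4)
        rt = np.arange(0, 60, 0.5)
        y = rng.exponential(100.0, len(rt))
        y = np.clip(y, 0, 220.0)  # max S/N below 3 relative to the median floor
        eic = EIC(200.0, 0.01, rt, y)
        assert detect_isotopologue_peaks(eic) == []

    def test_two_separated_gaussians(self):
        rt = np.arange(30, 120, 0.5)
        y = (5000 * np.exp(-((rt - 60) ** 2) / 18.0)
             + 4000 * np.exp(-((rt - 80) ** 2) / 18.0)
             + np.random.default_rng(2).exponential(50.0, len(rt)))
        eic = EIC(200.0, 0.01, rt, y)
        cands = detect_isotopologue_peaks(eic)
        apexes = sorted(c.apex_rt for c in cands)
        assert len(cands) == 2
        assert apexes[0] == pytest.approx(60.0, abs=1.0)
        assert apexes[1] == pytest.approx(80.0, abs=1.0)

    def test_all_zero_eic(self):
        rt = np.arange(0, 60, 0.5)
        assert detect_isotopologue_peaks(EIC(200.0, 0.01, rt, np.zeros_like(rt))) == []

    def test_apex_within_one_scan_on_noiseless_peak(self):
        """Strong noiseless peaks are located to within one scan interval."""
        for apex in (50.0, 61.3, 75.7):
            eic = gaussian_eic(apex_rt=apex, height=1e5)
            cands = detect_isotopologue_peaks(eic)
            assert len(cands) >= 1
            best = min(cands, key=lambda c: abs(c.apex_rt - apex))
            assert abs(best.apex_rt - apex) <= 0.5


class TestPPC:
    def test_identical_shapes_shifted_apex(self):
        a = gaussian_eic(apex_rt=60.0, span=12.0)
        b = gaussian_eic(apex_rt=75.0, span=12.0)
        cand = PeakCandidate(0, apex_rt=75.0, rt_bounds=(63.0, 87.0),
                             apex_height=5000.0, snr=100.0)
        assert ppc_score(cand, b, a) == pytest.approx(1.0, abs=1e-6)

    def test_negated_shape(self):
        a = gaussian_eic(apex_rt=60.0, span=12.0)
        b = EIC(a.mz_center, a.mz_tol, a.rt, -a.intensity, "r")
        cand = PeakCandidate(0, apex_rt=60.0, rt_bounds=(48.0, 72.0),
                             apex_height=5000.0, snr=100.0)
        assert ppc_score(cand, b, a) == pytest.approx(-1.0, abs=1e-6)

    def test_wide_vs_narrow_matches_bruteforce(self):
        """Score of unequal widths reproduces an independent implementation."""
        narrow = gaussian_eic(apex_rt=60.0, sigma=3.0, span=50.0)
        wide = gaussian_eic(apex_rt=60.0, sigma=12.0, span=50.0)
        cand = PeakCandidate(0, apex_rt=60.0, rt_bounds=(10.0, 110.0),
                             apex_height=5000.0, snr=100.0)
        got = ppc_score(cand, narrow, wide)
        assert 0.0 < got < 1.0

        # independent straight-line oracle of the same definition
        step = 0.5
        lo = min(10.0 - 60.0, wide.rt[0] - 60.0)
        hi = max(110.0 - 60.0, wide.rt[-1] - 60.0)
        grid = np.arange(lo, hi + step / 2, step)
        a = np.interp(grid, narrow.rt - 60.0, narrow.intensity, left=0, right=0)
        b = np.interp(grid, wide.rt - 60.0, wide.intensity, left=0, right=0)
        expected = pearsonr(a, b).statistic
        assert got == pytest.approx(expected, abs=1e-9)

    def test_constant_vector_flagged_zero(self):
        flat = EIC(200.0, 0.01, np.arange(0, 20, 0.5),
                   np.full(40, 7.0), "r")
        target = gaussian_eic(apex_rt=10.0, span=10.0)
        cand = PeakCandidate(0, apex_rt=10.0, rt_bounds=(5.0, 15.0),
                             apex_height=7.0, snr=10.0)
        assert ppc_score(cand, flat, target) == 0.0
        assert cand.constant_ppc_flag


def _cand(idx, rt, height=1000.0):
    return PeakCandidate(idx, apex_rt=rt, rt_bounds=(rt - 6, rt + 6),
                         apex_height=height, snr=50.0)


class TestGroupAndSelect:
    def test_three_apex_clustering(self):
        """{100.0, 101.5, 106.0} splits into {100.0, 101.5} and {106.0}."""
        cands = [_cand(0, 100.0), _cand(1, 101.5), _cand(2, 106.0)]
        target = make_target(rt=101.0)
        group = group_and_select(cands, target)
        assert set(group.members) == {0, 1}
        assert group.apex_spread <= 3.0

    def test_single_candidate_forms_group(self):
        target = make_target(rt=60.0)
        group = group_and_select([_cand(2, 61.0)], target)
        assert set(group.members) == {2}
        assert group.group_apex_rt == 61.0

    def test_equidistant_tie_goes_to_taller_peak(self):
        cands = [_cand(0, 95.0, height=500.0), _cand(1, 105.0, height=2000.0)]
        target = make_target(rt=100.0)
        group = group_and_select(cands, target)
        assert set(group.members) == {1}

    def test_no_candidates_gives_empty_group(self):
        group = group_and_select([], make_target())
        assert not group

    def test_bounds_readjusted_to_tallest_member(self):
        cands = [_cand(0, 100.0, height=500.0), _cand(3, 101.0, height=9000.0)]
        target = make_target(rt=100.0)
        group = group_and_select(cands, target)
        assert group.group_apex_rt == 101.0
        assert group.rt_bounds == (95.0, 107.0)

    def test_ppc_filter_is_monotone(self):
        """Lowering the PPC threshold never removes previously kept peaks."""
        rng = np.random.default_rng(5)
        target = make_target(rt=60.0)
        cands = []
        for i in range(12):
            c = _cand(i % 4, 55.0 + rng.uniform(-10, 10))
            c.ppc = rng.uniform(-1, 1)
            cands.append(c)
        kept_strict = {id(c) for c in cands if c.ppc >= 0.8}
        kept_loose = {id(c) for c in cands if c.ppc >= 0.6}
        assert kept_strict <= kept_loose


class TestExtractSample:
    def test_apex_spread_bound_on_all_outputs(self, small_pipeline):
        """Every selected group satisfies the 3 s apex-spread guarantee."""
        from isotrace.extraction import extract_sample

        spec, manifest, runs, _, targets = small_pipeline
        run = runs[sorted(runs)[0]]
        result = extract_sample(run, targets)
        assert any(result.groups.values())
        for group in result.groups.values():
            assert group.apex_spread <= 3.0 + 1e-9

    def test_highly_labeled_metabolite_anchored_on_heavy_isotopologue(self):
        """With M0 near noise the tallest member is a heavy isotopologue."""
        from isotrace import synthetic_data as syn
        from isotrace.extraction import extract_sample
        from isotrace.targets import build_target_list

        met = syn.MetaboliteSpec("hl", "hot", "C6H12O6", "[M-H]-", rt=200.0,
                                 base_intensity=5e5, a=-0.99, k=2.0)
        spec = syn.ScenarioSpec(metabolites=[met], time_points_h=(24.0,),
                                replicates=1, unlabeled_replicates=2, seed=11)
        manifest = syn.generate_scenario(spec)
        runs = syn.render_runs(manifest, spec)
        unl = [runs[r] for r in runs if r.startswith("unlabeled")]
        targets = build_target_list(syn.scenario_annotations(spec),
                                    syn.scenario_features(spec), unl)
        labeled_run = runs[[r for r in runs if r.startswith("t24h")][0]]
        result = extract_sample(labeled_run, targets)
        group = result.groups["hl"]
        assert group
        tallest = max(group.members.values(), key=lambda c: c.apex_height)
        assert tallest.isotopologue_index == 6

    def test_run_without_metabolite_gives_empty_group(self, small_pipeline):
        from isotrace.extraction import extract_sample
        from isotrace.raw_io import RawRun, Scan

        *_, targets = small_pipeline
        rts = np.arange(100.0, 1500.0, 5.0)
        blank = RawRun("blank", "negative",
                       [Scan(rt, np.array([999.0]), np.array([1.0])) for rt in rts])
        result = extract_sample(blank, targets[:3])
        assert not any(result.groups.values())
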