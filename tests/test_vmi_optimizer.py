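"""Pair enumeration, RMSE scoring, ranking and robustness summaries."""

import numpy as np
import pandas as pd
import pytest

from dectspr import noise_range_analysis as nr
from dectspr import phantom_sim as ps
from dectspr import physics_core as pc
from dectspr import vmi_optimizer as vo


class TestEnumeratePairs:
    def test_full_grid_yields_5050_pairs(self):
        assert len(vo.enumerate_pairs(40, 140, 1)) == 5050

    def test_three_point_grid_yields_three_pairs(self):
        assert vo.enumerate_pairs(40, 42, 1) == [(40.0, 41.0), (40.0, 42.0), (41.0, 42.0)]

    def test_single_energy_raises(self):
        with pytest.raises(ValueError):
            vo.enumerate_pairs(60, 60, 1)

    @pytest.mark.parametrize("k", [2, 5, 11])
    def test_pair_count_formula(self, k):
        pairs = vo.enumerate_pairs(40, 40 + k - 1, 1)
        assert len(pairs) == k * (k - 1) // 2


class TestClassification:
    def test_density_and_ean_rules(self, tissues):
        classes = vo.classify_tissues(tissues)
        assert classes["lung_inflated"] == "lung"
        assert classes["cortical_bone"] == "bone"
        assert classes["skeletal_muscle_2"] == "soft"

    def test_rules_are_configurable(self, tissues):
        classes = vo.classify_tissues(tissues, lung_density_max=1.0)
        assert classes["adipose_3"] == "lung"  # density 0.93 < 1.0


@pytest.fixture(scope="module")
def small_scorer(tissues, basis):
    energies = np.arange(40.0, 141.0, 10.0)
    return vo.PairScorer(tissues, basis, energies_keV=energies), energies


class TestTheoreticalScoring:
    def test_rmse_symmetric_in_pair_order(self, small_scorer):
        scorer, _ = small_scorer
        a = scorer.rmse((50.0, 100.0), "soft")
        b = scorer.rmse((100.0, 50.0), "soft")
        assert a == pytest.approx(b, abs=1e-6)

    def test_water_like_tissue_maps_accurately(self, basis):
        scorer = vo.PairScorer(
            {"water": pc.water()}, basis, energies_keV=(60.0, 100.0),
            classes={"water": "soft"},
        )
        spr, truth = scorer.map_class((60.0, 100.0), "soft")
        assert spr[0] == pytest.approx(truth[0], abs=0.01)

    def test_majority_of_pairs_reach_one_percent_for_soft_tissue(self, small_scorer):
        scorer, energies = small_scorer
        pairs = [(float(a), float(b)) for i, a in enumerate(energies)
                 for b in energies[i + 1:]]
        rmse = scorer.rmse_many(pairs, "soft")
        assert np.mean(rmse <= 1.0) > 0.5

    def test_empty_class_raises(self, basis):
        scorer = vo.PairScorer(
            {"water": pc.water()}, basis, energies_keV=(60.0, 100.0),
            classes={"water": "soft"},
        )
        with pytest.raises(ValueError):
            scorer.rmse((60.0, 100.0), "bone")


@pytest.fixture(scope="module")
def tiny_phantom_rois(inserts):
    spec = ps.PhantomSpec(
        "tiny", (70.0, 70.0), 30.0,
        inserts=(
            ps.InsertSpec("breast", (-35.0, 0.0)),
            ps.InsertSpec("muscle", (35.0, 0.0)),
        ),
    )
    phantom = ps.build_phantom(spec)
    rois = []
    for name in ("breast", "muscle"):
        cx, cy = phantom.insert_center_mm(name)
        mask = nr.cylinder_roi_mask(
            phantom.labels.shape, phantom.spacing_mm, (cx, cy, 15.0),
            height_mm=20.0,
            origin_mm=(phantom.origin_mm[0], phantom.origin_mm[1], 1.25),
        )
        rois.append((mask, inserts[name]))
    return phantom, rois


class TestMeasuredScoring:
    PAIR = (60.0, 100.0)

    def _acquire(self, phantom, seed, noise):
        acq = ps.AcquisitionSpec(
            ctdivol_mGy=10.0, vmi_keV=self.PAIR, include_native=False,
            repeats=1, base_seed=seed, noise=noise,
        )
        return ps.simulate_acquisition(phantom, acq, 0)

    def test_noise_free_measurement_matches_theory_on_the_inserts(
        self, tiny_phantom_rois, basis, inserts
    ):
        phantom, rois = tiny_phantom_rois
        ch = self._acquire(phantom, 0, ps.NoiseModel(0, 0, 0, 0))
        measured = vo.pair_rmse_measured(self.PAIR, ch, rois, basis)
        scorer = vo.PairScorer(
            {"breast": inserts["breast"], "muscle": inserts["muscle"]},
            basis, energies_keV=self.PAIR,
            classes={"breast": "soft", "muscle": "soft"},
        )
        assert measured == pytest.approx(scorer.rmse(self.PAIR, "soft"), abs=0.1)

    def test_different_seeds_give_different_rmse(self, tiny_phantom_rois, basis):
        phantom, rois = tiny_phantom_rois
        r1 = vo.pair_rmse_measured(
            self.PAIR, self._acquire(phantom, 1, ps.NoiseModel()), rois, basis
        )
        r2 = vo.pair_rmse_measured(
            self.PAIR, self._acquire(phantom, 2, ps.NoiseModel()), rois, basis
        )
        assert r1 != r2

    def test_zero_noise_repeats_are_identical(self, tiny_phantom_rois, basis):
        phantom, rois = tiny_phantom_rois
        quiet = ps.NoiseModel(0, 0, 0, 0)
        r1 = vo.pair_rmse_measured(self.PAIR, self._acquire(phantom, 1, quiet), rois, basis)
        r2 = vo.pair_rmse_measured(self.PAIR, self._acquire(phantom, 2, quiet), rois, basis)
        assert r1 == r2

    def test_missing_energy_raises(self, tiny_phantom_rois, basis):
        phantom, rois = tiny_phantom_rois
        ch = self._acquire(phantom, 0, ps.NoiseModel(0, 0, 0, 0))
        with pytest.raises(KeyError):
            vo.pair_rmse_measured((60.0, 120.0), ch, rois, basis)


class TestSelectOptimal:
    PAIRS = [(50.0, 60.0), (50.0, 70.0), (60.0, 70.0)]

    def test_single_repeat_ordering(self):
        theo = {"soft": np.array([0.5, 1.0, 3.0])}  # third pair excluded at 2%
        meas = {"soft": np.array([[[0.5, 1.0, 0.1]]])}
        assignment, summary = vo.select_optimal(self.PAIRS, theo, meas)
        assert assignment["soft"] == self.PAIRS[0]
        df = summary["soft"]
        assert df.loc[0, "times_ranked_first"] == 1
        assert bool(df.loc[2, "excluded"])

    def test_times_ranked_first_sums_to_repeat_count(self, rng):
        n_rep = 30
        theo = {"soft": np.array([0.5, 0.6, 0.7])}
        meas = {"soft": rng.uniform(0.2, 1.0, size=(2, n_rep, 3))}
        _, summary = vo.select_optimal(self.PAIRS, theo, meas)
        assert summary["soft"]["times_ranked_first"].sum() == n_rep

    def test_ranks_form_a_permutation_per_repeat(self, rng):
        theo = {"soft": np.array([0.5, 0.6, 0.7])}
        meas = {"soft": rng.uniform(0.2, 1.0, size=(1, 5, 3))}
        _, summary = vo.select_optimal(self.PAIRS, theo, meas)
        assert set(summary["soft"]["worst_rank"]) <= {1, 2, 3}

    def test_lowering_threshold_never_adds_pairs(self, rng):
        theo = {"soft": np.array([0.5, 1.5, 1.9])}
        meas = {"soft": rng.uniform(0.2, 1.0, size=(1, 4, 3))}
        _, loose = vo.select_optimal(self.PAIRS, theo, meas, exclude_threshold_pct=2.0)
        _, tight = vo.select_optimal(self.PAIRS, theo, meas, exclude_threshold_pct=1.0)
        assert set(np.where(loose["soft"]["excluded"])[0]) <= set(
            np.where(tight["soft"]["excluded"])[0]
        )

    def test_all_pairs_excluded_raises(self):
        theo = {"soft": np.array([5.0, 6.0, 7.0])}
        meas = {"soft": np.ones((1, 1, 3))}
        with pytest.raises(ValueError):
            vo.select_optimal(self.PAIRS, theo, meas)

    def test_collapsed_ean_distribution_fails_screen_and_is_rejected(self, rng):
        # discrete spikes (bound-pinned EAN) versus a healthy normal sample
        spikes = np.repeat([4.0, 54.0], 200) + 1e-6 * rng.standard_normal(400)
        normal = 7.5 + 0.3 * rng.standard_normal(400)
        assert vo.normality_pvalue(spikes) < 0.01
        assert vo.normality_pvalue(normal) > 0.01
        theo = {"soft": np.array([0.5, 0.6, 0.7])}
        meas = {"soft": np.array([[[0.1, 0.5, 0.5]]])}
        fail = {"soft": np.array([True, False, False])}  # best pair collapses
        assignment, summary = vo.select_optimal(
            self.PAIRS, theo, meas, normality_fail=fail
        )
        assert assignment["soft"] == self.PAIRS[1]
        assert bool(summary["soft"].loc[0, "excluded"])

    def test_vanishing_noise_recovers_the_theoretical_optimum(
        self, tiny_phantom_rois, basis, inserts
    ):
        phantom, rois = tiny_phantom_rois
        pairs = [(50.0, 70.0), (60.0, 100.0), (80.0, 120.0)]
        mats = {"breast": inserts["breast"], "muscle": inserts["muscle"]}
        classes = {"breast": "soft", "muscle": "soft"}
        energies = sorted({e for p in pairs for e in p})
        scorer = vo.PairScorer(mats, basis, energies_keV=energies, classes=classes)
        theo = {"soft": scorer.rmse_many(pairs, "soft")}
        acq = ps.AcquisitionSpec(
            ctdivol_mGy=10.0, vmi_keV=tuple(energies), include_native=False,
            repeats=2, base_seed=3, noise=ps.NoiseModel(0, 0, 0, 0),
        )
        meas = np.zeros((1, 2, len(pairs)))
        for rep in range(2):
            ch = ps.simulate_acquisition(phantom, acq, rep)
            for k, p in enumerate(pairs):
                meas[0, rep, k] = vo.pair_rmse_measured(p, ch, rois, basis)
        assignment, _ = vo.select_optimal(pairs, theo, {"soft": meas})
        assert assignment["soft"] == pairs[int(np.argmin(theo["soft"]))]
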