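"""Hashtag refinement, limiting-dilution estimation, and kappa tests."""

import math

import numpy as np
import pandas as pd
import pytest

from amlsc import syndata
from amlsc.auxstats import (
    HTOState,
    LDAExperiment,
    estimate_frequency,
    hashtag_boundary,
    kappa_score,
    lda_log_likelihood,
    refine_hto,
)


def _cluster_state(n=200, center=(0.0, 0.0), seed=0, extra=()):
    rng = np.random.default_rng(seed)
    pts = rng.normal(loc=center, scale=1.0, size=(n, 2))
    labels = ["H1"] * n
    coords = list(pts)
    for xy, lab in extra:
        coords.append(np.asarray(xy, dtype=float))
        labels.append(lab)
    return HTOState(np.asarray(coords), np.asarray(labels, dtype=object))


class TestRefineHTO:
    def test_negative_at_medoid_is_rescued(self):
        state = _cluster_state(extra=[((0.0, 0.0), "Negative")])
        refined, bounds = refine_hto(state)
        # the planted Negative sits essentially at the medoid: inside any box
        assert refined.labels[-1] == "H1"
        assert refined.provenance[-1] == "rescued"

    def test_far_singlet_is_discarded(self):
        state = _cluster_state(extra=[((50.0, 50.0), "H1")])
        refined, bounds = refine_hto(state)
        assert refined.labels[-1] == "Negative"
        assert refined.provenance[-1] == "discarded"

    def test_box_contains_at_least_the_quantile_of_own_cells(self):
        for seed in range(5):
            state = _cluster_state(n=500, seed=seed)
            _, bounds = refine_hto(state)
            inside = bounds["H1"].contains(state.embedding)
            assert inside.mean() >= 0.98

    def test_doublets_untouched(self):
        state = _cluster_state(extra=[((0.0, 0.0), "Doublet")])
        refined, _ = refine_hto(state)
        assert refined.labels[-1] == "Doublet"
        assert refined.provenance[-1] == "original"

    def test_small_hashtag_skipped_with_warning(self):
        state = HTOState(
            np.array([[0.0, 0.0], [1.0, 1.0]]), np.array(["H1", "H1"], dtype=object)
        )
        with pytest.warns(UserWarning, match="<3"):
            refined, bounds = refine_hto(state)
        assert "H1" not in bounds

    def test_idempotent_on_generated_data(self):
        emb, labels, _ = syndata.gen_hto(syndata.SynthConfig(seed=13))
        refined, _ = refine_hto(HTOState(emb, labels))
        twice, _ = refine_hto(refined)
        np.testing.assert_array_equal(twice.labels, refined.labels)
        np.testing.assert_array_equal(twice.provenance, refined.provenance)

    def test_rescue_and_discard_recovery_on_generated_data(self):
        cfg = syndata.SynthConfig(seed=14)
        emb, labels, truth = syndata.gen_hto(cfg)
        refined, _ = refine_hto(HTOState(emb, labels))
        rescuable = (truth["planted"] == "mislabeled_negative").to_numpy()
        stray = (truth["planted"] == "stray").to_numpy()
        assert (refined.provenance[rescuable] == "rescued").mean() >= 0.9
        assert (refined.provenance[stray] == "discarded").mean() >= 0.9
        # rescued cells get their generating hashtag back
        ok = refined.provenance[rescuable] == "rescued"
        assert (
            refined.labels[rescuable][ok] == truth.loc[rescuable, "true_label"][ok]
        ).all()

    def test_disc_region_is_subset_of_box(self):
        state = _cluster_state(n=300, seed=3)
        b_box = hashtag_boundary(state, "H1", region="box")
        b_disc = hashtag_boundary(state, "H1", region="disc")
        in_box = b_box.contains(state.embedding)
        in_disc = b_disc.contains(state.embedding)
        assert (in_disc <= in_box).all()


class TestLimitingDilution:
    def test_single_dose_closed_form(self):
        exp = LDAExperiment(
            pd.DataFrame({"dose": [1000], "n_tested": [10], "n_negative": [5]})
        )
        fit = estimate_frequency(exp)
        assert fit.frequency == pytest.approx(-math.log(0.5) / 1000, rel=1e-8)

    def test_mle_matches_grid_oracle(self):
        exp = LDAExperiment(
            pd.DataFrame(
                {
                    "dose": [100, 500, 2500],
                    "n_tested": [12, 12, 12],
                    "n_negative": [11, 7, 1],
                }
            )
        )
        fit = estimate_frequency(exp)
        grid = np.arange(1e-7, 2e-2, 1e-7)
        ll = [lda_log_likelihood(exp, f) for f in grid]
        f_grid = grid[int(np.argmax(ll))]
        assert fit.frequency == pytest.approx(f_grid, rel=1e-4)

    def test_dose_scale_consistency(self):
        t = pd.DataFrame(
            {"dose": [100, 500, 2500], "n_tested": [12, 12, 12], "n_negative": [11, 7, 1]}
        )
        f1 = estimate_frequency(LDAExperiment(t)).frequency
        t2 = t.assign(dose=t["dose"] * 10)
        f2 = estimate_frequency(LDAExperiment(t2)).frequency
        assert f2 == pytest.approx(f1 / 10, rel=1e-10)

    def test_all_negative_gives_zero_with_upper_bound(self):
        exp = LDAExperiment(
            pd.DataFrame({"dose": [1000], "n_tested": [10], "n_negative": [10]})
        )
        fit = estimate_frequency(exp)
        assert fit.frequency == 0.0 and fit.status == "all_negative"
        assert fit.ci[0] == 0.0
        assert fit.ci[1] == pytest.approx(-math.log(0.05) / 10000)

    def test_all_engrafted_reports_lower_bound(self):
        exp = LDAExperiment(
            pd.DataFrame({"dose": [1000], "n_tested": [10], "n_negative": [0]})
        )
        fit = estimate_frequency(exp)
        assert fit.status == "all_engrafted"
        assert math.isinf(fit.frequency)
        assert 0 < fit.ci[0] < math.inf and math.isinf(fit.ci[1])

    def test_invalid_table_rejected(self):
        with pytest.raises(ValueError, match="dose"):
            LDAExperiment(pd.DataFrame({"dose": [0], "n_tested": [5], "n_negative": [1]}))
        with pytest.raises(ValueError, match="n_negative"):
            LDAExperiment(pd.DataFrame({"dose": [10], "n_tested": [5], "n_negative": [6]}))

    def test_ci_covers_truth_on_generated_tables(self):
        covered = 0
        n_rep = 40
        for seed in range(n_rep):
            cfg = syndata.SynthConfig(seed=seed)
            table = syndata.gen_lda(cfg)
            fit = estimate_frequency(LDAExperiment(table))
            if fit.status == "ok" and fit.ci[0] <= cfg.lda_frequency <= fit.ci[1]:
                covered += 1
        assert covered / n_rep >= 0.85


class TestKappa:
    def test_identical_sets(self):
        assert kappa_score({"a", "b"}, {"a", "b"}, ["a", "b", "c", "d"]) == 1.0

    def test_complementary_halves_give_minus_one(self):
        uni = [f"g{i}" for i in range(10)]
        assert kappa_score(set(uni[:5]), set(uni[5:]), uni) == pytest.approx(-1.0)

    def test_symmetry_and_relabeling_invariance(self):
        rng = np.random.default_rng(0)
        uni = [f"g{i}" for i in range(50)]
        a = set(rng.choice(uni, 20, replace=False))
        b = set(rng.choice(uni, 15, replace=False))
        assert kappa_score(a, b, uni) == pytest.approx(kappa_score(b, a, uni))
        mapping = {g: f"x{i}" for i, g in enumerate(uni)}
        assert kappa_score(
            {mapping[g] for g in a}, {mapping[g] for g in b}, list(mapping.values())
        ) == pytest.approx(kappa_score(a, b, uni))

    def test_random_sets_kappa_near_zero(self):
        rng = np.random.default_rng(1)
        uni = [f"g{i}" for i in range(400)]
        kappas = []
        for _ in range(100):
            a = set(rng.choice(uni, 100, replace=False))
            b = set(rng.choice(uni, 100, replace=False))
            kappas.append(abs(kappa_score(a, b, uni)))
        assert np.mean(kappas) < 0.05

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(2)
        uni = [f"g{i}" for i in range(60)]
        for _ in range(20):
            a = set(rng.choice(uni, int(rng.integers(5, 40)), replace=False))
            b = set(rng.choice(uni, int(rng.integers(5, 40)), replace=False))
            va = [g in a for g in uni]
            vb = [g in b for g in uni]
            assert kappa_score(a, b, uni) == pytest.approx(
                cohen_kappa_score(va, vb), abs=1e-12
            )

    def test_degenerate_cases(self):
        uni = ["a", "b"]
        assert kappa_score(set(), set(), uni) == 1.0
        assert kappa_score(set(uni), set(uni), uni) == 1.0
        with pytest.raises(ValueError, match="universe"):
            kappa_score({"z"}, set(), uni)
        with pytest.raises(ValueError, match="empty"):
            kappa_score(set(), set(), [])
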