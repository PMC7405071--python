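"""Bayesian mixed models: scaling, recovery, evidence ratios, contrasts."""

import numpy as np
import pandas as pd
import pytest

import periotag as pt
from periotag.group_inference import (
    ACC_MODEL_TERMS,
    GaussianMixedModel,
    LogisticMixedLaplace,
    _evidence_ratio,
    build_design,
    directional_contrast,
    simulate_linear_mixed,
)


class TestScaleResponse:
    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(0)
        z = pt.scale_response(rng.normal(3.0, 2.0, size=500))
        assert abs(z.mean()) < 1e-12
        assert z.std() == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self):
        x = np.array([1.0, 2.0, 5.0, -1.0, 0.3])
        np.testing.assert_allclose(
            pt.scale_response(x), pt.scale_response(3.0 * x + 7.0), atol=1e-12
        )

    def test_order_preserved(self):
        x = np.array([3.0, 1.0, 2.0])
        assert list(np.argsort(pt.scale_response(x))) == list(np.argsort(x))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pt.scale_response(np.ones(10))


class TestEvidenceRatio:
    def test_identity_with_posterior_probability(self):
        """ER > 19 holds exactly when P(combination > 0) > 0.95 on draws."""
        rng = np.random.default_rng(1)
        for shift in (-0.5, 0.0, 0.3, 1.0, 2.0):
            draws = rng.normal(shift, 1.0, size=4000)
            p = float(np.mean(draws > 0))
            er = _evidence_ratio(draws)
            if p < 1.0:
                assert er == pytest.approx(p / (1 - p))
            assert (er > 19) == (p > 0.95)

    def test_symmetric_draws_give_er_one(self):
        draws = np.concatenate([np.linspace(0.01, 1, 500), -np.linspace(0.01, 1, 500)])
        assert _evidence_ratio(draws) == pytest.approx(1.0)

    def test_all_positive_draws_give_inf(self):
        assert _evidence_ratio(np.abs(np.random.default_rng(2).normal(size=100)) + 0.1) == float("inf")


class TestDesignMatrix:
    def test_interactions_are_products(self):
        df = pd.DataFrame({"A": [0, 1, 1], "B": [1, 1, 0]})
        X = build_design(df, ["A", "B", "A:B"])
        np.testing.assert_array_equal(X[:, 0], 1.0)
        np.testing.assert_array_equal(X[:, 3], df["A"] * df["B"])

    def test_missing_factor_rejected(self):
        with pytest.raises(KeyError, match="C"):
            build_design(pd.DataFrame({"A": [0, 1]}), ["C"])


class TestGaussianMixedModel:
    def test_recovers_planted_effects(self):
        truth = {"Intercept": -0.5, "Rhythm": 0.5, "Imagined": 0.6,
                 "Rhythm:Imagined": -0.2}
        hits = 0
        n_checks = 0
        for rep in range(3):
            df, y = simulate_linear_mixed(truth, n_participants=5,
                                          n_electrodes=6, seed=50 + rep)
            m = GaussianMixedModel(n_iter=800, n_burn=200, seed=rep).fit(df, y)
            for nm, true_val in truth.items():
                lo = np.quantile(m.draws_[nm], 0.025)
                hi = np.quantile(m.draws_[nm], 0.975)
                hits += lo <= true_val <= hi
                n_checks += 1
        assert hits / n_checks >= 0.75

    def test_seeded_determinism(self):
        df, y = simulate_linear_mixed({"Rhythm": 0.5}, n_participants=4,
                                      n_electrodes=4, seed=9)
        m1 = GaussianMixedModel(n_iter=300, n_burn=100, seed=3).fit(df, y)
        m2 = GaussianMixedModel(n_iter=300, n_burn=100, seed=3).fit(df, y)
        pd.testing.assert_frame_equal(m1.summary_, m2.summary_)

    def test_null_data_covers_zero(self):
        df, y = simulate_linear_mixed({}, n_participants=5, n_electrodes=6,
                                      seed=11)
        m = GaussianMixedModel(n_iter=800, n_burn=200, seed=0).fit(df, y)
        covered = sum(
            np.quantile(m.draws_[nm], 0.025) <= 0 <= np.quantile(m.draws_[nm], 0.975)
            for nm in ACC_MODEL_TERMS
        )
        assert covered >= 6  # at least 6 of 7 CIs cover the true zero


class TestDirectionalContrast:
    def test_planted_positive_coefficient_strong_evidence(self):
        df, y = simulate_linear_mixed({"Rhythm": 0.5}, n_participants=6,
                                      n_electrodes=8, seed=21)
        m = GaussianMixedModel(n_iter=600, n_burn=200, seed=0).fit(df, y)
        c = directional_contrast(m, ["Rhythm"])
        assert c.evidence_ratio > 19
        assert c.significant_at_05

    def test_direction_flip(self):
        df, y = simulate_linear_mixed({"Rhythm": 0.5}, n_participants=6,
                                      n_electrodes=8, seed=21)
        m = GaussianMixedModel(n_iter=600, n_burn=200, seed=0).fit(df, y)
        gt = directional_contrast(m, ["Rhythm"], ">")
        lt = directional_contrast(m, ["Rhythm"], "<")
        if np.isfinite(gt.evidence_ratio) and gt.evidence_ratio > 0:
            assert lt.evidence_ratio == pytest.approx(1.0 / gt.evidence_ratio)
        else:
            assert lt.evidence_ratio == 0.0

    def test_unknown_coefficient_rejected(self):
        df, y = simulate_linear_mixed({}, n_participants=3, n_electrodes=3, seed=0)
        m = GaussianMixedModel(n_iter=100, n_burn=50, seed=0).fit(df, y)
        with pytest.raises(KeyError, match="Bogus"):
            directional_contrast(m, ["Bogus"])


def _sig_table(overlap: bool, seed=0, n_electrodes=25):
    """Significance table with listen/imagine flags, optionally overlapping."""
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(4):
        for e in range(n_electrodes):
            tracker = e < 5
            for rhythm in (pt.UNSYNCOPATED, pt.SYNCOPATED):
                for tempo in (120.0, 140.0):
                    for pres in (1, 2):
                        for cond in ("listen", "imagine"):
                            if overlap:
                                sig = tracker and rng.random() < 0.8
                            else:
                                sig = rng.random() < 0.15
                            rows.append(
                                {
                                    "participant": f"P{p:02d}",
                                    "electrode": f"E{e:03d}",
                                    "rhythm": rhythm,
                                    "tempo_bpm": tempo,
                                    "audio_condition": cond,
                                    "signal_type": "rhythm",
                                    "presentation": pres,
                                    "band": "high_gamma",
                                    "acc": 0.4 if sig else 0.05,
                                    "significant": sig,
                                    "normalized_acc": (0.3 if sig else 0.0)
                                    + rng.normal(0, 0.05),
                                }
                            )
    return pd.DataFrame(rows)


class TestPresentationEffect:
    def test_planted_boost_detected_in_all_cells(self):
        table = _sig_table(overlap=True, seed=4)
        table.loc[table["presentation"] == 2, "normalized_acc"] += 0.2
        results = pt.presentation_effect(table, n_iter=400, n_burn=100, seed=0)
        assert len(results) == 8  # 2 rhythms x 2 tempi x 2 audio conditions
        assert all(c.estimate > 0 for c in results)
        assert all(c.evidence_ratio > 19 for c in results)

    def test_label_swap_flips_sign(self):
        table = _sig_table(overlap=True, seed=5)
        table.loc[table["presentation"] == 2, "normalized_acc"] += 0.2
        swapped = table.copy()
        swapped["presentation"] = swapped["presentation"].map({1: 2, 2: 1})
        a = pt.presentation_effect(table, n_iter=400, n_burn=100, seed=0)
        b = pt.presentation_effect(swapped, n_iter=400, n_burn=100, seed=0)
        for ca, cb in zip(a, b):
            assert np.sign(ca.estimate) == -np.sign(cb.estimate)

    def test_missing_presentation_level_skipped_with_warning(self):
        table = _sig_table(overlap=True, seed=6)
        table = table[table["presentation"] == 1]
        with pytest.warns(UserWarning, match="lacks both"):
            results = pt.presentation_effect(table, n_iter=100, n_burn=50)
        assert results == []


class TestOverlapModel:
    def test_shared_trackers_give_positive_coefficients(self):
        table = _sig_table(overlap=True, seed=7)
        li, il = pt.overlap_model(table, seed=0)
        assert li.estimate > 0.5 and il.estimate > 0.5
        assert li.evidence_ratio > 19 and il.evidence_ratio > 19

    def test_independent_flags_cover_zero(self):
        table = _sig_table(overlap=False, seed=8)
        li, il = pt.overlap_model(table, seed=0)
        assert li.ci95[0] <= 0.0 <= li.ci95[1] or abs(li.estimate) < 0.5

    def test_condition_relabel_swaps_directions(self):
        table = _sig_table(overlap=True, seed=9)
        swapped = table.copy()
        swapped["audio_condition"] = swapped["audio_condition"].map(
            {"listen": "imagine", "imagine": "listen"}
        )
        a = pt.overlap_model(table, seed=0)
        b = pt.overlap_model(swapped, seed=0)
        assert a[0].estimate == pytest.approx(b[1].estimate, abs=1e-9)
        assert a[1].estimate == pytest.approx(b[0].estimate, abs=1e-9)


class TestBandComparison:
    def test_high_gamma_only_tracking_gives_positive_contrast(self):
        hg = _sig_table(overlap=True, seed=10)
        beta = _sig_table(overlap=False, seed=11)
        beta["band"] = "beta"
        beta["significant"] = False
        c = pt.band_comparison(hg, beta, seed=0)
        assert c.estimate > 0
        assert c.evidence_ratio > 19

    def test_empty_beta_table_rejected(self):
        hg = _sig_table(overlap=True, seed=12)
        with pytest.raises(ValueError, match="beta"):
            pt.band_comparison(hg, pd.DataFrame())


class TestTableContrasts:
    def test_contrast_combinations_match_reference_coding(self):
        """The four condition hypotheses sum the correct coefficient sets
        under the white-noise/unsyncopated/listen reference cell."""
        df, y = simulate_linear_mixed(
            {"Rhythm": 0.4, "Rhythm:Syncopated": 0.1, "Rhythm:Imagined": -0.2,
             "Rhythm:Syncopated:Imagined": 0.3},
            n_participants=4, n_electrodes=5, seed=13,
        )
        m = GaussianMixedModel(n_iter=400, n_burn=100, seed=0).fit(df, y)
        results = {c.name: c for c in pt.table_contrasts(m)}
        assert set(results) == {
            "Unsyncopated/Listen", "Unsyncopated/Imagine",
            "Syncopated/Listen", "Syncopated/Imagine",
        }
        expected = (
            m.coef_["Rhythm"] + m.coef_["Rhythm:Syncopated"]
            + m.coef_["Rhythm:Imagined"] + m.coef_["Rhythm:Syncopated:Imagined"]
        )
        assert results["Syncopated/Imagine"].estimate == pytest.approx(
            expected, abs=1e-9
        )
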