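"""Item informativeness, reliability, validity and abbreviation."""

import numpy as np
import pandas as pd
import pytest

import delaykit as dk


def _noiseless_cohort(seed=5):
    """Heterogeneous agents answering without noise, clamping or rounding."""
    cfg = dk.calibration_config(tau_time=0.0, tau_money=0.0, n_participants=60)
    study = dk.simulate_study(cfg, seed=seed)
    item_k, scores = dk.score_study(study.responses, cfg.banks())
    return study, item_k, scores


class TestItemTotal:
    def test_noiseless_items_correlate_perfectly(self):
        """With no noise and no clamping every item's rate equals the scale
        rate, so every item-total r is exactly 1."""
        _, item_k, _ = _noiseless_cohort()
        for scale in ("time", "monetary"):
            tab = dk.item_total_correlations(item_k, scale, "phase1")
            assert not tab["undefined"].any()
            assert np.allclose(tab["r"], 1.0, atol=1e-12)

    def test_fully_clamped_item_is_undefined(self):
        """An item everyone answers at the same slider bound has zero
        variance and an undefined correlation, reported as such."""
        cfg = dk.calibration_config(
            n_participants=40, time_bank=dk.time_selection_bank(),
            round_responses=True,
        )
        # every agent's ideal delay for the $99 item is under a day here
        study = dk.simulate_study(cfg, seed=2)
        item_k, _ = dk.score_study(study.responses, cfg.banks())
        tab = dk.item_total_correlations(item_k, "time", "phase1")
        row = tab.set_index("item_id").loc["time_99"]
        assert row["undefined"] and not row["informative"]

    def test_default_cohort_ranks_v99_lowest(self, default_study):
        """Slider floor-clamping makes the $99-today item the least
        informative time item in a realistic cohort."""
        _, item_k, _ = default_study
        tab = dk.item_total_correlations(item_k, "time", "phase1").set_index("item_id")
        assert tab["r"].idxmin() == "time_99"

    def test_item_excluded_variant_lower(self, default_study):
        _, item_k, _ = default_study
        inc = dk.item_total_correlations(item_k, "time", "phase1")
        exc = dk.item_total_correlations(item_k, "time", "phase1",
                                         include_item=False)
        # removing the item from its own total can only weaken the coupling
        assert (exc["r"] <= inc["r"] + 1e-12).all()


class TestTestRetest:
    def test_identical_vectors_give_r_one(self):
        scores = pd.concat([
            pd.DataFrame({
                "participant_id": [f"p{i}" for i in range(20)],
                "phase": phase, "occasion": 0, "scale": "time",
                "k_geomean": np.exp(np.linspace(-5, -1, 20)),
                "log_k": np.linspace(-5, -1, 20),
                "n_items": 7, "n_clamped": 0,
            })
            for phase in ("phase1", "phase2_baseline")
        ])
        res = dk.test_retest(scores, "time")
        assert res.r == pytest.approx(1.0)
        assert res.n == 20

    def test_independent_phases_near_zero(self):
        """With no shared latent trait the between-phase r is sampling noise."""
        cfg = dk.calibration_config(rho_phases=0.0, n_participants=97)
        study = dk.simulate_study(cfg, seed=8)
        _, scores = dk.score_study(study.responses, cfg.banks())
        res = dk.test_retest(scores, "time")
        assert abs(res.r) < 3 / np.sqrt(res.n)

    def test_attenuation_law(self):
        """Observed stability = latent stability x reliability:
        r ~= rho * sigma^2 / (sigma^2 + tau^2/m) for m-item scales."""
        cfg = dk.calibration_config(n_participants=400)
        m = len(cfg.banks()["time"])
        pred = cfg.rho_phases * cfg.sigma_log_k**2 / (
            cfg.sigma_log_k**2 + cfg.tau_time**2 / m
        )
        zs = []
        for seed in np.random.SeedSequence(7).generate_state(6):
            study = dk.simulate_study(cfg, seed=int(seed % 2**31))
            _, scores = dk.score_study(study.responses, cfg.banks())
            zs.append(np.arctanh(dk.test_retest(scores, "time").r))
        zbar, se = np.mean(zs), np.std(zs, ddof=1) / np.sqrt(len(zs))
        assert abs(zbar - np.arctanh(pred)) < 3.2 * se

    def test_too_few_pairs_rejected(self):
        scores = pd.DataFrame({
            "participant_id": ["a", "a"], "phase": ["phase1", "phase2_baseline"],
            "occasion": 0, "scale": "time", "k_geomean": [0.1, 0.1],
            "log_k": [-2.3, -2.3], "n_items": 7, "n_clamped": 0,
        })
        with pytest.raises(ValueError):
            dk.test_retest(scores, "time")


class TestConvergentValidity:
    def test_diagonal_is_one_and_matrix_symmetric(self, default_study):
        _, _, scores = default_study
        r, p, n = dk.convergent_validity(scores)
        assert np.allclose(np.diag(r), 1.0)
        assert np.allclose(r, r.T)
        assert r.shape == (6, 6)
        assert (r.values <= 1.0 + 1e-12).all() and (r.values >= -1.0 - 1e-12).all()

    def test_noiseless_shared_trait_perfect_cross_correlation(self):
        """One latent rate driving both continuous instruments with no noise
        makes every within-phase cross-correlation exactly 1."""
        _, _, scores = _noiseless_cohort()
        r, _, _ = dk.convergent_validity(scores, scales=("time", "monetary"),
                                         phases=("phase1",))
        assert r.loc["phase1:time", "phase1:monetary"] == pytest.approx(1.0)

    def test_noisier_instrument_attenuates_more(self):
        """MCQ-time r exceeds MCQ-monetary r when the monetary instrument
        carries the larger occasion noise (attenuation ordering)."""
        cfg = dk.calibration_config(
            n_participants=400, tau_time=0.15, tau_money=0.9
        )
        study = dk.simulate_study(cfg, seed=3)
        _, scores = dk.score_study(study.responses, cfg.banks())
        r, _, _ = dk.convergent_validity(scores)
        assert (r.loc["phase1:mcq", "phase1:time"]
                > r.loc["phase1:mcq", "phase1:monetary"])


class TestAbbreviation:
    def test_full_subset_check_mode_gives_r_one(self, default_study):
        _, item_k, _ = default_study
        items = [f"time_{v}" for v in (10, 30, 40, 50, 70, 80)]
        draws = dk.abbreviation_analysis(
            item_k, "time", "phase1", items=items,
            subset_sizes=[6], iterations=3, seed=0, allow_full=True,
        )
        assert np.allclose(draws["r"], 1.0)

    def test_noiseless_any_subset_gives_r_one(self):
        _, item_k, _ = _noiseless_cohort()
        items = [i for i in dk.time_selection_bank().item_ids if i != "time_99"]
        draws = dk.abbreviation_analysis(item_k, "time", "phase1", items=items,
                                         iterations=10, seed=1)
        assert np.allclose(draws["r"], 1.0, atol=1e-10)

    def test_mean_r_nondecreasing_in_subset_size(self, default_study):
        _, item_k, _ = default_study
        tab = dk.item_total_correlations(item_k, "time", "phase1")
        items = sorted(tab.loc[tab["informative"], "item_id"])
        draws = dk.abbreviation_analysis(item_k, "time", "phase1", items=items,
                                         iterations=100, seed=0)
        summ = dk.abbreviation_summary(draws).sort_values("subset_size")
        diffs = np.diff(summ["mean_r"])
        slack = 2 * np.hypot(summ["mc_se"].values[1:], summ["mc_se"].values[:-1])
        assert (diffs >= -slack).all()

    def test_same_seed_reproduces_curve(self, default_study):
        _, item_k, _ = default_study
        items = [f"time_{v}" for v in (10, 30, 40, 50)]
        a = dk.abbreviation_analysis(item_k, "time", "phase1", items=items,
                                     iterations=20, seed=9)
        b = dk.abbreviation_analysis(item_k, "time", "phase1", items=items,
                                     iterations=20, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_oversized_subset_rejected(self, default_study):
        _, item_k, _ = default_study
        with pytest.raises(ValueError):
            dk.abbreviation_analysis(item_k, "time", "phase1",
                                     items=["time_10", "time_30"],
                                     subset_sizes=[2], iterations=1, seed=0)
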