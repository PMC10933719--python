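"""Straightliner detection, 3-SD outlier screening, analytic sample."""

import numpy as np
import pandas as pd
import pytest

import delaykit as dk
from delaykit.qc import QcFlag


def _responses(bank, per_participant, phase="phase1"):
    rows = []
    for pid, values in per_participant.items():
        for item_id, v in zip(bank.item_ids, values):
            rows.append({"participant_id": pid, "phase": phase, "occasion": 0,
                         "item_id": item_id, "value": v})
    return pd.DataFrame(rows)


def _scores(log_ks, phase="phase1", scale="time"):
    return pd.DataFrame(
        {
            "participant_id": [f"p{i:03d}" for i in range(len(log_ks))],
            "phase": phase, "occasion": 0, "scale": scale,
            "k_geomean": np.exp(log_ks), "log_k": log_ks,
            "n_items": 7, "n_clamped": 0,
        }
    )


class TestStraightliners:
    def test_all_minimum_and_all_maximum_flagged(self, time_bank):
        resp = _responses(time_bank, {
            "lo": [1.0] * 7,          # everything at the 1-day floor
            "hi": [364.0] * 7,        # everything at the 52-week maximum
            "mixed": [1, 30, 100, 364, 7, 14, 1],
        })
        flags = dk.flag_straightliners(resp, time_bank)
        got = dict(zip(flags["participant_id"], flags["flag"]))
        assert got == {"lo": "straightline_min", "hi": "straightline_max"}

    def test_consistently_means_every_item(self, time_bank):
        # six of seven at the floor is retained
        resp = _responses(time_bank, {"p": [1, 1, 1, 1, 1, 1, 2]})
        assert dk.flag_straightliners(resp, time_bank).empty

    def test_zero_days_counts_as_floor(self, time_bank):
        # slider shows 0 weeks but the deployed floor is 1 day: 0s straightline
        resp = _responses(time_bank, {"p": [0.0] * 7})
        flags = dk.flag_straightliners(resp, time_bank, min_delay_days=1.0)
        assert list(flags["flag"]) == ["straightline_min"]

    def test_monetary_bounds(self, monetary_bank):
        resp = _responses(monetary_bank, {"lo": [1.0] * 7, "hi": [99.0] * 7})
        flags = dk.flag_straightliners(resp, monetary_bank)
        assert set(flags["flag"]) == {"straightline_min", "straightline_max"}

    def test_mcq_bank_rejected(self, mcq_bank):
        with pytest.raises(ValueError):
            dk.flag_straightliners(pd.DataFrame(columns=["participant_id", "phase",
                                                         "occasion", "item_id",
                                                         "value"]), mcq_bank)


class TestSdOutliers:
    def test_planted_contaminant_flagged(self):
        """A point planted five population SDs out is caught by the 3-SD rule
        even after it inflates the sample SD."""
        rng = np.random.default_rng(1)
        log_ks = np.concatenate([rng.normal(0, 1, 96), [5.0]])
        flags = dk.flag_sd_outliers(_scores(log_ks), threshold=3.0)
        assert "p096" in set(flags["participant_id"])
        z = flags.set_index("participant_id").loc["p096", "z_score"]
        assert z > 3

    def test_symmetric_triplet_unflagged(self):
        assert dk.flag_sd_outliers(_scores(np.array([-1.0, 0.0, 1.0]))).empty

    def test_zero_variance_warns_and_flags_nothing(self):
        with pytest.warns(UserWarning, match="zero variance"):
            flags = dk.flag_sd_outliers(_scores(np.zeros(10)))
        assert flags.empty

    def test_fewer_than_three_estimates_rejected(self):
        with pytest.raises(ValueError):
            dk.flag_sd_outliers(_scores(np.array([0.0, 1.0])))

    def test_raw_scale_option(self):
        # on the raw (k) scale one lognormal tail point dominates
        rng = np.random.default_rng(2)
        log_ks = rng.normal(-3, 0.2, 50)
        log_ks[0] = 1.0
        raw = dk.flag_sd_outliers(_scores(log_ks), on="k_geomean")
        assert "p000" in set(raw["participant_id"])
        with pytest.raises(ValueError):
            dk.flag_sd_outliers(_scores(log_ks), on="median")


class TestAnalyticSample:
    def test_intersection(self):
        retained = {"phase1": {"A", "B", "C"}, "phase2_baseline": {"B", "C", "D"}}
        assert dk.build_analytic_sample(retained) == {"B", "C"}

    def test_flag_in_either_phase_excludes(self, contaminated_study):
        study, item_k, scores = contaminated_study
        res = dk.run_qc(study.responses, study.config.banks(), scores)
        for phase, retained in res.retained_by_phase.items():
            assert set(res.analytic_sample) <= retained

    def test_no_flags_retains_everyone(self):
        retained = {"phase1": {"A", "B"}, "phase2_baseline": {"A", "B"}}
        assert dk.build_analytic_sample(retained) == {"A", "B"}


class TestPipelineExactness:
    def test_planted_contamination_recovered_exactly(self, contaminated_study):
        """3 straightliners + 5 planted outliers -> exactly those 8 excluded,
        each carrying its planted flag type."""
        study, item_k, scores = contaminated_study
        res = dk.run_qc(study.responses, study.config.banks(), scores)
        truth = study.truth.set_index("participant_id")["behavior"]
        planted = sorted(truth[truth != "normal"].index)
        assert res.excluded == planted
        flags = res.decisions.groupby("participant_id")["flag"].agg(set)
        for pid in planted:
            if truth[pid] == "sd_outlier":
                assert flags[pid] == {QcFlag.SD_OUTLIER.value}
            else:
                assert flags[pid] == {truth[pid]}

    def test_qc_idempotent_on_retained_sample(self, contaminated_study):
        """Re-screening the retained sample finds no planted-magnitude
        contamination (clean-tail 3-SD re-flags are possible, never z >= 5)."""
        study, item_k, scores = contaminated_study
        res = dk.run_qc(study.responses, study.config.banks(), scores)
        keep = set(res.analytic_sample)
        responses2 = study.responses[study.responses["participant_id"].isin(keep)]
        scores2 = scores[scores["participant_id"].isin(keep)]
        res2 = dk.run_qc(responses2, study.config.banks(), scores2)
        assert not (res2.decisions["flag"] != "sd_outlier").any()
        assert (res2.decisions["z_score"].abs() < 5).all()

    def test_summary_counts(self, contaminated_study):
        study, item_k, scores = contaminated_study
        res = dk.run_qc(study.responses, study.config.banks(), scores)
        text = res.summary()
        assert "Analytic sample" in text and "89" in text
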