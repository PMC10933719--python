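"""Screen a cohort with planted straightliners and score outliers.

The contaminated preset plants 2 minimum-straightliners, 1 maximum-
straightliner and 5 respondents whose latent log-rate sits far outside the
clean distribution; QC should exclude exactly those 8.
"""

import delaykit as dk

study = dk.simulate_study(dk.contaminated_config(), seed=0)
item_k, scores = dk.score_study(study.responses, study.config.banks())
result = dk.run_qc(study.responses, study.config.banks(), scores)

print(result.summary())
print()
truth = study.truth.set_index("participant_id")["behavior"]
print("excluded -> planted behavior:")
for pid in result.excluded:
    print(f"  {pid}: {truth[pid]}")
print()
print("Straightliners are removed first; the 3-SD rule then standardizes")
print("each phase x scale log-score distribution in one pass.")
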