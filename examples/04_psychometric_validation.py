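"""Run the psychometric validation on a default synthetic cohort.

Item-total correlations expose the $99-today item (its indifference delay
is under a day for most respondents, so answers pile at the slider floor);
test-retest and convergent-validity correlations quantify stability and
agreement with the MCQ; random-subset curves show how few items suffice.
"""

import delaykit as dk

study = dk.simulate_study(dk.clean_config(), seed=0)
item_k, scores = dk.score_study(study.responses, study.config.banks())

tab = dk.item_total_correlations(item_k, "time", "phase1")
print("item-total correlations (time scale, phase 1):")
print(tab[["item_id", "r", "informative"]].round(3).to_string(index=False))

for scale in ("time", "monetary"):
    res = dk.test_retest(scores, scale)
    print(f"\ntest-retest ({scale}): r = {res.r:.3f}, p = {res.p:.2g}, n = {res.n}")

r, p, n = dk.convergent_validity(scores)
print(f"\nphase-1 time vs phase-1 MCQ: r = {r.loc['phase1:time', 'phase1:mcq']:.3f}")

items = sorted(tab.loc[tab["informative"], "item_id"])
draws = dk.abbreviation_analysis(item_k, "time", "phase1", items=items,
                                 iterations=100, seed=0)
print("\nabbreviation curve (subset vs full informative scale):")
print(dk.abbreviation_summary(draws).round(4).to_string(index=False))
print()
print("A single informative item already tracks the full scale closely;")
print("the mean correlation rises monotonically with subset size.")
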