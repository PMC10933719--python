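"""Score a handful of hand-written slider responses into discounting rates.

Each continuous item fixes two of (V, A, D) in V = A/(1 + kD), so a slider
answer determines the rate k in closed form; the scale score is the
geometric mean of the item rates.
"""

import pandas as pd

import delaykit as dk

# One participant: willing to wait 70 days to double $50, 150 days for $100
# over $70, ... and would take $40 today instead of $100 in a year.
rows = [
    ("time_50", 70), ("time_70", 150), ("time_10", 300),
    ("time_80", 40), ("time_40", 120), ("time_30", 200), ("time_99", 2),
    ("money_1year", 40), ("money_1month", 85), ("money_6months", 55),
    ("money_3months", 70), ("money_2weeks", 92), ("money_1week", 95),
    ("money_tomorrow", 99),
]
responses = pd.DataFrame(
    [{"participant_id": "p001", "phase": "phase1", "occasion": 0,
      "item_id": i, "value": v} for i, v in rows]
)

item_k, scores = dk.score_study(responses, dk.default_banks())

print(item_k[["item_id", "k", "clamped"]].to_string(index=False))
print()
print(scores[["scale", "k_geomean", "log_k", "n_items"]].to_string(index=False))
print()
print("Each per-item k is the rate (per day) at which the hyperbolic model")
print("makes the chosen response an indifference point; k_geomean is the")
print("scale score, and log_k is what every downstream analysis uses.")
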