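"""Classify genetic interactions from duplication-assay fold increases.

A double mutant beating kappa times the additive expectation of its single
mutants is synergistic (parallel pathways); one staying within kappa of the
stronger single is epistatic (same pathway).
"""

import sumoquant as sq

fixture = sq.load_printed_rates()
wt68 = float(fixture.loc[fixture["genotype"] == "Wild type", "rate_yel068c"].iloc[0])


def fold72(genotype: str) -> float:
    rate = float(fixture.loc[fixture["genotype"] == genotype, "rate_yel072w"].iloc[0])
    return rate / wt68


pairs = [
    ("siz1Δ", "siz2Δ", "siz1Δ siz2Δ"),
    ("esc2Δ", "mms21-11", "mms21-11 esc2Δ"),
    ("slx5Δ", "siz2Δ", "slx5Δ siz2Δ"),
]
for a, b, ab in pairs:
    call = sq.classify_interaction(
        fold72(a), fold72(b), fold72(ab), kappa=1.5, genotype_pair=(a, b)
    )
    print(f"{a} × {b}: folds ({call.fold_a:.0f}, {call.fold_b:.0f}) -> "
          f"{call.fold_ab:.0f} (additive expectation {call.expected_additive:.0f})"
          f"  =>  {call.category}")
# siz1Δ siz2Δ exceeds the additive expectation (redundant ligases acting in
# parallel); the esc2Δ mms21-11 double resembles mms21-11 alone (same
# pathway, epistasis).
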