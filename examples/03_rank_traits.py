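"""Rank traits by SVM-RFE and check that the planted signal is recovered.

Simulates 30 traits of which only 3 carry a 3-sigma class shift, ranks all
traits by recursive elimination of the smallest squared SVM weight, and
prints the ranking head with per-trait criteria.
"""

from phenoselect import SimulationConfig, select_top, simulate_two_class, svm_rfe

informative = [4, 17, 29]  # 0-based trait indices carrying the shift
config = SimulationConfig(
    n1=150, n2=150, p=30, epsilon=3.0, cov_family="identity",
    informative_subset=informative, seed=7,
)
table = simulate_two_class(config)

ranking = svm_rfe(table, C=1.0)
planted = {table.trait_names[j] for j in informative}

print("rank  trait        planted?  w^2 at first iteration")
first_iter = ranking.criteria_history[0]
for r, trait in enumerate(ranking.ranked_traits[:6], start=1):
    mark = "yes" if trait in planted else "no"
    print(f"{r:>4d}  {trait}   {mark:>3s}       {first_iter[trait]:.4f}")

top3 = set(select_top(ranking, 3))
print(f"\ntop-3 equals the planted subset: {top3 == planted}")
print(
    "-> the three shifted traits dominate the squared-weight criterion and"
    " survive elimination longest."
)
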