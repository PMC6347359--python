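"""Screen the fixed worked example of tested ovarian-cancer combinations.

Uses the bundled 14-drug / 12-combination fixture: expands each tested
combination to drug pairs, matches them against the 12-pair SL set (each
drug must target one SL endpoint, and no single tested drug may cover
both), then ranks the bundled novel-proposal table by annotation degree
(summed per-gene ovarian-neoplasms publication counts).
"""

from synletcombo import (
    DrugIndex,
    expand_pairwise,
    find_sl_matches,
    fixture_fig3,
    fixture_table1,
    fixture_table1_matches,
    rank_by_annotation_degree,
)

drugs, combos, sl_set = fixture_fig3()
index = DrugIndex(drugs)

print("tested combinations addressing an SL pair:")
n_addressing = 0
for combo in combos:
    matches = set()
    for pair in expand_pairwise(combo):
        matches |= find_sl_matches(pair, index, sl_set, drugs)
    if matches:
        n_addressing += 1
        names = " + ".join(sorted(index.get(i).name for i in combo))
        pairs = ", ".join(
            f"{m.gene_a}-{m.gene_b}" for m in sorted(matches)
        )
        print(f"  {names}: {pairs}")
print(f"total: {n_addressing} of {len(combos)} tested combinations "
      f"({sum(1 for c in combos if 'paclitaxel' in c)} involve paclitaxel)")

print()
print("top novel proposals ranked by annotation degree:")
ranked = rank_by_annotation_degree(fixture_table1_matches(), fixture_table1())
for p in ranked[:5]:
    print(
        f"  {p.match.drug_a} + {p.match.drug_b}: "
        f"{p.match.gene_a}-{p.match.gene_b}  "
        f"degree {p.annotation_degree} ({p.count_a} / {p.count_b})"
    )
print("The degree sums each SL partner's publication count in the disease")
print("context; better-characterized pairs rank higher.")
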