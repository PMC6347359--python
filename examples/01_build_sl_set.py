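"""Build a human SL pair set from a generated yeast screen.

Generates a small synthetic world, filters the yeast genetic-interaction
screen at the standard cutoffs (p < 0.05, epsilon < -0.08), merges the
multi-source ortholog tables, and maps the surviving yeast pairs to
canonical human gene pairs.
"""

from synletcombo import (
    SyntheticWorldConfig,
    filter_negative_interactions,
    generate_world,
    map_pairs_to_human,
    merge_ortholog_sources,
)

world = generate_world(SyntheticWorldConfig(seed=1))
screen = world.yeast_screen

yeast_pairs = filter_negative_interactions(screen.records)
ortholog_map = merge_ortholog_sources(world.ortholog_tables)
human_pairs = map_pairs_to_human(yeast_pairs, ortholog_map)

print(f"screen records:              {len(screen.records)}")
print(f"yeast SL pairs after filter: {len(yeast_pairs)}")
print(f"  (generator planted {len(screen.planted)}; the rest pass by chance)")
print(f"yeast genes with orthologs:  {len(ortholog_map)}")
print(f"human SL pairs after mapping:{len(human_pairs):>4}")
print()
print("One-to-many orthology expands each yeast pair into the full")
print("cross-product of human pairs; pairs with an unmapped endpoint or a")
print("shared ortholog (would-be self-pairs) contribute nothing.")
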