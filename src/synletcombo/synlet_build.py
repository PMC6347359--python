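"""Build a human SL pair set from a yeast genetic-interaction screen.

Double-knockout fitness screens in *S. cerevisiae* report, per gene pair, a
genetic-interaction score epsilon (negative = aggravating) and a p-value.
Strongly negative, significant interactions are treated as synthetic lethal.
Those yeast pairs are then transferred to human gene symbols through the
union of several orthology resources: a human pair (h1, h2) exists for a
yeast pair (y1, y2) whenever h1 is an ortholog of y1 and h2 of y2 (full
cross-product for one-to-many orthology), provided h1 != h2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .core import GenePair, YEAST_DERIVED, canonicalize_pairs

#: Default screen cutoffs: retain records with p_value < P_MAX and
#: epsilon < EPSILON_MAX (strict inequalities).
DEFAULT_P_MAX = 0.05
DEFAULT_EPSILON_MAX = -0.08


@dataclass(frozen=True)
class GeneticInteractionRecord:
    """One yeast double-knockout screen measurement."""

    query_gene: str
    array_gene: str
    epsilon: float
    p_value: float

    def problems(self) -> list[str]:
        """Validation issues with this record (empty list when valid)."""
        issues = []
        if not self.query_gene or not self.array_gene:
            issues.append("empty gene identifier")
        if not math.isfinite(self.epsilon):
            issues.append(f"non-finite epsilon {self.epsilon!r}")
        if not (0.0 <= self.p_value <= 1.0):
            issues.append(f"p_value {self.p_value!r} outside [0, 1]")
        return issues


@dataclass(frozen=True)
class OrthologRecord:
    """One yeast-gene -> human-gene assertion from one orthology resource."""

    yeast_gene: str
    human_gene: str
    source: str


def filter_negative_interactions(
    records: Iterable[GeneticInteractionRecord],
    p_max: float = DEFAULT_P_MAX,
    epsilon_max: float = DEFAULT_EPSILON_MAX,
) -> set[GenePair]:
    """Retain significantly aggravating interactions as yeast SL pairs.

    A record passes when ``p_value < p_max`` and ``epsilon < epsilon_max``
    (both strict).  Passing records are canonicalized: reversed duplicates
    collapse to one pair, self-pairs are dropped.

    Raises
    ------
    ValueError
        If any record carries a p-value outside [0, 1] or a non-finite
        epsilon; the message reports every offending row index.
    """
    records = list(records)
    bad = [
        f"row {i}: {'; '.join(probs)}"
        for i, rec in enumerate(records)
        if (probs := rec.problems())
    ]
    if bad:
        raise ValueError(
            "invalid genetic-interaction records:\n" + "\n".join(bad)
        )
    passing = [
        (r.query_gene, r.array_gene)
        for r in records
        if r.p_value < p_max and r.epsilon < epsilon_max
    ]
    return canonicalize_pairs(passing, species="yeast", provenance=YEAST_DERIVED)


def merge_ortholog_sources(
    tables: Iterable[Iterable[OrthologRecord]],
) -> dict[str, set[str]]:
    """Union per-source ortholog tables into one yeast -> {human} map.

    A yeast gene maps to the union of its human orthologs across all
    sources; duplicated assertions are idempotent.  Yeast genes absent from
    every table are absent from the map.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("at least one ortholog table is required")
    merged: dict[str, set[str]] = {}
    for table in tables:
        for rec in table:
            if not rec.yeast_gene or not rec.human_gene:
                raise ValueError(f"malformed ortholog record: {rec!r}")
            merged.setdefault(rec.yeast_gene, set()).add(rec.human_gene)
    return merged


def map_pairs_to_human(
    yeast_pairs: Iterable[GenePair],
    ortholog_map: Mapping[str, set[str]],
) -> set[GenePair]:
    """Transfer yeast SL pairs to human symbols via the ortholog map.

    Each yeast pair (y1, y2) yields every canonical human pair (h1, h2)
    with h1 in image(y1), h2 in image(y2) and h1 != h2 (full cross-product
    for one-to-many orthology).  A pair with either endpoint unmapped
    contributes nothing; output is deduplicated.
    """
    out: set[GenePair] = set()
    for pair in yeast_pairs:
        image_a = ortholog_map.get(pair.gene_a, set())
        image_b = ortholog_map.get(pair.gene_b, set())
        for h1 in image_a:
            for h2 in image_b:
                if h1 == h2:
                    continue
                out.add(
                    GenePair.make(
                        h1, h2, species="human", provenance=YEAST_DERIVED
                    )
                )
    return out


def build_human_sl_pairs(
    records: Iterable[GeneticInteractionRecord],
    ortholog_tables: Iterable[Iterable[OrthologRecord]],
    p_max: float = DEFAULT_P_MAX,
    epsilon_max: float = DEFAULT_EPSILON_MAX,
) -> set[GenePair]:
    """Full screen-to-human pipeline: filter, merge orthologs, map."""
    yeast_pairs = filter_negative_interactions(records, p_max, epsilon_max)
    ortholog_map = merge_ortholog_sources(ortholog_tables)
    return map_pairs_to_human(yeast_pairs, ortholog_map)
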