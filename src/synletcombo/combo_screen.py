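"""Screen clinical drug combinations against a synthetic-lethal pair set.

The screen proceeds in four steps:

1. filter a clinical-trials corpus down to late-phase (III/IV)
   interventional ovarian-cancer trials that study at least one
   multi-drug combination;
2. resolve arm drug names against a drug index (names + synonyms) and
   tally the distinct tested drug-id combinations;
3. expand each combination to unordered drug pairs and match every pair
   against the SL set: a match requires each drug to target one SL endpoint
   directly, with **no** single tested drug targeting both endpoints (a
   single such drug would address the pair alone, defeating the
   combination rationale);
4. propose novel combinations — drug pairs composable from the tested
   drugs but absent from the tested pairs — and rank all matches by
   annotation degree, the sum of the two SL partners' publication counts
   in the disease context.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core import GenePair, SLInteractionSet

TESTED = "tested"
NOVEL = "novel"

#: Controlled condition strings accepted by the trial filter
#: (case-insensitive exact match against each trial condition entry).
DEFAULT_CONDITION_TERMS: tuple[str, ...] = (
    "ovarian cancer",
    "ovarian neoplasms",
    "neoplasm of ovary",
    "ovarian carcinoma",
    "ovarian epithelial cancer",
    "neoplasms, ovarian",
)

DEFAULT_PHASES = frozenset({"III", "IV"})


@dataclass(frozen=True)
class DrugRecord:
    drug_id: str
    name: str
    synonyms: frozenset[str] = frozenset()
    targets: frozenset[str] = frozenset()
    modality: str = "drug"

    def __post_init__(self) -> None:
        if not self.drug_id or not self.name:
            raise ValueError("drug_id and name must be non-empty")


@dataclass(frozen=True)
class TrialRecord:
    trial_id: str
    phase: str
    study_type: str
    conditions: tuple[str, ...]
    arms: tuple[frozenset[str], ...]


class DrugIndex:
    """Case-insensitive resolution of drug names and synonyms to records."""

    def __init__(self, drugs: Iterable[DrugRecord]) -> None:
        self._by_id: dict[str, DrugRecord] = {}
        self._by_name: dict[str, DrugRecord] = {}
        for drug in drugs:
            if drug.drug_id in self._by_id:
                raise ValueError(f"duplicate drug_id {drug.drug_id!r}")
            self._by_id[drug.drug_id] = drug
            for name in {drug.name, *drug.synonyms}:
                self._by_name[name.lower()] = drug

    def resolve(self, name: str) -> DrugRecord | None:
        return self._by_name.get(name.lower())

    def get(self, drug_id: str) -> DrugRecord:
        return self._by_id[drug_id]

    @property
    def drugs(self) -> list[DrugRecord]:
        return sorted(self._by_id.values(), key=lambda d: d.drug_id)


@dataclass(frozen=True, order=True)
class SLMatch:
    """A drug pair addressing an SL gene pair, one endpoint per drug.

    Stored with (gene_a, gene_b) in canonical order; drug_a is the drug
    targeting gene_a, so the drug order follows the gene order.
    """

    drug_a: str
    drug_b: str
    gene_a: str
    gene_b: str
    status: str = TESTED

    def __post_init__(self) -> None:
        if self.drug_a == self.drug_b:
            raise ValueError(f"match requires two distinct drugs: {self.drug_a!r}")
        if self.gene_a >= self.gene_b:
            raise ValueError("gene endpoints must be in canonical order")

    @classmethod
    def make(
        cls, drug_x: str, gene_x: str, drug_y: str, gene_y: str, status: str
    ) -> "SLMatch":
        """Build a match from (drug, gene) assignments in either order."""
        if gene_x > gene_y:
            drug_x, drug_y = drug_y, drug_x
            gene_x, gene_y = gene_y, gene_x
        return cls(drug_x, drug_y, gene_x, gene_y, status)

    @property
    def drug_pair(self) -> frozenset[str]:
        return frozenset({self.drug_a, self.drug_b})

    @property
    def gene_pair(self) -> GenePair:
        return GenePair(self.gene_a, self.gene_b)


@dataclass(frozen=True)
class RankedProposal:
    match: SLMatch
    count_a: int
    count_b: int

    @property
    def annotation_degree(self) -> int:
        return self.count_a + self.count_b


def filter_trials(
    trials: Iterable[TrialRecord],
    phases: frozenset[str] = DEFAULT_PHASES,
    condition_terms: Sequence[str] = DEFAULT_CONDITION_TERMS,
) -> list[TrialRecord]:
    """Late-phase interventional trials on the disease with a combo arm.

    A trial is retained only if its phase is allowed, its study type is
    interventional, at least one condition entry equals one of the
    controlled terms (case-insensitive), and at least one arm studies two
    or more drugs/biologicals.
    """
    terms = {t.lower() for t in condition_terms}
    kept = []
    for trial in trials:
        if trial.phase not in phases:
            continue
        if trial.study_type != "interventional":
            continue
        if not any(c.lower() in terms for c in trial.conditions):
            continue
        if not any(len(arm) >= 2 for arm in trial.arms):
            continue
        kept.append(trial)
    return kept


def extract_tested_combinations(
    trials: Iterable[TrialRecord],
    drug_index: DrugIndex,
) -> list[tuple[frozenset[str], int]]:
    """Distinct tested drug-id combinations with their trial counts.

    Arm drug names are resolved through the index (names and synonyms,
    case-insensitive); unresolvable names are reported as warnings and the
    arm is skipped only if fewer than two resolvable drugs remain.  A
    combination studied in several arms of one trial counts that trial
    once.
    """
    counts: dict[frozenset[str], int] = {}
    for trial in trials:
        trial_combos: set[frozenset[str]] = set()
        for arm in trial.arms:
            ids = set()
            for name in arm:
                drug = drug_index.resolve(name)
                if drug is None:
                    warnings.warn(
                        f"trial {trial.trial_id}: unresolvable drug name "
                        f"{name!r}",
                        stacklevel=2,
                    )
                else:
                    ids.add(drug.drug_id)
            if len(ids) >= 2:
                trial_combos.add(frozenset(ids))
        for combo in trial_combos:
            counts[combo] = counts.get(combo, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], sorted(kv[0])))


def expand_pairwise(combination: frozenset[str]) -> set[tuple[str, str]]:
    """All C(n, 2) unordered drug pairs of a combination (n >= 2)."""
    if len(combination) < 2:
        raise ValueError(
            f"combination must hold at least 2 drugs, got {sorted(combination)}"
        )
    return set(itertools.combinations(sorted(combination), 2))


def filter_drugs_with_protein_targets(
    drugs: Iterable[DrugRecord],
) -> list[DrugRecord]:
    """Drugs with at least one protein target (DNA-only agents drop out)."""
    return [d for d in drugs if d.targets]


def _single_drug_covers(
    gene_a: str, gene_b: str, drugs: Iterable[DrugRecord]
) -> bool:
    return any(gene_a in d.targets and gene_b in d.targets for d in drugs)


def find_sl_matches(
    drug_pair: tuple[str, str] | frozenset[str],
    drug_index: DrugIndex,
    sl_set: SLInteractionSet,
    all_tested_drugs: Iterable[DrugRecord],
    status: str = TESTED,
) -> set[SLMatch]:
    """SL pairs addressed by a drug pair, one SL endpoint per drug.

    Emits a match for every (gene_a, gene_b) with gene_a targeted by one
    drug, gene_b by the other, the canonical pair in the SL set, and no
    drug in ``all_tested_drugs`` targeting both endpoints.  Symmetric in
    drug order.
    """
    ids = sorted(drug_pair)
    if len(ids) != 2:
        raise ValueError(f"expected exactly 2 drugs, got {ids}")
    d1, d2 = (drug_index.get(i) for i in ids)
    tested = list(all_tested_drugs)
    matches: set[SLMatch] = set()
    for ga in d1.targets:
        for gb in d2.targets:
            if ga == gb:
                continue
            if (ga, gb) not in sl_set:
                continue
            if _single_drug_covers(ga, gb, tested):
                continue
            matches.add(SLMatch.make(d1.drug_id, ga, d2.drug_id, gb, status))
    return matches


def propose_novel_combinations(
    drugs: Sequence[DrugRecord],
    tested_pairs: set[frozenset[str]] | set[tuple[str, str]],
    sl_set: SLInteractionSet,
    drug_index: DrugIndex | None = None,
) -> set[SLMatch]:
    """SL-addressing drug pairs composable from ``drugs`` but never tested.

    ``drugs`` should be the tested drugs with protein targets; the same
    single-drug-covers-both exclusion as :func:`find_sl_matches` applies,
    scoped to that full drug set.
    """
    targeted = filter_drugs_with_protein_targets(drugs)
    if drug_index is None:
        drug_index = DrugIndex(targeted)
    tested_sets = {frozenset(p) for p in tested_pairs}
    out: set[SLMatch] = set()
    for d1, d2 in itertools.combinations(sorted(targeted, key=lambda d: d.drug_id), 2):
        pair = frozenset({d1.drug_id, d2.drug_id})
        if pair in tested_sets:
            continue
        out |= find_sl_matches(
            (d1.drug_id, d2.drug_id), drug_index, sl_set, targeted, status=NOVEL
        )
    return out


def rank_by_annotation_degree(
    matches: Iterable[SLMatch],
    counts: Mapping[str, int],
) -> list[RankedProposal]:
    """Rank matches by the summed publication counts of the SL partners.

    Missing genes count 0 (with a warning).  Sorting is non-increasing in
    annotation degree with a deterministic lexicographic tie-break on
    (gene_a, gene_b, drug_a, drug_b).
    """
    proposals = []
    for match in matches:
        for gene in (match.gene_a, match.gene_b):
            if gene not in counts:
                warnings.warn(
                    f"no publication count for gene {gene!r}; using 0",
                    stacklevel=2,
                )
        proposals.append(
            RankedProposal(
                match=match,
                count_a=int(counts.get(match.gene_a, 0)),
                count_b=int(counts.get(match.gene_b, 0)),
            )
        )
    proposals.sort(
        key=lambda p: (
            -p.annotation_degree,
            p.match.gene_a,
            p.match.gene_b,
            p.match.drug_a,
            p.match.drug_b,
        )
    )
    return proposals


def screen_tested_combinations(
    trials: Iterable[TrialRecord],
    drugs: Sequence[DrugRecord],
    sl_set: SLInteractionSet,
    phases: frozenset[str] = DEFAULT_PHASES,
    condition_terms: Sequence[str] = DEFAULT_CONDITION_TERMS,
) -> tuple[dict[tuple[str, str], set[SLMatch]], set[tuple[str, str]], list[DrugRecord]]:
    """Full tested-combination screen.

    Returns (matches per tested drug pair, all tested drug pairs, tested
    drugs with protein targets).  The tested-drug universe used for the
    single-drug exclusion is the set of drugs with protein targets that
    occur in any retained combination.
    """
    index = DrugIndex(drugs)
    relevant = filter_trials(trials, phases=phases, condition_terms=condition_terms)
    combos = extract_tested_combinations(relevant, index)
    tested_ids = sorted({i for combo, _ in combos for i in combo})
    tested_targeted = filter_drugs_with_protein_targets(
        [index.get(i) for i in tested_ids]
    )
    targeted_ids = {d.drug_id for d in tested_targeted}
    pairs: set[tuple[str, str]] = set()
    for combo, _ in combos:
        pairs |= expand_pairwise(combo)
    matches: dict[tuple[str, str], set[SLMatch]] = {}
    for pair in sorted(pairs):
        if not set(pair) <= targeted_ids:
            matches[pair] = set()
            continue
        matches[pair] = find_sl_matches(
            pair, index, sl_set, tested_targeted, status=TESTED
        )
    return matches, pairs, tested_targeted
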