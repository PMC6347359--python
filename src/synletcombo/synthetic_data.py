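"""Seeded generators for every pipeline input, with planted ground truth.

No public screen/orthology/trial corpus is bundled; instead this module
generates statistically controlled stand-ins for all of them:

* a human gene universe with a random interaction network in which true SL
  pairs are planted to sit stochastically closer (shared-neighbor motifs);
* per-gene annotation profiles in five namespaces where true SL pairs
  receive extra shared terms, so their Dice coefficients are elevated by a
  configurable boost (boost 0 gives a null world with no signal);
* a yeast genetic-interaction screen whose planted pairs pass the epsilon
  and p-value cutoffs by construction, plus filler records that mostly
  fail, with the exact pass-set recorded for oracle testing;
* multi-source ortholog tables linking the yeast genes to the human ones;
* a drug corpus and a clinical-trial corpus in which a configured number
  of trials study combinations planted to address true SL pairs, alongside
  distractor trials that violate each filtering rule.

Every generator is a pure function of (config, seed); ground truth is
returned in machine-readable form so each downstream stage has an oracle.

Two fixed in-print worked examples are also provided: the 14-drug /
12-combination tested-combination example (:func:`fixture_fig3`) and the
per-gene ovarian-neoplasms publication counts with the top-ranked novel
proposals (:func:`fixture_table1`, :func:`fixture_table1_matches`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .combo_screen import NOVEL, DrugRecord, SLMatch, TrialRecord
from .core import GenePair, SLInteractionSet, YEAST_DERIVED, canonicalize_pairs
from .network_features import (
    NAMESPACES,
    AnnotationProfile,
    InteractionNetwork,
)
from .synlet_build import GeneticInteractionRecord, OrthologRecord

# Fixed per-generator RNG salts: each generator draws from an independent,
# reproducible stream of the world seed.
_SALT_SL = 11
_SALT_NET = 12
_SALT_ANN = 13
_SALT_SCREEN = 14
_SALT_ORTH = 15
_SALT_DRUGS = 16


@dataclass(frozen=True)
class SyntheticWorldConfig:
    """Sizes, rates and effect strengths of a generated world.

    The defaults describe a small world (200 genes, 40 planted SL pairs,
    20 drugs, 30 trials) that runs the complete pipeline in seconds;
    :meth:`classifier_benchmark` scales the gene/SL side up to support a
    2,000-instance balanced training problem.
    """

    n_genes: int = 200
    edge_density: float = 0.04
    n_namespaces: int = 5
    vocab_size: int = 50
    terms_per_gene: float = 6.0
    n_true_sl: int = 40
    annotation_overlap_boost: float = 2.0
    topology_boost: float = 0.9
    full_annotation_rate: float = 0.9
    n_yeast_genes: int = 150
    n_screen_records: int = 400
    ortholog_rate: float = 0.7
    one_to_many_rate: float = 0.2
    n_drugs: int = 20
    targets_per_drug: float = 3.0
    n_trials: int = 30
    n_planted_combos: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "edge_density",
            "ortholog_rate",
            "one_to_many_rate",
            "full_annotation_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("n_genes", "vocab_size", "n_true_sl", "n_yeast_genes", "n_drugs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        pool = self.sl_gene_pool_size
        if self.n_true_sl > pool * (pool - 1) // 2:
            raise ValueError("n_true_sl exceeds the SL gene-pool pair count")

    @property
    def sl_gene_pool_size(self) -> int:
        """True SL pairs are planted among the first third of the genes."""
        return max(3, self.n_genes // 3)

    def null_variant(self) -> "SyntheticWorldConfig":
        """Matched null world: no annotation or topology signal."""
        return replace(self, annotation_overlap_boost=0.0, topology_boost=0.0)

    @classmethod
    def classifier_benchmark(cls, seed: int = 1) -> "SyntheticWorldConfig":
        """World sized for a 1,000 + 1,000 balanced instance set."""
        return cls(
            n_genes=700,
            edge_density=0.01,
            n_true_sl=1000,
            n_yeast_genes=300,
            seed=seed,
        )


def gene_names(config: SyntheticWorldConfig) -> list[str]:
    return [f"HSG{i:04d}" for i in range(config.n_genes)]


def yeast_gene_names(config: SyntheticWorldConfig) -> list[str]:
    return [f"YGL{i:04d}" for i in range(config.n_yeast_genes)]


def plant_true_sl(config: SyntheticWorldConfig) -> set[GenePair]:
    """The world's planted true SL pairs (deterministic in the seed)."""
    rng = np.random.default_rng([config.seed, _SALT_SL])
    pool = gene_names(config)[: config.sl_gene_pool_size]
    chosen: set[tuple[str, str]] = set()
    while len(chosen) < config.n_true_sl:
        i, j = rng.integers(0, len(pool), size=2)
        if i == j:
            continue
        a, b = (pool[i], pool[j]) if i < j else (pool[j], pool[i])
        chosen.add((a, b))
    return {GenePair(a, b) for a, b in chosen}


def generate_interaction_network(
    config: SyntheticWorldConfig,
    true_sl: set[GenePair] | None = None,
) -> InteractionNetwork:
    """Random graph at the configured density with planted SL proximity.

    For each true SL pair, with probability ``topology_boost`` both
    endpoints are wired to a shared random neighbor, bounding their
    distance by two hops and making SL pairs stochastically closer than
    random pairs.
    """
    if true_sl is None:
        true_sl = plant_true_sl(config)
    rng = np.random.default_rng([config.seed, _SALT_NET])
    genes = gene_names(config)
    n = len(genes)
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(len(iu)) < config.edge_density
    edges = {(genes[i], genes[j]) for i, j in zip(iu[mask], ju[mask])}
    for pair in sorted(true_sl):
        if rng.random() < config.topology_boost:
            hub = genes[int(rng.integers(0, n))]
            if hub not in (pair.gene_a, pair.gene_b):
                edges.add(tuple(sorted((pair.gene_a, hub))))
                edges.add(tuple(sorted((pair.gene_b, hub))))
    if not edges:
        raise ValueError(
            "edge density and topology boost produced an empty edge set"
        )
    return InteractionNetwork(edges=edges, nodes=genes)


def generate_annotations(
    config: SyntheticWorldConfig,
    true_sl: set[GenePair],
) -> list[AnnotationProfile]:
    """Random per-namespace term sets with extra shared terms on SL pairs.

    Every SL endpoint gene is fully annotated; the remaining genes are
    fully annotated at ``full_annotation_rate`` (otherwise one namespace is
    left empty).  For each SL pair and namespace, Poisson(boost) shared
    terms are added to both endpoints; with boost 0 the Dice distribution
    over SL pairs matches that over random pairs.
    """
    rng = np.random.default_rng([config.seed, _SALT_ANN])
    genes = gene_names(config)
    namespaces = NAMESPACES[: config.n_namespaces]
    vocab = {
        ns: [f"{ns}:t{j:03d}" for j in range(config.vocab_size)]
        for ns in namespaces
    }
    sl_genes = {g for p in true_sl for g in (p.gene_a, p.gene_b)}
    terms: dict[str, dict[str, set[str]]] = {}
    for gene in genes:
        fully = gene in sl_genes or rng.random() < config.full_annotation_rate
        dropped = (
            None if fully else namespaces[int(rng.integers(0, len(namespaces)))]
        )
        terms[gene] = {}
        for ns in namespaces:
            if ns == dropped:
                terms[gene][ns] = set()
                continue
            k = 1 + rng.poisson(max(config.terms_per_gene - 1, 0.0))
            k = min(k, config.vocab_size)
            idx = rng.choice(config.vocab_size, size=k, replace=False)
            terms[gene][ns] = {vocab[ns][i] for i in idx}
    for pair in sorted(true_sl):
        for ns in namespaces:
            m = rng.poisson(config.annotation_overlap_boost)
            if m == 0:
                continue
            idx = rng.choice(config.vocab_size, size=min(m, config.vocab_size), replace=False)
            shared = {vocab[ns][i] for i in idx}
            terms[pair.gene_a][ns] |= shared
            terms[pair.gene_b][ns] |= shared
    return [
        AnnotationProfile(
            gene=g,
            terms_by_namespace={
                ns: frozenset(ts) for ns, ts in terms[g].items()
            },
        )
        for g in genes
    ]


@dataclass
class YeastScreen:
    """Generated screen records plus the generator's own pass-set oracle."""

    records: list[GeneticInteractionRecord]
    expected_pass: set[GenePair]
    planted: set[GenePair]


def generate_yeast_screen(
    config: SyntheticWorldConfig,
    planted_pairs: set[GenePair] | None = None,
) -> YeastScreen:
    """Screen records with planted pairs passing the SL cutoffs.

    Planted pairs draw epsilon strictly below -0.08 and p strictly below
    0.05; filler records draw epsilon ~ N(0, 0.05) and p ~ U(0, 1), so
    only a small tail passes by chance.  The exact pass-set (planted plus
    lucky fillers, canonicalized) is recorded by reapplying the cutoffs
    row by row, independently of the filter implementation under test.
    """
    rng = np.random.default_rng([config.seed, _SALT_SCREEN])
    ygenes = yeast_gene_names(config)
    if planted_pairs is None:
        planted_pairs = set()
        n_planted = min(config.n_true_sl, len(ygenes) // 2)
        order = rng.permutation(len(ygenes))
        for k in range(n_planted):
            a, b = ygenes[order[2 * k]], ygenes[order[2 * k + 1]]
            planted_pairs.add(GenePair.make(a, b, species="yeast"))
    records: list[GeneticInteractionRecord] = []
    for pair in sorted(planted_pairs):
        eps = -0.081 - abs(rng.normal(0.0, 0.1))
        p = rng.uniform(0.0, 0.049)
        a, b = pair.gene_a, pair.gene_b
        if rng.random() < 0.5:  # screen tables list either orientation
            a, b = b, a
        records.append(GeneticInteractionRecord(a, b, float(eps), float(p)))
    n_filler = max(config.n_screen_records - len(records), 0)
    for _ in range(n_filler):
        i, j = rng.integers(0, len(ygenes), size=2)
        if i == j:
            continue
        records.append(
            GeneticInteractionRecord(
                ygenes[i],
                ygenes[j],
                float(rng.normal(0.0, 0.05)),
                float(rng.uniform(0.0, 1.0)),
            )
        )
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    passing = [
        (r.query_gene, r.array_gene)
        for r in records
        if r.p_value < 0.05 and r.epsilon < -0.08
    ]
    expected = canonicalize_pairs(
        passing, species="yeast", provenance=YEAST_DERIVED
    )
    return YeastScreen(
        records=records, expected_pass=expected, planted=set(planted_pairs)
    )


#: Names used for the emulated orthology resources.
ORTHOLOG_SOURCES: tuple[str, ...] = ("roundup", "oma", "ensembl", "inparanoid", "homologene")


def generate_ortholog_tables(
    config: SyntheticWorldConfig,
) -> tuple[list[list[OrthologRecord]], dict[str, set[str]]]:
    """Per-source ortholog tables plus the merged ground-truth map.

    Each yeast gene acquires a human ortholog with probability
    ``ortholog_rate`` (and a second one with ``one_to_many_rate``); each
    assertion is written into one to three randomly chosen sources.
    """
    rng = np.random.default_rng([config.seed, _SALT_ORTH])
    ygenes = yeast_gene_names(config)
    hgenes = gene_names(config)
    tables: dict[str, list[OrthologRecord]] = {s: [] for s in ORTHOLOG_SOURCES}
    truth: dict[str, set[str]] = {}
    for yg in ygenes:
        if rng.random() >= config.ortholog_rate:
            continue
        images = {hgenes[int(rng.integers(0, len(hgenes)))]}
        if rng.random() < config.one_to_many_rate:
            images.add(hgenes[int(rng.integers(0, len(hgenes)))])
        truth[yg] = set(images)
        for hg in sorted(images):
            n_src = 1 + int(rng.integers(0, 3))
            src_idx = rng.choice(len(ORTHOLOG_SOURCES), size=n_src, replace=False)
            for si in src_idx:
                tables[ORTHOLOG_SOURCES[si]].append(
                    OrthologRecord(yg, hg, ORTHOLOG_SOURCES[si])
                )
    return [tables[s] for s in ORTHOLOG_SOURCES], truth


@dataclass
class DrugCorpus:
    """Generated drugs and trials with the planted-combination ground truth."""

    drugs: list[DrugRecord]
    trials: list[TrialRecord]
    planted_combinations: list[tuple[frozenset[str], GenePair]]
    distractor_trial_ids: set[str]
    tested_drug_ids: set[str]


def generate_drug_corpus(
    config: SyntheticWorldConfig,
    sl_set: SLInteractionSet,
) -> DrugCorpus:
    """Drug records plus a trial corpus with planted SL-addressing combos.

    ``n_planted_combos`` SL pairs whose endpoints no drug co-targets each
    receive a dedicated pair of single-target drugs and one late-phase
    interventional trial studying exactly that combination; the remaining
    trials split into filler trials (valid by every rule, random multi-drug
    arms) and distractor trials each violating one filtering rule (wrong
    phase, wrong condition, observational type, or single-drug arms only).
    """
    rng = np.random.default_rng([config.seed, _SALT_DRUGS])
    genes = gene_names(config)
    drugs: list[DrugRecord] = []
    for i in range(config.n_drugs):
        if rng.random() < 0.2:
            targets: frozenset[str] = frozenset()  # DNA-only agent analogue
        else:
            k = 1 + rng.poisson(max(config.targets_per_drug - 1, 0.0))
            idx = rng.choice(len(genes), size=min(k, len(genes)), replace=False)
            targets = frozenset(genes[j] for j in idx)
        name = f"drug-{i:02d}"
        drugs.append(
            DrugRecord(
                drug_id=f"DRG{i:03d}",
                name=name,
                synonyms=frozenset({f"{name}-alias"}),
                targets=targets,
                modality="drug" if rng.random() < 0.8 else "biological",
            )
        )
    # Plant combinations on SL pairs whose endpoints no existing drug
    # co-targets, so the single-drug exclusion cannot veto them.
    candidates = [
        p
        for p in sorted(sl_set.pairs)
        if not any(
            p.gene_a in d.targets and p.gene_b in d.targets for d in drugs
        )
    ]
    order = rng.permutation(len(candidates))
    planted: list[tuple[frozenset[str], GenePair]] = []
    for k in range(min(config.n_planted_combos, len(candidates))):
        pair = candidates[order[k]]
        da = DrugRecord(
            drug_id=f"DRGP{k:02d}A",
            name=f"planted-{k:02d}-a",
            targets=frozenset({pair.gene_a}),
        )
        db = DrugRecord(
            drug_id=f"DRGP{k:02d}B",
            name=f"planted-{k:02d}-b",
            targets=frozenset({pair.gene_b}),
        )
        drugs.extend([da, db])
        planted.append((frozenset({da.drug_id, db.drug_id}), pair))
    by_id = {d.drug_id: d for d in drugs}

    conditions = ("ovarian cancer", "ovarian neoplasms", "ovarian carcinoma")
    trials: list[TrialRecord] = []
    distractor_ids: set[str] = set()
    tid = itertools.count(1)

    def next_id() -> str:
        return f"NCT-SYN-{next(tid):04d}"

    for combo, _pair in planted:
        trials.append(
            TrialRecord(
                trial_id=next_id(),
                phase="III" if rng.random() < 0.7 else "IV",
                study_type="interventional",
                conditions=(conditions[int(rng.integers(0, len(conditions)))],),
                arms=(frozenset(by_id[i].name for i in combo),),
            )
        )
    n_distractors = min(10, max(config.n_trials - len(trials), 0))
    base_names = [d.name for d in drugs[: config.n_drugs]]

    def random_arm(min_size: int = 2) -> frozenset[str]:
        size = min_size + int(rng.integers(0, 2))
        idx = rng.choice(len(base_names), size=min(size, len(base_names)), replace=False)
        return frozenset(base_names[j] for j in idx)

    distractor_kinds = ("phase", "condition", "type", "arm")
    for k in range(n_distractors):
        kind = distractor_kinds[k % len(distractor_kinds)]
        trial = TrialRecord(
            trial_id=next_id(),
            phase="II" if kind == "phase" else "III",
            study_type="observational" if kind == "type" else "interventional",
            conditions=("hypertension",) if kind == "condition" else (conditions[0],),
            arms=(
                (frozenset({base_names[int(rng.integers(0, len(base_names)))]}),)
                if kind == "arm"
                else (random_arm(),)
            ),
        )
        trials.append(trial)
        distractor_ids.add(trial.trial_id)
    while len(trials) < config.n_trials:
        trials.append(
            TrialRecord(
                trial_id=next_id(),
                phase="III" if rng.random() < 0.7 else "IV",
                study_type="interventional",
                conditions=(conditions[int(rng.integers(0, len(conditions)))],),
                arms=(random_arm(),),
            )
        )
    order = rng.permutation(len(trials))
    trials = [trials[i] for i in order]
    id_by_name = {d.name: d.drug_id for d in drugs}
    tested_ids = {
        id_by_name[name]
        for t in trials
        if t.trial_id not in distractor_ids
        for arm in t.arms
        for name in arm
    }
    return DrugCorpus(
        drugs=drugs,
        trials=trials,
        planted_combinations=planted,
        distractor_trial_ids=distractor_ids,
        tested_drug_ids=tested_ids,
    )


@dataclass
class SyntheticWorld:
    """A complete generated input world plus all planted ground truth."""

    config: SyntheticWorldConfig
    genes: list[str]
    true_sl: set[GenePair]
    network: InteractionNetwork
    profiles: list[AnnotationProfile]
    yeast_screen: YeastScreen
    ortholog_tables: list[list[OrthologRecord]]
    ortholog_truth: dict[str, set[str]]
    drug_corpus: DrugCorpus

    @property
    def sl_set(self) -> SLInteractionSet:
        return SLInteractionSet(self.true_sl, provenance=YEAST_DERIVED)


def generate_world(config: SyntheticWorldConfig) -> SyntheticWorld:
    """Generate every pipeline input for one seeded world."""
    true_sl = plant_true_sl(config)
    network = generate_interaction_network(config, true_sl)
    profiles = generate_annotations(config, true_sl)
    screen = generate_yeast_screen(config)
    tables, truth = generate_ortholog_tables(config)
    corpus = generate_drug_corpus(
        config, SLInteractionSet(true_sl, provenance=YEAST_DERIVED)
    )
    return SyntheticWorld(
        config=config,
        genes=gene_names(config),
        true_sl=true_sl,
        network=network,
        profiles=profiles,
        yeast_screen=screen,
        ortholog_tables=tables,
        ortholog_truth=truth,
        drug_corpus=corpus,
    )


# ---------------------------------------------------------------------------
# Fixed worked-example fixtures (in-print data, normative for tests)
# ---------------------------------------------------------------------------

_FIG3_DRUGS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("paclitaxel", ("BCL2", "TUBB1")),
    ("docetaxel", ("BCL2",)),
    ("veliparib", ("PARP1", "PARP2")),
    ("olaparib", ("PARP1", "PARP2")),
    ("pertuzumab", ("ERBB2",)),
    ("trastuzumab", ("ERBB2",)),
    ("bevacizumab", ("VEGFA",)),
    ("gemcitabine", ("RRM1",)),
    ("fosbretabulin", ("TUBB",)),
    ("interferon gamma-1b", ("IFNGR1", "IFNGR2")),
    ("cediranib", ("KDR",)),
    (
        "nintedanib",
        ("KDR", "FGFR1", "FGFR2", "FGFR3", "PDGFA", "PDGFB", "SRC", "LCK"),
    ),
    ("valproic acid", ("ALDH5A1",)),
    ("hydralazine", ("AOC3",)),
)

_FIG3_SL_PAIRS: tuple[tuple[str, str], ...] = (
    ("PARP1", "BCL2"),
    ("PARP2", "BCL2"),
    ("ERBB2", "BCL2"),
    ("VEGFA", "BCL2"),
    ("RRM1", "BCL2"),
    ("TUBB", "BCL2"),
    ("KDR", "BCL2"),
    ("TUBB1", "IFNGR1"),
    ("TUBB1", "IFNGR2"),
    ("PARP1", "KDR"),
    ("PARP2", "KDR"),
    ("ALDH5A1", "AOC3"),
)

_FIG3_COMBOS: tuple[tuple[str, str], ...] = (
    ("paclitaxel", "veliparib"),
    ("paclitaxel", "pertuzumab"),
    ("paclitaxel", "trastuzumab"),
    ("paclitaxel", "bevacizumab"),
    ("paclitaxel", "gemcitabine"),
    ("paclitaxel", "fosbretabulin"),
    ("paclitaxel", "interferon gamma-1b"),
    ("paclitaxel", "cediranib"),
    ("paclitaxel", "nintedanib"),
    ("docetaxel", "bevacizumab"),
    ("olaparib", "cediranib"),
    ("valproic acid", "hydralazine"),
)


def _fig3_drug_id(name: str) -> str:
    return name.replace(" ", "_")


def fixture_fig3() -> tuple[list[DrugRecord], list[frozenset[str]], SLInteractionSet]:
    """The fixed tested-combination worked example.

    Returns 14 drugs with their protein-target sets, the 12 tested
    two-drug combinations (nine of which involve paclitaxel), and the
    12-pair SL set they address.
    """
    drugs = [
        DrugRecord(
            drug_id=_fig3_drug_id(name),
            name=name,
            targets=frozenset(targets),
        )
        for name, targets in _FIG3_DRUGS
    ]
    combos = [
        frozenset({_fig3_drug_id(a), _fig3_drug_id(b)}) for a, b in _FIG3_COMBOS
    ]
    sl_set = SLInteractionSet(
        (GenePair.make(a, b) for a, b in _FIG3_SL_PAIRS),
        provenance=YEAST_DERIVED,
    )
    return drugs, combos, sl_set


#: Per-gene ovarian-neoplasms publication counts of the ranking example.
_TABLE1_COUNTS: tuple[tuple[str, int], ...] = (
    ("ERBB2", 695),
    ("EGFR", 636),
    ("VEGFA", 567),
    ("JUN", 536),
    ("TOP1", 128),
    ("SRC", 113),
    ("BCL2", 66),
    ("PARP1", 41),
    ("FGFR2", 24),
    ("PDGFB", 23),
    ("KDR", 22),
    ("PDGFA", 19),
    ("FGFR1", 18),
    ("ABL1", 10),
    ("FGFR3", 7),
    ("LCK", 7),
    ("PARP2", 2),
    ("SPHK1", 2),
    ("ESD", 2),
)


def fixture_table1() -> dict[str, int]:
    """Per-gene publication counts of the printed ranking example."""
    return dict(_TABLE1_COUNTS)


#: (drug targeting partner A, drug targeting partner B, partner A, partner B)
#: rows of the printed novel-proposal ranking, in printed order.
_TABLE1_ROWS: tuple[tuple[str, str, str, str], ...] = (
    ("Pertuzumab", "Bevacizumab", "ERBB2", "VEGFA"),
    ("Trastuzumab", "Bevacizumab", "ERBB2", "VEGFA"),
    ("Pertuzumab", "Saracatinib", "ERBB2", "SRC"),
    ("Pertuzumab", "Nintedanib", "ERBB2", "SRC"),
    ("Trastuzumab", "Nintedanib", "ERBB2", "SRC"),
    ("Trastuzumab", "Saracatinib", "ERBB2", "SRC"),
    ("Pertuzumab", "Docetaxel", "ERBB2", "BCL2"),
    ("Trastuzumab", "Docetaxel", "ERBB2", "BCL2"),
    ("Trastuzumab", "Nintedanib", "EGFR", "SRC"),
    ("Trastuzumab", "Saracatinib", "EGFR", "SRC"),
    ("Pertuzumab", "Olaparib", "ERBB2", "PARP1"),
    ("Pertuzumab", "Veliparib", "ERBB2", "PARP1"),
    ("Trastuzumab", "Veliparib", "ERBB2", "PARP1"),
    ("Trastuzumab", "Olaparib", "ERBB2", "PARP1"),
    ("Pertuzumab", "Nintedanib", "ERBB2", "FGFR2"),
    ("Trastuzumab", "Nintedanib", "ERBB2", "FGFR2"),
    ("Pertuzumab", "Nintedanib", "ERBB2", "PDGFB"),
    ("Trastuzumab", "Nintedanib", "ERBB2", "PDGFB"),
    ("Pertuzumab", "Cediranib", "ERBB2", "KDR"),
    ("Pertuzumab", "Nintedanib", "ERBB2", "KDR"),
    ("Trastuzumab", "Cediranib", "ERBB2", "KDR"),
    ("Trastuzumab", "Nintedanib", "ERBB2", "KDR"),
    ("Pertuzumab", "Nintedanib", "ERBB2", "PDGFA"),
    ("Trastuzumab", "Nintedanib", "ERBB2", "PDGFA"),
    ("Pertuzumab", "Nintedanib", "ERBB2", "FGFR1"),
    ("Trastuzumab", "Nintedanib", "ERBB2", "FGFR1"),
    ("Pertuzumab", "Saracatinib", "ERBB2", "ABL1"),
    ("Trastuzumab", "Saracatinib", "ERBB2", "ABL1"),
    ("Pertuzumab", "Nintedanib", "ERBB2", "FGFR3"),
    ("Trastuzumab", "Nintedanib", "ERBB2", "FGFR3"),
    ("Pertuzumab", "Nintedanib", "ERBB2", "LCK"),
    ("Trastuzumab", "Nintedanib", "ERBB2", "LCK"),
    ("Pertuzumab", "Olaparib", "ERBB2", "PARP2"),
    ("Pertuzumab", "Veliparib", "ERBB2", "PARP2"),
    ("Trastuzumab", "Veliparib", "ERBB2", "PARP2"),
    ("Trastuzumab", "Olaparib", "ERBB2", "PARP2"),
    ("Pertuzumab", "Phenoxodiol", "ERBB2", "SPHK1"),
    ("Trastuzumab", "Phenoxodiol", "ERBB2", "SPHK1"),
    ("Trastuzumab", "Nintedanib", "EGFR", "FGFR1"),
    ("Trastuzumab", "Nintedanib", "EGFR", "LCK"),
    ("Vinblastine", "Paclitaxel", "JUN", "BCL2"),
    ("Vinblastine", "Docetaxel", "JUN", "BCL2"),
    ("Bevacizumab", "Nintedanib", "VEGFA", "PDGFB"),
    ("Bevacizumab", "Nintedanib", "VEGFA", "KDR"),
    ("Bevacizumab", "Cediranib", "VEGFA", "KDR"),
    ("Bevacizumab", "Nintedanib", "VEGFA", "PDGFA"),
    ("Bevacizumab", "Nintedanib", "VEGFA", "FGFR3"),
    ("Topotecan", "Glutathione", "TOP1", "ESD"),
    ("Topotecan", "Phenoxodiol", "TOP1", "SPHK1"),
    ("Docetaxel", "Veliparib", "BCL2", "PARP1"),
    ("Paclitaxel", "Olaparib", "BCL2", "PARP1"),
    ("Docetaxel", "Olaparib", "BCL2", "PARP1"),
)


def fixture_table1_matches() -> list[SLMatch]:
    """The printed novel drug-pair / SL-pair proposals as SLMatch records.

    Gene endpoints are canonicalized (drug order follows gene order), so
    rows printed gene-major may swap drug columns.
    """
    return [
        SLMatch.make(
            _fig3_drug_id(drug_a.lower()),
            gene_a,
            _fig3_drug_id(drug_b.lower()),
            gene_b,
            status=NOVEL,
        )
        for drug_a, drug_b, gene_a, gene_b in _TABLE1_ROWS
    ]
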