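"""Readers and writers for the pipeline's plain-text file formats.

All tables are tab-separated with a header row; trials are JSON lines.
Multi-valued cells (synonyms, targets, provenance tags) are pipe-separated.
Feature tables carry a ``# feature_version=...`` comment line so a trained
model is never applied to features in a different layout.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import joblib
import pandas as pd

from .combo_screen import DrugRecord, RankedProposal, TrialRecord
from .core import GenePair, SLInteractionSet
from .network_features import (
    FEATURE_ORDER,
    FEATURE_VERSION,
    AnnotationProfile,
    InteractionNetwork,
    PairFeatureVector,
)
from .sl_inference import SLClassifier
from .synlet_build import GeneticInteractionRecord, OrthologRecord


def _split_multi(cell: object) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or cell == "":
        return frozenset()
    return frozenset(str(cell).split("|"))


# -- yeast screen -----------------------------------------------------------

def write_screen_tsv(records: Iterable[GeneticInteractionRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            (r.query_gene, r.array_gene, r.epsilon, r.p_value)
            for r in records
        ],
        columns=["query_gene", "array_gene", "epsilon", "p_value"],
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_screen_tsv(path: str | Path) -> list[GeneticInteractionRecord]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        GeneticInteractionRecord(
            str(row.query_gene), str(row.array_gene), float(row.epsilon), float(row.p_value)
        )
        for row in df.itertuples(index=False)
    ]


# -- orthologs --------------------------------------------------------------

def write_ortholog_tsv(records: Iterable[OrthologRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.yeast_gene, r.human_gene, r.source) for r in records],
        columns=["yeast_gene", "human_gene", "source"],
    ).to_csv(path, sep="\t", index=False)


def read_ortholog_tsv(path: str | Path) -> list[OrthologRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        OrthologRecord(str(r.yeast_gene), str(r.human_gene), str(r.source))
        for r in df.itertuples(index=False)
    ]


# -- SL pair sets -----------------------------------------------------------

def write_sl_pairs_tsv(sl_set: SLInteractionSet, path: str | Path) -> None:
    rows = [
        (p.gene_a, p.gene_b, p.provenance or "")
        for p in sl_set  # iteration is sorted -> deterministic files
    ]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "provenance"]).to_csv(
        path, sep="\t", index=False
    )


def read_sl_pairs_tsv(path: str | Path, species: str = "human") -> SLInteractionSet:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = SLInteractionSet(species=species)
    for row in df.itertuples(index=False):
        tags = _split_multi(row.provenance)
        if tags:
            for tag in tags:
                out.add((str(row.gene_a), str(row.gene_b)), provenance=tag)
        else:
            out.add((str(row.gene_a), str(row.gene_b)))
    return out


# -- network & annotations --------------------------------------------------

def write_network_tsv(network: InteractionNetwork, path: str | Path) -> None:
    pd.DataFrame(
        sorted(network.edges), columns=["gene_a", "gene_b"]
    ).to_csv(path, sep="\t", index=False)


def read_network_tsv(path: str | Path) -> InteractionNetwork:
    df = pd.read_csv(path, sep="\t")
    return InteractionNetwork(
        edges=[(str(r.gene_a), str(r.gene_b)) for r in df.itertuples(index=False)]
    )


def write_annotations_tsv(profiles: Iterable[AnnotationProfile], path: str | Path) -> None:
    rows = [
        (p.gene, ns, term)
        for p in profiles
        for ns, terms in sorted(p.terms_by_namespace.items())
        for term in sorted(terms)
    ]
    pd.DataFrame(rows, columns=["gene", "namespace", "term"]).to_csv(
        path, sep="\t", index=False
    )


def read_annotations_tsv(path: str | Path) -> list[AnnotationProfile]:
    df = pd.read_csv(path, sep="\t")
    by_gene: dict[str, dict[str, set[str]]] = {}
    for row in df.itertuples(index=False):
        by_gene.setdefault(str(row.gene), {}).setdefault(
            str(row.namespace), set()
        ).add(str(row.term))
    return [
        AnnotationProfile(
            gene=g,
            terms_by_namespace={ns: frozenset(t) for ns, t in spaces.items()},
        )
        for g, spaces in sorted(by_gene.items())
    ]


# -- feature tables ---------------------------------------------------------

def write_features_tsv(
    features: Sequence[tuple[GenePair, PairFeatureVector]],
    path: str | Path,
) -> None:
    path = Path(path)
    versions = {fv.feature_version for _, fv in features} or {FEATURE_VERSION}
    if len(versions) > 1:
        raise ValueError(f"mixed feature versions: {sorted(versions)}")
    rows = [
        [pair.gene_a, pair.gene_b, *fv.as_array().tolist()]
        for pair, fv in features
    ]
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", *FEATURE_ORDER])
    with path.open("w") as fh:
        fh.write(f"# feature_version={next(iter(versions))}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_features_tsv(
    path: str | Path,
) -> list[tuple[GenePair, PairFeatureVector]]:
    path = Path(path)
    version = FEATURE_VERSION
    with path.open() as fh:
        first = fh.readline()
    if first.startswith("# feature_version="):
        version = first.strip().split("=", 1)[1]
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    out = []
    for row in df.itertuples(index=False):
        values = [getattr(row, name) for name in FEATURE_ORDER]
        out.append(
            (
                GenePair.make(str(row.gene_a), str(row.gene_b)),
                PairFeatureVector.from_array(values, feature_version=version),
            )
        )
    return out


# -- labels -----------------------------------------------------------------

def write_labels_tsv(labels: Mapping[tuple[str, str], str], path: str | Path) -> None:
    rows = sorted((a, b, lab) for (a, b), lab in labels.items())
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "label"]).to_csv(
        path, sep="\t", index=False
    )


def read_labels_tsv(path: str | Path) -> dict[tuple[str, str], str]:
    df = pd.read_csv(path, sep="\t")
    return {
        (str(r.gene_a), str(r.gene_b)): str(r.label)
        for r in df.itertuples(index=False)
    }


# -- drugs, trials, counts --------------------------------------------------

def write_drugs_tsv(drugs: Iterable[DrugRecord], path: str | Path) -> None:
    rows = [
        (
            d.drug_id,
            d.name,
            "|".join(sorted(d.synonyms)),
            d.modality,
            "|".join(sorted(d.targets)),
        )
        for d in sorted(drugs, key=lambda d: d.drug_id)
    ]
    pd.DataFrame(
        rows, columns=["drug_id", "name", "synonyms", "modality", "targets"]
    ).to_csv(path, sep="\t", index=False)


def read_drugs_tsv(path: str | Path) -> list[DrugRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [
        DrugRecord(
            drug_id=str(r.drug_id),
            name=str(r.name),
            synonyms=_split_multi(r.synonyms),
            modality=str(r.modality),
            targets=_split_multi(r.targets),
        )
        for r in df.itertuples(index=False)
    ]


def write_trials_jsonl(trials: Iterable[TrialRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for t in trials:
            fh.write(
                json.dumps(
                    {
                        "trial_id": t.trial_id,
                        "phase": t.phase,
                        "study_type": t.study_type,
                        "conditions": list(t.conditions),
                        "arms": [sorted(arm) for arm in t.arms],
                    }
                )
                + "\n"
            )


def read_trials_jsonl(path: str | Path) -> list[TrialRecord]:
    out = []
    with Path(path).open() as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            out.append(
                TrialRecord(
                    trial_id=str(obj["trial_id"]),
                    phase=str(obj["phase"]),
                    study_type=str(obj["study_type"]),
                    conditions=tuple(obj["conditions"]),
                    arms=tuple(frozenset(arm) for arm in obj["arms"]),
                )
            )
    return out


def write_counts_tsv(counts: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame(
        sorted(counts.items()), columns=["gene", "pmid_count"]
    ).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    return {str(r.gene): int(r.pmid_count) for r in df.itertuples(index=False)}


# -- ranked proposals -------------------------------------------------------

def write_proposals_tsv(proposals: Sequence[RankedProposal], path: str | Path) -> None:
    rows = [
        (
            p.match.drug_a,
            p.match.drug_b,
            p.match.gene_a,
            p.match.gene_b,
            p.annotation_degree,
            p.count_a,
            p.count_b,
            p.match.status,
        )
        for p in proposals
    ]
    pd.DataFrame(
        rows,
        columns=[
            "drug_a",
            "drug_b",
            "synlet_a",
            "synlet_b",
            "annotation_degree",
            "count_a",
            "count_b",
            "status",
        ],
    ).to_csv(path, sep="\t", index=False)


# -- model artifacts --------------------------------------------------------

def save_model(model: SLClassifier, path: str | Path) -> None:
    joblib.dump(
        {
            "estimator": model.estimator,
            "n_trees": model.n_trees,
            "seed": model.seed,
            "tree_grid": list(model.tree_grid),
            "cv_accuracy": model.cv_accuracy,
            "feature_version": model.feature_version,
        },
        path,
    )


def load_model(path: str | Path) -> SLClassifier:
    payload = joblib.load(path)
    return SLClassifier(
        estimator=payload["estimator"],
        n_trees=payload["n_trees"],
        seed=payload["seed"],
        tree_grid=tuple(payload["tree_grid"]),
        cv_accuracy=dict(payload["cv_accuracy"]),
        feature_version=payload["feature_version"],
    )
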