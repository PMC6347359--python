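"""End-to-end classifier benchmark on generated worlds.

Ties the synthetic-data generators to the inference pipeline: build a
world, featurize its planted SL pairs (positives) and an equal number of
sampled non-SL pairs (negatives), split 2/3-1/3, tune the forest by
cross-validation and evaluate on the held-out third.  Used both as a
signal-recovery check (planted worlds should be learnable) and as a null
calibration (boost-free worlds should sit at chance).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .core import SLInteractionSet, YEAST_DERIVED
from .network_features import (
    build_feature_table,
    eligible_nodes,
    node_statistics,
    profiles_by_gene,
)
from .sl_inference import (
    DEFAULT_TREE_GRID,
    ClassifierMetrics,
    LabeledInstance,
    NEGATIVE,
    POSITIVE,
    SLClassifier,
    evaluate_classifier,
    sample_negative_pairs,
    split_train_test,
    train_classifier,
)
from .synthetic_data import SyntheticWorldConfig, generate_world, SyntheticWorld


@dataclass
class BenchmarkResult:
    world: SyntheticWorld
    instances: list[LabeledInstance]
    train: list[LabeledInstance]
    test: list[LabeledInstance]
    model: SLClassifier
    metrics: ClassifierMetrics


def make_labeled_instances(
    world: SyntheticWorld,
    seed: int | None = None,
) -> list[LabeledInstance]:
    """Balanced instances: planted SL pairs vs sampled non-SL pairs.

    Positives are the world's planted SL pairs (their endpoints are fully
    annotated by construction); negatives are sampled among fully
    annotated genes taking part in no SL pair, one per positive.
    """
    if seed is None:
        seed = world.config.seed
    profiles = profiles_by_gene(world.profiles)
    stats = node_statistics(world.network)
    known = SLInteractionSet(world.true_sl, provenance=YEAST_DERIVED)
    eligible = eligible_nodes(world.profiles)
    positives = sorted(world.true_sl)
    negatives = sorted(
        sample_negative_pairs(eligible, known, n=len(positives), seed=seed)
    )
    instances: list[LabeledInstance] = []
    for pairs, label in ((positives, POSITIVE), (negatives, NEGATIVE)):
        for pair, fv in build_feature_table(
            pairs, profiles, stats, world.network
        ):
            instances.append(LabeledInstance(pair=pair, features=fv, label=label))
    return instances


def run_classifier_benchmark(
    config: SyntheticWorldConfig,
    train_fraction: float = 2.0 / 3.0,
    cv_folds: int = 10,
    tree_grid: Sequence[int] = DEFAULT_TREE_GRID,
) -> BenchmarkResult:
    """Generate a world, train the tuned forest, and evaluate held-out."""
    world = generate_world(config)
    instances = make_labeled_instances(world)
    train, test = split_train_test(
        instances, train_fraction=train_fraction, seed=config.seed
    )
    model = train_classifier(
        train, cv_folds=cv_folds, tree_grid=tree_grid, seed=config.seed
    )
    metrics = evaluate_classifier(model, test)
    return BenchmarkResult(
        world=world,
        instances=instances,
        train=train,
        test=test,
        model=model,
        metrics=metrics,
    )
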