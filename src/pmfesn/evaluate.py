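"""Max-similarity classification and the leave-one-case-out harness.

A held-out case is classified by computing its similarity to every
*original* (non-augmented) training sample and taking the class of the most
similar one; exact similarity ties are broken uniformly at random and
flagged. The harness repeats the entire training pipeline — stage-1
augmentation, stage-2 pair construction, fold-mean centering, training from
scratch — once per case, with the held-out case excluded from every one of
those steps, and aggregates the per-fold predictions into the full
imbalance-insensitive metric suite.

A fold whose held-out class has no remaining training exemplar (a singleton
class) still runs; its prediction is structurally forced to be wrong and the
fold is simply counted like any other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .augment import AugmentationPolicy, augment_to_balance
from .io import N_CLASSES, Dataset
from .metrics import EvaluationReport, FoldRecord, build_report
from .model import ModelState, SiameseSpec, TrainConfig, normalized_cosine, train
from .pairs import build_pairs, split_train_val
from .preprocess import PreparedSample, fold_mean_center, prepare_case

__all__ = ["LocoConfig", "predict", "loco_evaluate"]


def predict(
    state: ModelState,
    test: PreparedSample,
    originals: Sequence[PreparedSample],
    rng: Optional[np.random.Generator] = None,
    n_classes: int = N_CLASSES,
) -> FoldRecord:
    """Classify ``test`` by maximum similarity over the original samples.

    ``originals`` must be non-empty and contain no augmentation products.
    The per-class score is the maximum similarity to that class's originals
    (NaN for classes with no original in this fold). Exact ties for the
    global maximum are broken uniformly at random and flagged.
    """
    originals = list(originals)
    if not originals:
        raise ValueError("reference set is empty")
    augmented = [s.case_id for s in originals if s.provenance != "original"]
    if augmented:
        raise ValueError(f"augmented samples may not serve as references: {augmented}")
    rng = rng or np.random.default_rng(0)
    emb = state.embed([test] + originals, train=False)
    sims = normalized_cosine(emb[0][None, :], emb[1:])
    best = sims.max()
    contenders = np.flatnonzero(sims == best)
    tie = len(contenders) > 1
    pick = int(contenders[rng.integers(len(contenders))]) if tie else int(contenders[0])
    scores = np.full(n_classes, np.nan)
    for m in range(n_classes):
        mask = np.array([s.mrs == m for s in originals])
        if mask.any():
            scores[m] = sims[mask].max()
    return FoldRecord(
        held_out_case_id=test.case_id,
        true_mrs=test.mrs,
        predicted_mrs=originals[pick].mrs,
        class_scores=tuple(scores.tolist()),
        tie=tie,
    )


@dataclass(frozen=True)
class LocoConfig:
    """Everything one leave-one-case-out run needs besides the data."""

    spec: SiameseSpec = field(default_factory=SiameseSpec)
    train: TrainConfig = field(default_factory=TrainConfig)
    policy: AugmentationPolicy = field(default_factory=AugmentationPolicy)
    prepare_target: tuple = (150, 150, 21)
    n_classes: int = N_CLASSES


def _fold_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def loco_evaluate(dataset: Dataset, config: LocoConfig, seed: int = 0) -> EvaluationReport:
    """Run the full pipeline once per held-out case and aggregate metrics.

    Per fold, derived sub-seeds drive augmentation, pair sampling, the
    train/validation split, weight initialization, and tie breaking, so a
    run is fully reproducible from (dataset, config, seed). The held-out
    case contributes to none of augmentation, the fold mean, pairing, or
    training, and augmented samples never enter the reference set.
    """
    cases = list(dataset.cases)
    if len(cases) < 2:
        raise ValueError("need at least two cases")
    labels = {c.mrs for c in cases}
    if len(labels) < 2:
        raise ValueError("need at least two classes")

    prepared = [prepare_case(c, config.prepare_target) for c in cases]
    fold_seeds = np.random.SeedSequence(seed).spawn(len(cases))
    folds = []
    for i, test in enumerate(prepared):
        sub = fold_seeds[i].spawn(5)
        train_orig = [s for j, s in enumerate(prepared) if j != i]
        augmented = augment_to_balance(
            train_orig, config.policy, rng=np.random.default_rng(sub[0])
        )
        centered_train, centered_test = fold_mean_center(augmented, test)
        pairset = build_pairs(centered_train, seed=_fold_seed(sub[1]))
        tr, val = split_train_val(pairset, seed=_fold_seed(sub[2]))
        fold_cfg = TrainConfig(**{**config.train.__dict__, "seed": _fold_seed(sub[3])})
        state = train(config.spec, tr, val, fold_cfg)
        references = [s for s in centered_train if s.provenance == "original"]
        folds.append(
            predict(
                state,
                centered_test,
                references,
                rng=np.random.default_rng(sub[4]),
                n_classes=config.n_classes,
            )
        )
    return build_report(folds, config.n_classes)
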