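"""Repeated stratified k-fold multi-class evaluation of a gene panel.

Each repeat draws a fresh seeded stratified k-fold split, trains a
random forest on the panel genes only, predicts the held-out folds and
accumulates a predicted × truth confusion grid; grids are averaged over
repeats, so counts are fractional.  Per-repeat seeds derive
deterministically from the master seed via ``numpy.random.SeedSequence``
(prefix-stable: repeat r uses the same seed regardless of the total
repeat count).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .core import CohortAnnotation, ExpressionMatrix, MarkerPanel, PrfPipeError

__all__ = ["CVConfig", "ConfusionSummary", "repeated_cv", "true_rates"]

DEFAULT_LABELS = ("NS", "SMK", "COPD")


@dataclass
class CVConfig:
    """Repeated cross-validation settings (defaults: 5-fold, 100 repeats,
    500-tree forest with sqrt(p) features per split)."""

    k: int = 5
    repeats: int = 100
    seed: int = 0
    n_trees: int = 500
    max_features: str | float = "sqrt"
    labels: tuple[str, ...] = DEFAULT_LABELS
    classifier_factory: Callable[[int], object] | None = None

    def __post_init__(self) -> None:
        if self.k < 2:
            raise PrfPipeError("k must be >= 2")
        if self.repeats < 1:
            raise PrfPipeError("repeats must be >= 1")

    def make_classifier(self, seed: int):
        if self.classifier_factory is not None:
            return self.classifier_factory(seed)
        return RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=self.max_features,
            random_state=seed,
            n_jobs=1,
        )


@dataclass
class ConfusionSummary:
    """Repeat-averaged confusion counts (rows predicted, columns truth)."""

    mean_counts: pd.DataFrame
    n_samples: int
    repeats: int
    seed: int

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.mean_counts.index)

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.mean_counts.to_numpy()) / self.n_samples)

    @property
    def macro_accuracy(self) -> float:
        """Unweighted mean of the per-truth-class recall rates."""
        rates = [r for r in true_rates(self).values() if not np.isnan(r)]
        return float(np.mean(rates))

    def row_rates(self) -> dict[str, float]:
        """Precision-style rates: diagonal over the predicted-row sum."""
        counts = self.mean_counts
        out = {}
        for lab in self.labels:
            row = counts.loc[lab].sum()
            out[lab] = float(counts.loc[lab, lab] / row) if row > 0 else float("nan")
        return out

    def summary(self) -> str:
        lines = [
            f"Repeated {len(self.labels)}-class CV confusion "
            f"({self.repeats} repeats, n={self.n_samples})",
            self.mean_counts.round(2).to_string(),
            "true rate (per truth class): "
            + ", ".join(f"{k}={v:.2f}" for k, v in true_rates(self).items()),
            f"overall accuracy: {self.overall_accuracy:.3f}"
            f"   macro accuracy: {self.macro_accuracy:.3f}",
        ]
        return "\n".join(lines)


def repeated_cv(
    matrix: ExpressionMatrix,
    annotations: Sequence[CohortAnnotation],
    panel: MarkerPanel,
    config: CVConfig = CVConfig(),
) -> ConfusionSummary:
    """Repeated seeded stratified k-fold CV on the panel genes.

    Every sample is predicted exactly once per repeat, so the columns of
    ``mean_counts`` sum to the true class sizes exactly.
    """
    ann_by_id = {a.sample_id: a for a in annotations}
    missing = [s for s in matrix.sample_ids if s not in ann_by_id]
    if missing:
        raise PrfPipeError(f"samples without annotation: {missing}")
    y = np.array([ann_by_id[s].status.value for s in matrix.sample_ids])
    labels = list(config.labels)
    class_counts = pd.Series(y).value_counts()
    small = [lab for lab in labels if class_counts.get(lab, 0) < config.k]
    if small:
        raise PrfPipeError(f"classes with fewer than k={config.k} members: {small}")

    X = matrix.subset_genes(list(panel.gene_ids)).values.T  # samples x genes
    lab_index = {lab: i for i, lab in enumerate(labels)}
    y_idx = np.array([lab_index[v] for v in y])

    # two seed words per repeat: one for the fold split, one for the forest
    seeds = np.random.SeedSequence(config.seed).generate_state(2 * config.repeats)
    total = np.zeros((len(labels), len(labels)), dtype=float)
    for r in range(config.repeats):
        split_seed = int(seeds[2 * r] % (2**31))
        clf_seed = int(seeds[2 * r + 1] % (2**31))
        skf = StratifiedKFold(n_splits=config.k, shuffle=True, random_state=split_seed)
        for train, test in skf.split(X, y_idx):
            clf = config.make_classifier(clf_seed)
            clf.fit(X[train], y_idx[train])
            pred = clf.predict(X[test])
            np.add.at(total, (pred, y_idx[test]), 1.0)

    mean_counts = pd.DataFrame(total / config.repeats, index=labels, columns=labels)
    return ConfusionSummary(
        mean_counts=mean_counts,
        n_samples=len(y),
        repeats=config.repeats,
        seed=config.seed,
    )


def true_rates(summary: ConfusionSummary) -> dict[str, float]:
    """Per-class correct-classification rate: diagonal over the truth column.

    This is recall per truth class computed on the repeat-averaged grid;
    a truth class that was never seen yields a missing (NaN) rate.
    """
    counts = summary.mean_counts
    out = {}
    for lab in summary.labels:
        col = counts[lab].sum()
        out[lab] = float(counts.loc[lab, lab] / col) if col > 0 else float("nan")
    return out
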