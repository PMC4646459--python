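"""Reporting statistics for predicted DMR sets.

- prediction power: the percentage of predicted DMRs containing a feature
  (optionally stratified by flank region);
- prediction accuracy: the fraction of a single-polarity control set the
  classifier calls positive (recall on positive controls; anything near or
  below 50% on negative controls means no predictive signal);
- CpG-density distribution of predictions;
- overlap between two predicted site sets;
- stratified 10-fold cross-validation of the full training pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .boosting import BoostedEnsemble
from .features import (FeatureCatalog, GenomeSequence, GenomicWindow,
                       RepeatAnnotation, cpg_density,
                       extract_feature_matrix)
from .tan import TANModel

__all__ = [
    "ValidationReport",
    "prediction_power",
    "positive_density_bins",
    "prediction_accuracy",
    "site_set_overlap",
    "cpg_density_distribution",
    "cross_validate",
]


@dataclass(frozen=True)
class ValidationReport:
    set_name: str
    n_sites: int
    accuracy: float           # fraction of the set called positive
    polarity: str             # "positive" or "negative" control

    def __post_init__(self):
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must be in [0, 1]")
        if self.polarity not in ("positive", "negative"):
            raise ValueError("polarity must be positive or negative")


def prediction_power(dmr_features: pd.DataFrame,
                     predicates: Mapping[str, Callable[[np.ndarray],
                                                       np.ndarray]]
                     | None = None,
                     group_by_region: bool = False) -> pd.Series:
    """Percent of predicted DMRs satisfying each feature predicate.

    ``dmr_features`` is the annotated feature matrix of the merged DMRs
    (columns named ``name:region`` as written by the annotation step).
    The default predicate is presence (value > 0); pass a callable per
    column to override (e.g. a model-referenced density criterion).  With
    ``group_by_region`` the per-feature powers are averaged within each
    flank region.
    """
    if dmr_features.shape[0] == 0:
        raise ValueError("empty DMR set")
    powers = {}
    for col in dmr_features.columns:
        values = dmr_features[col].to_numpy()
        pred = (predicates or {}).get(col)
        hits = pred(values) if pred is not None else values > 0
        powers[col] = 100.0 * float(np.mean(hits))
    series = pd.Series(powers, name="prediction_power")
    if group_by_region:
        regions = [c.rsplit(":", 1)[1] if ":" in c else "base"
                   for c in series.index]
        return series.groupby(regions).mean()
    return series


def positive_density_bins(model: TANModel, feature: int
                          ) -> Callable[[np.ndarray], np.ndarray]:
    """Predicate: value falls in a bin where the positive-class likelihood
    exceeds the negative-class likelihood under the trained model.

    This is the model-referenced notion of "containing" a continuous
    feature such as CpG density.
    """
    table = model.cpts[feature]
    if table.ndim == 3:          # marginalise over the parent
        table = table.mean(axis=1)
    favored = np.flatnonzero(table[:, 1] > table[:, 0])
    edges = model.discretizer.edges[feature]

    def predicate(values: np.ndarray) -> np.ndarray:
        bins = np.searchsorted(edges, np.asarray(values, float), "left")
        return np.isin(bins, favored)

    return predicate


def prediction_accuracy(ensemble: BoostedEnsemble, catalog: FeatureCatalog,
                        labeled_regions: Sequence[GenomicWindow],
                        genome: GenomeSequence, repeats: RepeatAnnotation,
                        set_name: str = "validation",
                        polarity: str = "positive") -> ValidationReport:
    """Fraction of a single-polarity control set called positive."""
    regions = list(labeled_regions)
    if not regions:
        raise ValueError("empty validation set")
    X = extract_feature_matrix(regions, genome, repeats, catalog)
    calls = ensemble.predict(X.to_numpy())
    return ValidationReport(set_name, len(regions),
                            float(np.mean(calls == 1)), polarity)


def site_set_overlap(set_a: Sequence[GenomicWindow],
                     set_b: Sequence[GenomicWindow]
                     ) -> tuple[int, int, int]:
    """(|A only|, |B only|, |overlap|) with >= 1 bp interval overlap.

    Overlap is a maximum one-to-one matching between the two interval
    sets (greedy sweep by end coordinate), so each interval is counted
    once and the overlap count is symmetric.
    """
    a = sorted(set_a, key=lambda w: (w.chrom, w.end, w.start))
    b = sorted(set_b, key=lambda w: (w.chrom, w.end, w.start))
    i = j = matched = 0
    while i < len(a) and j < len(b):
        wa, wb = a[i], b[j]
        if wa.chrom != wb.chrom:
            if wa.chrom < wb.chrom:
                i += 1
            else:
                j += 1
        elif wa.start < wb.end and wb.start < wa.end:
            matched += 1
            i += 1
            j += 1
        elif wa.end <= wb.end:
            i += 1
        else:
            j += 1
    return len(a) - matched, len(b) - matched, matched


def cpg_density_distribution(merged_dmrs: Sequence[GenomicWindow],
                             genome: GenomeSequence,
                             bin_width: float = 0.5
                             ) -> tuple[pd.Series, float]:
    """Histogram of DMR CpG densities and the maximum observed density."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    densities = [cpg_density(genome.sequence(d.chrom, d.start, d.end))
                 for d in merged_dmrs]
    if not densities:
        return pd.Series(dtype=int), 0.0
    densities = np.asarray(densities)
    top = np.floor(densities.max() / bin_width) + 1  # max strictly inside
    edges = np.arange(0, (top + 1) * bin_width, bin_width)
    counts, _ = np.histogram(densities, bins=edges)
    labels = [f"[{edges[k]:g},{edges[k + 1]:g})"
              for k in range(len(counts))]
    return pd.Series(counts, index=labels), float(densities.max())


def cross_validate(X, y, fit_fn: Callable, n_folds: int = 10,
                   seed: int = 0) -> tuple[list[float], float]:
    """Stratified K-fold accuracy of a training procedure.

    ``fit_fn(X_train, y_train)`` must return an object with ``predict``.
    Returns (per-fold accuracies, mean accuracy); deterministic per seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError(f"need >= {n_folds} instances per class")
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True,
                               random_state=seed)
    accs = []
    for train_idx, test_idx in splitter.split(X, y):
        model = fit_fn(X[train_idx], y[train_idx])
        accs.append(float(np.mean(model.predict(X[test_idx])
                                  == y[test_idx])))
    return accs, float(np.mean(accs))
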