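"""Generalized-Query Active Learning (GQAL).

The learner starts from a small labeled set R and a large unlabeled pool U.
Each iteration it (1) finds the pool instance whose posterior is closest to
0.5 under the current TAN, (2) compresses that instance into a generalized
query — the few features most influential for its classification, each with
its observed discretization bin — (3) asks an oracle, which returns a label
with a confidence, (4) propagates a confident answer to every pool instance
matching the query, and (5) retrains and monitors accuracy on a held-out
set T1, stopping at a target accuracy or an iteration cap.  A final
held-out set T2 scores the finished model once.

Features that keep appearing in queries are, by construction, the ones the
model leans on; the per-feature usage tally with the "more than 5
appearances" filter yields the selected relevant-feature list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Protocol, Sequence

import numpy as np
import pandas as pd

from .tan import Discretizer, TANModel, fit_tan

__all__ = [
    "InstancePools",
    "GeneralizedQuery",
    "OracleResponse",
    "Oracle",
    "GQALConfig",
    "GQALResult",
    "most_uncertain_instance",
    "build_generalized_query",
    "propagate_oracle_answer",
    "run_gqal",
    "run_passive_baseline",
    "select_relevant_features",
    "write_learning_curve",
    "write_tally",
]


@dataclass(frozen=True)
class GeneralizedQuery:
    """A feature-subset question: each retained feature with its bin."""

    features: tuple[int, ...]
    bins: tuple[int, ...]

    def __post_init__(self):
        if not self.features:
            raise ValueError("query must retain at least one feature")
        if len(self.features) != len(self.bins):
            raise ValueError("features and bins must align")

    def matches(self, X_disc: np.ndarray) -> np.ndarray:
        """Boolean mask of rows whose values fall inside all query ranges."""
        idx = np.asarray(self.features)
        return np.all(X_disc[:, idx] == np.asarray(self.bins), axis=1)


@dataclass(frozen=True)
class OracleResponse:
    label: int
    confidence: float

    def __post_init__(self):
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must be in [0, 1]")


class Oracle(Protocol):
    def answer(self, query: GeneralizedQuery) -> OracleResponse: ...


@dataclass
class InstancePools:
    """Labeled set R, unlabeled pool U and the two test sets.

    R and U index into the shared pool matrix ``X``; the test sets carry
    their own matrices, so the four sets are disjoint by construction.
    """

    X: np.ndarray
    labels: np.ndarray          # label for R members, -1 for U members
    labeled_ids: list[int]
    unlabeled_ids: list[int]
    X_t1: np.ndarray
    y_t1: np.ndarray
    X_t2: np.ndarray
    y_t2: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if set(self.labeled_ids) & set(self.unlabeled_ids):
            raise ValueError("R and U overlap")

    @classmethod
    def from_arrays(cls, X, y_initial, initial_labeled: Sequence[int],
                    X_t1, y_t1, X_t2, y_t2) -> "InstancePools":
        X = np.asarray(X, dtype=float)
        labels = np.full(X.shape[0], -1, dtype=np.int64)
        labeled = sorted(int(i) for i in initial_labeled)
        labels[labeled] = np.asarray(y_initial, dtype=np.int64)[labeled]
        unlabeled = [i for i in range(X.shape[0]) if i not in set(labeled)]
        return cls(X, labels, labeled, unlabeled,
                   np.asarray(X_t1, float), np.asarray(y_t1, np.int64),
                   np.asarray(X_t2, float), np.asarray(y_t2, np.int64))


@dataclass
class GQALConfig:
    max_iterations: int = 50
    target_accuracy: float = 1.0
    confidence_floor: float = 0.6
    feature_budget: int = 10
    n_bins: int = 4
    smoothing: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class GQALResult:
    model: TANModel
    tally: np.ndarray            # feature id -> query appearances
    log: pd.DataFrame            # iteration, |R|, |U|, T1 acc, query size
    t2_accuracy: float
    discretizer: Discretizer


# ---------------------------------------------------------------------------
# steps


def most_uncertain_instance(model: TANModel, X_pool: np.ndarray,
                            ids: Sequence[int]) -> int:
    """Pool id minimizing |P(positive|x) - 0.5|; ties -> lowest id."""
    if len(ids) == 0:
        raise ValueError("unlabeled pool is exhausted")
    ids = np.asarray(ids)
    post = model.predict_proba(X_pool[ids])[:, 1]
    dist = np.abs(post - 0.5)
    order = np.lexsort((ids, dist))
    return int(ids[order[0]])


def build_generalized_query(model: TANModel, x_disc: np.ndarray,
                            feature_budget: int) -> GeneralizedQuery:
    """Keep the features most influential for this instance's class call.

    Influence of feature i is the magnitude of its class log-likelihood
    ratio ``|ln P(x_i | pa, +) - ln P(x_i | pa, -)|`` at the instance's
    observed bins.  Features with zero influence are don't-cares; at most
    ``feature_budget`` features are retained, each with its observed bin.
    """
    if feature_budget < 1:
        raise ValueError("feature budget must be >= 1")
    x_disc = np.asarray(x_disc, dtype=np.int64)
    influence = np.empty(model.n_features)
    for i, parent in enumerate(model.structure.parents):
        table = model.cpts[i]
        xi = min(int(x_disc[i]), table.shape[0] - 1)
        if parent is None:
            col = table[xi, :]
        else:
            xp = min(int(x_disc[parent]), table.shape[1] - 1)
            col = table[xi, xp, :]
        influence[i] = abs(np.log(col[1]) - np.log(col[0]))
    keep = np.flatnonzero(influence > 1e-12)
    if keep.size == 0:  # uninformative model: fall back to every feature
        keep = np.arange(model.n_features)
    order = np.lexsort((keep, -influence[keep]))
    chosen = np.sort(keep[order[:feature_budget]])
    return GeneralizedQuery(tuple(int(i) for i in chosen),
                            tuple(int(x_disc[i]) for i in chosen))


def propagate_oracle_answer(query: GeneralizedQuery,
                            response: OracleResponse,
                            pools: InstancePools,
                            X_disc: np.ndarray,
                            origin_id: int,
                            confidence_floor: float) -> int:
    """Label matching pool instances (or just the origin) and move them to R.

    A confident answer (confidence >= floor) labels every unlabeled
    instance matching the query; otherwise only the originating instance
    is labeled.  Returns the number of instances moved.
    """
    if response.confidence >= confidence_floor:
        mask = query.matches(X_disc)
        ids = [i for i in pools.unlabeled_ids if mask[i]]
        if origin_id not in ids:
            ids.append(origin_id)
    else:
        ids = [origin_id]
    for i in ids:
        pools.labels[i] = response.label
        pools.unlabeled_ids.remove(i)
        pools.labeled_ids.append(i)
    return len(ids)


# ---------------------------------------------------------------------------
# loop


def _fit_on_R(pools: InstancePools, disc: Discretizer,
              config: GQALConfig) -> TANModel:
    R = np.asarray(pools.labeled_ids)
    return fit_tan(pools.X[R], pools.labels[R], smoothing=config.smoothing,
                   discretizer=disc)


def _accuracy(model, X, y) -> float:
    return float(np.mean(model.predict(X) == y))


def run_gqal(pools: InstancePools, oracle: Oracle, config: GQALConfig,
             discretizer: Discretizer | None = None) -> GQALResult:
    """Run the GQAL loop until target accuracy or the iteration cap.

    The discretizer is fit once on R ∪ U (labels are not needed for
    binning) and shared with the oracle's matching, so query ranges refer
    to stable bins throughout the run.
    """
    R0 = np.asarray(pools.labeled_ids)
    if np.unique(pools.labels[R0]).size < 2:
        raise ValueError("initial labeled set must contain both classes")
    disc = discretizer or Discretizer.fit(pools.X, config.n_bins)
    X_disc = disc.transform(pools.X)
    tally = np.zeros(pools.X.shape[1], dtype=np.int64)
    rows = []
    model = _fit_on_R(pools, disc, config)
    for iteration in range(1, config.max_iterations + 1):
        if not pools.unlabeled_ids:
            break
        origin = most_uncertain_instance(model, pools.X,
                                         pools.unlabeled_ids)
        query = build_generalized_query(model, X_disc[origin],
                                        config.feature_budget)
        tally[list(query.features)] += 1
        response = oracle.answer(query)
        propagate_oracle_answer(query, response, pools, X_disc, origin,
                                config.confidence_floor)
        model = _fit_on_R(pools, disc, config)
        t1_acc = _accuracy(model, pools.X_t1, pools.y_t1)
        rows.append({"iteration": iteration,
                     "n_labeled": len(pools.labeled_ids),
                     "n_unlabeled": len(pools.unlabeled_ids),
                     "t1_accuracy": t1_acc,
                     "query_size": len(query.features)})
        if t1_acc >= config.target_accuracy:
            break
    log = pd.DataFrame(rows, columns=["iteration", "n_labeled",
                                      "n_unlabeled", "t1_accuracy",
                                      "query_size"])
    return GQALResult(model, tally, log,
                      _accuracy(model, pools.X_t2, pools.y_t2), disc)


def run_passive_baseline(pools: InstancePools, y_truth: np.ndarray,
                         config: GQALConfig, batch: int = 1,
                         discretizer: Discretizer | None = None
                         ) -> pd.DataFrame:
    """Random-sampling comparator: label ``batch`` random pool instances
    per iteration with their true labels, retrain, log T2 accuracy.

    Returns the learning-curve log (n_labeled vs t2_accuracy).
    """
    rng = np.random.default_rng(config.seed)
    disc = discretizer or Discretizer.fit(pools.X, config.n_bins)
    y_truth = np.asarray(y_truth, dtype=np.int64)
    rows = []
    for iteration in range(1, config.max_iterations + 1):
        if not pools.unlabeled_ids:
            break
        take = rng.choice(len(pools.unlabeled_ids),
                          size=min(batch, len(pools.unlabeled_ids)),
                          replace=False)
        for idx in sorted(take, reverse=True):
            i = pools.unlabeled_ids.pop(idx)
            pools.labels[i] = y_truth[i]
            pools.labeled_ids.append(i)
        model = _fit_on_R(pools, disc, config)
        rows.append({"iteration": iteration,
                     "n_labeled": len(pools.labeled_ids),
                     "t2_accuracy": _accuracy(model, pools.X_t2,
                                              pools.y_t2)})
    return pd.DataFrame(rows)


def select_relevant_features(tally: np.ndarray, min_appearances: int = 5,
                             manual_includes: Sequence[int] = ()
                             ) -> list[int]:
    """Features appearing strictly more than ``min_appearances`` times,
    plus manual inclusions, ordered by descending tally then identifier.

    Features at or below the threshold are don't-care attributes.
    """
    tally = np.asarray(tally)
    kept = set(int(i) for i in np.flatnonzero(tally > min_appearances))
    kept |= {int(i) for i in manual_includes}
    return sorted(kept, key=lambda i: (-int(tally[i]), i))


def write_learning_curve(log: pd.DataFrame, path) -> None:
    log.to_csv(path, sep="\t", index=False)


def write_tally(tally: np.ndarray, path,
                names: Sequence[str] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("feature\tappearances\n")
        for i, count in enumerate(tally):
            label = names[i] if names is not None else str(i)
            fh.write(f"{label}\t{int(count)}\n")
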