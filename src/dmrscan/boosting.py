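"""Imbalanced-class learning: AdaBoost.M1 over the weighted TAN.

Rare positive windows against a large background make plain classifiers
collapse onto the majority class.  Rather than under- or over-sampling,
instances are re-weighted: each boosting round fits a weighted TAN, raises
the weight of misclassified instances and lowers the weight of correct
ones, and the committee classifies by a weighted vote.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .tan import Discretizer, TANModel, fit_tan

__all__ = ["BoostedEnsemble", "fit_adaboost", "predict_ensemble"]

#: error floor used when a round is perfect, capping alpha at a finite value
_EPS_FLOOR = 1e-10


@dataclass
class BoostedEnsemble:
    """Sequence of (TAN, committee weight alpha) from AdaBoost."""

    models: list[TANModel]
    alphas: list[float]
    rounds_run: int = 0
    degenerate: bool = False  # first weak learner already at error >= 0.5

    def __post_init__(self):
        if len(self.models) != len(self.alphas):
            raise ValueError("models and alphas must align")
        if not all(math.isfinite(a) for a in self.alphas):
            raise ValueError("alphas must be finite")

    def __len__(self) -> int:
        return len(self.models)

    def decision_margin(self, X) -> np.ndarray:
        """Weighted vote sum over +/-1 learner outputs."""
        if not self.models:
            raise ValueError("empty ensemble")
        margin = np.zeros(np.atleast_2d(np.asarray(X, dtype=float)).shape[0])
        for model, alpha in zip(self.models, self.alphas):
            margin += alpha * (2.0 * model.predict(X) - 1.0)
        return margin

    def predict(self, X) -> np.ndarray:
        # an exact zero margin resolves to the negative (non-DMR) class
        return (self.decision_margin(X) > 0).astype(np.int64)

    def to_json(self) -> str:
        return json.dumps({
            "alphas": self.alphas,
            "models": [m.to_json() for m in self.models],
            "rounds_run": self.rounds_run,
            "degenerate": self.degenerate,
        })

    @classmethod
    def from_json(cls, text: str) -> "BoostedEnsemble":
        doc = json.loads(text)
        return cls([TANModel.from_json(m) for m in doc["models"]],
                   doc["alphas"], doc["rounds_run"], doc["degenerate"])


def fit_adaboost(feature_matrix, labels, rounds: int = 25,
                 smoothing: float = 1.0, n_bins: int = 2,
                 discretizer: Discretizer | None = None,
                 feature_names: list[str] | None = None,
                 trace: list | None = None) -> BoostedEnsemble:
    """Two-class AdaBoost.M1 with weighted TAN base learners.

    Weights start uniform (summing to 1).  Round t fits a TAN under the
    current weights, measures its weighted error eps_t, sets
    ``alpha_t = 0.5 * ln((1 - eps_t) / eps_t)``, multiplies weights by
    ``exp(+/-alpha_t)`` and renormalises.  A perfect round stops boosting
    with alpha capped at the value for error 1e-10; a round at error >= 0.5
    is discarded and boosting stops (if it is the very first round the
    learner is kept with alpha 0 and the ensemble flagged degenerate, so
    prediction falls back to the negative class).

    Discretization is fit once on the full training matrix and shared by
    all rounds, so weight changes never reshuffle bins.  The default is a
    coarse 2-bin (median) split: boosting wants weak base learners, and a
    finely binned TAN is strong enough to drive the weighted error near
    zero in one round, leaving re-weighting nothing to do.  ``trace``, if
    given, collects per-round (eps_t, alpha_t, weights-after-update).
    """
    X = np.asarray(feature_matrix, dtype=float) \
        if not hasattr(feature_matrix, "to_numpy") \
        else feature_matrix.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=np.int64)
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    if np.unique(y).size < 2:
        raise ValueError("training set contains a single class")
    n = X.shape[0]
    if discretizer is None:
        discretizer = Discretizer.fit(X, n_bins)
    w = np.full(n, 1.0 / n)
    sign = 2.0 * y - 1.0

    models: list[TANModel] = []
    alphas: list[float] = []
    degenerate = False
    t = 0
    for t in range(1, rounds + 1):
        model = fit_tan(X, y, w, smoothing=smoothing,
                        discretizer=discretizer, feature_names=feature_names)
        pred = model.predict(X)
        miss = pred != y
        eps = float(w[miss].sum())
        if eps >= 0.5:
            if not models:
                models.append(model)
                alphas.append(0.0)
                degenerate = True
            break
        eps_eff = max(eps, _EPS_FLOOR)
        alpha = 0.5 * math.log((1.0 - eps_eff) / eps_eff)
        models.append(model)
        alphas.append(alpha)
        w = w * np.exp(alpha * np.where(miss, 1.0, -1.0))
        w = w / w.sum()
        if trace is not None:
            trace.append((eps, alpha, w.copy()))
        if eps <= 0.0:
            break
    return BoostedEnsemble(models, alphas, rounds_run=t,
                           degenerate=degenerate)


def predict_ensemble(ensemble: BoostedEnsemble,
                     feature_vector) -> tuple[int, float]:
    """(label, margin) for one instance; margin 0 ties resolve negative."""
    vec = np.asarray(feature_vector, dtype=float)[None, :]
    margin = float(ensemble.decision_margin(vec)[0])
    return (1 if margin > 0 else 0), margin
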