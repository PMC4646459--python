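"""Weighted Tree-Augmented Naive Bayes (TAN).

TAN relaxes naive Bayes by allowing each attribute one extra parent beside
the class, with the attribute tree chosen as the maximum-weight spanning
tree under class-conditional mutual information (the Chow-Liu construction
conditioned on the class).  Everything is weighted so the same fitter
serves AdaBoost: structure search, class prior and conditional probability
tables all use instance weights.

Attributes are discretized with equal-frequency bins fit on the training
matrix; additive (Laplace) smoothing keeps every probability positive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "Discretizer",
    "TANStructure",
    "TANModel",
    "discretize_fit",
    "conditional_mutual_information",
    "pairwise_cmi_matrix",
    "build_tan_structure",
    "structure_from_cmi",
    "maximum_spanning_tree",
    "fit_tan",
    "fit_naive_bayes",
    "tan_posterior",
]


def _as_array(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


# ---------------------------------------------------------------------------
# discretization


class Discretizer:
    """Per-feature equal-frequency binning.

    ``edges[j]`` holds the interior cut points of feature j (strictly
    increasing, all below the training maximum).  A value maps to the
    number of edges strictly below it, so out-of-range values clip to the
    first/last bin and a constant feature collapses to a single bin.
    """

    def __init__(self, edges: Sequence[np.ndarray]):
        self.edges = [np.asarray(e, dtype=float) for e in edges]
        for e in self.edges:
            if np.any(np.diff(e) <= 0):
                raise ValueError("bin edges must be strictly increasing")

    @property
    def n_features(self) -> int:
        return len(self.edges)

    @property
    def n_bins(self) -> list[int]:
        return [len(e) + 1 for e in self.edges]

    @classmethod
    def fit(cls, X, n_bins: int = 4) -> "Discretizer":
        X = _as_array(X)
        if X.shape[0] == 0:
            raise ValueError("cannot fit discretizer on an empty matrix")
        if n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        qs = np.arange(1, n_bins) / n_bins
        edges = []
        for j in range(X.shape[1]):
            col = X[:, j]
            e = np.unique(np.quantile(col, qs))
            edges.append(e[e < col.max()])
        return cls(edges)

    def transform(self, X) -> np.ndarray:
        X = _as_array(X)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features:
            raise ValueError("feature count mismatch")
        out = np.empty(X.shape, dtype=np.int64)
        for j, e in enumerate(self.edges):
            out[:, j] = np.searchsorted(e, X[:, j], side="left")
        return out


def discretize_fit(feature_matrix, n_bins: int = 4) -> Discretizer:
    """Fit equal-frequency bin edges from a training matrix."""
    return Discretizer.fit(feature_matrix, n_bins)


# ---------------------------------------------------------------------------
# class-conditional mutual information


def conditional_mutual_information(xi, xj, y, instance_weights=None) -> float:
    """I(Xi; Xj | Y) in nats from weighted empirical frequencies.

    Returns 0 for any pair involving a constant column.
    """
    xi = np.asarray(xi, dtype=np.int64)
    xj = np.asarray(xj, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    if not (xi.shape == xj.shape == y.shape):
        raise ValueError("columns must have equal length")
    w = (np.ones(xi.size, dtype=float) if instance_weights is None
         else np.asarray(instance_weights, dtype=float))
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    if np.unique(xi).size < 2 or np.unique(xj).size < 2:
        return 0.0
    ki, kj, kc = xi.max() + 1, xj.max() + 1, y.max() + 1
    joint = np.zeros((ki, kj, kc))
    np.add.at(joint, (xi, xj, y), w)
    joint /= joint.sum()
    return _cmi_from_joint(joint)


def _cmi_from_joint(joint: np.ndarray) -> float:
    """CMI from a normalized (a, b, c) probability table."""
    pc = joint.sum(axis=(0, 1))
    pac = joint.sum(axis=1)
    pbc = joint.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = joint * pc[None, None, :] / (
            pac[:, None, :] * pbc[None, :, :])
        terms = joint * np.log(ratio)
    return float(np.nansum(terms))


def pairwise_cmi_matrix(X_disc: np.ndarray, y: np.ndarray,
                        instance_weights=None) -> np.ndarray:
    """All pairwise I(Xi; Xj | Y) at once.

    Joint counts for every attribute pair come from one weighted cross
    product of the one-hot encoded matrix per class, which keeps structure
    search fast inside boosting/active-learning loops.
    """
    X_disc = np.asarray(X_disc, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    n, d = X_disc.shape
    w = (np.ones(n) if instance_weights is None
         else np.asarray(instance_weights, dtype=float))
    bins = X_disc.max(axis=0) + 1
    offsets = np.concatenate([[0], np.cumsum(bins)])
    total = int(offsets[-1])
    onehot = np.zeros((n, total))
    onehot[np.arange(n)[:, None], X_disc + offsets[:-1]] = 1.0
    classes = np.unique(y)
    joints = [ (onehot * (w * (y == c))[:, None]).T @ onehot
               for c in classes ]
    grand = np.stack(joints, axis=-1)  # (total, total, n_classes)
    grand /= grand.sum()
    cmi = np.zeros((d, d))
    constant = bins < 2
    for i in range(d):
        for j in range(i + 1, d):
            if constant[i] or constant[j]:
                continue
            block = grand[offsets[i]:offsets[i + 1],
                          offsets[j]:offsets[j + 1], :]
            block = block / block.sum()
            cmi[i, j] = cmi[j, i] = _cmi_from_joint(block)
    return cmi


# ---------------------------------------------------------------------------
# structure


@dataclass(frozen=True)
class TANStructure:
    """Attribute forest: ``parents[i]`` is the parent attribute or None.

    A proper TAN structure is a single tree (exactly one root); the all-None
    forest doubles as the naive-Bayes structure.  The class is an implicit
    extra parent of every attribute either way.
    """

    parents: tuple[Optional[int], ...]

    def __post_init__(self):
        n = len(self.parents)
        if n and not any(p is None for p in self.parents):
            raise ValueError("structure needs at least one root")
        # walking up from every node must terminate (no cycles)
        for i in range(n):
            seen, node = set(), i
            while self.parents[node] is not None:
                if node in seen:
                    raise ValueError("cycle in structure")
                seen.add(node)
                node = self.parents[node]

    @property
    def roots(self) -> list[int]:
        return [i for i, p in enumerate(self.parents) if p is None]

    @property
    def root(self) -> Optional[int]:
        roots = self.roots
        return roots[0] if roots else None

    @property
    def is_tree(self) -> bool:
        return len(self.parents) > 0 and len(self.roots) == 1

    @property
    def edges(self) -> list[tuple[int, int]]:
        return [(p, i) for i, p in enumerate(self.parents) if p is not None]

    @classmethod
    def naive(cls, n: int) -> "TANStructure":
        return cls(tuple([None] * n))


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, a):
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def maximum_spanning_tree(weight: np.ndarray) -> list[tuple[int, int]]:
    """Kruskal with the deterministic tie-break (-weight, i, j)."""
    d = weight.shape[0]
    order = sorted(((i, j) for i in range(d) for j in range(i + 1, d)),
                   key=lambda ij: (-weight[ij[0], ij[1]], ij[0], ij[1]))
    uf = _UnionFind(d)
    edges = []
    for i, j in order:
        if uf.union(i, j):
            edges.append((i, j))
            if len(edges) == d - 1:
                break
    return edges


def build_tan_structure(X_disc, labels, instance_weights=None) -> TANStructure:
    """Chow-Liu attribute tree over class-conditional mutual information.

    Root is the lowest-index attribute; edges are directed away from it.
    Ties between equal-weight edges break on the lower (i, j) index pair,
    making the structure reproducible.
    """
    X_disc = np.asarray(X_disc, dtype=np.int64)
    d = X_disc.shape[1]
    if d == 0:
        return TANStructure(())
    if d == 1:
        return TANStructure((None,))
    cmi = pairwise_cmi_matrix(X_disc, labels, instance_weights)
    return structure_from_cmi(cmi)


def structure_from_cmi(cmi: np.ndarray) -> TANStructure:
    d = cmi.shape[0]
    edges = maximum_spanning_tree(cmi)
    adjacency = {i: [] for i in range(d)}
    for i, j in edges:
        adjacency[i].append(j)
        adjacency[j].append(i)
    parents: list[Optional[int]] = [None] * d
    visited = {0}
    stack = [0]
    while stack:
        node = stack.pop()
        for nb in sorted(adjacency[node]):
            if nb not in visited:
                visited.add(nb)
                parents[nb] = node
                stack.append(nb)
    return TANStructure(tuple(parents))


# ---------------------------------------------------------------------------
# model


class TANModel:
    """Fitted TAN: structure, class prior, smoothed CPTs, discretizer."""

    def __init__(self, structure: TANStructure, class_prior: np.ndarray,
                 cpts: list[np.ndarray], discretizer: Discretizer,
                 smoothing: float, feature_names: list[str] | None = None):
        self.structure = structure
        self.class_prior = np.asarray(class_prior, dtype=float)
        self.cpts = [np.asarray(t, dtype=float) for t in cpts]
        self.discretizer = discretizer
        self.smoothing = smoothing
        self.feature_names = feature_names
        for i, table in enumerate(self.cpts):
            sums = table.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError(f"CPT {i} columns do not sum to 1")
            if np.any(table <= 0):
                raise ValueError(f"CPT {i} has non-positive entries")

    @property
    def n_features(self) -> int:
        return len(self.cpts)

    def _log_posterior(self, X) -> np.ndarray:
        Xd = X if (isinstance(X, np.ndarray) and X.dtype == np.int64
                   and X.ndim == 2) else self.discretizer.transform(X)
        if Xd.shape[1] != self.n_features:
            raise ValueError("feature schema mismatch")
        logp = np.tile(np.log(self.class_prior), (Xd.shape[0], 1))
        for i, parent in enumerate(self.structure.parents):
            table = np.log(self.cpts[i])
            xi = np.clip(Xd[:, i], 0, table.shape[0] - 1)
            if parent is None:
                logp += table[xi, :]
            else:
                xp = np.clip(Xd[:, parent], 0, table.shape[1] - 1)
                logp += table[xi, xp, :]
        return logp

    def predict_proba(self, X) -> np.ndarray:
        logp = self._log_posterior(X)
        return np.exp(logp - logsumexp(logp, axis=1, keepdims=True))

    def predict(self, X) -> np.ndarray:
        return np.argmax(self._log_posterior(X), axis=1)

    # -- serialization ---------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "parents": [p for p in self.structure.parents],
            "class_prior": self.class_prior.tolist(),
            "cpts": [t.tolist() for t in self.cpts],
            "edges": [e.tolist() for e in self.discretizer.edges],
            "smoothing": self.smoothing,
            "feature_names": self.feature_names,
        }
        return json.dumps(doc)

    @classmethod
    def from_json(cls, text: str) -> "TANModel":
        doc = json.loads(text)
        return cls(TANStructure(tuple(doc["parents"])),
                   np.array(doc["class_prior"]),
                   [np.array(t) for t in doc["cpts"]],
                   Discretizer([np.array(e) for e in doc["edges"]]),
                   doc["smoothing"], doc.get("feature_names"))


def _estimate_cpts(Xd: np.ndarray, y: np.ndarray, w: np.ndarray,
                   structure: TANStructure, n_bins: list[int],
                   n_classes: int, smoothing: float) -> list[np.ndarray]:
    cpts = []
    for i, parent in enumerate(structure.parents):
        if parent is None:
            counts = np.zeros((n_bins[i], n_classes))
            np.add.at(counts, (Xd[:, i], y), w)
        else:
            counts = np.zeros((n_bins[i], n_bins[parent], n_classes))
            np.add.at(counts, (Xd[:, i], Xd[:, parent], y), w)
        counts += smoothing
        cpts.append(counts / counts.sum(axis=0, keepdims=True))
    return cpts


def fit_tan(feature_matrix, labels, instance_weights=None,
            smoothing: float = 1.0, n_bins: int = 4,
            discretizer: Discretizer | None = None,
            feature_names: list[str] | None = None,
            naive: bool = False) -> TANModel:
    """Fit a weighted TAN (or plain naive Bayes with ``naive=True``).

    Requires both classes present with positive total weight.  Uniform
    scaling of the weights leaves the model unchanged.
    """
    X = _as_array(feature_matrix)
    y = np.asarray(labels, dtype=np.int64)
    n = X.shape[0]
    w = (np.ones(n) if instance_weights is None
         else np.asarray(instance_weights, dtype=float))
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative with positive sum")
    # normalize to total mass n so the smoothing constant means the same
    # thing at any weight scale (doubling all weights changes nothing)
    w = w * (n / w.sum())
    if isinstance(feature_matrix, pd.DataFrame) and feature_names is None:
        feature_names = list(feature_matrix.columns)
    n_classes = int(y.max()) + 1 if y.size else 0
    class_w = np.zeros(n_classes)
    np.add.at(class_w, y, w)
    if np.count_nonzero(class_w) < 2:
        raise ValueError("training set is degenerate: a single class "
                         "carries all the weight")
    if discretizer is None:
        discretizer = Discretizer.fit(X, n_bins)
    Xd = discretizer.transform(X)
    bins = discretizer.n_bins
    if naive or X.shape[1] <= 1:
        structure = TANStructure.naive(X.shape[1])
    else:
        structure = build_tan_structure(Xd, y, w)
    cpts = _estimate_cpts(Xd, y, w, structure, bins, n_classes, smoothing)
    prior = class_w + smoothing
    prior = prior / prior.sum()
    return TANModel(structure, prior, cpts, discretizer, smoothing,
                    feature_names)


def fit_naive_bayes(feature_matrix, labels, instance_weights=None,
                    **kwargs) -> TANModel:
    """Naive Bayes baseline sharing the TAN estimation machinery."""
    return fit_tan(feature_matrix, labels, instance_weights, naive=True,
                   **kwargs)


def tan_posterior(model: TANModel, feature_vector) -> np.ndarray:
    """P(Y | x) for one instance; entries sum to 1 (log-space compute)."""
    vec = np.asarray(feature_vector, dtype=float)
    if vec.ndim != 1 or vec.size != model.n_features:
        raise ValueError("feature schema mismatch")
    return model.predict_proba(vec[None, :])[0]
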