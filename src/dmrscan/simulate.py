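"""Synthetic data emulating the epimutation study regime.

Real transgenerational DMR training sets are not redistributable, so every
downstream module is exercised on synthetic genomes that reproduce the
characteristics reported for them: rare positive 1-kb windows sitting in
CpG deserts (measured density below ~2 CpG/100 bp) with short planted
motifs (CCGG / GCGC / TCGG) and repeat-enriched flanks, embedded in a
multi-chromosome background whose CpG density is markedly higher, with
optional spatial clustering of the planted runs.  The ground truth doubles
as the simulated oracle for active learning.

All randomness flows from the single spec seed through named
``numpy.random.SeedSequence`` children (sequence, placement, planting,
repeats, sampling), so every artifact is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .features import (FeatureCatalog, FeatureSpec, GenomeSequence,
                       GenomicWindow, RepeatAnnotation, count_cpg)
from .gqal import GeneralizedQuery, OracleResponse
from .scan import make_windows
from .tan import TANStructure

__all__ = [
    "SyntheticSpec",
    "TruthSet",
    "generate_genome",
    "signature_catalog",
    "build_training_table",
    "SimulatedOracle",
    "make_oracle",
    "make_tabular_task",
    "make_imbalanced_task",
    "make_chain_task",
    "TreeSampler",
    "make_tree_sampler",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = 0, 1, 2, 3


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic genome.

    Defaults reflect the reported DMR characteristics: a CpG-desert
    signature below 2 CpG/100 bp against a background of ~4 CpG/100 bp
    (base composition 30/20/20/30), motifs CCGG/GCGC/TCGG planted in every
    positive window, positive runs of 3-6 consecutive 1-kb tiles, and
    repeat-family enrichment in the 1-kb flanks of each run.
    """

    seed: int
    chromosome_lengths: tuple[int, ...] = (2_000_000,) * 5
    tile_size: int = 1000
    base_probs: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    desert_threshold: float = 2.0
    motifs: tuple[str, ...] = ("CCGG", "GCGC", "TCGG")
    motifs_per_window: tuple[int, int] = (3, 8)
    n_dmr_runs: int = 40
    run_length_range: tuple[int, int] = (3, 6)
    flank_repeat_family: str = "desert_flank_rep"
    flank_repeats_per_side: int = 2
    background_repeat_families: tuple[str, ...] = ("bgrepA", "bgrepB",
                                                   "bgrepC")
    background_repeat_rate: float = 1.0 / 50_000
    cluster_regions: tuple[tuple[int, int, int], ...] = ()
    cluster_fraction: float = 0.0

    def __post_init__(self):
        if abs(sum(self.base_probs) - 1.0) > 1e-9:
            raise ValueError("base probabilities must sum to 1")
        if not 0.0 <= self.cluster_fraction <= 1.0:
            raise ValueError("cluster_fraction must be in [0, 1]")
        max_run_bp = self.run_length_range[1] * self.tile_size
        if min(self.chromosome_lengths) < max_run_bp:
            raise ValueError("chromosomes shorter than the longest run")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(len(self.chromosome_lengths))]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chromosome_lengths))


@dataclass
class TruthSet:
    """Planted intervals plus the deterministic labeling function."""

    dmr_runs: list[GenomicWindow]
    cluster_regions: list[GenomicWindow]
    tile_size: int

    def label(self, window: GenomicWindow) -> int:
        for run in self.dmr_runs:
            if (run.chrom == window.chrom and run.start <= window.start
                    and window.end <= run.end):
                return 1
        return 0

    def window_labels(self, windows: Sequence[GenomicWindow]) -> np.ndarray:
        return np.array([self.label(w) for w in windows], dtype=np.int64)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for k, run in enumerate(self.dmr_runs, start=1):
                fh.write(f"{run.chrom}\t{run.start}\t{run.end}"
                         f"\tplanted{k:03d}\n")


def _place_runs(spec: SyntheticSpec, rng: np.random.Generator
                ) -> list[GenomicWindow]:
    """Non-overlapping runs with a one-window gap so runs never abut."""
    names = spec.chrom_names
    n_windows = [length // spec.tile_size
                 for length in spec.chromosome_lengths]
    occupied = {name: set() for name in names}
    runs: list[GenomicWindow] = []
    n_clustered = int(round(spec.cluster_fraction * spec.n_dmr_runs)) \
        if spec.cluster_regions else 0
    for k in range(spec.n_dmr_runs):
        length = int(rng.integers(spec.run_length_range[0],
                                  spec.run_length_range[1] + 1))
        for _attempt in range(10_000):
            if k < n_clustered:
                ci = int(rng.integers(len(spec.cluster_regions)))
                chrom_idx, lo, hi = spec.cluster_regions[ci]
                w_lo = lo // spec.tile_size
                w_hi = hi // spec.tile_size - length
            else:
                chrom_idx = int(rng.integers(len(names)))
                w_lo, w_hi = 0, n_windows[chrom_idx] - length
            if w_hi <= w_lo:
                continue
            start_w = int(rng.integers(w_lo, w_hi))
            span = range(start_w - 1, start_w + length + 1)
            if occupied[names[chrom_idx]].intersection(span):
                continue
            occupied[names[chrom_idx]].update(span)
            runs.append(GenomicWindow(names[chrom_idx],
                                      start_w * spec.tile_size,
                                      (start_w + length) * spec.tile_size))
            break
        else:
            raise ValueError("could not place runs: spec infeasible")
    return sorted(runs)


def _break_cpg(seq: np.ndarray) -> None:
    """Replace the G of every CG dinucleotide with T, in place."""
    mask = (seq[:-1] == _C) & (seq[1:] == _G)
    idx = np.flatnonzero(mask) + 1
    seq[idx] = _T


def _plant_window(seq: np.ndarray, spec: SyntheticSpec,
                  rng: np.random.Generator) -> None:
    """Rewrite one tile to the DMR signature (CpG desert + motifs)."""
    _break_cpg(seq)
    n_motifs = int(rng.integers(spec.motifs_per_window[0],
                                spec.motifs_per_window[1] + 1))
    placed: list[tuple[int, int]] = []
    for _ in range(n_motifs):
        motif = spec.motifs[int(rng.integers(len(spec.motifs)))]
        enc = np.array(["ACGT".index(ch) for ch in motif], dtype=seq.dtype)
        for _attempt in range(200):
            pos = int(rng.integers(0, seq.size - enc.size + 1))
            if all(pos + enc.size <= s or pos >= e for s, e in placed):
                seq[pos:pos + enc.size] = enc
                placed.append((pos, pos + enc.size))
                break
    # motif planting may create a few stray CGs at motif borders; trim any
    # surplus so the measured density is guaranteed below the threshold
    limit = int(spec.desert_threshold * seq.size / 100)
    while True:
        cg_pos = np.flatnonzero((seq[:-1] == _C) & (seq[1:] == _G))
        if cg_pos.size < limit:
            break
        outside = [p for p in cg_pos
                   if all(p + 2 <= s or p >= e for s, e in placed)]
        if not outside:
            break
        seq[outside[-1] + 1] = _T


def generate_genome(spec: SyntheticSpec
                    ) -> tuple[GenomeSequence, RepeatAnnotation, TruthSet]:
    """Background genome with planted DMR runs, repeats and ground truth."""
    children = np.random.SeedSequence(spec.seed).spawn(4)
    rng_seq, rng_place, rng_plant, rng_rep = map(np.random.default_rng,
                                                 children)
    runs = _place_runs(spec, rng_place)
    chroms: dict[str, str] = {}
    for name, length in spec.lengths.items():
        seq = rng_seq.choice(4, size=length,
                             p=spec.base_probs).astype(np.uint8)
        for run in runs:
            if run.chrom != name:
                continue
            for ws in range(run.start, run.end, spec.tile_size):
                view = seq[ws:ws + spec.tile_size]
                _plant_window(view, spec, rng_plant)
        chroms[name] = _BASES[seq].tobytes().decode("ascii")
    genome = GenomeSequence(chroms)

    repeats = RepeatAnnotation()
    for name, length in spec.lengths.items():
        n_bg = int(round(length * spec.background_repeat_rate))
        for _ in range(n_bg):
            start = int(rng_rep.integers(0, max(1, length - 2000)))
            size = int(rng_rep.integers(200, 2001))
            family = spec.background_repeat_families[
                int(rng_rep.integers(len(spec.background_repeat_families)))]
            repeats.add(name, start, min(start + size, length), family)
    flank = spec.tile_size  # enrichment confined to the 1-kb flanks
    for run in runs:
        length = spec.lengths[run.chrom]
        for lo, hi in ((max(0, run.start - flank), run.start),
                       (run.end, min(length, run.end + flank))):
            for _ in range(spec.flank_repeats_per_side):
                if hi - lo < 120:
                    continue
                size = int(rng_rep.integers(100, min(500, hi - lo)))
                start = int(rng_rep.integers(lo, hi - size))
                repeats.add(run.chrom, start, start + size,
                            spec.flank_repeat_family)

    clusters = [GenomicWindow(spec.chrom_names[ci], lo, hi)
                for ci, lo, hi in spec.cluster_regions]
    truth = TruthSet(runs, clusters, spec.tile_size)
    # signature guarantee: every planted window is a CpG desert
    for run in runs:
        for ws in range(run.start, run.end, spec.tile_size):
            seq = genome.sequence(run.chrom, ws, ws + spec.tile_size)
            density = 100.0 * count_cpg(seq) / len(seq)
            if density >= spec.desert_threshold:
                raise AssertionError("planted window violates signature")
    return genome, repeats, truth


def signature_catalog(spec: SyntheticSpec, n_noise_motifs: int = 3,
                      seed: int = 0) -> FeatureCatalog:
    """Compact catalog for synthetic end-to-end runs.

    CpG information, the planted motifs on the base window, the enriched
    repeat family on both 1-kb flanks, one background repeat family per
    flank, and a few noise motifs that carry no planted signal.
    """
    rng = np.random.default_rng(seed)
    specs = [FeatureSpec("site_length", "cpg_info", "base", "length"),
             FeatureSpec("cpg_count", "cpg_info", "base", "cpg_count"),
             FeatureSpec("cpg_density", "cpg_info", "base", "cpg_density")]
    for motif in spec.motifs:
        specs.append(FeatureSpec(f"motif_{motif}", "sequence_motif",
                                 "base", motif))
    for region in ("up1k", "dn1k"):
        specs.append(FeatureSpec(spec.flank_repeat_family, "repeat_element",
                                 region, spec.flank_repeat_family))
        specs.append(FeatureSpec(spec.background_repeat_families[0],
                                 "repeat_element", region,
                                 spec.background_repeat_families[0]))
    for j in range(n_noise_motifs):
        pat = "".join(rng.choice(list("ACGT"))
                      for _ in range(int(rng.integers(5, 8))))
        specs.append(FeatureSpec(f"noise_motif{j}", "sequence_motif",
                                 "base", pat))
    return FeatureCatalog(specs)


def build_training_table(genome: GenomeSequence, repeats: RepeatAnnotation,
                         truth: TruthSet, catalog: FeatureCatalog,
                         n_positive: int, imbalance_ratio: int,
                         seed: int) -> tuple[pd.DataFrame, np.ndarray,
                                             list[GenomicWindow]]:
    """Labeled training table: planted positives vs background windows.

    Emits ``n_positive`` planted windows and ``n_positive * ratio``
    background windows annotated under ``catalog``, labels taken from the
    truth function.
    """
    from .features import extract_feature_matrix

    windows = make_windows(genome.lengths, truth.tile_size)
    labels = truth.window_labels(windows)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    n_negative = n_positive * imbalance_ratio
    if n_positive > pos_idx.size or n_negative > neg_idx.size:
        raise ValueError("not enough windows for the requested table")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    chosen = np.concatenate([rng.choice(pos_idx, n_positive, replace=False),
                             rng.choice(neg_idx, n_negative,
                                        replace=False)])
    chosen.sort()
    selected = [windows[i] for i in chosen]
    X = extract_feature_matrix(selected, genome, repeats, catalog)
    return X, labels[chosen], selected


# ---------------------------------------------------------------------------
# simulated oracle


class SimulatedOracle:
    """Answers generalized queries from ground truth.

    The label is the majority truth label among reference instances whose
    discretized values match the query; the confidence is the majority
    fraction.  With ``noise_rate`` > 0 the label flips with that
    probability (seeded, hence reproducible).
    """

    def __init__(self, X_disc: np.ndarray, y_truth: np.ndarray,
                 noise_rate: float = 0.0, seed: int = 0):
        if not 0.0 <= noise_rate < 0.5:
            raise ValueError("noise_rate must be in [0, 0.5)")
        self.X_disc = np.asarray(X_disc, dtype=np.int64)
        self.y = np.asarray(y_truth, dtype=np.int64)
        self.noise_rate = noise_rate
        self._rng = np.random.default_rng(seed)
        self.calls = 0

    def answer(self, query: GeneralizedQuery) -> OracleResponse:
        self.calls += 1
        mask = query.matches(self.X_disc)
        if not mask.any():
            return OracleResponse(0, 0.0)
        labels = self.y[mask]
        n_pos = int(labels.sum())
        label = 1 if n_pos * 2 > labels.size else 0
        confidence = max(n_pos, labels.size - n_pos) / labels.size
        if self.noise_rate > 0 and self._rng.random() < self.noise_rate:
            label = 1 - label
        return OracleResponse(label, float(confidence))


def make_oracle(X_disc: np.ndarray, y_truth: np.ndarray,
                noise_rate: float = 0.0, seed: int = 0) -> SimulatedOracle:
    return SimulatedOracle(X_disc, y_truth, noise_rate, seed)


# ---------------------------------------------------------------------------
# tabular benchmark tasks


def make_tabular_task(n_instances: int = 2000, n_informative: int = 5,
                      n_noise: int = 45, shift: float = 2.0,
                      seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Balanced task with a few informative Gaussian features.

    Informative features are shifted by ``shift`` standard deviations in
    the positive class; noise features are class-independent N(0, 1).
    The informative columns come first.
    """
    rng = np.random.default_rng(seed)
    y = (rng.random(n_instances) < 0.5).astype(np.int64)
    X = rng.normal(size=(n_instances, n_informative + n_noise))
    X[:, :n_informative] += shift * y[:, None]
    return X, y


def make_imbalanced_task(n_instances: int = 5000, n_features: int = 20,
                         imbalance: int = 50, shift: float = 0.6,
                         seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Rare-positive task (about 1 positive per ``imbalance`` negatives).

    The per-feature shift is weak so a single classifier is imperfect and
    re-weighting has room to improve minority recall.
    """
    rng = np.random.default_rng(seed)
    n_pos = max(2, round(n_instances / (imbalance + 1)))
    y = np.zeros(n_instances, dtype=np.int64)
    y[rng.choice(n_instances, n_pos, replace=False)] = 1
    X = rng.normal(size=(n_instances, n_features))
    X += shift * y[:, None]
    return X, y


def make_chain_task(n_instances: int = 4000, n_features: int = 6,
                    copy_fidelity: float = 0.9, seed: int = 0
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Binary attributes with strong pairwise dependence along a chain.

    x0 follows the class; each later attribute copies its predecessor
    with probability ``copy_fidelity``.  Naive Bayes double-counts the
    chained evidence, which a TAN's attribute tree absorbs.
    """
    rng = np.random.default_rng(seed)
    y = (rng.random(n_instances) < 0.5).astype(np.int64)
    X = np.empty((n_instances, n_features), dtype=float)
    X[:, 0] = np.where(rng.random(n_instances) < 0.8, y, 1 - y)
    for j in range(1, n_features):
        copy = rng.random(n_instances) < copy_fidelity
        X[:, j] = np.where(copy, X[:, j - 1], rng.integers(0, 2,
                                                           n_instances))
    return X, y


class TreeSampler:
    """A known tree-structured generative model over binary attributes.

    Used as an exact oracle: samples follow the TAN factorisation with
    randomly drawn CPTs, and :meth:`posterior` computes P(Y|x) from the
    true parameters, against which a fitted model can be compared.
    """

    def __init__(self, structure: TANStructure, prior: np.ndarray,
                 cpts: list[np.ndarray], seed: int):
        self.structure = structure
        self.prior = prior
        self.cpts = cpts  # root: (2, 2); child: (2, 2, 2) [xi, xp, y]
        self._rng = np.random.default_rng(seed)

    def sample(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        y = (self._rng.random(n) < self.prior[1]).astype(np.int64)
        d = len(self.structure.parents)
        X = np.zeros((n, d), dtype=np.int64)
        order = _topological_order(self.structure)
        for i in order:
            parent = self.structure.parents[i]
            if parent is None:
                p1 = self.cpts[i][1, y]
            else:
                p1 = self.cpts[i][1, X[:, parent], y]
            X[:, i] = self._rng.random(n) < p1
        return X.astype(float), y

    def posterior(self, X: np.ndarray) -> np.ndarray:
        """Exact P(Y=1 | x) from the generating parameters."""
        X = np.asarray(X, dtype=np.int64)
        logp = np.tile(np.log(self.prior), (X.shape[0], 1))
        for i, parent in enumerate(self.structure.parents):
            if parent is None:
                logp += np.log(self.cpts[i][X[:, i], :])
            else:
                logp += np.log(self.cpts[i][X[:, i], X[:, parent], :])
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p[:, 1] / p.sum(axis=1)


def _topological_order(structure: TANStructure) -> list[int]:
    order, placed = [], set()
    pending = list(range(len(structure.parents)))
    while pending:
        for i in list(pending):
            parent = structure.parents[i]
            if parent is None or parent in placed:
                order.append(i)
                placed.add(i)
                pending.remove(i)
    return order


def make_tree_sampler(n_features: int = 6, seed: int = 0,
                      concentration: float = 0.35) -> TreeSampler:
    """Random chain-tree sampler with moderately sharp CPTs."""
    rng = np.random.default_rng(seed)
    parents = tuple([None] + [int(rng.integers(0, i))
                              for i in range(1, n_features)])
    structure = TANStructure(parents)
    prior = np.array([0.5, 0.5])
    cpts = []
    for i, parent in enumerate(parents):
        shape = (2, 2) if parent is None else (2, 2, 2)
        p1 = rng.beta(concentration, concentration, size=shape[1:])
        p1 = np.clip(p1, 0.05, 0.95)
        cpts.append(np.stack([1 - p1, p1], axis=0))
    return TreeSampler(structure, prior, cpts, seed + 1)
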