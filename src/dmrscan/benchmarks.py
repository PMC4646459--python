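"""Synthetic benchmark experiments validating each pipeline stage.

These runners define the package's self-validation suite on the synthetic
study conditions: structure-search exactness, posterior calibration,
boosting identities, active-learning feature recovery and label
efficiency, the imbalance benefit, end-to-end scan recovery and cluster
detection.  The test suite and the acceptance script both call them, so
the numbers reported in either place come from the same computations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .boosting import BoostedEnsemble, fit_adaboost
from .clusters import detect_clusters
from .evaluation import positive_density_bins, prediction_power
from .features import GenomicWindow, cpg_density, extract_feature_matrix
from .gqal import GQALConfig, InstancePools, run_gqal, run_passive_baseline
from .scan import make_windows, classify_windows, merge_consecutive
from .simulate import (SyntheticSpec, build_training_table, generate_genome,
                       make_imbalanced_task, make_oracle, make_tabular_task,
                       make_tree_sampler, signature_catalog, _place_runs)
from .tan import Discretizer, fit_tan, structure_from_cmi

__all__ = [
    "enumerate_spanning_trees",
    "chow_liu_agreement",
    "tan_posterior_mae",
    "adaboost_identities",
    "gqal_benchmark",
    "imbalance_benchmark",
    "scan_benchmark",
    "cluster_benchmark",
    "cluster_null_benchmark",
]


# ---------------------------------------------------------------------------
# TAN: structure search vs exhaustive enumeration


def enumerate_spanning_trees(n: int):
    """All labeled spanning trees on n nodes via Prüfer sequences."""
    if n == 1:
        yield []
        return
    if n == 2:
        yield [(0, 1)]
        return
    for seq in itertools.product(range(n), repeat=n - 2):
        degree = [1] * n
        for v in seq:
            degree[v] += 1
        edges, ptr = [], list(seq)
        avail = sorted(i for i in range(n) if degree[i] == 1)
        for v in ptr:
            leaf = avail.pop(0)
            edges.append((min(leaf, v), max(leaf, v)))
            degree[v] -= 1
            if degree[v] == 1:
                import bisect

                bisect.insort(avail, v)
        edges.append((avail[0], avail[1]))
        yield edges


def chow_liu_agreement(n_trials: int = 100, seed: int = 0) -> float:
    """Fraction of random CMI matrices (<= 5 attributes) where the Kruskal
    tree attains the exhaustive maximum spanning-tree weight."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_trials):
        d = int(rng.integers(2, 6))
        w = rng.random((d, d))
        w = np.triu(w, 1)
        w = w + w.T
        found = structure_from_cmi(w)
        found_weight = sum(w[a, b] for a, b in found.edges)
        best = max(sum(w[a, b] for a, b in tree)
                   for tree in enumerate_spanning_trees(d))
        agree += math.isclose(found_weight, best, rel_tol=0, abs_tol=1e-12)
    return agree / n_trials


def tan_posterior_mae(seed: int = 0, n_train: int = 5000,
                      n_test: int = 2000, n_models: int = 3) -> float:
    """MAE between fitted TAN posteriors and the exact posteriors of the
    tree-structured generative models the data were sampled from.

    Averaged over several random generative models: a single random tree
    can contain an edge too weak to recover from finite data, which says
    nothing about the estimator.
    """
    errors = []
    for k in range(n_models):
        sampler = make_tree_sampler(6, seed=seed + k)
        X, y = sampler.sample(n_train)
        Xt, _ = sampler.sample(n_test)
        model = fit_tan(X, y)
        fitted = model.predict_proba(Xt)[:, 1]
        exact = sampler.posterior(Xt.astype(np.int64))
        errors.append(np.mean(np.abs(fitted - exact)))
    return float(np.mean(errors))


# ---------------------------------------------------------------------------
# AdaBoost identities


@dataclass
class BoostReport:
    max_reweight_deviation: float   # max |0.5 - predecessor error| per round
    train_error: float
    error_bound: float              # Freund-Schapire product bound
    rounds: int


def adaboost_identities(seed: int = 0, n_instances: int = 2000,
                        rounds: int = 15) -> BoostReport:
    X, y = make_imbalanced_task(n_instances=n_instances, imbalance=20,
                                seed=seed)
    trace: list = []
    ensemble = fit_adaboost(X, y, rounds=rounds, trace=trace)
    dev = 0.0
    for t, (eps, alpha, w_after) in enumerate(trace):
        pred = ensemble.models[t].predict(X)
        err = float(w_after[pred != y].sum())
        dev = max(dev, abs(err - 0.5))
    train_error = float(np.mean(ensemble.predict(X) != y))
    bound = float(np.prod([2.0 * math.sqrt(e * (1.0 - e))
                           for e, _, _ in trace])) if trace else 1.0
    return BoostReport(dev, train_error, bound, len(ensemble))


# ---------------------------------------------------------------------------
# GQAL benchmark (5 informative / 45 noise features)


@dataclass
class GQALSeedResult:
    informative_tally: np.ndarray
    noise_tally_max: int
    rank_ok: bool                   # every informative above every noise
    n_recovered: int                # informative features with tally > 5
    oracle_calls_to_target: float   # inf when target accuracy not reached
    passive_labels_to_target: float
    t2_accuracy: float


def _gqal_task_pools(seed: int, n_initial: int = 20):
    X, y = make_tabular_task(seed=seed)
    X_m, y_m = make_tabular_task(n_instances=500, seed=seed + 500)
    rng = np.random.default_rng(seed + 77)
    initial = np.concatenate(
        [rng.choice(np.flatnonzero(y == c), n_initial // 2, replace=False)
         for c in (0, 1)])
    pools = InstancePools.from_arrays(X, y, initial, X_m, y_m, X_m, y_m)
    return X, y, initial, pools


def gqal_seed_run(seed: int, target: float = 0.95,
                  max_iterations: int = 60,
                  feature_budget: int = 3) -> GQALSeedResult:
    """One seed of the active-learning benchmark plus its passive arm.

    The query budget is 3 on this 50-feature task: queries must be coarse
    enough to match other pool instances or generalization cannot occur.
    Oracle effort for GQAL is the number of generalized queries answered;
    for the passive arm it is the number of instances labeled.
    """
    X, y, initial, pools = _gqal_task_pools(seed)
    disc = Discretizer.fit(X, 4)
    oracle = make_oracle(disc.transform(X), y, seed=seed)
    config = GQALConfig(max_iterations=max_iterations, target_accuracy=2.0,
                        feature_budget=feature_budget, seed=seed)
    result = run_gqal(pools, oracle, config, discretizer=disc)
    informative = result.tally[:5]
    noise_max = int(result.tally[5:].max())
    crossed = result.log[result.log.t1_accuracy >= target]
    calls = float(crossed.iteration.iloc[0]) if len(crossed) else math.inf

    _, _, _, pools_passive = _gqal_task_pools(seed)
    passive_log = run_passive_baseline(
        pools_passive, y, GQALConfig(max_iterations=100, seed=seed),
        batch=10, discretizer=disc)
    crossed_p = passive_log[passive_log.t2_accuracy >= target]
    labels_p = float(crossed_p.n_labeled.iloc[0]) if len(crossed_p) \
        else math.inf
    return GQALSeedResult(informative, noise_max,
                          bool(informative.min() > noise_max),
                          int(np.sum(informative > 5)), calls, labels_p,
                          result.t2_accuracy)


def gqal_benchmark(n_seeds: int = 20, base_seed: int = 0) -> dict:
    results = [gqal_seed_run(base_seed + s) for s in range(n_seeds)]
    ratios = [r.oracle_calls_to_target / r.passive_labels_to_target
              for r in results]
    return {
        "rank_ok_fraction": float(np.mean([r.rank_ok for r in results])),
        "recovered_fraction": float(np.mean(
            [r.n_recovered / 5 for r in results])),
        "median_label_budget_ratio": float(np.median(ratios)),
        "results": results,
    }


# ---------------------------------------------------------------------------
# imbalance benefit


def imbalance_benchmark(n_seeds: int = 20, base_seed: int = 0,
                        rounds: int = 25) -> dict:
    single_recall, boosted_recall = [], []
    for s in range(n_seeds):
        X, y = make_imbalanced_task(seed=base_seed + s)
        Xt, yt = make_imbalanced_task(seed=base_seed + s + 4000)
        single = fit_tan(X, y, n_bins=2)
        ensemble = fit_adaboost(X, y, rounds=rounds)
        single_recall.append(float(np.mean(
            single.predict(Xt[yt == 1]) == 1)))
        boosted_recall.append(float(np.mean(
            ensemble.predict(Xt[yt == 1]) == 1)))
    return {
        "single_median_recall": float(np.median(single_recall)),
        "boosted_median_recall": float(np.median(boosted_recall)),
        "single_recall": single_recall,
        "boosted_recall": boosted_recall,
    }


# ---------------------------------------------------------------------------
# end-to-end scan


def scan_benchmark(seed: int = 0, n_train_positive: int = 120,
                   imbalance_ratio: int = 3, rounds: int = 10,
                   n_bins: int = 8) -> dict:
    """Generate, train on the planted signature, scan, merge, evaluate.

    The training table keeps a moderate 1:3 imbalance with 8 discretization
    bins so that equal-frequency bin edges fall inside the positive
    (CpG-desert) density mass rather than entirely within the background
    bulk; the exact-coordinate recovery contract needs per-window recall
    near 1, not the weak-learner regime of the imbalance benchmark.
    """
    spec = SyntheticSpec(seed=seed)
    genome, repeats, truth = generate_genome(spec)
    catalog = signature_catalog(spec)
    X, y, _ = build_training_table(genome, repeats, truth, catalog,
                                   n_train_positive, imbalance_ratio,
                                   seed=seed + 1)
    ensemble = fit_adaboost(X, y, rounds=rounds, n_bins=n_bins,
                            feature_names=list(X.columns))
    windows = make_windows(genome.lengths, spec.tile_size)
    sites = list(classify_windows(windows, genome, repeats, catalog,
                                  ensemble))
    dmrs = merge_consecutive(sites, min_run=3)
    planted = {(r.chrom, r.start, r.end) for r in truth.dmr_runs}
    reported = {(d.chrom, d.start, d.end) for d in dmrs}
    exact = reported & planted
    densities = [cpg_density(genome.sequence(d.chrom, d.start, d.end))
                 for d in dmrs]
    # prediction power is a per-site statistic: evaluate on the 1-kb
    # constituent sites of the stringent merged list, where short-motif
    # presence is informative
    spans = {(d.chrom, d.start, d.end) for d in dmrs}
    site_windows = [s.window for s in sites if s.positive and any(
        s.window.chrom == c and lo <= s.window.start and s.window.end <= hi
        for c, lo, hi in spans)]
    feature_df = extract_feature_matrix(site_windows, genome, repeats,
                                        catalog)
    density_col = "cpg_density:base"
    predicates = {density_col: positive_density_bins(
        ensemble.models[0], list(X.columns).index(density_col))}
    power = prediction_power(feature_df, predicates)
    noise_cols = [c for c in feature_df.columns if c.startswith("noise")]
    return {
        "n_positive_windows": int(sum(s.positive for s in sites)),
        "n_merged_dmrs": len(dmrs),
        "n_exact": len(exact),
        "all_exact": len(exact) == len(reported),
        "sensitivity": len(exact) / len(planted),
        "max_dmr_density": float(max(densities)) if densities else 0.0,
        "density_power": float(power[density_col]),
        "max_noise_power": float(power[noise_cols].max())
        if noise_cols else 0.0,
        "ensemble": ensemble,
        "dmrs": dmrs,
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# cluster detection


def _cluster_spec(seed: int, clustered: bool) -> SyntheticSpec:
    regions = (((0, 2_000_000, 5_000_000), (1, 6_000_000, 9_000_000),
                (2, 1_000_000, 4_000_000), (4, 5_500_000, 8_500_000))
               if clustered else ())
    return SyntheticSpec(
        seed=seed, chromosome_lengths=(10_000_000,) * 5, n_dmr_runs=200,
        cluster_regions=regions, cluster_fraction=0.6 if clustered else 0.0)


def cluster_benchmark(seed: int = 0, alpha: float = 0.05) -> dict:
    """Planted-enrichment recovery: 200 DMRs, 60% inside 4 x 3-Mb regions."""
    spec = _cluster_spec(seed, clustered=True)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    dmrs = _place_runs(spec, rng)
    _, found = detect_clusters(dmrs, spec.lengths, alpha=alpha)
    regions = [GenomicWindow(spec.chrom_names[ci], lo, hi)
               for ci, lo, hi in spec.cluster_regions]
    hit = sum(any(c.chrom == r.chrom and c.start < r.end and r.start < c.end
                  for c in found) for r in regions)
    cluster_bp = sum(len(c) for c in found)
    inside_bp = 0
    for c in found:
        for r in regions:
            if c.chrom == r.chrom:
                inside_bp += max(0, min(c.end, r.end) - max(c.start,
                                                            r.start))
    return {
        "n_planted_regions": len(regions),
        "n_regions_hit": int(hit),
        "n_clusters": len(found),
        "cluster_bp_inside_fraction": inside_bp / cluster_bp
        if cluster_bp else 0.0,
        "clusters": found,
        "dmrs": dmrs,
    }


def cluster_null_benchmark(n_seeds: int = 20, base_seed: int = 0,
                           alpha: float = 0.05) -> dict:
    """Uniform DMR placement: clusters should almost never be detected."""
    seeds_with_clusters = 0
    for s in range(n_seeds):
        spec = _cluster_spec(base_seed + s, clustered=False)
        rng = np.random.default_rng(
            np.random.SeedSequence(base_seed + s).spawn(2)[1])
        dmrs = _place_runs(spec, rng)
        _, found = detect_clusters(dmrs, spec.lengths, alpha=alpha)
        seeds_with_clusters += bool(found)
    return {"n_seeds": n_seeds,
            "seeds_with_clusters": seeds_with_clusters}
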