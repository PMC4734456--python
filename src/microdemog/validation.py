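"""Simulation studies validating the statistical machinery end to end.

The cohort-level results of a real survey cannot be reproduced without its
sequence data, so the pipeline is validated by *properties* instead: exact
agreement with brute-force oracles where exact answers exist (UniFrac edge
enumeration, exhaustive subsample expectations, classical ANOVA), and
calibration/recovery behavior on synthetic cohorts with known ground truth
(type-I error of the permutation tests, FDR control, effect-size recovery,
and the membership-vs-abundance detection pattern of planted rare-lineage
effects).  Both the test suite and ``scripts/acceptance.py`` run these.

Problem sizes are scaled so the full battery runs in minutes on one CPU;
they are stated per function.
"""

from __future__ import annotations

import itertools

import dendropy
import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from ._util import substream
from .association_overall import DesignSpec, build_design, distance_r2, permanova_joint
from .data_model import DistanceMatrix
from .diversity_alpha import (
    coverage_at_size,
    pick_target_coverage,
    richness_at_size,
    standardize_at_coverage,
)
from .diversity_beta import pairwise_distances, unweighted_unifrac, weighted_unifrac
from .synthetic_data import (
    EffectSpec,
    SimConfig,
    simulate_counts,
    simulate_metadata,
    simulate_null_distance,
    simulate_tree,
)
from .taxa_signatures import bh_fdr, permutation_f_tests

__all__ = [
    "bruteforce_unifrac",
    "unifrac_oracle_max_error",
    "permanova_null_rejection_rate",
    "euclidean_anova_max_diff",
    "effect_size_recovery",
    "richness_interpolation_max_error",
    "empirical_fdr_at_q",
    "membership_dominance_fraction",
]


# ---------------------------------------------------------------------------
# Exact oracles


def bruteforce_unifrac(newick: str, counts_a: dict, counts_b: dict,
                       weighted: bool) -> float:
    """Reference UniFrac by explicit enumeration of each edge's leaf set."""
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    tot_a = float(sum(counts_a.values()))
    tot_b = float(sum(counts_b.values()))
    unique = union = num = den = 0.0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        leaves = [lf.taxon.label for lf in node.leaf_iter()]
        bl = node.edge.length or 0.0
        mass_a = sum(counts_a.get(l, 0) for l in leaves)
        mass_b = sum(counts_b.get(l, 0) for l in leaves)
        if mass_a > 0 or mass_b > 0:
            union += bl
            if (mass_a > 0) != (mass_b > 0):
                unique += bl
        pa, pb = mass_a / tot_a, mass_b / tot_b
        num += bl * abs(pa - pb)
        den += bl * (pa + pb)
    if weighted:
        return num / den if den > 0 else 0.0
    return unique / union if union > 0 else 0.0


def unifrac_oracle_max_error(n_trees: int = 50, seed: int = 0) -> float:
    """Max |implementation - brute force| over random small trees, both metrics."""
    rng = substream(seed, "unifrac_oracle")
    worst = 0.0
    for rep in range(n_trees):
        n_tips = int(rng.integers(3, 9))
        tree = simulate_tree(n_tips, seed=int(rng.integers(2 ** 31)))
        ids = tree.tip_labels
        a = rng.integers(0, 5, n_tips)
        b = rng.integers(0, 5, n_tips)
        a[0] = max(a[0], 1)
        b[-1] = max(b[-1], 1)
        da, db = dict(zip(ids, a)), dict(zip(ids, b))
        for weighted, fn in ((False, unweighted_unifrac), (True, weighted_unifrac)):
            got = fn(a, b, tree, ids)
            want = bruteforce_unifrac(tree.to_newick(), da, db, weighted)
            worst = max(worst, abs(got - want))
    return worst


def euclidean_anova_max_diff(n_reps: int = 5, n: int = 16, seed: int = 0) -> float:
    """PERMANOVA pseudo-F vs classical joint ANOVA F on Euclidean distances.

    When the distance matrix is the Euclidean distance of a scalar response
    the two must agree exactly.
    """
    from scipy.spatial.distance import pdist, squareform

    rng = substream(seed, "euclid")
    worst = 0.0
    for rep in range(n_reps):
        cfg = SimConfig(n_samples=n, n_otus=2, seed=int(rng.integers(2 ** 31)))
        meta = simulate_metadata(cfg)
        y = rng.normal(size=n)
        D = DistanceMatrix(meta.sample_ids, squareform(pdist(y[:, None])))
        for cov in ("sex", "bmi"):
            design = build_design(meta, DesignSpec(cov))
            full = np.hstack([design.Z, design.x_obs])

            def rss(M):
                beta, *_ = np.linalg.lstsq(M, y, rcond=None)
                r = y - M @ beta
                return float(r @ r)

            f_classic = (((rss(design.Z) - rss(full)) / design.p)
                         / (rss(full) / (n - design.rank_full)))
            res = permanova_joint(D, meta, DesignSpec(cov), n_perm=1, seed=0)
            worst = max(worst, abs(res.statistic - f_classic))
    return worst


def richness_interpolation_max_error(n_samples: int = 30, seed: int = 0) -> float:
    """Coverage-standardized richness vs exhaustive subsample expectation.

    Random samples of depth <= 12; the target coverage is the cohort
    minimum so every sample interpolates.  The expectation at the chosen
    size m* is enumerated over all C(n, m*) subsamples.
    """
    rng = substream(seed, "richness_oracle")
    worst = 0.0
    for _ in range(n_samples):
        depth = int(rng.integers(5, 13))
        n_otus = int(rng.integers(3, 7))
        counts = rng.multinomial(depth, rng.dirichlet(np.ones(n_otus)))
        if (counts > 0).sum() == 0:
            continue
        target = coverage_at_size(counts, int(counts.sum()), corrected=False) * 0.8
        target = max(target, 0.05)
        rich, _ = standardize_at_coverage(counts, "s", target, corrected=False)
        m = int(rich.m)
        if m > counts.sum():
            continue
        reads = np.repeat(np.arange(len(counts)), counts)
        vals = [len(set(reads[list(c)]))
                for c in itertools.combinations(range(len(reads)), m)]
        worst = max(worst, abs(rich.value - float(np.mean(vals))))
    return worst


# ---------------------------------------------------------------------------
# Calibration studies


def permanova_null_rejection_rate(n: int = 50, n_reps: int = 500,
                                  n_perm: int = 200, alpha: float = 0.05,
                                  covariate: str = "sex",
                                  seed: int = 0) -> float:
    """Type-I error of the joint PERMANOVA on signal-free distance matrices."""
    rng = substream(seed, "permanova_null")
    rejections = 0
    for rep in range(n_reps):
        s = int(rng.integers(2 ** 31))
        D = simulate_null_distance(n, seed=s)
        meta = simulate_metadata(SimConfig(n_samples=n, n_otus=2, seed=s))
        res = permanova_joint(D, meta, DesignSpec(covariate), n_perm=n_perm, seed=s)
        rejections += res.p_value <= alpha
    return rejections / n_reps


def effect_size_recovery(magnitudes=(0.0, 1.5, 3.0), n_reps: int = 20,
                         n: int = 60, n_otus: int = 200, seed: int = 0):
    """Adjusted distance-based R² of a planted presence-mode effect.

    Returns (mean adjusted R² per magnitude, Spearman rho of magnitude vs
    adjusted R² over all runs).  Common random numbers across magnitudes:
    replicate r uses the same cohort seed at every magnitude, so the curves
    differ only through the planted effect.
    """
    rng = substream(seed, "effect_recovery")
    rep_seeds = [int(rng.integers(2 ** 31)) for _ in range(n_reps)]
    means = {}
    xs, ys = [], []
    for mag in magnitudes:
        vals = []
        for s in rep_seeds:
            cfg = SimConfig(
                n_samples=n, n_otus=n_otus, depth_min=1500, depth_max=3000,
                effects=(EffectSpec("alcohol", "presence", mag),), seed=s)
            tree = simulate_tree(n_otus, s)
            meta = simulate_metadata(cfg)
            table = simulate_counts(cfg, meta, tree)
            D = pairwise_distances(table, tree, "unweighted", seed=s)
            _, r2_adj = distance_r2(D, meta, DesignSpec("alcohol"))
            vals.append(r2_adj)
            xs.append(mag)
            ys.append(r2_adj)
        means[mag] = float(np.mean(vals))
    rho = float(spearmanr(xs, ys).statistic)
    return means, rho


def empirical_fdr_at_q(q_threshold: float = 0.10, n_taxa: int = 50,
                       n_reps: int = 200, n: int = 60, n_perm: int = 200,
                       covariate: str = "sex", seed: int = 0) -> float:
    """Observed FDR of the taxon screen on all-null Dirichlet taxa.

    Every discovery is false by construction; reported is the mean, over
    replicates, of (false discoveries / max(discoveries, 1)).
    """
    rng = substream(seed, "fdr_null")
    fdps = []
    for rep in range(n_reps):
        s = int(rng.integers(2 ** 31))
        meta = simulate_metadata(SimConfig(n_samples=n, n_otus=2, seed=s))
        local = substream(s, "taxa")
        Y = local.dirichlet(np.full(n_taxa, 0.5), size=n)
        _, p, _ = permutation_f_tests(np.sqrt(Y), meta, DesignSpec(covariate),
                                      n_perm=n_perm, seed=s)
        q = bh_fdr(p)
        discoveries = int((q < q_threshold).sum())
        fdps.append(discoveries / max(discoveries, 1) if discoveries else 0.0)
    return float(np.mean(fdps))


def membership_dominance_fraction(n_reps: int = 20, magnitude: float = 2.0,
                                  n: int = 70, n_otus: int = 300,
                                  n_perm: int = 999, seed: int = 0) -> float:
    """How often a planted rare-lineage (presence-mode) BMI effect yields a
    smaller PERMANOVA p with unweighted than with weighted UniFrac.

    Presence-mode effects change which rare lineages occur, barely moving
    abundance mass, so membership-sensitive (unweighted) analysis should
    dominate — the qualitative pattern expected of covariates acting on the
    rare biosphere.  Comparing two p-values requires them not to be
    censored at the permutation floor, so this study uses 999 permutations
    (ties at the floor are unordered and would count against dominance).
    """
    rng = substream(seed, "dominance")
    wins = 0
    for rep in range(n_reps):
        s = int(rng.integers(2 ** 31))
        cfg = SimConfig(
            n_samples=n, n_otus=n_otus, depth_min=2000, depth_max=4000,
            effects=(EffectSpec("bmi", "presence", magnitude),), seed=s)
        tree = simulate_tree(n_otus, s)
        meta = simulate_metadata(cfg)
        table = simulate_counts(cfg, meta, tree)
        p = {}
        for metric in ("unweighted", "weighted"):
            D = pairwise_distances(table, tree, metric, seed=s)
            p[metric] = permanova_joint(D, meta, DesignSpec("bmi"),
                                        n_perm=n_perm, seed=s).p_value
        wins += p["unweighted"] < p["weighted"]
    return wins / n_reps
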