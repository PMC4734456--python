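"""Between-sample (β) diversity: UniFrac distances, Gower centering, PCoA.

UniFrac measures community dissimilarity along a shared phylogeny.  The
unweighted form compares membership only: the fraction of branch length
leading exclusively to tips present in one of the two communities, out of
the branch length leading to tips present in either.  The weighted form
compares abundance flow: sum_e b_e |p_A(e) - p_B(e)| over edges, where
p_X(e) is the fraction of community X's reads descending through edge e,
normalized by sum_e b_e (p_A(e) + p_B(e)) so the distance lies in [0, 1].
The edge above the root is ignored by convention (it can never separate
the two communities).

Gower centering turns squared distances into the inner-product matrix
G = (I - 11'/n) (-d_ij^2 / 2) (I - 11'/n) whose trace is the total
dispersion; it underlies both PCoA and the distance-based R^2 used for
effect sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_model import CountTable, DistanceMatrix, PhyloTree, ValidationError
from .diversity_alpha import rarefy

logger = logging.getLogger("microdemog")

__all__ = [
    "GowerMatrix",
    "Ordination",
    "unweighted_unifrac",
    "weighted_unifrac",
    "pairwise_distances",
    "gower_center",
    "pcoa",
]


def _edge_abundance(tree: PhyloTree, otu_ids, counts: np.ndarray):
    """Per-edge branch lengths and per-sample read mass under each edge."""
    lengths, membership = tree.edge_arrays(tuple(otu_ids))
    # (E, S) matrix: reads of each sample descending through each edge
    mass = membership.astype(float) @ counts.T.astype(float)
    return lengths, membership, mass


def _check_pair(a, b):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("UniFrac undefined for an empty community")
    return a, b


def unweighted_unifrac(a, b, tree: PhyloTree, otu_ids=None) -> float:
    """Unweighted UniFrac distance between two count vectors.

    Presence/absence only: (branch length unique to one community) /
    (branch length present in either community).
    """
    otu_ids = list(otu_ids) if otu_ids is not None else tree.tip_labels
    a, b = _check_pair(a, b)
    lengths, _, mass = _edge_abundance(tree, otu_ids, np.vstack([a, b]))
    pa, pb = mass[:, 0] > 0, mass[:, 1] > 0
    union = float(lengths[pa | pb].sum())
    if union == 0:
        return 0.0
    unique = float(lengths[pa ^ pb].sum())
    return unique / union


def weighted_unifrac(a, b, tree: PhyloTree, otu_ids=None,
                     normalized: bool = True) -> float:
    """Weighted (abundance-sensitive) UniFrac distance.

    The normalized form (default) divides by sum_e b_e (p_A + p_B) and is
    bounded by [0, 1]; ``normalized=False`` returns the raw branch-mass
    difference sum_e b_e |p_A - p_B|.
    """
    otu_ids = list(otu_ids) if otu_ids is not None else tree.tip_labels
    a, b = _check_pair(a, b)
    lengths, _, mass = _edge_abundance(tree, otu_ids, np.vstack([a, b]))
    pa = mass[:, 0] / a.sum()
    pb = mass[:, 1] / b.sum()
    raw = float(np.sum(lengths * np.abs(pa - pb)))
    if not normalized:
        return raw
    denom = float(np.sum(lengths * (pa + pb)))
    return raw / denom if denom > 0 else 0.0


def pairwise_distances(table: CountTable, tree: PhyloTree,
                       metric: str = "unweighted",
                       rarefy_depth: int | str = "auto",
                       seed: int = 0,
                       prune_missing: bool = False) -> DistanceMatrix:
    """All pairwise UniFrac distances, after rarefying the count table.

    Rarefaction (to the minimum sample depth by default) removes
    depth-driven presence/absence artifacts before distance calculation.
    OTUs absent from the tree are a hard error unless ``prune_missing``.
    """
    if metric not in ("unweighted", "weighted"):
        raise ValueError(f"unknown metric {metric!r}")
    tips = set(tree.tip_labels)
    missing = [o for o in table.otu_ids if o not in tips]
    if missing:
        if not prune_missing:
            raise ValidationError(
                f"{len(missing)} table OTUs absent from tree (e.g. {missing[:3]}); "
                "pass prune_missing=True to drop them"
            )
        logger.warning("dropping %d OTUs absent from tree", len(missing))
        table = CountTable(table.data.drop(columns=missing))
    if set(tree.tip_labels) != set(table.otu_ids):
        tree = tree.prune_to(table.otu_ids)

    if rarefy_depth == "auto":
        rarefy_depth = int(table.depths().min())
    table = rarefy(table, int(rarefy_depth), seed)
    if table.n_samples < 2:
        raise ValueError("fewer than 2 samples survived rarefaction")

    counts = table.counts
    lengths, _, mass = _edge_abundance(tree, table.otu_ids, counts)
    n = table.n_samples
    d = np.zeros((n, n))
    if metric == "unweighted":
        pres = mass > 0  # (E, S)
        shared = (pres * lengths[:, None]).T @ pres  # (S, S)
        per_sample = (pres * lengths[:, None]).sum(axis=0)
        union = per_sample[:, None] + per_sample[None, :] - shared
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(union > 0, 1.0 - shared / union, 0.0)
    else:
        depths = counts.sum(axis=1).astype(float)
        p = mass / depths[None, :]  # (E, S)
        bl = lengths[:, None]
        for i in range(n):
            diff = np.abs(p[:, i][:, None] - p[:, i + 1:])
            tot = p[:, i][:, None] + p[:, i + 1:]
            num = (bl * diff).sum(axis=0)
            den = (bl * tot).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                row = np.where(den > 0, num / den, 0.0)
            d[i, i + 1:] = row
            d[i + 1:, i] = row
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(table.sample_ids, np.clip(d, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Gower centering and PCoA


@dataclass(frozen=True)
class GowerMatrix:
    """Double-centered inner-product form of a distance matrix."""

    sample_ids: tuple
    values: np.ndarray

    @property
    def total_dispersion(self) -> float:
        return float(np.trace(self.values))


def gower_center(D: DistanceMatrix) -> GowerMatrix:
    """G = (I - 11'/n) A (I - 11'/n) with A = (-d_ij^2 / 2).

    Rows and columns of G sum to zero; tr(G) equals the total dispersion
    sum_{i<j} d_ij^2 / n.
    """
    d = D.values
    n = d.shape[0]
    A = -0.5 * d ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    G = (G + G.T) / 2.0
    return GowerMatrix(tuple(D.sample_ids), G)


@dataclass(frozen=True)
class Ordination:
    """PCoA coordinates and per-axis explained variance fractions."""

    sample_ids: tuple
    coordinates: np.ndarray  # (n, k)
    explained: np.ndarray  # fractions of positive-eigenvalue variance
    eigenvalues: np.ndarray


def pcoa(D: DistanceMatrix, k: int = 2) -> Ordination:
    """Principal coordinate analysis of a distance matrix.

    Eigendecomposition of the Gower matrix; axes are eigenvectors scaled
    by the square root of their (positive) eigenvalues.  Negative
    eigenvalues — which arise for non-Euclidean distances such as
    UniFrac — are dropped with a diagnostic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    G = gower_center(D).values
    eigval, eigvec = np.linalg.eigh(G)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(1e-10, 1e-10 * max(abs(eigval[0]), 1.0)) if eigval.size else 0.0
    pos = eigval > tol
    n_neg = int((eigval < -tol).sum())
    if n_neg:
        logger.info("pcoa: dropped %d negative eigenvalues (non-Euclidean distances)",
                    n_neg)
    lam = eigval[pos]
    vec = eigvec[:, pos]
    if k > lam.size:
        logger.warning("pcoa: only %d positive eigenvalues; truncating k=%d",
                       lam.size, k)
        k = lam.size
    coords = vec[:, :k] * np.sqrt(lam[:k])
    explained = lam[:k] / lam.sum() if lam.size else np.zeros(0)
    return Ordination(tuple(D.sample_ids), coords, explained, eigval)
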