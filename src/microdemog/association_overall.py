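"""Overall covariate-microbiota association tests and effect sizes.

Each covariate X is tested one at a time with the model

    Microbiota ~ Batch + X + X:Batch

where Batch absorbs sequencing-batch effects and the interaction lets the
association strength differ between batches.  The test is always *joint*
over the main and interaction terms — the null is "no association in any
batch".  For α-diversity the model is an ordinary least-squares regression
with a likelihood-ratio test; for β-diversity it is PERMANOVA on the
distance matrix with a pseudo-F statistic and a permutation p-value.

Effect size is the distance-based coefficient of determination

    R^2 = tr(H G H) / tr(G)

with G the Gower-centered distance matrix and H a design projection.  The
R^2 reported per covariate is sequential (batch first): the increment
tr(H_full G H_full) - tr(H_batch G H_batch) over tr(G), so batch variance
is never credited to the covariate.  Small-sample inflation is corrected by

    R^2_adj = 1 - (1 - R^2) (n - 1) / (n - p - 1),

where p is the degrees of freedom of the covariate terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.stats import chi2

from ._util import substream
from .data_model import DistanceMatrix, SampleMetadata, ValidationError
from .diversity_beta import gower_center

logger = logging.getLogger("microdemog")

__all__ = [
    "DesignSpec",
    "Design",
    "AssociationResult",
    "build_design",
    "permanova_joint",
    "distance_r2",
    "alpha_lrt",
    "permute_within_strata",
]

#: covariates modeled as continuous (single-column) terms by default
CONTINUOUS_COVARIATES = ("age", "bmi")


@dataclass(frozen=True)
class DesignSpec:
    """Which covariate to test, how to encode it, and the batch column."""

    covariate: str
    kind: str = "auto"  # "continuous" | "categorical" | "auto"
    batch: str = "batch"
    interaction: bool = True

    def resolved_kind(self) -> str:
        if self.kind != "auto":
            return self.kind
        return "continuous" if self.covariate in CONTINUOUS_COVARIATES else "categorical"


@dataclass
class AssociationResult:
    covariate: str
    metric: str
    statistic: float
    p_value: float
    n: int
    df: int
    n_perm: int | None = None
    r2: float | None = None
    r2_adj: float | None = None
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Design construction


@dataclass
class Design:
    """Reduced (Batch) and full (Batch + X + X:Batch) design matrices.

    ``x_builder`` rebuilds the covariate block (main + interaction columns)
    from a permuted copy of the raw covariate values, which is what the
    permutation tests shuffle.
    """

    Z: np.ndarray  # reduced design: intercept + batch dummies
    x_obs: np.ndarray  # observed covariate block
    x_builder: object  # callable: raw values -> covariate block
    values: np.ndarray  # raw covariate values (permutable)
    strata: np.ndarray  # integer batch codes (permutation strata)
    p: int  # rank(full) - rank(reduced)
    rank_reduced: int
    rank_full: int
    dropped_columns: list[str]


def build_design(meta: SampleMetadata, spec: DesignSpec) -> Design:
    """Reference-coded design matrices for one covariate test.

    Aliased covariate columns (those adding no rank beyond the batch
    terms) are dropped with a logged report; a covariate aliased in full
    leaves p = 0 and the caller decides whether that is an error.
    """
    batch = meta[spec.batch]
    if batch.isna().any():
        raise ValidationError("missing batch labels")
    batch_levels = sorted(pd.unique(batch))
    codes = np.array([batch_levels.index(b) for b in batch])
    n = len(codes)
    Z = np.column_stack(
        [np.ones(n)] + [(codes == lv).astype(float) for lv in range(1, len(batch_levels))]
    )

    col = meta[spec.covariate]
    kind = spec.resolved_kind()
    use_interaction = spec.interaction and len(batch_levels) >= 2
    if spec.interaction and len(batch_levels) < 2:
        logger.warning("single batch level: interaction term omitted")

    if kind == "continuous":
        values = col.to_numpy(dtype=float)
        if np.nanstd(values) == 0:
            raise ValidationError(f"degenerate covariate {spec.covariate!r} (constant)")

        def main_cols(v):
            return np.asarray(v, dtype=float)[:, None]

        names = [spec.covariate]
    else:
        values = col.to_numpy(dtype=object)
        levels = sorted(pd.unique(values))
        if len(levels) < 2:
            raise ValidationError(f"degenerate covariate {spec.covariate!r} (constant)")

        def main_cols(v, _levels=levels):
            v = np.asarray(v, dtype=object)
            return np.column_stack([(v == lv).astype(float) for lv in _levels[1:]])

        names = [f"{spec.covariate}[{lv}]" for lv in levels[1:]]

    def x_builder(v):
        xm = main_cols(v)
        if not use_interaction:
            return xm
        inter = [xm * Z[:, j][:, None] for j in range(1, Z.shape[1])]
        return np.hstack([xm] + inter)

    x_obs = x_builder(values)
    all_names = list(names)
    if use_interaction:
        for j in range(1, Z.shape[1]):
            all_names += [f"{nm}:batch[{batch_levels[j]}]" for nm in names]

    rank_reduced = np.linalg.matrix_rank(Z)
    rank_full = np.linalg.matrix_rank(np.hstack([Z, x_obs]))
    p = int(rank_full - rank_reduced)
    # identify aliased covariate columns for the report
    dropped = []
    if p < x_obs.shape[1]:
        rank_sofar = rank_reduced
        M = Z
        for j in range(x_obs.shape[1]):
            Mj = np.hstack([M, x_obs[:, j][:, None]])
            r = np.linalg.matrix_rank(Mj)
            if r > rank_sofar:
                M, rank_sofar = Mj, r
            else:
                dropped.append(all_names[j])
        logger.warning("design for %r: aliased columns dropped: %s",
                       spec.covariate, dropped)
    return Design(Z, x_obs, x_builder, values, codes, p,
                  int(rank_reduced), int(rank_full), dropped)


def complete_case(meta: SampleMetadata, spec: DesignSpec) -> list[str]:
    """Sample ids with non-missing covariate and batch (complete case)."""
    col = meta[spec.covariate]
    ok = ~(col.isna() | meta[spec.batch].isna())
    return [s for s, keep in zip(meta.sample_ids, ok) if keep]


def permute_within_strata(strata: np.ndarray, rng) -> np.ndarray:
    """A permutation of 0..n-1 that only shuffles within each stratum."""
    idx = np.arange(len(strata))
    for s in np.unique(strata):
        pos = np.flatnonzero(strata == s)
        idx[pos] = pos[rng.permutation(len(pos))]
    return idx


# ---------------------------------------------------------------------------
# PERMANOVA


def _orth(M: np.ndarray) -> np.ndarray:
    return linalg.orth(M) if M.size else np.zeros((M.shape[0], 0))


def _trace_proj(G: np.ndarray, Q: np.ndarray) -> float:
    """tr(H G H) = tr(Q' G Q) for the projection H = Q Q'."""
    if Q.shape[1] == 0:
        return 0.0
    return float(np.sum(Q * (G @ Q)))


def _pseudo_f(tr_full, tr_red, tr_g, p, n, rank_full):
    ss_joint = tr_full - tr_red
    ss_res = tr_g - tr_full
    denom_df = n - rank_full
    if denom_df <= 0 or ss_res <= 0:
        return np.inf if ss_joint > 0 else 0.0
    return (ss_joint / p) / (ss_res / denom_df)


def permanova_joint(D: DistanceMatrix, meta: SampleMetadata, spec: DesignSpec,
                    n_perm: int = 1000, seed: int = 0,
                    permute_within_batch: bool = True) -> AssociationResult:
    """Joint (main + interaction) PERMANOVA of one covariate on a distance matrix.

    pseudo-F = [(tr(H_f G H_f) - tr(H_r G H_r)) / p] /
               [tr((I - H_f) G (I - H_f)) / (n - rank_full)]

    The permutation null shuffles the covariate values; by default the
    shuffle is restricted to within-batch strata so the batch structure is
    preserved under the null.  The p-value uses the add-one convention
    (1 + #{F_perm >= F_obs}) / (1 + n_perm), and ties count as exceedances.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ids = complete_case(meta, spec)
    if len(ids) < len(meta.sample_ids):
        logger.info("%s: %d samples dropped (missing values)",
                    spec.covariate, len(meta.sample_ids) - len(ids))
    Ds = D.select_samples(ids)
    ms = meta.select_samples(ids)
    n = Ds.n
    design = build_design(ms, spec)
    if design.p == 0:
        raise ValidationError(
            f"degenerate design: covariate {spec.covariate!r} fully aliased with batch"
        )
    if n < design.p + 2:
        raise ValidationError("too few samples for the requested design")
    G = gower_center(Ds).values
    tr_g = float(np.trace(G))
    Qz = _orth(design.Z)
    tr_red = _trace_proj(G, Qz)

    def tr_full_of(xblock):
        xr = xblock - Qz @ (Qz.T @ xblock)  # residualize on the reduced design
        Qx = _orth(xr)
        return tr_red + _trace_proj(G, Qx)

    tr_full = tr_full_of(design.x_obs)
    f_obs = _pseudo_f(tr_full, tr_red, tr_g, design.p, n, design.rank_full)

    rng = substream(seed, "permanova", spec.covariate)
    exceed = 0
    for _ in range(n_perm):
        if permute_within_batch:
            idx = permute_within_strata(design.strata, rng)
        else:
            idx = rng.permutation(n)
        xb = design.x_builder(design.values[idx])
        f_perm = _pseudo_f(tr_full_of(xb), tr_red, tr_g, design.p, n,
                           design.rank_full)
        if f_perm >= f_obs - 1e-12:
            exceed += 1
    p_value = (1.0 + exceed) / (1.0 + n_perm)

    r2 = (tr_full - tr_red) / tr_g if tr_g > 0 else 0.0
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - design.p - 1)
    return AssociationResult(
        covariate=spec.covariate, metric="permanova", statistic=float(f_obs),
        p_value=float(p_value), n=n, df=design.p, n_perm=n_perm,
        r2=float(r2), r2_adj=float(r2_adj),
    )


def distance_r2(D: DistanceMatrix, meta: SampleMetadata, spec: DesignSpec,
                scope: str = "sequential") -> tuple[float, float]:
    """Distance-based (R^2, adjusted R^2) for one covariate.

    ``scope="sequential"`` (default) credits the covariate only with
    variance beyond batch: [tr(H_f G H_f) - tr(H_batch G H_batch)]/tr(G).
    ``scope="marginal"`` ignores batch and projects on the covariate block
    alone.  The adjustment 1 - (1 - R^2)(n-1)/(n-p-1) may be negative; it
    is never floored here.
    """
    if scope not in ("sequential", "marginal"):
        raise ValueError(f"unknown scope {scope!r}")
    ids = complete_case(meta, spec)
    Ds = D.select_samples(ids)
    ms = meta.select_samples(ids)
    n = Ds.n
    design = build_design(ms, spec)
    if design.p == 0:
        raise ValidationError("degenerate design: covariate fully aliased with batch")
    if n <= design.p + 1:
        raise ValidationError("adjusted R^2 undefined: n <= p + 1")
    G = gower_center(Ds).values
    tr_g = float(np.trace(G))
    if scope == "sequential":
        Qz = _orth(design.Z)
        tr_red = _trace_proj(G, Qz)
        xr = design.x_obs - Qz @ (Qz.T @ design.x_obs)
        tr_full = tr_red + _trace_proj(G, _orth(xr))
        r2 = (tr_full - tr_red) / tr_g if tr_g > 0 else 0.0
    else:
        ones = np.ones((n, 1))
        M = np.hstack([ones, design.x_builder(design.values)])
        Q1 = _orth(ones)
        r2 = ((_trace_proj(G, _orth(M)) - _trace_proj(G, Q1)) / tr_g
              if tr_g > 0 else 0.0)
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - design.p - 1)
    return float(r2), float(r2_adj)


# ---------------------------------------------------------------------------
# α-diversity regression


def _rss(y: np.ndarray, M: np.ndarray) -> float:
    Q = _orth(M)
    resid = y - Q @ (Q.T @ y)
    return float(resid @ resid)


def alpha_lrt(alpha_values: pd.Series, meta: SampleMetadata,
              spec: DesignSpec) -> AssociationResult:
    """Likelihood-ratio test of one covariate on an α-diversity outcome.

    OLS fits of the reduced (Batch) and full (Batch + X + X:Batch) models;
    the LRT statistic n·ln(RSS_r/RSS_f) is referred to a chi-square with p
    degrees of freedom (large-sample normal-likelihood form).
    """
    y_all = alpha_values.reindex(meta.sample_ids)
    ok = ~(y_all.isna() | meta[spec.covariate].isna() | meta[spec.batch].isna())
    ids = [s for s, keep in zip(meta.sample_ids, ok) if keep]
    ms = meta.select_samples(ids)
    y = y_all.loc[ids].to_numpy(dtype=float)
    n = len(y)
    design = build_design(ms, spec)
    if design.p == 0:
        raise ValidationError("degenerate design: covariate fully aliased with batch")
    if n < design.rank_full + 2:
        raise ValidationError("too few samples for the requested design")
    rss_r = _rss(y, design.Z)
    rss_f = _rss(y, np.hstack([design.Z, design.x_obs]))
    flags = []
    if rss_f <= max(1e-12 * float(y @ y), 0.0):
        flags.append("exact_fit")
        stat, p_value = np.inf, 0.0
    else:
        stat = n * np.log(rss_r / rss_f)
        p_value = float(chi2.sf(stat, design.p))
    r2 = 1.0 - rss_f / rss_r if rss_r > 0 else 0.0
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - design.p - 1)
    return AssociationResult(
        covariate=spec.covariate, metric="alpha_lrt", statistic=float(stat),
        p_value=p_value, n=n, df=design.p, r2=float(r2), r2_adj=float(r2_adj),
        flags=flags,
    )
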