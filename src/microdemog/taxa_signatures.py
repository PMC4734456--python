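"""Taxon-level association signatures: aggregation, filtering, permutation
F-tests with batch adjustment, BH-FDR, and fold-change reporting.

OTU counts are aggregated to phylum/family/genus proportions; taxa that
are too rare to test reliably are removed (prevalence > 10% and median
nonzero proportion > 0.05% required); each remaining taxon's square-root
transformed proportion is tested against a covariate with the same joint
batch-adjusted linear model used for the overall association tests, but
with a permutation F-test instead of a parametric one (taxon proportions
are far from normal).  Benjamini-Hochberg FDR is controlled within each
rank x covariate family, and significant taxa are reported with group mean
proportions and log2 fold changes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._util import substream
from .association_overall import (
    DesignSpec,
    build_design,
    complete_case,
    permute_within_strata,
    _orth,
)
from .data_model import CountTable, SampleMetadata, TaxonomyMap, ValidationError
from .synthetic_data import CONTINUOUS_THRESHOLD, EXPOSED_LEVEL

logger = logging.getLogger("microdemog")

__all__ = [
    "TaxaTable",
    "aggregate",
    "filter_taxa",
    "taxon_test",
    "permutation_f_tests",
    "bh_fdr",
    "log2_fold_change",
    "signature_report",
    "DEFAULT_SIGNATURE_COVARIATES",
]

#: covariates screened at taxon level by default (age excluded: it shows no
#: overall association and is entangled with batch in a two-round design)
DEFAULT_SIGNATURE_COVARIATES = ("bmi", "sex", "race", "tobacco", "alcohol")


@dataclass
class TaxaTable:
    """Sample x taxon relative abundances at one taxonomic rank.

    Taxon labels carry their phylum prefix below the phylum rank
    (e.g. "Firmicutes; Eubacterium").  Rows of a freshly aggregated table
    sum to 1; a filtered table keeps only the tested subset of columns.
    """

    data: pd.DataFrame
    rank: str

    def __post_init__(self):
        arr = self.data.to_numpy()
        if np.any(arr < -1e-12) or np.any(arr > 1 + 1e-9):
            raise ValidationError("taxa proportions outside [0, 1]")

    @property
    def sample_ids(self):
        return list(self.data.index)

    @property
    def taxa(self):
        return list(self.data.columns)


def aggregate(table: CountTable, tax: TaxonomyMap, rank: str) -> TaxaTable:
    """Sum OTU counts within each rank label and convert to proportions.

    OTUs unmapped at a sub-phylum rank aggregate into
    "<phylum>; unclassified"; reads are conserved by construction.
    """
    if rank not in TaxonomyMap.RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    ri = TaxonomyMap.RANKS.index(rank)
    labels = []
    for otu in table.otu_ids:
        lin = tax.lineage(otu)
        if rank == "phylum":
            labels.append(lin[0])
        elif lin[0] == TaxonomyMap.UNCLASSIFIED:
            labels.append(TaxonomyMap.UNCLASSIFIED)
        else:
            labels.append(f"{lin[0]}; {lin[ri]}")
    grouped = table.data.T.groupby(np.asarray(labels)).sum().T
    depths = grouped.sum(axis=1).astype(float)
    props = grouped.div(depths, axis=0)
    return TaxaTable(props, rank)


def filter_taxa(taxa: TaxaTable, min_prevalence: float = 0.10,
                min_median_nonzero: float = 0.0005) -> TaxaTable:
    """Keep taxa with prevalence > 10% and median nonzero proportion > 0.05%."""
    arr = taxa.data.to_numpy()
    keep = []
    for j, name in enumerate(taxa.data.columns):
        col = arr[:, j]
        nz = col[col > 0]
        prevalence = nz.size / col.size
        if prevalence <= min_prevalence:
            continue
        if nz.size == 0 or np.median(nz) <= min_median_nonzero:
            continue
        keep.append(name)
    logger.info("filter_taxa(%s): kept %d / %d taxa", taxa.rank, len(keep),
                taxa.data.shape[1])
    return TaxaTable(taxa.data[keep], taxa.rank)


# ---------------------------------------------------------------------------
# Permutation F-tests


def permutation_f_tests(Y: np.ndarray, meta: SampleMetadata, spec: DesignSpec,
                        n_perm: int = 1000, seed: int = 0,
                        permute_within_batch: bool = True):
    """Joint permutation F-tests of one covariate for many responses at once.

    ``Y`` is (n_samples, n_responses), already transformed.  Returns
    (F, p_values, flags); constant responses get F = 0, p = 1 and a flag.
    The F statistic for each response is the classical joint F of the
    covariate terms after batch; significance comes from permuting the
    covariate (within batch strata by default) with add-one correction.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Y = np.asarray(Y, dtype=float)
    n, t = Y.shape
    design = build_design(meta, spec)
    if design.p == 0:
        raise ValidationError("degenerate design: covariate fully aliased with batch")
    Qz = _orth(design.Z)
    Yr = Y - Qz @ (Qz.T @ Y)
    rss_r = np.sum(Yr ** 2, axis=0)
    const = np.isclose(rss_r, 0.0, atol=1e-14)
    denom_df = n - design.rank_full

    def f_stats(xblock):
        xr = xblock - Qz @ (Qz.T @ xblock)
        Qx = _orth(xr)
        proj = Qx.T @ Yr
        ss_x = np.sum(proj ** 2, axis=0)
        rss_f = np.maximum(rss_r - ss_x, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = (ss_x / design.p) / (rss_f / denom_df)
        f = np.where(rss_f <= 1e-14 * np.maximum(rss_r, 1e-300),
                     np.where(ss_x > 0, np.inf, 0.0), f)
        return f

    f_obs = f_stats(design.x_obs)
    rng = substream(seed, "taxon_f", spec.covariate)
    exceed = np.zeros(t)
    for _ in range(n_perm):
        if permute_within_batch:
            idx = permute_within_strata(design.strata, rng)
        else:
            idx = rng.permutation(n)
        f_perm = f_stats(design.x_builder(design.values[idx]))
        exceed += (f_perm >= f_obs - 1e-12)
    p = (1.0 + exceed) / (1.0 + n_perm)
    flags = [["constant"] if c else [] for c in const]
    f_obs = np.where(const, 0.0, f_obs)
    p = np.where(const, 1.0, p)
    return f_obs, p, flags


def taxon_test(y, meta: SampleMetadata, spec: DesignSpec, n_perm: int = 1000,
               seed: int = 0) -> float:
    """Permutation F-test p-value for one taxon's proportion vector.

    The proportions are square-root transformed (variance stabilization)
    before the batch-adjusted joint F-test.
    """
    y = np.asarray(y, dtype=float)
    t = np.sqrt(y)
    _, p, flags = permutation_f_tests(t[:, None], meta, spec, n_perm, seed)
    return float(p[0])


# ---------------------------------------------------------------------------
# FDR and fold changes


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (adjusted p-values), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def log2_fold_change(mean_a: float, mean_b: float) -> float:
    """log2(mean_a / mean_b); NaN (undefined) when either mean is zero.

    No pseudo-count is added: a zero group mean yields an explicit
    undefined value rather than a silently shifted number.
    """
    if mean_a < 0 or mean_b < 0:
        raise ValueError("mean proportions must be non-negative")
    if mean_a == 0 or mean_b == 0:
        return float("nan")
    return float(np.log2(mean_a / mean_b))


# ---------------------------------------------------------------------------
# Report


_GROUP_LABELS = {"bmi": ("Obese", "Normal"), "age": ("50+", "<50")}


def _group_masks(meta: SampleMetadata, covariate: str):
    """Exposed/reference split used for reporting group means.

    Continuous covariates are discretized for display only (BMI at
    30 kg/m^2, age at 50 y); the association tests themselves always use
    the continuous values.
    """
    col = meta[covariate]
    if covariate in CONTINUOUS_THRESHOLD:
        vals = col.to_numpy(dtype=float)
        exposed = vals > CONTINUOUS_THRESHOLD[covariate]
        la, lb = _GROUP_LABELS.get(covariate, ("high", "low"))
        return exposed, la, lb
    level = EXPOSED_LEVEL.get(covariate)
    if level is None:
        levels = sorted(pd.unique(col.dropna()))
        level = levels[-1]
    exposed = col.to_numpy() == level
    return exposed, str(level), f"not-{level}"


def signature_report(taxa_by_rank: dict[str, TaxaTable], meta: SampleMetadata,
                     covariates=DEFAULT_SIGNATURE_COVARIATES,
                     q_threshold: float = 0.10, n_perm: int = 1000,
                     seed: int = 0, batch: str = "batch") -> pd.DataFrame:
    """Significant taxon-covariate associations across ranks.

    For each rank and covariate: permutation F-tests on sqrt proportions,
    BH-FDR within that rank x covariate family, and a report row for every
    taxon with q below the threshold, carrying raw-proportion group means
    and the log2 fold change (exposed over reference).
    """
    rows = []
    for rank, taxa in taxa_by_rank.items():
        if not taxa.taxa:
            continue
        for cov in covariates:
            spec = DesignSpec(cov, batch=batch)
            ids = complete_case(meta, spec)
            ms = meta.select_samples(ids)
            sub = taxa.data.loc[ids]
            Y = np.sqrt(sub.to_numpy(dtype=float))
            _, p, _ = permutation_f_tests(Y, ms, spec, n_perm=n_perm, seed=seed)
            q = bh_fdr(p)
            exposed, label_a, label_b = _group_masks(ms, cov)
            for j, taxon in enumerate(sub.columns):
                if q[j] >= q_threshold:
                    continue
                col = sub[taxon].to_numpy(dtype=float)
                mean_a = float(col[exposed].mean()) if exposed.any() else 0.0
                mean_b = float(col[~exposed].mean()) if (~exposed).any() else 0.0
                rows.append({
                    "rank": rank, "covariate": cov, "taxon": taxon,
                    "group_a": label_a, "group_b": label_b,
                    "mean_a": mean_a, "mean_b": mean_b,
                    "log2_fold_change": log2_fold_change(mean_a, mean_b),
                    "p_value": float(p[j]), "q_value": float(q[j]),
                    "n": len(ids), "n_perm": n_perm,
                })
    cols = ["rank", "covariate", "taxon", "group_a", "group_b", "mean_a",
            "mean_b", "log2_fold_change", "p_value", "q_value", "n", "n_perm"]
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values(["covariate", "rank", "q_value", "taxon"]).reset_index(drop=True)
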