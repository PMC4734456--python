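"""Within-sample (α) diversity: rarefaction, Good-Turing coverage, and
coverage-standardized richness and Shannon diversity.

Comparing raw richness across samples of unequal depth is biased, and even
equal-depth (rarefied) comparison compares samples at unequal
*completeness*.  This module instead standardizes each sample to a common
estimated sample coverage (the Good-Turing fraction of the community's
individuals belonging to already-observed species): for each sample it
finds the (possibly extrapolated) size m* at which estimated coverage
reaches the target and reports richness and Shannon diversity at m*.

Because sequencing errors inflate the singleton count f1 — and f1 drives
both the coverage estimate and richness extrapolation — the observed f1
can first be replaced by a more robust estimate derived from the doubleton
and tripleton counts (see :func:`correct_singletons`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma

from ._util import choose_ratio, content_stream, lchoose
from .data_model import CountTable

logger = logging.getLogger("microdemog")

__all__ = [
    "FrequencyCounts",
    "AlphaResult",
    "rarefy",
    "shannon",
    "correct_singletons",
    "coverage",
    "coverage_at_size",
    "richness_at_size",
    "shannon_at_size",
    "standardize_at_coverage",
    "pick_target_coverage",
    "alpha_diversity_table",
]


# ---------------------------------------------------------------------------
# Frequency counts


@dataclass(frozen=True)
class FrequencyCounts:
    """Species frequency counts of one sample: f[k] = #OTUs with k reads.

    ``n`` is the sample depth, so sum(k * f[k]) == n.  After singleton
    correction f1 (and hence n) may be non-integer.
    """

    f: dict[int, float]
    n: float

    @classmethod
    def from_counts(cls, counts) -> "FrequencyCounts":
        x = np.asarray(counts)
        x = x[x > 0]
        if x.size == 0:
            raise ValueError("all-zero count vector")
        ks, cts = np.unique(x.astype(np.int64), return_counts=True)
        return cls({int(k): float(c) for k, c in zip(ks, cts)}, float(x.sum()))

    def __getitem__(self, k: int) -> float:
        return self.f.get(k, 0.0)

    @property
    def s_obs(self) -> float:
        return float(sum(self.f.values()))


def correct_singletons(fc: FrequencyCounts) -> FrequencyCounts:
    """Replace the observed singleton count f1 by a robust estimate.

    Sequencing errors mostly create spurious low-frequency OTUs, inflating
    f1.  Doubletons and higher counts are far less affected, so f1 is
    re-estimated from them through the Good-Turing frequency ladder: the
    same Cauchy-Schwarz argument that yields the Chao1 bound
    f0 <= f1^2/(2 f2) yields, one rung up,

        f1_hat = ((n - 1) / n) * 2 * f2^2 / (3 * f3),

    which we use whenever tripletons are present.  When f2, f3 (and f4) are
    all zero there is no higher-order information and the observed f1 is
    kept.  The depth is adjusted (n' = n - f1 + f1_hat) so that
    sum(k * f[k]) remains consistent.
    """
    f1, f2, f3 = fc[1], fc[2], fc[3]
    n = fc.n
    if f3 > 0 and f2 > 0 and n > 1:
        f1_hat = (n - 1.0) / n * 2.0 * f2 * f2 / (3.0 * f3)
    else:
        f1_hat = f1  # fallback: no usable higher-order counts
    f1_hat = max(f1_hat, 0.0)
    new_f = dict(fc.f)
    if f1_hat > 0:
        new_f[1] = f1_hat
    else:
        new_f.pop(1, None)
    return FrequencyCounts(new_f, fc.n - f1 + f1_hat)


def coverage(fc: FrequencyCounts) -> float:
    """Estimated sample coverage at the full depth n (Good-Turing).

    C_hat = 1 - (f1/n) * [(n-1) f1 / ((n-1) f1 + 2 f2)].
    """
    if fc.n <= 0:
        raise ValueError("coverage undefined for empty sample")
    f1, f2, n = fc[1], fc[2], fc.n
    if f1 == 0:
        return 1.0
    if n <= 1:
        return 0.0
    return 1.0 - (f1 / n) * ((n - 1) * f1 / ((n - 1) * f1 + 2 * f2))


# ---------------------------------------------------------------------------
# Rarefaction


def rarefy(table: CountTable, depth: int, seed: int) -> CountTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples shallower than ``depth`` are dropped with a warning.  Each
    sample's subsample is drawn from a stream keyed by the byte content of
    its count vector, so identical rows subsample identically and results
    do not depend on sample order.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be >= 1")
    keep_rows = {}
    dropped = []
    for sid in table.sample_ids:
        row = table.data.loc[sid].to_numpy()
        total = int(row.sum())
        if total < depth:
            dropped.append(sid)
            continue
        if total == depth:
            keep_rows[sid] = row
            continue
        rng = content_stream(seed, row.tobytes())
        keep_rows[sid] = rng.multivariate_hypergeometric(row, depth)
    if dropped:
        logger.warning("rarefy: dropped %d samples below depth %d: %s",
                       len(dropped), depth, dropped[:5])
    if not keep_rows:
        raise ValueError(f"no samples at or above rarefaction depth {depth}")
    df = pd.DataFrame.from_dict(keep_rows, orient="index", columns=table.otu_ids)
    df.index.name = "sample_id"
    return CountTable(df)


# ---------------------------------------------------------------------------
# Shannon


def shannon(counts) -> float:
    """Shannon diversity H = -sum p_i ln p_i, in nats."""
    x = np.asarray(counts, dtype=float)
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("all-zero count vector")
    p = x / x.sum()
    return float(-(p * np.log(p)).sum())


# ---------------------------------------------------------------------------
# Interpolation / extrapolation machinery


def _distinct(counts):
    x = np.asarray(counts)
    x = x[x > 0].astype(np.int64)
    ks, ws = np.unique(x, return_counts=True)
    return x, ks.astype(float), ws.astype(float)


def coverage_at_size(counts, m: int, corrected: bool = False) -> float:
    """Estimated coverage of a hypothetical sample of size m <= n.

    For m < n the exact expectation C_hat(m) = 1 - sum_i (x_i/n)
    C(n-x_i, m)/C(n-1, m); at m = n the Good-Turing estimate.
    """
    x, ks, ws = _distinct(counts)
    n = int(x.sum())
    if m >= n:
        fc = FrequencyCounts.from_counts(x)
        return coverage(correct_singletons(fc) if corrected else fc)
    ratios = choose_ratio(n - ks, m, n - 1, m)
    return float(1.0 - np.sum(ws * (ks / n) * ratios))


def richness_at_size(counts, m: float, corrected: bool = False) -> float:
    """Expected OTU richness of a sample of size m.

    Interpolation (m <= n) is the exact hypergeometric expectation
    S_hat(m) = S_obs - sum_i C(n-x_i, m)/C(n, m); extrapolation uses the
    Chao1 unseen-species estimate f0_hat and approaches S_obs + f0_hat.
    """
    x, ks, ws = _distinct(counts)
    n = int(x.sum())
    s_obs = float(ws.sum())
    if m <= n:
        return float(s_obs - np.sum(ws * choose_ratio(n - ks, m, n, m)))
    fc = FrequencyCounts.from_counts(x)
    if corrected:
        fc = correct_singletons(fc)
    f1, f2 = fc[1], fc[2]
    if f1 == 0:
        return s_obs
    nn = fc.n
    if f2 > 0:
        f0 = (nn - 1.0) / nn * f1 * f1 / (2.0 * f2)
    else:
        f0 = (nn - 1.0) / nn * f1 * (f1 - 1.0) / 2.0
    if f0 <= 0:
        return s_obs
    j = m - n
    return float(s_obs + f0 * (1.0 - (1.0 - f1 / (nn * f0 + f1)) ** j))


def _entropy_asymptotic(counts) -> float:
    """Asymptotic Shannon entropy estimator (low-bias, Good-Turing based)."""
    x, ks, ws = _distinct(counts)
    n = int(x.sum())
    if n <= 1:
        return 0.0
    part1 = float(np.sum(ws * (ks / n) * (digamma(n) - digamma(ks))))
    fc = FrequencyCounts.from_counts(x)
    f1, f2 = fc[1], fc[2]
    if f1 == 0:
        return part1
    if f2 > 0:
        A = 2.0 * f2 / ((n - 1) * f1 + 2.0 * f2)
    elif f1 > 1:
        A = 2.0 / ((n - 1) * (f1 - 1) + 2.0)
    else:
        A = 1.0
    if A >= 1.0:
        return part1
    r = np.arange(1, n)
    series = np.sum(np.exp(r * np.log1p(-A)) / r)
    part2 = (f1 / n) * (1.0 - A) ** (1 - n) * (-np.log(A) - series)
    return part1 + float(part2)


def shannon_at_size(counts, m: float) -> float:
    """Expected Shannon diversity of a sample of size m (nats).

    Interpolation (m < n) is the exact expectation over hypergeometric
    subsamples, computed per frequency class with the mass windowed around
    the hypergeometric mean; extrapolation blends the observed entropy with
    the asymptotic estimator: H(n+j) = (n H_n + j H_inf) / (n+j).
    """
    x, ks, ws = _distinct(counts)
    n = int(x.sum())
    if m >= n:
        h_obs = shannon(x)
        if m == n:
            return h_obs
        h_inf = max(_entropy_asymptotic(x), h_obs)
        j = m - n
        return float((n * h_obs + j * h_inf) / (n + j))
    m = int(m)
    if m <= 1:
        return 0.0
    total = 0.0
    for xk, w in zip(ks, ws):
        mu = m * xk / n
        sd = np.sqrt(max(mu * (1 - xk / n) * (n - m) / max(n - 1, 1), 0.0))
        lo = max(1, int(np.floor(mu - 10 * sd - 5)))
        hi = min(int(xk), m, int(np.ceil(mu + 10 * sd + 5)))
        if hi < lo:
            continue
        k = np.arange(lo, hi + 1, dtype=float)
        # hypergeometric pmf: C(x,k) C(n-x, m-k) / C(n,m), in log space
        logpmf = lchoose(xk, k) + lchoose(n - xk, m - k) - lchoose(n, m)
        pmf = np.exp(logpmf)
        frac = k / m
        total += w * float(np.sum(pmf * (-frac * np.log(frac))))
    return total


# ---------------------------------------------------------------------------
# Coverage standardization


@dataclass(frozen=True)
class AlphaResult:
    """One sample's diversity value standardized at a coverage level."""

    sample_id: str
    metric: str  # "observed_otus" | "shannon"
    value: float
    coverage_level: float
    m: float  # (possibly extrapolated) sample size used
    extrapolated: bool = False
    flagged: bool = False  # target coverage unreachable within the cap


def _size_for_coverage(counts, target: float, corrected: bool,
                       extrapolation_cap: float = 2.0):
    """Smallest sample size m whose estimated coverage reaches ``target``.

    Returns (m, extrapolated, flagged).  Extrapolation is capped at
    ``extrapolation_cap * n`` (default 2n), beyond which reliability
    degrades; a capped result is flagged.
    """
    x = np.asarray(counts)
    n = int(x[x > 0].sum())
    c_full = coverage_at_size(x, n, corrected=corrected)
    if target <= c_full + 1e-12:
        lo, hi = 1, n
        while lo < hi:
            mid = (lo + hi) // 2
            if coverage_at_size(x, mid, corrected=corrected) >= target - 1e-12:
                hi = mid
            else:
                lo = mid + 1
        return lo, False, False
    fc = FrequencyCounts.from_counts(x)
    if corrected:
        fc = correct_singletons(fc)
    f1, f2, nn = fc[1], fc[2], fc.n
    cap = int(np.floor(extrapolation_cap * n))
    if f1 <= 0 or nn <= 1:
        return n, False, True  # coverage is already 1; target > 1 unreachable
    B = (nn - 1) * f1 / ((nn - 1) * f1 + 2 * f2)
    if B >= 1.0 or B <= 0.0:
        return cap, True, True
    j = np.log((1.0 - target) * nn / f1) / np.log(B) - 1.0
    j = int(np.ceil(j - 1e-9))
    if j <= 0:
        return n, False, False
    if n + j > cap:
        logger.warning("coverage target %.4f needs m=%d > %dx depth cap; capped",
                       target, n + j, int(extrapolation_cap))
        return cap, True, True
    return n + j, True, False


def standardize_at_coverage(counts, sample_id: str, target: float,
                            corrected: bool = True) -> tuple[AlphaResult, AlphaResult]:
    """Richness and Shannon diversity standardized at ``target`` coverage.

    Both metrics are evaluated at the same size m*, the smallest sample
    size whose estimated coverage reaches the target.
    """
    if not (0.0 < target <= 1.0):
        raise ValueError("target coverage must be in (0, 1]")
    x = np.asarray(counts)
    if x[x > 0].size == 0:
        raise ValueError("all-zero count vector")
    m, extrap, flagged = _size_for_coverage(x, target, corrected)
    rich = richness_at_size(x, m, corrected=corrected)
    shan = shannon_at_size(x, m)
    return (
        AlphaResult(sample_id, "observed_otus", rich, target, m, extrap, flagged),
        AlphaResult(sample_id, "shannon", shan, target, m, extrap, flagged),
    )


def pick_target_coverage(table: CountTable, corrected: bool = True) -> float:
    """Minimum estimated sample coverage across all samples.

    Standardizing at this level means every sample can be *interpolated*
    (or at worst held at its own depth), never extrapolated.
    """
    covs = []
    for sid in table.sample_ids:
        fc = FrequencyCounts.from_counts(table.data.loc[sid].to_numpy())
        if corrected:
            fc = correct_singletons(fc)
        covs.append(coverage(fc))
    return float(min(covs))


def alpha_diversity_table(table: CountTable, target: float | str = "auto",
                          corrected: bool = True) -> pd.DataFrame:
    """Coverage-standardized α-diversity for every sample (long format)."""
    if target == "auto":
        target = pick_target_coverage(table, corrected=corrected)
    rows = []
    for sid in table.sample_ids:
        x = table.data.loc[sid].to_numpy()
        for res in standardize_at_coverage(x, sid, float(target), corrected):
            rows.append({
                "sample_id": res.sample_id, "metric": res.metric,
                "value": res.value, "coverage_level": res.coverage_level,
                "m": res.m, "extrapolated": res.extrapolated,
                "flagged": res.flagged,
            })
    return pd.DataFrame(rows)
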