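"""Shared numerical and seeding helpers."""

from __future__ import annotations

import zlib

import numpy as np
from scipy.special import gammaln

__all__ = ["substream", "content_stream", "lchoose", "choose_ratio"]


def substream(seed: int, *names: str | int) -> np.random.Generator:
    """Return an independent RNG derived from a master seed and a label path.

    Every stochastic stage of the pipeline draws from its own named
    substream so stages can be re-run or reordered without perturbing
    each other's draws.
    """
    keys = [zlib.crc32(str(n).encode()) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *keys]))


def content_stream(seed: int, payload: bytes) -> np.random.Generator:
    """RNG keyed by the byte content of its input.

    Used for per-sample rarefaction: two samples with identical count
    vectors receive identical subsamples regardless of their ids.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(payload)]))


def lchoose(n, k):
    """log of the binomial coefficient C(n, k), elementwise, -inf where k > n."""
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where((k < 0) | (k > n), -np.inf, out)


def choose_ratio(n1, k1, n2, k2):
    """C(n1, k1) / C(n2, k2) computed in log space; 0 where the numerator vanishes."""
    num = lchoose(n1, k1)
    den = lchoose(n2, k2)
    return np.where(np.isneginf(num), 0.0, np.exp(num - den))
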