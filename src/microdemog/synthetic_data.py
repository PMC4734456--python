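"""Seeded synthetic cohorts with the statistical structure of a two-batch
16S gut microbiome survey.

The generator emulates a ~118-subject cohort sequenced in two batches:
1,745 OTUs dominated by rare, low-abundance lineages; demographic and
behavioral covariates drawn from the cohort's marginal frequencies; read
depths log-uniform over roughly 30,000-390,000; and small planted covariate
effects concentrated on rare clades of the phylogeny.

The count model is Dirichlet-multinomial with log-normal base
concentrations — the standard overdispersed model for 16S count data.
Covariate effects come in two modes:

* ``presence`` — the effect multiplies the per-sample occupancy probability
  of a designated rare clade (tips below one internal node) in exposed
  subjects, shifting community membership with almost no abundance signal;
* ``abundance`` — the effect tilts the Dirichlet concentrations of a random
  OTU subset in exposed subjects, shifting relative abundances.

Magnitudes are log2 fold changes, so magnitude 0 is an exact null.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import pdist, squareform
import pandas as pd

from ._util import substream
from .data_model import (
    CountTable,
    DistanceMatrix,
    PhyloTree,
    SampleMetadata,
    TaxonomyMap,
    ValidationError,
)

__all__ = [
    "EffectSpec",
    "SimConfig",
    "simulate_tree",
    "simulate_metadata",
    "simulate_taxonomy",
    "simulate_counts",
    "simulate_null_distance",
    "simulate_cohort",
]

#: Exposure definition used by effect specs: for categorical covariates the
#: listed level is "exposed"; continuous covariates are thresholded.
EXPOSED_LEVEL = {"sex": "F", "race": "non-white", "alcohol": "Y", "tobacco": "Y"}
CONTINUOUS_THRESHOLD = {"bmi": 30.0, "age": 50.0}


@dataclass(frozen=True)
class EffectSpec:
    """One planted covariate effect."""

    covariate: str
    mode: str = "presence"  # "presence" | "abundance"
    magnitude: float = 0.0  # log2 fold change; 0 = null

    def __post_init__(self):
        if self.mode not in ("presence", "abundance"):
            raise ValueError(f"unknown effect mode {self.mode!r}")
        if self.magnitude < 0:
            raise ValueError("effect magnitude must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Study-condition defaults for the synthetic cohort."""

    n_samples: int = 118
    n_otus: int = 1745
    n_batches: int = 2
    #: log-normal sd of base Dirichlet concentrations (rare-dominated profile)
    lognormal_sigma: float = 2.2
    #: total Dirichlet concentration (controls subject-to-subject overdispersion)
    theta: float = 250.0
    effects: tuple[EffectSpec, ...] = ()
    batch_effect_magnitude: float = 0.0
    #: fraction of OTUs tilted by batch / abundance-mode effects
    effect_otu_fraction: float = 0.10
    #: target tip fraction of the designated rare clade (presence effects)
    rare_clade_fraction: tuple[float, float] = (0.03, 0.12)
    #: max base relative-abundance mass of the designated clade; keeps the
    #: planted occupancy shift on genuinely rare lineages (little weight)
    rare_clade_max_mass: float = 0.02
    #: baseline per-sample occupancy probability of rare-clade OTUs
    rare_clade_occupancy: float = 0.20
    depth_min: int = 30_000
    depth_max: int = 390_000
    marginals: dict = field(default_factory=lambda: {
        "sex_f": 0.508, "race_white": 0.873, "alcohol_y": 0.678,
        "tobacco_y": 0.144, "bmi_mean": 27.3, "bmi_sd": 4.9,
    })
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 2 or self.n_otus < 2 or self.n_batches < 1:
            raise ValueError("sizes must be >= 2 (batches >= 1)")
        if self.depth_min <= 0 or self.depth_max < self.depth_min:
            raise ValueError("depth range must be positive and ordered")
        if self.batch_effect_magnitude < 0:
            raise ValueError("batch effect magnitude must be >= 0")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Tree


def simulate_tree(n_tips: int, seed: int) -> PhyloTree:
    """Random rooted bifurcating tree by iterative random joining.

    Exponential branch lengths (mean 0.1).  A rooted binary tree over L
    tips built this way has 2L-2 edges below the root.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = substream(seed, "tree")
    width = max(4, len(str(n_tips)))
    nodes = [f"OTU_{i + 1:0{width}d}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = sorted((int(i), int(j)))
        b1, b2 = rng.exponential(0.1, size=2)
        merged = f"({nodes[i]}:{b1:.6f},{nodes[j]}:{b2:.6f})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return PhyloTree.from_newick(nodes[0] + ";")


# ---------------------------------------------------------------------------
# Metadata


def simulate_metadata(config: SimConfig) -> SampleMetadata:
    """Draw covariates from the configured marginals.

    Batch is assigned by sample-index blocks (first half / second half for
    two batches), mimicking two recruitment rounds; with two batches the
    first block draws ages 20-49 and the second 50-79, reproducing the
    age-batch entanglement of a two-round design.
    """
    rng = substream(config.seed, "metadata")
    n = config.n_samples
    m = config.marginals
    ids = [f"S{i + 1:04d}" for i in range(n)]
    bounds = np.linspace(0, n, config.n_batches + 1).round().astype(int)
    batch = np.empty(n, dtype=object)
    age = np.empty(n)
    for b in range(config.n_batches):
        lo, hi = bounds[b], bounds[b + 1]
        batch[lo:hi] = f"batch{b + 1}"
        if config.n_batches == 2:
            a_lo, a_hi = (20.0, 50.0) if b == 0 else (50.0, 80.0)
        else:
            a_lo, a_hi = 20.0, 80.0
        age[lo:hi] = rng.uniform(a_lo, a_hi, size=hi - lo)
    sex = np.where(rng.random(n) < m["sex_f"], "F", "M")
    race = np.where(rng.random(n) < m["race_white"], "white", "non-white")
    bmi = np.clip(rng.normal(m["bmi_mean"], m["bmi_sd"], size=n), 16.0, 55.0)
    alcohol = np.where(rng.random(n) < m["alcohol_y"], "Y", "N")
    tobacco = np.where(rng.random(n) < m["tobacco_y"], "Y", "N")
    df = pd.DataFrame(
        {"age": np.round(age, 1), "sex": sex, "race": race,
         "bmi": np.round(bmi, 1), "alcohol": alcohol, "tobacco": tobacco,
         "batch": batch},
        index=pd.Index(ids, name="sample_id"),
    )
    return SampleMetadata(df)


def exposure_vector(meta: SampleMetadata, covariate: str) -> np.ndarray:
    """Boolean exposed/unexposed split used by the effect machinery."""
    if covariate not in meta.data.columns:
        raise ValidationError(f"effect references unknown covariate {covariate!r}")
    col = meta[covariate]
    if covariate in CONTINUOUS_THRESHOLD:
        return col.to_numpy(dtype=float) > CONTINUOUS_THRESHOLD[covariate]
    level = EXPOSED_LEVEL.get(covariate)
    if level is None:
        raise ValidationError(f"no exposure rule for covariate {covariate!r}")
    return col.to_numpy() == level


# ---------------------------------------------------------------------------
# Taxonomy


def simulate_taxonomy(tree: PhyloTree, seed: int,
                      n_phyla: int | None = None,
                      n_families: int | None = None,
                      n_genera: int | None = None) -> TaxonomyMap:
    """Assign a nested phylum/family/genus labelling along the tree's leaf order.

    Rank counts default to the 11/80/171 proportions of a ~1,745-OTU gut
    survey, scaled to the tree size.  Genera are contiguous leaf blocks,
    nested inside families, nested inside phyla, so taxonomy tracks the
    phylogeny.
    """
    tips = tree.tip_labels
    n = len(tips)
    n_phyla = n_phyla or max(2, round(11 * n / 1745))
    n_families = n_families or max(n_phyla, round(80 * n / 1745))
    n_genera = n_genera or max(n_families, round(171 * n / 1745))
    n_genera = min(n_genera, n)
    n_families = min(n_families, n_genera)
    n_phyla = min(n_phyla, n_families)
    rng = substream(seed, "taxonomy")

    def blocks(total, k):
        w = rng.dirichlet(np.full(k, 2.0))
        sizes = np.maximum(1, np.round(w * total).astype(int))
        while sizes.sum() > total:
            sizes[np.argmax(sizes)] -= 1
        while sizes.sum() < total:
            sizes[np.argmin(sizes)] += 1
        return np.repeat(np.arange(k), sizes)

    genus_of = blocks(n, n_genera)
    family_of_genus = np.sort(blocks(n_genera, n_families))
    phylum_of_family = np.sort(blocks(n_families, n_phyla))
    mapping = {}
    for i, tip in enumerate(tips):
        g = genus_of[i]
        f = family_of_genus[g]
        p = phylum_of_family[f]
        mapping[tip] = (f"Phylum{p + 1:02d}", f"Family{f + 1:03d}", f"Genus{g + 1:04d}")
    return TaxonomyMap(mapping)


# ---------------------------------------------------------------------------
# Counts


def _pick_rare_clade(tree: PhyloTree, otu_ids, frac_range, p_base, max_mass,
                     rng) -> np.ndarray:
    """Tip mask of a random internal clade: right size range, low abundance.

    Candidates are internal edges whose tip count falls in the target
    fraction range; among those, only clades carrying at most ``max_mass``
    of the base composition qualify (falling back to the lowest-mass
    candidate), so the planted occupancy shift sits on rare lineages.
    """
    _, membership = tree.edge_arrays(tuple(otu_ids))
    sizes = membership.sum(axis=1)
    lo = max(2, int(np.floor(frac_range[0] * len(otu_ids))))
    hi = max(lo, int(np.ceil(frac_range[1] * len(otu_ids))))
    candidates = np.flatnonzero((sizes >= lo) & (sizes <= hi))
    if candidates.size == 0:
        candidates = np.flatnonzero((sizes >= 2) & (sizes <= max(2, hi)))
    masses = membership[candidates].astype(float) @ p_base
    light = candidates[masses <= max_mass]
    if light.size == 0:
        light = candidates[[int(np.argmin(masses))]]
    choice = light[rng.integers(light.size)]
    return membership[choice].copy()


def simulate_counts(config: SimConfig, meta: SampleMetadata,
                    tree: PhyloTree) -> CountTable:
    """Dirichlet-multinomial counts with planted covariate and batch effects."""
    otu_ids = tree.tip_labels
    if len(otu_ids) != config.n_otus:
        raise ValidationError(
            f"tree has {len(otu_ids)} tips but config.n_otus={config.n_otus}"
        )
    n = len(meta.sample_ids)
    rng_base = substream(config.seed, "base")
    p_base = np.exp(rng_base.normal(0.0, config.lognormal_sigma, size=len(otu_ids)))
    p_base /= p_base.sum()
    alpha0 = config.theta * p_base

    # batch tilt: a random OTU subset up/down-weighted in non-reference batches
    rng_b = substream(config.seed, "batch_effect")
    n_tilt = max(1, int(round(config.effect_otu_fraction * len(otu_ids))))
    batch_otus = rng_b.choice(len(otu_ids), size=n_tilt, replace=False)
    batch_sign = rng_b.choice([-1.0, 1.0], size=n_tilt)
    batches = meta["batch"].to_numpy()
    ref_batch = batches[0]

    presence_specs = [e for e in config.effects if e.mode == "presence"]
    abundance_specs = [e for e in config.effects if e.mode == "abundance"]

    clade_mask = None
    if presence_specs:
        rng_c = substream(config.seed, "clade")
        clade_mask = _pick_rare_clade(tree, otu_ids, config.rare_clade_fraction,
                                      p_base, config.rare_clade_max_mass, rng_c)
    abundance_targets = {}
    for e in abundance_specs:
        rng_e = substream(config.seed, "abundance", e.covariate)
        abundance_targets[e.covariate] = rng_e.choice(
            len(otu_ids), size=n_tilt, replace=False
        )
    exposures = {e.covariate: exposure_vector(meta, e.covariate)
                 for e in config.effects}

    rng_counts = substream(config.seed, "counts")
    depths = np.exp(
        rng_counts.uniform(np.log(config.depth_min), np.log(config.depth_max), size=n)
    ).astype(np.int64)
    depths = np.clip(depths, config.depth_min, config.depth_max)

    counts = np.zeros((n, len(otu_ids)), dtype=np.int64)
    for s in range(n):
        a = alpha0.copy()
        if config.batch_effect_magnitude > 0 and batches[s] != ref_batch:
            a[batch_otus] *= 2.0 ** (config.batch_effect_magnitude * batch_sign)
        for e in abundance_specs:
            if exposures[e.covariate][s]:
                a[abundance_targets[e.covariate]] *= 2.0 ** e.magnitude
        if clade_mask is not None:
            q = config.rare_clade_occupancy
            mult = 1.0
            for e in presence_specs:
                if exposures[e.covariate][s]:
                    mult *= 2.0 ** e.magnitude
            q_s = min(0.95, q * mult)
            occupied = rng_counts.random(clade_mask.sum()) < q_s
            a_clade = a[clade_mask]
            a_clade[~occupied] = 0.0
            a[clade_mask] = a_clade
        g = rng_counts.gamma(np.maximum(a, 0.0))
        if g.sum() <= 0:
            g[np.argmax(alpha0)] = 1.0
        p = g / g.sum()
        counts[s] = rng_counts.multinomial(depths[s], p)
        if counts[s].sum() == 0:  # pragma: no cover - depth >= 1 prevents this
            counts[s, np.argmax(p)] = depths[s]
    df = pd.DataFrame(counts, index=pd.Index(meta.sample_ids, name="sample_id"),
                      columns=otu_ids)
    return CountTable(df)


# ---------------------------------------------------------------------------
# Null distances


def simulate_null_distance(n: int, seed: int, dim: int = 5) -> DistanceMatrix:
    """Euclidean distances between i.i.d. standard normal points.

    Carries no covariate signal by construction; used to check the type-I
    error of the permutation machinery.
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    rng = substream(seed, "null_distance")
    pts = rng.standard_normal((n, dim))
    d = squareform(pdist(pts))
    ids = [f"S{i + 1:04d}" for i in range(n)]
    return DistanceMatrix(ids, d)


# ---------------------------------------------------------------------------
# Convenience


def simulate_cohort(config: SimConfig):
    """Generate (table, tree, taxonomy, metadata) for one synthetic cohort."""
    tree = simulate_tree(config.n_otus, config.seed)
    meta = simulate_metadata(config)
    tax = simulate_taxonomy(tree, config.seed)
    table = simulate_counts(config, meta, tree)
    return table, tree, tax, meta
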