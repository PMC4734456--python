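"""Config-driven orchestration of the full analysis.

One call (or ``microdemog run --config config.yaml``) takes a cohort —
either real files (counts TSV, Newick tree, taxonomy TSV, metadata TSV) or
a simulated one — through cohort summary, coverage-standardized
α-diversity with LRT association tests, rarefaction + UniFrac distances,
joint batch-interaction PERMANOVA with distance-based effect sizes, PCoA
coordinates, and taxon-level signatures.  Every stage writes a TSV into
the output directory; an existing stage output is reused rather than
recomputed, so deleting a single artifact and re-running recomputes only
that stage.  Runs are byte-for-byte reproducible for a fixed config.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._util import substream
from .association_overall import DesignSpec, alpha_lrt, permanova_joint
from .data_model import (
    DistanceMatrix,
    SampleMetadata,
    align,
    read_count_table,
    read_metadata,
    read_newick,
    read_taxonomy,
)
from .diversity_alpha import alpha_diversity_table
from .diversity_beta import pairwise_distances, pcoa
from .synthetic_data import SimConfig, EffectSpec, simulate_cohort
from .taxa_signatures import aggregate, filter_taxa, signature_report

logger = logging.getLogger("microdemog")

__all__ = ["PipelineConfig", "summarize_cohort", "run_pipeline"]

DEFAULT_COVARIATES = ("age", "sex", "race", "bmi", "alcohol", "tobacco")


@dataclass
class PipelineConfig:
    out_dir: str = "results"
    inputs: dict | None = None  # counts/tree/taxonomy/metadata paths
    simulate: SimConfig | None = None
    covariates: tuple = DEFAULT_COVARIATES
    signature_covariates: tuple = ("bmi", "sex", "race", "tobacco", "alcohol")
    batch: str = "batch"
    n_perm: int = 1000
    seed: int = 7
    rarefy_depth: int | str = "auto"
    target_coverage: float | str = "auto"
    singleton_correction: bool = True
    q_threshold: float = 0.10
    ranks: tuple = ("phylum", "family", "genus")
    pcoa_axes: int = 2

    def __post_init__(self):
        if (self.inputs is None) == (self.simulate is None):
            raise ValueError("config must set exactly one of 'inputs' or 'simulate'")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        if sim is not None:
            effects = tuple(EffectSpec(**e) for e in sim.pop("effects", []))
            sim = SimConfig(effects=effects, **sim)
        fields = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
        return cls(simulate=sim, **fields)


# ---------------------------------------------------------------------------
# Cohort summary


def _pct(count: int, total: int) -> float:
    """Percentage rounded to 1 decimal, half up (as printed in reports)."""
    if total == 0:
        return 0.0
    return float(Decimal(100 * count / total).quantize(Decimal("0.1"),
                                                       rounding=ROUND_HALF_UP))


def summarize_cohort(meta: SampleMetadata, age_cutoff: float = 50.0) -> pd.DataFrame:
    """Per age-stratum counts and percentages of the cohort characteristics.

    Strata are age < cutoff and age >= cutoff (default 50 y); within each,
    the count and percentage of females, whites, BMI > 30 kg/m^2, alcohol
    users, and smokers.
    """
    if "age" not in meta.data.columns or meta["age"].isna().all():
        raise ValueError("cohort summary requires an age column")
    age = meta["age"].to_numpy(dtype=float)
    rows = []
    for label, mask in ((f"Age <{age_cutoff:g} years", age < age_cutoff),
                        (f"Age >={age_cutoff:g} years", age >= age_cutoff)):
        n = int(mask.sum())
        sub = meta.data.loc[mask]
        checks = [
            ("Sex, F", (sub["sex"] == "F").sum()),
            ("Race, W", (sub["race"] == "white").sum()),
            ("BMI >30 kg/m^2", (sub["bmi"].astype(float) > 30).sum()),
            ("Alcohol use (Y)", (sub["alcohol"] == "Y").sum()),
            ("Smoking (Y)", (sub["tobacco"] == "Y").sum()),
        ]
        for name, count in checks:
            rows.append({"stratum": label, "n_stratum": n,
                         "characteristic": name, "count": int(count),
                         "percent": _pct(int(count), n)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Stage plumbing


def _write(df: pd.DataFrame, path: Path, header: list[str], index=False) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        fh.write(df.to_csv(sep="\t", index=index, float_format="%.10g"))


def _read(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute (or resume) the full analysis; returns artifact paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / f"{name}.tsv" for name in (
        "cohort_summary", "alpha", "alpha_assoc", "dist_unweighted",
        "dist_weighted", "beta_assoc", "effect_sizes", "pcoa", "signatures",
    )}
    paths["manifest"] = out / "manifest.yaml"
    stamp = [f"microdemog {__version__}", f"seed={config.seed}"]
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "n_perm": config.n_perm, "stages": {}}

    def stage(name):
        def deco(fn):
            p = paths[name]
            if p.exists():
                logger.info("stage %s: cached (%s)", name, p)
                manifest["stages"][name] = "cached"
                return
            try:
                fn(p)
            except Exception as exc:
                raise RuntimeError(
                    f"pipeline stage {name!r} failed: {exc}. "
                    f"Delete {p.parent} contents to force a clean re-run."
                ) from exc
            manifest["stages"][name] = "computed"
        return deco

    # -- inputs -------------------------------------------------------------
    input_dir = out / "inputs"
    if config.simulate is not None:
        input_dir.mkdir(exist_ok=True)
        fpaths = {k: input_dir / v for k, v in (
            ("counts", "counts.tsv"), ("tree", "tree.nwk"),
            ("taxonomy", "taxonomy.tsv"), ("metadata", "metadata.tsv"))}
        if not all(p.exists() for p in fpaths.values()):
            table, tree, tax, meta = simulate_cohort(config.simulate)
            table.to_tsv(fpaths["counts"])
            tree.to_file(fpaths["tree"])
            tax.to_tsv(fpaths["taxonomy"])
            meta.to_tsv(fpaths["metadata"])
        manifest["simulate_seed"] = config.simulate.seed
    else:
        fpaths = {k: Path(v) for k, v in config.inputs.items()}

    table = read_count_table(fpaths["counts"])
    tree = read_newick(fpaths["tree"])
    tax = read_taxonomy(fpaths["taxonomy"])
    meta = read_metadata(fpaths["metadata"])
    aligned = align(table, meta, tree)
    table, meta, tree = aligned.table, aligned.metadata, aligned.tree
    manifest["n_samples"] = table.n_samples
    manifest["n_otus"] = table.n_otus

    # -- cohort summary -----------------------------------------------------
    @stage("cohort_summary")
    def _cohort(p):
        _write(summarize_cohort(meta), p, stamp + ["cohort summary by age stratum"])

    # -- alpha diversity ----------------------------------------------------
    @stage("alpha")
    def _alpha(p):
        df = alpha_diversity_table(table, target=config.target_coverage,
                                   corrected=config.singleton_correction)
        _write(df, p, stamp + ["coverage-standardized alpha diversity"])

    alpha_df = _read(paths["alpha"])
    alpha_wide = alpha_df.pivot(index="sample_id", columns="metric", values="value")

    @stage("alpha_assoc")
    def _alpha_assoc(p):
        rows = []
        for metric in ("observed_otus", "shannon"):
            vals = alpha_wide[metric]
            row = {"metric": metric}
            for cov in config.covariates:
                res = alpha_lrt(vals, meta, DesignSpec(cov, batch=config.batch))
                row[cov] = res.p_value
            rows.append(row)
        _write(pd.DataFrame(rows), p,
               stamp + ["alpha-diversity association p-values (LRT, joint main+interaction)"])

    # -- distances ----------------------------------------------------------
    for metric in ("unweighted", "weighted"):
        @stage(f"dist_{metric}")
        def _dist(p, metric=metric):
            D = pairwise_distances(table, tree, metric=metric,
                                   rarefy_depth=config.rarefy_depth,
                                   seed=config.seed, prune_missing=True)
            D.to_tsv(p)

    dists = {m: DistanceMatrix.from_tsv(paths[f"dist_{m}"])
             for m in ("unweighted", "weighted")}

    # -- beta association + effect sizes ------------------------------------
    # the two artifacts are computed together; losing one invalidates both
    if paths["beta_assoc"].exists() and not paths["effect_sizes"].exists():
        paths["beta_assoc"].unlink()

    @stage("beta_assoc")
    def _beta(p):
        rows = []
        effect_rows = []
        for metric, D in dists.items():
            row = {"metric": f"{metric}_unifrac"}
            for cov in config.covariates:
                res = permanova_joint(D, meta, DesignSpec(cov, batch=config.batch),
                                      n_perm=config.n_perm, seed=config.seed)
                row[cov] = res.p_value
                if metric == "unweighted":
                    effect_rows.append({
                        "covariate": cov, "r2": res.r2, "r2_adj": res.r2_adj,
                        "r2_pct": float(Decimal(100 * res.r2).quantize(
                            Decimal("0.01"), rounding=ROUND_HALF_UP)),
                        "r2_adj_pct": float(Decimal(100 * max(res.r2_adj, 0.0)).quantize(
                            Decimal("0.01"), rounding=ROUND_HALF_UP)),
                        "pseudo_f": res.statistic, "df": res.df, "n": res.n,
                    })
            rows.append(row)
        _write(pd.DataFrame(rows), p,
               stamp + [f"PERMANOVA p-values ({config.n_perm} permutations, joint main+interaction)"])
        _write(pd.DataFrame(effect_rows), paths["effect_sizes"],
               stamp + ["distance-based R2 (unweighted UniFrac, sequential after batch);"
                        " *_pct columns rounded for display, adjusted floored at 0"])
        manifest["stages"]["effect_sizes"] = "computed"

    if paths["effect_sizes"].exists() and "effect_sizes" not in manifest["stages"]:
        manifest["stages"]["effect_sizes"] = "cached"

    # -- ordination ---------------------------------------------------------
    @stage("pcoa")
    def _pcoa(p):
        ord_ = pcoa(dists["unweighted"], k=config.pcoa_axes)
        df = pd.DataFrame(ord_.coordinates,
                          columns=[f"PC{i+1}" for i in range(ord_.coordinates.shape[1])])
        df.insert(0, "sample_id", list(ord_.sample_ids))
        header = stamp + ["PCoA of unweighted UniFrac distances",
                          "explained: " + ", ".join(
                              f"PC{i+1}={e:.4f}" for i, e in enumerate(ord_.explained))]
        _write(df, p, header)

    # -- taxa signatures ----------------------------------------------------
    @stage("signatures")
    def _sig(p):
        taxa_by_rank = {r: filter_taxa(aggregate(table, tax, r)) for r in config.ranks}
        df = signature_report(taxa_by_rank, meta,
                              covariates=config.signature_covariates,
                              q_threshold=config.q_threshold,
                              n_perm=config.n_perm, seed=config.seed,
                              batch=config.batch)
        _write(df, p, stamp + [f"taxa with q < {config.q_threshold} "
                               f"(BH-FDR within rank x covariate)"])

    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return paths
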