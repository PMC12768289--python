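"""End-to-end run configuration and consolidated report generation.

One :class:`RunConfig` drives every stage — limit screening, water indices,
sediment indices, deterministic health risk, Monte Carlo cancer risk, and
source statistics — and :func:`run_full_report` writes per-stage CSV/JSON
outputs plus a plain-text summary.  The summary only restates stage outputs;
it never recomputes a number.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import (
    core_data,
    health_risk,
    probabilistic_risk,
    sediment_indices,
    source_stats,
    synthetic_data,
    water_indices,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "validate_config", "run_full_report"]


@dataclass
class RunConfig:
    out_dir: Path
    water_table: Path | None = None  # None -> bundled survey table
    sediment_table: Path | None = None
    limit_set: str = "ecr"
    reference_overrides: dict = field(default_factory=dict)
    cohorts: tuple[str, ...] = ("adult", "child")
    pathways: tuple[str, ...] = health_risk.PATHWAYS
    mc_n: int = 10_000
    mc_seed: int = 42
    mc_threshold: float = 1e-6
    hca_k_water: int = 3
    hca_k_sediment: int = 5


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of issues (empty = ok); never raises."""
    issues = []
    for name in ("water_table", "sediment_table"):
        p = getattr(config, name)
        if p is not None and not Path(p).is_file():
            issues.append(f"{name}: file {p} does not exist")
    if config.limit_set.lower() not in core_data.LIMIT_SETS:
        issues.append(
            f"limit_set: unknown {config.limit_set!r}; "
            f"choose from {sorted(core_data.LIMIT_SETS)}"
        )
    known = core_data.builtin_references().elements
    for el, fields in config.reference_overrides.items():
        if el not in known:
            issues.append(f"reference_overrides.{el}: unknown element")
        for f, v in dict(fields).items():
            if not isinstance(v, (int, float)) or (v <= 0 and f != "ideal"):
                issues.append(f"reference_overrides.{el}.{f} must be > 0")
    for c in config.cohorts:
        if c not in ("adult", "child"):
            issues.append(f"cohorts: unknown cohort {c!r}")
    for p in config.pathways:
        if p not in health_risk.PATHWAYS:
            issues.append(f"pathways: unknown pathway {p!r}")
    if config.mc_n < 1:
        issues.append("mc_n must be >= 1")
    if config.mc_threshold <= 0:
        issues.append("mc_threshold must be > 0")
    return issues


def _load(path: Path | None, medium: str) -> core_data.ConcentrationTable:
    if path is None:
        return synthetic_data.bundled_table(medium)
    return core_data.read_concentration_table(path, medium)


def run_full_report(config: RunConfig) -> Path:
    """Run every stage and write outputs under ``config.out_dir``.

    Returns the path of the summary file.  Raises on the first failing stage
    (already-written outputs are retained).
    """
    issues = validate_config(config)
    if issues:
        raise core_data.ConfigurationError("invalid run config: " + "; ".join(issues))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    refs = core_data.builtin_references(config.reference_overrides or None)
    profiles = core_data.builtin_exposure_profiles()
    summary: list[str] = ["# metalrisk report", ""]

    stage = "water tables"
    try:
        water = _load(config.water_table, "water")
        sediment = _load(config.sediment_table, "sediment")

        stage = "limit screening"
        exceed = core_data.compare_to_limits(water, refs, "who")
        pairs = exceed.exceeding()
        summary.append(
            f"WHO limit exceedances in water: {exceed.n_exceedances} "
            + (f"({', '.join(f'{e} at {s}' for s, e in pairs)})" if pairs else "")
        )

        stage = "water indices"
        widx = water_indices.water_index_table(water, refs, config.limit_set)
        widx.to_csv(out / "water_indices.csv")
        summary.append(
            f"Water indices ({config.limit_set.upper()}): max HPI "
            f"{widx.hpi.max():.3g} ({widx.hpi.idxmax()}), max HEI "
            f"{widx.hei.max():.3g} ({widx.hei.idxmax()}); "
            f"{(widx.fitness == 'fit').sum()}/{len(widx)} sites fit for domestic use"
        )

        stage = "sediment indices"
        sed_results = sediment_indices.sediment_index_table(sediment, refs)
        long = sediment_indices.sediment_long_table(sed_results)
        long.to_csv(out / "sediment_indices.csv", index=False)
        per = {r.site: (r.per, r.per_class) for r in sed_results}
        worst = max(per, key=lambda s: per[s][0])
        summary.append(
            "Sediment PER classes: "
            + ", ".join(f"{s}={v:.1f} ({c})" for s, (v, c) in per.items())
        )
        summary.append(f"Highest PER: {worst} ({per[worst][0]:.1f}, {per[worst][1]})")

        stage = "health risk"
        risk = health_risk.risk_summary(
            water, refs, {c: profiles[c] for c in config.cohorts},
            pathways=config.pathways,
        )
        risk.to_csv(out / "health_risk.csv", index=False)
        summary.append(
            f"Health risk: max HQ {risk.max_hq.max():.3g}, "
            f"TCR bands: {risk.tcr_class.value_counts().to_dict()}"
        )

        stage = "monte carlo"
        mc_out = {}
        for cohort in config.cohorts:
            tcr = risk.loc[risk.cohort == cohort, "tcr"]
            fit = probabilistic_risk.fit_lognormal_moments(
                float(tcr.mean()), float(tcr.std(ddof=1))
            )
            sim = probabilistic_risk.simulate(
                fit, n=config.mc_n, seed=config.mc_seed,
                threshold=config.mc_threshold,
            )
            mc_out[cohort] = {
                "mean": fit.source_mean, "sd": fit.source_sd,
                "mu": fit.mu, "sigma": fit.sigma,
                "n_iter": sim.n_iter, "seed": sim.seed,
                "percentiles": sim.percentiles,
                "threshold": sim.threshold, "exceedance": sim.exceedance,
            }
        (out / "mc_risk.json").write_text(json.dumps(mc_out, indent=2))
        summary.append(
            "Monte Carlo TCR medians: "
            + ", ".join(f"{c}={v['percentiles'][50]:.3g}" for c, v in mc_out.items())
        )

        stage = "source statistics"
        for name, table, k in (
            ("water", water, config.hca_k_water),
            ("sediment", sediment, config.hca_k_sediment),
        ):
            corr = source_stats.pearson_matrix(table)
            corr.r.to_csv(out / f"correlation_{name}.csv")
            pca = source_stats.pca_correlation(table)
            pca.loadings.to_csv(out / f"pca_loadings_{name}.csv")
            pd.Series(
                pca.variance_fraction,
                index=pca.loadings.columns,
                name="variance_fraction",
            ).to_csv(out / f"pca_scree_{name}.csv")
            tree = source_stats.ward_cluster(table)
            pd.DataFrame(
                tree.merges, columns=["a", "b", "height", "size"]
            ).to_csv(out / f"hca_linkage_{name}.csv", index=False)
            (out / f"hca_{name}.nwk").write_text(source_stats.to_newick(tree))
            groups = source_stats.cut(tree, k)
            groups.to_csv(out / f"hca_clusters_{name}.csv")
            summary.append(
                f"{name.capitalize()} clusters (k={k}): "
                + ", ".join(
                    f"{{{','.join(groups.index[groups == g])}}}"
                    for g in sorted(groups.unique())
                )
            )
    except Exception:
        logger.exception("report stage failed: %s", stage)
        raise

    summary_path = out / "summary.md"
    summary_path.write_text("\n".join(summary) + "\n", encoding="utf-8")
    return summary_path
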