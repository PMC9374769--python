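"""End-to-end orchestration: from input tables to publication-shaped outputs.

``run_pipeline`` executes the full chain — pooling, diversity metrics, MEM
autocorrelation decomposition, landscape connectivity, co-occurrence,
per-metric PLS path models with bootstrap, and the attribution regressions
— and returns (optionally writes) flat CSV tables:

* ``autocorrelation.csv`` — S+, S-, permutation p per metric;
* ``path_coefficients.csv`` — metric x factor beta, SE, CI, significance;
* ``path_summary.csv`` — per-factor mean |beta| and CV;
* ``attribution_<component>.csv`` — best AICc subset per component;
* ``report.json`` — correlation of S+ with S-, the correlated-errors LR
  test, the confound screen, and provenance (seeds, options).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .attribution import (correlated_errors_lr_test, exhaustive_aicc_regression,
                          metric_correlation_pcoa, s_correlation)
from .connectivity import build_patch_graph, connectivity_metrics
from .cooccurrence import site_cooccurrence_scores
from .diversity import METRIC_NAMES, diversity_profile
from .io import (pool_quadrats, read_community_table, read_patch_map,
                 read_site_table)
from .plssem import bootstrap_paths, default_measurement_spec, path_summary_stats
from .spatial import MoranEigenvectorMaps
from .synthetic import SyntheticConfig, generate_dataset

logger = logging.getLogger(__name__)

__all__ = ["load_config", "run_pipeline"]

DEFAULTS = {
    "spatial": {"exponent": 1.0, "mode": "raw", "n_perm": 9999, "seed": 0},
    "graph": {"radius_m": 20_000.0, "betweenness": "fractional"},
    "plssem": {"scheme": "centroid", "n_boot": 10_000, "seed": 0,
               "screening": False},
    "attribution": {"transform": "sqrt2"},
}


def load_config(path) -> dict:
    """Read a YAML pipeline config and fill stage defaults."""
    cfg = yaml.safe_load(Path(path).read_text()) or {}
    return _with_defaults(cfg)


def _with_defaults(cfg: dict) -> dict:
    out = {k: dict(v) for k, v in DEFAULTS.items()}
    for stage, opts in cfg.items():
        if stage in out and isinstance(opts, dict):
            out[stage].update(opts)
        else:
            out[stage] = opts
    return out


def _load_inputs(cfg: dict):
    if "simulate" in cfg:
        sim = dict(cfg["simulate"] or {})
        data = generate_dataset(SyntheticConfig(**sim))
        return data.records, data.sites, data.patches
    inputs = cfg["inputs"]
    records = read_community_table(inputs["community"])
    pooled = pool_quadrats(records)
    sites = read_site_table(inputs["sites"], community=pooled,
                            coordinate_mode=inputs.get("coordinate_mode",
                                                       "projected"))
    patches = read_patch_map(inputs["patches"], sites=sites)
    return records, sites, patches


def run_pipeline(cfg: dict, outdir=None) -> dict:
    """Run every stage; returns a dict of result tables and the report."""
    cfg = _with_defaults(cfg)
    records, sites, patches = _load_inputs(cfg)
    pooled = pool_quadrats(records)
    site_order = pooled.site_ids
    site_rows = sites.table.set_index("site_id").loc[site_order]

    profile = diversity_profile(pooled)

    sp = cfg["spatial"]
    mem = MoranEigenvectorMaps(exponent=sp["exponent"], mode=sp["mode"],
                               n_perm=sp["n_perm"]).fit(
        site_rows[["x", "y"]].to_numpy())
    sac_rows = {}
    for j, metric in enumerate(METRIC_NAMES):
        x = profile[metric].to_numpy()
        ok = np.isfinite(x)
        if not ok.all():
            logger.warning("metric %s undefined at %d sites: subset analysis",
                           metric, (~ok).sum())
            sub = MoranEigenvectorMaps(
                exponent=sp["exponent"], mode=sp["mode"], n_perm=sp["n_perm"]
            ).fit(site_rows.loc[ok, ["x", "y"]].to_numpy())
            s_plus, s_minus = sub.transform(x[ok][:, None])[0]
            p_plus, p_minus = sub.permutation_test(
                x[ok], seed=(sp["seed"], j))
        else:
            s_plus, s_minus = mem.transform(x[:, None])[0]
            p_plus, p_minus = mem.permutation_test(x, seed=(sp["seed"], j))
        sac_rows[metric] = {"s_plus": s_plus, "s_minus": s_minus,
                            "p_plus": p_plus, "p_minus": p_minus}
    sac = pd.DataFrame(sac_rows).T.rename_axis("metric")

    gr = cfg["graph"]
    graph = build_patch_graph(patches, radius=gr["radius_m"])
    sampled_patch_ids = patches.table.loc[
        patches.table["is_sampled"].astype(bool)].set_index("site_id")["patch_id"]
    conn = connectivity_metrics(graph, sampled_patch_ids.loc[site_order].tolist(),
                                betweenness=gr["betweenness"])
    conn.index = site_order

    cooc = site_cooccurrence_scores(records).loc[site_order]

    indicators = pd.concat(
        [conn, cooc[["cooccurrence"]],
         site_rows[[c for c in site_rows.columns if c not in ("x", "y")]],
         profile],
        axis=1,
    )

    pl = cfg["plssem"]
    env_indicators = None
    if pl.get("screening"):
        from .plssem import pls1_screening
        candidates = indicators[
            [c for c in ("altitude", "slope", "MAWS", "SnowNDays", "NDVI",
                         "dNDVI") if c in indicators.columns]]
        keep: set = set()
        for metric in METRIC_NAMES:
            y = indicators[metric]
            ok = y.notna() & candidates.notna().all(axis=1)
            keep |= set(pls1_screening(candidates[ok], y[ok]))
        if keep:
            env_indicators = tuple(c for c in candidates.columns if c in keep)
            logger.info("screened environment indicators: %s", env_indicators)
        else:
            logger.warning("screening kept no variables; using all")
    path_rows, boot_tables = {}, {}
    for j, metric in enumerate(METRIC_NAMES):
        spec = default_measurement_spec(metric)
        if env_indicators is not None:
            spec.exogenous = [
                b if b.name != "environment" else
                type(b)("environment", env_indicators, "B")
                for b in spec.exogenous
            ]
        cols = spec.all_indicators()
        sub = indicators[cols].dropna()
        if len(sub) < len(indicators):
            logger.warning("PLS-SEM for %s uses %d complete sites",
                           metric, len(sub))
        boot = bootstrap_paths(sub, spec=spec, n_boot=pl["n_boot"],
                               seed=(pl["seed"], j), scheme=pl["scheme"])
        boot_tables[metric] = boot.table
        path_rows[metric] = boot.table["beta"]
    path_matrix = pd.DataFrame(path_rows).T.rename_axis("metric")
    summary = path_summary_stats(path_matrix)
    table2 = pd.concat(
        {m: t for m, t in boot_tables.items()}, names=["metric", "factor"])

    at = cfg["attribution"]
    pcoa = metric_correlation_pcoa(profile, transform=at["transform"])
    screen = {}
    for comp in ("s_plus", "s_minus"):
        fit = exhaustive_aicc_regression(sac[comp], pcoa.coordinates)
        screen[comp] = {
            "predictors": list(fit.best_.predictors),
            "adj_r2": fit.best_.adj_r2, "model_p": fit.best_.model_p,
            "aicc": fit.best_.aicc,
        }
    attrib = {}
    for comp in ("s_plus", "s_minus"):
        fit = exhaustive_aicc_regression(sac[comp], path_matrix)
        attrib[comp] = fit
    r = s_correlation(sac["s_plus"], sac["s_minus"])
    slope, lr, p_lr = correlated_errors_lr_test(
        sac["s_plus"].to_numpy(), sac["s_minus"].to_numpy(),
        pcoa.correlation.to_numpy())

    report = {
        "spatsig_version": __version__,
        "options": {k: cfg[k] for k in DEFAULTS},
        "n_sites": len(site_order),
        "s_plus_s_minus_pearson_r": r,
        "correlated_errors": {"slope": slope, "LR": lr, "df": 1, "p": p_lr},
        "confound_screen": screen,
        "attribution": {
            comp: {
                "predictors": list(fit.best_.predictors),
                "adj_r2": fit.best_.adj_r2,
                "F": fit.best_.fvalue,
                "df": [fit.best_.df_num, fit.best_.df_den],
                "model_p": fit.best_.model_p,
                "shapiro_p": fit.best_.shapiro_p,
                "coefficients": fit.best_.coefficients.to_dict("index"),
            } for comp, fit in attrib.items()
        },
    }

    results = {
        "profile": profile,
        "autocorrelation": sac,
        "eigenvalues": pd.DataFrame({"eigenvalue": mem.eigenvalues_}),
        "connectivity": conn,
        "cooccurrence": cooc,
        "path_coefficients": table2,
        "path_matrix": path_matrix,
        "path_summary": summary,
        "report": report,
    }
    if outdir is not None:
        _write(results, attrib, Path(outdir))
    return results


def _write(results: dict, attrib: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for name in ("profile", "autocorrelation", "eigenvalues", "connectivity",
                 "cooccurrence", "path_coefficients", "path_matrix",
                 "path_summary"):
        results[name].to_csv(outdir / f"{name}.csv")
    for comp, fit in attrib.items():
        fit.best_.coefficients.assign(
            adj_r2=fit.best_.adj_r2, F=fit.best_.fvalue,
            model_p=fit.best_.model_p, aicc=fit.best_.aicc,
            shapiro_p=fit.best_.shapiro_p,
        ).to_csv(outdir / f"attribution_{comp}.csv")
    (outdir / "report.json").write_text(
        json.dumps(results["report"], indent=2, default=float))
    logger.info("wrote pipeline outputs to %s", outdir)
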