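"""End-to-end pipeline: simulate -> votes -> rates -> impute -> compare -> fit
-> counterfactual, with per-stage seeds derived from one global seed so any
stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._util import round_half_up, spawn_seed
from .compare import compare_groups
from .config import CensoringRule, GeneratorConfig, ImputationModelSpec
from .counterfactual import required_reduction, state_slope
from .imputation import fit_imputation_model, rubin_combine
from .model import sensitivity_suite
from .rates import age_adjust, rate_deltas
from .standards import us2000_standard_million
from .synthetic import generate_panel, write_outputs
from .votes import classify_counties, net_republican_gain

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "run_out"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    censoring: CensoringRule = field(default_factory=CensoringRule)
    imputation: ImputationModelSpec = field(default_factory=ImputationModelSpec)
    pca_variance_fraction: float = 0.9
    n_counterfactual_states: int = 3
    compare_variables: tuple = ("age_2015", "income_2015", "bachelor_2015")


def _despair_deltas_per_dataset(imp, panel):
    """Per-imputation despair rate changes (crude rates; single stratum)."""
    std = us2000_standard_million()
    out = []
    for completed in imp.datasets():
        adj = age_adjust(completed.assign(age_group="all"), std)
        out.append(rate_deltas(adj))
    return out


def run_all(config: RunConfig) -> dict:
    """Run the full pipeline; returns a report dict (also written to disk)."""
    cfg = config
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "version": __version__}

    # --- simulate ------------------------------------------------------------
    gen_cfg = dataclasses.replace(cfg.generator, seed=spawn_seed(cfg.seed, "simulate"))
    data = generate_panel(gen_cfg)
    write_outputs(data, out / "synthetic")
    panel = data.panel
    report["n_counties"] = len(panel)
    report["n_states"] = panel["state_id"].nunique()

    # --- votes ---------------------------------------------------------------
    gains = net_republican_gain(panel)
    labels, counts = classify_counties(panel)
    gains = gains.merge(labels, on="county_id")
    gains.to_csv(out / "net_gain.csv", index=False)
    report["gain_classes"] = {k: int(v) for k, v in counts.items()}
    report["median_net_gain"] = float(gains["net_gain"].median())

    # --- rates ---------------------------------------------------------------
    std = us2000_standard_million()
    allcause = data.deaths[data.deaths["cause_group"] == "all_cause"]
    adj = age_adjust(allcause, std)
    deltas = rate_deltas(adj)
    deltas.to_csv(out / "rates.csv", index=False)

    # --- impute the despair stream ------------------------------------------
    despair = data.deaths[data.deaths["cause_group"] == "despair"]
    n_suppressed = int(despair["suppressed"].sum())
    report["n_suppressed_despair_cells"] = n_suppressed
    imp_spec = dataclasses.replace(cfg.imputation, seed=spawn_seed(cfg.seed, "impute"))
    if n_suppressed:
        imp = fit_imputation_model(despair, cfg.censoring, imp_spec)
        report["imputation_diagnostics"] = {
            k: v for k, v in imp.diagnostics.items() if k != "rhat"}
        report["imputation_max_rhat"] = imp.diagnostics["max_rhat"]
        with open(out / "imputation_diagnostics.json", "w") as fh:
            json.dump(imp.diagnostics, fh, indent=2, default=float)
        despair_deltas = _despair_deltas_per_dataset(imp, panel)
        for m, completed in enumerate(imp.datasets()):
            completed.to_csv(out / f"despair_completed_{m}.csv", index=False)
    else:
        imp = None
        report["imputation"] = "no imputation needed"
        despair_deltas = [rate_deltas(age_adjust(despair, std))]

    # --- clustered comparisons (swing-class contrast) ------------------------
    merged = panel.merge(labels, on="county_id").merge(
        deltas[["county_id", "rate_2000", "rate_2015", "delta"]], on="county_id")
    two = merged[merged["label"].isin(["republican_gain", "democratic_gain"])]
    comparisons = {}
    for var in (*cfg.compare_variables, "rate_2015", "delta"):
        res = compare_groups(two[var], two["label"], two["state_id"], variable=var)
        comparisons[var] = {
            "means": res.means, "difference": res.difference,
            "se": res.se, "p": res.pvalue,
        }
    # despair delta: estimate per completed dataset, pooled by Rubin's rules
    est, wvar = [], []
    for dd in despair_deltas:
        sub = two.merge(dd[dd["cause_group"] == "despair"][["county_id", "delta"]]
                        .rename(columns={"delta": "d_despair"}), on="county_id")
        r = compare_groups(sub["d_despair"], sub["label"], sub["state_id"],
                           variable="d_despair")
        est.append(r.difference)
        wvar.append(r.se**2)
    if len(est) >= 2:
        pooled = rubin_combine(est, wvar)
        comparisons["d_despair"] = {"difference": pooled.estimate, "se": pooled.se,
                                    "df": pooled.df, "m": pooled.m,
                                    "model": "rubin-combined"}
    else:
        comparisons["d_despair"] = {"difference": est[0], "se": float(np.sqrt(wvar[0])),
                                    "model": "single-dataset"}
    pd.DataFrame(comparisons).T.to_csv(out / "comparisons.csv")
    report["comparisons"] = comparisons

    # --- multivariable fits ---------------------------------------------------
    fits = sensitivity_suite(panel, deltas, cfg.pca_variance_fraction)
    with open(out / "fit.json", "w") as fh:
        json.dump({k: f.to_dict() for k, f in fits.items()}, fh, indent=2, default=float)
    primary = fits["primary"]
    report["fit"] = {
        k: {"death_rate_coef": float(f.coef.get(f.slope_name, np.nan)),
            "r2_fixed": f.r2_fixed, "r2_total": f.r2_total}
        for k, f in fits.items()
    }

    # --- electoral counterfactual --------------------------------------------
    sv = panel.groupby("state_id")[["votes_rep_2016", "votes_dem_2016",
                                    "votes_total_2016"]].sum()
    margin = 100.0 * (sv["votes_rep_2016"] - sv["votes_dem_2016"]) / sv["votes_total_2016"]
    rep_won = margin[margin > 0].sort_values()
    rows = []
    for st in rep_won.index:
        try:
            slope = state_slope(primary, st)
        except (ValueError, KeyError):
            continue
        cf = required_reduction(slope, float(rep_won[st]), state_id=st)
        rows.append({"state_id": st, "victory_margin": cf.victory_margin,
                     "slope_per_1pct": cf.slope_per_1pct,
                     "required_reduction": cf.required_reduction,
                     "required_reduction_rounded": cf.required_reduction_rounded,
                     "interpretation": "association-based, not causal"})
        if len(rows) >= cfg.n_counterfactual_states:
            break
    cf_df = pd.DataFrame(rows)
    cf_df.to_csv(out / "counterfactual.csv", index=False)
    report["counterfactual"] = rows

    report["median_net_gain_rounded"] = round_half_up(report["median_net_gain"], 0)
    with open(out / "run_log.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report
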