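"""End-to-end orchestration: simulate -> screen -> dimensionality ->
calibrate -> DIF -> CAT, each stage reading the previous stage's serialized
outputs and writing its own, plus external-validity reporting.

A run writes a manifest (seed, stage toggles, thresholds actually applied,
per-stage summaries) so any run can be audited and reproduced.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from ._codes import write_responses_csv
from .bank import ItemBank
from .cat import CATConfig, impute_missing, simulate_cat
from .dif import run_dif_suite
from .dimensionality import efa, parallel_analysis, polychoric_matrix, residual_correlations
from .gpcm import (compare_models, eap_scores, fit_gpcm, information_share,
                   low_discrimination_items, transform_score)
from .screening import (ScreeningThresholds, apply_screening, cronbach_alpha,
                        describe_items, inter_item_correlations)
from .synthetic import SimulationConfig, generate_bank, simulate_responses, study_like_config

log = logging.getLogger("catbank")

__all__ = ["PipelineConfig", "run_pipeline", "validity_report"]


@dataclass
class PipelineConfig:
    seed: int = 0
    n_persons: int = 458
    simulation: SimulationConfig | None = None     # default: study_like_config
    run_screening: bool = True
    run_dimensionality: bool = True
    run_dif: bool = True
    run_cat: bool = True
    screening_thresholds: ScreeningThresholds = field(default_factory=ScreeningThresholds)
    local_dependence_threshold: float = 0.20
    dif_alpha: float = 0.01
    dif_purify: bool = False
    cat_scenarios: tuple[float, ...] = (0.33, 0.44, 0.55)
    em_max_cycles: int = 500
    em_tol: float = 1e-4

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "screening_thresholds" in d:
            d["screening_thresholds"] = ScreeningThresholds(**d["screening_thresholds"])
        if "simulation" in d and d["simulation"] is not None:
            d["simulation"] = SimulationConfig(**d["simulation"])
        if "cat_scenarios" in d:
            d["cat_scenarios"] = tuple(d["cat_scenarios"])
        return cls(**d)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the enabled stages in order; returns the manifest dict.

    Artifacts: responses/groups CSV, descriptives TSV, screening JSON,
    factor-solution JSON, residual-flag TSV, calibrated bank JSON,
    calibration report TSV, score CSV, DIF TSV, CAT scenario TSV and the
    manifest JSON.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    sim = config.simulation or study_like_config(seed=config.seed,
                                                 n_persons=config.n_persons)
    log.info("simulate: %d persons x %d items", sim.n_persons, sim.n_items)
    params, true_bank = generate_bank(sim)
    responses, groups = simulate_responses(params, sim)
    K = sim.n_categories
    reverse = sorted(sim.reverse_coded)
    write_responses_csv(responses, outdir / "responses.csv")
    groups.to_csv(outdir / "groups.csv", index=False)
    true_bank.to_json(outdir / "true_bank.json")
    sim.to_yaml(outdir / "simulation.yaml")
    manifest["stages"]["simulate"] = {"n_persons": sim.n_persons, "n_items": sim.n_items,
                                      "n_categories": K, "seed": sim.seed}

    analysis = responses
    retained = list(responses.columns)
    if config.run_screening:
        desc = describe_items(responses, K, reverse_items=reverse)
        corr = inter_item_correlations(responses, reverse_items=reverse, n_categories=K)
        report = apply_screening(desc, corr, config.screening_thresholds)
        from .screening import reverse_code
        rev = reverse_code(responses, reverse, K)
        report.cronbach_alpha = cronbach_alpha(rev[report.retained])
        retained = report.retained
        desc.to_csv(outdir / "descriptives.tsv", sep="\t")
        (outdir / "screening.json").write_text(json.dumps({
            "retained": report.retained,
            "excluded": report.excluded,
            "flagged_pairs": report.flagged_pairs,
            "cronbach_alpha": report.cronbach_alpha,
            "thresholds": asdict(report.thresholds),
        }, default=_jsonable, indent=1))
        manifest["stages"]["screening"] = {
            "n_retained": len(retained), "excluded": report.excluded,
            "cronbach_alpha": report.cronbach_alpha,
            "thresholds": asdict(report.thresholds)}
        log.info("screening: retained %d of %d items", len(retained), sim.n_items)

    from .screening import reverse_code
    analysis = reverse_code(responses, reverse, K)[retained]

    if config.run_dimensionality:
        poly = polychoric_matrix(analysis)
        n_obs = len(analysis)
        sol = efa(poly, 1, n_obs=n_obs)
        n_factors = parallel_analysis(analysis, seed=config.seed)
        flagged, suggestion = residual_correlations(
            poly, sol, threshold=config.local_dependence_threshold)
        (outdir / "factor_solution.json").write_text(json.dumps({
            "n_factors_parallel": n_factors,
            "eigenvalues": sol.eigenvalues,
            "eigenvalue_ratio": sol.eigenvalue_ratio,
            "explained_variance_first": sol.explained_variance_first,
            "loadings": sol.loadings,
            "fit": asdict(sol.fit) if sol.fit else None,
        }, default=_jsonable, indent=1))
        pd.DataFrame(flagged, columns=["item_a", "item_b", "residual_r"]) \
            .to_csv(outdir / "residual_flags.tsv", sep="\t", index=False)
        manifest["stages"]["dimensionality"] = {
            "n_factors_parallel": n_factors,
            "rmsea": sol.fit.rmsea if sol.fit else None,
            "cfi": sol.fit.cfi if sol.fit else None,
            "tli": sol.fit.tli if sol.fit else None,
            "local_dependence_threshold": config.local_dependence_threshold,
            "n_flagged_pairs": len(flagged),
            "deletion_suggestion": suggestion}
        log.info("dimensionality: parallel analysis keeps %d factor(s)", n_factors)

    pcm = fit_gpcm(analysis, n_categories=K, equal_slopes=True,
                   max_cycles=config.em_max_cycles, tol=config.em_tol,
                   compute_infit=False)
    gpcm = fit_gpcm(analysis, n_categories=K,
                    max_cycles=config.em_max_cycles, tol=config.em_tol)
    comparison = compare_models(pcm, gpcm)
    chosen = gpcm if comparison.p_value < 0.05 else pcm
    bank = chosen.bank
    bank.to_json(outdir / "bank.json")
    pd.DataFrame({
        "item_id": bank.ids,
        "discrimination": bank.discriminations,
        **{f"b{k+1}": [it.thresholds[k] if k < it.n_categories - 1 else np.nan
                       for it in bank] for k in range(K - 1)},
        "infit_mnsq": [chosen.infit.get(i, np.nan) for i in bank.ids],
    }).to_csv(outdir / "calibration.tsv", sep="\t", index=False)
    manifest["stages"]["calibrate"] = {
        "model": chosen.model,
        "lrt_chi2": comparison.chi2, "lrt_df": comparison.df,
        "lrt_p": comparison.p_value,
        "aic_pcm": pcm.aic, "aic_gpcm": gpcm.aic,
        "bic_pcm": pcm.bic, "bic_gpcm": gpcm.bic,
        "low_discrimination": low_discrimination_items(bank),
        "information_share_-2_1": information_share(bank, -2.0, 1.0)}
    log.info("calibrate: %s chosen (LRT chi2=%.2f, p=%.2g)", chosen.model,
             comparison.chi2, comparison.p_value)

    theta, sem = eap_scores(analysis, bank)
    scores = pd.DataFrame({"person": analysis.index, "theta": theta, "sem": sem,
                           "score_0_100": transform_score(theta)})
    scores.to_csv(outdir / "scores.csv", index=False)

    if config.run_dif:
        dif = run_dif_suite(analysis, bank, groups, purify=config.dif_purify,
                            alpha=config.dif_alpha)
        dif.to_csv(outdir / "dif.tsv", sep="\t", index=False)
        manifest["stages"]["dif"] = {
            "n_tests": len(dif), "alpha": config.dif_alpha,
            "purify": config.dif_purify,
            "n_flagged": int(dif["flagged"].sum()),
            "classes": dif["zumbo_class"].value_counts().to_dict()}
        log.info("dif: %d tests, %d flagged", len(dif), int(dif["flagged"].sum()))

    if config.run_cat:
        completed, flags = impute_missing(analysis, bank)
        evaluation = simulate_cat(completed, bank, scenarios=config.cat_scenarios,
                                  config=CATConfig(stop_sem=config.cat_scenarios[0]))
        evaluation.table.to_csv(outdir / "cat_scenarios.tsv", sep="\t", index=False)
        manifest["stages"]["cat"] = {
            "scenarios": list(config.cat_scenarios),
            "n_prior_filled_persons": len(flags),
            "table": evaluation.table.to_dict(orient="records")}
        log.info("cat: %s", evaluation.table.to_string(index=False))

    (outdir / "manifest.json").write_text(json.dumps(manifest, default=_jsonable, indent=1))
    return manifest


def validity_report(scores, external: pd.DataFrame) -> pd.DataFrame:
    """Associations between scores and external person-level variables.

    Numeric columns: Pearson r (pairwise complete).  Two-level columns:
    Welch t-test with group means +/- SD.  Columns with >= 3 levels: one-way
    ANOVA.  Columns with fewer than 3 complete pairs are flagged undefined.
    """
    s = np.asarray(scores, dtype=float)
    rows = []
    for col in external.columns:
        v = external[col]
        rec: dict = {"variable": str(col)}
        if pd.api.types.is_numeric_dtype(v):
            ok = np.isfinite(s) & v.notna().to_numpy()
            if ok.sum() < 3:
                rec.update(kind="undefined", r=np.nan, p_value=np.nan)
            else:
                r, p = stats.pearsonr(s[ok], v.to_numpy(dtype=float)[ok])
                rec.update(kind="pearson", r=float(r), p_value=float(p), n=int(ok.sum()))
        else:
            ok = np.isfinite(s) & v.notna().to_numpy()
            levels = pd.unique(v[ok])
            samples = [s[ok & (v == lv).to_numpy()] for lv in levels]
            if len(levels) < 2 or any(len(x) < 2 for x in samples):
                rec.update(kind="undefined", p_value=np.nan)
            elif len(levels) == 2:
                t, p = stats.ttest_ind(samples[0], samples[1], equal_var=False)
                rec.update(kind="t-test", p_value=float(p),
                           group_means={str(lv): f"{x.mean():.2f} ± {x.std(ddof=1):.2f}"
                                        for lv, x in zip(levels, samples)})
            else:
                f, p = stats.f_oneway(*samples)
                rec.update(kind="anova", p_value=float(p),
                           group_means={str(lv): f"{x.mean():.2f} ± {x.std(ddof=1):.2f}"
                                        for lv, x in zip(levels, samples)})
        rows.append(rec)
    return pd.DataFrame(rows)
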