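"""End-to-end analysis pipeline: from input files to a structured report.

Stages (each toggleable): demography summaries → growth-curve residuals →
ancestor-score GLMs (selection response) → animal models (heritability and
genetic correlation).  Every report embeds the configuration, seed and
package version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .animal_model import (
    fit_bivariate_animal_model,
    fit_gaussian_animal_model,
    fit_threshold_animal_model,
    genetic_correlation,
    h2_latent,
    h2_observed_scale,
)
from .demography import (
    fit_multinomial_trend,
    laterality_from_records,
    load_records,
    records_to_frame,
    summarize_scores,
)
from .growth import fit_growth_curve, residual_mass_frame
from .pedigree import Pedigree, mean_ancestor_scores, read_pedigree
from .simulate import SimulationConfig, simulate_programme, write_dataset
from .truncpois import fit_mass_vs_generations, fit_trunc_poisson, percent_reduction

log = logging.getLogger("felhip")


@dataclass
class PipelineConfig:
    pedigree: str | Path = ""
    phenotypes: str | Path = ""
    out_dir: str | Path = "felhip_out"
    seed: int = 0
    # stage toggles
    run_demography: bool = True
    run_growth: bool = True
    run_glm: bool = True
    run_animal_models: bool = True
    run_bivariate: bool = True
    # MCMC settings (scaled for desk-size datasets)
    n_chains: int = 2
    n_iter: int = 2000
    burn_in: int = 600
    thin: int = 2
    rhat_max: float = 1.1

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for p in (self.pedigree, self.phenotypes):
            if p and not Path(p).exists():
                raise FileNotFoundError(p)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pedigree"] = str(d["pedigree"])
        d["phenotypes"] = str(d["phenotypes"])
        d["out_dir"] = str(d["out_dir"])
        return d


def _config_hash(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, pd.DataFrame):
        return json.loads(x.to_json(orient="split"))
    if isinstance(x, pd.Series):
        return x.to_dict()
    return x


def cmd_simulate(out_dir, *, seed: int = 0, config: SimulationConfig | None
                 = None, **overrides) -> dict:
    """Generate a synthetic programme dataset into ``out_dir``."""
    cfg = config or SimulationConfig(seed=seed, **overrides)
    sim = simulate_programme(cfg)
    paths = write_dataset(sim, out_dir)
    meta = {
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "config_hash": _config_hash(dataclasses.asdict(cfg)),
        "version": __version__,
        "n_individuals": len(sim.pedigree),
        "n_records": len(sim.records),
    }
    meta_path = Path(out_dir) / "simulation.json"
    meta_path.write_text(json.dumps(_jsonable(meta), indent=2))
    log.info("simulated %d cats (%d records) -> %s (config %s)",
             len(sim.pedigree), len(sim.records), out_dir,
             meta["config_hash"])
    paths["meta"] = meta_path
    return {"paths": {k: str(v) for k, v in paths.items()}, **meta}


def cmd_analyze(config: PipelineConfig) -> dict:
    """Run the staged analysis; returns (and writes) the report dict.

    Stage failures are recorded in the report under ``failures`` and the
    remaining stages still run; callers can treat a non-empty failure list
    as a non-zero exit condition.
    """
    config.validate()
    out = Path(config.out_dir)
    (out / "tables").mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": _config_hash(
            {k: v for k, v in config.to_dict().items() if k != "out_dir"}),
        "failures": [],
    }
    ped = read_pedigree(config.pedigree, add_missing_founders=True)
    records = load_records(config.phenotypes)
    df = records_to_frame(records)
    log.info("loaded %d pedigree members, %d phenotype records",
             len(ped), len(df))

    if config.run_demography:
        try:
            s = summarize_scores(records)
            lat = laterality_from_records(records)
            trend = fit_multinomial_trend(records)
            years = sorted(df["year"].unique())
            grid = {sex: trend.predict_proportions(years, sex)
                    for sex in ("female", "male")}
            for sex, g in grid.items():
                g.to_csv(out / "tables" / f"trend_{sex}.csv")
            report["demography"] = {
                "n": s.n,
                "prevalence_percent": s.prevalence_percent,
                "max_share_percent": s.max_share_percent,
                "unilateral_percent": 100 * lat["unilateral_frac"],
                "bilateral_percent": 100 * lat["bilateral_frac"],
            }
            s.table.counts.to_csv(out / "tables" / "score_table.csv")
        except Exception as e:  # noqa: BLE001 - partial reports by design
            report["failures"].append({"stage": "demography", "error": str(e)})

    growth_df = df
    if config.run_growth and df["mass_kg"].notna().sum() >= 20:
        try:
            model = fit_growth_curve(df)
            growth_df = residual_mass_frame(model, df)
            report["growth"] = {
                "curves": model.to_dict(),
                "n_massed": int(df["mass_kg"].notna().sum()),
            }
            (out / "growth_params.json").write_text(
                json.dumps(_jsonable(model.to_dict()), indent=2))
        except Exception as e:  # noqa: BLE001
            report["failures"].append({"stage": "growth", "error": str(e)})

    # screening dates for ancestor scores: decimal assessment year
    screened = {r.id: r.year + r.age_days / 365.25 / 1000 for r in records}
    anc = mean_ancestor_scores(ped, screened)
    growth_df = growth_df.merge(
        anc.rename("mean_ancestor_score"), left_on="id", right_index=True,
        how="left")
    growth_df.to_csv(out / "tables" / "phenotypes_augmented.csv", index=False)

    if config.run_glm:
        try:
            glm_df = growth_df.dropna(subset=["mean_ancestor_score"])
            score_model = fit_trunc_poisson(
                glm_df, response="max_score",
                covariates=["mean_ancestor_score", "age_days", "sex"],
                seed=config.seed)
            red = percent_reduction(score_model, "mean_ancestor_score",
                                    1.0, 8.0)
            report["selection_response"] = {
                "coefficients": score_model.coef.to_dict(),
                "reduction_gen1_to_gen8_percent": red,
            }
            if "residual_mass" in glm_df and \
                    glm_df["residual_mass"].notna().sum() > 50:
                mass_fit = fit_mass_vs_generations(
                    glm_df.dropna(subset=["residual_mass"]),
                    extra=("age_days", "sex"))
                mass_fit.pop("fit")
                report["mass_response"] = mass_fit
        except Exception as e:  # noqa: BLE001
            report["failures"].append({"stage": "glm", "error": str(e)})

    if config.run_animal_models:
        try:
            long = pd.concat([
                df[["id", "sex", "age_days"]].assign(score=df["left"]),
                df[["id", "sex", "age_days"]].assign(score=df["right"]),
            ], ignore_index=True)
            fit = fit_threshold_animal_model(
                long, ped, n_iter=config.n_iter, burn_in=config.burn_in,
                thin=config.thin, n_chains=config.n_chains,
                seed=config.seed, check=False)
            draws = fit.draws
            h2l = h2_latent(draws)
            h2o = h2_observed_scale(
                draws["v_a"].to_numpy(), draws["v_pe"].to_numpy(),
                np.column_stack([np.zeros(len(draws)), draws["cut2"],
                                 draws["cut3"]]),
                draws["mu"].to_numpy())
            diag = fit.diagnostics(["v_a", "v_pe"]) \
                if config.n_chains >= 2 else None
            converged = diag is None or bool(
                (diag["rhat"].fillna(1.0) < config.rhat_max).all())
            block = {
                "h2_latent": _ci_block(h2l),
                "h2_data_scale": _ci_block(h2o),
                "converged": converged,
            }
            if diag is not None:
                block["diagnostics"] = diag.to_dict()
            if not converged:
                block["note"] = "chains not converged; summaries withheld"
                block.pop("h2_latent"), block.pop("h2_data_scale")
            report["hip_score_animal_model"] = block
            fit.draws.to_csv(out / "tables" / "posterior_hip.csv",
                             index=False)
        except Exception as e:  # noqa: BLE001
            report["failures"].append(
                {"stage": "animal_model_hip", "error": str(e)})

        massed = growth_df.dropna(subset=["residual_mass"]) \
            if "residual_mass" in growth_df else pd.DataFrame()
        if len(massed) >= 200:
            try:
                gfit = fit_gaussian_animal_model(
                    massed, ped, n_iter=config.n_iter,
                    burn_in=config.burn_in, thin=config.thin,
                    n_chains=config.n_chains, seed=config.seed, check=False)
                gd = gfit.draws
                h2m = gd["v_a"] / (gd["v_a"] + gd["v_r"])
                report["mass_animal_model"] = {
                    "h2": _ci_block(h2m.to_numpy())}
            except Exception as e:  # noqa: BLE001
                report["failures"].append(
                    {"stage": "animal_model_mass", "error": str(e)})
        if config.run_bivariate and len(massed) >= 200:
            try:
                long = pd.concat([
                    df[["id", "sex"]].assign(score=df["left"]),
                    df[["id", "sex"]].assign(score=df["right"]),
                ], ignore_index=True)
                bfit = fit_bivariate_animal_model(
                    long, massed, ped, include_pe=(True, False),
                    n_iter=config.n_iter, burn_in=config.burn_in,
                    thin=config.thin, n_chains=config.n_chains,
                    seed=config.seed, check=False)
                rg = genetic_correlation(bfit.draws)
                rg.pop("draws")
                report["genetic_correlation_hip_mass"] = rg
                bfit.draws.to_csv(
                    out / "tables" / "posterior_bivariate.csv", index=False)
            except Exception as e:  # noqa: BLE001
                report["failures"].append(
                    {"stage": "animal_model_bivariate", "error": str(e)})

    (out / "report.json").write_text(
        json.dumps(_jsonable(report), indent=2))
    log.info("report written to %s (%d stage failures)",
             out / "report.json", len(report["failures"]))
    return report


def _ci_block(x: np.ndarray) -> dict:
    lo, hi = np.quantile(x, [0.025, 0.975])
    return {"mean": float(np.mean(x)), "ci_2.5%": float(lo),
            "ci_97.5%": float(hi)}
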