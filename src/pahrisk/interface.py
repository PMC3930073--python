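"""Pipeline orchestration: configuration, I/O, logging and reporting.

Ties the stages into one reproducible run in the assessment's natural order:
concentrations -> BaP equivalents -> deterministic risk grid and threshold
inversion -> Monte Carlo -> sensitivity.  Outputs are plain CSV plus a JSON
run manifest (seed, package version, config hash, input checksums) so a run
can be audited and reproduced byte-for-byte.  Exit/validation status never
depends on the magnitude of the computed risk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from decimal import ROUND_HALF_UP, Decimal
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .bap_equivalence import (
    PEFTable, bap_equivalents, distance_regression, load_pef_table,
    read_pef_csv, read_profiles_csv, summarize,
)
from .deterministic_risk import (
    IngestionScenario, InhalationScenario,
    ingestion_risk, inhalation_risk, literature_comparison,
    threshold_concentration_ngg,
)
from .probabilistic_risk import (
    DistributionSpec, ScenarioDistributions, monte_carlo_risk,
    spearman_sensitivity, summarize_distribution,
)
from .synthetic_data import load_fixture

log = logging.getLogger("pahrisk")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a pipeline run needs, with the study's conventions as defaults.

    Exactly one concentration source is active: bundled fixtures
    (``use_fixtures=True``) or a site CSV path.  ``seed`` drives every
    stochastic stage; there is no time-based fallback.
    """

    use_fixtures: bool = True
    site_csv: str | None = None
    pef_csv: str | None = None
    pef_table: str = "nisbet_lagoy_1992"
    use_printed_bap_equivalents: bool = True
    irs_mg_per_day: tuple[float, ...] = (361.0, 37.0, 20.0)
    efs_days_per_year: tuple[float, ...] = (365.0, 153.0)
    n_trials: int = 10_000
    seed: int = 0
    thresholds: tuple[float, ...] = (1e-5, 1e-6)
    background_per_100k: float = 7.0
    output_dir: str = "pahrisk_output"

    def __post_init__(self) -> None:
        if self.use_fixtures and self.site_csv is not None:
            raise ValueError("configure either fixtures or a site CSV, not both")
        if not self.use_fixtures and self.site_csv is None:
            raise ValueError("a site CSV path is required when fixtures are disabled")

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["irs_mg_per_day"] = list(self.irs_mg_per_day)
        d["efs_days_per_year"] = list(self.efs_days_per_year)
        d["thresholds"] = list(self.thresholds)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text)
        if not isinstance(d, dict):
            raise ValueError("config must be a YAML mapping")
        for key in ("irs_mg_per_day", "efs_days_per_year", "thresholds"):
            if key in d:
                d[key] = tuple(d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full assessment and write the report bundle to disk.

    Returns the in-memory bundle (dict of DataFrames/dicts); writes
    site_summary, deterministic grid, threshold table, MC draws + summary,
    sensitivity table, inhalation table, literature comparison and the run
    manifest under ``cfg.output_dir``.
    """
    outdir = Path(cfg.output_dir)
    manifest_inputs: dict[str, str] = {}

    # --- concentrations -> BaP equivalents -------------------------------
    if cfg.use_fixtures:
        soil = load_fixture("table1")
        profiles = list(soil.profiles)
        log.info("loaded bundled soil panel: %d profiles", len(profiles))
        if cfg.use_printed_bap_equivalents:
            values = list(soil.bap_equivalents)
        else:
            pefs = load_pef_table(cfg.pef_table)
            values = bap_equivalents(profiles, pefs)
    else:
        site_path = Path(cfg.site_csv)
        profiles = read_profiles_csv(site_path, medium="soil")
        manifest_inputs[str(site_path)] = _checksum(site_path)
        if cfg.pef_csv is not None:
            pefs = read_pef_csv(Path(cfg.pef_csv))
            manifest_inputs[str(cfg.pef_csv)] = _checksum(Path(cfg.pef_csv))
        else:
            pefs = load_pef_table(cfg.pef_table)
        values = bap_equivalents(profiles, pefs)
    if not profiles:
        raise ValueError("validation failed: site table contains no samples")

    summary = summarize(values)
    distances = [p.distance_km for p in profiles]
    regression = (
        distance_regression(distances=distances, values=values)
        if all(d is not None for d in distances) and len(set(distances)) > 1
        else None
    )

    # --- deterministic grid + thresholds ---------------------------------
    det_rows, thr_rows = [], []
    for cs_label, cs_ngg in (("max", summary.max), ("mean", summary.mean)):
        for ir in cfg.irs_mg_per_day:
            for ef in cfg.efs_days_per_year:
                s = IngestionScenario.from_soil_ngg(cs_ngg, ir_mg_per_day=ir, ef_days_per_year=ef)
                est = ingestion_risk(s)
                det_rows.append(
                    {"cs": cs_label, "cs_ng_per_g": cs_ngg, "ir_mg_per_day": ir,
                     "ef_days_per_year": ef, "risk": est.risk,
                     "exceeds_negligible": est.exceeds_negligible}
                )
    for ir in cfg.irs_mg_per_day:
        for ef in cfg.efs_days_per_year:
            s = IngestionScenario(cs_mg_per_kg=1.0, ir_mg_per_day=ir, ef_days_per_year=ef)
            thr_rows.append(
                {"ir_mg_per_day": ir, "ef_days_per_year": ef,
                 "threshold_ng_per_g": threshold_concentration_ngg(s, cfg.thresholds[0])}
            )
    deterministic = pd.DataFrame(det_rows)
    thresholds_table = pd.DataFrame(thr_rows)

    # --- probabilistic stage ---------------------------------------------
    mc_results, mc_summaries = {}, {}
    for name in ("table4", "table5"):
        specs = load_fixture(name)
        dists = ScenarioDistributions(specs=specs, n_trials=cfg.n_trials, seed=cfg.seed)
        rd = monte_carlo_risk(dists)
        mc_results[name] = rd
        mc_summaries[name] = summarize_distribution(rd, thresholds=cfg.thresholds)
        log.info("MC %s: mean risk %.3g (n=%d)", name, rd.mean, cfg.n_trials)

    # sensitivity run: field Cs and IR vary per the field scenario, EF spans
    # the seasonal-to-full-year range
    sens_specs = dict(load_fixture("table4"))
    sens_specs["EF"] = DistributionSpec.uniform(153.0, 365.0)
    sens_rd = monte_carlo_risk(
        ScenarioDistributions(specs=sens_specs, n_trials=cfg.n_trials, seed=cfg.seed)
    )
    sens = spearman_sensitivity(sens_rd)

    # --- inhalation over the measured air series --------------------------
    air = load_fixture("table7")
    inh_rows = []
    for _, row in air.iterrows():
        est = inhalation_risk(InhalationScenario.from_air_ugm3(row["concentration_ug_per_m3"]))
        inh_rows.append(
            {"statistic": row["statistic"],
             "concentration_ug_per_m3": row["concentration_ug_per_m3"],
             "risk": est.risk, "exceeds_negligible": est.exceeds_negligible}
        )
    inhalation = pd.DataFrame(inh_rows)

    # --- literature comparison -------------------------------------------
    lit = load_fixture("table3")
    lit_max = literature_comparison(
        [(r["location"], r["max_mg_per_kg"]) for _, r in lit.iterrows()
         if pd.notna(r["max_mg_per_kg"])]
    )
    lit_mean = literature_comparison(
        [(r["location"], r["mean_mg_per_kg"]) for _, r in lit.iterrows()
         if pd.notna(r["mean_mg_per_kg"])]
    )

    bundle = {
        "config": cfg,
        "site_summary": summary,
        "regression": regression,
        "deterministic": deterministic,
        "thresholds": thresholds_table,
        "mc_results": mc_results,
        "mc_summaries": mc_summaries,
        "sensitivity": sens,
        "inhalation": inhalation,
        "literature_max": lit_max,
        "literature_mean": lit_mean,
    }

    # --- write outputs ----------------------------------------------------
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([dataclasses.asdict(summary)]).to_csv(outdir / "site_summary.csv", index=False)
    deterministic.to_csv(outdir / "deterministic_grid.csv", index=False)
    thresholds_table.to_csv(outdir / "thresholds.csv", index=False)
    inhalation.to_csv(outdir / "inhalation.csv", index=False)
    lit_max.to_csv(outdir / "literature_max.csv", index=False)
    lit_mean.to_csv(outdir / "literature_mean.csv", index=False)
    pd.DataFrame(
        {name: rd.draws for name, rd in mc_results.items()}
    ).to_csv(outdir / "mc_draws.csv", index=False)
    pd.DataFrame(
        [{"scenario": n, "mean": s["mean"], "mean_per_100k": s["mean_per_100k"],
          "p5": s["percentiles"][5.0], "p50": s["percentiles"][50.0],
          "p95": s["percentiles"][95.0],
          **{f"prob_exceeds_{t:g}": p for t, p in s["prob_exceeds"].items()}}
         for n, s in mc_summaries.items()]
    ).to_csv(outdir / "mc_summary.csv", index=False)
    pd.DataFrame(
        [{"variable": v, "spearman_rho": sens.rho[v]} for v in sens.ranking]
    ).to_csv(outdir / "sensitivity.csv", index=False)

    manifest = {
        "package": "pahrisk",
        "version": __version__,
        "seed": cfg.seed,
        "n_trials": cfg.n_trials,
        "config_hash": cfg.config_hash(),
        "config": yaml.safe_load(cfg.to_yaml()),
        "input_checksums": manifest_inputs,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (outdir / "report.md").write_text(render_report(bundle))
    log.info("pipeline outputs written to %s", outdir)
    return bundle


def _fmt_risk(x: float) -> str:
    """3 significant figures, decimal half-up (printed-table convention)."""
    if x == 0:
        return "0.00E+00"
    d = Decimal(repr(x))
    exp = d.adjusted()
    mantissa = d.scaleb(-exp).quantize(Decimal("1.00"), rounding=ROUND_HALF_UP)
    if mantissa >= 10:
        mantissa, exp = mantissa.scaleb(-1).quantize(Decimal("1.00")), exp + 1
    return f"{mantissa}E{exp:+03d}"


def render_report(bundle: Mapping) -> str:
    """Human-readable markdown report: risks at 3 significant figures,
    threshold concentrations in whole ng/g, negligibility flags spelled out."""
    cfg: PipelineConfig = bundle["config"]
    s = bundle["site_summary"]
    lines = [
        "# PAH excess-lifetime-cancer-risk report",
        "",
        "## Site summary (BaP equivalents, ng/g)",
        "",
        f"n = {s.n}, mean = {s.mean:.2f} +/- {s.sd:.2f} (SD), "
        f"median = {s.median:.2f}, max = {s.max:.2f}",
    ]
    reg = bundle.get("regression")
    if reg is not None:
        lines += [
            "",
            f"Distance regression: F({reg.df_num}, {reg.df_den}) = "
            f"{reg.f_statistic:.2f}, p = {reg.p_value:.2f} "
            f"({'no ' if reg.p_value > 0.05 else ''}significant distance trend)",
        ]
    lines += ["", "## Deterministic ingestion risk", "",
              "| Cs | IR (mg/d) | EF (d/yr) | risk | flag |", "|---|---|---|---|---|"]
    for _, row in bundle["deterministic"].iterrows():
        flag = "exceeds 1e-5" if row["exceeds_negligible"] else "negligible"
        lines.append(
            f"| {row['cs']} ({row['cs_ng_per_g']:.2f} ng/g) | {row['ir_mg_per_day']:g} "
            f"| {row['ef_days_per_year']:g} | {_fmt_risk(row['risk'])} | {flag} |"
        )
    lines += ["", f"## Soil concentration at the {cfg.thresholds[0]:g} risk threshold", "",
              "| IR (mg/d) | EF (d/yr) | threshold (ng/g) |", "|---|---|---|"]
    for _, row in bundle["thresholds"].iterrows():
        lines.append(
            f"| {row['ir_mg_per_day']:g} | {row['ef_days_per_year']:g} "
            f"| {round(row['threshold_ng_per_g']):d} |"
        )
    lines += ["", "## Monte Carlo risk", ""]
    for name, summ in bundle["mc_summaries"].items():
        lines.append(
            f"- {name}: mean {_fmt_risk(summ['mean'])} "
            f"({summ['mean_per_100k']:.2f} per 100,000), "
            f"95th pct {_fmt_risk(summ['percentiles'][95.0])}, "
            f"P(risk > {cfg.thresholds[0]:g}) = {summ['prob_exceeds'][cfg.thresholds[0]]:.4f}"
        )
    sens = bundle["sensitivity"]
    lines += ["", "## Sensitivity (Spearman rho vs risk)", ""]
    for v in sens.ranking:
        lines.append(f"- {v}: {sens.rho[v]:+.2f}")
    lines += ["", "## Inhalation risk (measured air series)", "",
              "| statistic | CA (ug/m3) | risk | flag |", "|---|---|---|---|"]
    for _, row in bundle["inhalation"].iterrows():
        flag = "exceeds 1e-5" if row["exceeds_negligible"] else "negligible"
        lines.append(
            f"| {row['statistic']} | {row['concentration_ug_per_m3']:.3G} "
            f"| {_fmt_risk(row['risk'])} | {flag} |"
        )
    lines += ["", "## Literature comparison (IR 20 mg/d)", "",
              "| location | BaP eq (mg/kg) | risk | >1e-5 | >1e-6 |", "|---|---|---|---|---|"]
    for _, row in bundle["literature_max"].iterrows():
        lines.append(
            f"| {row['location']} (max) | {row['bap_eq_mg_per_kg']:g} "
            f"| {_fmt_risk(row['risk'])} | {'yes' if row['above_1e-5'] else 'no'} "
            f"| {'yes' if row['above_1e-6'] else 'no'} |"
        )
    lines.append("")
    return "\n".join(lines)
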