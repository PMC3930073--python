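"""Synthetic sites, receptor populations, and the bundled study fixtures.

The generators emulate the statistical structure the risk assessment
assumes: right-skewed (lognormal) soil concentration fields parameterised by
their arithmetic mean/SD, an optional linear trend with distance to the
nearest extraction pad (zero slope reproduces the study's null finding), and
heavy-tailed soil-ingestion-rate populations (lognormal, arithmetic mean 52
and SD 119 mg/d in the measured population, whose 95th percentile is
~361 mg/d and median ~37 mg/d).  Every generator is driven by an explicit
seed and is bit-for-bit reproducible.

:func:`load_fixture` exposes the study's printed tables (soil concentration
panel, literature comparison, the two Monte Carlo input tables, and the air
series) as typed in-memory objects so every stage is testable without
downloads.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .analytes import BENZO_A_PYRENE, canonical_name
from .bap_equivalence import PAHProfile, PEFTable, load_pef_table, read_profiles_csv
from .deterministic_risk import IngestionScenario
from .probabilistic_risk import DistributionSpec

FIXTURES = ("table1", "table3", "table4", "table5", "table7")


@dataclass(frozen=True)
class SyntheticSiteConfig:
    """Parameters of a synthetic soil-concentration field (BaP-equivalent scale)."""

    n_samples: int = 18
    conc_mean: float = 15.70          # ng/g, arithmetic
    conc_sd: float = 29.67            # ng/g, arithmetic
    distance_range_km: tuple[float, float] = (0.1, 34.0)
    distance_effect: float = 0.0      # ng/g per km; 0 = no spatial trend
    analyte_mixture: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.conc_mean <= 0 or self.conc_sd < 0:
            raise ValueError("conc_mean must be positive and conc_sd non-negative")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.analyte_mixture is not None:
            total = sum(self.analyte_mixture.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"analyte_mixture fractions must sum to 1, got {total}")


@dataclass(frozen=True)
class SyntheticPopulationConfig:
    """Parameters of a synthetic receptor population (ingestion-rate scale)."""

    n_receptors: int = 10_000
    ir_mean: float = 52.0             # mg/d, arithmetic
    ir_sd: float = 119.0              # mg/d, arithmetic
    bw: float = 80.0                  # kg
    ef_days: float = 153.0
    cs_mg_per_kg: float = 0.0998      # fixed soil concentration per receptor
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_receptors", "ir_mean", "ir_sd", "bw", "ef_days", "cs_mg_per_kg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _sample_ln(mean: float, sd: float, n: int, rng: np.random.Generator) -> np.ndarray:
    mu, sigma = DistributionSpec.lognormal(mean, sd).log_params()
    return rng.lognormal(mean=mu, sigma=sigma, size=n)


def generate_site(
    cfg: SyntheticSiteConfig, pefs: PEFTable | None = None
) -> list[PAHProfile]:
    """Draw a synthetic site of soil profiles on the BaP-equivalent scale.

    Totals are lognormal(conc_mean, conc_sd) plus ``distance_effect`` times a
    uniform distance draw.  Without an analyte mixture the whole total is
    carried by benzo[a]pyrene (PEF 1), so the PEF-weighted sum recovers it
    trivially; with a mixture the total is decomposed so the weighted sum
    under ``pefs`` reconstructs it exactly (round-trip property).
    """
    rng = np.random.default_rng(cfg.seed)
    distances = rng.uniform(*cfg.distance_range_km, size=cfg.n_samples)
    if cfg.conc_sd == 0:
        totals = np.full(cfg.n_samples, cfg.conc_mean)
    else:
        totals = _sample_ln(cfg.conc_mean, cfg.conc_sd, cfg.n_samples, rng)
    totals = totals + cfg.distance_effect * distances
    totals = np.clip(totals, 0.0, None)

    if cfg.analyte_mixture is not None:
        pefs = pefs or load_pef_table()
        weights: dict[str, float] = {}
        for analyte, fraction in cfg.analyte_mixture.items():
            pef = pefs[analyte]
            if fraction > 0 and pef == 0:
                raise ValueError(
                    f"infeasible mixture: analyte {analyte!r} has PEF 0 but carries mass"
                )
            if fraction > 0:
                weights[canonical_name(analyte)] = fraction / pef

    profiles = []
    for i, (total, dist) in enumerate(zip(totals, distances), start=1):
        if cfg.analyte_mixture is None:
            conc = {BENZO_A_PYRENE: float(total)}
        else:
            conc = {a: float(total * w) for a, w in weights.items()}
        profiles.append(
            PAHProfile(
                sample_id=f"synthetic-{i}",
                medium="soil",
                concentrations=conc,
                detected={a: True for a in conc},
                distance_km=float(dist),
                unit="ng/g",
            )
        )
    return profiles


def generate_population(cfg: SyntheticPopulationConfig) -> list[IngestionScenario]:
    """Draw a synthetic receptor population with lognormal ingestion rates."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.ir_sd == 0:
        irs = np.full(cfg.n_receptors, cfg.ir_mean)
    else:
        irs = _sample_ln(cfg.ir_mean, cfg.ir_sd, cfg.n_receptors, rng)
    return [
        IngestionScenario(
            cs_mg_per_kg=cfg.cs_mg_per_kg,
            ir_mg_per_day=float(ir),
            ef_days_per_year=cfg.ef_days,
            bw_kg=cfg.bw,
        )
        for ir in irs
    ]


# ---------------------------------------------------------------------------
# Bundled study fixtures


@dataclass(frozen=True)
class SoilTable:
    """The measured soil panel: per-sample profiles plus the printed
    aggregate rows (total PAH and BaP equivalents, both ng/g).

    The printed BaP-equivalent row is authoritative for downstream stages;
    recomputing it from the analyte rows under a candidate PEF table is a
    diagnostic (see :func:`pahrisk.bap_equivalence.bap_equivalents`), not a
    replacement.
    """

    profiles: tuple[PAHProfile, ...]
    sum_pah: tuple[float, ...]
    bap_equivalents: tuple[float, ...]

    @property
    def distances_km(self) -> tuple[float, ...]:
        return tuple(p.distance_km for p in self.profiles)


def _data_path(filename: str):
    return resources.as_file(resources.files("pahrisk.data") / filename)


def load_fixture(name: str):
    """Load one of the bundled study tables.

    - ``table1`` -> :class:`SoilTable` (18 soil profiles + printed aggregates)
    - ``table3`` -> DataFrame of literature BaP equivalents and printed risks
    - ``table4``/``table5`` -> dict variable -> :class:`DistributionSpec`
      (the field-concentration and maximum-concentration MC scenarios)
    - ``table7`` -> DataFrame of the air series (ug/m3) and printed risks
    """
    if name not in FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; available: {FIXTURES}")
    if name == "table1":
        with _data_path("table1_soil.csv") as path:
            profiles = read_profiles_csv(path, medium="soil")
            raw = pd.read_csv(path, comment="#", index_col=0)
        return SoilTable(
            profiles=tuple(profiles),
            sum_pah=tuple(raw.loc["sum_pah"].astype(float)),
            bap_equivalents=tuple(raw.loc["bap_equivalents"].astype(float)),
        )
    if name == "table3":
        with _data_path("table3_literature.csv") as path:
            return pd.read_csv(path, comment="#")
    if name in ("table4", "table5"):
        with _data_path(f"{name}_distributions.csv") as path:
            df = pd.read_csv(path, comment="#")
        specs: dict[str, DistributionSpec] = {}
        for _, row in df.iterrows():
            if row["family"] == "lognormal":
                specs[row["variable"]] = DistributionSpec.lognormal(
                    float(row["mean"]), float(row["sd"])
                )
            else:
                specs[row["variable"]] = DistributionSpec.uniform(
                    float(row["min"]), float(row["max"])
                )
        return specs
    with _data_path("table7_air.csv") as path:
        return pd.read_csv(path, comment="#")
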