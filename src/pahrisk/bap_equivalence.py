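"""Benzo[a]pyrene (BaP) equivalency for multi-analyte PAH profiles.

A mixture of carcinogenic PAHs is screened by re-expressing it as the single
BaP concentration of equal carcinogenic potency: each analyte concentration
is weighted by its potency equivalency factor (PEF, dimensionless, BaP = 1)
and the weighted contributions are summed.  This module holds the sample
container (:class:`PAHProfile`), the PEF table, the weighted sum itself, and
the site-level summary and distance-regression operations the risk stages
consume.

Non-detects ("-" cells in field tables) contribute exactly zero to every
aggregate by default; half-detection-limit substitution is available via
``nd_substitute`` on the CSV reader for sensitivity checks but is never the
default.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .analytes import CANONICAL_EPA16, BENZO_A_PYRENE, canonical_name, display_name

Medium = Literal["soil", "air_particulate", "air_vapour"]

#: Units expected per medium at the API boundary (measurement units).
MEDIUM_UNITS = {"soil": "ng/g", "air_particulate": "ng/m3", "air_vapour": "ng/m3"}


@dataclass(frozen=True)
class PAHProfile:
    """One sample's PAH analyte concentrations.

    Concentrations are keyed by canonical analyte name and carry the medium's
    measurement unit (ng/g dry weight for soil, ng/m3 for air).  ``detected``
    flags analytes reported below detection; non-detects contribute zero to
    any aggregate.
    """

    sample_id: str
    medium: Medium
    concentrations: Mapping[str, float]
    detected: Mapping[str, bool] = field(default_factory=dict)
    distance_km: float | None = None
    unit: str = "ng/g"

    def __post_init__(self) -> None:
        for name, value in self.concentrations.items():
            key = canonical_name(name)
            if key not in CANONICAL_EPA16:
                raise ValueError(f"unknown PAH analyte: {name!r}")
            if not np.isfinite(value) or value < 0:
                raise ValueError(
                    f"concentration for {name!r} must be finite and >= 0, got {value}"
                )
        if self.distance_km is not None and self.distance_km < 0:
            raise ValueError("distance_km must be non-negative")

    def is_detected(self, analyte: str) -> bool:
        key = canonical_name(analyte)
        return bool(self.detected.get(key, key in map(canonical_name, self.concentrations)))


@dataclass(frozen=True)
class PEFTable:
    """Analyte -> potency equivalency factor relative to BaP (BaP = 1)."""

    factors: Mapping[str, float]
    source_label: str = "unspecified"

    def __post_init__(self) -> None:
        canon = {canonical_name(k): float(v) for k, v in self.factors.items()}
        object.__setattr__(self, "factors", canon)
        for name, f in canon.items():
            if not (0.0 <= f <= 10.0):
                raise ValueError(f"PEF for {name!r} out of range [0, 10]: {f}")
        if canon.get(BENZO_A_PYRENE) != 1.0:
            raise ValueError("PEF table must assign benzo[a]pyrene a factor of exactly 1.0")

    def __getitem__(self, analyte: str) -> float:
        key = canonical_name(analyte)
        if key not in self.factors:
            raise KeyError(f"no PEF for analyte {display_name(key)!r} in table {self.source_label!r}")
        return self.factors[key]

    def __contains__(self, analyte: str) -> bool:
        return canonical_name(analyte) in self.factors


@dataclass(frozen=True)
class SiteSummary:
    """Descriptive statistics of a set of concentrations (sample SD, n-1)."""

    n: int
    mean: float
    sd: float
    median: float
    max: float
    sum_pah: float


@dataclass(frozen=True)
class RegressionResult:
    """OLS of concentration on distance with the F test of the slope."""

    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float


def bap_equivalent(profile: PAHProfile, pefs: PEFTable) -> float:
    """PEF-weighted sum of the detected analytes, in the profile's unit.

    Linear in the concentrations and invariant to analyte order.  Raises
    ``KeyError`` naming the analyte if a detected analyte has no PEF.
    """
    terms = []
    for name, conc in profile.concentrations.items():
        key = canonical_name(name)
        if not profile.detected.get(key, True):
            continue
        terms.append(conc * pefs[key])
    # fsum: exactly-rounded sum, so the result is analyte-order invariant
    return math.fsum(terms)


def summarize(values: Sequence[float]) -> SiteSummary:
    """Mean, sample SD, median, max and sum of a concentration column.

    The median for even n is the mean of the two central order statistics.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty list of values")
    if not np.all(np.isfinite(arr)):
        raise ValueError("all values must be finite")
    return SiteSummary(
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        median=float(np.median(arr)),
        max=float(arr.max()),
        sum_pah=float(arr.sum()),
    )


def distance_regression(
    profiles: Sequence[PAHProfile] | None = None,
    pefs: PEFTable | None = None,
    *,
    distances: Sequence[float] | None = None,
    values: Sequence[float] | None = None,
) -> RegressionResult:
    """OLS of BaP-equivalent concentration (untransformed) on distance.

    Accepts either profiles (+ a PEF table to weight them) or precomputed
    ``(distances, values)`` pairs.  The slope is tested with an F statistic
    on (1, n-2) degrees of freedom; p is the upper tail of the F distribution
    (equivalent to the two-sided t test of the slope).
    """
    if profiles is not None:
        if values is not None or distances is not None:
            raise ValueError("pass either profiles or (distances, values), not both")
        pairs = [(p.distance_km, p) for p in profiles if p.distance_km is not None]
        if len(pairs) < 3:
            raise ValueError("need at least 3 profiles with distance_km")
        distances = [d for d, _ in pairs]
        if pefs is None:
            raise ValueError("a PEF table is required to weight profiles")
        values = [bap_equivalent(p, pefs) for _, p in pairs]
    if distances is None or values is None:
        raise ValueError("distances and values are required")
    x = np.asarray(distances, dtype=float)
    y = np.asarray(values, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 matched (distance, value) pairs")
    if np.ptp(x) == 0:
        raise ValueError("all distances identical: zero-variance predictor")
    lr = stats.linregress(x, y)
    n = x.size
    r2 = float(lr.rvalue**2)
    df_num, df_den = 1, n - 2
    if r2 >= 1.0:
        f_stat = float("inf")
        p = 0.0
    else:
        f_stat = r2 / df_num / ((1.0 - r2) / df_den)
        p = float(stats.f.sf(f_stat, df_num, df_den))
    return RegressionResult(
        slope=float(lr.slope),
        intercept=float(lr.intercept),
        r_squared=r2,
        f_statistic=f_stat,
        df_num=df_num,
        df_den=df_den,
        p_value=p,
    )


# ---------------------------------------------------------------------------
# CSV I/O


def read_pef_csv(path: str | Path, source_label: str | None = None) -> PEFTable:
    """Read an ``analyte,factor`` CSV into a :class:`PEFTable`."""
    path = Path(path)
    factors: dict[str, float] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            if row[0].strip().lower() in {"analyte", "pah"}:
                continue
            factors[row[0]] = float(row[1])
    return PEFTable(factors=factors, source_label=source_label or path.stem)


def load_pef_table(name: str = "nisbet_lagoy_1992") -> PEFTable:
    """Load one of the bundled published PEF schemes.

    ``nisbet_lagoy_1992`` (the default; dibenz[a,h]anthracene = 5, 2-3-ring
    PAHs 0.001) or ``calepa_oehha_1994`` (carcinogenic PAHs only, others 0).
    """
    available = ("nisbet_lagoy_1992", "calepa_oehha_1994")
    if name not in available:
        raise ValueError(f"unknown PEF table {name!r}; available: {available}")
    ref = resources.files("pahrisk.data") / f"pef_{name}.csv"
    with resources.as_file(ref) as path:
        return read_pef_csv(path, source_label=name)


def _parse_cell(cell: str, nd_substitute: float) -> tuple[float, bool]:
    cell = cell.strip()
    if cell in {"", "-", "nd", "ND", "n.d."}:
        return nd_substitute, False
    return float(cell), True


def read_profiles_csv(
    path: str | Path,
    medium: Medium = "soil",
    unit: str | None = None,
    nd_substitute: float = 0.0,
) -> list[PAHProfile]:
    """Read an analyte-by-sample CSV into profiles.

    Orientation is auto-detected: if the first column holds analyte names the
    table is analytes-as-rows (samples as columns), otherwise samples-as-rows
    (analytes as columns).  ``-`` or empty cells are non-detects; by default
    they contribute zero (set ``nd_substitute`` to e.g. half the detection
    limit to explore substitution schemes).  A ``distance_km`` row/column is
    honoured when present.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    if not rows:
        raise ValueError(f"empty profile table: {path}")
    header, body = rows[0], rows[1:]
    unit = unit or MEDIUM_UNITS[medium]

    first_col = [r[0] for r in body]
    analytes_as_rows = any(canonical_name(v) in CANONICAL_EPA16 for v in first_col)

    if analytes_as_rows:
        sample_ids = [h.strip() for h in header[1:]]
        conc: dict[str, dict[str, float]] = {s: {} for s in sample_ids}
        det: dict[str, dict[str, bool]] = {s: {} for s in sample_ids}
        dist: dict[str, float | None] = {s: None for s in sample_ids}
        for row in body:
            label = row[0].strip()
            key = canonical_name(label)
            if key in CANONICAL_EPA16:
                for s, cell in zip(sample_ids, row[1:]):
                    value, detected = _parse_cell(cell, nd_substitute)
                    conc[s][key] = value
                    det[s][key] = detected
            elif "distance" in label.lower():
                for s, cell in zip(sample_ids, row[1:]):
                    dist[s] = float(cell) if cell.strip() else None
            # other rows (e.g. printed aggregate rows) are ignored here
        return [
            PAHProfile(
                sample_id=s, medium=medium, concentrations=conc[s],
                detected=det[s], distance_km=dist[s], unit=unit,
            )
            for s in sample_ids
        ]

    # samples as rows
    columns = [h.strip() for h in header]
    profiles = []
    for row in body:
        sample_id = row[0].strip()
        conc2: dict[str, float] = {}
        det2: dict[str, bool] = {}
        distance: float | None = None
        for col, cell in zip(columns[1:], row[1:]):
            key = canonical_name(col)
            if key in CANONICAL_EPA16:
                value, detected = _parse_cell(cell, nd_substitute)
                conc2[key] = value
                det2[key] = detected
            elif "distance" in col.lower():
                distance = float(cell) if cell.strip() else None
        profiles.append(
            PAHProfile(
                sample_id=sample_id, medium=medium, concentrations=conc2,
                detected=det2, distance_km=distance, unit=unit,
            )
        )
    return profiles


def bap_equivalents(profiles: Iterable[PAHProfile], pefs: PEFTable) -> list[float]:
    """Vector convenience: :func:`bap_equivalent` over many profiles."""
    return [bap_equivalent(p, pefs) for p in profiles]
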