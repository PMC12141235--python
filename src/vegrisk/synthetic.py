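"""Seeded synthetic surveillance datasets with the structure the analysis assumes.

The national surveillance database behind this kind of study is not openly
deposited, so the generator emulates its statistical shape: province ×
vegetable × year strata with highly skewed batch counts, per-stratum
exceedance probabilities in the low percent range (up to ~0.29), and
heavy-tailed exceedance multiples (stratum means spanning ~2–18, tail values
approaching ~48). Every batch is Bernoulli(p_exceed) non-compliant; a
non-compliant batch carries one violating pesticide at C = multiple × limit
with the multiple drawn from a shifted log-normal (1 + LogNormal, support
strictly above 1, so C > MRL by construction); compliant batches carry
sub-limit detections per pesticide-specific detection rates. A banned
pesticide (no tolerance) can be planted in a panel; its violations are
scored against the compliance policy's reference limit.

The same seed reproduces the dataset byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geodata import capitals_frame
from .ingest import ConfigError

DEFAULT_BANNED_REFERENCE = 0.01  # mg/kg, matches CompliancePolicy default


@dataclass(frozen=True)
class PanelPesticide:
    """One pesticide in a vegetable's testing panel."""

    name: str
    mrl: Optional[float]  # mg/kg; None only for banned substances
    banned: bool = False
    p_detect_when_compliant: float = 0.0

    def __post_init__(self) -> None:
        if self.mrl is None and not self.banned:
            raise ConfigError(f"{self.name}: non-banned panel entry needs an mrl")
        if self.mrl is not None and not (self.mrl > 0):
            raise ConfigError(f"{self.name}: mrl must be positive")
        if not (0.0 <= self.p_detect_when_compliant <= 1.0):
            raise ConfigError(f"{self.name}: p_detect_when_compliant outside [0, 1]")


@dataclass(frozen=True)
class StratumSpec:
    """Sampling plan and risk level for one province × vegetable × year cell."""

    province: str
    vegetable: str
    year: int
    n_batches: int
    p_exceed: float
    severity_log_mean: float
    severity_log_sd: float
    pesticide_panel: tuple[PanelPesticide, ...]

    def __post_init__(self) -> None:
        if self.n_batches < 0:
            raise ConfigError("n_batches must be >= 0")
        if not (0.0 <= self.p_exceed <= 1.0):
            raise ConfigError(f"p_exceed {self.p_exceed} outside [0, 1]")
        if self.severity_log_sd < 0:
            raise ConfigError("severity_log_sd must be >= 0")
        if self.p_exceed > 0 and not self.pesticide_panel:
            raise ConfigError("a stratum with exceedances needs a pesticide panel")

    @property
    def expected_severity(self) -> float:
        """Mean of the exceedance multiple, 1 + exp(mu + sd^2/2)."""
        return 1.0 + math.exp(self.severity_log_mean + self.severity_log_sd**2 / 2)

    @property
    def severity_sd(self) -> float:
        """Standard deviation of the exceedance multiple."""
        s2 = self.severity_log_sd**2
        return math.exp(self.severity_log_mean + s2 / 2) * math.sqrt(math.expm1(s2))


def severity_log_mean_for(mean_multiple: float, log_sd: float) -> float:
    """Log-mean giving the shifted log-normal a target mean exceedance multiple."""
    if not (mean_multiple > 1.0):
        raise ConfigError("mean exceedance multiple must be > 1")
    return math.log(mean_multiple - 1.0) - log_sd**2 / 2


@dataclass(frozen=True)
class GeneratorConfig:
    strata: tuple[StratumSpec, ...]
    seed: int
    geo: pd.DataFrame = field(default_factory=capitals_frame)
    banned_reference_mgkg: float = DEFAULT_BANNED_REFERENCE
    microgram_row_rate: float = 0.1  # fraction of compliant rows emitted in µg/kg

    def __post_init__(self) -> None:
        if not self.strata:
            raise ConfigError("generator config has no strata")
        if not (0.0 <= self.microgram_row_rate <= 1.0):
            raise ConfigError("microgram_row_rate outside [0, 1]")


def generate(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw one dataset: (records, mrl_table, geo_table) as DataFrames.

    ``records`` uses the ingest dialect (one row per batch-pesticide
    detection; a blank pesticide/concentration row marks a batch with no
    detections). The MRL table is the union of the panels. Identical config
    and seed reproduce identical frames.
    """
    rng = np.random.default_rng(config.seed)
    rows: list[tuple] = []
    batch_no = 0

    for spec in config.strata:
        n = spec.n_batches
        if n == 0:
            continue
        panel = spec.pesticide_panel
        nc = rng.random(n) < spec.p_exceed
        viol_idx = rng.integers(0, len(panel), size=n) if panel else np.zeros(n, int)
        multiples = 1.0 + rng.lognormal(spec.severity_log_mean, spec.severity_log_sd, size=n)
        # sub-limit detections for every non-banned panel pesticide
        det = (
            rng.random((n, len(panel))) if panel else np.zeros((n, 0))
        )
        det_conc = (
            rng.uniform(0.0, 1.0, size=(n, len(panel))) if panel else np.zeros((n, 0))
        )
        ug = rng.random((n, len(panel))) < config.microgram_row_rate if panel else np.zeros((n, 0), bool)

        for b in range(n):
            batch_no += 1
            bid = f"B{batch_no:07d}"
            emitted = 0
            if nc[b] and panel:
                p = panel[viol_idx[b]]
                ref = p.mrl if p.mrl is not None else config.banned_reference_mgkg
                conc = multiples[b] * ref
                rows.append(
                    (spec.province, spec.vegetable, spec.year, bid, p.name,
                     repr(float(conc)), "mg/kg")
                )
                emitted += 1
            for j, p in enumerate(panel):
                if nc[b] and j == viol_idx[b]:
                    continue
                if p.banned:
                    continue  # any banned detection is a violation; keep clean
                if det[b, j] < p.p_detect_when_compliant:
                    conc = det_conc[b, j] * p.mrl  # strictly below the limit
                    if ug[b, j]:
                        rows.append(
                            (spec.province, spec.vegetable, spec.year, bid, p.name,
                             repr(float(conc * 1000.0)), "µg/kg")
                        )
                    else:
                        rows.append(
                            (spec.province, spec.vegetable, spec.year, bid, p.name,
                             repr(float(conc)), "mg/kg")
                        )
                    emitted += 1
            if emitted == 0:
                rows.append((spec.province, spec.vegetable, spec.year, bid, "", "", ""))

    records = pd.DataFrame(
        rows,
        columns=["province", "vegetable", "year", "batch_id", "pesticide",
                 "concentration", "unit"],
    )
    mrl = mrl_frame(config.strata)
    return records, mrl, config.geo.copy()


def mrl_frame(strata: Sequence[StratumSpec]) -> pd.DataFrame:
    """MRL reference table implied by the panels (one row per pair)."""
    seen: dict[tuple[str, str], tuple] = {}
    for spec in strata:
        for p in spec.pesticide_panel:
            key = (spec.vegetable, p.name)
            row = (spec.vegetable, p.name,
                   "" if p.mrl is None else repr(float(p.mrl)),
                   1 if p.banned else 0)
            if key in seen and seen[key] != row:
                raise ConfigError(f"conflicting MRL definitions for {key}")
            seen[key] = row
    return pd.DataFrame(
        sorted(seen.values()),
        columns=["vegetable", "pesticide", "mrl_mg_per_kg", "banned"],
    )


# ---------------------------------------------------------------------------
# Packaged paper-magnitude scenario

_NE = ("Heilongjiang", "Jilin", "Liaoning", "Shandong", "Jiangsu")
_SW = ("Chongqing", "Sichuan", "Guizhou", "Yunnan")
_CENTRAL = ("Henan", "Hubei", "Hunan")

# vegetable -> (batches per province-year, p_exceed, mean severity multiple,
#               severity log-sd)
_VEG_PLAN: dict[str, tuple[int, float, float, float]] = {
    "pepper": (60, 0.029, 3.7, 0.9),
    "chinese cabbage": (52, 0.0135, 7.6, 0.9),
    "tomato": (50, 0.0013, 3.0, 0.7),
    "eggplant": (46, 0.011, 3.2, 0.8),
    "celery": (40, 0.036, 8.2, 0.9),
    "potato": (35, 0.0016, 4.4, 0.8),
    "cowpea": (30, 0.074, 8.3, 0.9),
    "leek": (29, 0.093, 8.8, 0.9),
    "ginger": (25, 0.081, 4.6, 0.8),
    "spinach": (24, 0.025, 7.7, 0.9),
    "bean sprout": (22, 0.008, 17.6, 1.1),
    "cucumber": (20, 0.005, 4.8, 0.8),
    "shallot": (7, 0.062, 3.8, 0.8),
    "wax gourd": (4, 0.006, 2.6, 0.6),
}

_PANELS: dict[str, tuple[PanelPesticide, ...]] = {
    "pepper": (
        PanelPesticide("clothianidin", 0.2, False, 0.06),
        PanelPesticide("acetamiprid", 1.0, False, 0.05),
        PanelPesticide("imidacloprid", 1.0, False, 0.05),
    ),
    "chinese cabbage": (
        PanelPesticide("clothianidin", 0.2, False, 0.04),
        PanelPesticide("cypermethrin", 1.0, False, 0.04),
    ),
    "tomato": (
        PanelPesticide("imidacloprid", 1.0, False, 0.05),
        PanelPesticide("difenoconazole", 0.5, False, 0.03),
    ),
    "eggplant": (
        PanelPesticide("imidacloprid", 1.0, False, 0.05),
        PanelPesticide("cypermethrin", 0.5, False, 0.03),
    ),
    "celery": (
        PanelPesticide("chlorpyrifos", None, True, 0.0),
        PanelPesticide("difenoconazole", 1.0, False, 0.04),
        PanelPesticide("imidacloprid", 0.5, False, 0.05),
    ),
    "potato": (
        PanelPesticide("imidacloprid", 0.5, False, 0.03),
        PanelPesticide("metalaxyl", 0.05, False, 0.02),
    ),
    "cowpea": (
        PanelPesticide("carbendazim", 0.5, False, 0.05),
        PanelPesticide("acetamiprid", 0.4, False, 0.04),
        PanelPesticide("thiamethoxam", 0.3, False, 0.03),
        PanelPesticide("chlorpyrifos", None, True, 0.0),
    ),
    "leek": (
        PanelPesticide("procymidone", 0.2, False, 0.05),
        PanelPesticide("clothianidin", 0.2, False, 0.03),
        PanelPesticide("chlorpyrifos", None, True, 0.0),
    ),
    "ginger": (
        PanelPesticide("clothianidin", 0.2, False, 0.06),
        PanelPesticide("carbendazim", 0.5, False, 0.04),
    ),
    "spinach": (
        PanelPesticide("chlorpyrifos", None, True, 0.0),
        PanelPesticide("imidacloprid", 0.5, False, 0.05),
    ),
    "bean sprout": (
        PanelPesticide("carbendazim", 0.5, False, 0.03),
    ),
    "cucumber": (
        PanelPesticide("imidacloprid", 1.0, False, 0.05),
        PanelPesticide("pyraclostrobin", 0.5, False, 0.03),
    ),
    "shallot": (
        PanelPesticide("procymidone", 0.2, False, 0.04),
        PanelPesticide("clothianidin", 0.2, False, 0.03),
    ),
    "wax gourd": (
        PanelPesticide("imidacloprid", 0.5, False, 0.03),
    ),
}

#: regional exceedance multiplier planting the northeast -> southwest shift
_REGION_YEAR_FACTOR = {2021: {"ne": 2.5, "sw": 0.4, "central": 1.0},
                       2022: {"ne": 1.0, "sw": 1.0, "central": 1.0},
                       2023: {"ne": 0.4, "sw": 2.5, "central": 1.0}}

P_EXCEED_CAP = 0.29  # stratum probabilities stay inside the observed range


def paper_like_scenario(seed: int = 20210, scale: float = 1.0) -> GeneratorConfig:
    """Packaged three-year scenario with paper-magnitude structure.

    Twelve provinces × fourteen vegetable categories over 2021–2023 with
    skewed batch counts, a banned pesticide (chlorpyrifos) in several panels,
    and high-risk strata concentrated in the northeast in 2021 and in the
    southwest in 2023, so the whole-vegetable risk centroid migrates
    northeast → southwest. ``scale`` multiplies every stratum's batch count.
    """
    if scale <= 0:
        raise ConfigError("scale must be positive")
    strata: list[StratumSpec] = []
    for province in _NE + _CENTRAL + _SW:
        region = "ne" if province in _NE else "sw" if province in _SW else "central"
        for vegetable, (n, p, sev_mean, sev_sd) in _VEG_PLAN.items():
            for year in (2021, 2022, 2023):
                factor = _REGION_YEAR_FACTOR[year][region]
                strata.append(
                    StratumSpec(
                        province=province,
                        vegetable=vegetable,
                        year=year,
                        n_batches=max(1, round(n * scale)),
                        p_exceed=min(p * factor, P_EXCEED_CAP),
                        severity_log_mean=severity_log_mean_for(sev_mean, sev_sd),
                        severity_log_sd=sev_sd,
                        pesticide_panel=_PANELS[vegetable],
                    )
                )
    return GeneratorConfig(strata=tuple(strata), seed=seed)


def single_stratum_config(
    n_batches: int,
    p_exceed: float,
    mean_severity: float,
    seed: int,
    severity_log_sd: float = 0.8,
    province: str = "Jiangsu",
    vegetable: str = "celery",
    year: int = 2022,
) -> GeneratorConfig:
    """One-stratum config, convenient for calibration and recovery checks."""
    spec = StratumSpec(
        province=province,
        vegetable=vegetable,
        year=year,
        n_batches=n_batches,
        p_exceed=p_exceed,
        severity_log_mean=severity_log_mean_for(mean_severity, severity_log_sd),
        severity_log_sd=severity_log_sd,
        pesticide_panel=_PANELS[vegetable],
    )
    return GeneratorConfig(strata=(spec,), seed=seed)
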