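"""Risk-index computation, threshold classification and summary tables.

The residue risk index multiplies the probability of a risk event by its
severity, IR = P × S:

* **P** — exceedance probability of a stratum (one province × vegetable
  cell): non-compliant batches M over sampled batches N.
* **S** — mean worst-case hazard of the stratum's non-compliant batches
  (0 when none are non-compliant). A config switch instead averages over all
  N batches for the literal all-sample reading.
* Aggregates pool strata by direct weighting: P = ΣM/ΣN and S as the
  batch-count-weighted mean of stratum hazards.

The regulatory benchmark is a 98% pass rate (acceptable exceedance
probability 2%) at the acceptable-maximum hazard 1, giving the threshold
IR₀ = 0.02: a stratum, vegetable or province at or above it is high-risk.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .ingest import ConfigError

HIGH, LOW = "high", "low"

#: denominator for the stratum hazard mean
S_NONCOMPLIANT, S_ALL = "noncompliant", "all"


@dataclass(frozen=True)
class ThresholdConfig:
    """Acceptable probability × acceptable hazard = risk threshold IR₀."""

    p_max: float = 0.02
    s_max: float = 1.0

    @property
    def ir0(self) -> float:
        return self.p_max * self.s_max

    def __post_init__(self) -> None:
        if not (0 < self.p_max <= 1):
            raise ConfigError("p_max must be in (0, 1]")
        if not (self.s_max > 0):
            raise ConfigError("s_max must be positive")


def risk_index(p: float, s: float) -> float:
    """IR = P × S (P a fraction, S the dimensionless hazard)."""
    if p < 0 or s < 0:
        raise ValueError("P and S must be non-negative")
    return p * s


def classify(ir: float, threshold: ThresholdConfig | float = ThresholdConfig()) -> str:
    """Classify a risk index: high iff IR ≥ IR₀ (default 0.02)."""
    ir0 = threshold if isinstance(threshold, (int, float)) else threshold.ir0
    if ir < 0:
        raise ValueError(f"risk index must be non-negative, got {ir}")
    return HIGH if ir >= ir0 else LOW


_REQUIRED = ("province", "vegetable", "compliant", "hazard")


def stratum_risk(
    assessments: pd.DataFrame,
    s_denominator: str = S_NONCOMPLIANT,
    by: Sequence[str] = ("province", "vegetable"),
    min_n_flag: int = 10,
) -> pd.DataFrame:
    """Per-stratum risk table from a batch assessment table.

    Returns one row per observed group with columns ``*by, n, m, p, s, ir,
    small_sample``: sampled batches N, non-compliant batches M, exceedance
    probability P = M/N (a fraction), mean hazard S, risk index IR = P × S,
    and a small-sample marker for strata under ``min_n_flag`` batches.
    P, S and IR are all identically 0 when M = 0.
    """
    if s_denominator not in {S_NONCOMPLIANT, S_ALL}:
        raise ConfigError(f"unknown s_denominator {s_denominator!r}")
    for c in list(by) + ["compliant", "hazard"]:
        if c not in assessments.columns:
            raise ConfigError(f"assessment table lacks column {c!r}")
    if assessments.empty:
        return pd.DataFrame(
            columns=[*by, "n", "m", "p", "s", "ir", "small_sample"]
        )

    df = assessments.copy()
    df["compliant"] = df["compliant"].astype(bool)
    df["_nc"] = (~df["compliant"]).astype(int)
    g = df.groupby(list(by), sort=True)
    out = g.agg(
        n=("hazard", "size"),
        m=("_nc", "sum"),
        hazard_sum=("hazard", "sum"),
    ).reset_index()
    out["p"] = out["m"] / out["n"]
    denom = out["m"] if s_denominator == S_NONCOMPLIANT else out["n"]
    with np.errstate(invalid="ignore", divide="ignore"):
        s = out["hazard_sum"] / denom
    out["s"] = np.where(out["m"] > 0, s, 0.0)
    out["ir"] = out["p"] * out["s"]
    out["small_sample"] = out["n"] < min_n_flag
    return out.drop(columns=["hazard_sum"])


#: weighting of stratum hazards in aggregation
W_BATCHES, W_NONCOMPLIANT = "batches", "noncompliant"


def aggregate(
    strata: pd.DataFrame,
    level: Literal["vegetable", "province"],
    threshold: ThresholdConfig = ThresholdConfig(),
    s_weights: str = W_BATCHES,
) -> pd.DataFrame:
    """Direct-weighted vegetable- or province-level risk table.

    Pools strata over the other dimension: P = ΣM/ΣN; S is the weighted mean
    of stratum hazards, weighted by sampled batches N (default) or by
    non-compliant batches M; IR = P × S with threshold classification.
    ``group_count`` is the number of contributing strata (provinces sampled
    for a vegetable, or vegetables sampled in a province). Rows are ranked by
    IR descending, ties broken by pooled N descending then key.
    """
    if level not in {"vegetable", "province"}:
        raise ConfigError(f"level must be 'vegetable' or 'province', got {level!r}")
    if s_weights not in {W_BATCHES, W_NONCOMPLIANT}:
        raise ConfigError(f"unknown s_weights {s_weights!r}")
    if strata.empty:
        return pd.DataFrame(
            columns=["rank", level, "group_count", "n", "m", "p", "s", "ir", "risk_class"]
        )
    df = strata.copy()
    w = df["n"] if s_weights == W_BATCHES else df["m"]
    df["_sw"] = df["s"] * w
    df["_w"] = w
    g = df.groupby(level, sort=True)
    out = g.agg(
        group_count=("n", "size"),
        n=("n", "sum"),
        m=("m", "sum"),
        sw=("_sw", "sum"),
        w=("_w", "sum"),
    ).reset_index()
    out["p"] = out["m"] / out["n"]
    with np.errstate(invalid="ignore", divide="ignore"):
        s = out["sw"] / out["w"]
    out["s"] = np.where(out["w"] > 0, s, 0.0)
    out["ir"] = out["p"] * out["s"]
    out["risk_class"] = [classify(v, threshold) for v in out["ir"]]
    out = out.sort_values(
        ["ir", "n", level], ascending=[False, False, True], kind="mergesort"
    ).reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out.drop(columns=["sw", "w"])


def provincial_yearly_risk(
    assessments: pd.DataFrame,
    s_denominator: str = S_NONCOMPLIANT,
    vegetable: str | None = None,
) -> pd.DataFrame:
    """Province-level IR per year, the weights of the spatial centroid.

    With ``vegetable`` set, restricts to that category (category-specific
    centroid); otherwise pools all vegetables per province and year.
    Returns columns year, province, n, m, p, s, ir.
    """
    df = assessments
    if vegetable is not None:
        df = df[df["vegetable"] == vegetable]
    strata = stratum_risk(df, s_denominator=s_denominator, by=("year", "province", "vegetable"))
    if strata.empty:
        return pd.DataFrame(columns=["year", "province", "n", "m", "p", "s", "ir"])
    rows = []
    for year, sub in strata.groupby("year", sort=True):
        agg = aggregate(sub, "province")
        agg.insert(0, "year", year)
        rows.append(agg[["year", "province", "n", "m", "p", "s", "ir"]])
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Summary tables


def top_share(counts: pd.Series, n: int = 5) -> float:
    """Share (fraction) held by the n largest values of a count series."""
    total = counts.sum()
    if total == 0:
        return 0.0
    return float(counts.sort_values(ascending=False).head(n).sum() / total)


def composition_stats(assessments: pd.DataFrame, top_n: int = 5) -> dict[str, pd.DataFrame]:
    """Sampling-share and exceedance-composition tables.

    Returns:
      * ``batch_share_vegetable`` / ``batch_share_province`` — sampled-batch
        counts with each key's share of the total;
      * ``exceedance_by_pesticide`` — non-compliant batch counts by trigger
        pesticide with shares of all non-compliant batches;
      * ``exceedance_share_vegetable`` — non-compliant counts and shares by
        vegetable;
      * ``top_shares`` — one-row summary with the pooled share of the top-N
        keys in each table.
    """
    def share_table(series: pd.Series, key: str) -> pd.DataFrame:
        counts = series.value_counts()
        t = counts.rename("count").rename_axis(key).reset_index()
        total = t["count"].sum()
        t["share"] = t["count"] / total if total else 0.0
        t.insert(0, "rank", np.arange(1, len(t) + 1))
        return t

    nc = assessments[~assessments["compliant"].astype(bool)]
    tables = {
        "batch_share_vegetable": share_table(assessments["vegetable"], "vegetable"),
        "batch_share_province": share_table(assessments["province"], "province"),
        "exceedance_by_pesticide": share_table(
            nc["trigger_pesticide"].replace("", np.nan).dropna(), "pesticide"
        ),
        "exceedance_share_vegetable": share_table(nc["vegetable"], "vegetable"),
    }
    tables["top_shares"] = pd.DataFrame(
        [
            {
                "top_n": top_n,
                "vegetable_batch_share": tables["batch_share_vegetable"]["count"].head(top_n).sum()
                / max(len(assessments), 1),
                "province_batch_share": tables["batch_share_province"]["count"].head(top_n).sum()
                / max(len(assessments), 1),
                "pesticide_exceedance_share": tables["exceedance_by_pesticide"]["count"].head(top_n).sum()
                / max(len(nc), 1),
            }
        ]
    )
    return tables


def descriptive_stats(strata: pd.DataFrame) -> pd.DataFrame:
    """Mean / sd / min / max of P, S and IR over the stratum list.

    Sample standard deviation (ddof=1); a single stratum reports sd 0.
    """
    if strata.empty:
        raise ConfigError("descriptive_stats requires at least one stratum")
    rows = []
    for var in ("p", "s", "ir"):
        x = strata[var].to_numpy(dtype=float)
        sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        rows.append(
            {
                "variable": var,
                "obs": len(x),
                "mean": float(np.mean(x)),
                "sd": sd,
                "min": float(np.min(x)),
                "max": float(np.max(x)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reporting-boundary rounding


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up (report rendering only; internals stay exact)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def render_risk_table(table: pd.DataFrame, level: str) -> pd.DataFrame:
    """Render an aggregate table at report precision.

    P as a percentage with two decimals, S and IR to three decimals,
    round-half-up — applied only at this reporting boundary.
    """
    out = table.copy()
    out["p_pct"] = [round_half_up(v * 100, 2) for v in out["p"]]
    out["s"] = [round_half_up(v, 3) for v in out["s"]]
    out["ir"] = [round_half_up(v, 3) for v in out["ir"]]
    cols = ["rank", level, "group_count", "n", "m", "p_pct", "s", "ir", "risk_class"]
    return out[cols]
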