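"""Per-sample compliance classification and worst-case hazard scoring.

A sampled batch is **non-compliant** when any residue strictly exceeds its
maximum residue limit (MRL) or when a banned pesticide is detected at all.
The batch's hazard score follows the worst-case principle: the maximum of
the concentration-to-limit ratios over its violating measurements,

    S = max_k C_k / MRL_k ,

so S = 1 marks the acceptable maximum (equality with the limit is compliant,
hazard 0) and larger values mean proportionally worse exceedances. Banned
substances without a tolerance are scored against a small policy reference
limit and floored at 1, so any banned detection contributes at least the
acceptable-maximum hazard.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .ingest import (
    BANNED,
    LIMIT,
    NO_LIMIT,
    ConfigError,
    InspectionRecord,
    LimitBinding,
    MRLTable,
    match_mrl,
)

#: trigger kinds
OVER_LIMIT, BANNED_DETECTION, NONE = "over-limit", "banned-detection", "none"


@dataclass(frozen=True)
class CompliancePolicy:
    """Scoring conventions for cases the standards leave open.

    banned_reference_mgkg
        Reference limit Q (mg/kg) used to score detections of banned
        substances that carry no tolerance; their hazard is max(C/Q, floor).
    banned_floor
        Minimum hazard contribution of any banned detection (default 1.0,
        the acceptable-maximum hazard; set 0 for the plain ratio).
    no_limit_policy
        What a detection with no applicable standard means: ``"ignore"``
        (not a violation; no limit exists to exceed) or ``"error"``.
    """

    banned_reference_mgkg: float = 0.01
    banned_floor: float = 1.0
    no_limit_policy: str = "ignore"

    def __post_init__(self) -> None:
        if not (self.banned_reference_mgkg > 0):
            raise ConfigError("banned_reference_mgkg must be positive")
        if self.banned_floor < 0:
            raise ConfigError("banned_floor must be non-negative")
        if self.no_limit_policy not in {"ignore", "error"}:
            raise ConfigError("no_limit_policy must be 'ignore' or 'error'")


@dataclass(frozen=True)
class SampleAssessment:
    """Outcome of screening one batch against its limits."""

    batch_id: str
    province: str
    vegetable: str
    year: int
    compliant: bool
    hazard: float  # 0 when compliant; worst-case ratio otherwise
    trigger_pesticide: Optional[str] = None
    trigger_kind: str = NONE


class UnboundMeasurementError(ConfigError):
    """A measurement reached assessment without a limit binding."""


def assess_sample(
    record: InspectionRecord,
    bindings: Sequence[LimitBinding],
    policy: CompliancePolicy | None = None,
) -> SampleAssessment:
    """Classify one batch and compute its worst-case hazard score.

    ``bindings`` must cover exactly the record's measurements (as produced by
    :func:`vegrisk.ingest.match_mrl`). A batch with no detections is
    compliant with hazard 0. Equality with the limit (C == MRL) is compliant;
    exceedance requires C strictly greater than MRL.
    """
    policy = policy or CompliancePolicy()
    if len(bindings) != len(record.measurements):
        raise UnboundMeasurementError(
            f"batch {record.batch_id}: {len(record.measurements)} measurements "
            f"but {len(bindings)} bindings"
        )

    # (ratio, kind, pesticide) for every violating measurement
    violations: list[tuple[float, str, str]] = []
    for b in bindings:
        c = b.measurement.concentration
        if b.kind == LIMIT:
            assert b.entry is not None and b.entry.mrl is not None
            if c > b.entry.mrl:  # strict: C == MRL is compliant
                violations.append((c / b.entry.mrl, OVER_LIMIT, b.measurement.pesticide))
        elif b.kind == BANNED:
            # any detection of a banned substance is a violation
            assert b.entry is not None
            ref = b.entry.mrl if b.entry.mrl is not None else policy.banned_reference_mgkg
            violations.append(
                (max(c / ref, policy.banned_floor), BANNED_DETECTION, b.measurement.pesticide)
            )
        elif b.kind == NO_LIMIT:
            if policy.no_limit_policy == "error":
                raise UnboundMeasurementError(
                    f"batch {record.batch_id}: no limit configured for "
                    f"{b.measurement.pesticide!r} on {record.vegetable!r}"
                )
        else:  # pragma: no cover - binding kinds are closed
            raise UnboundMeasurementError(
                f"batch {record.batch_id}: unknown binding kind {b.kind!r} "
                f"for {b.measurement.pesticide!r}"
            )

    if not violations:
        return SampleAssessment(
            batch_id=record.batch_id,
            province=record.province,
            vegetable=record.vegetable,
            year=record.year,
            compliant=True,
            hazard=0.0,
        )
    # worst case wins; exact-ratio ties broken by kind then name so the
    # outcome never depends on measurement order
    ratio, kind, pesticide = min(
        violations, key=lambda v: (-v[0], v[1] != BANNED_DETECTION, v[2])
    )
    return SampleAssessment(
        batch_id=record.batch_id,
        province=record.province,
        vegetable=record.vegetable,
        year=record.year,
        compliant=False,
        hazard=ratio,
        trigger_pesticide=pesticide,
        trigger_kind=kind,
    )


def assess_records(
    records: Iterable[InspectionRecord],
    mrl_table: MRLTable,
    policy: CompliancePolicy | None = None,
) -> pd.DataFrame:
    """Screen every batch; returns the assessment table.

    Columns: batch_id, province, vegetable, year, compliant, hazard,
    trigger_pesticide, trigger_kind — the dialect consumed by the risk-index
    stage.
    """
    policy = policy or CompliancePolicy()
    rows = []
    for r in records:
        a = assess_sample(r, match_mrl(r, mrl_table), policy)
        rows.append(
            (a.batch_id, a.province, a.vegetable, a.year, a.compliant,
             a.hazard, a.trigger_pesticide or "", a.trigger_kind)
        )
    return pd.DataFrame(
        rows,
        columns=["batch_id", "province", "vegetable", "year", "compliant",
                 "hazard", "trigger_pesticide", "trigger_kind"],
    )
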