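"""Domain types, delimited-text I/O and shared configuration.

Fish and otolith records arrive as UTF-8 delimited text (comma by
default, tab accepted) with a mandatory header row. Ring radii are
packed ``;``-separated inside a single field. Rows violating a record
invariant are rejected, not fixed, and each rejection is logged exactly
once with a machine-readable reason code.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("scarid")

SEXES = {"male", "female", "unknown"}
STAGES = {"immature", "developing", "spawning_capable", "regressing", "regenerating"}
MATURE_STAGES = STAGES - {"immature"}
STRATA = {"inshore", "offshore"}
GEARS = {"gillnet", "spear"}

FISH_COLUMNS = [
    "fish_id",
    "total_length",
    "total_weight",
    "sex",
    "stage",
    "gonad_weight",
    "capture_date",
    "stratum",
    "gear",
    "eviscerated",
]
OTOLITH_COLUMNS = [
    "fish_id",
    "reading_id",
    "ring_radii",
    "otolith_radius",
    "otolith_weight",
    "capture_month",
]


@dataclass
class FishRecord:
    """One sampled fish from a landing or collection event.

    Lengths are total length (TL) in cm, weights in g. ``stage`` follows
    the five-phase gonad classification; every phase other than
    ``immature`` counts as sexually mature (adult).
    """

    fish_id: str
    total_length: float
    total_weight: float | None = None
    sex: str = "unknown"
    stage: str | None = None
    gonad_weight: float | None = None
    capture_date: date | None = None
    stratum: str | None = None
    gear: str | None = None
    eviscerated: bool = False

    @property
    def capture_month(self) -> int | None:
        return None if self.capture_date is None else self.capture_date.month

    @property
    def mature(self) -> bool | None:
        """True for any stage past immature; None when stage missing."""
        if self.stage is None:
            return None
        return self.stage in MATURE_STAGES

    def validate(self) -> str | None:
        """Return a reason code if an invariant fails, else None."""
        if not np.isfinite(self.total_length) or self.total_length <= 0:
            return "nonpositive_length"
        if self.total_weight is not None and self.total_weight <= 0:
            return "nonpositive_weight"
        if (
            self.gonad_weight is not None
            and self.total_weight is not None
            and self.gonad_weight >= self.total_weight
        ):
            return "gonad_exceeds_total"
        if self.gonad_weight is not None and self.gonad_weight < 0:
            return "negative_gonad_weight"
        if self.sex not in SEXES:
            return "unknown_sex_code"
        if self.stage is not None and self.stage not in STAGES:
            return "unknown_stage_code"
        if self.stratum is not None and self.stratum not in STRATA:
            return "unknown_stratum"
        if self.gear is not None and self.gear not in GEARS:
            return "unknown_gear"
        return None


@dataclass
class OtolithRecord:
    """One reading of one sagittal otolith.

    ``ring_radii`` are core-to-ring distances (mm) along the reading
    axis, strictly increasing; ``otolith_radius`` is core-to-edge along
    the same axis, so the margin ``otolith_radius - ring_radii[-1]`` is
    non-negative.
    """

    fish_id: str
    reading_id: int
    ring_radii: tuple[float, ...]
    otolith_radius: float
    otolith_weight: float | None = None
    capture_month: int | None = None

    @property
    def ring_count(self) -> int:
        return len(self.ring_radii)

    def validate(self) -> str | None:
        radii = np.asarray(self.ring_radii, dtype=float)
        if radii.size and not np.all(np.diff(radii) > 0):
            return "radii_not_increasing"
        if radii.size and radii[0] <= 0:
            return "nonpositive_radius"
        if self.otolith_radius <= 0:
            return "nonpositive_otolith_radius"
        if radii.size and radii[-1] > self.otolith_radius + 1e-9:
            return "ring_beyond_edge"
        if self.reading_id not in (1, 2):
            return "bad_reading_id"
        if self.capture_month is not None and not 1 <= self.capture_month <= 12:
            return "bad_month"
        return None


@dataclass
class AnalysisConfig:
    """Knobs shared by the analysis stages.

    ``mcmc_iterations`` is the total number of posterior draws before
    thinning; ``thin``/``burn_in_fraction`` mirror the 1:100 thinning
    ratio of the field-standard long-chain setup at desk scale.
    ``m_coefficients`` are (a, b) of the empirical natural-mortality
    law ln(M) = a + b·ln(tmax); the default is the maximum-age form
    M = 4.899·tmax^-0.916.
    """

    length_bin_width: float = 5.0
    mcmc_iterations: int = 100_000
    thin: int = 100
    burn_in_fraction: float = 0.10
    seed: int = 0
    m_coefficients: tuple[float, float] = (float(np.log(4.899)), -0.916)
    z_method: str = "chapman_robson"  # or "catch_curve"
    reading_used: str = "2"  # "1", "2" or "mean"
    abi_exponent_mode: str = "estimate"  # or "fixed"
    abi_exponent: float = 1.0
    credible_level: float = 0.90
    mir_max_length: float = 50.0
    biological_intercept_length: float = 13.5
    biological_intercept_radius: float | None = None

    def __post_init__(self) -> None:
        if self.length_bin_width <= 0:
            raise ValueError("length_bin_width must be positive")
        if min(self.mcmc_iterations, self.thin) <= 0:
            raise ValueError("MCMC counts must be positive")
        if not 0 < self.credible_level < 1:
            raise ValueError("credible_level must lie in (0, 1)")
        if self.z_method not in {"chapman_robson", "catch_curve"}:
            raise ValueError(f"unknown z_method {self.z_method!r}")
        if self.reading_used not in {"1", "2", "mean"}:
            raise ValueError(f"unknown reading_used {self.reading_used!r}")


@dataclass
class RejectionLog:
    """Accumulates (row_number, reason_code) pairs, each row once."""

    rejected: list[tuple[int, str]] = field(default_factory=list)

    def reject(self, row: int, reason: str) -> None:
        self.rejected.append((row, reason))
        logger.warning("row %d rejected: %s", row, reason)

    def __len__(self) -> int:
        return len(self.rejected)


# ---------------------------------------------------------------------------
# delimited-text readers / writers
# ---------------------------------------------------------------------------


def _sniff_delimiter(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _parse_optional_float(text: str) -> float | None:
    text = text.strip()
    return None if text in ("", "NA", "nan") else float(text)


def _parse_date(text: str) -> date:
    return datetime.strptime(text.strip(), "%Y-%m-%d").date()


def read_fish_table(
    path: str | Path, log: RejectionLog | None = None
) -> list[FishRecord]:
    """Read per-fish records from a delimited text file.

    Rows violating record invariants (e.g. gonad weight at or above
    total weight, non-positive length) or with unparsable dates are
    rejected and logged with their 1-based data row number. A missing
    mandatory column raises ``ValueError`` naming the column.
    """
    path = Path(path)
    log = log if log is not None else RejectionLog()
    records: list[FishRecord] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=_sniff_delimiter(path))
        header = reader.fieldnames or []
        for col in FISH_COLUMNS:
            if col not in header:
                raise ValueError(f"missing mandatory column: {col}")
        for i, row in enumerate(reader, start=1):
            try:
                rec = FishRecord(
                    fish_id=row["fish_id"].strip(),
                    total_length=float(row["total_length"]),
                    total_weight=_parse_optional_float(row["total_weight"]),
                    sex=row["sex"].strip() or "unknown",
                    stage=row["stage"].strip() or None,
                    gonad_weight=_parse_optional_float(row["gonad_weight"]),
                    capture_date=(
                        _parse_date(row["capture_date"])
                        if row["capture_date"].strip()
                        else None
                    ),
                    stratum=row["stratum"].strip() or None,
                    gear=row["gear"].strip() or None,
                    eviscerated=row["eviscerated"].strip().lower()
                    in ("1", "true", "yes"),
                )
            except ValueError:
                log.reject(i, "unparsable_field")
                continue
            reason = rec.validate()
            if reason is not None:
                log.reject(i, reason)
                continue
            records.append(rec)
    logger.info("read %d fish records from %s (%d rejected)", len(records), path, len(log))
    return records


def write_fish_table(records: Iterable[FishRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(FISH_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.fish_id,
                    f"{r.total_length:.2f}",
                    "" if r.total_weight is None else f"{r.total_weight:.2f}",
                    r.sex,
                    r.stage or "",
                    "" if r.gonad_weight is None else f"{r.gonad_weight:.4f}",
                    "" if r.capture_date is None else r.capture_date.isoformat(),
                    r.stratum or "",
                    r.gear or "",
                    "1" if r.eviscerated else "0",
                ]
            )


def read_otolith_table(
    path: str | Path, log: RejectionLog | None = None
) -> list[OtolithRecord]:
    """Read per-(fish, reading) otolith rows; radii packed ``;``-separated.

    Non-increasing radii reject the row. Readings are left unsorted;
    pair them per fish with :func:`pair_readings`.
    """
    path = Path(path)
    log = log if log is not None else RejectionLog()
    records: list[OtolithRecord] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=_sniff_delimiter(path))
        header = reader.fieldnames or []
        for col in OTOLITH_COLUMNS:
            if col not in header:
                raise ValueError(f"missing mandatory column: {col}")
        for i, row in enumerate(reader, start=1):
            try:
                packed = row["ring_radii"].strip()
                radii = tuple(float(x) for x in packed.split(";") if x.strip()) if packed else ()
                month = row["capture_month"].strip()
                rec = OtolithRecord(
                    fish_id=row["fish_id"].strip(),
                    reading_id=int(row["reading_id"]),
                    ring_radii=radii,
                    otolith_radius=float(row["otolith_radius"]),
                    otolith_weight=_parse_optional_float(row["otolith_weight"]),
                    capture_month=int(month) if month else None,
                )
            except ValueError:
                log.reject(i, "unparsable_field")
                continue
            reason = rec.validate()
            if reason is not None:
                log.reject(i, reason)
                continue
            records.append(rec)
    logger.info(
        "read %d otolith readings from %s (%d rejected)", len(records), path, len(log)
    )
    return records


def write_otolith_table(records: Iterable[OtolithRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(OTOLITH_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.fish_id,
                    r.reading_id,
                    ";".join(f"{x:.4f}" for x in r.ring_radii),
                    f"{r.otolith_radius:.4f}",
                    "" if r.otolith_weight is None else f"{r.otolith_weight:.4f}",
                    "" if r.capture_month is None else r.capture_month,
                ]
            )


def pair_readings(
    records: Sequence[OtolithRecord],
) -> dict[str, dict[int, OtolithRecord]]:
    """Group otolith readings by fish_id, keyed by reading_id."""
    paired: dict[str, dict[int, OtolithRecord]] = {}
    for rec in records:
        paired.setdefault(rec.fish_id, {})[rec.reading_id] = rec
    return paired


# ---------------------------------------------------------------------------
# length-weight regression (imputes TW of eviscerated fish)
# ---------------------------------------------------------------------------


@dataclass
class LengthWeightFit:
    """TL->TW regression; linear in the raw scale or power-law (log-log).

    For ``model='power'`` slope/intercept are in log space:
    TW = exp(intercept)·TL^slope.
    """

    slope: float
    intercept: float
    r_squared: float
    n: int
    model: str = "linear"


def fit_length_weight(
    records: Sequence[FishRecord], model: str = "linear"
) -> LengthWeightFit:
    """Fit the TL-TW relation on records where both are present.

    Fewer than 3 complete pairs raises ``ValueError('insufficient data')``.
    """
    from scipy import stats

    pairs = [
        (r.total_length, r.total_weight)
        for r in records
        if r.total_weight is not None and not r.eviscerated
    ]
    if len(pairs) < 3:
        raise ValueError("insufficient data: need >=3 complete length-weight pairs")
    tl = np.array([p[0] for p in pairs])
    tw = np.array([p[1] for p in pairs])
    if model == "power":
        res = stats.linregress(np.log(tl), np.log(tw))
    elif model == "linear":
        res = stats.linregress(tl, tw)
    else:
        raise ValueError(f"unknown model {model!r}")
    return LengthWeightFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=len(pairs),
        model=model,
    )


def predict_weight_from_length(fit: LengthWeightFit, tl: float) -> float:
    """Predicted total weight (g) at total length ``tl`` (cm)."""
    if fit.model == "power":
        return float(np.exp(fit.intercept) * tl**fit.slope)
    return float(fit.intercept + fit.slope * tl)


def impute_eviscerated_weights(
    records: Sequence[FishRecord], fit: LengthWeightFit
) -> int:
    """Fill total_weight of eviscerated fish in place; returns count filled."""
    n = 0
    for r in records:
        if r.eviscerated:
            r.total_weight = predict_weight_from_length(fit, r.total_length)
            n += 1
    return n
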