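"""Conversion of brain/blood exposure measurements into log BB and binary calls.

log BB is the base-10 logarithm of the steady-state brain-to-blood (or
brain-to-plasma) concentration ratio.  For time-course studies the same ratio
is formed from the brain and plasma AUCs.  Compounds with log BB >= -1 are
scored permeable (1), below -1 non-permeable (0).  When a study reports
concentrations for several brain regions the regions are averaged before the
ratio is taken; when several independent studies score one compound the binary
scores are reconciled by a replicate policy (strict agreement by default).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

LOGBB_POSITIVE_CUTOFF = -1.0


class Score(enum.IntEnum):
    NEGATIVE = 0
    POSITIVE = 1


class Conflict(enum.Enum):
    """Sentinel for irreconcilable replicate scores."""

    CONFLICT = "conflict"


@dataclass(frozen=True)
class BBBMeasurement:
    """One experimental determination of brain exposure for one compound."""

    compound_id: str
    basis: str  # concentration_ratio | auc_ratio | precomputed_logbb
    brain_values: tuple[float, ...] = ()
    blood_value: float | None = None
    logbb: float | None = None
    species: str = "unknown"
    source_ref: str = ""

    def __post_init__(self) -> None:
        if self.basis == "precomputed_logbb":
            if self.logbb is None:
                raise ValueError("precomputed_logbb basis requires a logbb value")
        else:
            if not self.brain_values or self.blood_value is None:
                raise ValueError(f"{self.basis} basis requires brain_values and blood_value")


@dataclass
class ActivityRecord:
    """Per-compound scored activity after replicate resolution."""

    compound_id: str
    logbb_values: list[float] = field(default_factory=list)
    score: Score | Conflict = Conflict.CONFLICT
    n_sources: int = 1


def compute_logbb(brain: float, blood: float) -> float:
    """log10 of the brain/blood concentration (or AUC) ratio.

    Both inputs must be positive and expressed in the same units; the ratio is
    unit free.  Below-detection values must be resolved by the caller.
    """
    if not (brain > 0 and blood > 0):
        raise ValueError(f"brain and blood values must be > 0, got {brain!r}/{blood!r}")
    return math.log10(brain / blood)


def aggregate_brain_regions(brain_values: Sequence[float], *, log_space: bool = False) -> float:
    """Average per-region brain concentrations into a single value.

    Averaging happens on the concentration scale by default; ``log_space=True``
    switches to a geometric mean for studies best summarised multiplicatively.
    """
    if len(brain_values) == 0:
        raise ValueError("cannot average an empty list of brain regions")
    values = np.asarray(brain_values, dtype=float)
    if np.any(values <= 0):
        raise ValueError("brain region concentrations must be > 0")
    if log_space:
        return float(np.exp(np.mean(np.log(values))))
    return float(np.mean(values))


def binarize_logbb(logbb: float) -> int:
    """Binary permeability call: 1 iff log BB >= -1 (boundary inclusive)."""
    if not math.isfinite(logbb):
        raise ValueError(f"log BB must be finite, got {logbb!r}")
    return int(logbb >= LOGBB_POSITIVE_CUTOFF)


def measurement_logbb(measurement: BBBMeasurement, *, log_space_regions: bool = False) -> float:
    """log BB of one measurement, averaging brain regions first if needed."""
    if measurement.basis == "precomputed_logbb":
        assert measurement.logbb is not None
        return float(measurement.logbb)
    brain = aggregate_brain_regions(measurement.brain_values, log_space=log_space_regions)
    assert measurement.blood_value is not None
    return compute_logbb(brain, measurement.blood_value)


def resolve_replicates(scores: Sequence[int], policy: str = "strict") -> Score | Conflict:
    """Reconcile independent binary scores for one compound.

    strict   -- unanimity required; any disagreement is a conflict (the
                compound is excluded from training unless manually resolved).
    majority -- strict majority wins; exact tie is a conflict.
    """
    if len(scores) == 0:
        raise ValueError("cannot resolve an empty replicate list")
    if any(s not in (0, 1) for s in scores):
        raise ValueError("replicate scores must be 0 or 1")
    n_pos = sum(scores)
    n = len(scores)
    if policy == "strict":
        if n_pos == n:
            return Score.POSITIVE
        if n_pos == 0:
            return Score.NEGATIVE
        return Conflict.CONFLICT
    if policy == "majority":
        if 2 * n_pos > n:
            return Score.POSITIVE
        if 2 * n_pos < n:
            return Score.NEGATIVE
        return Conflict.CONFLICT
    raise ValueError(f"unknown replicate policy {policy!r}")


def score_measurements(
    measurements: Iterable[BBBMeasurement],
    policy: str = "strict",
    *,
    log_space_regions: bool = False,
) -> list[ActivityRecord]:
    """Score a stream of measurements into per-compound activity records.

    Each measurement is converted to log BB and binarized independently;
    per-compound binary scores are then resolved under ``policy``.
    """
    by_compound: dict[str, list[float]] = {}
    for m in measurements:
        by_compound.setdefault(m.compound_id, []).append(
            measurement_logbb(m, log_space_regions=log_space_regions)
        )
    records = []
    for compound_id, logbbs in by_compound.items():
        binary = [binarize_logbb(v) for v in logbbs]
        records.append(
            ActivityRecord(
                compound_id=compound_id,
                logbb_values=logbbs,
                score=resolve_replicates(binary, policy),
                n_sources=len(logbbs),
            )
        )
    return records


# ---------------------------------------------------------------------------
# CSV interfaces


def read_measurements_csv(path) -> list[BBBMeasurement]:
    """Read measurements from CSV.

    Expected columns: compound_id, basis, brain_values (';'-separated),
    blood_value, logbb, species, ref.  Empty cells are treated as absent.
    """
    df = pd.read_csv(path, dtype={"compound_id": str})
    out = []
    for row in df.itertuples(index=False):
        brain_raw = getattr(row, "brain_values", None)
        brain: tuple[float, ...] = ()
        if isinstance(brain_raw, str) and brain_raw.strip():
            brain = tuple(float(x) for x in brain_raw.split(";"))
        elif isinstance(brain_raw, (int, float)) and not math.isnan(brain_raw):
            brain = (float(brain_raw),)
        blood = getattr(row, "blood_value", None)
        blood = None if blood is None or (isinstance(blood, float) and math.isnan(blood)) else float(blood)
        logbb = getattr(row, "logbb", None)
        logbb = None if logbb is None or (isinstance(logbb, float) and math.isnan(logbb)) else float(logbb)
        out.append(
            BBBMeasurement(
                compound_id=str(row.compound_id),
                basis=str(row.basis),
                brain_values=brain,
                blood_value=blood,
                logbb=logbb,
                species=str(getattr(row, "species", "unknown")),
                source_ref=str(getattr(row, "ref", "")),
            )
        )
    return out


def write_scores_csv(records: Sequence[ActivityRecord], path) -> None:
    """Write per-compound scored activity: compound_id, logbb, score."""
    rows = []
    for r in records:
        rows.append(
            {
                "compound_id": r.compound_id,
                "logbb": np.mean(r.logbb_values) if r.logbb_values else np.nan,
                "score": r.score.value if isinstance(r.score, Score) else "conflict",
                "n_sources": r.n_sources,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
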