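"""Panel-level statistics linking landscape topography to enzyme activity.

Given a panel of enzyme variants (wild type plus point mutants, each with an
ISR, a binding free energy ΔG_bind, a catalytic barrier ΔG‡ and an activity
ln(kcat/Km)), this module computes Pearson correlations between any pair of
fields, the conditional subsets used for them (variants whose barrier or
affinity lies within a tolerance of the wild type), hot-spot classification
by an ISR threshold, and the transition-state-theory relation that converts
the two free energies into an activity:

    ln(kcat/Km) = offset − (ΔG_bind + ΔG‡) / (R·T)

with ΔG_bind ≤ 0 favorable and ΔG‡ ≥ 0, so that tighter binding and a lower
barrier both raise the activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _scipy_stats

from .errors import InsufficientDataError, UsageError, ValidationError
from .io_formats import VariantRecord

__all__ = [
    "R_GAS_KCAL",
    "AnalysisResult",
    "HotSpotCall",
    "pearson_r",
    "spearman_r",
    "classify_hot_spots",
    "filter_by_reference",
    "correlate_panel",
    "activity_from_energies",
    "FIELD_ALIASES",
]

logger = logging.getLogger("isrscape")

#: Gas constant in kcal/(mol·K).
R_GAS_KCAL = 1.987204259e-3

#: Documented hot-spot threshold presets (unit-less ISR).
HOT_SPOT_PRESETS = {"ppe": 4.0, "phbh": 4.5}

FIELD_ALIASES = {
    "isr": "isr",
    "affinity": "binding_affinity",
    "binding_affinity": "binding_affinity",
    "barrier": "reaction_barrier",
    "reaction_barrier": "reaction_barrier",
    "activity": "ln_activity",
    "ln_activity": "ln_activity",
}


@dataclass(frozen=True)
class AnalysisResult:
    """Outcome of one correlation analysis over a (possibly filtered) panel."""

    x_field: str
    y_field: str
    subset_rule: str
    n_used: int
    pearson_r: float
    slope: float
    intercept: float


@dataclass(frozen=True)
class HotSpotCall:
    """Hot-spot decision for one variant: flagged iff isr < threshold (strict)."""

    variant_id: str
    isr: float
    threshold: float
    is_hot_spot: bool


def _check_pair(xs: Sequence[float], ys: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size != ys.size:
        raise UsageError(f"length mismatch: {xs.size} vs {ys.size}")
    if xs.size < 3:
        raise InsufficientDataError(f"need >= 3 pairs, got {xs.size}")
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        raise InsufficientDataError("zero variance in one of the inputs")
    return xs, ys


def pearson_r(xs: Sequence[float], ys: Sequence[float]) -> float:
    """Pearson product-moment correlation of two equal-length numeric lists."""
    xs, ys = _check_pair(xs, ys)
    return float(_scipy_stats.pearsonr(xs, ys).statistic)


def spearman_r(xs: Sequence[float], ys: Sequence[float]) -> float:
    """Spearman rank correlation (offered as an option; Pearson is the default)."""
    xs, ys = _check_pair(xs, ys)
    return float(_scipy_stats.spearmanr(xs, ys).statistic)


def classify_hot_spots(
    records: Sequence[VariantRecord], threshold: float = 4.0
) -> list[HotSpotCall]:
    """Flag variants whose ISR falls strictly below a threshold.

    A variant is a hot spot when its alanine substitution drops the ISR below
    the threshold, signalling a large loss of intrinsic specificity. The
    threshold is free; 4.0 (serine-protease-like panels) and 4.5
    (hydroxylase-like panels) are the documented presets
    (:data:`HOT_SPOT_PRESETS`). An ISR exactly equal to the threshold is NOT
    a hot spot.
    """
    calls = []
    for record in records:
        if record.isr is None:
            raise ValidationError(
                f"variant {record.variant_id!r} has no ISR; cannot classify"
            )
        calls.append(
            HotSpotCall(
                variant_id=record.variant_id,
                isr=record.isr,
                threshold=threshold,
                is_hot_spot=record.isr < threshold,
            )
        )
    return calls


def _resolve_field(field: str) -> str:
    try:
        return FIELD_ALIASES[field.strip().lower()]
    except KeyError:
        raise UsageError(
            f"unknown field {field!r}; expected one of {sorted(set(FIELD_ALIASES))}"
        )


def filter_by_reference(
    records: Sequence[VariantRecord], field: str, tolerance: float = 1.5
) -> list[VariantRecord]:
    """Keep variants whose ``field`` lies within ``tolerance`` of the wild type.

    ``field`` is ``"affinity"`` or ``"barrier"`` (kcal/mol); the comparison
    ``|value − value_WT| <= tolerance`` is inclusive, the wild type is always
    retained, and input order is preserved. Exactly one wild-type record is
    required and the field must be present on every record.
    """
    attr = _resolve_field(field)
    if attr not in ("binding_affinity", "reaction_barrier"):
        raise UsageError(f"filter field must be affinity or barrier, got {field!r}")
    if tolerance < 0:
        raise UsageError(f"tolerance must be >= 0, got {tolerance!r}")
    wild = [r for r in records if r.is_wild_type]
    if len(wild) != 1:
        raise ValidationError(
            f"expected exactly one wild-type record, found {len(wild)}"
        )
    reference = getattr(wild[0], attr)
    if reference is None:
        raise ValidationError(f"wild-type record is missing field {field!r}")
    kept = []
    for record in records:
        value = getattr(record, attr)
        if value is None:
            raise ValidationError(
                f"variant {record.variant_id!r} is missing field {field!r}"
            )
        if record.is_wild_type or abs(value - reference) <= tolerance:
            kept.append(record)
    return kept


def correlate_panel(
    records: Sequence[VariantRecord],
    x_field: str,
    y_field: str,
    subset: tuple[str, float] | None = None,
) -> AnalysisResult:
    """Pearson correlation and least-squares line between two panel fields.

    ``subset``, when given, is a ``(field, tolerance)`` pair applied through
    :func:`filter_by_reference` before correlating. Records missing either
    field are dropped per-analysis (pairwise deletion) and logged.
    """
    x_attr = _resolve_field(x_field)
    y_attr = _resolve_field(y_field)
    if subset is not None:
        field, tolerance = subset
        records = filter_by_reference(records, field, tolerance)
        rule = f"|{field} - {field}_WT| <= {tolerance} kcal/mol"
    else:
        rule = "none"

    xs, ys = [], []
    dropped = []
    for record in records:
        x = getattr(record, x_attr)
        y = getattr(record, y_attr)
        if x is None or y is None:
            dropped.append(record.variant_id)
        else:
            xs.append(x)
            ys.append(y)
    if dropped:
        logger.info(
            "correlate_panel(%s, %s): dropped %d records with missing fields: %s",
            x_field, y_field, len(dropped), ", ".join(dropped),
        )
    if len(xs) < 3:
        raise InsufficientDataError(
            f"only {len(xs)} usable records for {x_field} vs {y_field}; need >= 3"
        )
    r = pearson_r(xs, ys)
    fit = _scipy_stats.linregress(xs, ys)
    return AnalysisResult(
        x_field=x_attr,
        y_field=y_attr,
        subset_rule=rule,
        n_used=len(xs),
        pearson_r=r,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )


def activity_from_energies(
    dg_bind: float,
    dg_barrier: float,
    temperature: float = 298.15,
    offset: float = 0.0,
) -> float:
    """ln(kcat/Km) from a binding free energy and a catalytic barrier.

    Implements ``offset − (dg_bind + dg_barrier)/(R·T)`` with energies in
    kcal/mol and R in kcal/(mol·K): more favorable (more negative) binding
    and a lower barrier both raise the activity. With the default
    ``offset=0`` activities are meaningful only relative to one another.
    """
    if temperature <= 0:
        raise UsageError(f"temperature must be positive, got {temperature!r}")
    return float(offset - (dg_bind + dg_barrier) / (R_GAS_KCAL * temperature))
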