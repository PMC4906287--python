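"""Topography statistics of a binding energy landscape.

A docked decoy ensemble defines a landscape: the lowest-energy pose is the
native enzyme–substrate complex, and the remaining poses are non-native
decoys. The funnel toward the native state is summarized by

* the energy gap  δE = ⟨E_D⟩ − E_n  (decoy mean minus native energy), and
* the roughness   ΔE               (spread of the non-native energies),

whose ratio ISR = δE/ΔE (intrinsic specificity ratio) is unit-less and
invariant under any affine rescaling of the energies. A larger ISR means a
more funneled landscape: the native state is better discriminated from the
decoys. An optional configurational-entropy divisor generalizes the ratio to
δE/(ΔE·sqrt(2S)) for users who can supply S; by default ligand entropy
changes are ignored and the simple ratio is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import (
    DegenerateLandscapeError,
    InsufficientDataError,
    UnstableEstimateError,
    UsageError,
)
from .io_formats import DecoyEnsemble

__all__ = [
    "LandscapeStats",
    "IsrInterval",
    "landscape_stats",
    "isr_value",
    "bootstrap_isr",
]

logger = logging.getLogger("isrscape")

#: Smallest roughness (kcal/mol) treated as non-degenerate.
ROUGHNESS_EPS = 1e-12


@dataclass(frozen=True)
class LandscapeStats:
    """Summary statistics of one decoy ensemble's landscape (energies in kcal/mol)."""

    system_id: str
    e_native: float
    mean_decoy: float
    delta_gap: float
    roughness: float
    isr: float
    n_total: int
    n_decoys: int
    entropy_term: float | None = None


@dataclass(frozen=True)
class IsrInterval:
    """Percentile-bootstrap interval for an ensemble's ISR.

    ``lower <= upper`` always holds; ``lower <= point <= upper`` is not
    guaranteed by the percentile method and is not asserted.
    """

    point: float
    lower: float
    upper: float
    level: float
    n_boot: int
    n_degenerate: int
    seed: int


def isr_value(
    delta_gap: float, roughness: float, entropy_term: float | None = None
) -> float:
    """Intrinsic specificity ratio from a gap and a roughness (both kcal/mol).

    Returns ``delta_gap / roughness``, or ``delta_gap / (roughness *
    sqrt(2 * entropy_term))`` when a configurational-entropy term is given.
    A negative gap (anti-funneled landscape) is allowed and yields a negative
    ratio with a logged warning.
    """
    if roughness <= 0:
        raise DegenerateLandscapeError(
            f"roughness must be positive, got {roughness!r}"
        )
    if entropy_term is not None and entropy_term <= 0:
        raise UsageError(f"entropy_term must be positive, got {entropy_term!r}")
    if delta_gap < 0:
        logger.warning(
            "negative energy gap %.6g: anti-funneled landscape, ISR will be negative",
            delta_gap,
        )
    divisor = roughness
    if entropy_term is not None:
        divisor = roughness * np.sqrt(2.0 * entropy_term)
    return float(delta_gap / divisor)


def landscape_stats(
    ensemble: DecoyEnsemble,
    include_native_in_mean: bool = False,
    spread_estimator: Literal["sample_sd", "population_sd"] = "sample_sd",
) -> LandscapeStats:
    """Compute native energy, decoy mean, gap, roughness and ISR for one ensemble.

    The native pose is the single pose attaining the minimum energy (the first
    in file order on ties; the others remain decoys). By default the native is
    excluded from both the decoy mean and the roughness; pass
    ``include_native_in_mean=True`` for the all-states reading of the mean.
    The roughness is always estimated over the non-native set, with the sample
    standard deviation (n−1) by default.

    Raises :class:`InsufficientDataError` below 3 poses and
    :class:`DegenerateLandscapeError` when all decoys share one energy.
    """
    energies = ensemble.energies
    n = energies.size
    if n < 3:
        raise InsufficientDataError(
            f"system {ensemble.system_id!r}: need >= 3 poses (1 native + >= 2 decoys), got {n}"
        )
    if spread_estimator not in ("sample_sd", "population_sd"):
        raise UsageError(f"unknown spread_estimator {spread_estimator!r}")

    native_idx = int(np.argmin(energies))
    e_native = float(energies[native_idx])
    decoys = np.delete(energies, native_idx)

    mean_decoy = float(energies.mean() if include_native_in_mean else decoys.mean())
    ddof = 1 if spread_estimator == "sample_sd" else 0
    roughness = float(decoys.std(ddof=ddof))
    if roughness <= ROUGHNESS_EPS:
        raise DegenerateLandscapeError(
            f"system {ensemble.system_id!r}: all {decoys.size} decoys share energy "
            f"{decoys[0]:.6g} kcal/mol; ISR is undefined"
        )
    delta_gap = mean_decoy - e_native
    return LandscapeStats(
        system_id=ensemble.system_id,
        e_native=e_native,
        mean_decoy=mean_decoy,
        delta_gap=delta_gap,
        roughness=roughness,
        isr=isr_value(delta_gap, roughness),
        n_total=n,
        n_decoys=int(decoys.size),
    )


def bootstrap_isr(
    ensemble: DecoyEnsemble,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> IsrInterval:
    """Percentile-bootstrap interval for the ISR of one ensemble.

    The full ensemble is resampled with replacement ``n_boot`` times; each
    resample re-identifies its own native (minimum) pose and recomputes the
    ISR under the default convention (native excluded from the mean, sample
    standard deviation). Degenerate resamples (zero roughness) are skipped
    and counted; more than 50% of them raises
    :class:`UnstableEstimateError`. Identical seeds give identical intervals.
    """
    if n_boot < 100:
        raise UsageError(f"n_boot must be >= 100, got {n_boot}")
    if not 0.0 < level < 1.0:
        raise UsageError(f"level must be in (0, 1), got {level!r}")
    point = landscape_stats(ensemble).isr

    energies = ensemble.energies
    n = energies.size
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    resampled = energies[idx]

    # Closed form for "exclude one instance of the minimum": with m the
    # per-resample minimum, the decoy mean and sample variance follow from
    # the resample's sum and sum of squares.
    m = resampled.min(axis=1)
    s1 = resampled.sum(axis=1)
    s2 = np.square(resampled).sum(axis=1)
    n_d = n - 1
    mean_d = (s1 - m) / n_d
    var_d = (s2 - m * m - n_d * mean_d * mean_d) / (n_d - 1)
    var_d = np.maximum(var_d, 0.0)

    sd_d = np.sqrt(var_d)
    ok = sd_d > ROUGHNESS_EPS
    n_degenerate = int(n_boot - ok.sum())
    if n_degenerate > n_boot // 2:
        raise UnstableEstimateError(
            f"{n_degenerate}/{n_boot} bootstrap resamples were degenerate"
        )
    if n_degenerate:
        logger.info("bootstrap_isr: skipped %d degenerate resamples", n_degenerate)
    isr_boot = (mean_d[ok] - m[ok]) / sd_d[ok]

    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(isr_boot, [alpha, 1.0 - alpha])
    return IsrInterval(
        point=point,
        lower=float(lower),
        upper=float(upper),
        level=level,
        n_boot=n_boot,
        n_degenerate=n_degenerate,
        seed=seed,
    )
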