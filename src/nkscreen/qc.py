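"""Plate quality control and luminescence-interference diagnostics.

The assay window of a plate is summarized by the Z' statistic over the
negative controls (full donor, top of the window) and the substrate controls
(no donor, bottom of the window):

    Z' = 1 - (3*SD_negative + 3*SD_substrate) / (Average_negative - Average_substrate)

Z' = 1 is a perfect window; values near or below 0 mean the control bands
overlap and the plate is unusable. Standard deviations are sample SDs
(n - 1 denominator).

Interference checks ask whether a compound shifts the luciferase signal at
fixed donor: a nucleoside co-incubated with ATP (autoluminescence /
luciferase inhibition) or AMP titrated against the ATP standard curve.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .calibration import StandardCurve

__all__ = [
    "PlateQC",
    "InterferenceResult",
    "z_prime",
    "plate_qc",
    "interference_check",
    "amp_titration_check",
    "DEFAULT_SHIFT_THRESHOLD",
]

DEFAULT_SHIFT_THRESHOLD = 0.10


class QCError(ValueError):
    pass


@dataclass(frozen=True)
class PlateQC:
    plate_id: str
    avg_negative: float
    sd_negative: float
    avg_substrate: float
    sd_substrate: float
    z_prime: float


@dataclass(frozen=True)
class InterferenceResult:
    compound: str
    mean_with: float
    mean_without: float
    relative_shift: float
    interferes: bool


def z_prime(
    negatives: Sequence[float],
    substrates: Sequence[float],
    plate_id: str = "",
) -> PlateQC:
    """Z' factor of one plate from its negative and substrate control wells."""
    neg = np.asarray(negatives, dtype=float)
    sub = np.asarray(substrates, dtype=float)
    if neg.size < 2 or sub.size < 2:
        raise QCError(
            f"need >= 2 wells per control group, got {neg.size} and {sub.size}"
        )
    avg_n, avg_s = float(neg.mean()), float(sub.mean())
    if avg_n == avg_s:
        raise QCError("negative and substrate control means coincide; Z' undefined")
    sd_n = float(neg.std(ddof=1))
    sd_s = float(sub.std(ddof=1))
    z = 1.0 - (3.0 * sd_n + 3.0 * sd_s) / (avg_n - avg_s)
    return PlateQC(
        plate_id=plate_id,
        avg_negative=avg_n,
        sd_negative=sd_n,
        avg_substrate=avg_s,
        sd_substrate=sd_s,
        z_prime=z,
    )


def plate_qc(annotated) -> PlateQC:
    """Z' of an annotated plate table, pooling all negative/substrate controls."""
    neg = annotated.loc[annotated["role"] == "negative_control", "rlu"]
    sub = annotated.loc[annotated["role"] == "substrate_control", "rlu"]
    plate_id = str(annotated["plate_id"].iloc[0]) if len(annotated) else ""
    return z_prime(neg.to_list(), sub.to_list(), plate_id=plate_id)


def _welch_rejects(a: np.ndarray, b: np.ndarray, alpha: float) -> bool:
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        return bool(a.mean() != b.mean())
    p = stats.ttest_ind(a, b, equal_var=False).pvalue
    return bool(np.isfinite(p) and p < alpha)


def interference_check(
    with_compound: Sequence[float],
    without: Sequence[float],
    compound: str = "",
    shift_threshold: float = DEFAULT_SHIFT_THRESHOLD,
    alpha: float = 0.05,
    effect_floor: float = 0.05,
) -> InterferenceResult:
    """Does a co-incubated compound shift the luminescence at fixed donor?

    A compound interferes when the relative mean shift exceeds
    ``shift_threshold``, or when a Welch two-sample test rejects equality at
    ``alpha`` AND the shift still exceeds ``effect_floor`` (statistical
    significance alone is not enough for a practically irrelevant shift).
    """
    w = np.asarray(with_compound, dtype=float)
    wo = np.asarray(without, dtype=float)
    if w.size < 2 or wo.size < 2:
        raise QCError("need >= 2 replicates in each condition")
    mean_wo = float(wo.mean())
    if mean_wo <= 0:
        raise QCError("reference (without-compound) mean must be > 0")
    mean_w = float(w.mean())
    shift = (mean_w - mean_wo) / mean_wo
    interferes = abs(shift) > shift_threshold or (
        _welch_rejects(w, wo, alpha) and abs(shift) > effect_floor
    )
    return InterferenceResult(
        compound=compound,
        mean_with=mean_w,
        mean_without=mean_wo,
        relative_shift=shift,
        interferes=interferes,
    )


def amp_titration_check(
    series: Sequence[tuple[float, float, Sequence[float]]],
    curve: StandardCurve | None = None,
    shift_threshold: float = DEFAULT_SHIFT_THRESHOLD,
) -> list[InterferenceResult]:
    """Check mixed AMP/ATP standards against the expected pure-ATP signal.

    ``series`` holds (AMP uM, ATP uM, RLU replicates) levels. The expected
    signal for each level's ATP content comes from a fitted ATP standard
    curve if given, otherwise from the AMP-free level with the same ATP
    concentration (a hard error if neither reference exists). Levels whose
    mean deviates from the expectation by more than ``shift_threshold``
    (relative) are flagged as AMP interference.
    """
    if not series:
        raise QCError("empty AMP titration series")
    amp_free: dict[float, float] = {
        atp: float(np.mean(rlus)) for amp, atp, rlus in series if amp == 0
    }
    results = []
    for amp, atp, rlus in series:
        mean_obs = float(np.mean(rlus))
        if curve is not None:
            expected = curve.predict(atp)
        elif atp in amp_free:
            expected = amp_free[atp]
        else:
            raise QCError(
                f"no reference for level AMP {amp} uM / ATP {atp} uM: provide a "
                "fitted ATP curve or an AMP-free level at each ATP concentration"
            )
        label = f"AMP {amp:g} uM / ATP {atp:g} uM"
        if expected <= 0:
            # zero-ATP level: any signal at all is AMP-derived luminescence
            shift = 0.0 if mean_obs == 0 else float("inf")
        else:
            shift = (mean_obs - expected) / expected
        results.append(
            InterferenceResult(
                compound=label,
                mean_with=mean_obs,
                mean_without=expected,
                relative_shift=shift,
                interferes=abs(shift) > shift_threshold,
            )
        )
    return results
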