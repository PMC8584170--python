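"""Standard-curve fitting and phosphate-donor acceptance ranking.

The assay reads residual donor concentration off a linear standard curve
(ordinary least squares on all replicate points, intercept free). Donors are
ranked by their luminescence at a reference concentration relative to ATP;
donors at or below the acceptance floor (default 30 RLU) are not usable
substrates of the luciferase.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "DonorAcceptance",
    "InvertedConcentration",
    "fit_standard_curve",
    "fit_standard_curves",
    "invert_curve",
    "rank_donor_acceptance",
    "ACCEPTANCE_FLOOR_RLU",
]

ACCEPTANCE_FLOOR_RLU = 30.0


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class StandardCurve:
    """Fitted linear donor-concentration -> RLU model."""

    donor: str
    slope: float  # RLU per uM
    intercept: float  # RLU
    r_squared: float
    range: tuple[float, float]  # calibrated concentration range, uM
    n_points: int

    def predict(self, conc_uM: float) -> float:
        return self.slope * conc_uM + self.intercept


class InvertedConcentration(NamedTuple):
    value: float  # uM, clipped to [0, range max]
    extrapolated: bool


@dataclass(frozen=True)
class DonorAcceptance:
    donor: str
    signal_at_ref: float  # RLU at the reference concentration
    relative_signal: float  # fraction of the ATP signal
    accepted: bool


def fit_standard_curve(
    standards: Sequence[tuple[float, float]], donor: str
) -> StandardCurve:
    """OLS fit of RLU on concentration over all replicate points.

    r-squared is computed on the same replicate points (not on level means),
    so it reflects replicate scatter. Requires >= 3 distinct concentrations.
    """
    if len(standards) == 0:
        raise CalibrationError("no standard points")
    conc = np.asarray([c for c, _ in standards], dtype=float)
    rlu = np.asarray([r for _, r in standards], dtype=float)
    distinct = np.unique(conc)
    if distinct.size < 3:
        raise CalibrationError(
            f"need >= 3 distinct concentrations, got {distinct.size}"
        )
    if np.var(conc) == 0.0:
        raise CalibrationError("zero concentration variance")
    fit = stats.linregress(conc, rlu)
    # constant response has undefined correlation; report r^2 = 0 (no signal)
    r2 = float(fit.rvalue) ** 2
    if not np.isfinite(r2):
        r2 = 0.0
    return StandardCurve(
        donor=donor,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        range=(float(distinct.min()), float(distinct.max())),
        n_points=len(standards),
    )


def fit_standard_curves(annotated: pd.DataFrame) -> list[StandardCurve]:
    """Fit one curve per donor from the standard wells of an annotated table."""
    std = annotated[annotated["role"] == "standard"]
    curves = []
    for donor, grp in std.groupby("donor", sort=True):
        points = list(zip(grp["donor_conc_uM"].astype(float), grp["rlu"].astype(float)))
        curves.append(fit_standard_curve(points, donor=str(donor)))
    return curves


def invert_curve(curve: StandardCurve, rlu: float) -> InvertedConcentration:
    """Map an RLU back to concentration, clipping to the calibrated range.

    Values landing outside [range min, range max] are clipped into
    [0, range max] and flagged as extrapolated.
    """
    if curve.slope <= 0:
        raise CalibrationError(
            f"cannot invert curve for {curve.donor!r}: slope {curve.slope} <= 0"
        )
    raw = (rlu - curve.intercept) / curve.slope
    lo, hi = curve.range
    extrapolated = raw < lo or raw > hi
    return InvertedConcentration(value=min(hi, max(0.0, raw)), extrapolated=extrapolated)


def rank_donor_acceptance(
    signals: Mapping[str, float],
    reference: str = "ATP",
    floor: float = ACCEPTANCE_FLOOR_RLU,
) -> list[DonorAcceptance]:
    """Rank donors by signal at the reference concentration, ATP-relative.

    Sorted by descending signal, ties broken alphabetically; a donor is
    accepted when its signal exceeds the floor.
    """
    if reference not in signals:
        raise CalibrationError(f"reference donor {reference!r} missing from signals")
    ref_signal = float(signals[reference])
    if ref_signal <= 0:
        raise CalibrationError(f"reference donor {reference!r} has no signal")
    ranked = sorted(signals.items(), key=lambda kv: (-float(kv[1]), kv[0]))
    return [
        DonorAcceptance(
            donor=donor,
            signal_at_ref=float(sig),
            relative_signal=float(sig) / ref_signal,
            accepted=float(sig) > floor,
        )
        for donor, sig in ranked
    ]


def curves_to_frame(curves: Iterable[StandardCurve]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "donor": c.donor,
                "slope": c.slope,
                "intercept": c.intercept,
                "r_squared": c.r_squared,
                "range_min": c.range[0],
                "range_max": c.range[1],
                "n_points": c.n_points,
            }
            for c in curves
        ]
    )
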