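"""HPLC peak-area quantification and luminescence cross-validation.

Peaks are assigned analyte identities by nearest retention-time match within
a tolerance. Quantification is ratio-based within a pool, so it needs no
response calibration:

    consumed ATP [%] = (1 - A_ATP / (A_ATP + A_ADP + A_AMP)) * 100
    product      [%] = sum(P_product) / (P_substrate + sum(P_product)) * 100

The comparison against luminescence results reports per-group absolute
deviations in percentage points; agreement within single-digit points is
what validates the plate assay.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .plate_io import Peak, PeakTable
from .quantification import ReactionResult

__all__ = [
    "RetentionLibrary",
    "MethodComparison",
    "annotate_peaks",
    "hplc_consumed_atp",
    "hplc_product",
    "quantify_peak_tables",
    "compare_methods",
    "ADENOSINE_POOL",
]

logger = logging.getLogger("nkscreen")

ADENOSINE_POOL = ("ATP", "ADP", "AMP")


class HplcError(ValueError):
    pass


@dataclass(frozen=True)
class RetentionLibrary:
    """Expected retention times per analyte with a matching tolerance."""

    entries: Mapping[str, float]  # analyte -> minutes
    tolerance: float = 0.3  # minutes

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise HplcError("tolerance must be > 0")
        if not self.entries:
            raise HplcError("empty retention library")
        items = sorted(self.entries.items(), key=lambda kv: kv[1])
        for (a1, t1), (a2, t2) in zip(items, items[1:]):
            if t2 - t1 <= 2 * self.tolerance:
                raise HplcError(
                    f"retention times of {a1!r} ({t1}) and {a2!r} ({t2}) are "
                    f"closer than 2x tolerance ({2 * self.tolerance})"
                )


@dataclass(frozen=True)
class MethodComparison:
    enzyme: str
    substrate: str
    donor: str
    product_lum_pct: float
    product_hplc_pct: float
    abs_deviation: float  # percentage points
    consumed_lum_pct: float
    consumed_hplc_pct: float


def annotate_peaks(table: PeakTable, library: RetentionLibrary) -> PeakTable:
    """Label peaks with the nearest library analyte within tolerance.

    Peaks with no entry in range stay unlabeled. When two peaks claim the
    same analyte the nearer one wins and the loser is unlabeled with a
    warning; two library entries equidistant from one peak is a method
    ambiguity and a hard error.
    """
    assignments: dict[int, str] = {}
    best_for_analyte: dict[str, tuple[float, int]] = {}
    for i, peak in enumerate(table.peaks):
        candidates = sorted(
            (
                (abs(peak.retention_time - t), analyte)
                for analyte, t in library.entries.items()
                if abs(peak.retention_time - t) <= library.tolerance
            )
        )
        if not candidates:
            continue
        if len(candidates) > 1 and candidates[0][0] == candidates[1][0]:
            raise HplcError(
                f"sample {table.sample_id!r}: peak at {peak.retention_time} min "
                f"is equidistant from {candidates[0][1]!r} and {candidates[1][1]!r}"
            )
        dist, analyte = candidates[0]
        prev = best_for_analyte.get(analyte)
        if prev is not None:
            prev_dist, prev_i = prev
            if dist < prev_dist:
                logger.warning(
                    "sample %s: peak at %s min displaced from %r by a nearer peak",
                    table.sample_id,
                    table.peaks[prev_i].retention_time,
                    analyte,
                )
                del assignments[prev_i]
            else:
                logger.warning(
                    "sample %s: peak at %s min left unlabeled, %r already matched",
                    table.sample_id,
                    peak.retention_time,
                    analyte,
                )
                continue
        best_for_analyte[analyte] = (dist, i)
        assignments[i] = analyte
    return PeakTable(
        sample_id=table.sample_id,
        peaks=[
            replace(p, analyte=assignments.get(i)) for i, p in enumerate(table.peaks)
        ],
    )


def hplc_consumed_atp(table: PeakTable) -> float:
    """Percent donor consumed from the adenosine-pool area ratio.

    Absent ADP/AMP peaks count as zero area (low-conversion samples often
    show none); a zero total pool is uninterpretable.
    """
    areas = {a: table.area_of(a) for a in ADENOSINE_POOL}
    total = sum(areas.values())
    if total <= 0:
        raise HplcError(
            f"sample {table.sample_id!r}: adenosine pool has zero total area"
        )
    return (1.0 - areas["ATP"] / total) * 100.0


def hplc_product(
    table: PeakTable, substrate: str, products: Sequence[str]
) -> float:
    """Percent product formed from the substrate/product area ratio."""
    if not products:
        raise HplcError("at least one product analyte must be declared")
    p_sum = sum(table.area_of(p) for p in products)
    total = table.area_of(substrate) + p_sum
    if total <= 0:
        raise HplcError(
            f"sample {table.sample_id!r}: substrate+product pool has zero total area"
        )
    return 100.0 * p_sum / total


def quantify_peak_tables(
    tables: Iterable[PeakTable],
    library: RetentionLibrary,
    substrate_products: Mapping[str, Sequence[str]],
    sample_substrates: Mapping[str, str],
) -> pd.DataFrame:
    """Annotate and quantify many samples at once.

    ``sample_substrates`` maps sample_id -> substrate analyte;
    ``substrate_products`` maps substrate -> its expected product analytes.
    Returns a frame with sample_id, consumed_hplc_pct, product_hplc_pct.
    """
    rows = []
    for table in tables:
        labeled = annotate_peaks(table, library)
        substrate = sample_substrates[table.sample_id]
        products = substrate_products[substrate]
        rows.append(
            {
                "sample_id": table.sample_id,
                "substrate": substrate,
                "consumed_hplc_pct": hplc_consumed_atp(labeled),
                "product_hplc_pct": hplc_product(labeled, substrate, products),
            }
        )
    return pd.DataFrame(rows)


def compare_methods(
    lum: Sequence[ReactionResult],
    hplc: Sequence[tuple[tuple[str, str, str], float, float]],
) -> tuple[list[MethodComparison], dict[str, float], list[tuple[str, str, str]]]:
    """Pair luminescence and HPLC results by (enzyme, substrate, donor).

    ``hplc`` holds (group key, consumed %, product %) entries. Returns the
    paired comparisons, a min/max/mean summary of the absolute product
    deviations (percentage points), and the keys seen by only one method
    (excluded from the summary). No shared group at all is a hard error.
    """
    lum_by_key = {(r.enzyme, r.substrate, r.donor): r for r in lum}
    hplc_by_key = {key: (consumed, product) for key, consumed, product in hplc}
    shared = sorted(set(lum_by_key) & set(hplc_by_key))
    if not shared:
        raise HplcError("no shared (enzyme, substrate, donor) groups to compare")
    unpaired = sorted(set(lum_by_key) ^ set(hplc_by_key))
    comparisons = []
    for key in shared:
        r = lum_by_key[key]
        consumed_h, product_h = hplc_by_key[key]
        comparisons.append(
            MethodComparison(
                enzyme=key[0],
                substrate=key[1],
                donor=key[2],
                product_lum_pct=r.product_pct,
                product_hplc_pct=product_h,
                abs_deviation=abs(r.product_pct - product_h),
                consumed_lum_pct=r.consumed_donor_pct,
                consumed_hplc_pct=consumed_h,
            )
        )
    devs = np.asarray([c.abs_deviation for c in comparisons])
    summary = {
        "min_deviation": float(devs.min()),
        "max_deviation": float(devs.max()),
        "mean_deviation": float(devs.mean()),
    }
    return comparisons, summary, unpaired
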