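"""Consumed-donor and product-formation quantification.

The percent of phosphate donor consumed in a kinase reaction is computed
from the luminescence of the reaction well against its same-plate controls:

    consumed [%] = 100 - 100 * (R + B + S) / (N + S)

where R is the mean reaction signal, N the mean negative control (no
enzyme), S the mean substrate control (no donor) and B = N - basal the
basal-activity correction (enzyme, no substrate), floored at 0. Product
(monophosphate) formation follows by multiplying with the donor:substrate
molar ratio (1.2 for the standard 0.4 mM / 0.33 mM setup). Both percentages
are restricted to 0-100%. Conversions between 0 and the verification
threshold (default 10%) are flagged for orthogonal confirmation (HPLC or a
repeat at higher enzyme load), since weak apparent consumption is where
false positives live.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ControlSet",
    "ReactionResult",
    "SpectrumMatrix",
    "consumed_donor",
    "product_formation",
    "stoichiometric_ratio",
    "quantify_plate",
    "build_spectrum",
    "results_to_frame",
    "DEFAULT_RATIO",
    "DEFAULT_VERIFY_THRESHOLD",
]

logger = logging.getLogger("nkscreen")

DEFAULT_RATIO = 1.2
DEFAULT_VERIFY_THRESHOLD = 10.0  # percent product below which to re-verify


class QuantificationError(ValueError):
    pass


def _clamp_pct(x: float) -> float:
    return min(100.0, max(0.0, x))


@dataclass(frozen=True)
class ControlSet:
    """Averaged same-plate control signals for one reaction group."""

    N: float  # mean negative control (no enzyme), RLU
    basal: float | None  # mean basal-activity control (no substrate), RLU
    S: float  # mean substrate control (no donor), RLU

    @property
    def B(self) -> float:
        """Basal correction N - basal, floored at 0 (0 if no basal control)."""
        if self.basal is None:
            return 0.0
        return max(0.0, self.N - self.basal)


@dataclass(frozen=True)
class ReactionResult:
    enzyme: str
    substrate: str
    donor: str
    R: float  # mean reaction RLU
    consumed_donor_pct: float
    product_pct: float
    n_replicates: int
    sd_pct: float
    flag_verify: bool


@dataclass
class SpectrumMatrix:
    """Enzyme x substrate matrix of percent product formation."""

    values: pd.DataFrame  # float, NaN where not screened
    flags: pd.DataFrame  # bool, True where verification is advised


def consumed_donor(R: float, controls: ControlSet) -> float:
    """Percent donor consumed for a mean reaction signal R, clamped to 0-100."""
    denom = controls.N + controls.S
    if denom <= 0:
        raise QuantificationError(
            f"uninterpretable plate: N + S = {denom} (must be > 0)"
        )
    return _clamp_pct(100.0 - 100.0 * (R + controls.B + controls.S) / denom)


def product_formation(consumed_pct: float, donor_substrate_ratio: float = DEFAULT_RATIO) -> float:
    """Percent product formed from percent donor consumed, clamped to 0-100."""
    if donor_substrate_ratio <= 0:
        raise QuantificationError(
            f"donor:substrate ratio must be > 0, got {donor_substrate_ratio}"
        )
    return _clamp_pct(consumed_pct * donor_substrate_ratio)


def stoichiometric_ratio(
    donor_conc_uM: float, substrate_conc_uM: float, sig_figs: int = 2
) -> float:
    """Donor:substrate molar ratio rounded to significant figures.

    The standard assay setup (400 uM donor, 330 uM nucleoside) gives 1.2,
    the conventional product-formation multiplier.
    """
    if donor_conc_uM <= 0 or substrate_conc_uM <= 0:
        raise QuantificationError("concentrations must be > 0")
    ratio = donor_conc_uM / substrate_conc_uM
    exponent = math.floor(math.log10(abs(ratio)))
    return round(ratio, sig_figs - 1 - exponent)


def _match_controls(
    annotated: pd.DataFrame, enzyme: str, substrate: str, donor: str
) -> ControlSet:
    """Assemble the control set a reaction group is entitled to.

    Negative controls share the group's substrate and donor (chemically they
    contain both); a donor-only negative control (no substrate) is accepted
    as a fallback. Substrate controls share the substrate; basal controls
    share enzyme and donor.
    """
    neg = annotated[
        (annotated["role"] == "negative_control")
        & (annotated["donor"] == donor)
        & (annotated["substrate"] == substrate)
    ]
    if neg.empty:
        neg = annotated[
            (annotated["role"] == "negative_control")
            & (annotated["donor"] == donor)
            & (annotated["substrate"].isna())
        ]
    if neg.empty:
        raise QuantificationError(
            f"group ({enzyme}, {substrate}, {donor}): no negative control on plate"
        )
    sub = annotated[
        (annotated["role"] == "substrate_control")
        & (annotated["substrate"] == substrate)
    ]
    if sub.empty:
        raise QuantificationError(
            f"group ({enzyme}, {substrate}, {donor}): no substrate control on plate"
        )
    bas = annotated[
        (annotated["role"] == "basal_control")
        & (annotated["enzyme"] == enzyme)
        & (annotated["donor"] == donor)
    ]
    basal: float | None
    if bas.empty:
        logger.warning(
            "group (%s, %s, %s): no basal control, B set to 0",
            enzyme,
            substrate,
            donor,
        )
        basal = None
    else:
        basal = float(bas["rlu"].mean())
    return ControlSet(N=float(neg["rlu"].mean()), basal=basal, S=float(sub["rlu"].mean()))


def quantify_plate(
    annotated: pd.DataFrame,
    ratio: float = DEFAULT_RATIO,
    verify_threshold: float = DEFAULT_VERIFY_THRESHOLD,
) -> list[ReactionResult]:
    """Quantify every reaction group of an annotated plate table.

    Controls are averaged first; the group mean R goes through the consumed
    and product equations with clamping after each. The replicate spread
    (sd_pct) pushes each replicate's RLU through both equations before a
    single final clamp, then takes the sample SD of the per-replicate
    product percentages.
    """
    reactions = annotated[annotated["role"] == "reaction"]
    results: list[ReactionResult] = []
    keys = (
        reactions[["enzyme", "substrate", "donor"]]
        .drop_duplicates()
        .sort_values(["enzyme", "substrate", "donor"])
    )
    for enzyme, substrate, donor in keys.itertuples(index=False):
        grp = reactions[
            (reactions["enzyme"] == enzyme)
            & (reactions["substrate"] == substrate)
            & (reactions["donor"] == donor)
        ]
        controls = _match_controls(annotated, enzyme, substrate, donor)
        rlus = grp["rlu"].astype(float).to_numpy()
        R = float(rlus.mean())
        consumed = consumed_donor(R, controls)
        product = product_formation(consumed, ratio)
        denom = controls.N + controls.S
        per_rep_raw = 100.0 - 100.0 * (rlus + controls.B + controls.S) / denom
        per_rep_product = np.clip(per_rep_raw * ratio, 0.0, 100.0)
        sd = float(np.std(per_rep_product, ddof=1)) if len(rlus) > 1 else 0.0
        results.append(
            ReactionResult(
                enzyme=str(enzyme),
                substrate=str(substrate),
                donor=str(donor),
                R=R,
                consumed_donor_pct=consumed,
                product_pct=product,
                n_replicates=len(rlus),
                sd_pct=sd,
                flag_verify=0.0 < product < verify_threshold,
            )
        )
    return results


def results_to_frame(results: Iterable[ReactionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "enzyme": r.enzyme,
                "substrate": r.substrate,
                "donor": r.donor,
                "R_mean_rlu": r.R,
                "consumed_pct": r.consumed_donor_pct,
                "product_pct": r.product_pct,
                "sd_pct": r.sd_pct,
                "n": r.n_replicates,
                "flag_verify": r.flag_verify,
            }
            for r in results
        ],
        columns=[
            "enzyme",
            "substrate",
            "donor",
            "R_mean_rlu",
            "consumed_pct",
            "product_pct",
            "sd_pct",
            "n",
            "flag_verify",
        ],
    )


def build_spectrum(results: Sequence[ReactionResult]) -> SpectrumMatrix:
    """Assemble the enzyme x substrate substrate-spectrum matrix.

    Cells are percent product formation (NaN where a pair was not screened);
    duplicate (enzyme, substrate) results — e.g. the same pair on two plates
    or with two donors — are averaged with a warning, and their verify flags
    are OR-combined.
    """
    enzymes = sorted({r.enzyme for r in results})
    substrates = sorted({r.substrate for r in results})
    values = pd.DataFrame(np.nan, index=enzymes, columns=substrates, dtype=float)
    flags = pd.DataFrame(False, index=enzymes, columns=substrates, dtype=bool)
    buckets: dict[tuple[str, str], list[ReactionResult]] = {}
    for r in results:
        buckets.setdefault((r.enzyme, r.substrate), []).append(r)
    for (enzyme, substrate), rs in buckets.items():
        if len(rs) > 1:
            logger.warning(
                "pair (%s, %s) screened %d times; averaging", enzyme, substrate, len(rs)
            )
        values.loc[enzyme, substrate] = float(np.mean([r.product_pct for r in rs]))
        flags.loc[enzyme, substrate] = any(r.flag_verify for r in rs)
    return SpectrumMatrix(values=values, flags=flags)
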