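"""Synthetic plates and chromatograms with known ground truth.

The generator emulates the statistical structure of a luciferase
ATP-depletion kinase screen so every downstream stage (calibration, QC,
quantification, HPLC cross-check) can be exercised against a known answer:

* a linear donor-concentration -> RLU response per phosphate donor, with
  donor-specific sensitivity matching the relative signals of the assay's
  luciferase (ATP by far the strongest, dATP/GTP/UTP/CTP weak, dGTP/dCTP/TTP
  at the noise floor);
* per-well multiplicative Gaussian noise (plate-reader repeatability);
* enzyme basal donor consumption without substrate (captured by the basal
  control and the B correction);
* minor nonenzymatic ATP degradation to AMP (~1% of the pool);
* a true conversion fraction per (enzyme, substrate) pair, the quantity the
  assay estimates.

A matched HPLC peak table routes the consumed donor to ADP, degradation to
AMP, and converted substrate to its monophosphate, so peak-area ratios carry
the same ground truth as the luminescence signals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .plate_io import (
    N_COLUMNS,
    ROWS,
    LuminescenceReading,
    PeakTable,
    Peak,
    PlateError,
    PlateLayout,
    Well,
    WellAddress,
)

__all__ = [
    "DonorResponseModel",
    "SimulationConfig",
    "default_donor_models",
    "default_screen",
    "simulate_plate",
    "simulate_screen",
    "simulate_peak_table",
    "simulate_standard_series",
    "expected_lum_quantification",
    "expected_hplc_quantification",
    "DEFAULT_TRUE_CONVERSION",
    "DEFAULT_RETENTION_TIMES",
    "DEFAULT_PRODUCTS",
]


@dataclass(frozen=True)
class DonorResponseModel:
    """Linear luminescence response RLU(c) = slope*c + intercept."""

    donor: str
    slope: float  # RLU per uM
    intercept: float = 0.0  # RLU at zero donor

    def __post_init__(self) -> None:
        if self.slope < 0 or self.intercept < 0:
            raise ValueError("slope and intercept must be nonnegative")

    def rlu(self, conc_uM: float) -> float:
        return self.slope * conc_uM + self.intercept


# Signals of the luciferase at 500 uM donor: ATP dominates by ~50x over the
# best alternative donor; dGTP/dCTP/TTP sit below the 30 RLU acceptance floor.
_DONOR_RLU_AT_500 = {
    "ATP": 57892.0,
    "dATP": 1128.0,
    "GTP": 504.0,
    "UTP": 220.0,
    "CTP": 161.0,
    "dGTP": 20.0,
    "dCTP": 20.0,
    "TTP": 20.0,
}


def default_donor_models() -> list[DonorResponseModel]:
    """Donor response models scaled to the assay's 500 uM reference signals."""
    return [
        DonorResponseModel(donor=d, slope=rlu / 500.0, intercept=0.0)
        for d, rlu in _DONOR_RLU_AT_500.items()
    ]


# Conversion fractions emulating a human deoxycytidine kinase natural-substrate
# panel: strong deoxynucleoside + cytidine turnover, a low thymidine side
# activity, and no detectable activity on Ado/Guo/Urd. Illustrative defaults.
DEFAULT_TRUE_CONVERSION: dict[tuple[str, str], float] = {
    ("HsdCK", "dCyd"): 0.97,
    ("HsdCK", "dAdo"): 0.95,
    ("HsdCK", "dGuo"): 0.88,
    ("HsdCK", "Cyd"): 0.85,
    ("HsdCK", "Thd"): 0.13,
    ("HsdCK", "Ado"): 0.0,
    ("HsdCK", "Guo"): 0.0,
    ("HsdCK", "Urd"): 0.0,
}

# Retention times (min). AMP/ADP/ATP are the chromatographic method's typical
# times; all other entries are SYNTHETIC placeholders for the simulator,
# spaced > 0.6 min apart so nearest-within-tolerance matching is unambiguous.
DEFAULT_RETENTION_TIMES: dict[str, float] = {
    "AMP": 8.2,
    "ADP": 15.4,
    "ATP": 22.9,
    # synthetic nucleoside-monophosphate times
    "CMP": 3.1,
    "UMP": 3.9,
    "TMP": 4.7,
    "dCMP": 5.5,
    "GMP": 6.3,
    "dGMP": 7.1,
    "dAMP": 9.4,
    # synthetic nucleoside times
    "Cyd": 2.3,
    "Urd": 10.3,
    "dCyd": 11.1,
    "Guo": 11.9,
    "dGuo": 12.7,
    "Thd": 13.5,
    "Ado": 17.0,
    "dAdo": 17.8,
}

# Expected monophosphate product per nucleoside substrate (single
# phosphorylation: the kinase transfers one phosphate).
DEFAULT_PRODUCTS: dict[str, str] = {
    "Ado": "AMP",
    "dAdo": "dAMP",
    "Guo": "GMP",
    "dGuo": "dGMP",
    "Cyd": "CMP",
    "dCyd": "dCMP",
    "Urd": "UMP",
    "Thd": "TMP",
}

DEFAULT_STANDARD_LEVELS = (0.0, 50.0, 100.0, 200.0, 300.0, 400.0, 500.0)


@dataclass
class SimulationConfig:
    """Study conditions of a simulated screen.

    Defaults mirror the assay protocol: 0.4 mM donor, 0.33 mM nucleoside,
    duplicate standards, triplicate reactions, ~2% basal donor consumption,
    ~1% nonenzymatic ATP degradation, 3% multiplicative measurement noise.
    """

    seed: int
    noise_cv: float = 0.03
    n_replicates: int = 3
    n_standard_replicates: int = 2
    donor_models: list[DonorResponseModel] = field(default_factory=default_donor_models)
    true_conversion: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_CONVERSION)
    )
    basal_consumption: float = 0.02
    atp_degradation: float = 0.01
    donor_conc: float = 400.0  # uM
    substrate_conc: float = 333.0  # uM
    standard_levels: tuple[float, ...] = DEFAULT_STANDARD_LEVELS
    substrate_autolum_rlu: float = 0.0  # optional autoluminescence injection
    hplc_area_scale: float = 1000.0  # arbitrary mAU*s per unit molar fraction

    def __post_init__(self) -> None:
        for name in ("basal_consumption", "atp_degradation"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for enz_sub, conv in self.true_conversion.items():
            if not 0.0 <= conv <= 1.0:
                raise ValueError(f"true_conversion{enz_sub} must be in [0, 1]")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.donor_conc <= 0 or self.substrate_conc <= 0:
            raise ValueError("donor_conc and substrate_conc must be > 0")

    def donor_model(self, donor: str) -> DonorResponseModel:
        for m in self.donor_models:
            if m.donor == donor:
                return m
        raise KeyError(f"no donor response model for {donor!r}")


def default_screen(config: SimulationConfig | None = None) -> list[tuple[str, str, str]]:
    """(enzyme, substrate, donor) triples of the default single-plate screen."""
    pairs = DEFAULT_TRUE_CONVERSION if config is None else config.true_conversion
    return [(e, s, "ATP") for (e, s) in pairs]


# ---------------------------------------------------------------------------
# closed-form mass balance (the oracle the estimators are checked against)

def _clamp(x: float, lo: float = 0.0, hi: float = 100.0) -> float:
    return min(hi, max(lo, x))


def _fractions(
    conv: float, config: SimulationConfig
) -> tuple[float, float, float, float]:
    """(enzymatic consumed, basal, degraded, residual) donor fractions."""
    f = min(1.0, conv * config.substrate_conc / config.donor_conc)
    b = config.basal_consumption
    d = config.atp_degradation
    resid = max(0.0, 1.0 - f - b - d)
    return f, b, d, resid


def expected_lum_quantification(
    conv: float, config: SimulationConfig, ratio: float = 1.2
) -> tuple[float, float]:
    """Noise-free (consumed %, product %) the luminescence pipeline returns.

    Derived from the control scheme: with S = 0 the percent consumed reduces
    to 100*(basal_signal - R)/N, i.e. the enzymatic consumption rescaled by
    the degradation-shrunk negative control.
    """
    f, b, d, resid = _fractions(conv, config)
    consumed = _clamp(100.0 * (1.0 - (resid + b) / (1.0 - d)))
    product = _clamp(consumed * ratio)
    return consumed, product


def expected_hplc_quantification(
    conv: float,
    config: SimulationConfig,
    amp_is_product: bool = False,
) -> tuple[float, float]:
    """Noise-free (consumed ATP %, product %) HPLC peak-area ratios return.

    For an adenosine substrate (``amp_is_product``) the AMP peak from
    nonenzymatic ATP degradation falls into the product pool and inflates
    the apparent product — the same confound a real chromatogram has.
    """
    f, b, d, resid = _fractions(conv, config)
    consumed = 100.0 * (1.0 - resid)  # all ATP loss: enzymatic + basal + degraded
    actual_conv = min(1.0, f * config.donor_conc / config.substrate_conc)
    p, s = actual_conv, 1.0 - actual_conv
    if amp_is_product:
        p += d
    product = 100.0 * p / (s + p)
    return consumed, product


# ---------------------------------------------------------------------------
# plate simulation

def _well_addresses() -> list[WellAddress]:
    # column-major fill: A1, B1, ..., H1, A2, ...
    return [
        WellAddress(row, col)
        for col in range(1, N_COLUMNS + 1)
        for row in ROWS
    ]


def _noisy(rng: np.random.Generator, clean: float, cv: float) -> float:
    if cv == 0.0:
        return max(0.0, clean)
    return max(0.0, clean * (1.0 + rng.normal(0.0, cv)))


def sample_id_for(plate_id: str, enzyme: str, substrate: str, donor: str) -> str:
    return f"{plate_id}:{enzyme}:{substrate}:{donor}"


def simulate_plate(
    config: SimulationConfig,
    screen: Sequence[tuple[str, str, str]] | None = None,
    plate_id: str = "plate1",
    rng: np.random.Generator | None = None,
) -> tuple[PlateLayout, LuminescenceReading, pd.DataFrame]:
    """Simulate one 96-well plate: layout, reader export, and ground truth.

    The plate carries a duplicate donor standard series (ATP by default),
    ``n_replicates`` reaction wells per (enzyme, substrate, donor) triple, and
    the three control types, shared where chemistry allows: negative controls
    per (substrate, donor), substrate controls per substrate, basal controls
    per (enzyme, donor). Deterministic under a fixed seed.

    Returns the layout, the reading, and a truth table with one row per
    reaction group (true conversion and the consumed/basal/degraded/residual
    donor fractions realized on the plate).
    """
    if screen is None:
        screen = default_screen(config)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cv = config.noise_cv
    layout = PlateLayout(plate_id=plate_id)
    values: dict[WellAddress, float] = {}
    addresses = iter(_well_addresses())

    # capacity accounting up front so over-full screens fail loudly
    neg_keys = sorted({(s, d) for _, s, d in screen})
    sub_keys = sorted({s for _, s, _ in screen})
    bas_keys = sorted({(e, d) for e, _, d in screen})
    standard_donor = screen[0][2] if screen else "ATP"
    n_standards = len(config.standard_levels) * config.n_standard_replicates
    demand = (
        n_standards
        + len(screen) * config.n_replicates
        + (len(neg_keys) + len(sub_keys) + len(bas_keys)) * config.n_replicates
    )
    if demand > len(ROWS) * N_COLUMNS:
        raise PlateError(
            f"screen needs {demand} wells but a plate has {len(ROWS) * N_COLUMNS}"
        )

    def place(well: Well, clean_rlu: float) -> None:
        addr = next(addresses)
        layout.wells[addr] = well
        values[addr] = _noisy(rng, clean_rlu, cv)

    # standard series, duplicates per level
    std_model = config.donor_model(standard_donor)
    for level in config.standard_levels:
        for rep in range(1, config.n_standard_replicates + 1):
            place(
                Well(
                    role="standard",
                    donor=standard_donor,
                    donor_conc_uM=level,
                    replicate=rep,
                ),
                std_model.rlu(level),
            )

    autolum = config.substrate_autolum_rlu
    truth_rows = []

    for enzyme, substrate, donor in screen:
        model = config.donor_model(donor)
        conv = config.true_conversion.get((enzyme, substrate), 0.0)
        f, b, d, resid = _fractions(conv, config)
        c_res = config.donor_conc * resid
        for rep in range(1, config.n_replicates + 1):
            place(
                Well(
                    role="reaction",
                    enzyme=enzyme,
                    substrate=substrate,
                    donor=donor,
                    replicate=rep,
                ),
                model.rlu(c_res) + autolum,
            )
        truth_rows.append(
            {
                "plate_id": plate_id,
                "sample_id": sample_id_for(plate_id, enzyme, substrate, donor),
                "enzyme": enzyme,
                "substrate": substrate,
                "donor": donor,
                "true_conversion": conv,
                "consumed_frac": f,
                "basal_frac": b,
                "degraded_frac": d,
                "residual_frac": resid,
                "donor_conc_uM": config.donor_conc,
                "substrate_conc_uM": config.substrate_conc,
            }
        )

    # negative control: substrate + donor, no enzyme -> full donor minus degradation
    for substrate, donor in neg_keys:
        model = config.donor_model(donor)
        c_neg = config.donor_conc * (1.0 - config.atp_degradation)
        for rep in range(1, config.n_replicates + 1):
            place(
                Well(
                    role="negative_control",
                    substrate=substrate,
                    donor=donor,
                    replicate=rep,
                ),
                model.rlu(c_neg) + autolum,
            )

    # substrate control: substrate only, no donor -> baseline signal
    for substrate in sub_keys:
        for rep in range(1, config.n_replicates + 1):
            place(
                Well(role="substrate_control", substrate=substrate, replicate=rep),
                std_model.intercept + autolum,
            )

    # basal control: enzyme + donor, no substrate
    for enzyme, donor in bas_keys:
        model = config.donor_model(donor)
        c_bas = config.donor_conc * (
            1.0 - config.basal_consumption - config.atp_degradation
        )
        for rep in range(1, config.n_replicates + 1):
            place(
                Well(role="basal_control", enzyme=enzyme, donor=donor, replicate=rep),
                model.rlu(c_bas),
            )

    layout.validate()
    reading = LuminescenceReading(plate_id=plate_id, values=values)
    truth = pd.DataFrame(truth_rows)
    return layout, reading, truth


def simulate_screen(
    config: SimulationConfig,
    screen: Sequence[tuple[str, str, str]] | None = None,
    max_groups_per_plate: int = 8,
) -> tuple[list[PlateLayout], list[LuminescenceReading], pd.DataFrame]:
    """Simulate a screen across as many plates as needed.

    Groups are chunked by enzyme (one enzyme's panel per plate, split when a
    panel alone exceeds ``max_groups_per_plate``), mirroring how a bench
    screen is laid out. A single RNG drawn from the config seed feeds every
    plate, so the whole screen is reproducible.
    """
    if screen is None:
        screen = default_screen(config)
    rng = np.random.default_rng(config.seed)
    layouts: list[PlateLayout] = []
    readings: list[LuminescenceReading] = []
    truths: list[pd.DataFrame] = []
    plate_no = itertools.count(1)
    for enzyme, triples in itertools.groupby(
        sorted(screen), key=lambda t: t[0]
    ):
        triples = list(triples)
        for i in range(0, len(triples), max_groups_per_plate):
            chunk = triples[i : i + max_groups_per_plate]
            pid = f"plate{next(plate_no)}"
            layout, reading, truth = simulate_plate(
                config, chunk, plate_id=pid, rng=rng
            )
            layouts.append(layout)
            readings.append(reading)
            truths.append(truth)
    truth = (
        pd.concat(truths, ignore_index=True)
        if truths
        else pd.DataFrame()
    )
    return layouts, readings, truth


def simulate_standard_series(
    config: SimulationConfig,
    donor: str = "ATP",
    rng: np.random.Generator | None = None,
) -> list[tuple[float, float]]:
    """(concentration uM, RLU) points of a simulated standard series."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    model = config.donor_model(donor)
    return [
        (level, _noisy(rng, model.rlu(level), config.noise_cv))
        for level in config.standard_levels
        for _ in range(config.n_standard_replicates)
    ]


# ---------------------------------------------------------------------------
# chromatogram simulation

def simulate_peak_table(
    config: SimulationConfig,
    truth: pd.DataFrame,
    rng: np.random.Generator | None = None,
    retention_times: dict[str, float] | None = None,
    products: dict[str, str] | None = None,
) -> list[PeakTable]:
    """Emit HPLC peak tables matching a plate's ground truth.

    Per reaction sample the adenosine pool is split ATP (residual), ADP
    (enzymatically + basally consumed donor, single-phosphorylation routing)
    and AMP (nonenzymatic degradation); the nucleoside pool is split
    substrate / monophosphate product. Peak areas are molar fractions scaled
    by ``hplc_area_scale`` with the same multiplicative noise as the reader.
    Zero-fraction species emit no peak, as on a real chromatogram.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    rts = retention_times or DEFAULT_RETENTION_TIMES
    prods = products or DEFAULT_PRODUCTS
    cv = config.noise_cv
    scale = config.hplc_area_scale
    tables: list[PeakTable] = []
    for _, row in truth.iterrows():
        sid = row["sample_id"]
        substrate = row["substrate"]
        resid = row["residual_frac"]
        degraded = row["degraded_frac"]
        adp = max(0.0, 1.0 - resid - degraded)
        conv = min(
            1.0,
            row["consumed_frac"] * row["donor_conc_uM"] / row["substrate_conc_uM"],
        )
        peaks: list[Peak] = []

        def add(analyte: str, fraction: float) -> None:
            if fraction <= 0.0:
                return
            if analyte not in rts:
                raise KeyError(f"no retention time for analyte {analyte!r}")
            peaks.append(
                Peak(
                    retention_time=rts[analyte],
                    area=_noisy(rng, scale * fraction, cv),
                )
            )

        add("ATP", resid)
        add("ADP", adp)
        add("AMP", degraded)
        product = prods.get(substrate)
        if product is None:
            raise KeyError(f"no product analyte declared for substrate {substrate!r}")
        if product in ("ATP", "ADP", "AMP") and conv > 0.0:
            # the product peak would merge with an adenosine-pool peak and the
            # two area pools would no longer separate; a real chromatogram has
            # the same ambiguity
            raise PlateError(
                f"substrate {substrate!r} converts into adenosine-pool analyte "
                f"{product!r}; peak pools are not separable"
            )
        add(substrate, 1.0 - conv)
        add(product, conv)
        peaks.sort(key=lambda p: p.retention_time)
        tables.append(PeakTable(sample_id=sid, peaks=peaks))
    return tables
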