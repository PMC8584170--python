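"""Plate data model and file I/O.

Wells on a 96-well plate are addressed row letter (A–H) + 1-based column
(1–12). A plate layout assigns each used well a role: a kinase reaction, one
of the three control types (negative = no enzyme, substrate = no phosphate
donor, basal = no nucleoside substrate), a donor standard, or a blank.
Plate-reader exports map wells to relative light units (RLU); HPLC exports
are integrated peak tables (retention time + area per peak).

All files are plain CSV with a header row:

* layout:   ``well,role,enzyme,substrate,donor,donor_conc_uM,replicate``
* readings: ``well,rlu``
* peaks:    ``sample_id,rt_min,area[,analyte]``
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

logger = logging.getLogger("nkscreen")

ROWS = "ABCDEFGH"
N_COLUMNS = 12

VALID_ROLES = frozenset(
    {
        "reaction",
        "negative_control",
        "substrate_control",
        "basal_control",
        "standard",
        "blank",
    }
)

_WELL_RE = re.compile(r"^([A-Ha-h])(\d{1,2})$")


class PlateError(ValueError):
    """Raised for invalid plate layouts, readings, or peak tables."""


@dataclass(frozen=True, order=True)
class WellAddress:
    """A 96-well plate position, e.g. ``B7``."""

    row: str
    column: int

    def __post_init__(self) -> None:
        if self.row not in ROWS:
            raise PlateError(f"well row must be one of {ROWS}, got {self.row!r}")
        if not 1 <= self.column <= N_COLUMNS:
            raise PlateError(
                f"well column must be in 1..{N_COLUMNS}, got {self.column}"
            )

    @classmethod
    def parse(cls, text: str) -> "WellAddress":
        m = _WELL_RE.match(str(text).strip())
        if not m:
            raise PlateError(f"cannot parse well address {text!r}")
        return cls(m.group(1).upper(), int(m.group(2)))

    def __str__(self) -> str:  # canonical unpadded form, "A1" .. "H12"
        return f"{self.row}{self.column}"


@dataclass(frozen=True)
class Well:
    """Role and annotations of one layout position."""

    role: str
    enzyme: str | None = None
    substrate: str | None = None
    donor: str | None = None
    donor_conc_uM: float | None = None
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES:
            raise PlateError(f"unknown well role {self.role!r}")
        if self.replicate < 1:
            raise PlateError(f"replicate index must be >= 1, got {self.replicate}")


@dataclass
class PlateLayout:
    """Map of well addresses to roles/annotations for one plate."""

    plate_id: str
    wells: dict[WellAddress, Well] = field(default_factory=dict)

    def validate(self) -> None:
        for addr, well in self.wells.items():
            if well.role == "standard":
                if well.donor_conc_uM is None:
                    raise PlateError(
                        f"standard well {addr} has no donor_conc_uM"
                    )
                if well.enzyme is not None:
                    raise PlateError(f"standard well {addr} must not carry an enzyme")
            if well.role == "reaction" and not (
                well.enzyme and well.substrate and well.donor
            ):
                raise PlateError(
                    f"reaction well {addr} needs enzyme, substrate and donor"
                )

    def non_blank_addresses(self) -> list[WellAddress]:
        return sorted(a for a, w in self.wells.items() if w.role != "blank")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for addr in sorted(self.wells):
            w = self.wells[addr]
            rows.append(
                {
                    "well": str(addr),
                    "role": w.role,
                    "enzyme": w.enzyme,
                    "substrate": w.substrate,
                    "donor": w.donor,
                    "donor_conc_uM": w.donor_conc_uM,
                    "replicate": w.replicate,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "well",
                "role",
                "enzyme",
                "substrate",
                "donor",
                "donor_conc_uM",
                "replicate",
            ],
        )


@dataclass
class LuminescenceReading:
    """Per-well RLU values of one plate-reader export."""

    plate_id: str
    values: dict[WellAddress, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for addr, rlu in self.values.items():
            if rlu < 0:
                raise PlateError(f"negative RLU {rlu} at well {addr}")


@dataclass(frozen=True)
class Peak:
    """One integrated chromatographic peak."""

    retention_time: float  # minutes
    area: float  # mAU*s, carried opaquely
    analyte: str | None = None

    def __post_init__(self) -> None:
        if self.retention_time < 0:
            raise PlateError(f"negative retention time {self.retention_time}")
        if self.area < 0:
            raise PlateError(f"negative peak area {self.area}")


@dataclass
class PeakTable:
    """Labeled or unlabeled HPLC peaks of a single sample."""

    sample_id: str
    peaks: list[Peak] = field(default_factory=list)

    def area_of(self, analyte: str) -> float:
        """Total area of a labeled analyte (0 if absent)."""
        return sum(p.area for p in self.peaks if p.analyte == analyte)

    def labeled(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for p in self.peaks:
            if p.analyte is not None:
                if p.analyte in out:
                    raise PlateError(
                        f"analyte {p.analyte!r} labeled twice in sample "
                        f"{self.sample_id!r}"
                    )
                out[p.analyte] = p.area
        return out


# ---------------------------------------------------------------------------
# number parsing

def parse_rlu(text: str, decimal_style: str = "us") -> float:
    """Parse an RLU number, accepting thousands separators.

    ``us`` style: comma groups thousands, dot is the decimal mark
    ("57,892" -> 57892.0). ``de`` style: dot groups thousands, comma is the
    decimal mark ("57.892" -> 57892.0). Dot-thousands is never auto-detected
    in ``us`` style because it is ambiguous with decimals.
    """
    s = str(text).strip()
    if decimal_style == "us":
        if "," in s:
            if not re.fullmatch(r"-?\d{1,3}(,\d{3})+(\.\d+)?", s):
                raise PlateError(f"malformed thousands grouping in {s!r}")
            s = s.replace(",", "")
    elif decimal_style == "de":
        if "." in s and not re.fullmatch(r"-?\d{1,3}(\.\d{3})+(,\d+)?", s):
            raise PlateError(f"malformed thousands grouping in {s!r}")
        s = s.replace(".", "").replace(",", ".")
    else:
        raise PlateError(f"unknown decimal style {decimal_style!r}")
    try:
        return float(s)
    except ValueError as exc:
        raise PlateError(f"unparseable number {text!r}") from exc


# ---------------------------------------------------------------------------
# readers / writers

_LAYOUT_COLUMNS = ["well", "role", "enzyme", "substrate", "donor", "donor_conc_uM", "replicate"]


def _opt(value) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    return s or None


def _source_name(source) -> str:
    return str(source) if isinstance(source, (str, Path)) else "<buffer>"


def read_plate_layout(source, plate_id: str | None = None) -> PlateLayout:
    """Read and validate a plate-layout CSV (path or open file object).

    Role strings are normalized case-insensitively (spaces/hyphens become
    underscores). Duplicate well addresses and standards lacking a
    concentration are hard errors.
    """
    path = _source_name(source)
    if plate_id is None:
        plate_id = Path(path).stem if path != "<buffer>" else "plate"
    df = pd.read_csv(source, dtype=str)
    missing = [c for c in _LAYOUT_COLUMNS if c not in df.columns]
    if missing:
        raise PlateError(f"{path}: layout is missing columns {missing}")
    layout = PlateLayout(plate_id=plate_id)
    for i, row in df.iterrows():
        addr = WellAddress.parse(row["well"])
        if addr in layout.wells:
            raise PlateError(f"{path}: duplicate well address {addr}")
        role = str(row["role"]).strip().lower().replace(" ", "_").replace("-", "_")
        if role not in VALID_ROLES:
            raise PlateError(f"{path}: unknown role {row['role']!r} at well {addr}")
        conc = _opt(row["donor_conc_uM"])
        rep = _opt(row["replicate"])
        layout.wells[addr] = Well(
            role=role,
            enzyme=_opt(row["enzyme"]),
            substrate=_opt(row["substrate"]),
            donor=_opt(row["donor"]),
            donor_conc_uM=float(conc) if conc is not None else None,
            replicate=int(rep) if rep is not None else 1,
        )
    layout.validate()
    return layout


def write_plate_layout(layout: PlateLayout, path: str | Path) -> None:
    layout.to_frame().to_csv(path, index=False)


def read_reader_export(
    source, plate_id: str, decimal_style: str = "us"
) -> LuminescenceReading:
    """Read a plate-reader export CSV (``well,rlu``) into RLU values."""
    path = _source_name(source)
    df = pd.read_csv(source, dtype=str)
    for col in ("well", "rlu"):
        if col not in df.columns:
            raise PlateError(f"{path}: reader export is missing column {col!r}")
    values: dict[WellAddress, float] = {}
    for i, row in df.iterrows():
        addr = WellAddress.parse(row["well"])
        try:
            rlu = parse_rlu(row["rlu"], decimal_style)
        except PlateError as exc:
            raise PlateError(f"{path} row {i + 2}: {exc}") from exc
        if rlu < 0:
            raise PlateError(f"{path} row {i + 2}: negative RLU {rlu} at well {addr}")
        values[addr] = rlu
    return LuminescenceReading(plate_id=plate_id, values=values)


def write_reader_export(reading: LuminescenceReading, path: str | Path) -> None:
    df = pd.DataFrame(
        {"well": [str(a) for a in sorted(reading.values)],
         "rlu": [reading.values[a] for a in sorted(reading.values)]}
    )
    df.to_csv(path, index=False)


def read_peak_table(path: str | Path) -> list[PeakTable]:
    """Read an HPLC peak CSV (``sample_id,rt_min,area[,analyte]``).

    Returns one :class:`PeakTable` per sample, in file order of first
    appearance. Negative areas are hard errors.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str})
    for col in ("sample_id", "rt_min", "area"):
        if col not in df.columns:
            raise PlateError(f"{path}: peak table is missing column {col!r}")
    has_analyte = "analyte" in df.columns
    tables: dict[str, PeakTable] = {}
    for _, row in df.iterrows():
        sid = str(row["sample_id"])
        if sid not in tables:
            tables[sid] = PeakTable(sample_id=sid)
        analyte = _opt(row["analyte"]) if has_analyte else None
        area = float(row["area"])
        if area < 0:
            raise PlateError(f"{path}: negative peak area {area} in sample {sid!r}")
        tables[sid].peaks.append(
            Peak(retention_time=float(row["rt_min"]), area=area, analyte=analyte)
        )
    return list(tables.values())


def write_peak_tables(tables: Iterable[PeakTable], path: str | Path) -> None:
    rows = [
        {
            "sample_id": t.sample_id,
            "rt_min": p.retention_time,
            "area": p.area,
            "analyte": p.analyte,
        }
        for t in tables
        for p in t.peaks
    ]
    pd.DataFrame(rows, columns=["sample_id", "rt_min", "area", "analyte"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# joining

def join_layout(readings: LuminescenceReading, layout: PlateLayout) -> pd.DataFrame:
    """Join RLU readings onto layout annotations.

    Returns one record per non-blank layout well (columns: plate_id, well,
    role, enzyme, substrate, donor, donor_conc_uM, replicate, rlu). A layout
    well without a reading is a hard error; readings for wells absent from
    the layout are dropped with a warning.
    """
    if readings.plate_id != layout.plate_id:
        raise PlateError(
            f"plate_id mismatch: readings {readings.plate_id!r} vs "
            f"layout {layout.plate_id!r}"
        )
    wanted = layout.non_blank_addresses()
    missing = [str(a) for a in wanted if a not in readings.values]
    if missing:
        raise PlateError(
            f"plate {layout.plate_id!r}: no reading for layout wells "
            + ", ".join(missing)
        )
    extra = sorted(set(readings.values) - set(layout.wells))
    if extra:
        logger.warning(
            "plate %s: readings for %d wells absent from layout dropped (%s)",
            layout.plate_id,
            len(extra),
            ", ".join(str(a) for a in extra),
        )
    records = []
    for addr in wanted:
        w = layout.wells[addr]
        records.append(
            {
                "plate_id": layout.plate_id,
                "well": str(addr),
                "role": w.role,
                "enzyme": w.enzyme,
                "substrate": w.substrate,
                "donor": w.donor,
                "donor_conc_uM": w.donor_conc_uM,
                "replicate": w.replicate,
                "rlu": readings.values[addr],
            }
        )
    return pd.DataFrame(
        records,
        columns=[
            "plate_id",
            "well",
            "role",
            "enzyme",
            "substrate",
            "donor",
            "donor_conc_uM",
            "replicate",
            "rlu",
        ],
    )
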