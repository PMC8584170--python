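"""End-to-end screen orchestration: calibrate -> QC -> quantify -> HPLC -> report.

A run is driven by a :class:`RunConfig` (usually loaded from YAML), consumes
layout/readings(/peaks) CSVs, and writes curves.csv, qc.csv, results.csv,
matrix.csv, optionally hplc_results.csv and comparison.csv, plus a plain-text
summary report. A plate whose Z' falls below the configured minimum marks the
run as failed (the report is still written).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import calibration, hplc, plate_io, qc, quantification
from .synthetic import DEFAULT_PRODUCTS, DEFAULT_RETENTION_TIMES

__all__ = ["RunConfig", "RunBundle", "run_screen"]

logger = logging.getLogger("nkscreen")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    layout: Path
    readings: Path
    out_dir: Path
    peaks: Path | None = None
    retention_times: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RETENTION_TIMES)
    )
    products: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_PRODUCTS))
    rt_tolerance: float = 0.3
    verify_threshold: float = quantification.DEFAULT_VERIFY_THRESHOLD
    donor_substrate_ratio: float = quantification.DEFAULT_RATIO
    interference_shift: float = qc.DEFAULT_SHIFT_THRESHOLD
    z_prime_min: float = 0.5
    decimal_style: str = "us"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        for key in ("layout", "readings", "peaks", "out_dir"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = Path(kwargs[key])
        try:
            cfg = cls(**kwargs)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for key in ("layout", "readings"):
            p = getattr(self, key)
            if not Path(p).exists():
                raise ConfigError(f"{key} file does not exist: {p}")
        if self.peaks is not None and not Path(self.peaks).exists():
            raise ConfigError(f"peaks file does not exist: {self.peaks}")
        if not 0 < self.verify_threshold <= 100:
            raise ConfigError("verify_threshold must be in (0, 100]")
        if self.donor_substrate_ratio <= 0:
            raise ConfigError("donor_substrate_ratio must be > 0")


@dataclass
class RunBundle:
    results: pd.DataFrame
    curves: pd.DataFrame
    qc: pd.DataFrame
    matrix: pd.DataFrame
    comparison: pd.DataFrame | None
    report_path: Path
    qc_pass: bool


def _read_plates(config: RunConfig):
    """Layout/readings CSVs may cover several plates via a plate_id column."""
    layout_df = pd.read_csv(config.layout, dtype=str)
    readings_df = pd.read_csv(config.readings, dtype=str)
    if "plate_id" in layout_df.columns:
        plate_ids = sorted(layout_df["plate_id"].dropna().unique())
    else:
        plate_ids = [Path(config.layout).stem]
        layout_df["plate_id"] = plate_ids[0]
        readings_df["plate_id"] = plate_ids[0]
    if "plate_id" not in readings_df.columns:
        if len(plate_ids) > 1:
            raise ConfigError("multi-plate layout but readings lack a plate_id column")
        readings_df["plate_id"] = plate_ids[0]
    annotated_frames = []
    import io

    for pid in plate_ids:
        lsub = layout_df[layout_df["plate_id"] == pid].drop(columns=["plate_id"])
        rsub = readings_df[readings_df["plate_id"] == pid].drop(columns=["plate_id"])
        # reuse the validating CSV readers on per-plate slices
        lbuf, rbuf = io.StringIO(), io.StringIO()
        lsub.to_csv(lbuf, index=False)
        rsub.to_csv(rbuf, index=False)
        lbuf.seek(0), rbuf.seek(0)
        layout = plate_io.read_plate_layout(lbuf, plate_id=pid)  # type: ignore[arg-type]
        reading = plate_io.read_reader_export(
            rbuf, plate_id=pid, decimal_style=config.decimal_style  # type: ignore[arg-type]
        )
        annotated_frames.append(plate_io.join_layout(reading, layout))
    return plate_ids, annotated_frames


def run_screen(config: RunConfig) -> RunBundle:
    """Execute the full pipeline and write the report bundle."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    plate_ids, annotated_frames = _read_plates(config)
    annotated_all = pd.concat(annotated_frames, ignore_index=True)

    logger.info("stage=calibrate plates=%d", len(plate_ids))
    curves = calibration.fit_standard_curves(annotated_all)
    curves_df = calibration.curves_to_frame(curves)
    curves_df.to_csv(out / "curves.csv", index=False)

    logger.info("stage=qc")
    qc_rows = []
    for frame in annotated_frames:
        pq = qc.plate_qc(frame)
        qc_rows.append(
            {
                "plate_id": pq.plate_id,
                "avg_negative": pq.avg_negative,
                "sd_negative": pq.sd_negative,
                "avg_substrate": pq.avg_substrate,
                "sd_substrate": pq.sd_substrate,
                "z_prime": pq.z_prime,
            }
        )
    qc_df = pd.DataFrame(qc_rows)
    qc_df.to_csv(out / "qc.csv", index=False)

    logger.info("stage=quantify")
    results = []
    for frame in annotated_frames:
        results.extend(
            quantification.quantify_plate(
                frame,
                ratio=config.donor_substrate_ratio,
                verify_threshold=config.verify_threshold,
            )
        )
    results_df = quantification.results_to_frame(results)
    results_df.to_csv(out / "results.csv", index=False)

    spectrum = quantification.build_spectrum(results)
    spectrum.values.to_csv(out / "matrix.csv", index_label="enzyme")
    spectrum.flags.to_csv(out / "matrix_flags.csv", index_label="enzyme")

    comparison_df = None
    if config.peaks is not None:
        logger.info("stage=hplc")
        tables = plate_io.read_peak_table(config.peaks)
        library = hplc.RetentionLibrary(
            entries=config.retention_times, tolerance=config.rt_tolerance
        )
        sample_substrates = {}
        for r in results:
            for pid in plate_ids:
                sample_substrates[f"{pid}:{r.enzyme}:{r.substrate}:{r.donor}"] = (
                    r.substrate
                )
        substrate_products = {s: [p] for s, p in config.products.items()}
        known = [t for t in tables if t.sample_id in sample_substrates]
        hplc_df = hplc.quantify_peak_tables(
            known, library, substrate_products, sample_substrates
        )
        hplc_df.to_csv(out / "hplc_results.csv", index=False)
        hplc_entries = []
        for _, row in hplc_df.iterrows():
            pid, enzyme, substrate, donor = str(row["sample_id"]).split(":")
            hplc_entries.append(
                (
                    (enzyme, substrate, donor),
                    float(row["consumed_hplc_pct"]),
                    float(row["product_hplc_pct"]),
                )
            )
        comparisons, summary, unpaired = hplc.compare_methods(results, hplc_entries)
        comparison_df = pd.DataFrame(
            [
                {
                    "enzyme": c.enzyme,
                    "substrate": c.substrate,
                    "donor": c.donor,
                    "product_lum_pct": c.product_lum_pct,
                    "product_hplc_pct": c.product_hplc_pct,
                    "abs_deviation": c.abs_deviation,
                    "consumed_lum_pct": c.consumed_lum_pct,
                    "consumed_hplc_pct": c.consumed_hplc_pct,
                }
                for c in comparisons
            ]
        )
        comparison_df.to_csv(out / "comparison.csv", index=False)

    qc_pass = bool((qc_df["z_prime"] >= config.z_prime_min).all())
    report_path = out / "report.txt"
    _write_report(
        report_path, config, curves_df, qc_df, results_df, comparison_df, qc_pass
    )
    return RunBundle(
        results=results_df,
        curves=curves_df,
        qc=qc_df,
        matrix=spectrum.values,
        comparison=comparison_df,
        report_path=report_path,
        qc_pass=qc_pass,
    )


def _write_report(path, config, curves_df, qc_df, results_df, comparison_df, qc_pass):
    lines = ["nucleoside-kinase screen report", "=" * 32, ""]
    lines.append("standard curves:")
    for _, c in curves_df.iterrows():
        lines.append(
            f"  {c['donor']}: slope {c['slope']:.4g} RLU/uM, "
            f"r^2 {c['r_squared']:.4f} over {c['range_min']:g}-{c['range_max']:g} uM"
        )
    lines.append("")
    lines.append(f"plate QC (Z' minimum {config.z_prime_min}):")
    for _, row in qc_df.iterrows():
        verdict = "pass" if row["z_prime"] >= config.z_prime_min else "FAIL"
        lines.append(f"  {row['plate_id']}: Z' = {row['z_prime']:.3f} [{verdict}]")
    lines.append("")
    flagged = results_df[results_df["flag_verify"]]
    lines.append(
        f"reaction groups: {len(results_df)}; "
        f"flagged for verification (< {config.verify_threshold:g}% product): "
        f"{len(flagged)}"
    )
    for _, row in flagged.iterrows():
        lines.append(
            f"  verify {row['enzyme']} + {row['substrate']} ({row['donor']}): "
            f"product {row['product_pct']:.1f}%"
        )
    if comparison_df is not None and len(comparison_df):
        lines.append("")
        lines.append(
            "luminescence vs HPLC: mean |deviation| "
            f"{comparison_df['abs_deviation'].mean():.2f} points "
            f"(max {comparison_df['abs_deviation'].max():.2f})"
        )
    lines.append("")
    lines.append(f"overall QC: {'PASS' if qc_pass else 'FAIL'}")
    Path(path).write_text("\n".join(lines) + "\n")
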