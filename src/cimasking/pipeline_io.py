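"""Threshold-table schema, readers/writers, config, and the full pipeline.

The canonical interchange format is a tidy long-format table, one row per
measured threshold:

========== ===============================================================
column      meaning
========== ===============================================================
subject     subject identifier
ear         probe ear, ``left`` or ``right``
condition   ``unmasked`` | ``contra_masked`` | ``ipsi_masked``
masker_location  ``apical`` | ``middle`` | ``none`` (unmasked rows)
masker_place     continuous electrode coordinate of the masker (masked rows)
masker_level     masker current in μA (masked rows)
probe_place      continuous electrode coordinate of the probe
threshold        measured detection threshold in μA
========== ===============================================================

:func:`run_full_analysis` executes the whole chain on such a table:
shift functions → range normalization → contralateral peak → ±3-electrode
windowed areas → per-subject×location area and peak difference measures →
pooled 20% trimmed means with 2000-resample percentile-bootstrap CIs and
the CI-below-1 significance rule → peak-aligned average profiles.
Subject×location cells missing a condition are excluded (never imputed),
logged, and reported with the pooled n.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import masking_analysis as ma
from . import virtual_listener as vl
from .errors import (
    CimaskingError,
    DegenerateFunctionError,
    NoPeakError,
    UndefinedRatioError,
    ValidationError,
    WindowError,
)
from .robust_stats import BootstrapCI, percentile_bootstrap_ci
from .stimulus_space import ElectrodeArray

logger = logging.getLogger(__name__)

__all__ = [
    "THRESHOLD_COLUMNS",
    "S1_COLUMN_MAP",
    "AnalysisConfig",
    "AnalysisReport",
    "validate_threshold_table",
    "read_threshold_table",
    "write_threshold_table",
    "run_full_analysis",
    "params_to_dict",
    "params_from_dict",
    "design_to_dict",
    "design_from_dict",
]

THRESHOLD_COLUMNS = (
    "subject",
    "ear",
    "condition",
    "masker_location",
    "masker_place",
    "masker_level",
    "probe_place",
    "threshold",
)

CONDITIONS = ("unmasked", "contra_masked", "ipsi_masked")

# Column-name profile for supplementary spreadsheets that use descriptive
# headers; pass as ``column_map`` to :func:`read_threshold_table`.
S1_COLUMN_MAP = {
    "Subject": "subject",
    "Ear": "ear",
    "Condition": "condition",
    "Masker Location": "masker_location",
    "Masker Place": "masker_place",
    "Masker Level (uA)": "masker_level",
    "Probe Place": "probe_place",
    "Threshold (uA)": "threshold",
}


def validate_threshold_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate schema and invariants; raises with every problem listed."""
    problems: List[str] = []
    missing = [c for c in THRESHOLD_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError("threshold table is missing columns", missing)

    df = df.copy()
    for col in ("masker_place", "masker_level", "probe_place", "threshold"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna() & (df[col].astype(str) != "")]
        for i in bad:
            problems.append(f"row {i}: non-numeric {col} ({df.loc[i, col]!r})")
        df[col] = coerced

    for i in df.index[df["threshold"].isna() | (df["threshold"] <= 0)]:
        problems.append(f"row {i}: threshold must be a positive number")
    for i in df.index[~df["ear"].isin(["left", "right"])]:
        problems.append(f"row {i}: ear must be left|right, got {df.loc[i, 'ear']!r}")
    for i in df.index[~df["condition"].isin(CONDITIONS)]:
        problems.append(f"row {i}: unknown condition {df.loc[i, 'condition']!r}")

    unmasked = df["condition"] == "unmasked"
    for i in df.index[unmasked & (df["masker_location"] != "none")]:
        problems.append(f"row {i}: unmasked rows require masker_location 'none'")
    for i in df.index[~unmasked & (df["masker_place"].isna() | df["masker_level"].isna())]:
        problems.append(f"row {i}: masked rows require masker_place and masker_level")

    key = ["subject", "condition", "masker_location", "probe_place"]
    dup = df.duplicated(subset=key, keep=False)
    for keyval, grp in df[dup].groupby(key):
        problems.append(f"duplicate key {tuple(keyval)} in rows {list(grp.index)}")

    if problems:
        raise ValidationError("threshold table failed validation", problems)
    return df


def read_threshold_table(
    path,
    fmt: Optional[Literal["csv", "xlsx"]] = None,
    column_map: Optional[Dict[str, str]] = None,
) -> pd.DataFrame:
    """Read and validate a threshold table from CSV or XLSX.

    ``column_map`` renames file columns to the canonical schema (e.g.
    :data:`S1_COLUMN_MAP` for descriptive spreadsheet headers).
    """
    path = Path(path)
    fmt = fmt or ("xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv")
    if fmt == "xlsx":
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    return validate_threshold_table(df)


def write_threshold_table(df: pd.DataFrame, path) -> None:
    """Write CSV with 9 significant digits (round-trip stable)."""
    df.to_csv(path, index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnalysisConfig:
    """Every tunable of the analysis chain, with study-condition defaults."""

    window_halfwidth: float = 3.0  # electrodes
    grid_step: float = 0.01  # electrodes, for interpolated outputs
    normalization: Literal["minmax", "peak"] = "minmax"
    peak_mode: Literal["absolute", "gaussian"] = "absolute"
    trim: float = 0.2
    n_boot: int = 2000
    conf: float = 0.95
    seed: int = 0
    array: ElectrodeArray = field(default_factory=ElectrodeArray)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        array_cfg = raw.pop("array", {})
        array = ElectrodeArray(
            n_electrodes=int(array_cfg.get("n_electrodes", 16)),
            electrode_pitch=float(array_cfg.get("pitch_mm", 1.1)),
        )
        return cls(array=array, **raw)

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        raw["array"] = {
            "n_electrodes": self.array.n_electrodes,
            "pitch_mm": self.array.electrode_pitch,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Full analysis
# ---------------------------------------------------------------------------

@dataclass
class AnalysisReport:
    functions: pd.DataFrame  # one row per shift function (peaks, areas, coverage)
    measures: pd.DataFrame  # one row per subject × location × measure kind
    area_ci: Optional[BootstrapCI]
    peak_ci: Optional[BootstrapCI]
    aligned_contralateral: pd.DataFrame
    aligned_ipsilateral: pd.DataFrame
    exclusions: pd.DataFrame  # subject, masker_location, reason
    config: AnalysisConfig = field(default_factory=AnalysisConfig)

    def summary(self) -> str:
        lines = ["Masking-function analysis summary", "=" * 34]
        for name, ci in (("area", self.area_ci), ("peak", self.peak_ci)):
            if ci is None:
                lines.append(f"{name} difference measure: no complete cells")
                continue
            verdict = "significant reduction" if ci.significant_reduction else "not significant"
            lines.append(
                f"{name} difference measure (contra/ipsi): "
                f"20% trimmed mean = {ci.point_estimate:.3f}, "
                f"{ci.conf_level:.0%} CI [{ci.lower:.3f}, {ci.upper:.3f}], "
                f"n = {ci.n}, n_boot = {ci.n_boot}, seed = {ci.seed} -> {verdict}"
            )
        if len(self.exclusions):
            lines.append(f"excluded cells: {len(self.exclusions)}")
            for _, row in self.exclusions.iterrows():
                lines.append(f"  {row['subject']} / {row['masker_location']}: {row['reason']}")
        return "\n".join(lines)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.functions.to_csv(outdir / "functions.csv", index=False, float_format="%.9g")
        self.measures.to_csv(outdir / "measures.csv", index=False, float_format="%.9g")
        self.aligned_contralateral.to_csv(
            outdir / "aligned_contralateral.csv", index=False, float_format="%.9g"
        )
        self.aligned_ipsilateral.to_csv(
            outdir / "aligned_ipsilateral.csv", index=False, float_format="%.9g"
        )
        self.exclusions.to_csv(outdir / "exclusions.csv", index=False)
        rows = []
        for name, ci in (("area", self.area_ci), ("peak", self.peak_ci)):
            if ci is None:
                continue
            rows.append(
                {
                    "measure": name,
                    "n": ci.n,
                    "trimmed_mean": ci.point_estimate,
                    "ci_lower": ci.lower,
                    "ci_upper": ci.upper,
                    "conf_level": ci.conf_level,
                    "n_boot": ci.n_boot,
                    "trim": ci.trim,
                    "seed": ci.seed,
                    "significant_reduction": ci.significant_reduction,
                }
            )
        pd.DataFrame(rows).to_csv(outdir / "bootstrap.csv", index=False, float_format="%.9g")
        (outdir / "report.txt").write_text(self.summary() + "\n")


def _cell_frames(df: pd.DataFrame, subject: str, location: str):
    unmasked = df[(df["subject"] == subject) & (df["condition"] == "unmasked")]
    contra = df[
        (df["subject"] == subject)
        & (df["condition"] == "contra_masked")
        & (df["masker_location"] == location)
    ]
    ipsi = df[
        (df["subject"] == subject)
        & (df["condition"] == "ipsi_masked")
        & (df["masker_location"] == location)
    ]
    return unmasked, contra, ipsi


def run_full_analysis(table: pd.DataFrame, config: AnalysisConfig = AnalysisConfig()) -> AnalysisReport:
    """Execute the complete masking analysis on a threshold table."""
    df = validate_threshold_table(table)

    cells = (
        df[df["condition"] != "unmasked"][["subject", "masker_location"]]
        .drop_duplicates()
        .sort_values(["subject", "masker_location"])
    )

    func_rows: List[dict] = []
    measure_rows: List[dict] = []
    exclusions: List[dict] = []
    contra_fns: List[ma.ShiftFunction] = []
    ipsi_fns: List[ma.ShiftFunction] = []
    area_values: List[float] = []
    peak_values: List[float] = []

    for subject, location in cells.itertuples(index=False):
        unmasked, contra, ipsi = _cell_frames(df, subject, location)
        missing = [
            name
            for name, frame in (("unmasked", unmasked), ("contra_masked", contra), ("ipsi_masked", ipsi))
            if len(frame) == 0
        ]
        if missing:
            reason = f"missing condition(s): {', '.join(missing)}"
            logger.warning("excluding %s / %s: %s", subject, location, reason)
            exclusions.append({"subject": subject, "masker_location": location, "reason": reason})
            continue
        try:
            sf_contra = ma.compute_shift_function(
                contra, unmasked, subject=subject,
                masker_kind="contralateral", masker_location=location,
            )
            sf_ipsi = ma.compute_shift_function(
                ipsi, unmasked, subject=subject,
                masker_kind="ipsilateral", masker_location=location,
            )
            center = ma.locate_ipsi_masker(sf_contra, config.peak_mode)
            norm_contra = ma.normalize_shift_function(sf_contra, config.normalization)
            norm_ipsi = ma.normalize_shift_function(sf_ipsi, config.normalization)
            area_dm, wa_contra, wa_ipsi = ma.area_difference_measure(
                norm_contra, norm_ipsi, center, config.window_halfwidth
            )
            peak_cmp = ma.peak_difference_measure(sf_contra, sf_ipsi, config.peak_mode)
        except (DegenerateFunctionError, NoPeakError, WindowError, UndefinedRatioError) as err:
            reason = f"{type(err).__name__}: {err}"
            logger.warning("excluding %s / %s: %s", subject, location, reason)
            exclusions.append({"subject": subject, "masker_location": location, "reason": reason})
            continue

        contra_fns.append(sf_contra)
        ipsi_fns.append(sf_ipsi)
        area_values.append(area_dm.value)
        peak_values.append(peak_cmp.ratio.value)

        for fn, peak, wa in (
            (sf_contra, peak_cmp.contra_peak, wa_contra),
            (sf_ipsi, peak_cmp.ipsi_peak, wa_ipsi),
        ):
            func_rows.append(
                {
                    "subject": subject,
                    "masker_kind": fn.masker_kind,
                    "masker_location": location,
                    "peak_place": peak.peak_place,
                    "peak_magnitude_uA": peak.peak_magnitude,
                    "fit_kind": peak.fit_kind,
                    "window_center": center,
                    "windowed_area": wa.area,
                    "window_coverage": wa.coverage,
                    "norm_range_min_uA": ma.normalize_shift_function(fn, "minmax").normalization_range[0]
                    if fn.shifts.max() > fn.shifts.min()
                    else np.nan,
                    "norm_range_max_uA": float(fn.shifts.max()),
                }
            )
        measure_rows.append(
            {
                "subject": subject,
                "masker_location": location,
                "kind": "area",
                "value": area_dm.value,
                "difference_uA": np.nan,
            }
        )
        measure_rows.append(
            {
                "subject": subject,
                "masker_location": location,
                "kind": "peak",
                "value": peak_cmp.ratio.value,
                "difference_uA": peak_cmp.difference_ua,
            }
        )

    area_seed, peak_seed = (int(s.generate_state(1)[0] % 2**31) for s in
                            np.random.SeedSequence(config.seed).spawn(2))
    area_ci = (
        percentile_bootstrap_ci(area_values, config.trim, config.n_boot, config.conf, seed=area_seed)
        if len(area_values) >= 2
        else None
    )
    peak_ci = (
        percentile_bootstrap_ci(peak_values, config.trim, config.n_boot, config.conf, seed=peak_seed)
        if len(peak_values) >= 2
        else None
    )

    aligned_contra = (
        ma.align_to_peak_and_average(contra_fns, peak_mode=config.peak_mode)
        if contra_fns
        else pd.DataFrame(columns=["rel_place", "mean_shift", "n"])
    )
    aligned_ipsi = (
        ma.align_to_peak_and_average(ipsi_fns, peak_mode=config.peak_mode)
        if ipsi_fns
        else pd.DataFrame(columns=["rel_place", "mean_shift", "n"])
    )

    return AnalysisReport(
        functions=pd.DataFrame(func_rows),
        measures=pd.DataFrame(measure_rows),
        area_ci=area_ci,
        peak_ci=peak_ci,
        aligned_contralateral=aligned_contra,
        aligned_ipsilateral=aligned_ipsi,
        exclusions=pd.DataFrame(exclusions, columns=["subject", "masker_location", "reason"]),
        config=config,
    )


# ---------------------------------------------------------------------------
# Listener/design (de)serialization for config files
# ---------------------------------------------------------------------------

def params_to_dict(params: vl.ListenerParams) -> dict:
    d = dataclasses.asdict(params)
    for ear in ("left", "right"):
        d[ear]["threshold_poly"] = list(d[ear]["threshold_poly"])
        if math.isinf(d[ear]["psychometric_slope"]):
            d[ear]["psychometric_slope"] = "inf"
    if math.isinf(d["choice_slope"]):
        d["choice_slope"] = "inf"
    return d


def params_from_dict(d: dict) -> vl.ListenerParams:
    def ear(sub: dict) -> vl.EarParams:
        sub = dict(sub)
        sub["threshold_poly"] = tuple(sub.get("threshold_poly", ()))
        if sub.get("psychometric_slope") == "inf":
            sub["psychometric_slope"] = math.inf
        return vl.EarParams(**sub)

    choice = d.get("choice_slope", 4.0)
    return vl.ListenerParams(
        subject=d.get("subject", "S01"),
        left=ear(d["left"]),
        right=ear(d["right"]),
        masking=vl.MaskingParams(**d.get("masking", {})),
        choice_slope=math.inf if choice == "inf" else float(choice),
    )


def design_to_dict(design: vl.ExperimentDesign) -> dict:
    return {
        "probe_places": [float(p) for p in design.probe_places],
        "masker_places": {name: float(p) for name, p in design.masker_places},
        "probe_ear": design.probe_ear,
        "conditions": list(design.conditions),
        "seed": design.seed,
        "peak_mode": design.peak_mode,
        "array": {
            "n_electrodes": design.array.n_electrodes,
            "pitch_mm": design.array.electrode_pitch,
        },
        "bekesy_start_margin_db": design.bekesy_start_margin_db,
        "max_level_ua": design.max_level_ua,
    }


def design_from_dict(d: dict) -> vl.ExperimentDesign:
    array_cfg = d.get("array", {})
    kwargs = dict(
        probe_ear=d.get("probe_ear", "left"),
        seed=int(d.get("seed", 0)),
        peak_mode=d.get("peak_mode", "absolute"),
        array=ElectrodeArray(
            n_electrodes=int(array_cfg.get("n_electrodes", 16)),
            electrode_pitch=float(array_cfg.get("pitch_mm", 1.1)),
        ),
        bekesy_start_margin_db=float(d.get("bekesy_start_margin_db", 6.0)),
        max_level_ua=float(d.get("max_level_ua", 4000.0)),
    )
    if "probe_places" in d:
        kwargs["probe_places"] = tuple(float(p) for p in d["probe_places"])
    if "masker_places" in d:
        kwargs["masker_places"] = tuple((k, float(v)) for k, v in d["masker_places"].items())
    if "conditions" in d:
        kwargs["conditions"] = tuple(d["conditions"])
    return vl.ExperimentDesign(**kwargs)
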