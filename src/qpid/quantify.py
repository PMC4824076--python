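"""Scan-table parsing, fluorescence calibration and occupancy ratios.

A scan table holds one record per chip chamber with three background-
corrected channels: free DNA in the chamber (solution channel), DNA bound
under the button, and immobilized protein under the button.  The ratio of
the two button channels is the per-chamber fractional-occupancy readout;
the solution channel is converted to a free concentration through a linear
calibration curve.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: required scan-table columns, in file order (row/col are 1-based on disk)
SCAN_COLUMNS = [
    "row",
    "col",
    "section",
    "chamber_dna",
    "button_dna",
    "button_protein",
    "bg_chamber",
    "bg_button_dna",
    "bg_button_protein",
]


class NoProteinError(ValueError):
    """Protein signal at or below local background: chamber unusable."""


class DegenerateFitError(ValueError):
    """Calibration points do not determine a line."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear intensity = slope * conc + intercept calibration."""

    slope: float  # RFU per uM
    intercept: float  # RFU
    n_points: int
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"calibration slope must be positive, got {self.slope}")
        if self.n_points < 2:
            raise ValueError("calibration needs at least 2 points")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "slope": self.slope,
                    "intercept": self.intercept,
                    "n_points": self.n_points,
                    "r_squared": self.r_squared,
                },
                indent=2,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationCurve":
        d = json.loads(Path(path).read_text())
        return cls(d["slope"], d["intercept"], int(d["n_points"]), d["r_squared"])


@dataclass
class OccupancyRecord:
    """Replicate-aggregated occupancy at one (protein, oligo, dilution)."""

    protein: str
    oligo: object
    free_conc: float  # uM
    ratio: float
    n_replicates: int
    ratio_sd: float = 0.0


def fit_calibration(points) -> CalibrationCurve:
    """Ordinary least-squares line through (concentration, intensity) points.

    ``points`` is an iterable of (conc_uM, intensity_RFU) pairs or a
    two-column DataFrame.  Concentrations outside the recommended
    0.005-1 uM range only raise a warning.
    """
    if isinstance(points, pd.DataFrame):
        conc = points.iloc[:, 0].to_numpy(float)
        intensity = points.iloc[:, 1].to_numpy(float)
    else:
        arr = np.asarray(list(points), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("points must be (conc, intensity) pairs")
        conc, intensity = arr[:, 0], arr[:, 1]
    if len(conc) < 2 or np.ptp(conc) == 0:
        raise DegenerateFitError("need >= 2 distinct concentrations")
    if conc.min() < 0.005 - 1e-12 or conc.max() > 1.0 + 1e-12:
        warnings.warn(
            "calibration concentrations outside the recommended 0.005-1 uM range",
            stacklevel=2,
        )
    slope, intercept = np.polyfit(conc, intensity, 1)
    resid = intensity - (slope * conc + intercept)
    ss_tot = float(np.sum((intensity - intensity.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return CalibrationCurve(float(slope), float(intercept), len(conc), r2)


def intensity_to_conc(curve: CalibrationCurve, intensity) -> np.ndarray | float:
    """Invert the calibration line; negative concentrations clamp to zero."""
    conc = (np.asarray(intensity, dtype=float) - curve.intercept) / curve.slope
    n_neg = int(np.sum(conc < 0))
    if n_neg:
        log.warning("clamped %d negative calibrated concentration(s) to 0", n_neg)
    conc = np.clip(conc, 0.0, None)
    if np.isscalar(intensity):
        return float(conc)
    return conc


def compute_ratio(record) -> float:
    """Background-corrected bound-DNA / protein ratio for one chamber.

    ``record`` is any mapping with button_dna, bg_button_dna, button_protein
    and bg_button_protein entries.  A protein signal at or below background
    raises :class:`NoProteinError` (the chamber is excluded from fitting);
    a negative DNA numerator clamps to zero.
    """
    protein = record["button_protein"] - record["bg_button_protein"]
    if protein <= 0:
        raise NoProteinError("protein signal at or below local background")
    dna = record["button_dna"] - record["bg_button_dna"]
    return max(dna, 0.0) / protein


def compute_ratios(scan: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`compute_ratio`; unusable chambers yield NaN."""
    protein = scan["button_protein"] - scan["bg_button_protein"]
    dna = (scan["button_dna"] - scan["bg_button_dna"]).clip(lower=0.0)
    ratio = dna / protein
    bad = protein <= 0
    if bad.any():
        log.warning("%d chamber(s) with no protein signal excluded", int(bad.sum()))
        ratio[bad] = np.nan
    return ratio


def aggregate_replicates(records: list[OccupancyRecord]) -> OccupancyRecord | None:
    """Mean ratio / free concentration over replicate chambers.

    Returns ``None`` (missing-data marker) when no usable record remains.
    The spread is the population standard deviation.
    """
    usable = [r for r in records if np.isfinite(r.ratio) and np.isfinite(r.free_conc)]
    if not usable:
        return None
    ratios = np.array([r.ratio for r in usable])
    concs = np.array([r.free_conc for r in usable])
    first = usable[0]
    return OccupancyRecord(
        protein=first.protein,
        oligo=first.oligo,
        free_conc=float(concs.mean()),
        ratio=float(ratios.mean()),
        n_replicates=len(usable),
        ratio_sd=float(ratios.std(ddof=0)),
    )


def quantify_scan(
    scan: pd.DataFrame,
    curve: CalibrationCurve,
    aggregate: bool = True,
) -> pd.DataFrame:
    """Full chamber-level quantification of an annotated scan table.

    Requires the layout annotation columns ``protein``, ``oligo`` and
    ``dilution_index`` (the chip simulator emits them; for external scans
    merge them in from the layout first).  With ``aggregate=True`` returns
    one row per (protein, oligo, dilution_index) with replicate-aggregated
    ratio and calibrated mean free concentration; with ``aggregate=False``
    one row per usable chamber (preferred for Kd fitting — replicate
    sections differ in immobilized protein and hence in depletion, so
    averaging free concentrations across them distorts the isotherm).
    """
    for col in ("protein", "oligo", "dilution_index"):
        if col not in scan.columns:
            raise ValueError(f"scan table lacks layout annotation column {col!r}")
    df = scan.copy()
    df["ratio"] = compute_ratios(df)
    chamber_sig = df["chamber_dna"] - df["bg_chamber"]
    df["free_conc"] = intensity_to_conc(curve, chamber_sig.clip(lower=0.0).to_numpy())
    # a solution-channel signal that does not clear the local background
    # means the free concentration is below the detection floor, not at the
    # calibration line's x-intercept: mark those chambers unusable instead
    # of reporting a phantom concentration
    below = (chamber_sig <= 0.5 * df["bg_chamber"]).to_numpy() | (chamber_sig <= 0).to_numpy()
    if below.any():
        log.info("%d chamber(s) below the free-DNA detection floor dropped", int(below.sum()))
        df.loc[below, "free_conc"] = np.nan

    if not aggregate:
        keep = np.isfinite(df["ratio"]) & np.isfinite(df["free_conc"])
        out = df.loc[keep, ["protein", "oligo", "dilution_index", "free_conc", "ratio"]].copy()
        out["ratio_sd"] = 0.0
        out["n_replicates"] = 1
        return out.reset_index(drop=True)

    rows = []
    for (protein, oligo, dil), grp in df.groupby(
        ["protein", "oligo", "dilution_index"], sort=True
    ):
        ok = grp[np.isfinite(grp["ratio"]) & np.isfinite(grp["free_conc"])]
        if len(ok) == 0:
            continue
        rows.append(
            {
                "protein": protein,
                "oligo": oligo,
                "dilution_index": dil,
                "free_conc": float(ok["free_conc"].mean()),
                "ratio": float(ok["ratio"].mean()),
                "ratio_sd": float(ok["ratio"].std(ddof=0)),
                "n_replicates": int(len(ok)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def write_scan_table(scan: pd.DataFrame, path: str | Path) -> None:
    """Write a tab-delimited scan table, row/col emitted 1-based."""
    df = scan.copy()
    df["row"] = df["row"] + 1
    df["col"] = df["col"] + 1
    ordered = SCAN_COLUMNS + [c for c in df.columns if c not in SCAN_COLUMNS]
    df[ordered].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_scan_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited scan table back to 0-based coordinates.

    Extra columns are preserved; missing required columns raise.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SCAN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"scan table missing columns: {missing}")
    df["row"] = df["row"].astype(int) - 1
    df["col"] = df["col"].astype(int) - 1
    return df


def read_calibration_points(path: str | Path) -> pd.DataFrame:
    """Two-column tab-delimited `conc_uM intensity` file."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("calibration file needs two columns: conc_uM, intensity")
    return df.iloc[:, :2]
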