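"""Equilibrium dissociation-constant estimation and group statistics.

Binding series pair the measured free DNA concentration with the
background-corrected bound-DNA / protein ratio.  Because the free
concentration is measured directly in each chamber, the simple
single-site hyperbola ratio = Rmax * c / (Kd + c) is valid even under
ligand depletion.  Fits outside the quantitative sensitivity window
(1e-3 .. 50 uM) are censored and rendered '-' in reports.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

log = logging.getLogger(__name__)

QUANTITATIVE = "quantitative"
CENSORED_WEAK = "censored_weak"
CENSORED_STRONG = "censored_strong"
FAILED = "failed"

KD_UPPER_UM = 50.0
KD_LOWER_UM = 1e-3

#: minimum number of distinct free concentrations for a fit
MIN_POINTS = 4


@dataclass
class BindingSeries:
    protein: str
    oligo: object
    conc: np.ndarray  # uM, free
    ratio: np.ndarray
    sd: np.ndarray | None = None
    n: np.ndarray | None = None

    @property
    def fittable(self) -> bool:
        return len(np.unique(self.conc)) >= MIN_POINTS


@dataclass
class KdFit:
    kd: float  # uM
    rmax: float
    kd_se: float
    rss: float
    converged: bool
    status: str
    n_points: int = 0
    protein: str = ""
    oligo: object = None

    @property
    def display(self) -> str:
        """Human-readable Kd; censored-weak and failed fits render '-'."""
        if self.status in (CENSORED_WEAK, FAILED):
            return "-"
        return f"{self.kd:.3g}"


@dataclass
class AffinitySummary:
    label: str
    mean_kd: float
    spread: float  # population SD, uM
    n: int
    n_censored: int = 0


def hyperbola(c, rmax, kd):
    return rmax * c / (kd + c)


def _saturation_detected(c, r, rss_hyp, alpha: float = 0.05) -> bool:
    """Extra-sum-of-squares F test of the hyperbola against a straight line
    through the origin (its Kd -> infinity limit).  False means the series
    shows no significant saturation, so Kd is unbounded above."""
    n = len(c)
    if n < 3 or rss_hyp <= 0:
        return True
    slope = float(np.dot(r, c) / np.dot(c, c))
    rss_lin = float(np.sum((r - slope * c) ** 2))
    f_stat = (rss_lin - rss_hyp) / (rss_hyp / (n - 2))
    return f_stat > stats.f.ppf(1 - alpha, 1, n - 2)


def assemble_series(occupancy: pd.DataFrame) -> list[BindingSeries]:
    """One binding series per (protein, oligo) from an occupancy table.

    Points with non-positive free concentration or missing ratio are
    dropped with a log entry; series with fewer than four distinct usable
    concentrations are still returned but flagged unfittable.
    """
    series = []
    for (protein, oligo), grp in occupancy.groupby(["protein", "oligo"], sort=True):
        ok = grp[(grp["free_conc"] > 0) & np.isfinite(grp["ratio"])]
        dropped = len(grp) - len(ok)
        if dropped:
            log.info("(%s, %s): dropped %d unusable point(s)", protein, oligo, dropped)
        ok = ok.sort_values("free_conc")
        series.append(
            BindingSeries(
                protein=protein,
                oligo=oligo,
                conc=ok["free_conc"].to_numpy(float),
                ratio=ok["ratio"].to_numpy(float),
                sd=ok["ratio_sd"].to_numpy(float) if "ratio_sd" in ok else None,
                n=ok["n_replicates"].to_numpy(int) if "n_replicates" in ok else None,
            )
        )
    return series


def fit_kd(series: BindingSeries) -> KdFit:
    """Nonlinear least-squares fit of the single-site isotherm.

    Multi-start initialization: Kd starts at the minimum, geometric mean
    and maximum of the observed concentrations, Rmax at the largest
    observed ratio; the lowest-RSS solution wins, ties broken by smaller
    Kd.  Fits with Kd above 50 uM or an unconstrained Kd (relative SE
    over 100%) are censored weak; below 1e-3 uM censored strong.
    """
    if not series.fittable:
        return KdFit(
            kd=math.nan, rmax=math.nan, kd_se=math.nan, rss=math.nan,
            converged=False, status=FAILED, n_points=len(series.conc),
            protein=series.protein, oligo=series.oligo,
        )
    c, r = series.conc, series.ratio
    rmax0 = max(float(r.max()), 1e-12)
    geo = float(np.exp(np.mean(np.log(c))))
    starts = [float(c.min()), geo, float(c.max())]
    best = None
    for kd0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = optimize.curve_fit(
                    hyperbola, c, r, p0=[rmax0, kd0],
                    bounds=([0.0, 1e-12], [np.inf, np.inf]), maxfev=20000,
                )
        except (RuntimeError, optimize.OptimizeWarning):
            continue
        rss = float(np.sum((r - hyperbola(c, *popt)) ** 2))
        cand = (rss, popt[1], popt, pcov)
        if best is None or (rss, popt[1]) < (best[0], best[1]):
            best = cand
    if best is None:
        return KdFit(
            kd=math.nan, rmax=math.nan, kd_se=math.nan, rss=math.nan,
            converged=False, status=FAILED, n_points=len(c),
            protein=series.protein, oligo=series.oligo,
        )
    rss, kd, (rmax, _), pcov = best
    kd_se = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else math.inf
    if kd > KD_UPPER_UM or not math.isfinite(kd_se) or (kd > 0 and kd_se / kd > 1.0):
        status = CENSORED_WEAK
    elif not _saturation_detected(c, r, rss):
        # a line through the origin (the Kd -> infinity limit) fits as well
        # as the hyperbola: the data only bound Kd from below
        status = CENSORED_WEAK
    elif kd < KD_LOWER_UM:
        status = CENSORED_STRONG
    else:
        status = QUANTITATIVE
    return KdFit(
        kd=float(kd), rmax=float(rmax), kd_se=kd_se, rss=rss,
        converged=True, status=status, n_points=len(c),
        protein=series.protein, oligo=series.oligo,
    )


def fit_all(occupancy: pd.DataFrame) -> list[KdFit]:
    return [fit_kd(s) for s in assemble_series(occupancy)]


def summarize_group(kds, label: str = "") -> AffinitySummary | None:
    """Mean and population SD over quantitative Kd values.

    ``None``/NaN entries (censored) are excluded and counted; returns
    ``None`` when everything is censored.  For a pair, the population SD
    equals half the absolute difference.
    """
    vals = np.array([k for k in kds if k is not None and np.isfinite(k)], dtype=float)
    n_censored = len(list(kds)) - len(vals)
    if len(vals) == 0:
        return None
    return AffinitySummary(
        label=label,
        mean_kd=float(vals.mean()),
        spread=float(vals.std(ddof=0)),
        n=len(vals),
        n_censored=n_censored,
    )


def affinity_of(fit: KdFit) -> float | None:
    """1/Kd in 1/uM; censored-weak and failed fits count as zero affinity."""
    if fit.status in (CENSORED_WEAK, FAILED):
        return 0.0 if fit.status == CENSORED_WEAK else None
    return 1.0 / fit.kd


def affinity_difference(fit_a: KdFit, fit_b: KdFit) -> float | None:
    """Difference in affinity constants 1/Kd(a) - 1/Kd(b), in 1/uM.

    Censored-weak fits contribute zero affinity; when both fits are
    censored or failed the difference is undefined (``None``).
    """
    a, b = affinity_of(fit_a), affinity_of(fit_b)
    if a is None or b is None:
        return None
    if fit_a.status in (CENSORED_WEAK, FAILED) and fit_b.status in (CENSORED_WEAK, FAILED):
        return None
    return a - b


def compare_groups(values_by_category: dict, mode: str = "unpaired-rank"):
    """One-sided rank test that the first category is stochastically larger.

    ``unpaired-rank`` runs a Wilcoxon rank-sum (Mann-Whitney U) test on two
    independent categories; ``paired-signed-rank`` a Wilcoxon signed-rank
    test over paired per-item differences.  All-tied data degenerates to
    p = 1 with a warning.
    """
    if len(values_by_category) != 2:
        raise ValueError("exactly two categories required")
    (la, a), (lb, b) = values_by_category.items()
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if mode == "unpaired-rank":
        if np.ptp(np.concatenate([a, b])) == 0:
            warnings.warn("degenerate comparison: all values tied", stacklevel=2)
            return 0.0, 1.0
        res = stats.mannwhitneyu(a, b, alternative="greater")
        return float(res.statistic), float(res.pvalue)
    if mode == "paired-signed-rank":
        if len(a) != len(b):
            raise ValueError("paired mode requires equal-length categories")
        d = a - b
        if np.all(d == 0):
            warnings.warn("degenerate comparison: all paired differences zero", stacklevel=2)
            return 0.0, 1.0
        res = stats.wilcoxon(d, alternative="greater")
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Kd table I/O
# ---------------------------------------------------------------------------


def fits_to_frame(fits: list[KdFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein": f.protein,
                "oligo": f.oligo,
                "kd_uM": f.kd,
                "kd_se": f.kd_se,
                "rmax": f.rmax,
                "status": f.status,
                "n_points": f.n_points,
            }
            for f in fits
        ]
    )


def write_kd_table(fits: list[KdFit], path: str | Path) -> None:
    fits_to_frame(fits).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_kd_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
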