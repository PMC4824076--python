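"""Synthetic data generation: chip scans, genomes with planted sites,
pentamer shape tables and planted regression ground truth.

Everything here is seeded and deterministic: the same seed reproduces
byte-identical scan tables, FASTA and peak files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .quantify import CalibrationCurve
from .shape import ShapeTable, all_pentamers, revcomp

FOUR_SECTION = "four-section"
WHOLE_CHIP = "whole-chip"

CRE_FULL = "TGACGTCA"
CRE_HALF = "CGTCA"

CATEGORIES = ("A_only", "B_only", "both", "unbound")


# ---------------------------------------------------------------------------
# Dilution series and mass-action equilibrium
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DilutionSeries:
    """Geometric dilution ladder from start_conc down to end_conc (uM)."""

    start_conc: float
    end_conc: float
    n_points: int
    values: tuple

    def __len__(self) -> int:
        return self.n_points


def make_dilution_series(start: float, end: float, n: int) -> DilutionSeries:
    """Geometric series of n concentrations with ratio (end/start)^(1/(n-1))."""
    if start <= 0 or end <= 0:
        raise ValueError("concentrations must be positive")
    if end >= start:
        raise ValueError("series must be strictly decreasing: start > end")
    if n < 2:
        raise ValueError("need at least 2 dilution points")
    ratio = (end / start) ** (1.0 / (n - 1))
    values = start * ratio ** np.arange(n)
    values[-1] = end  # kill accumulated round-off at the printed endpoint
    return DilutionSeries(start_conc=start, end_conc=end, n_points=n, values=tuple(values))


def solve_equilibrium(total_dna, protein_sites, kd):
    """Closed-form single-site equilibrium with ligand depletion.

    bound = ((D+P+K) - sqrt((D+P+K)^2 - 4 D P)) / 2, free = D - bound.
    Accepts scalars or arrays; all concentrations in uM.
    """
    d = np.asarray(total_dna, dtype=float)
    p = np.asarray(protein_sites, dtype=float)
    k = np.asarray(kd, dtype=float)
    if np.any(d < 0) or np.any(p < 0):
        raise ValueError("concentrations must be non-negative")
    if np.any(k <= 0):
        raise ValueError("kd must be positive")
    s = d + p + k
    disc = s * s - 4.0 * d * p
    bound = 0.5 * (s - np.sqrt(np.maximum(disc, 0.0)))
    bound = np.minimum(bound, np.minimum(d, p))  # numerical safety
    free = d - bound
    if np.isscalar(total_dna) and np.isscalar(protein_sites) and np.isscalar(kd):
        return float(bound), float(free)
    return bound, free


@dataclass(frozen=True)
class ChamberTruth:
    """Ground-truth equilibrium state of one chamber (all uM)."""

    total_dna: float
    protein_sites: float
    kd_true: float
    bound: float
    free: float

    @classmethod
    def at_equilibrium(cls, total_dna: float, protein_sites: float, kd: float) -> "ChamberTruth":
        bound, free = solve_equilibrium(total_dna, protein_sites, kd)
        return cls(total_dna, protein_sites, kd, bound, free)

    def __post_init__(self) -> None:
        if abs((self.bound + self.free) - self.total_dna) > 1e-12 * max(self.total_dna, 1.0):
            raise ValueError("mass not conserved")
        if not (0 <= self.bound <= min(self.total_dna, self.protein_sites) + 1e-12):
            raise ValueError("bound outside physical range")


# ---------------------------------------------------------------------------
# Chip layout and scan simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model: per-section protein CV range, signal-to-background
    ratio, per-channel multiplicative read noise, and the master seed."""

    protein_cv_range: tuple = (0.06, 0.40)
    snr: float = 100.0
    intensity_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.protein_cv_range
        if not (0 < lo <= hi < 1):
            raise ValueError("protein CV range must satisfy 0 < lo <= hi < 1")
        if self.snr <= 1:
            raise ValueError("snr must exceed 1")


NOISELESS = NoiseSpec(protein_cv_range=(1e-12, 1e-12), snr=math.inf, intensity_cv=0.0)


@dataclass(frozen=True)
class ChipLayout:
    """64x64 chamber array mapped to (section, protein, oligo, dilution).

    four-section mode: four independent 32x32 quarters, each pairing 32
    oligos with the 32-point dilution ladder exactly once; one protein per
    section (repeating a protein makes the sections replicates).
    whole-chip mode: one protein, 128 oligos x 32 dilutions over all 4096
    cells.
    """

    mode: str
    oligos: tuple
    proteins: tuple
    n_rows: int = 64
    n_cols: int = 64

    def __post_init__(self) -> None:
        if self.mode not in (FOUR_SECTION, WHOLE_CHIP):
            raise ValueError(f"unknown layout mode {self.mode!r}")
        if self.mode == FOUR_SECTION:
            if len(self.oligos) != 32:
                raise ValueError("four-section layout requires exactly 32 oligos")
            if len(self.proteins) != 4:
                raise ValueError("four-section layout requires 4 proteins (one per section)")
        else:
            if len(self.oligos) != 128:
                raise ValueError("whole-chip layout requires exactly 128 oligos")
            if len(self.proteins) != 1:
                raise ValueError("whole-chip layout takes a single protein")

    @property
    def n_dilutions(self) -> int:
        return 32

    def cells(self) -> pd.DataFrame:
        """One record per chamber: row, col, section, protein, oligo,
        dilution_index, replicate (row-major order, 0-based)."""
        rows, cols = np.meshgrid(np.arange(self.n_rows), np.arange(self.n_cols), indexing="ij")
        rows, cols = rows.ravel(), cols.ravel()
        section = (rows // 32) * 2 + (cols // 32)
        if self.mode == FOUR_SECTION:
            oligo_idx = rows % 32
            dil = cols % 32
            protein = np.array([self.proteins[s] for s in section])
            seen: dict[str, int] = {}
            rep_of_section = []
            for s in range(4):
                p = self.proteins[s]
                rep_of_section.append(seen.get(p, 0))
                seen[p] = seen.get(p, 0) + 1
            replicate = np.array([rep_of_section[s] for s in section])
        else:
            idx = rows * self.n_cols + cols
            oligo_idx = idx // 32
            dil = idx % 32
            protein = np.full(len(rows), self.proteins[0], dtype=object)
            replicate = np.zeros(len(rows), dtype=int)
        return pd.DataFrame(
            {
                "row": rows,
                "col": cols,
                "section": section,
                "protein": protein,
                "oligo": [self.oligos[i] for i in oligo_idx],
                "dilution_index": dil,
                "replicate": replicate,
            }
        )

    def cell_map(self) -> dict:
        """(row, col) -> (section, oligo, dilution_index, replicate)."""
        df = self.cells()
        return {
            (int(r.row), int(r.col)): (int(r.section), r.oligo, int(r.dilution_index), int(r.replicate))
            for r in df.itertuples()
        }


def simulate_chip(
    layout: ChipLayout,
    truths: dict,
    spotted_concs: DilutionSeries,
    noise: NoiseSpec,
    calibration: CalibrationCurve,
    protein_sites_uM: float = 0.5,
    button_dna_gain: float = 30000.0,
    protein_gain: float = 20000.0,
) -> pd.DataFrame:
    """Simulate a full scan table for one chip.

    Per chamber: the spotted DNA is perturbed multiplicatively, the protein
    level is drawn with a per-section CV sampled from the noise spec, the
    mass-action equilibrium is solved, and three fluorescence channels are
    produced — the calibration line applied to the free concentration
    (solution channel) and linear gains applied to bound DNA and protein
    (button channels) — each with multiplicative read noise plus a
    background of signal/snr with 10% jitter.
    """
    if len(spotted_concs) != layout.n_dilutions:
        raise ValueError(
            f"dilution series has {len(spotted_concs)} points, layout expects {layout.n_dilutions}"
        )
    cells = layout.cells()
    missing = sorted(
        {(p, o) for p, o in zip(cells["protein"], cells["oligo"])} - set(truths)
    )
    if missing:
        raise KeyError(f"missing ground-truth Kd for mapped pair(s): {missing[:5]}")

    rng = np.random.default_rng(noise.seed)
    lo, hi = noise.protein_cv_range
    section_cv = rng.uniform(lo, hi, size=4)

    n = len(cells)
    nominal = np.array([spotted_concs.values[i] for i in cells["dilution_index"]])
    kd = np.array([truths[(p, o)] for p, o in zip(cells["protein"], cells["oligo"])])

    icv = noise.intensity_cv
    total_dna = np.clip(nominal * (1.0 + rng.normal(0.0, 1.0, n) * icv), 1e-9, None)
    cv = section_cv[cells["section"].to_numpy()]
    protein = np.clip(protein_sites_uM * (1.0 + rng.normal(0.0, 1.0, n) * cv), 1e-9, None)

    bound, free = solve_equilibrium(total_dna, protein, kd)

    def channel(signal):
        sig = np.clip(signal * (1.0 + rng.normal(0.0, 1.0, n) * icv), 0.0, None)
        if math.isinf(noise.snr):
            return sig, np.zeros(n)
        # background is a chip-wide floor per channel (typical signal / snr),
        # jittered per chamber; the reported local background is an
        # independently jittered estimate of the same floor
        level = float(sig.mean()) / noise.snr
        bg_added = np.clip(level * (1.0 + rng.normal(0.0, 1.0, n) * 0.10), 0.0, None)
        bg_est = np.clip(level * (1.0 + rng.normal(0.0, 1.0, n) * 0.10), 0.0, None)
        return sig + bg_added, bg_est

    chamber_sig = np.clip(calibration.slope * free + calibration.intercept, 0.0, None)
    chamber_dna, bg_chamber = channel(chamber_sig)
    button_dna, bg_button_dna = channel(button_dna_gain * bound)
    button_protein, bg_button_protein = channel(protein_gain * protein)

    scan = cells.copy()
    scan["chamber_dna"] = chamber_dna
    scan["button_dna"] = button_dna
    scan["button_protein"] = button_protein
    scan["bg_chamber"] = bg_chamber
    scan["bg_button_dna"] = bg_button_dna
    scan["bg_button_protein"] = bg_button_protein
    return scan


# ---------------------------------------------------------------------------
# Synthetic pentamer shape table
# ---------------------------------------------------------------------------


def synth_pentamer_table(seed: int) -> ShapeTable:
    """Random but physically plausible pentamer shape table.

    Satisfies the reverse-complement symmetry contract by construction and
    narrows the minor groove with A/T content so A-tracts sit below the
    table mean (MGW 2.8-6.2 A, ProT -17..-1 deg, Roll -9..9 deg,
    HelT 30-40 deg).
    """
    rng = np.random.default_rng(seed)
    values: dict[str, tuple] = {}
    for p in all_pentamers():
        rc = revcomp(p)
        if rc < p:
            continue  # handled via its canonical partner
        gc = sum(b in "GC" for b in p) / 5.0
        mgw = float(np.clip(3.2 + 2.4 * gc + rng.normal(0.0, 0.15), 2.8, 6.2))
        prot = float(np.clip(-9.0 - 6.0 * (1 - gc) + rng.normal(0.0, 1.5), -17.0, -1.0))
        rl = float(np.clip(rng.normal(0.0, 3.0), -9.0, 9.0))
        rr = float(np.clip(rng.normal(0.0, 3.0), -9.0, 9.0))
        hl = float(np.clip(34.0 + rng.normal(0.0, 1.5), 30.0, 40.0))
        hr = float(np.clip(34.0 + rng.normal(0.0, 1.5), 30.0, 40.0))
        if rc == p:  # palindromic pentamer: the two central steps coincide
            rr, hr = rl, hl
        values[p] = (mgw, prot, rl, rr, hl, hr)
        if rc != p:
            values[rc] = (mgw, prot, rr, rl, hr, hl)
    return ShapeTable(values)


# ---------------------------------------------------------------------------
# Synthetic genome with planted sites and peak files
# ---------------------------------------------------------------------------

_FORBIDDEN = (CRE_HALF, revcomp(CRE_HALF))  # any CRE occurrence contains one of these


def _scrub_motifs(seq: list, protected: list, rng) -> None:
    """Mutate bases so no CRE half/full-site occurrence survives outside
    the protected (planted-core) intervals.  In-place, deterministic."""
    text = "".join(seq)
    for _ in range(20):
        dirty = False
        for motif in _FORBIDDEN:
            start = 0
            while True:
                i = text.find(motif, start)
                if i == -1:
                    break
                start = i + 1
                span = range(i, i + len(motif))
                if any(i >= s and i + len(motif) <= e for s, e in protected):
                    continue
                # mutate a base of the occurrence outside every protected core
                for j in span:
                    if not any(s <= j < e for s, e in protected):
                        choices = [b for b in "ACGT" if b != seq[j]]
                        seq[j] = choices[int(rng.integers(len(choices)))]
                        dirty = True
                        break
        text = "".join(seq)
        if not dirty:
            return
    raise RuntimeError("motif scrub failed to converge")


def _category_counts(n: int, fractions: dict, rng) -> list:
    fr = {c: float(fractions.get(c, 0.0)) for c in CATEGORIES}
    if abs(sum(fr.values()) - 1.0) > 1e-9:
        raise ValueError("category fractions must sum to 1")
    raw = {c: fr[c] * n for c in CATEGORIES}
    counts = {c: int(math.floor(raw[c])) for c in CATEGORIES}
    rest = n - sum(counts.values())
    for c in sorted(CATEGORIES, key=lambda c: raw[c] - counts[c], reverse=True)[:rest]:
        counts[c] += 1
    out = [c for c in CATEGORIES for _ in range(counts[c])]
    rng.shuffle(out)
    return out


def _peak_frame(rows: list) -> pd.DataFrame:
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "score", "strand",
                 "signalValue", "pValue", "qValue", "peak"],
    )


@dataclass
class SyntheticGenome:
    """A small genome with planted sites plus matching peak files."""

    chrom: str
    sequence: str
    truth: pd.DataFrame
    chip_a: pd.DataFrame
    chip_b: pd.DataFrame
    dnase: pd.DataFrame

    def write(self, out_dir: str | Path) -> dict:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": out / "genome.fa",
            "truth": out / "truth.tsv",
            "chip_a": out / "chip_a.narrowPeak",
            "chip_b": out / "chip_b.narrowPeak",
            "dnase": out / "dnase.narrowPeak",
        }
        write_fasta({self.chrom: self.sequence}, paths["genome"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        for key in ("chip_a", "chip_b", "dnase"):
            getattr(self, key).to_csv(paths[key], sep="\t", index=False, header=False)
        return paths


def synth_genome_and_peaks(
    length: int,
    n_full_sites: int,
    n_half_sites: int,
    category_fractions: dict | None = None,
    seed: int = 0,
    chrom: str = "chr1",
) -> SyntheticGenome:
    """Random genome with planted CRE / CRE half-sites and peak sets.

    Planted sites are at least 400 bp apart and at least 210 bp from the
    chromosome ends; every site sits inside a DNase peak; ChIP-A / ChIP-B
    peaks cover sites according to the assigned category (A_only, B_only,
    both, unbound).  The background contains no spurious motif occurrence,
    so scanning recovers exactly the planted sites.
    """
    if category_fractions is None:
        category_fractions = {c: 0.25 for c in CATEGORIES}
    n_sites = n_full_sites + n_half_sites
    if n_sites < 1:
        raise ValueError("need at least one site")
    if length < 400 * n_sites:
        raise ValueError("genome too short for the requested number of sites")
    slot = (length - 420) // n_sites
    if slot < 400:
        raise ValueError("infeasible packing: sites cannot be spaced 400 bp apart")

    rng = np.random.default_rng(seed)
    site_types = ["CRE_full"] * n_full_sites + ["CRE_half"] * n_half_sites
    rng.shuffle(site_types)
    categories = _category_counts(n_sites, category_fractions, rng)

    seq = list("ACGT"[i] for i in rng.integers(0, 4, size=length))

    records = []
    protected = []
    for i, (stype, cat) in enumerate(zip(site_types, categories)):
        motif = CRE_FULL if stype == "CRE_full" else CRE_HALF
        jitter = int(rng.integers(0, max(slot - 400, 1)))
        start = 210 + i * slot + jitter
        end = start + len(motif)
        if stype == "CRE_full":
            strand = "+"  # palindromic
            planted = motif
        else:
            strand = "+" if rng.integers(2) == 0 else "-"
            planted = motif if strand == "+" else revcomp(motif)
        seq[start:end] = list(planted)
        protected.append((start, end))
        records.append(
            {
                "site_id": f"site{i:04d}",
                "chrom": chrom,
                "start": start,
                "end": end,
                "strand": strand,
                "site_type": stype,
                "category": cat,
            }
        )
    _scrub_motifs(seq, protected, rng)

    truth = pd.DataFrame(records)
    dnase_rows, a_rows, b_rows = [], [], []
    for r in records:
        start, end, cat = r["start"], r["end"], r["category"]
        mid = (start + end) // 2
        dnase_rows.append(
            (chrom, max(start - 150, 0), min(end + 150, length), f"dnase_{r['site_id']}",
             500, ".", 5.0, -1, -1, mid - max(start - 150, 0))
        )
        if cat in ("A_only", "both"):
            a_rows.append(
                (chrom, max(start - 120, 0), min(end + 120, length), f"chipA_{r['site_id']}",
                 800, ".", 8.0, -1, -1, mid - max(start - 120, 0))
            )
        if cat in ("B_only", "both"):
            b_rows.append(
                (chrom, max(start - 120, 0), min(end + 120, length), f"chipB_{r['site_id']}",
                 800, ".", 8.0, -1, -1, mid - max(start - 120, 0))
            )
    return SyntheticGenome(
        chrom=chrom,
        sequence="".join(seq),
        truth=truth,
        chip_a=_peak_frame(a_rows),
        chip_b=_peak_frame(b_rows),
        dnase=_peak_frame(dnase_rows),
    )


# ---------------------------------------------------------------------------
# Planted shape-regression ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedShapeModel:
    """Linear ground truth mapping shape features to affinity (1/Kd, 1/uM)."""

    intercept: float
    weights: dict  # column label -> coefficient
    noise_sd: float = 0.0

    def affinities(self, design: pd.DataFrame, rng=None) -> np.ndarray:
        y = np.full(len(design), self.intercept, dtype=float)
        for col, w in self.weights.items():
            if col not in design.columns:
                raise KeyError(f"planted weight column {col!r} absent from design matrix")
            y += w * design[col].to_numpy(float)
        if self.noise_sd > 0:
            if rng is None:
                raise ValueError("noise_sd > 0 requires an rng")
            y += rng.normal(0.0, self.noise_sd, size=len(y))
        return np.clip(y, 1e-6, None)  # affinities stay strictly positive

    def kds(self, design: pd.DataFrame, rng=None) -> np.ndarray:
        return 1.0 / self.affinities(design, rng)


# ---------------------------------------------------------------------------
# FASTA helpers
# ---------------------------------------------------------------------------


def write_fasta(seqs: dict, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def simulate_calibration_points(
    curve_slope: float,
    curve_intercept: float,
    n: int,
    conc_min: float,
    conc_max: float,
    cv: float,
    seed: int,
) -> pd.DataFrame:
    """Simulated calibration series with multiplicative intensity noise.

    Under multiplicative noise the high-concentration points carry
    essentially all the slope information, so the design replicates the
    full-scale anchor heavily (~86% of points) with small low-end blocks
    pinning the intercept — the allocation that lets unweighted OLS
    recover the slope to 1%.
    """
    rng = np.random.default_rng(seed)
    n_top = int(round(0.86 * n))
    n_mid = int(round(0.08 * n))
    n_bot = n - n_top - n_mid
    conc = np.concatenate(
        [
            np.full(n_top, conc_max),
            np.full(n_mid, min(10.0 * conc_min, conc_max)),
            np.full(n_bot, conc_min),
        ]
    )
    intensity = (curve_slope * conc + curve_intercept) * (1.0 + rng.normal(0.0, cv, size=n))
    return pd.DataFrame({"conc_uM": conc, "intensity": intensity})
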