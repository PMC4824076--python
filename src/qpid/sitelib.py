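"""Genomic binding-site scanning, filtering and library design.

Scans genomes / peak sequences for the CRE full site (TGACGTCA, its own
reverse complement) and the CRE half-site (CGTCA / TGACG on the minus
strand), extracts 200 bp windows centred on the first site in each peak,
applies the full-site-in-flank exclusion, assigns bound/unbound
categories from ChIP and DNase peak sets, and samples the measurement
library.  Coordinates are 0-based half-open internally and 1-based in
emitted reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .shape import revcomp

log = logging.getLogger(__name__)

CRE_FULL = "TGACGTCA"
CRE_HALF = "CGTCA"

MOTIFS = {"CRE_full": CRE_FULL, "CRE_half": CRE_HALF}

WINDOW = 200
FLANK_EXCLUSION = 15

LIB_CATEGORIES = ("A_only", "B_only", "both", "accessible_unbound", "control")


@dataclass(frozen=True)
class SiteHit:
    chrom: str
    position: int  # 0-based start of the matched core
    strand: str
    site_type: str

    @property
    def width(self) -> int:
        return len(MOTIFS[self.site_type])

    @property
    def end(self) -> int:
        return self.position + self.width


@dataclass
class LibraryEntry:
    entry_id: str
    chrom: str
    start: int  # 0-based half-open window on the genome
    end: int
    strand: str
    site_type: str
    sequence: str
    core_offset: int  # 0-based offset of the core within the window
    category: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) != WINDOW:
            raise ValueError(f"library entry must be {WINDOW} bp, got {len(self.sequence)}")


class PeakSet:
    """Sorted per-chromosome intervals from a narrowPeak / BED file."""

    def __init__(self, intervals: pd.DataFrame):
        required = {"chrom", "start", "end"}
        if not required <= set(intervals.columns):
            raise ValueError(f"peak table needs columns {sorted(required)}")
        if (intervals["start"] >= intervals["end"]).any():
            raise ValueError("peak with start >= end")
        self.intervals = intervals.sort_values(["chrom", "start"]).reset_index(drop=True)
        self._by_chrom = {}
        for chrom, grp in self.intervals.groupby("chrom"):
            starts = grp["start"].to_numpy(int)
            ends = grp["end"].to_numpy(int)
            self._by_chrom[chrom] = (starts, ends, int((ends - starts).max()))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return self.intervals.itertuples()

    def contains(self, chrom: str, start: int, end: int) -> bool:
        """True if [start, end) lies fully inside some peak interval."""
        if chrom not in self._by_chrom:
            return False
        starts, ends, maxlen = self._by_chrom[chrom]
        i = int(np.searchsorted(starts, start, side="right")) - 1
        # peaks are sorted by start; any peak spanning `start` begins
        # within `maxlen` of it, so a bounded walk back suffices
        while i >= 0 and starts[i] > start - maxlen:
            if starts[i] <= start and ends[i] >= end:
                return True
            i -= 1
        return False

    @classmethod
    def from_file(cls, path: str | Path, label: str = "") -> "PeakSet":
        names = ["chrom", "start", "end", "name", "score", "strand",
                 "signalValue", "pValue", "qValue", "peak"]
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
        df.columns = names[: df.shape[1]]
        return cls(df[["chrom", "start", "end"]].assign(label=label or Path(path).stem))


def find_sites(seq: str, site_type: str, chrom: str = "") -> list[SiteHit]:
    """All motif occurrences in either orientation, sorted by position.

    N never matches.  For the palindromic full site forward and reverse
    matches coincide and are reported once with strand '+'.
    """
    if site_type not in MOTIFS:
        raise ValueError(f"unknown site type {site_type!r}")
    motif = MOTIFS[site_type]
    rc = revcomp(motif)
    seq = seq.upper()
    hits: dict[int, SiteHit] = {}
    for m, strand in ((motif, "+"), (rc, "-")):
        if strand == "-" and m == motif:
            continue  # palindromic: forward scan already covered it
        start = 0
        while True:
            i = seq.find(m, start)
            if i == -1:
                break
            start = i + 1
            if i not in hits:  # '+' scanned first wins on identical coordinates
                hits[i] = SiteHit(chrom=chrom, position=i, strand=strand, site_type=site_type)
    return [hits[i] for i in sorted(hits)]


def window_start(core_start: int, core_width: int) -> int:
    """Start of the 200 bp window centred on a core: core_start - (100 - floor(w/2))."""
    return core_start - (100 - core_width // 2)


def first_site_window(
    genome, chrom: str, peak_start: int, peak_end: int, site_type: str, entry_id: str = ""
) -> LibraryEntry | None:
    """200 bp window around the first (leftmost) site core inside a peak.

    ``genome`` maps chromosome name to sequence string.  Returns ``None``
    when the peak holds no site or the window would be clipped at a
    chromosome end (logged as a boundary warning).
    """
    chromseq = genome[chrom]
    sub = chromseq[peak_start:peak_end]
    hits = [h for h in find_sites(sub, site_type, chrom) if peak_start + h.end <= peak_end]
    if not hits:
        return None
    hit = hits[0]
    core_start = peak_start + hit.position
    start = window_start(core_start, hit.width)
    end = start + WINDOW
    if start < 0 or end > len(chromseq):
        log.warning("window for site at %s:%d clipped at chromosome end; rejected", chrom, core_start)
        return None
    return LibraryEntry(
        entry_id=entry_id or f"{chrom}:{core_start}",
        chrom=chrom,
        start=start,
        end=end,
        strand=hit.strand,
        site_type=site_type,
        sequence=chromseq[start:end],
        core_offset=core_start - start,
    )


def exclude_full_in_flanks(entry: LibraryEntry) -> bool:
    """Keep/drop rule for half-site entries: drop when a CRE full site
    overlaps the 15 bp immediately 5' or 3' of the core.  Returns True to
    keep."""
    if entry.site_type != "CRE_half":
        raise ValueError("flank exclusion applies to CRE_half entries only")
    w = len(CRE_HALF)
    core = entry.core_offset
    flanks = [(core - FLANK_EXCLUSION, core), (core + w, core + w + FLANK_EXCLUSION)]
    seq = entry.sequence
    start = 0
    while True:
        i = seq.find(CRE_FULL, start)
        if i == -1:
            return True
        start = i + 1
        s, e = i, i + len(CRE_FULL)
        for fs, fe in flanks:
            if s < fe and e > fs:  # any overlap with a flank
                return False


def categorize_sites(
    sites: list[SiteHit], chip_a: PeakSet, chip_b: PeakSet, dnase: PeakSet
) -> dict[SiteHit, str | None]:
    """Bound/unbound category per site.

    Only sites whose core lies fully inside a DNase peak are considered
    (others map to ``None`` = excluded); within the accessible set, overlap
    with ChIP-A only -> A_only, ChIP-B only -> B_only, both -> both,
    neither -> accessible_unbound.
    """
    out: dict[SiteHit, str | None] = {}
    for site in sites:
        if not dnase.contains(site.chrom, site.position, site.end):
            out[site] = None
            continue
        in_a = chip_a.contains(site.chrom, site.position, site.end)
        in_b = chip_b.contains(site.chrom, site.position, site.end)
        if in_a and in_b:
            out[site] = "both"
        elif in_a:
            out[site] = "A_only"
        elif in_b:
            out[site] = "B_only"
        else:
            out[site] = "accessible_unbound"
    return out


def design_library(
    candidates: dict[str, list[LibraryEntry]],
    quota: dict[str, int],
    seed: int = 0,
) -> list[LibraryEntry]:
    """Seeded uniform sampling without replacement per category.

    ``candidates`` maps category -> pool of :class:`LibraryEntry`; a
    quota larger than its pool raises a shortfall error naming the
    category.
    """
    rng = np.random.default_rng(seed)
    chosen: list[LibraryEntry] = []
    for cat in LIB_CATEGORIES:
        want = int(quota.get(cat, 0))
        if want == 0:
            continue
        pool = candidates.get(cat, [])
        if want > len(pool):
            raise ValueError(f"quota {want} exceeds {len(pool)} candidates for category {cat!r}")
        idx = rng.choice(len(pool), size=want, replace=False)
        for i in sorted(idx):
            entry = pool[int(i)]
            entry.category = cat
            chosen.append(entry)
    return chosen


def harvest_candidates(
    genome: dict,
    chip_a: PeakSet,
    chip_b: PeakSet,
    dnase: PeakSet,
    site_type: str,
) -> dict[str, list[LibraryEntry]]:
    """Candidate library entries per category from DNase-accessible peaks.

    Walks the DNase peaks (the accessible candidate pool), extracts the
    first-site window of each, applies the half-site flank exclusion, and
    categorizes the site core against the ChIP peak sets.
    """
    pools: dict[str, list[LibraryEntry]] = {c: [] for c in LIB_CATEGORIES}
    n_scanned = n_window = n_kept = 0
    for k, peak in enumerate(dnase):
        n_scanned += 1
        entry = first_site_window(
            genome, peak.chrom, int(peak.start), int(peak.end), site_type, entry_id=f"lib{k:05d}"
        )
        if entry is None:
            continue
        n_window += 1
        if site_type == "CRE_half" and not exclude_full_in_flanks(entry):
            continue
        core_end = entry.start + entry.core_offset + len(MOTIFS[site_type])
        site = SiteHit(
            chrom=entry.chrom,
            position=entry.start + entry.core_offset,
            strand=entry.strand,
            site_type=site_type,
        )
        cat = categorize_sites([site], chip_a, chip_b, dnase)[site]
        if cat is None:
            continue
        entry.category = cat
        pools[cat].append(entry)
        n_kept += 1
    log.info(
        "library harvest: %d peaks scanned, %d windows extracted, %d candidates kept",
        n_scanned, n_window, n_kept,
    )
    return pools


# ---------------------------------------------------------------------------
# Library output (FASTA + annotation table, 1-based inclusive in reports)
# ---------------------------------------------------------------------------


def library_to_frame(entries: list[LibraryEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": e.entry_id,
                "chrom": e.chrom,
                "start": e.start + 1,  # 1-based inclusive for reports
                "end": e.end,
                "strand": e.strand,
                "site_type": e.site_type,
                "category": e.category,
                "core_offset": e.core_offset + 1,
            }
            for e in entries
        ]
    )


def write_library(entries: list[LibraryEntry], out_dir: str | Path) -> dict:
    from .chipsim import write_fasta

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"fasta": out / "library.fa", "table": out / "library.tsv"}
    write_fasta({e.entry_id: e.sequence for e in entries}, paths["fasta"])
    library_to_frame(entries).to_csv(paths["table"], sep="\t", index=False)
    return paths
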