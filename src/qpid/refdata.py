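"""Bundled reference inputs for the demo pipeline and acceptance runs.

The oligonucleotide mini-library (32 double-stranded probes covering CRE,
CRE half-site, AP-1 and mutant elements in two genomic scaffolds), the
published per-oligo dissociation-constant panel used as simulation ground
truth, and the printed linear fluorescence calibration are all plain data:
they are inputs to the simulator, not measured outputs.
"""

from __future__ import annotations

import math

# ---------------------------------------------------------------------------
# Oligonucleotide mini-library (probe id -> sequence, 5'->3')
# ---------------------------------------------------------------------------

OLIGO_LIBRARY: dict[int, str] = {
    1: "GGCCACTACCGCTTCCTCCACATGACGTCATGGTTTTCTCCACCAAGGAAGT",
    2: "TTATGACCTGGGAGTGACGTCATGGAATCCACAGA",
    3: "GGCCACTACCGCTTCCTCCACATGAGTCATGGTTTTCTCCACCAAGGAAGT",
    4: "TTATGACCTGGGAGTGAGTCAATGGAATCCACAGA",
    5: "GGCCACTACCGCTTCCTCCACATGGCGTCATGGTTTTCTCCACCAAGGAAGT",
    6: "TTATCCACTTGCGCTCGCCGAGTGGCGTCACCAGCGGTACTGTAATGACGAT",
    7: "GGCCACTACCGCTTCCTCCACAAATAAAATTGGTTTTCTCCACCAAGGAAGT",
    8: "GGCCACTACCGCTTCCTCCACATGAGATCATGGTTTTCTCCACCAAGGAAGT",
    9: "GGCCACTACCGCTTCCTCCACATGTCTACATGGTTTTCTCCACCAAGGAAGT",
    10: "GCAGGGACCCAAAGCAGCAGCCTGAGCTCATGATCAGAGTGAAAGGAGAAGG",
    11: "CAGGGACCCAAAGCAGCAGCCTGTCTACATGATCAGAGTGAAAGGAGAAGGC",
    12: "TTGGCCCCAGATTGCCACAGAATCCTGGTGGGGACGACGGGGGAGAGATTCC",
    13: "CCACGTCATTATGACCTGGGAGTGCGTGAATGGAATCCACAGATGAGGGCCC",
    14: "CCAAAAATTTATGACCTGGGAGTGCGTGAATGGAATCCACAGATGAGGGCCC",
    15: "TTATGACCTGGGAGTGCGTGAATGGAATCCACAGA",
    16: "TTATGACCTGGGAGTAAATGAATGGAATCCACAGA",
    17: "TTATGACCTGGGAGAATAAAATTGGAATCCACAGA",
    18: "AGCCCATTTATCCACGTCATTATGACCTGGGAG",
    19: "AGCCCATTTATCCAAAAATTTATGACCTGGGAG",
    20: "GTAATGCAGAAGTTCATTCCGACCAGTTCTTTAGCGCTTACAATGCAAAAA",
    21: "GTAATGCAGAAAAAATTTCCGACCAGTTCTTTAGCGCTTACAATGCAAAAA",
    22: "GTAATGCAGAAGTTCATAATAAATGTTCTTTAGCGCTTACAATGCAAAAAC",
    23: "GTAATGCAGAAGTTCATTCCGACCAGTTCTTTAATAAATCAATGCAAAAAC",
    24: "AAAAAAAAAAAGAAAGAAATTAAACTCAAAAATTGCATGGTTTAGAAGAGGG",
    25: "AAAAAAAAAAAGAAAGAAATTAAAAAATAAAATTGCATGGTTTAGAAGAGGG",
    26: "AAGCGGAAAGACAGAGTCACCACTACGTCACGTGGAGTCCGCTTTACAGACT",
    27: "AAGCGGAAAGACAGAGTCACCAAATAAAATCGTGGAGTCCGCTTTACAGACT",
    28: "GTGTGCGTGCTCTGAGCAGCGAGCACGTCAGACTGCGCCCAGTGGGGAGAGG",
    29: "GTGTGCGTGCTCTGAGCAGCGAAATAAAATGACTGCGCCCAGTGGGGAGAGG",
    30: "CACATGAGATCATGGGAATTTCCACCAAGGAAGTTTTCCGAGGGTTGAATGAGA",
    31: "CACATGAGATCATAGATTTCGAAACCAAGGAAGTTTTCCGAGGGTTGAATGAGA",
    32: "CTCCGGCGGTATGAC",
}

#: Binding-site element carried by the first seven probes.
OLIGO_SITE_TYPE: dict[int, str] = {
    1: "CRE",
    2: "CRE",
    3: "AP-1",
    4: "AP-1",
    5: "HS",
    6: "HS",
    7: "Mutant",
}

# ---------------------------------------------------------------------------
# Reference dissociation constants (uM).  None marks an interaction too weak
# for quantitative measurement (> 50 uM), rendered '-' in reports.
# ---------------------------------------------------------------------------

REFERENCE_KD_PANEL: dict[str, dict[int, float | None]] = {
    "ATF1": {1: 0.04, 2: 0.03, 3: 11.0, 4: 17.0, 5: 0.17, 6: 0.04, 7: None},
    "c-Jun": {1: 1.3, 2: 2.4, 3: 2.5, 4: None, 5: None, 6: None, 7: None},
    "c-Fos": {1: None, 2: None, 3: None, 4: None, 5: None, 6: None, 7: None},
    "c-Fos/c-Jun": {1: 0.19, 2: 0.15, 3: 0.27, 4: 0.50, 5: 3.5, 6: 4.0, 7: None},
}

#: Kd planted for interactions marked too weak (well above the 50 uM limit).
CENSORED_PLANT_KD_UM = 500.0

# Printed linear fluorescence calibration: intensity = slope * conc + intercept
CAL_SLOPE_RFU_PER_UM = 35579.0
CAL_INTERCEPT_RFU = -1471.0
CAL_CONC_MIN_UM = 0.005
CAL_CONC_MAX_UM = 1.0
CAL_N_POINTS = 128

# Dilution-series endpoints spotted on the chip (uM)
DILUTION_START_UM = 2.0
DILUTION_END_UM = 0.0156
DILUTION_N = 32

# Quantitative sensitivity window (uM)
KD_UPPER_LIMIT_UM = 50.0
KD_LOWER_LIMIT_UM = 1e-3

# Core binding-site motifs
CRE_FULL = "TGACGTCA"
CRE_HALF = "CGTCA"
AP1_ELEMENT = "TGAGTCA"


def reference_truths(
    proteins: list[str] | None = None,
    n_oligos: int = 32,
    censored_kd: float = CENSORED_PLANT_KD_UM,
) -> dict[tuple[str, int], float]:
    """Ground-truth Kd map for simulating a chip from the reference panel.

    Oligos beyond the annotated seven receive log-spaced Kd values spanning
    the quantitative window so filler probes exercise the full dynamic range.
    """
    if proteins is None:
        proteins = list(REFERENCE_KD_PANEL)
    truths: dict[tuple[str, int], float] = {}
    n_fill = max(n_oligos - 7, 1)
    for protein in proteins:
        panel = REFERENCE_KD_PANEL[protein]
        for oligo in range(1, n_oligos + 1):
            if oligo in panel:
                kd = panel[oligo]
                truths[(protein, oligo)] = censored_kd if kd is None else kd
            else:
                frac = (oligo - 8) / max(n_fill - 1, 1)
                truths[(protein, oligo)] = 10.0 ** (math.log10(0.05) + frac * (math.log10(20.0) - math.log10(0.05)))
    return truths
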