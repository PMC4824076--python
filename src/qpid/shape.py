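"""Pentamer-table DNA shape features, feature vectors and distances.

Shape of a base pair is predicted from the pentamer centred on it: minor
groove width (MGW, Angstrom) and propeller twist (ProT, degrees) are
per-base parameters; roll and helix twist (Roll, HelT, degrees) are
base-pair-step parameters stored per pentamer as the two central steps
(left = step into the centre base, right = step out of it).  To give every
feature one value per base — so a w-long core with k flanks always yields a
4(2k+w)-long vector — each position's Roll/HelT is the mean of its two
central step values.

Feature blocks are serialized in the frozen order HelT, MGW, Roll, ProT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

FEATURES = ("HelT", "MGW", "Roll", "ProT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

TABLE_COLUMNS = ["pentamer", "mgw", "prot", "roll_left", "roll_right", "helt_left", "helt_right"]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def all_pentamers() -> list[str]:
    bases = "ACGT"
    return [a + b + c + d + e for a in bases for b in bases for c in bases for d in bases for e in bases]


class ShapeTableError(ValueError):
    pass


@dataclass(frozen=True)
class ShapeTable:
    """Lookup pentamer -> (mgw, prot, roll_left, roll_right, helt_left, helt_right)."""

    values: dict

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = 1024 - len(self.values)
        if missing:
            raise ShapeTableError(f"{missing} pentamers missing from shape table")
        for p, v in self.values.items():
            q = self.values.get(revcomp(p))
            if q is None:
                raise ShapeTableError(f"reverse complement of {p} missing")
            mgw, prot, rl, rr, hl, hr = v
            if not (
                math.isclose(mgw, q[0], abs_tol=1e-9)
                and math.isclose(prot, q[1], abs_tol=1e-9)
                and math.isclose(rl, q[3], abs_tol=1e-9)
                and math.isclose(rr, q[2], abs_tol=1e-9)
                and math.isclose(hl, q[5], abs_tol=1e-9)
                and math.isclose(hr, q[4], abs_tol=1e-9)
            ):
                raise ShapeTableError(f"reverse-complement symmetry violated at {p}")

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"pentamer": p, "mgw": v[0], "prot": v[1], "roll_left": v[2],
             "roll_right": v[3], "helt_left": v[4], "helt_right": v[5]}
            for p, v in sorted(self.values.items())
        ]
        pd.DataFrame(rows, columns=TABLE_COLUMNS).to_csv(path, sep="\t", index=False, float_format="%.4f")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ShapeTable":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise ShapeTableError(f"shape table missing columns: {missing}")
        values = {
            str(r.pentamer): (float(r.mgw), float(r.prot), float(r.roll_left),
                              float(r.roll_right), float(r.helt_left), float(r.helt_right))
            for r in df.itertuples()
        }
        return cls(values)


@dataclass
class ShapeTracks:
    """Per-position shape tracks; the first/last two positions are undefined (NaN)."""

    mgw: np.ndarray
    prot: np.ndarray
    roll: np.ndarray
    helt: np.ndarray

    def __len__(self) -> int:
        return len(self.mgw)

    def defined(self) -> np.ndarray:
        return np.isfinite(self.mgw)


@dataclass
class FeatureVector:
    """4(2k+w)-long shape representation of a core plus its k-bp flanks.

    ``core_start`` is 1-based within the source sequence; ``values`` holds
    the four feature blocks (HelT, MGW, Roll, ProT), each 2k+w long, 5'->3'.
    """

    core_start: int
    core_width: int
    flank: int
    values: np.ndarray

    def __post_init__(self) -> None:
        expect = 4 * (2 * self.flank + self.core_width)
        if len(self.values) != expect:
            raise ValueError(f"feature vector length {len(self.values)} != {expect}")

    @property
    def block_length(self) -> int:
        return 2 * self.flank + self.core_width

    def block(self, feature: str) -> np.ndarray:
        i = FEATURES.index(feature)
        n = self.block_length
        return self.values[i * n : (i + 1) * n]


@dataclass
class ReferenceProfile:
    """Element-wise mean feature vector over a set of aligned sites."""

    core_width: int
    flank: int
    values: np.ndarray
    n_sites: int
    source: str = ""

    @property
    def block_length(self) -> int:
        return 2 * self.flank + self.core_width

    def block(self, feature: str) -> np.ndarray:
        i = FEATURES.index(feature)
        n = self.block_length
        return self.values[i * n : (i + 1) * n]


def predict_shape(seq: str, table: ShapeTable) -> ShapeTracks:
    """Predict the four per-base shape tracks of ``seq``.

    Position i (0-based, 2 <= i <= L-3) reads MGW/ProT from the pentamer
    centred on it and Roll/HelT as the mean of that pentamer's two central
    step values.
    """
    seq = seq.upper()
    if len(seq) < 5:
        raise ValueError("sequence shorter than one pentamer")
    if set(seq) - set("ACGT"):
        raise ValueError(f"ambiguous base in sequence: {sorted(set(seq) - set('ACGT'))}")
    n = len(seq)
    mgw = np.full(n, np.nan)
    prot = np.full(n, np.nan)
    roll = np.full(n, np.nan)
    helt = np.full(n, np.nan)
    for i in range(2, n - 2):
        v = table.values[seq[i - 2 : i + 3]]
        mgw[i] = v[0]
        prot[i] = v[1]
        roll[i] = 0.5 * (v[2] + v[3])
        helt[i] = 0.5 * (v[4] + v[5])
    return ShapeTracks(mgw=mgw, prot=prot, roll=roll, helt=helt)


def build_feature_vector(
    seq: str, core_start: int, w: int, k: int, table: ShapeTable
) -> FeatureVector:
    """Shape feature vector of the w-long core at 1-based ``core_start``.

    The sequence must extend at least k+2 bases beyond the core on each
    side so that every included position has full pentamer context.
    """
    if core_start < 1:
        raise ValueError("core_start is 1-based and must be >= 1")
    start0 = core_start - 1
    left = start0
    right = len(seq) - (start0 + w)
    need = k + 2
    if left < need or right < need:
        raise ValueError(
            f"insufficient flanking context: need {need} bases each side, have {left} / {right}"
        )
    tracks = predict_shape(seq, table)
    sl = slice(start0 - k, start0 + w + k)
    values = np.concatenate([tracks.helt[sl], tracks.mgw[sl], tracks.roll[sl], tracks.prot[sl]])
    assert np.all(np.isfinite(values))
    return FeatureVector(core_start=core_start, core_width=w, flank=k, values=values)


def reference_profile(
    sites: list[str], w: int, k: int, table: ShapeTable, core_start: int | None = None, source: str = ""
) -> ReferenceProfile:
    """Mean feature vector of equal-length sites sharing one core offset.

    Minus-strand sites must be reverse-complemented by the caller before
    this is invoked.  ``core_start`` defaults to centring the core.
    """
    if not sites:
        raise ValueError("no sites given")
    length = len(sites[0])
    if any(len(s) != length for s in sites):
        raise ValueError("sites have inconsistent lengths")
    if core_start is None:
        core_start = (length - w) // 2 + 1
    vectors = [build_feature_vector(s, core_start, w, k, table).values for s in sites]
    return ReferenceProfile(
        core_width=w, flank=k, values=np.mean(vectors, axis=0), n_sites=len(sites), source=source
    )


def normalized_distance(
    query: FeatureVector, profile: ReferenceProfile, scope: str = "per-feature"
):
    """Euclidean distance divided by the square root of the vector length.

    ``scope='per-feature'`` returns a dict feature -> distance over each
    2k+w block; ``scope='overall'`` one number over the full 4(2k+w) vector.
    """
    if (query.core_width, query.flank) != (profile.core_width, profile.flank):
        raise ValueError("query and profile layouts differ")
    if scope == "overall":
        diff = query.values - profile.values
        return float(np.linalg.norm(diff) / math.sqrt(len(diff)))
    if scope == "per-feature":
        out = {}
        for f in FEATURES:
            diff = query.block(f) - profile.block(f)
            out[f] = float(np.linalg.norm(diff) / math.sqrt(len(diff)))
        return out
    raise ValueError(f"unknown scope {scope!r}")


def concordance_binomial(n_comparisons: int, n_concordant: int) -> float:
    """Exact one-sided tail P(X >= n_concordant), X ~ Binomial(n, 1/2)."""
    if n_comparisons < 1 or not 0 <= n_concordant <= n_comparisons:
        raise ValueError("invalid counts")
    total = sum(math.comb(n_comparisons, i) for i in range(n_concordant, n_comparisons + 1))
    return total / 2**n_comparisons


# ---------------------------------------------------------------------------
# Vector / profile serialization (3-line header recording w, k, block order)
# ---------------------------------------------------------------------------


def write_vectors(vectors: dict, w: int, k: int, path: str | Path) -> None:
    lines = [f"# w={w}", f"# k={k}", "# blocks=" + ",".join(FEATURES)]
    lines.append("id\t" + "\t".join(f"v{i}" for i in range(4 * (2 * k + w))))
    for name, vec in vectors.items():
        vals = vec.values if hasattr(vec, "values") else np.asarray(vec)
        lines.append(name + "\t" + "\t".join(f"{x:.5f}" for x in vals))
    Path(path).write_text("\n".join(lines) + "\n")


def read_vectors(path: str | Path):
    """Returns (w, k, dict id -> np.ndarray)."""
    lines = Path(path).read_text().splitlines()
    w = int(lines[0].split("=")[1])
    k = int(lines[1].split("=")[1])
    blocks = lines[2].split("=")[1].split(",")
    if tuple(blocks) != FEATURES:
        raise ValueError(f"unsupported block order {blocks}")
    out = {}
    for line in lines[4:]:
        if not line.strip():
            continue
        name, *vals = line.split("\t")
        out[name] = np.array([float(v) for v in vals])
    return w, k, out
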