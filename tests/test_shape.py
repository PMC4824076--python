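import math

import numpy as np
import pytest

from qpid.shape import (
    FEATURES,
    FeatureVector,
    ReferenceProfile,
    ShapeTable,
    ShapeTableError,
    build_feature_vector,
    concordance_binomial,
    normalized_distance,
    predict_shape,
    read_vectors,
    reference_profile,
    revcomp,
    write_vectors,
)


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def naive_predict(seq, table):
    """Independent per-position lookup, no shared machinery with predict_shape."""
    out = {f: [math.nan] * len(seq) for f in ("mgw", "prot", "roll", "helt")}
    for i in range(len(seq)):
        if i < 2 or i > len(seq) - 3:
            continue
        pent = seq[i - 2 : i + 3]
        mgw, prot, rl, rr, hl, hr = table.values[pent]
        out["mgw"][i] = mgw
        out["prot"][i] = prot
        out["roll"][i] = (rl + rr) / 2.0
        out["helt"][i] = (hl + hr) / 2.0
    return out


class TestShapeTable:
    def test_missing_pentamer_rejected(self, pentamer_table):
        broken = dict(pentamer_table.values)
        broken.pop("ACGTA")
        with pytest.raises(ShapeTableError):
            ShapeTable(broken)

    def test_symmetry_violation_rejected(self, pentamer_table):
        broken = dict(pentamer_table.values)
        mgw, prot, rl, rr, hl, hr = broken["AAAAA"]
        broken["AAAAA"] = (mgw + 1.0, prot, rl, rr, hl, hr)
        with pytest.raises(ShapeTableError):
            ShapeTable(broken)

    def test_tsv_round_trip(self, pentamer_table, tmp_path):
        path = tmp_path / "pentamers.tsv"
        pentamer_table.to_tsv(path)
        back = ShapeTable.from_tsv(path)
        assert back.values["ACGTA"] == pytest.approx(pentamer_table.values["ACGTA"], abs=1e-4)


class TestPredictShape:
    def test_minimal_sequence(self, pentamer_table):
        tracks = predict_shape("ACGTA", pentamer_table)
        assert tracks.defined().sum() == 1
        assert np.isfinite(tracks.mgw[2])

    def test_homopolymer_constant(self, pentamer_table):
        tracks = predict_shape("A" * 20, pentamer_table)
        interior = tracks.mgw[2:-2]
        assert np.allclose(interior, interior[0])

    def test_strand_symmetry(self, pentamer_table):
        rng = np.random.default_rng(1)
        for _ in range(100):
            seq = random_seq(rng, int(rng.integers(5, 40)))
            fwd = predict_shape(seq, pentamer_table)
            rev = predict_shape(revcomp(seq), pentamer_table)
            for track in ("mgw", "prot", "roll", "helt"):
                a = getattr(fwd, track)
                b = getattr(rev, track)[::-1]
                assert np.allclose(a[np.isfinite(a)], b[np.isfinite(b)], atol=1e-9)

    def test_matches_naive(self, pentamer_table):
        rng = np.random.default_rng(2)
        for _ in range(1000):
            seq = random_seq(rng, 50)
            tracks = predict_shape(seq, pentamer_table)
            ref = naive_predict(seq, pentamer_table)
            assert np.allclose(tracks.mgw[2:-2], ref["mgw"][2:-2])
            assert np.allclose(tracks.roll[2:-2], ref["roll"][2:-2])
            assert np.allclose(tracks.helt[2:-2], ref["helt"][2:-2])
            assert np.allclose(tracks.prot[2:-2], ref["prot"][2:-2])

    def test_ambiguous_base(self, pentamer_table):
        with pytest.raises(ValueError):
            predict_shape("ACGNN", pentamer_table)

    def test_too_short(self, pentamer_table):
        with pytest.raises(ValueError):
            predict_shape("ACG", pentamer_table)


class TestFeatureVector:
    def test_length_formula(self, pentamer_table):
        rng = np.random.default_rng(3)
        seq = random_seq(rng, 40)
        vec = build_feature_vector(seq, core_start=16, w=5, k=10, table=pentamer_table)
        assert len(vec.values) == 4 * (2 * 10 + 5) == 100

    def test_zero_flank(self, pentamer_table):
        rng = np.random.default_rng(4)
        seq = random_seq(rng, 20)
        vec = build_feature_vector(seq, core_start=5, w=8, k=0, table=pentamer_table)
        assert len(vec.values) == 32

    def test_block_layout(self, pentamer_table):
        rng = np.random.default_rng(5)
        seq = random_seq(rng, 40)
        vec = build_feature_vector(seq, core_start=16, w=5, k=10, table=pentamer_table)
        tracks = predict_shape(seq, pentamer_table)
        sl = slice(15 - 10, 15 + 5 + 10)
        assert np.allclose(vec.block("HelT"), tracks.helt[sl])
        assert np.allclose(vec.block("MGW"), tracks.mgw[sl])
        assert np.allclose(vec.block("Roll"), tracks.roll[sl])
        assert np.allclose(vec.block("ProT"), tracks.prot[sl])

    def test_insufficient_context(self, pentamer_table):
        rng = np.random.default_rng(6)
        seq = random_seq(rng, 30)
        with pytest.raises(ValueError, match="flanking context"):
            build_feature_vector(seq, core_start=2, w=5, k=10, table=pentamer_table)

    def test_all_values_defined(self, pentamer_table):
        rng = np.random.default_rng(7)
        for _ in range(20):
            seq = random_seq(rng, 60)
            vec = build_feature_vector(seq, core_start=25, w=8, k=7, table=pentamer_table)
            assert np.all(np.isfinite(vec.values))


class TestReferenceProfile:
    def test_single_site(self, pentamer_table):
        rng = np.random.default_rng(8)
        seq = random_seq(rng, 25)
        prof = reference_profile([seq], w=5, k=5, table=pentamer_table)
        vec = build_feature_vector(seq, core_start=11, w=5, k=5, table=pentamer_table)
        assert np.allclose(prof.values, vec.values)
        assert prof.n_sites == 1

    def test_duplicate_site(self, pentamer_table):
        rng = np.random.default_rng(9)
        seq = random_seq(rng, 25)
        single = reference_profile([seq], w=5, k=5, table=pentamer_table)
        double = reference_profile([seq, seq], w=5, k=5, table=pentamer_table)
        assert np.allclose(single.values, double.values)

    def test_hand_average(self, pentamer_table):
        # independent oracle: average of two vectors built by direct lookup
        rng = np.random.default_rng(10)
        s1, s2 = random_seq(rng, 25), random_seq(rng, 25)
        prof = reference_profile([s1, s2], w=5, k=5, table=pentamer_table)
        expected = []
        for feat_idx in range(4):  # HelT, MGW, Roll, ProT
            for pos in range(5, 20):  # core starts at 0-based 10; span core_start-k .. core_start+w+k
                vals = []
                for s in (s1, s2):
                    pent = s[pos - 2 : pos + 3]
                    mgw, prot, rl, rr, hl, hr = pentamer_table.values[pent]
                    vals.append([(hl + hr) / 2, mgw, (rl + rr) / 2, prot][feat_idx])
                expected.append(np.mean(vals))
        assert np.allclose(prof.values, expected)

    def test_inconsistent_lengths(self, pentamer_table):
        with pytest.raises(ValueError):
            reference_profile(["A" * 25, "A" * 24], w=5, k=5, table=pentamer_table)


class TestNormalizedDistance:
    def _pair(self, block_q, block_p, w=2, k=0):
        n = 2 * k + w
        q = np.zeros(4 * n)
        p = np.zeros(4 * n)
        q[:n] = block_q  # HelT block
        p[:n] = block_p
        query = FeatureVector(core_start=1, core_width=w, flank=k, values=q)
        profile = ReferenceProfile(core_width=w, flank=k, values=p, n_sites=1)
        return query, profile

    def test_identity(self, pentamer_table):
        rng = np.random.default_rng(11)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 25))
        vec = build_feature_vector(seq, 11, 5, 5, pentamer_table)
        prof = reference_profile([seq], w=5, k=5, table=pentamer_table)
        assert normalized_distance(vec, prof, scope="overall") == pytest.approx(0.0, abs=1e-12)
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in normalized_distance(vec, prof).values())

    def test_hand_example(self):
        query, profile = self._pair([1.0, 2.0], [3.0, 4.0])
        d = normalized_distance(query, profile, scope="per-feature")
        assert d["HelT"] == pytest.approx(2.0)  # ||(-2,-2)|| / sqrt(2)
        assert d["MGW"] == 0.0

    def test_homogeneity(self):
        query, profile = self._pair([1.0, 2.0], [3.0, 4.0])
        base = normalized_distance(query, profile, scope="overall")
        for c in (0.5, 3.0, -2.0):
            q2 = FeatureVector(1, query.core_width, query.flank, query.values * c)
            p2 = ReferenceProfile(profile.core_width, profile.flank, profile.values * c, 1)
            assert normalized_distance(q2, p2, scope="overall") == pytest.approx(abs(c) * base)

    def test_strand_invariance(self, pentamer_table):
        rng = np.random.default_rng(12)
        sites = [  # aligned 25-mers, core at centre
            "".join("ACGT"[i] for i in rng.integers(0, 4, 25)) for _ in range(10)
        ]
        query_seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 25))
        prof_fwd = reference_profile(sites, w=5, k=5, table=pentamer_table)
        vec_fwd = build_feature_vector(query_seq, 11, 5, 5, pentamer_table)
        prof_rev = reference_profile([revcomp(s) for s in sites], w=5, k=5, table=pentamer_table)
        vec_rev = build_feature_vector(revcomp(query_seq), 11, 5, 5, pentamer_table)
        d_fwd = normalized_distance(vec_fwd, prof_fwd, scope="overall")
        d_rev = normalized_distance(vec_rev, prof_rev, scope="overall")
        assert d_fwd == pytest.approx(d_rev, rel=1e-9)

    def test_layout_mismatch(self):
        query, _ = self._pair([1.0, 2.0], [3.0, 4.0])
        other = ReferenceProfile(core_width=3, flank=1, values=np.zeros(20), n_sites=1)
        with pytest.raises(ValueError):
            normalized_distance(query, other)

    def test_unknown_scope(self):
        query, profile = self._pair([1.0, 2.0], [3.0, 4.0])
        with pytest.raises(ValueError):
            normalized_distance(query, profile, scope="median")


class TestConcordanceBinomial:
    def brute_force(self, n, k):
        """Enumerate all 2^n equally likely outcomes."""
        hits = sum(1 for mask in range(2**n) if bin(mask).count("1") >= k)
        return hits / 2**n

    def test_printed_reconstruction(self):
        assert concordance_binomial(8, 7) == pytest.approx(9 / 256)
        assert round(concordance_binomial(8, 7), 3) == 0.035

    def test_perfect_concordance(self):
        assert concordance_binomial(8, 8) == pytest.approx(1 / 256)

    def test_full_tail(self):
        assert concordance_binomial(4, 0) == 1.0

    def test_matches_enumeration(self):
        for n in range(1, 13):
            for k in range(n + 1):
                assert concordance_binomial(n, k) == pytest.approx(self.brute_force(n, k), abs=1e-15)

    @pytest.mark.parametrize("n,k", [(0, 0), (5, 6), (5, -1)])
    def test_invalid(self, n, k):
        with pytest.raises(ValueError):
            concordance_binomial(n, k)


class TestVectorIO:
    def test_round_trip(self, pentamer_table, tmp_path):
        rng = np.random.default_rng(13)
        seqs = {f"s{i}": "".join("ACGT"[j] for j in rng.integers(0, 4, 40)) for i in range(3)}
        vectors = {
            name: build_feature_vector(seq, 16, 5, 10, pentamer_table) for name, seq in seqs.items()
        }
        path = tmp_path / "vectors.tsv"
        write_vectors(vectors, 5, 10, path)
        w, k, back = read_vectors(path)
        assert (w, k) == (5, 10)
        for name in vectors:
            assert np.allclose(back[name], vectors[name].values, atol=1e-4)
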