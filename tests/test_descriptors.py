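import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from cellumine import descriptors as d
from cellumine.seqio import PROTEIN_ALPHABET, ProteinRecord

protein_seq = st.text(alphabet=PROTEIN_ALPHABET, min_size=5, max_size=80)


class TestCompositionBlocks:
    def test_aac_homopolymer(self):
        v = d.aac("AAAA")
        assert v[0] == 1.0 and v[1:].sum() == 0.0

    def test_aac_two_letter(self):
        v = d.aac("ACAC")
        assert v[0] == 0.5 and v[1] == 0.5

    def test_aac_oracle_200mer(self, random_protein):
        seq = random_protein(200, seed=3)
        np.testing.assert_allclose(d.aac(seq), oracles.bf_aac(seq), atol=1e-12)
        assert d.aac(seq).sum() == pytest.approx(1.0, abs=1e-9)

    def test_dpc_enumeration(self):
        v = d.dpc("ACAC")
        names = [f"{a}{b}" for a in PROTEIN_ALPHABET for b in PROTEIN_ALPHABET]
        got = dict(zip(names, v))
        assert got["AC"] == pytest.approx(2 / 3)
        assert got["CA"] == pytest.approx(1 / 3)
        assert sum(x for k, x in got.items() if k not in ("AC", "CA")) == 0

    def test_dpc_pair(self):
        v = d.dpc("AA")
        assert v[0] == 1.0

    def test_dpc_oracle(self, random_protein):
        seq = random_protein(100, seed=4)
        np.testing.assert_allclose(d.dpc(seq), oracles.bf_dpc(seq), atol=1e-12)

    def test_gaac_simple(self):
        v = d.gaac("GK")  # aliphatic + positive
        assert v[0] == 0.5 and v[2] == 0.5

    def test_gaac_all_negative(self):
        assert d.gaac("DDDD")[3] == 1.0

    def test_gaac_gdpc_oracle(self, random_protein):
        seq = random_protein(100, seed=5)
        np.testing.assert_allclose(d.gaac(seq), oracles.bf_gaac(seq), atol=1e-12)
        np.testing.assert_allclose(d.gdpc(seq), oracles.bf_gdpc(seq), atol=1e-12)

    def test_conjoint_triad_tripeptide(self):
        v = d.conjoint_triad("ARC")
        assert np.count_nonzero(v) == 1
        assert v.max() == 1.0

    def test_conjoint_triad_homopolymer(self):
        v = d.conjoint_triad("LLLLL")
        assert np.count_nonzero(v) == 1 and v.max() == 1.0

    def test_conjoint_triad_oracle(self, random_protein):
        seq = random_protein(60, seed=6)
        np.testing.assert_allclose(
            d.conjoint_triad(seq), oracles.bf_conjoint_triad(seq), atol=1e-12
        )

    @given(protein_seq)
    @settings(max_examples=50)
    def test_composition_blocks_sum_to_one(self, seq):
        for fn in (d.aac, d.dpc, d.gaac, d.gdpc, d.conjoint_triad):
            assert fn(seq).sum() == pytest.approx(1.0, abs=1e-9)
        # CTDC sums to 1 per attribute
        c = d.ctdc(seq).reshape(7, 3)
        np.testing.assert_allclose(c.sum(axis=1), 1.0, atol=1e-9)

    def test_length_preconditions(self):
        with pytest.raises(ValueError):
            d.dpc("A")
        with pytest.raises(ValueError):
            d.conjoint_triad("AC")


class TestCTD:
    def test_homopolymer_composition_and_transitions(self):
        comp = d.ctdc("LLLL").reshape(7, 3)
        trans = d.ctdt("LLLL")
        for row in comp:
            assert sorted(row) == [0.0, 0.0, 1.0]
        assert trans.sum() == 0.0

    def test_distribution_single_occurrence(self):
        # D occurs only at position 1 of a 10-mer; D is group 1 of hydrophobicity
        seq = "D" + "G" * 9
        v = d.ctdd(seq).reshape(7, 3, 5)
        hydro = v[0]  # hydrophobicity attribute
        np.testing.assert_allclose(hydro[0], 10.0)  # polar group: all five = 10%

    def test_ctd_oracle_80mer(self, random_protein):
        seq = random_protein(80, seed=7)
        np.testing.assert_allclose(d.ctdc(seq), oracles.bf_ctdc(seq), atol=1e-12)
        np.testing.assert_allclose(d.ctdt(seq), oracles.bf_ctdt(seq), atol=1e-12)
        np.testing.assert_allclose(d.ctdd(seq), oracles.bf_ctdd(seq), atol=1e-12)


class TestPAAC:
    def test_homopolymer_reduces_to_aac(self):
        v = d.paac("AAAAAA", lam=3)
        np.testing.assert_allclose(v[:20], d.aac("AAAAAA"))
        np.testing.assert_allclose(v[20:], 0.0)

    def test_zero_weight_is_padded_aac(self, random_protein):
        seq = random_protein(30, seed=8)
        v = d.paac(seq, lam=4, w=0.0)
        np.testing.assert_allclose(v[:20], d.aac(seq))
        np.testing.assert_allclose(v[20:], 0.0)

    def test_against_independent_reimplementation(self):
        v = d.paac("MKVLI", lam=2, w=0.05)
        np.testing.assert_allclose(v, oracles.bf_paac("MKVLI", 2, 0.05), atol=1e-12)

    def test_oracle_random(self, random_protein):
        seq = random_protein(40, seed=9)
        np.testing.assert_allclose(
            d.paac(seq, 4, 0.05), oracles.bf_paac(seq, 4, 0.05), atol=1e-12
        )

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="lam"):
            d.paac("MKV", lam=4)


class TestAtomBond:
    def test_glycine_atoms(self):
        v = d.atom_bond("G")
        np.testing.assert_allclose(v[:5], [0.2, 0.5, 0.1, 0.2, 0.0])

    @given(protein_seq)
    @settings(max_examples=30)
    def test_atom_fractions_sum_to_one(self, seq):
        assert d.atom_bond(seq)[:5].sum() == pytest.approx(1.0, abs=1e-9)

    def test_length_invariance(self):
        np.testing.assert_allclose(d.atom_bond("GG"), d.atom_bond("G"))


class TestFeaturize:
    def test_default_dimension(self, random_protein):
        rec = ProteinRecord("a", random_protein(50, seed=10))
        m = d.featurize([rec])
        assert m.shape == (1, 973)
        # 20+400+5+25+21+21+105+343+24+9
        assert len(d.DescriptorConfig().column_names()) == 973

    def test_empty_record_list(self):
        m = d.featurize([])
        assert m.shape == (0, 973)
        assert len(m.columns) == 973

    def test_identical_sequences_identical_rows(self, random_protein):
        seq = random_protein(60, seed=11)
        m = d.featurize([ProteinRecord("a", seq), ProteinRecord("b", seq)])
        np.testing.assert_array_equal(m.data[0], m.data[1])

    def test_permutation_equivariance(self, protein_records):
        m1 = d.featurize(protein_records)
        m2 = d.featurize(protein_records[::-1])
        np.testing.assert_array_equal(m1.data, m2.data[::-1])

    def test_short_sequence_lists_offenders(self):
        with pytest.raises(ValueError, match="tiny"):
            d.featurize([ProteinRecord("tiny", "MKV")])

    def test_unique_column_names(self):
        names = d.DescriptorConfig().column_names()
        assert len(set(names)) == len(names)

    def test_tsv_roundtrip(self, tmp_path, protein_records):
        m = d.featurize(protein_records, d.DescriptorConfig(blocks=("aac", "gaac")))
        path = tmp_path / "features.tsv"
        m.write_tsv(path)
        back = d.FeatureMatrix.read_tsv(path)
        assert back.ids == m.ids and back.columns == m.columns
        np.testing.assert_allclose(back.data, m.data, atol=1e-12)
        assert back.provenance == m.provenance


class TestDropDuplicateColumns:
    def test_two_equal_columns(self):
        m = d.FeatureMatrix(["r1", "r2"], ["a", "b"], [[1.0, 1.0], [2.0, 2.0]])
        out = d.drop_duplicate_columns(m)
        assert out.columns == ["a"]
        assert out.provenance[-1]["dropped"] == ["b"]

    def test_all_distinct_unchanged(self, rng):
        m = d.FeatureMatrix(["r1", "r2"], ["a", "b"], rng.normal(size=(2, 2)))
        assert d.drop_duplicate_columns(m).columns == ["a", "b"]

    def test_planted_duplicates(self, rng):
        data = rng.normal(size=(30, 45))
        dup = data[:, [3, 7, 11, 20, 40]]
        full = np.hstack([data, dup])
        cols = [f"c{i}" for i in range(50)]
        m = d.FeatureMatrix([f"r{i}" for i in range(30)], cols, full)
        out = d.drop_duplicate_columns(m)
        assert out.shape[1] == 45


class TestScaler:
    def test_basic_column(self):
        m = d.FeatureMatrix(["a", "b", "c"], ["x"], [[0.0], [5.0], [10.0]])
        state = d.fit_scaler(m)
        out = d.apply_scaler(state, m)
        np.testing.assert_allclose(out.data[:, 0], [0.0, 0.5, 1.0])

    def test_constant_column_maps_to_zero(self):
        m = d.FeatureMatrix(["a", "b"], ["x"], [[3.0], [3.0]])
        out = d.apply_scaler(d.fit_scaler(m), m)
        np.testing.assert_allclose(out.data, 0.0)

    def test_no_clipping_outside_range(self):
        train = d.FeatureMatrix(["a", "b"], ["x"], [[0.0], [10.0]])
        state = d.fit_scaler(train)
        test = d.FeatureMatrix(["c"], ["x"], [[12.0]])
        assert d.apply_scaler(state, test).data[0, 0] == pytest.approx(1.2)

    def test_fit_apply_gives_unit_range(self, rng):
        data = rng.normal(size=(10, 5))
        m = d.FeatureMatrix([f"r{i}" for i in range(10)], [f"c{i}" for i in range(5)], data)
        out = d.apply_scaler(d.fit_scaler(m), m)
        np.testing.assert_allclose(out.data.min(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.data.max(axis=0), 1.0, atol=1e-12)

    def test_single_row_fit_errors(self):
        m = d.FeatureMatrix(["a"], ["x"], [[1.0]])
        with pytest.raises(ValueError):
            d.fit_scaler(m)

    def test_column_mismatch_errors(self):
        m = d.FeatureMatrix(["a", "b"], ["x"], [[0.0], [1.0]])
        state = d.fit_scaler(m)
        other = d.FeatureMatrix(["a", "b"], ["y"], [[0.0], [1.0]])
        with pytest.raises(ValueError):
            d.apply_scaler(state, other)
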