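import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellumine import seqio
from cellumine.seqio import (
    NucleotideRecord,
    ProteinRecord,
    clean_sequence,
    greedy_cluster,
    greedy_cluster_detailed,
    pairwise_identity,
    read_fasta,
    six_frame_translate,
    write_fasta,
)

protein_text = st.text(alphabet=seqio.PROTEIN_ALPHABET + "xzbju*-. 123", min_size=0, max_size=60)


class TestReadFasta:
    def test_single_record(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">a\nMKV\n")
        (rec,) = read_fasta(path)
        assert rec == ProteinRecord("a", "MKV")

    def test_case_folding_and_order(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">a\nmkv\n>b\nGG\n")
        recs = read_fasta(path)
        assert [r.id for r in recs] == ["a", "b"]
        assert recs[0].seq == "MKV"

    def test_wrapped_lines(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">a\nMKV\nLIA\n")
        assert read_fasta(path)[0].seq == "MKVLIA"

    def test_empty_sequence_names_record(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">a\n\n")
        with pytest.raises(ValueError, match="a"):
            read_fasta(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_fasta(tmp_path / "nope.fasta")

    def test_empty_file(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text("")
        with pytest.raises(ValueError, match="no records"):
            read_fasta(path)

    def test_nucleotide_ambiguity_to_n(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">c\nacgtry\n")
        (rec,) = read_fasta(path, "nucleotide")
        assert rec.seq == "ACGTNN"

    def test_roundtrip(self, tmp_path):
        records = [ProteinRecord("x", "MKVLI" * 30), ProteinRecord("y", "GG")]
        path = tmp_path / "out.fasta"
        write_fasta(records, path)
        assert read_fasta(path) == records


class TestCleanSequence:
    def test_paper_rule(self):
        assert clean_sequence("MK*XV") == "MKV"

    def test_identity_on_full_alphabet(self):
        assert clean_sequence("ACDEFGHIKLMNPQRSTVWY") == "ACDEFGHIKLMNPQRSTVWY"

    def test_nothing_remains(self):
        with pytest.raises(ValueError):
            clean_sequence("XXBZ")

    def test_lowercase_and_gaps(self):
        assert clean_sequence("m-k v.u") == "MKV"

    @given(protein_text)
    @settings(max_examples=100)
    def test_idempotent(self, raw):
        try:
            once = clean_sequence(raw)
        except ValueError:
            return
        assert clean_sequence(once) == once


class TestSixFrameTranslate:
    def test_simple_codons(self):
        frames = six_frame_translate(NucleotideRecord("c", "ATGGCC"))
        plus1 = frames[0]
        assert plus1.frame == 1
        assert [p.seq for p in plus1.peptides] == ["MA"]

    def test_stop_split(self):
        frames = six_frame_translate(NucleotideRecord("c", "ATGTAAATG"))
        assert [p.seq for p in frames[0].peptides] == ["M", "M"]
        assert [p.aa_start for p in frames[0].peptides] == [0, 2]
        assert [p.nt_start for p in frames[0].peptides] == [0, 6]

    def test_n_codon_breaks_segment(self):
        frames = six_frame_translate(NucleotideRecord("c", "ATGANTATG"))
        assert [p.seq for p in frames[0].peptides] == ["M", "M"]

    def test_reverse_complement_symmetry(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=60))
        contig = NucleotideRecord("c", seq)
        rc = contig.reverse_complement()
        fwd = six_frame_translate(contig)
        rev = six_frame_translate(rc)
        assert [p.seq for p in fwd[0].peptides] == [p.seq for p in rev[3].peptides]

    def test_short_contig_empty_frames(self):
        frames = six_frame_translate(NucleotideRecord("c", "AT"))
        assert all(f.peptides == () for f in frames)

    @given(st.text(alphabet="ACGT", min_size=3, max_size=120))
    @settings(max_examples=60)
    def test_peptide_length_bound(self, seq):
        for frame in six_frame_translate(NucleotideRecord("c", seq)):
            total = sum(len(p.seq) for p in frame.peptides)
            assert total <= len(seq) // 3


class TestGreedyCluster:
    def test_identical_collapse(self):
        recs = [ProteinRecord("a", "MKVLIMKVLI"), ProteinRecord("b", "MKVLIMKVLI")]
        assert len(greedy_cluster(recs, 0.9)) == 1

    def test_disjoint(self):
        recs = [ProteinRecord("a", "MKVLI"), ProteinRecord("b", "AAAAA")]
        assert len(greedy_cluster(recs, 0.9)) == 2

    def test_representative_is_longest(self):
        recs = [ProteinRecord("short", "MKVLIMKVL"), ProteinRecord("long", "MKVLIMKVLI")]
        reps = greedy_cluster(recs, 0.8)
        assert [r.id for r in reps] == ["long"]

    def test_variants_collapse_against_bruteforce(self, random_protein):
        # 50-mer plus 3 single-substitution variants and 6 unrelated randoms
        base = random_protein(50, seed=1)
        variants = []
        for i, pos in enumerate((5, 20, 40)):
            repl = "W" if base[pos] != "W" else "G"
            variants.append(
                ProteinRecord(f"v{i}", base[:pos] + repl + base[pos + 1 :])
            )
        unrelated = [
            ProteinRecord(f"u{i}", random_protein(50, seed=50 + i)) for i in range(6)
        ]
        records = [ProteinRecord("base", base)] + variants + unrelated
        # brute-force all-pairs identity matrix -> connected components at 0.9
        n = len(records)
        ident = np.eye(n)
        for i in range(n):
            for j in range(i + 1, n):
                ident[i, j] = ident[j, i] = pairwise_identity(
                    records[i].seq, records[j].seq
                )
        # Hamming lower bound confirms the planted variants reach >= 0.9
        for v in variants:
            matches = sum(a == b for a, b in zip(base, v.seq))
            assert matches / 50 >= 0.9
        adjacency = ident >= 0.9
        seen = set()
        components = 0
        for i in range(n):
            if i in seen:
                continue
            components += 1
            stack = [i]
            while stack:
                k = stack.pop()
                if k in seen:
                    continue
                seen.add(k)
                stack.extend(j for j in range(n) if adjacency[k, j] and j not in seen)
        reps = greedy_cluster(records, 0.9)
        assert components == 7
        assert len(reps) == components

    def test_empty_input(self):
        assert greedy_cluster([], 0.9) == []

    def test_every_record_in_exactly_one_cluster(self, random_protein):
        records = [ProteinRecord(f"r{i}", random_protein(30, seed=i)) for i in range(8)]
        clusters = greedy_cluster_detailed(records, 0.5)
        member_ids = [m.id for c in clusters for m, _ in c.members]
        assert sorted(member_ids) == sorted(r.id for r in records)

    def test_threshold_monotonicity(self, random_protein):
        records = [ProteinRecord(f"r{i}", random_protein(25, seed=i)) for i in range(10)]
        sizes = [len(greedy_cluster(records, t)) for t in (0.9, 0.6, 0.3)]
        assert sizes == sorted(sizes, reverse=True)

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            greedy_cluster([], 0.0)

    def test_cluster_report(self, tmp_path):
        recs = [ProteinRecord("a", "MKVLIMKVLI"), ProteinRecord("b", "MKVLIMKVLI")]
        clusters = greedy_cluster_detailed(recs, 0.9)
        path = tmp_path / "clusters.tsv"
        seqio.write_cluster_report(clusters, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "representative_id\tmember_id\tidentity"
        assert len(lines) == 3
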