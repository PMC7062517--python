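import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dropchim import (
    MoleculeKey,
    SimConfig,
    Whitelist,
    build_count_matrix,
    correct_barcode,
    correct_umis,
    filter_umi,
    simulate_reads,
)
from dropchim.types import phred_encode

from .oracles import brute_correct_barcode, brute_correct_umis, brute_demux

HIGH = phred_encode([30, 30, 30, 30])


class TestCorrectBarcode:
    def test_whitelist_member_identity(self):
        wl = Whitelist({"AAAA": 10, "CCCC": 5})
        assert correct_barcode("AAAA", HIGH, wl) == "AAAA"

    def test_single_candidate_corrected(self):
        wl = Whitelist({"AAAA": 100, "CCCC": 100})
        assert correct_barcode("AAAT", HIGH, wl) == "AAAA"

    def test_symmetric_candidates_rejected(self):
        wl = Whitelist({"AAAA": 50, "AAAC": 50})
        # AAAG is Hamming-1 from both with equal quality: posterior 0.5 < 0.975
        assert correct_barcode("AAAG", HIGH, wl) is None

    def test_abundance_breaks_symmetry(self):
        wl = Whitelist({"AAAA": 1000, "AAAC": 1})
        assert correct_barcode("AAAG", HIGH, wl) == "AAAA"

    def test_no_candidate(self):
        wl = Whitelist({"AAAA": 10})
        assert correct_barcode("GGGG", HIGH, wl) is None

    def test_length_mismatch_raises(self):
        wl = Whitelist({"AAAA": 10})
        with pytest.raises(ValueError, match="length"):
            correct_barcode("AAAAA", phred_encode([30] * 5), wl)

    def test_never_returns_non_member(self):
        rng = np.random.default_rng(0)
        wl = Whitelist({"ACGT": 9, "TCGT": 3, "AGGT": 7})
        bases = "ACGT"
        for _ in range(200):
            obs = "".join(rng.choice(list(bases), 4))
            quals = phred_encode(rng.integers(5, 40, 4))
            out = correct_barcode(obs, quals, wl)
            assert out is None or out in wl

    def test_matches_bruteforce_scan(self):
        rng = np.random.default_rng(1)
        members = ["AACG", "AACT", "GACG", "TTTT", "TTTA"]
        abundances = {m: int(a) for m, a in zip(members, rng.integers(1, 200, len(members)))}
        wl = Whitelist(abundances)
        for _ in range(300):
            obs = "".join(rng.choice(list("ACGT"), 4))
            q = rng.integers(5, 41, 4)
            assert correct_barcode(obs, phred_encode(q), wl) == brute_correct_barcode(
                obs, list(q), abundances
            )


class TestFilterUmi:
    def test_homopolymer_rejected(self):
        assert filter_umi("AAAAAAAAAA", phred_encode([40] * 10)) is False

    def test_quality_exactly_10_rejected(self):
        quals = [30] * 9 + [10]
        assert filter_umi("ACGTACGTAC", phred_encode(quals)) is False

    def test_quality_11_passes(self):
        quals = [30] * 9 + [11]
        assert filter_umi("ACGTACGTAC", phred_encode(quals)) is True

    def test_good_umi_passes(self):
        assert filter_umi("ACGTACGTAC", phred_encode([30] * 10)) is True

    def test_empty_umi_raises(self):
        with pytest.raises(ValueError):
            filter_umi("", "")


class TestCorrectUmis:
    def test_merge_into_more_prolific(self):
        mols = [MoleculeKey("BC", "AAAA", "G1", 5), MoleculeKey("BC", "AAAT", "G1", 1)]
        out = correct_umis(mols)
        assert out == {MoleculeKey("BC", "AAAA", "G1", 6)}

    def test_equal_support_no_merge(self):
        mols = [MoleculeKey("BC", "AAAA", "G1", 3), MoleculeKey("BC", "AAAT", "G1", 3)]
        assert correct_umis(mols) == set(mols)

    def test_different_genes_no_merge(self):
        mols = [MoleculeKey("BC", "AAAA", "G1", 5), MoleculeKey("BC", "AAAT", "G2", 1)]
        assert correct_umis(mols) == set(mols)

    def test_distance_two_no_merge(self):
        mols = [MoleculeKey("BC", "AAAA", "G1", 5), MoleculeKey("BC", "AATT", "G1", 1)]
        assert correct_umis(mols) == set(mols)

    def test_multiple_barcodes_rejected(self):
        mols = [MoleculeKey("BC1", "AAAA", "G1", 1), MoleculeKey("BC2", "AAAT", "G1", 1)]
        with pytest.raises(ValueError, match="single barcode"):
            correct_umis(mols)

    @given(
        st.dictionaries(
            st.text(alphabet="ACGT", min_size=4, max_size=4),
            st.integers(min_value=1, max_value=20),
            min_size=1,
            max_size=12,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_bruteforce_and_conserves_reads(self, umi_reads):
        mols = [MoleculeKey("BC", u, "G1", r) for u, r in umi_reads.items()]
        out = correct_umis(mols)
        expected = brute_correct_umis(umi_reads)
        assert {(m.umi, m.reads) for m in out} == set(expected.items())
        assert sum(m.reads for m in out) == sum(umi_reads.values())
        assert len(out) <= len(mols)


def _read_row(bc, umi, gene, bq=None, uq=None):
    return (bc, bq or phred_encode([35] * len(bc)), umi, uq or phred_encode([35] * len(umi)), gene)


def _frame(rows):
    return pd.DataFrame(rows, columns=["barcode", "barcode_quals", "umi", "umi_quals", "gene"])


class TestBuildCountMatrix:
    def test_lossless_roundtrip(self):
        cfg = SimConfig(n_cells=60, mean_cell_umis=80, seed=3)
        reads, wl, truth = simulate_reads(cfg)
        rec = build_count_matrix(reads, wl, genes=truth.counts.genes,
                                 barcodes=truth.counts.barcodes)
        assert rec.equals(truth.counts)

    def test_duplicate_reads_count_once(self):
        wl = Whitelist({"AAAACCCC": 10})
        rows = [_read_row("AAAACCCC", "ACGTACGT", "G1")] * 10
        cm = build_count_matrix(_frame(rows), wl)
        assert cm.matrix.sum() == 1

    def test_multigene_tie_dropped(self):
        wl = Whitelist({"AAAACCCC": 10})
        rows = [_read_row("AAAACCCC", "ACGTACGT", "G1"), _read_row("AAAACCCC", "ACGTACGT", "G2")]
        with pytest.warns(UserWarning, match="all reads rejected"):
            cm = build_count_matrix(_frame(rows), wl)
        assert cm.matrix.sum() == 0

    def test_multigene_majority_wins(self):
        wl = Whitelist({"AAAACCCC": 10})
        rows = [_read_row("AAAACCCC", "ACGTACGT", "G1")] * 3 + [
            _read_row("AAAACCCC", "ACGTACGT", "G2")
        ]
        cm = build_count_matrix(_frame(rows), wl)
        assert dict(zip(cm.genes, np.asarray(cm.matrix.sum(axis=1)).ravel())) == {"G1": 1}

    def test_all_rejected_warns_returns_empty(self):
        wl = Whitelist({"AAAACCCC": 10})
        rows = [_read_row("AAAACCCC", "AAAAAAAA", "G1")]  # homopolymer UMI
        with pytest.warns(UserWarning, match="all reads rejected"):
            cm = build_count_matrix(_frame(rows), wl)
        assert cm.matrix.nnz == 0

    def test_mixed_fixture_matches_bruteforce(self):
        """~50 reads with correctable barcode and UMI errors vs the pure-python
        demultiplexer."""
        rng = np.random.default_rng(17)
        wl_counts = {"AAAACCCC": 40, "GGGGTTTT": 30, "ACACACAC": 25}
        wl = Whitelist(wl_counts)
        genes = ["G1", "G2", "G3"]
        rows = []
        for bc in wl_counts:
            for gene in genes:
                for _ in range(4):
                    umi = "".join(rng.choice(list("ACGT"), 8))
                    if len(set(umi)) == 1:
                        umi = "ACGTACGT"
                    rows.append(_read_row(bc, umi, gene))
        # correctable barcode errors (one low-quality mismatch)
        rows.append(_read_row("AAAACCCA", "ACGTACGT", "G1",
                              bq=phred_encode([35] * 7 + [8])))
        rows.append(_read_row("GGGGTTTA", "TGCATGCA", "G2",
                              bq=phred_encode([35] * 7 + [8])))
        # UMI merge fixture: prolific UMI plus a Hamming-1 satellite
        rows += [_read_row("ACACACAC", "AAACCCGG", "G3")] * 5
        rows.append(_read_row("ACACACAC", "AAACCCGT", "G3"))
        # rejected reads: homopolymer UMI, low-quality UMI, off-whitelist barcode
        rows.append(_read_row("AAAACCCC", "TTTTTTTT", "G1"))
        rows.append(_read_row("AAAACCCC", "ACGTTGCA", "G1", uq=phred_encode([9] * 8)))
        rows.append(_read_row("CCCCAAAA", "ACGTACGT", "G1"))
        cm = build_count_matrix(_frame(rows), wl)
        expected = brute_demux([tuple(r) for r in rows], wl_counts)
        got = {
            (bc, gene): int(cm.matrix[i, j])
            for i, gene in enumerate(cm.genes)
            for j, bc in enumerate(cm.barcodes)
            if cm.matrix[i, j] != 0
        }
        assert got == expected

    @pytest.mark.parametrize("seed", [0, 1])
    def test_random_reads_match_bruteforce(self, seed):
        """Random small read sets (<=100 reads) against the brute-force oracle."""
        rng = np.random.default_rng(seed)
        wl_counts = {"AAAA": 30, "AAAT": 12, "CCGG": 20, "TTTT": 5}
        wl = Whitelist(wl_counts)
        rows = []
        for _ in range(100):
            bc = "".join(rng.choice(list("ACGT"), 4))
            umi = "".join(rng.choice(list("ACGT"), 4))
            gene = rng.choice(["G1", "G2"])
            bq = phred_encode(rng.integers(5, 41, 4))
            uq = phred_encode(rng.integers(5, 41, 4))
            rows.append((bc, bq, umi, uq, gene))
        expected = brute_demux(rows, wl_counts)
        if not expected:
            pytest.skip("degenerate draw: oracle rejects everything")
        cm = build_count_matrix(_frame(rows), wl)
        got = {
            (bc, gene): int(cm.matrix[i, j])
            for i, gene in enumerate(cm.genes)
            for j, bc in enumerate(cm.barcodes)
            if cm.matrix[i, j] != 0
        }
        assert got == expected
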