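"""Clade-stratified conservation fractions and calls."""

import pytest
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from flavoscore.conservation import (
    CladeTable,
    ConservationConfig,
    MsaError,
    call_position,
    check_clade_coverage,
    classify_conservation,
    column_for_reference_position,
    conservation_fractions,
    read_clade_table,
    read_msa,
)
from flavoscore.fixtures import MsaSpec, make_synthetic_msa, write_clade_table_tsv


def msa_of(rows: dict[str, str]) -> MultipleSeqAlignment:
    return MultipleSeqAlignment(
        [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in rows.items()]
    )


@pytest.fixture
def four_row_msa(tmp_path):
    rows = {"h1": "ACDE", "h2": "ACDE", "m1": "ACDF", "o1": "GCDE"}
    clades = CladeTable(
        {"h1": "chordata", "h2": "chordata", "m1": "metazoa", "o1": "other"}
    )
    return rows, clades


class TestReaders:
    def test_fasta_msa_and_clade_table(self, tmp_path, four_row_msa):
        rows, clades = four_row_msa
        mp = tmp_path / "aln.fasta"
        mp.write_text("".join(f">{k}\n{v}\n" for k, v in rows.items()))
        cp = tmp_path / "clades.tsv"
        write_clade_table_tsv(clades, cp)
        msa = read_msa(mp)
        table = read_clade_table(cp)
        assert len(msa) == 4
        check_clade_coverage(msa, table)  # must not raise

    def test_missing_id_in_clade_table_named(self, tmp_path, four_row_msa):
        rows, _ = four_row_msa
        mp = tmp_path / "aln.fasta"
        mp.write_text("".join(f">{k}\n{v}\n" for k, v in rows.items()))
        msa = read_msa(mp)
        incomplete = CladeTable({"h1": "chordata", "h2": "chordata",
                                 "m1": "metazoa"})
        with pytest.raises(MsaError, match="o1"):
            check_clade_coverage(msa, incomplete)

    def test_ragged_msa_rejected(self, tmp_path):
        mp = tmp_path / "ragged.fasta"
        mp.write_text(">a\nACDE\n>b\nACD\n")
        with pytest.raises(MsaError):
            read_msa(mp)

    def test_unknown_clade_label_rejected(self):
        with pytest.raises(ValueError, match="unknown clade"):
            CladeTable({"x": "plantae"})


class TestColumnLookup:
    def test_ungapped_reference(self):
        msa = msa_of({"ref": "ACDEF", "x": "ACDEF"})
        assert column_for_reference_position(msa, "ref", 5) == 5

    def test_gapped_reference(self):
        msa = msa_of({"ref": "AC--DE", "x": "ACGGDE"})
        assert column_for_reference_position(msa, "ref", 3) == 5

    def test_position_beyond_reference_length(self):
        msa = msa_of({"ref": "AC--DE", "x": "ACGGDE"})
        with pytest.raises(IndexError):
            column_for_reference_position(msa, "ref", 5)

    def test_agrees_with_scan_count_oracle(self, rng):
        for _ in range(20):
            n = 30
            chars = [
                "-" if rng.random() < 0.3 else "ACDEFGHIK"[rng.integers(9)]
                for _ in range(n)
            ]
            row = "".join(chars)
            msa = msa_of({"ref": row, "x": "A" * n})
            nongap = [i + 1 for i, c in enumerate(row) if c != "-"]
            for pos, col in enumerate(nongap, start=1):
                assert column_for_reference_position(msa, "ref", pos) == col


class TestFractions:
    def test_fully_conserved_column(self, four_row_msa):
        rows, clades = four_row_msa
        fr = conservation_fractions(msa_of(rows), 2, clades, "C")
        assert fr == {"chordata": 1.0, "metazoa": 1.0, "eukaryota": 1.0,
                      "all": 1.0}

    def test_cumulative_membership(self, four_row_msa):
        rows, clades = four_row_msa
        # column 1: chordates AA, metazoan A, other G
        fr = conservation_fractions(msa_of(rows), 1, clades, "A")
        assert fr["chordata"] == 1.0
        assert fr["metazoa"] == 1.0  # 3/3 incl. chordates
        assert fr["all"] == pytest.approx(3 / 4)

    def test_gap_counts_as_mismatch(self):
        msa = msa_of({"a": "A", "b": "-"})
        clades = CladeTable({"a": "chordata", "b": "chordata"})
        fr = conservation_fractions(msa, 1, clades, "A")
        assert fr["chordata"] == pytest.approx(0.5)

    def test_constructed_96_percent_metazoa(self):
        # 96 of 100 metazoan rows match; 50 of 100 additional eukaryote rows
        rows = {}
        clades = {}
        for i in range(100):
            sid = f"m{i}"
            rows[sid] = "A" if i < 96 else "S"
            clades[sid] = "metazoa"
        for i in range(100):
            sid = f"e{i}"
            rows[sid] = "A" if i < 4 else "S"  # (96+4)/200 = 0.50 overall
            clades[sid] = "eukaryota"
        fr = conservation_fractions(msa_of(rows), 1, CladeTable(clades), "A")
        assert fr["metazoa"] == pytest.approx(0.96)
        assert fr["eukaryota"] == pytest.approx(0.50)


class TestClassify:
    @pytest.mark.parametrize(
        "fractions, expected",
        [
            ({"chordata": 1, "metazoa": 1, "eukaryota": 1, "all": 1}, "all"),
            ({"chordata": 0.99, "metazoa": 0.96, "eukaryota": 0.80,
              "all": 0.60}, "metazoa"),
            ({"chordata": 0.95, "metazoa": 0.90, "eukaryota": 0.40,
              "all": 0.30}, "none"),  # strict > at the threshold
            ({"chordata": 0.40, "metazoa": 0.97, "eukaryota": 0.20,
              "all": 0.10}, "metazoa"),
        ],
    )
    def test_most_general_clade_above_threshold(self, fractions, expected):
        call = classify_conservation(fractions)
        assert call.call == expected

    def test_threshold_monotonicity(self):
        fractions = {"chordata": 0.99, "metazoa": 0.97, "eukaryota": 0.96,
                     "all": 0.80}
        order = ["none", "chordata", "metazoa", "eukaryota", "all"]
        prev_rank = len(order)
        for th in (0.90, 0.95, 0.965, 0.98):
            call = classify_conservation(fractions, ConservationConfig(th))
            rank = order.index(call.call)
            assert rank <= prev_rank  # raising threshold never broadens
            prev_rank = rank

    def test_empty_clade_not_evaluable(self):
        msa = msa_of({"o1": "A", "o2": "A"})
        clades = CladeTable({"o1": "other", "o2": "other"})
        fr = conservation_fractions(msa, 1, clades, "A")
        assert "chordata" not in fr
        assert classify_conservation(fr).call == "all"


class TestSyntheticRecovery:
    def test_target_calls_recovered(self):
        targets = ("all", "eukaryota", "metazoa", "chordata", "none")
        spec = MsaSpec(reference="AAAAA", target_calls=targets, seed=7)
        msa, clades = make_synthetic_msa(spec)
        for pos, want in enumerate(targets, start=1):
            got = call_position(msa, clades, "ref", pos)
            assert got.call == want, f"column {pos}"

    def test_generator_deterministic_under_seed(self):
        spec = MsaSpec(reference="ACD", target_calls=("all", "none", "metazoa"),
                       seed=11)
        m1, _ = make_synthetic_msa(spec)
        m2, _ = make_synthetic_msa(spec)
        assert [str(r.seq) for r in m1] == [str(r.seq) for r in m2]

    def test_infeasible_spec_errors_with_minimum_count(self):
        # eukaryota block too small: cumulative metazoa cannot stay <= 0.95
        spec = MsaSpec(reference="A", target_calls=("metazoa",),
                       n_chordata=40, n_metazoa=60, n_eukaryota=1, n_other=1)
        with pytest.raises(ValueError, match="at least"):
            make_synthetic_msa(spec)
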