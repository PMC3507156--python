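import numpy as np
import pytest

from triadcore.conservation import (
    Alignment,
    classify_conservation,
    column_occupancy,
    conservation_table,
    map_reference_numbering,
    progressive_align,
    read_alignment,
    write_alignment_fasta,
)
from triadcore.synthetic import make_synthetic_alignment


@pytest.fixture
def toy_alignment():
    return Alignment(ids=["s1", "s2"], rows=["AC-G", "ACTG"])


def test_fasta_and_clustal_inputs_are_equivalent(tmp_path, toy_alignment):
    fasta = tmp_path / "aln.fasta"
    fasta.write_text(">s1\nAC-G\n>s2\nACTG\n")
    clustal = tmp_path / "aln.aln"
    clustal.write_text(
        "CLUSTAL W (1.83) multiple sequence alignment\n\n"
        "s1              AC-G\n"
        "s2              ACTG\n"
    )
    a = read_alignment(fasta, "fasta")
    b = read_alignment(clustal, "clustal")
    assert a.rows == b.rows == toy_alignment.rows
    assert a.length == 4


def test_ragged_fasta_names_the_offending_row(tmp_path):
    path = tmp_path / "ragged.fasta"
    path.write_text(">ok\nACDG\n>short\nAC\n")
    with pytest.raises(ValueError, match="short"):
        read_alignment(path, "fasta")


def test_unknown_characters_reported_with_position():
    with pytest.raises(ValueError, match="position 3"):
        Alignment(ids=["a", "b"], rows=["AC1G", "ACTG"])


def test_reference_numbering_skips_reference_gaps():
    aln = Alignment(ids=["ref", "q"], rows=["A-CD", "AACD"])
    mapping = map_reference_numbering(aln, "ref", first_number=10)
    assert mapping == {1: 10, 3: 11, 4: 12}


def test_reference_numbering_is_consecutive_without_gaps():
    aln = Alignment(ids=["ref", "q"], rows=["ACDEFG", "ACDEFG"])
    mapping = map_reference_numbering(aln, "ref", first_number=158)
    assert list(mapping.values()) == list(range(158, 164))
    assert len(mapping) == len("ACDEFG")


def test_catalytic_columns_map_to_reference_numbers():
    # a reference row numbered from 156 puts the conserved Ser at 158
    aln = Alignment(ids=["cbp2", "q1", "q2"],
                    rows=["GESYA", "GDSYA", "G-SFA"])
    mapping = map_reference_numbering(aln, "cbp2", first_number=156)
    assert mapping[3] == 158
    assert aln.row("cbp2")[2] == "S"


def test_occupancy_all_same_residue_is_invariant():
    aln = make_synthetic_alignment(13, 1, [("G", 1.0)], seed=0)
    prof = column_occupancy(aln, 1)
    assert prof.occupancy_pct == 100.0
    assert prof.category == "invariant"
    assert prof.modal_residue == "G"


def test_occupancy_ten_of_thirteen_rounds_to_77():
    aln = make_synthetic_alignment(13, 1, [("G", 10 / 13)], seed=1)
    prof = column_occupancy(aln, 1, residue="G")
    assert prof.occupancy_pct == pytest.approx(100 * 10 / 13)
    assert prof.occupancy_rounded == 77
    assert prof.category == "medium"


def test_occupancy_counts_gaps_in_denominator():
    aln = Alignment(ids=list("abcd"), rows=["G-", "G-", "A-", "C-"])
    prof = column_occupancy(aln, 1, residue="G")
    assert prof.occupancy_pct == pytest.approx(50.0)
    gap_col = column_occupancy(aln, 2, residue="G")
    assert gap_col.occupancy_pct == 0.0


def test_occupancy_column_out_of_range(toy_alignment):
    with pytest.raises(IndexError):
        column_occupancy(toy_alignment, 5)


def test_conservation_categories_at_thresholds():
    assert classify_conservation(100.0) == "invariant"
    assert classify_conservation(75.0) == "medium"
    assert classify_conservation(60.0) == "medium"
    assert classify_conservation(20.0) == "low"
    with pytest.raises(ValueError):
        classify_conservation(120.0)


def test_occupancy_invariant_under_row_reordering():
    aln = make_synthetic_alignment(10, 6, [("A", 0.6)] * 6, seed=3)
    perm = np.random.default_rng(0).permutation(10)
    shuffled = Alignment(ids=[aln.ids[i] for i in perm],
                         rows=[aln.rows[i] for i in perm])
    for col in range(1, 7):
        assert column_occupancy(aln, col, "A").occupancy_pct == \
            column_occupancy(shuffled, col, "A").occupancy_pct


def test_column_counts_partition_the_rows():
    aln = make_synthetic_alignment(9, 5, [("W", 0.5)] * 5, seed=4)
    for col in range(1, 6):
        column = aln.column(col)
        assert len(column) == aln.n_rows


def test_conservation_table_maps_reference_positions():
    aln = Alignment(ids=["ref", "a", "b"], rows=["GAS", "GAS", "GCS"])
    profiles = conservation_table(aln, reference_id="ref", first_number=156)
    assert [p.ref_number for p in profiles] == [156, 157, 158]
    assert profiles[0].category == "invariant"
    assert profiles[1].occupancy_pct == pytest.approx(100 * 2 / 3)


def test_progressive_aligner_recovers_planted_conserved_block(tmp_path):
    rng = np.random.default_rng(9)
    letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    block = "".join(rng.choice(letters, size=25))
    seqs = {
        f"s{i}": "".join(rng.choice(letters, size=5 + i)) + block
        + "".join(rng.choice(letters, size=8 - i))
        for i in range(4)
    }
    aln = progressive_align(seqs)
    assert len({len(r) for r in aln.rows}) == 1
    # the planted block must produce 25 consecutive invariant-ish columns
    full_cols = [
        col for col in range(1, aln.length + 1)
        if column_occupancy(aln, col).occupancy_pct == 100.0
    ]
    assert len(full_cols) >= 25
    # round trip through FASTA keeps the alignment intact
    path = write_alignment_fasta(aln, tmp_path / "out.fasta")
    again = read_alignment(path, "fasta")
    assert again.rows == aln.rows
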