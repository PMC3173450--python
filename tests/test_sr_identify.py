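import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from srcensus import (
    ColumnClassCounts,
    DomainHit,
    MsaMatrix,
    ProteinRecord,
    classify_columns,
    dedupe_identical,
    extract_and_concatenate_rrms,
    filter_by_evalue,
    remove_sparse_columns,
    validate_sr,
)
from srcensus.errors import ConsistencyError
from srcensus.sr_identify import count_sr_dipeptides
from srcensus.synthetic import simulate_msa, simulate_protein_family


def hit(pid="P", kind="RRM", start=1, end=50, evalue=1e-10):
    return DomainHit(pid, kind, start, end, evalue)


# ---------------------------------------------------------------------------
# e-value filter

@pytest.mark.parametrize(
    "evalue,kept", [(1e-4, True), (1e-3, True), (1e-2, False)]
)
def test_evalue_threshold_strictly_greater_excluded(evalue, kept):
    hits = [hit(evalue=evalue)]
    assert (len(filter_by_evalue(hits)) == 1) is kept


def test_empty_hit_list_stays_empty():
    assert filter_by_evalue([]) == []


# ---------------------------------------------------------------------------
# architecture rules

def make_protein(seq, rrm_coords, evalue=1e-10):
    hits = tuple(DomainHit("P", "RRM", s, e, evalue) for s, e in rrm_coords)
    return ProteinRecord("P", seq, hits)


def test_canonical_two_rrm_protein_accepted():
    seq = "M" + "A" * 10 + "G" * 80 + "L" * 10 + "V" * 80 + "P" * 5 + "RSRSPSRS" + "G"
    rrm1 = (12, 91)
    rrm2 = (102, 181)
    verdict = validate_sr(make_protein(seq, [rrm1, rrm2]))
    assert verdict.accepted and verdict.reasons == ()


def test_missing_met_start_rejected():
    seq = "A" * 20 + "G" * 80 + "RSRSRS"
    verdict = validate_sr(make_protein(seq, [(21, 100)]))
    assert not verdict.accepted
    assert verdict.reasons == ("met_start",)


def test_two_dipeptides_insufficient():
    seq = "M" + "A" * 10 + "G" * 80 + "RSKRS"
    verdict = validate_sr(make_protein(seq, [(12, 91)]))
    assert verdict.reasons == ("rs_dipeptides",)


def test_three_rrms_rejected():
    seq = "M" + "G" * 240 + "RSRSRS"
    verdict = validate_sr(make_protein(seq, [(2, 81), (82, 161), (162, 241)]))
    assert "rrm_count" in verdict.reasons


def test_rs_region_before_rrm_flags_position():
    seq = "M" + "RSRSRSRS" + "A" * 5 + "G" * 80 + "P" * 3 + "SRSRSR"
    verdict = validate_sr(make_protein(seq, [(15, 94)]))
    assert verdict.reasons == ("rrm_position",)


def test_all_rrm_hits_failing_evalue_named_as_such():
    seq = "M" + "A" * 10 + "G" * 80 + "RSRSRS"
    verdict = validate_sr(make_protein(seq, [(12, 91)], evalue=0.5))
    assert verdict.reasons == ("evalue",)


def test_dipeptide_counting_is_non_overlapping():
    assert count_sr_dipeptides("RSRS") == 2
    assert count_sr_dipeptides("SRS") == 1
    assert count_sr_dipeptides("RRSSRR") == 2
    assert count_sr_dipeptides("KAKA") == 0


def test_generator_labels_recovered_exactly():
    """Planted rule violations are recovered with zero error, one rule each."""
    mix = {"valid": 4, "evalue": 2, "met_start": 2, "rrm_count": 2,
           "rrm_position": 2, "rs_dipeptides": 2}
    proteins, labels = simulate_protein_family(40, mix, seed=8)
    assert len(proteins) == 40
    for p in proteins:
        verdict = validate_sr(p)
        if labels[p.id] == "valid":
            assert verdict.accepted, (p.id, verdict.reasons)
        else:
            assert verdict.reasons == (labels[p.id],), (p.id, verdict.reasons)


# ---------------------------------------------------------------------------
# RRM extraction / concatenation

def test_concatenation_width_and_gap_fill():
    p1 = ProteinRecord("a", "MGGGGAAAACCCC" + "RSRSRS",
                       (hit("a", start=6, end=9), hit("a", start=10, end=13)))
    p2 = ProteinRecord("b", "MGGGGTTTT" + "RSRSRS", (hit("b", start=6, end=9),))
    n_aln = MsaMatrix(("a", "b"), ("AAAA-", "TT-TT"))
    c_aln = MsaMatrix(("a",), ("CC-CC",))
    cat = extract_and_concatenate_rrms([p1, p2], n_aln, c_aln)
    assert cat.n_cols == n_aln.n_cols + c_aln.n_cols
    assert cat.row("a") == "AAAA-CC-CC"
    assert cat.row("b") == "TT-TT-----"  # single-RRM row gap-filled


def test_concatenation_checks_residues_against_coordinates():
    p = ProteinRecord("a", "MGGGGAAAA" + "RSRSRS", (hit("a", start=6, end=9),))
    wrong = MsaMatrix(("a",), ("TTTT",))
    with pytest.raises(ConsistencyError):
        extract_and_concatenate_rrms([p], wrong, MsaMatrix((), ()))


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 5_000))
def test_degap_round_trip_preserves_rrm_residues(seed):
    rng = np.random.default_rng(seed)
    proteins, labels = simulate_protein_family(6, {"valid": 1}, seed=seed)
    two = [p for p in proteins if len(p.rrm_hits()) == 2]
    one = [p for p in proteins if len(p.rrm_hits()) == 1]
    # build trivial alignments (rows = ungapped RRMs padded with terminal gaps)
    def block(ps, which):
        seqs = {p.id: p.sequence[p.rrm_hits()[which].start - 1: p.rrm_hits()[which].end]
                for p in ps}
        width = max(map(len, seqs.values()), default=0)
        return MsaMatrix(tuple(seqs), tuple(s + "-" * (width - len(s)) for s in seqs.values()))
    n_aln = block(two + one, 0)
    c_aln = block(two, 1)
    cat = extract_and_concatenate_rrms(two + one, n_aln, c_aln)
    for p in two + one:
        row = cat.row(p.id)
        n_w = n_aln.n_cols
        got = (row[:n_w] + row[n_w:]).replace("-", "")
        expected = "".join(
            p.sequence[h.start - 1: h.end] for h in p.rrm_hits()
        )
        assert got == expected


# ---------------------------------------------------------------------------
# column operations

def test_sparse_columns_removed():
    msa = MsaMatrix(
        ("a", "b", "c"),
        ("A-C-", "A--A", "A--C"),
    )
    # col0: 3 residues keep; col1: 0 drop; col2: 1 drop; col3: 2 keep
    out = remove_sparse_columns(msa)
    assert out.rows == ("A-", "AA", "AC")


def test_sparse_removal_idempotent_on_random_alignments():
    for seed in range(10):
        msa, _ = simulate_msa(8, (5, 6, 4), seed=seed)
        once = remove_sparse_columns(msa)
        assert remove_sparse_columns(once).rows == once.rows


def test_dedupe_collapses_identical_rows():
    msa = MsaMatrix(("a", "b", "c", "d"), ("AC-", "GT-", "AC-", "GGG"))
    reduced, rep_map = dedupe_identical(msa)
    assert reduced.ids == ("a", "b", "d")
    assert rep_map["a"] == ["c"]


def test_dedupe_identity_when_all_unique():
    msa = MsaMatrix(("a", "b"), ("AC", "GT"))
    reduced, rep_map = dedupe_identical(msa)
    assert reduced == msa and all(not v for v in rep_map.values())


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 5_000), st.integers(1, 5))
def test_dedupe_removes_exactly_k_duplicated_rows(seed, k):
    base, _ = dedupe_identical(simulate_msa(6, (4, 5, 3), seed=seed)[0])
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, base.n_rows, size=k)
    ids = base.ids + tuple(f"dup{i}" for i in range(k))
    rows = base.rows + tuple(base.rows[j] for j in picks)
    reduced, _ = dedupe_identical(MsaMatrix(ids, rows))
    assert reduced.n_rows == base.n_rows == len(rows) - k


@pytest.mark.parametrize(
    "column,expected",
    [
        ("AAAA", "constant"),
        ("AAGG", "informative"),
        ("AAGC", "uninformative"),
        ("A-A-", "constant"),
        ("AAG-", "uninformative"),
        ("AXAA", "constant"),  # 'X' is missing data
        ("----", "constant"),  # no states at all: nothing varies
    ],
)
def test_column_classification_cases(column, expected):
    msa = MsaMatrix(tuple("abcd"), tuple(column))
    cc = classify_columns(msa)
    got = {
        "constant": cc.n_constant,
        "informative": cc.n_informative,
        "uninformative": cc.n_uninformative,
    }
    assert got[expected] == 1 and cc.n_columns == 1


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_column_class_partition_identity(seed):
    rng = np.random.default_rng(seed)
    shape = tuple(int(x) for x in rng.integers(0, 30, size=3))
    n_rows = int(rng.integers(4, 12))
    msa, expected = simulate_msa(n_rows, shape, seed=seed)
    cc = classify_columns(msa)
    assert cc == expected
    assert cc.n_constant + cc.n_informative + cc.n_uninformative == cc.n_columns


def test_partition_counts_must_sum():
    with pytest.raises(ValueError):
        ColumnClassCounts(10, 5, 3, 1)
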