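"""Format readers/writers: FASTA, hit tables, minimal SAM, OBO, annotations."""

import io

import pytest

from txstratkit import seqio
from txstratkit.seqio import FormatError, HitTableColumns


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "text, expected",
    [
        (">c1\nACGT\n", [("c1", "ACGT")]),
        (">c1 desc\nAC\nGT\n", [("c1", "ACGT")]),  # wrapping + header token
        (">c1\nacgt\n>c2\nTT\n", [("c1", "ACGT"), ("c2", "TT")]),  # uppercasing
    ],
)
def test_read_fasta(text, expected):
    contigs = seqio.read_fasta(io.StringIO(text))
    assert [(c.id, c.sequence) for c in contigs] == expected
    assert all(c.length == len(c.sequence) for c in contigs)


def test_read_fasta_duplicate_id_names_offender():
    with pytest.raises(FormatError, match="c1"):
        seqio.read_fasta(io.StringIO(">c1\nAC\n>c1\nGT\n"))


def test_read_fasta_empty_sequence_is_error():
    with pytest.raises(FormatError, match="empty"):
        seqio.read_fasta(io.StringIO(">c1\n>c2\nACGT\n"))


def test_fasta_round_trip(demo_bundle):
    buf = io.StringIO()
    seqio.write_fasta(demo_bundle.contigs, buf)
    buf.seek(0)
    again = seqio.read_fasta(buf)
    assert [(c.id, c.sequence) for c in again] == [
        (c.id, c.sequence) for c in demo_bundle.contigs
    ]


# ---------------------------------------------------------------------------
# Hit tables
# ---------------------------------------------------------------------------


def _hit_row(query="c1", subject="sp|X", evalue="1e-05", bitscore="88"):
    fields = [query, subject] + ["0"] * 8 + [evalue, bitscore]
    return "\t".join(fields)


def test_read_hits_threshold_and_tagging():
    text = _hit_row(evalue="1e-05") + "\n" + _hit_row(query="c2", evalue="0.5") + "\n"
    hits = seqio.read_hits(io.StringIO(text), "binA", evalue_threshold=1e-3)
    assert [h.query_id for h in hits] == ["c1"]  # 0.5 row dropped at the 1e-3 cutoff
    assert hits[0].bin == "binA"
    assert hits[0].evalue == pytest.approx(1e-5)
    assert hits[0].bitscore == pytest.approx(88.0)


def test_read_hits_empty_file():
    assert seqio.read_hits(io.StringIO(""), "binA") == []


def test_read_hits_non_numeric_evalue_reports_line():
    text = _hit_row() + "\n" + _hit_row(evalue="oops") + "\n"
    with pytest.raises(FormatError, match="line 2"):
        seqio.read_hits(io.StringIO(text), "binA")


def test_read_hits_custom_columns():
    text = "1e-05\tc1\tsbj\t42\n"
    cols = HitTableColumns(query=1, subject=2, evalue=0, bitscore=3)
    hits = seqio.read_hits(io.StringIO(text), "b", columns=cols)
    assert hits[0].query_id == "c1" and hits[0].bitscore == 42.0


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------


def _sam_line(qname="r1", flag=0, rname="c1"):
    return "\t".join([qname, str(flag), rname, "0", "255", "*", "*", "0", "0", "*", "*"])


def test_read_sam_flag_semantics():
    text = "@HD\tVN:1.6\n" + "\n".join(
        [
            _sam_line("r1", 0, "c1"),
            _sam_line("r2", 4, "*"),
            _sam_line("r3", 256, "c1"),  # secondary: excluded
            _sam_line("r4", 2048, "c1"),  # supplementary: excluded
        ]
    )
    records = seqio.read_sam(io.StringIO(text))
    assert [(r.read_id, r.reference_id) for r in records] == [("r1", "c1"), ("r2", None)]
    assert records[0].is_aligned and not records[1].is_aligned


def test_read_sam_record_accounting():
    """aligned + unaligned = n - secondary - supplementary."""
    lines = [_sam_line(f"r{i}", 0, "c1") for i in range(5)]
    lines += [_sam_line(f"u{i}", 4, "*") for i in range(3)]
    lines += [_sam_line(f"s{i}", 256, "c1") for i in range(2)]
    lines += [_sam_line("x", 2048, "c1")]
    records = seqio.read_sam(io.StringIO("\n".join(lines)))
    aligned = sum(r.is_aligned for r in records)
    unaligned = sum(not r.is_aligned for r in records)
    assert aligned + unaligned == len(lines) - 3
    assert (aligned, unaligned) == (5, 3)


def test_read_sam_short_record_reports_line():
    with pytest.raises(FormatError, match="line 2"):
        seqio.read_sam(io.StringIO(_sam_line() + "\nr2\t0\tc1\n"))


# ---------------------------------------------------------------------------
# OBO
# ---------------------------------------------------------------------------


def test_read_obo_parents_and_obsolete(small_dag):
    assert small_dag.term("GO:0000002").parents == ("GO:0000001",)
    assert small_dag.term("GO:0000004").parents == ("GO:0000002", "GO:0000003")
    assert small_dag.term("GO:0000005").obsolete
    assert small_dag.roots("molecular_function") == ["GO:0000001"]


def test_read_obo_cycle_is_error():
    obo = (
        "format-version: 1.2\n\n"
        "[Term]\nid: GO:0000001\nname: a\nis_a: GO:0000002\n\n"
        "[Term]\nid: GO:0000002\nname: b\nis_a: GO:0000001\n"
    )
    with pytest.raises(FormatError, match="cycle"):
        seqio.read_obo(io.StringIO(obo))


def test_read_obo_dangling_parent_is_error():
    obo = "format-version: 1.2\n\n[Term]\nid: GO:0000001\nname: a\nis_a: GO:0000099\n"
    with pytest.raises(FormatError, match="GO:0000099"):
        seqio.read_obo(io.StringIO(obo))


def test_obo_ancestors_finite_and_self_excluded(demo_bundle):
    """Repeated parent lookup terminates and never revisits the start term."""
    dag = seqio.read_obo(io.StringIO(demo_bundle.obo_text))
    for tid in dag:
        ancestors, frontier = set(), {tid}
        while frontier:
            frontier = {p for t in frontier for p in dag.term(t).parents} - ancestors
            ancestors |= frontier
        assert tid not in ancestors


def test_read_obo_relationship_allow_list():
    obo = (
        "format-version: 1.2\n\n"
        "[Term]\nid: GO:0000001\nname: a\n\n"
        "[Term]\nid: GO:0000002\nname: b\nis_a: GO:0000001\nrelationship: part_of GO:0000001\n"
    )
    dag = seqio.read_obo(io.StringIO(obo))
    assert dag.term("GO:0000002").parents == ("GO:0000001",)
    dag2 = seqio.read_obo(io.StringIO(obo), relationships=("is_a", "part_of"))
    assert dag2.term("GO:0000002").parents == ("GO:0000001",)


# ---------------------------------------------------------------------------
# Annotation tables
# ---------------------------------------------------------------------------


def test_read_annotations_go_unresolved(small_dag):
    text = "contig_id\tlabel\nc1\tGO:0000002\nc2\tGO:9999999\n"
    table = seqio.read_annotations(io.StringIO(text), ontology=small_dag, kind="go")
    assert table.unresolved == {"GO:9999999"}
    assert table.by_contig()["c1"] == {"GO:0000002"}


def test_read_annotations_malformed_ec_reports_line():
    text = "contig_id\tlabel\nc1\t1.1.1.1\nc2\tnot-an-ec\n"
    with pytest.raises(FormatError, match="line 3"):
        seqio.read_annotations(io.StringIO(text), kind="ec")
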