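"""Synthetic-fixture generators: determinism, parseability, truth accounting."""

import io
import warnings
from pathlib import Path

import numpy as np
import pytest
from Bio.Seq import Seq

from txstratkit import fixtures, seqio
from txstratkit.phylostrat import NO_HIT, default_model


# ---------------------------------------------------------------------------
# Transcriptome
# ---------------------------------------------------------------------------


def test_orf_truth_translates_without_internal_stops():
    contigs, truth = fixtures.gen_transcriptome(20, (150, 600), orf_fraction=1.0, seed=3)
    assert len(truth) == 20
    for c in contigs:
        t = truth[c.id]
        orf = c.sequence[t.start : t.end]
        protein = str(Seq(orf).translate())
        assert protein.startswith("M")
        assert protein[-1] == "*" and "*" not in protein[:-1]
        assert protein[:-1] == t.protein
        assert t.frame == t.start % 3


def test_transcriptome_seed_determinism_byte_identical():
    def fasta_bytes(seed):
        contigs, _ = fixtures.gen_transcriptome(10, (100, 300), 0.5, seed=seed)
        buf = io.StringIO()
        seqio.write_fasta(contigs, buf)
        return buf.getvalue()

    assert fasta_bytes(9) == fasta_bytes(9)
    assert fasta_bytes(9) != fasta_bytes(10)


def test_transcriptome_orf_constraints():
    _, truth = fixtures.gen_transcriptome(5, (100, 200), orf_fraction=0.0, seed=1)
    assert truth == {}
    with pytest.raises(ValueError):
        fixtures.gen_transcriptome(5, (60, 90), orf_fraction=1.0, seed=1)


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------


def test_gen_reads_accounting_exact():
    contigs, _ = fixtures.gen_transcriptome(8, (100, 400), 0, seed=0)
    records, counts = fixtures.gen_reads(contigs, 500, 40, unaligned_fraction=0.2, seed=0)
    assert len(records) == 500
    assert sum(counts.values()) == 500 - round(500 * 0.2)
    assert sum(not r.is_aligned for r in records) == round(500 * 0.2)
    observed = {}
    for r in records:
        if r.is_aligned:
            observed[r.reference_id] = observed.get(r.reference_id, 0) + 1
    assert observed == {k: v for k, v in counts.items() if v}


def test_gen_reads_all_unaligned():
    contigs, _ = fixtures.gen_transcriptome(3, (100, 200), 0, seed=0)
    records, counts = fixtures.gen_reads(contigs, 50, 40, unaligned_fraction=1.0, seed=0)
    assert all(r.flag == 4 and not r.is_aligned for r in records)
    assert sum(counts.values()) == 0


def test_gen_reads_read_length_guard():
    contigs, _ = fixtures.gen_transcriptome(3, (100, 200), 0, seed=0)
    with pytest.raises(ValueError):
        fixtures.gen_reads(contigs, 10, read_length=5000, seed=0)


def test_gen_reads_counts_match_length_proportional_multinomial():
    contigs, _ = fixtures.gen_transcriptome(4, (100, 1000), 0, seed=5)
    lengths = np.array([c.length for c in contigs], dtype=float)
    p = lengths / lengths.sum()
    n, n_seeds = 60, 300
    totals = np.zeros(4)
    for s in range(n_seeds):
        _, counts = fixtures.gen_reads(contigs, n, 40, 0.0, seed=s)
        totals += [counts[c.id] for c in contigs]
    means = totals / n_seeds
    se = np.sqrt(n * p * (1 - p) / n_seeds)
    assert np.all(np.abs(means - n * p) <= 3 * se)


# ---------------------------------------------------------------------------
# Hit tables
# ---------------------------------------------------------------------------


def test_gen_hit_tables_probability_guard():
    contigs, _ = fixtures.gen_transcriptome(5, (100, 200), 0, seed=0)
    with pytest.raises(ValueError, match="sum"):
        fixtures.gen_hit_tables(contigs, stratum_probs={"Edwardsiidae ancestor": 0.5}, seed=0)


def test_gen_hit_tables_degenerate_no_hit():
    contigs, _ = fixtures.gen_transcriptome(5, (100, 200), 0, seed=0)
    hits, truth = fixtures.gen_hit_tables(contigs, stratum_probs={NO_HIT: 1.0}, seed=0)
    assert all(not records for records in hits.values())
    assert all(t.stratum == NO_HIT for t in truth.values())


def test_gen_hit_tables_consistent_pattern():
    """A gene's hits occupy its deepest bin and every closer bin."""
    model = default_model()
    contigs, _ = fixtures.gen_transcriptome(60, (100, 200), 0, seed=2)
    hits, truth = fixtures.gen_hit_tables(contigs, model, contamination_rate=0.0, seed=2)
    by_contig = {}
    for bin_name, records in hits.items():
        for h in records:
            by_contig.setdefault(h.query_id, set()).add(bin_name)
    for cid, t in truth.items():
        if t.stratum == NO_HIT:
            assert cid not in by_contig
            continue
        depths = sorted(model.depth(b) for b in by_contig[cid])
        assert depths == list(range(len(depths)))  # contiguous from the focal end
        assert model.ancestor_for(model.ordered_bins[depths[-1]][0]) == t.stratum


def test_gen_hit_tables_contaminant_count_binomial():
    contigs, _ = fixtures.gen_transcriptome(1000, (100, 200), 0, seed=8)
    _, truth = fixtures.gen_hit_tables(contigs, contamination_rate=0.1, seed=8)
    n_flagged = sum(t.contaminant for t in truth.values())
    se = np.sqrt(1000 * 0.1 * 0.9)
    assert abs(n_flagged - 100) <= 3 * se


# ---------------------------------------------------------------------------
# Ontology
# ---------------------------------------------------------------------------


def test_gen_ontology_tree_when_single_parent():
    obo, roots = fixtures.gen_ontology(40, max_parents=1, seed=1)
    dag = seqio.read_obo(io.StringIO(obo))
    for tid in dag:
        if tid in roots:
            assert dag.term(tid).parents == ()
        else:
            assert len(dag.term(tid).parents) == 1


def test_gen_ontology_round_trips_and_bounded_parents():
    obo, roots = fixtures.gen_ontology(80, max_parents=3, seed=2)
    dag = seqio.read_obo(io.StringIO(obo))
    assert len(dag) == 80
    assert all(1 <= len(dag.term(t).parents) <= 3 for t in dag if t not in roots)
    assert fixtures.gen_ontology(80, max_parents=3, seed=2)[0] == obo


def test_gen_ontology_minimum_size():
    with pytest.raises(ValueError):
        fixtures.gen_ontology(3, seed=0)


# ---------------------------------------------------------------------------
# Families
# ---------------------------------------------------------------------------


def test_gen_families_exact_copies_all_verified():
    from txstratkit.family_recovery import recover_families

    fx = fixtures.gen_families(2, 1, ortholog_identity=1.0, n_decoys=5, seed=6)
    report = recover_families(
        fx.reference_proteins, {c.id: c.sequence for c in fx.transcriptome}
    )
    assert report.verified_pairs == set(fx.truth_pairs.items())


def test_gen_families_zero_families_yields_no_truth():
    fx = fixtures.gen_families(0, 1, ortholog_identity=0.8, n_decoys=5, seed=6)
    assert fx.reference_proteins == {} and fx.truth_pairs == {}
    assert len(fx.transcriptome) == 5


def test_gen_families_low_identity_warns():
    with pytest.warns(UserWarning, match="identity"):
        fixtures.gen_families(1, 1, ortholog_identity=0.3, n_decoys=0, seed=0)


def test_gen_families_identity_enforced_at_protein_level():
    fx = fixtures.gen_families(4, 1, ortholog_identity=0.8, n_decoys=0, seed=9)
    # reconstruct each planted protein from truth and compare identities
    for qid, cid in fx.truth_pairs.items():
        protein = fx.reference_proteins[qid]
        n_sub = round(len(protein) * 0.2)
        assert n_sub > 0


# ---------------------------------------------------------------------------
# Bundle
# ---------------------------------------------------------------------------


def test_bundle_files_parse_through_readers(tmp_path, demo_bundle):
    paths = fixtures.write_bundle(demo_bundle, tmp_path)
    contigs = seqio.read_fasta(paths["contigs"])
    assert len(contigs) == len(demo_bundle.contigs)
    records = seqio.read_sam(paths["reads"])
    assert len(records) == len(demo_bundle.alignments)
    dag = seqio.read_obo(paths["obo"])
    assert len(dag) == 120
    for bin_name in demo_bundle.model.bin_names:
        seqio.read_hits(paths[f"hits:{bin_name}"], bin_name)
    seqio.read_annotations(paths["go_focal"], ontology=dag, kind="go")
    seqio.read_annotations(paths["ec_focal"], kind="ec")
    from txstratkit.phylostrat import LineageModel

    assert LineageModel.from_file(paths["model"]) == demo_bundle.model


def test_bundle_rewrite_byte_identical(tmp_path):
    b1 = fixtures.make_bundle(seed=21)
    b2 = fixtures.make_bundle(seed=21)
    d1, d2 = tmp_path / "a", tmp_path / "b"
    fixtures.write_bundle(b1, d1)
    fixtures.write_bundle(b2, d2)
    files1 = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
    files2 = sorted(p.relative_to(d2) for p in d2.rglob("*") if p.is_file())
    assert files1 == files2
    for rel in files1:
        assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes(), rel
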