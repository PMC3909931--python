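"""Seeded synthetic-fixture generators with recorded ground truth.

Every generator is deterministic in its seed (byte-identical outputs on
regeneration) and emulates one input class of the toolkit:

* contigs with embedded open reading frames,
* uniformly placed fixed-length read alignments (SAM),
* taxon-binned homology hit tables drawn under a known gene-birth
  stratum per gene, with optional injected contamination,
* small multi-parent ontologies in OBO 1.2,
* ortholog families planted at a stated protein identity among decoys.

What these emulate — and what they do not (sequencing error, expression
heterogeneity, paralogy, biased database composition) — is discussed in
the package's methods documentation; the generators exist so every
analysis stage runs offline at desk scale against known truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable

from . import phylostrat
from .phylostrat import LineageModel, NO_HIT, default_model
from .saturation import derive_seed
from .seqio import (
    AlignmentRecord,
    AnnotationTable,
    Contig,
    HitRecord,
    write_annotations,
    write_fasta,
    write_hits,
    write_sam,
)

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_AA = sorted(set(_TABLE.forward_table.values()))
_CODING_CODONS = sorted(_TABLE.forward_table)
_STOP_CODONS = sorted(_TABLE.stop_codons)
_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon in _CODING_CODONS:
    _CODONS_BY_AA.setdefault(_TABLE.forward_table[_codon], []).append(_codon)

_NT = np.array(list("ACGT"))


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_NT, size=n))


# ---------------------------------------------------------------------------
# Transcriptome
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OrfTruth:
    contig_id: str
    start: int  # 0-based, inclusive; position of the ATG
    end: int  # exclusive; end of the stop codon
    frame: int  # start % 3, forward strand
    protein: str  # translation incl. leading M, excl. stop


def gen_transcriptome(
    n_contigs: int,
    length_range: tuple[int, int] = (100, 2000),
    orf_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[list[Contig], dict[str, OrfTruth]]:
    """Random-composition contigs, a stated fraction carrying an embedded
    ORF (ATG, >= 30 amino-acid codons, stop) at recorded coordinates."""
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    lo, hi = length_range
    if lo < 60 or hi > 20000 or lo > hi:
        raise ValueError("length_range must lie within [60, 20000]")
    if orf_fraction > 0 and lo < 96:
        raise ValueError("embedding an ORF requires contig length >= 96 nt")
    rng = np.random.default_rng(derive_seed(seed, "transcriptome"))
    width = len(str(n_contigs))
    contigs: list[Contig] = []
    truth: dict[str, OrfTruth] = {}
    for i in range(n_contigs):
        cid = f"contig{i + 1:0{width}d}"
        length = int(rng.integers(lo, hi + 1))
        seq = _random_nt(rng, length)
        if rng.random() < orf_fraction:
            max_aa = min(length // 3 - 2, 400)
            n_aa = int(rng.integers(30, max_aa + 1))
            codons = ["ATG"]
            protein = ["M"]
            for _ in range(n_aa):
                codon = _CODING_CODONS[rng.integers(len(_CODING_CODONS))]
                codons.append(codon)
                protein.append(_TABLE.forward_table[codon])
            codons.append(_STOP_CODONS[rng.integers(len(_STOP_CODONS))])
            orf = "".join(codons)
            start = int(rng.integers(0, length - len(orf) + 1))
            seq = seq[:start] + orf + seq[start + len(orf):]
            truth[cid] = OrfTruth(cid, start, start + len(orf), start % 3, "".join(protein))
        contigs.append(Contig(id=cid, sequence=seq))
    return contigs, truth


# ---------------------------------------------------------------------------
# Reads / alignments
# ---------------------------------------------------------------------------


def gen_reads(
    contigs: Sequence[Contig],
    n_reads: int,
    read_length: int = 40,
    unaligned_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[list[AlignmentRecord], dict[str, int]]:
    """Simulated alignment outcomes: aligned reads land on contigs with
    probability proportional to contig length; a stated fraction is
    emitted unaligned (FLAG 4). Returns records (shuffled order) and the
    true per-contig aligned counts, which sum to
    ``n_reads - round(n_reads * unaligned_fraction)`` exactly."""
    if read_length > min(c.length for c in contigs):
        raise ValueError("read_length exceeds the shortest contig")
    rng = np.random.default_rng(derive_seed(seed, "reads"))
    n_unaligned = int(round(n_reads * unaligned_fraction))
    n_aligned = n_reads - n_unaligned
    lengths = np.array([c.length for c in contigs], dtype=float)
    counts = rng.multinomial(n_aligned, lengths / lengths.sum())
    records: list[AlignmentRecord] = []
    ridx = 0
    width = max(len(str(n_reads)), 1)
    for contig, k in zip(contigs, counts):
        for _ in range(int(k)):
            records.append(AlignmentRecord(f"read{ridx:0{width}d}", 0, contig.id))
            ridx += 1
    for _ in range(n_unaligned):
        records.append(AlignmentRecord(f"read{ridx:0{width}d}", 4, None))
        ridx += 1
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    truth = {c.id: int(k) for c, k in zip(contigs, counts)}
    return records, truth


# ---------------------------------------------------------------------------
# Taxon-binned hit tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StratumTruth:
    contig_id: str
    stratum: str  # ancestor label, or NO_HIT
    contaminant: bool


def default_stratum_probs(model: LineageModel | None = None) -> dict[str, float]:
    """A realistic gene-birth stratum mix for the default lineage model.

    60% of contigs produce no hit (short or fast-evolving sequences);
    among hit-producing genes the strata echo a typical anthozoan
    survey: ~19.2% tracing to the bacterial/eukaryote split, ~10.8% to
    the metazoan ancestor, ~2.2% to the cnidarian ancestor and ~16%
    confamilial-only.
    """
    if model is None:
        model = default_model()
    labels = [label for _, label in model.ordered_bins]
    probs = dict(zip(labels, (0.064, 0.0088, 0.1192, 0.0432, 0.08, 0.008, 0.0768)))
    probs[NO_HIT] = 0.6
    return probs


def gen_hit_tables(
    contigs: Sequence[Contig],
    model: LineageModel | None = None,
    stratum_probs: Mapping[str, float] | None = None,
    contamination_rate: float = 0.0,
    seed: int = 0,
) -> tuple[dict[str, list[HitRecord]], dict[str, StratumTruth]]:
    """Per-bin hit tables drawn under a known stratum per gene.

    Each non-contaminant contig draws a true stratum; hits are generated
    in the stratum's deepest bin and in every bin closer to the focal
    species (a consistency-preserving pattern), so deepest-hit-wins
    assignment recovers the stratum exactly. Contaminants (at
    ``contamination_rate``) instead receive hits only in the model's
    distal contamination bins — the signature the contamination flag
    detects.
    """
    if model is None:
        model = default_model()
    if stratum_probs is None:
        stratum_probs = default_stratum_probs(model)
    labels = list(stratum_probs)
    p = np.array([stratum_probs[l] for l in labels], dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"stratum probabilities sum to {p.sum()!r}, not 1")
    label_to_bin: dict[str, str] = {}
    for bin_name, label in model.ordered_bins:
        label_to_bin.setdefault(label, bin_name)
    for label in labels:
        if label != NO_HIT and label not in label_to_bin:
            raise KeyError(f"stratum label {label!r} not in the lineage model")
    distal_in_lineage = sorted(
        set(model.in_lineage_bins) & set(model.contamination_distal), key=model.depth
    )
    if contamination_rate > 0 and not distal_in_lineage:
        raise ValueError("model has no in-lineage distal bins to host contaminants")

    rng = np.random.default_rng(derive_seed(seed, "hit_tables"))
    hits: dict[str, list[HitRecord]] = {b: [] for b in model.bin_names}
    truth: dict[str, StratumTruth] = {}

    def emit(contig_id: str, bin_name: str) -> None:
        evalue = float(10.0 ** -rng.uniform(4.0, 30.0))
        bitscore = float(np.round(rng.uniform(50.0, 300.0), 1))
        subject = f"{bin_name}|sbj{rng.integers(1, 10_000)}"
        hits[bin_name].append(HitRecord(contig_id, subject, bin_name, evalue, bitscore))

    for contig in contigs:
        if rng.random() < contamination_rate:
            host = distal_in_lineage[int(rng.integers(len(distal_in_lineage)))]
            emit(contig.id, host)
            truth[contig.id] = StratumTruth(contig.id, model.ancestor_for(host), True)
            continue
        stratum = labels[int(rng.choice(len(labels), p=p))]
        truth[contig.id] = StratumTruth(contig.id, stratum, False)
        if stratum == NO_HIT:
            continue
        deepest = model.depth(label_to_bin[stratum])
        for bin_name, _ in model.ordered_bins[: deepest + 1]:
            emit(contig.id, bin_name)
    return hits, truth


# ---------------------------------------------------------------------------
# Ontologies
# ---------------------------------------------------------------------------


def gen_ontology(
    n_terms: int,
    max_parents: int = 2,
    seed: int = 0,
    namespaces: Sequence[str] = ("molecular_function",),
) -> tuple[str, list[str]]:
    """A random acyclic multi-parent ontology as OBO 1.2 text.

    Term i may only point at earlier terms, so the graph is acyclic by
    construction; each non-root term has between 1 and ``max_parents``
    parents within its namespace (``max_parents=1`` yields a tree).
    Returns the OBO text and the namespace-root term ids.
    """
    if n_terms < 4:
        raise ValueError("n_terms must be >= 4")
    if max_parents < 1:
        raise ValueError("max_parents must be >= 1")
    rng = np.random.default_rng(derive_seed(seed, "ontology"))
    ids = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    ns_of: dict[str, str] = {}
    parents: dict[str, list[str]] = {}
    roots = []
    for i, tid in enumerate(ids):
        if i < len(namespaces):
            ns_of[tid] = namespaces[i]
            parents[tid] = []
            roots.append(tid)
            continue
        first = ids[int(rng.integers(0, i))]
        ns = ns_of[first]
        extra_pool = [t for t in ids[:i] if ns_of[t] == ns and t != first]
        n_extra = int(rng.integers(0, max_parents))  # total parents in [1, max_parents]
        extra = (
            [extra_pool[j] for j in rng.choice(len(extra_pool), size=min(n_extra, len(extra_pool)), replace=False)]
            if extra_pool and n_extra
            else []
        )
        ns_of[tid] = ns
        parents[tid] = [first] + sorted(extra)
    lines = ["format-version: 1.2", "ontology: synthetic-go", ""]
    for tid in ids:
        lines.append("[Term]")
        lines.append(f"id: {tid}")
        lines.append(f"name: synthetic term {tid[3:].lstrip('0') or '0'}")
        lines.append(f"namespace: {ns_of[tid]}")
        for p in parents[tid]:
            lines.append(f"is_a: {p}")
        lines.append("")
    return "\n".join(lines), roots


def gen_go_annotations(
    contig_ids: Sequence[str],
    term_ids: Sequence[str],
    n_pairs: int,
    seed: int = 0,
) -> AnnotationTable:
    """Random contig-to-term annotation pairs (deduplicated, sorted)."""
    rng = np.random.default_rng(derive_seed(seed, "go_annotations"))
    pairs = {
        (
            contig_ids[int(rng.integers(len(contig_ids)))],
            term_ids[int(rng.integers(len(term_ids)))],
        )
        for _ in range(n_pairs)
    }
    return AnnotationTable(pairs=sorted(pairs))


def gen_ec_annotations(
    focal_contigs: Sequence[str],
    reference_contigs: Sequence[str],
    seed: int = 0,
    n_pool: int = 60,
    n_focal: int = 30,
    n_reference: int = 25,
) -> tuple[AnnotationTable, AnnotationTable]:
    """Two species' EC annotation tables drawn from one enzyme pool, so
    the shared/exclusive partition is non-trivial by construction."""
    rng = np.random.default_rng(derive_seed(seed, "ec_annotations"))
    pool = sorted(
        {
            f"{rng.integers(1, 8)}.{rng.integers(1, 30)}.{rng.integers(1, 30)}.{rng.integers(1, 200)}"
            for _ in range(n_pool)
        }
    )
    focal = [pool[i] for i in rng.choice(len(pool), size=min(n_focal, len(pool)), replace=False)]
    reference = [pool[i] for i in rng.choice(len(pool), size=min(n_reference, len(pool)), replace=False)]

    def attach(ecs: list[str], contigs: Sequence[str]) -> AnnotationTable:
        pairs = sorted(
            {(contigs[int(rng.integers(len(contigs)))], ec) for ec in ecs}
        )
        return AnnotationTable(pairs=pairs)

    return attach(sorted(focal), focal_contigs), attach(sorted(reference), reference_contigs)


# ---------------------------------------------------------------------------
# Gene families
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FamiliesFixture:
    reference_proteins: dict[str, str]
    transcriptome: list[Contig]
    truth_pairs: dict[str, str]  # query protein id -> planted ortholog contig id
    families: dict[str, str]  # query protein id -> family name


def _mutate_protein(protein: str, identity: float, rng: np.random.Generator) -> str:
    n_sub = int(round(len(protein) * (1.0 - identity)))
    positions = rng.choice(len(protein), size=n_sub, replace=False)
    out = list(protein)
    for pos in positions:
        choices = [a for a in _AA if a != out[pos]]
        out[pos] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    codons = [
        _CODONS_BY_AA[aa][int(rng.integers(len(_CODONS_BY_AA[aa])))] for aa in protein
    ]
    codons.append(_STOP_CODONS[int(rng.integers(len(_STOP_CODONS)))])
    return "".join(codons)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def gen_families(
    n_families: int,
    members_per_family: int = 1,
    ortholog_identity: float = 0.8,
    n_decoys: int = 20,
    seed: int = 0,
) -> FamiliesFixture:
    """Reference proteins with planted transcriptome orthologs.

    Each reference protein is random; its planted ortholog is a copy
    point-substituted down to ``ortholog_identity`` at the protein level,
    reverse-translated through uniformly random synonymous codons, and
    embedded in a contig at a random offset and strand among random
    flanks. Decoys are unrelated random contigs. Identity below 0.4
    triggers a warning: recovery is no longer guaranteed.
    """
    if not 0 < ortholog_identity <= 1:
        raise ValueError("ortholog_identity must be in (0, 1]")
    if ortholog_identity < 0.4:
        warnings.warn("ortholog identity < 0.4: recovery is not guaranteed", stacklevel=2)
    rng = np.random.default_rng(derive_seed(seed, "families"))
    proteins: dict[str, str] = {}
    contigs: list[Contig] = []
    truth: dict[str, str] = {}
    families: dict[str, str] = {}
    for f in range(n_families):
        fam = f"fam{f + 1}"
        for m in range(members_per_family):
            qid = f"{fam}_q{m + 1}"
            length = int(rng.integers(90, 151))
            protein = "M" + "".join(
                _AA[int(rng.integers(len(_AA)))] for _ in range(length - 1)
            )
            proteins[qid] = protein
            families[qid] = fam
            mutant = _mutate_protein(protein, ortholog_identity, rng)
            orf = _reverse_translate(mutant, rng)
            if rng.random() < 0.5:
                orf = _revcomp(orf)
            left = _random_nt(rng, int(rng.integers(30, 120)))
            right = _random_nt(rng, int(rng.integers(30, 120)))
            cid = f"ortho_{qid}"
            contigs.append(Contig(id=cid, sequence=left + orf + right))
            truth[qid] = cid
    for d in range(n_decoys):
        length = int(rng.integers(300, 700))
        contigs.append(Contig(id=f"decoy{d + 1:03d}", sequence=_random_nt(rng, length)))
    return FamiliesFixture(
        reference_proteins=proteins, transcriptome=contigs, truth_pairs=truth, families=families
    )


# ---------------------------------------------------------------------------
# Full bundle
# ---------------------------------------------------------------------------


@dataclass
class FixtureBundle:
    seed: int
    contigs: list[Contig]
    orf_truth: dict[str, OrfTruth]
    alignments: list[AlignmentRecord]
    aligned_counts: dict[str, int]
    model: LineageModel
    hit_tables: dict[str, list[HitRecord]]
    stratum_truth: dict[str, StratumTruth]
    obo_text: str
    ontology_roots: list[str]
    go_focal: AnnotationTable
    go_reference: AnnotationTable
    ec_focal: AnnotationTable
    ec_reference: AnnotationTable
    families_fixture: FamiliesFixture


#: Demo-scale generation parameters (desk-scale end-to-end run).
DEMO_PRESET = {
    "n_contigs": 150,
    "length_range": (150, 1500),
    "orf_fraction": 0.5,
    "n_reads": 100_000,
    "read_length": 40,
    "unaligned_fraction": 0.15,
    "contamination_rate": 0.05,
    "n_ontology_terms": 120,
    "max_parents": 2,
    "n_go_pairs": 120,
    "n_families": 3,
    "members_per_family": 1,
    "ortholog_identity": 0.8,
    "n_decoys": 10,
}

PRESETS = {"demo": DEMO_PRESET}


def make_bundle(seed: int, preset: str = "demo") -> FixtureBundle:
    """Generate a coherent fixture bundle for every toolkit stage."""
    try:
        p = PRESETS[preset]
    except KeyError:
        raise ValueError(f"unknown preset {preset!r}; available: {sorted(PRESETS)}") from None
    contigs, orf_truth = gen_transcriptome(
        p["n_contigs"], p["length_range"], p["orf_fraction"], seed=seed
    )
    alignments, counts = gen_reads(
        contigs, p["n_reads"], p["read_length"], p["unaligned_fraction"], seed=seed
    )
    model = default_model()
    hit_tables, stratum_truth = gen_hit_tables(
        contigs, model, contamination_rate=p["contamination_rate"], seed=seed
    )
    obo_text, roots = gen_ontology(p["n_ontology_terms"], p["max_parents"], seed=seed)
    n_terms = p["n_ontology_terms"]
    term_ids = [f"GO:{i + 1:07d}" for i in range(len(roots), n_terms)]
    contig_ids = [c.id for c in contigs]
    go_focal = gen_go_annotations(contig_ids, term_ids, p["n_go_pairs"], seed=derive_seed(seed, "go_a"))
    go_reference = gen_go_annotations(
        [f"ref{i:04d}" for i in range(1, 101)], term_ids, p["n_go_pairs"], seed=derive_seed(seed, "go_b")
    )
    ec_focal, ec_reference = gen_ec_annotations(
        contig_ids, [f"ref{i:04d}" for i in range(1, 101)], seed=seed
    )
    fam = gen_families(
        p["n_families"], p["members_per_family"], p["ortholog_identity"], p["n_decoys"], seed=seed
    )
    return FixtureBundle(
        seed=seed,
        contigs=contigs,
        orf_truth=orf_truth,
        alignments=alignments,
        aligned_counts=counts,
        model=model,
        hit_tables=hit_tables,
        stratum_truth=stratum_truth,
        obo_text=obo_text,
        ontology_roots=roots,
        go_focal=go_focal,
        go_reference=go_reference,
        ec_focal=ec_focal,
        ec_reference=ec_reference,
        families_fixture=fam,
    )


def write_bundle(bundle: FixtureBundle, outdir) -> dict[str, Path]:
    """Write a bundle to disk (plus a truth/ subdirectory of TSVs).

    Returns a name -> path map of everything written. Outputs are fully
    determined by the bundle, so rewriting a same-seed bundle is
    byte-identical.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    hits_dir = out / "hits"
    hits_dir.mkdir(exist_ok=True)
    paths: dict[str, Path] = {}

    def note(name: str, path: Path) -> Path:
        paths[name] = path
        return path

    write_fasta(bundle.contigs, note("contigs", out / "contigs.fa"))
    write_sam(bundle.alignments, note("reads", out / "reads.sam"))
    bundle.model.to_file(note("model", out / "model.tsv"))
    for bin_name, hits in bundle.hit_tables.items():
        write_hits(hits, note(f"hits:{bin_name}", hits_dir / f"{bin_name}.tsv"))
    note("obo", out / "ontology.obo").write_text(bundle.obo_text)
    write_annotations(bundle.go_focal, note("go_focal", out / "go_focal.tsv"))
    write_annotations(bundle.go_reference, note("go_reference", out / "go_reference.tsv"))
    write_annotations(bundle.ec_focal, note("ec_focal", out / "ec_focal.tsv"))
    write_annotations(bundle.ec_reference, note("ec_reference", out / "ec_reference.tsv"))
    fam = bundle.families_fixture
    with note("family_queries", out / "family_queries.fa").open("w") as fh:
        for qid in sorted(fam.reference_proteins):
            fh.write(f">{qid}\n{fam.reference_proteins[qid]}\n")
    write_fasta(fam.transcriptome, note("family_transcriptome", out / "family_transcriptome.fa"))

    with note("truth:strata", truth_dir / "strata.tsv").open("w") as fh:
        fh.write("contig_id\tstratum\tcontaminant\n")
        for cid in sorted(bundle.stratum_truth):
            t = bundle.stratum_truth[cid]
            fh.write(f"{cid}\t{t.stratum}\t{int(t.contaminant)}\n")
    with note("truth:aligned_counts", truth_dir / "aligned_counts.tsv").open("w") as fh:
        fh.write("contig_id\tn_aligned\n")
        for cid in sorted(bundle.aligned_counts):
            fh.write(f"{cid}\t{bundle.aligned_counts[cid]}\n")
    with note("truth:orfs", truth_dir / "orfs.tsv").open("w") as fh:
        fh.write("contig_id\tstart\tend\tframe\tprotein\n")
        for cid in sorted(bundle.orf_truth):
            t = bundle.orf_truth[cid]
            fh.write(f"{cid}\t{t.start}\t{t.end}\t{t.frame}\t{t.protein}\n")
    with note("truth:family_pairs", truth_dir / "family_pairs.tsv").open("w") as fh:
        fh.write("query_id\tfamily\tortholog_contig\n")
        for qid in sorted(fam.truth_pairs):
            fh.write(f"{qid}\t{fam.families[qid]}\t{fam.truth_pairs[qid]}\n")
    return paths
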