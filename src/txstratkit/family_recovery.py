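"""Reciprocal-search gene-family recovery.

The protocol: query a transcriptome with reference proteins in a
translated search, keep the top-k candidates per query, then search each
candidate (translated) back against the full reference protein set. A
candidate is a verified family member only if its reciprocal best hit is
the original query protein — the classic reciprocal-best-hit ortholog
criterion.

The search step is abstracted behind a :class:`SearchBackend` contract so
external translated-search tools can be plugged in; the built-in backend
(six-frame translation + affine-gap Smith-Waterman with BLOSUM62) makes
the whole protocol runnable offline. The built-in backend ranks by raw
alignment score; E-values are not computed, since only ranking matters
to the reciprocal criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Mapping, Protocol, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

STOP = "*"
_IUPAC_NT = set("ACGTU" "RYSWKMBDHVN")

#: Search modes of the backend contract.
PROTEIN_VS_TRANSLATED = "protein-vs-translated-nucleotide"
TRANSLATED_VS_PROTEIN = "nucleotide-translated-vs-protein"


# ---------------------------------------------------------------------------
# Six-frame translation
# ---------------------------------------------------------------------------


def six_frame_translate(sequence: str) -> tuple[str, str, str, str, str, str]:
    """Translate a nucleotide sequence in all six reading frames.

    Returns (+1, +2, +3, -1, -2, -3); reverse frames translate the
    reverse complement. Standard genetic code; stop codons are emitted as
    ``*`` (frames are not split at stops at this layer). Ambiguity codes
    translate to X; any non-IUPAC character is an error.
    """
    seq = sequence.upper().replace("U", "T")
    bad = set(seq) - _IUPAC_NT
    if bad:
        raise ValueError(f"non-IUPAC nucleotide characters: {sorted(bad)}")
    # collapse partial ambiguity codes to N so every ambiguous codon -> X
    clean = "".join(c if c in "ACGT" else "N" for c in seq)
    rc = str(Seq(clean).reverse_complement())
    frames = []
    for template in (clean, rc):
        for off in range(3):
            sub = template[off : off + 3 * ((len(template) - off) // 3)]
            frames.append(str(Seq(sub).translate()))
    return tuple(frames)


# ---------------------------------------------------------------------------
# Local alignment
# ---------------------------------------------------------------------------


@lru_cache(maxsize=1)
def default_matrix():
    """BLOSUM62 with stop symbols penalized at the matrix minimum.

    Scoring ``*`` at the minimum against everything (including itself)
    keeps read-through matches across stop codons from winning a frame.
    """
    m = substitution_matrices.load("BLOSUM62").copy()
    floor = float(np.min(m))
    i = m.alphabet.index(STOP)
    m[i, :] = floor
    m[:, i] = floor
    return m


def local_align(
    peptide_a: str,
    peptide_b: str,
    matrix=None,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> tuple[float, tuple | None]:
    """Smith-Waterman local alignment with affine gaps.

    A gap of length k costs ``gap_open + k * gap_extend`` (the BLAST
    convention; defaults are BLAST's protein defaults). Returns
    ``(score, aligned_spans)`` where ``aligned_spans`` is the pair of
    coordinate blocks of the best alignment, or None for an empty/zero
    alignment. The score floor is 0.
    """
    if matrix is None:
        matrix = default_matrix()
    if not peptide_a or not peptide_b:
        return 0.0, None
    alphabet = set(matrix.alphabet)
    missing = (set(peptide_a) | set(peptide_b)) - alphabet
    if missing:
        raise ValueError(f"residues missing from substitution matrix: {sorted(missing)}")
    aligner = PairwiseAligner(
        mode="local",
        substitution_matrix=matrix,
        open_gap_score=-(gap_open + gap_extend),
        extend_gap_score=-gap_extend,
    )
    score = float(aligner.score(peptide_a, peptide_b))
    if score <= 0.0:
        return 0.0, None
    aln = next(iter(aligner.align(peptide_a, peptide_b)))
    spans = tuple(tuple((int(s), int(e)) for s, e in side) for side in aln.aligned)
    return score, spans


# ---------------------------------------------------------------------------
# Search backend
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SearchHit:
    query_id: str
    subject_id: str
    score: float
    evalue: float | None = None


class SearchBackend(Protocol):
    """Contract for translated homology search.

    ``search`` returns, per query id, hits sorted by descending score
    (ties broken by subject id) and must be deterministic for fixed
    inputs.
    """

    def search(
        self, queries: Mapping[str, str], subjects: Mapping[str, str], mode: str
    ) -> dict[str, list[SearchHit]]: ...


class BuiltinAligner:
    """Six-frame translation + Smith-Waterman backend.

    A nucleotide sequence's score against a protein is the maximum local
    alignment score over its six translated frames.
    """

    def __init__(self, matrix=None, gap_open: float = 11.0, gap_extend: float = 1.0):
        self.matrix = matrix if matrix is not None else default_matrix()
        self.gap_open = gap_open
        self.gap_extend = gap_extend
        self._frame_cache: dict[str, tuple[str, ...]] = {}

    def _frames(self, nt: str) -> tuple[str, ...]:
        if nt not in self._frame_cache:
            self._frame_cache[nt] = six_frame_translate(nt)
        return self._frame_cache[nt]

    def _score(self, protein: str, nucleotide: str) -> float:
        return max(
            local_align(protein, f, self.matrix, self.gap_open, self.gap_extend)[0]
            for f in self._frames(nucleotide)
        )

    def search(
        self, queries: Mapping[str, str], subjects: Mapping[str, str], mode: str
    ) -> dict[str, list[SearchHit]]:
        if mode not in (PROTEIN_VS_TRANSLATED, TRANSLATED_VS_PROTEIN):
            raise ValueError(f"unknown search mode {mode!r}")
        out: dict[str, list[SearchHit]] = {}
        for qid in sorted(queries):
            hits = []
            for sid in sorted(subjects):
                if mode == PROTEIN_VS_TRANSLATED:
                    score = self._score(queries[qid], subjects[sid])
                else:
                    score = self._score(subjects[sid], queries[qid])
                if score > 0:
                    hits.append(SearchHit(qid, sid, score))
            hits.sort(key=lambda h: (-h.score, h.subject_id))
            out[qid] = hits
        return out


# ---------------------------------------------------------------------------
# Recovery protocol
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CandidateVerdict:
    candidate_id: str
    score: float
    reciprocal_top: str | None
    verified: bool


@dataclass
class FamilyRecoveryReport:
    """Per reference protein: candidates and reciprocal verdicts; per
    family: verified member counts."""

    per_query: dict[str, list[CandidateVerdict]]
    families: dict[str, str]  # query id -> family name

    @property
    def verified_pairs(self) -> set[tuple[str, str]]:
        return {
            (q, v.candidate_id)
            for q, verdicts in self.per_query.items()
            for v in verdicts
            if v.verified
        }

    def family_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for q, verdicts in self.per_query.items():
            fam = self.families.get(q, q)
            counts.setdefault(fam, 0)
            counts[fam] += sum(v.verified for v in verdicts)
        return counts

    def to_rows(self) -> list[dict]:
        rows = []
        for q in sorted(self.per_query):
            for v in self.per_query[q]:
                rows.append(
                    {
                        "family": self.families.get(q, q),
                        "query": q,
                        "candidate": v.candidate_id,
                        "score": v.score,
                        "reciprocal_top": v.reciprocal_top or "",
                        "verified": v.verified,
                    }
                )
        return rows


def recover_families(
    reference_proteins: Mapping[str, str],
    transcriptome: Mapping[str, str],
    backend: SearchBackend | None = None,
    top_k: int = 10,
    min_score: float = 50.0,
    families: Mapping[str, str] | None = None,
    relaxed: bool = False,
) -> FamilyRecoveryReport:
    """Run the reciprocal-search family-recovery protocol.

    Step 1: each reference protein queries the transcriptome
    (protein-vs-translated); at most ``top_k`` hits scoring at least
    ``min_score`` are retained as candidates. Step 2: each candidate
    transcript is searched (translated) against the full reference
    protein set; it is verified iff its reciprocal top hit (ties broken
    by score then lexicographic subject id) is the original query — or,
    with ``relaxed=True``, any member of the same declared family.

    ``min_score`` is a free parameter of the protocol; the conservative
    default of 50 (raw alignment score) suppresses chance matches of
    unrelated random sequences while retaining genuine homologs.
    """
    if not reference_proteins:
        raise ValueError("empty reference protein set")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if backend is None:
        backend = BuiltinAligner()
    families = dict(families or {})

    forward = backend.search(reference_proteins, dict(transcriptome), PROTEIN_VS_TRANSLATED)
    candidates: dict[str, list[SearchHit]] = {
        q: [h for h in hits if h.score >= min_score][:top_k] for q, hits in forward.items()
    }
    needed = sorted({h.subject_id for hits in candidates.values() for h in hits})
    reciprocal = backend.search(
        {cid: transcriptome[cid] for cid in needed}, dict(reference_proteins), TRANSLATED_VS_PROTEIN
    )

    per_query: dict[str, list[CandidateVerdict]] = {}
    for q in sorted(reference_proteins):
        verdicts = []
        for hit in candidates.get(q, []):
            back = reciprocal.get(hit.subject_id, [])
            top = back[0].subject_id if back else None
            if relaxed and top is not None:
                verified = families.get(top, top) == families.get(q, q)
            else:
                verified = top == q
            verdicts.append(
                CandidateVerdict(
                    candidate_id=hit.subject_id,
                    score=hit.score,
                    reciprocal_top=top,
                    verified=verified,
                )
            )
        per_query[q] = verdicts
    return FamilyRecoveryReport(per_query=per_query, families=families)
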