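"""Phylostratigraphy: infer each contig's evolutionary origin from the
pattern of taxonomic bins in which it has homology hits.

A :class:`LineageModel` orders database bins from the focal species'
closest relative outward; each bin maps to the ancestral branch a hit in
that bin (and no deeper) implies. The deepest-hit-wins rule assigns each
contig the ancestor label of its most distant in-lineage hit bin. A
contamination heuristic flags contigs whose hits are confined to distal
bins with none in the intermediate eukaryote bins — the signature of
transcripts from co-sampled organisms rather than the focal animal. The
flag is advisory and never changes the assigned origin.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

#: Reserved origin labels for contigs without an in-lineage ancestor.
NO_HIT = "no_hit"
OUT_OF_LINEAGE_ONLY = "out_of_lineage_only"


@dataclass(frozen=True)
class LineageModel:
    """Ordered taxonomic bins mapped to ancestral-branch labels.

    ``ordered_bins`` runs from the most recently diverged bin (closest
    relative of the focal species) to the most distant. Bins in
    ``out_of_lineage_bins`` (e.g. viruses) sit on no branch of the
    focal species' line of descent. The optional contamination sets
    configure :func:`flag_contamination`.
    """

    ordered_bins: tuple[tuple[str, str], ...]
    out_of_lineage_bins: tuple[str, ...] = ()
    focal_name: str = "focal species"
    contamination_distal: frozenset[str] = frozenset()
    contamination_intermediate: frozenset[str] = frozenset()

    def __post_init__(self):
        if not self.ordered_bins:
            raise ValueError("ordered_bins must be non-empty")
        names = [b for b, _ in self.ordered_bins] + list(self.out_of_lineage_bins)
        if len(names) != len(set(names)):
            raise ValueError("bin names must be unique across the model")

    @property
    def in_lineage_bins(self) -> tuple[str, ...]:
        return tuple(b for b, _ in self.ordered_bins)

    @property
    def bin_names(self) -> tuple[str, ...]:
        return self.in_lineage_bins + tuple(self.out_of_lineage_bins)

    def depth(self, bin_name: str) -> int:
        """Rank of an in-lineage bin; 0 = closest relative, larger = deeper."""
        for i, (b, _) in enumerate(self.ordered_bins):
            if b == bin_name:
                return i
        raise KeyError(f"unknown in-lineage bin: {bin_name!r}")

    def ancestor_for(self, bin_name: str) -> str:
        return self.ordered_bins[self.depth(bin_name)][1]

    def check_bins(self, hit_bins: Iterable[str]) -> None:
        known = set(self.bin_names)
        for b in hit_bins:
            if b not in known:
                raise KeyError(f"unknown taxonomic bin: {b!r}")

    def to_file(self, dest) -> None:
        close = False
        if not hasattr(dest, "write"):
            dest, close = open(dest, "w"), True
        try:
            dest.write(f"# focal: {self.focal_name}\n")
            for b, label in self.ordered_bins:
                dest.write(f"{b}\t{label}\n")
            if self.out_of_lineage_bins:
                dest.write("[out_of_lineage]\n")
                for b in self.out_of_lineage_bins:
                    dest.write(f"{b}\n")
            if self.contamination_distal:
                dest.write("[contamination_distal]\n")
                for b in sorted(self.contamination_distal):
                    dest.write(f"{b}\n")
            if self.contamination_intermediate:
                dest.write("[contamination_intermediate]\n")
                for b in sorted(self.contamination_intermediate):
                    dest.write(f"{b}\n")
        finally:
            if close:
                dest.close()

    @classmethod
    def from_file(cls, source) -> "LineageModel":
        """Read a model file: ordered ``bin<TAB>ancestor_label`` lines, then
        optional ``[out_of_lineage]`` / contamination-set sections of bare
        bin names."""
        close = False
        if not hasattr(source, "read"):
            source, close = open(source), True
        try:
            ordered: list[tuple[str, str]] = []
            sections: dict[str, list[str]] = {
                "out_of_lineage": [],
                "contamination_distal": [],
                "contamination_intermediate": [],
            }
            section = None
            focal = "focal species"
            for line in source:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("# focal:"):
                    focal = line.split(":", 1)[1].strip()
                    continue
                if line.startswith("#"):
                    continue
                if line.startswith("[") and line.endswith("]"):
                    section = line[1:-1]
                    if section not in sections:
                        raise ValueError(f"unknown model section [{section}]")
                    continue
                if section is None:
                    parts = line.split("\t")
                    if len(parts) != 2:
                        raise ValueError(f"expected 'bin<TAB>label', got {line!r}")
                    ordered.append((parts[0], parts[1]))
                else:
                    sections[section].append(line)
            return cls(
                ordered_bins=tuple(ordered),
                out_of_lineage_bins=tuple(sections["out_of_lineage"]),
                focal_name=focal,
                contamination_distal=frozenset(sections["contamination_distal"]),
                contamination_intermediate=frozenset(sections["contamination_intermediate"]),
            )
        finally:
            if close:
                source.close()


def default_model(merge_prokaryote_labels: bool = False) -> LineageModel:
    """The eight-bin anthozoan lineage model used throughout the fixtures.

    Bins run from the confamilial sister species outward to prokaryotes,
    with viruses out-of-lineage. With ``merge_prokaryote_labels`` the
    Archaea and Eubacteria bins share one cellular-ancestor label (the
    merged class some surveys report) instead of distinct archaeal and
    bacterial divergence labels.
    """
    archaea_label = "ancestor of Archaea + Eukaryota"
    eubacteria_label = "ancestor of Eubacteria + Eukaryota"
    if merge_prokaryote_labels:
        archaea_label = eubacteria_label = "cellular ancestor"
    return LineageModel(
        ordered_bins=(
            ("N_vectensis", "Edwardsiidae ancestor"),
            ("Cnidaria_excl_Nv", "Cnidaria ancestor"),
            ("Bilateria", "Eumetazoa ancestor"),
            ("basal_Metazoa", "Metazoa ancestor"),
            ("other_Eukaryota", "Eukaryota ancestor"),
            ("Archaea", archaea_label),
            ("Eubacteria", eubacteria_label),
        ),
        out_of_lineage_bins=("viruses",),
        focal_name="E_lineata",
        contamination_distal=frozenset({"Archaea", "Eubacteria", "viruses"}),
        contamination_intermediate=frozenset({"Bilateria", "basal_Metazoa", "other_Eukaryota"}),
    )


@dataclass(frozen=True)
class OriginAssignment:
    contig_id: str
    origin_label: str  # ancestor label, NO_HIT, or OUT_OF_LINEAGE_ONLY
    deepest_bin: str | None
    contamination_flag: bool
    hit_bins: frozenset[str]

    @property
    def has_ancestor(self) -> bool:
        return self.origin_label not in (NO_HIT, OUT_OF_LINEAGE_ONLY)


def flag_contamination(hit_bins: Iterable[str], model: LineageModel) -> bool:
    """True iff the deepest hit bin is in the model's distal set and no hit
    falls in any intermediate bin.

    Contigs hitting only distant lineages (prokaryotes, viruses) while
    skipping every intermediate eukaryote bin likely derive from
    co-sampled organisms, not the focal animal. With empty configured
    sets the heuristic is inert (always False).
    """
    bins = set(hit_bins)
    model.check_bins(bins)
    if not bins or not model.contamination_distal:
        return False
    in_lineage = bins & set(model.in_lineage_bins)
    if in_lineage:
        deepest = max(in_lineage, key=model.depth)
    else:
        deepest = None  # out-of-lineage hits only
    deepest_is_distal = (deepest in model.contamination_distal) if deepest else bool(
        bins & model.contamination_distal
    )
    return deepest_is_distal and not (bins & model.contamination_intermediate)


def assign_origin(contig_id: str, hit_bins: Iterable[str], model: LineageModel) -> OriginAssignment:
    """Assign a contig's origin by the deepest-hit-wins rule.

    The deepest in-lineage bin with a hit sets the origin (a single distal
    hit suffices). Virus and other out-of-lineage hits are ignored
    whenever any in-lineage hit exists; contigs hitting out-of-lineage
    bins only form their own category, as do contigs with no hits at all.
    """
    bins = frozenset(hit_bins)
    model.check_bins(bins)
    in_lineage = bins & set(model.in_lineage_bins)
    if not bins:
        label, deepest = NO_HIT, None
    elif not in_lineage:
        label, deepest = OUT_OF_LINEAGE_ONLY, None
    else:
        deepest = max(in_lineage, key=model.depth)
        label = model.ancestor_for(deepest)
    return OriginAssignment(
        contig_id=contig_id,
        origin_label=label,
        deepest_bin=deepest,
        contamination_flag=flag_contamination(bins, model),
        hit_bins=bins,
    )


def assign_origins(
    hits_by_contig: Mapping[str, Iterable[str]], model: LineageModel
) -> list[OriginAssignment]:
    return [assign_origin(cid, bins, model) for cid, bins in hits_by_contig.items()]


@dataclass(frozen=True)
class StratumSummary:
    """Counts and percentages per ancestral branch.

    Percentages are over contigs assigned an in-lineage ancestor label
    (contigs producing informative hits); no-hit, out-of-lineage-only and
    contamination-flagged contigs are tallied separately.
    """

    counts: dict[str, int]
    percentages: dict[str, float]
    n_assigned: int
    n_no_hit: int
    n_out_of_lineage_only: int
    n_contamination_flagged: int


def summarize_strata(assignments: Sequence[OriginAssignment]) -> StratumSummary:
    if not assignments:
        raise ValueError("no assignments to summarize")
    counts: Counter[str] = Counter(a.origin_label for a in assignments if a.has_ancestor)
    n_assigned = sum(counts.values())
    percentages = (
        {label: 100.0 * c / n_assigned for label, c in counts.items()} if n_assigned else {}
    )
    return StratumSummary(
        counts=dict(counts),
        percentages=percentages,
        n_assigned=n_assigned,
        n_no_hit=sum(1 for a in assignments if a.origin_label == NO_HIT),
        n_out_of_lineage_only=sum(1 for a in assignments if a.origin_label == OUT_OF_LINEAGE_ONLY),
        n_contamination_flagged=sum(1 for a in assignments if a.contamination_flag),
    )
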