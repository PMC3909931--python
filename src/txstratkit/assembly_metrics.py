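"""Assembly-level summary statistics: N50, contig counts, length
histograms, and hit-rate-by-length tables."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seqio import Contig


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    total_length: int
    n50: int
    #: ordered (lower, upper, count) bins; [lower, upper) except the last, closed
    length_histogram: tuple[tuple[int, int, int], ...]


def n50(lengths: Sequence[int]) -> int:
    """N50: the largest L such that contigs of length >= L hold at least
    half the total assembly length.

    Computed by sorting descending and accumulating until the running sum
    first reaches total/2 (a running sum exactly equal to total/2 counts:
    that contig's length is the N50).
    """
    if len(lengths) == 0:
        raise ValueError("n50 of an empty length list is undefined")
    arr = np.asarray(lengths)
    if arr.ndim != 1 or np.any(arr <= 0):
        raise ValueError("lengths must be positive integers")
    desc = np.sort(arr)[::-1]
    csum = np.cumsum(desc)
    idx = int(np.searchsorted(2 * csum, csum[-1], side="left"))
    return int(desc[idx])


def _bin_index(length: int, bins: Sequence[tuple[int, int]]) -> int | None:
    """Index of the (lower, upper) bin holding ``length``; [lower, upper)
    except the last bin, which is closed. None when outside every bin."""
    for i, (lo, hi) in enumerate(bins):
        last = i == len(bins) - 1
        if lo <= length < hi or (last and length == hi):
            return i
    return None


def assembly_stats(
    contigs: Sequence[Contig],
    bin_edges: Sequence[int] = (0, 500, 1000, 2000, 5000, 20000),
) -> AssemblyStats:
    """Summarize an assembly: counts, total length, N50, length histogram.

    ``bin_edges`` define consecutive bins, closed-open except the last.
    Contigs longer than the final edge are counted in the last bin so the
    histogram always sums to the contig count.
    """
    if not contigs:
        raise ValueError("empty assembly")
    lengths = [c.length for c in contigs]
    bins = list(zip(bin_edges[:-1], bin_edges[1:]))
    counts = [0] * len(bins)
    for L in lengths:
        idx = _bin_index(L, bins)
        if idx is None:
            idx = 0 if L < bins[0][0] else len(bins) - 1
        counts[idx] += 1
    return AssemblyStats(
        n_contigs=len(contigs),
        total_length=int(sum(lengths)),
        n50=n50(lengths),
        length_histogram=tuple((lo, hi, c) for (lo, hi), c in zip(bins, counts)),
    )


@dataclass(frozen=True)
class HitRateSummary:
    """Per-length-bin counts of contigs with and without homology hits.

    ``no_hit_focus_fraction`` is the fraction of all no-hit contigs that
    fall in the caller-named focus bin (the shape of short-no-hit-contig
    statistics); None when there are no no-hit contigs (absent, not zero).
    """

    bins: tuple[tuple[int, int], ...]
    n_with_hit: tuple[int, ...]
    n_without_hit: tuple[int, ...]
    n_unbinned: int
    no_hit_focus_fraction: float | None


def hit_rate_by_length(
    contigs: Sequence[Contig],
    hit_flags: Mapping[str, bool],
    bins: Sequence[tuple[int, int]],
    no_hit_focus: tuple[int, int] | None = None,
) -> HitRateSummary:
    """Tally hit/no-hit contigs per length bin.

    ``bins`` are (lower, upper) pairs, closed-open except the last (closed).
    Every contig must appear in ``hit_flags``. When ``no_hit_focus`` names
    one of the bins, the fraction of no-hit contigs falling in it is
    reported (denominator: all no-hit contigs, binned or not).
    """
    if not bins:
        raise ValueError("empty bin list")
    bins = tuple(tuple(b) for b in bins)
    if no_hit_focus is not None and tuple(no_hit_focus) not in bins:
        raise ValueError(f"focus bin {no_hit_focus} not among the bins")
    with_hit = [0] * len(bins)
    without_hit = [0] * len(bins)
    unbinned = 0
    n_no_hit = 0
    focus_count = 0
    for c in contigs:
        if c.id not in hit_flags:
            raise KeyError(f"contig {c.id!r} missing from hit_flags")
        has_hit = bool(hit_flags[c.id])
        idx = _bin_index(c.length, bins)
        if idx is None:
            unbinned += 1
        elif has_hit:
            with_hit[idx] += 1
        else:
            without_hit[idx] += 1
        if not has_hit:
            n_no_hit += 1
            if idx is not None and no_hit_focus is not None and bins[idx] == tuple(no_hit_focus):
                focus_count += 1
    fraction = None
    if no_hit_focus is not None and n_no_hit > 0:
        fraction = focus_count / n_no_hit
    return HitRateSummary(
        bins=bins,
        n_with_hit=tuple(with_hit),
        n_without_hit=tuple(without_hit),
        n_unbinned=unbinned,
        no_hit_focus_fraction=fraction,
    )
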