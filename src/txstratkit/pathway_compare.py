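"""Enzyme Commission (EC) pathway-set comparison.

Extract EC numbers from two species' annotation tables, partition them
into shared / focal-only / reference-only sets, and emit an iPath-style
colored edge selection for pathway-map visualization.

EC normalization: an optional ``EC:`` prefix is stripped and partial
numbers are padded with ``-`` to four dotted fields; comparison is then
exact string equality (no hierarchical matching of partial ECs to their
children).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .seqio import AnnotationTable, FormatError

_EC_BODY = re.compile(r"^\d+(?:\.(?:\d+|-)){0,3}$")

#: iPath selection palette: class -> hex color.
DEFAULT_PALETTE = {
    "shared": "#00ff00",  # found in both species
    "only_reference": "#ff0000",  # reference species only
    "only_focal": "#ffff00",  # focal species only
}
DEFAULT_WIDTH = 10


def normalize_ec(label: str) -> str:
    """Normalize one EC label: strip ``EC:``, pad to four fields with ``-``."""
    body = label[3:] if label.upper().startswith("EC:") else label
    if not _EC_BODY.match(body):
        raise ValueError(f"malformed EC number: {label!r}")
    fields = body.split(".")
    return ".".join(fields + ["-"] * (4 - len(fields)))


def extract_ec(annotations: AnnotationTable) -> tuple[set[str], dict[str, set[str]]]:
    """Collect normalized EC numbers from an annotation table.

    Returns the deduplicated EC set and the contig -> EC-set map.
    Malformed labels are errors naming the offending row.
    """
    ec_set: set[str] = set()
    by_contig: dict[str, set[str]] = {}
    for row, (cid, label) in enumerate(annotations.pairs, start=1):
        try:
            ec = normalize_ec(label)
        except ValueError:
            raise FormatError(f"annotation row {row}: malformed EC number {label!r}") from None
        ec_set.add(ec)
        by_contig.setdefault(cid, set()).add(ec)
    return ec_set, by_contig


@dataclass(frozen=True)
class EcPartition:
    """Disjoint partition of two species' enzyme sets.

    ``n_matched`` is the number of EC numbers found in the focal species
    (shared plus focal-exclusive), the headline count of such surveys.
    """

    shared: frozenset[str]
    only_focal: frozenset[str]
    only_reference: frozenset[str]

    @property
    def n_matched(self) -> int:
        return len(self.shared) + len(self.only_focal)


def compare_ec(focal_set: Iterable[str], reference_set: Iterable[str]) -> EcPartition:
    """Exact set partition of normalized EC numbers."""
    focal = frozenset(focal_set)
    reference = frozenset(reference_set)
    return EcPartition(
        shared=focal & reference,
        only_focal=focal - reference,
        only_reference=reference - focal,
    )


def ipath_edgelist(
    partition: EcPartition,
    palette: Mapping[str, str] | None = None,
    width: int = DEFAULT_WIDTH,
) -> list[str]:
    """Render a partition as iPath selection lines.

    One line per EC number: ``<EC> <#RRGGBB> W<width>``. ECs absent from
    both species are simply omitted (the viewer renders unselected edges
    in its own default gray/black).
    """
    palette = dict(palette) if palette is not None else dict(DEFAULT_PALETTE)
    missing = set(DEFAULT_PALETTE) - set(palette)
    if missing:
        raise ValueError(f"palette missing classes: {sorted(missing)}")
    lines = []
    for cls in ("shared", "only_focal", "only_reference"):
        for ec in sorted(getattr(partition, cls)):
            lines.append(f"{ec} {palette[cls]} W{width}")
    return lines


def parse_ipath_edgelist(
    lines: Sequence[str], palette: Mapping[str, str] | None = None
) -> dict[str, str]:
    """Invert :func:`ipath_edgelist`: map each EC back to its class."""
    palette = dict(palette) if palette is not None else dict(DEFAULT_PALETTE)
    color_to_class = {color.lower(): cls for cls, color in palette.items()}
    out: dict[str, str] = {}
    for line in lines:
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"malformed iPath line: {line!r}")
        ec, color, _width = parts
        try:
            out[ec] = color_to_class[color.lower()]
        except KeyError:
            raise ValueError(f"unknown color {color!r} in iPath line") from None
    return out
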