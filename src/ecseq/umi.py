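"""Molecular-index (UMI) extraction and amplicon assignment.

Each read pair carries a random oligonucleotide index (default 16 bp) at the
5' end of both mates, ligated in the adapters before amplification.  The
ordered concatenation of the two indexes, after orientation normalization,
is the family key: a molecule sequenced in either direction yields the same
key, so one molecule founds exactly one read family.

Orientation is inferred from which amplicon end the template start matches:
the mate whose template begins at the amplicon 5' end is the "left" mate,
the mate reading inward from the 3' end is the "right" mate.  After
assignment both mates are stored in forward (amplicon) orientation with a
0-based start offset, so downstream consensus building is purely positional.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import edlib

from ._dna import revcomp
from .io import AmpliconReference, FastqRead

__all__ = [
    "TaggedRead",
    "Rejection",
    "AmpliconIndex",
    "extract_index",
    "assign_amplicon",
    "directional_collapse",
]


@dataclass(slots=True)
class TaggedRead:
    """One sequencing read after index extraction.

    ``bases``/``quality_string`` hold the template after the index was
    removed; once the pair is assigned to an amplicon they are normalized to
    the forward strand of the amplicon, ``start`` is the 0-based offset on
    the amplicon, and ``anchor`` records which amplicon end the read was
    anchored to ("left" = 5' end, "right" = 3' end).
    """

    bases: str
    quality_string: str
    mate: int
    index: str
    name: str = ""
    family_index: str | None = None
    amplicon_name: str | None = None
    orientation: str | None = None  # orientation of the whole pair
    start: int = 0
    anchor: str = "left"

    @property
    def qualities(self) -> list[int]:
        """Phred scores decoded from the Phred+33 quality string."""
        return [ord(c) - 33 for c in self.quality_string]

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class Rejection:
    """A read pair excluded from the pipeline, with the reason recorded."""

    reason: str  # "too_short" | "unassigned" | "ambiguous"
    name: str = ""


def extract_index(
    pair: tuple[FastqRead, FastqRead],
    index_length: int = 16,
    min_insert: int = 30,
) -> tuple[TaggedRead, TaggedRead] | Rejection:
    """Split each mate into its molecular index and template sequence.

    The first ``index_length`` bases of each mate are removed and recorded;
    the remainder is the template.  Pairs whose template would be shorter
    than ``min_insert`` are rejected with reason ``"too_short"`` (counted by
    the caller, never fatal).  ``index_length=0`` is the degenerate
    no-indexing mode (template = full read).
    """
    r1, r2 = pair
    if len(r1.sequence) < index_length + min_insert or len(
        r2.sequence
    ) < index_length + min_insert:
        return Rejection("too_short", r1.name)
    return (
        TaggedRead(
            bases=r1.sequence[index_length:].upper(),
            quality_string=r1.quality[index_length:],
            mate=1,
            index=r1.sequence[:index_length].upper(),
            name=r1.name,
        ),
        TaggedRead(
            bases=r2.sequence[index_length:].upper(),
            quality_string=r2.quality[index_length:],
            mate=2,
            index=r2.sequence[:index_length].upper(),
            name=r2.name,
        ),
    )


class AmpliconIndex:
    """Anchor k-mers of every amplicon end, for fast template assignment.

    A template that starts with (within ``max_edits`` edits of) an
    amplicon's first k bases is anchored to its left end; one starting with
    the reverse complement of the last k bases is anchored to the right end.
    Exact matches resolve through a dict; near matches fall back to
    edit-distance comparison against every anchor.
    """

    def __init__(
        self,
        references: Sequence[AmpliconReference],
        k: int = 20,
        max_edits: int = 2,
    ):
        self.references = {a.name: a for a in references}
        if len(self.references) != len(references):
            raise ValueError("duplicate amplicon names")
        self.k = k
        self.max_edits = max_edits
        self.anchors: list[tuple[str, str, str]] = []  # (kmer, name, side)
        self._exact: dict[str, list[tuple[str, str]]] = {}
        for amp in references:
            if len(amp.sequence) < k:
                raise ValueError(f"amplicon {amp.name} shorter than anchor k={k}")
            for kmer, side in (
                (amp.sequence[:k], "left"),
                (revcomp(amp.sequence[-k:]), "right"),
            ):
                self.anchors.append((kmer, amp.name, side))
                self._exact.setdefault(kmer, []).append((amp.name, side))

    def match_end(self, template: str) -> list[tuple[str, str, int]]:
        """All (amplicon, side, distance) anchors at the minimal edit
        distance <= max_edits from the template start; empty if none."""
        prefix = template[: self.k]
        hit = self._exact.get(prefix)
        if hit is not None:
            return [(name, side, 0) for name, side in hit]
        if len(prefix) < self.k:
            return []
        best: list[tuple[str, str, int]] = []
        best_d = self.max_edits + 1
        for kmer, name, side in self.anchors:
            d = edlib.align(prefix, kmer, mode="NW", k=self.max_edits)["editDistance"]
            if d < 0:
                continue
            if d < best_d:
                best, best_d = [(name, side, d)], d
            elif d == best_d:
                best.append((name, side, d))
        return best


def _resolve_assignment(
    m1: list[tuple[str, str, int]], m2: list[tuple[str, str, int]]
):
    """Combine per-mate anchor matches into (amplicon, mate1_side) or a
    rejection reason string."""
    a1 = {name for name, _, _ in m1}
    a2 = {name for name, _, _ in m2}
    if not a1 and not a2:
        return "unassigned"
    if len(a1) > 1 or len(a2) > 1:
        return "ambiguous"
    if a1 and a2 and a1 != a2:
        return "ambiguous"
    name = next(iter(a1 or a2))
    sides1 = {side for _, side, _ in m1}
    sides2 = {side for _, side, _ in m2}
    if len(sides1) > 1 or len(sides2) > 1:
        return "ambiguous"
    if sides1 and sides2:
        if sides1 == sides2:  # both mates on the same end: not a proper pair
            return "ambiguous"
        mate1_side = next(iter(sides1))
    elif sides1:
        mate1_side = next(iter(sides1))
    else:
        mate1_side = "left" if next(iter(sides2)) == "right" else "right"
    return name, mate1_side


def _normalize_right(template: str, quality: str, amplicon_length: int):
    """Express a right-anchored template in forward amplicon coordinates."""
    fwd = revcomp(template)
    qual = quality[::-1]
    if len(fwd) > amplicon_length:
        fwd = fwd[-amplicon_length:]
        qual = qual[-amplicon_length:]
    return fwd, qual, amplicon_length - len(fwd)


def assign_amplicon(
    pair: tuple[TaggedRead, TaggedRead],
    index: AmpliconIndex,
) -> tuple[TaggedRead, TaggedRead] | Rejection:
    """Assign a tagged pair to an amplicon and normalize its orientation.

    On success both reads carry ``amplicon_name``, the pair orientation
    ("forward" if mate 1 anchors the amplicon 5' end), forward-normalized
    bases with ``start`` offsets, and the shared ``family_index``
    (left-mate index + right-mate index).  Otherwise a :class:`Rejection`
    with reason ``"unassigned"`` or ``"ambiguous"`` is returned.
    """
    r1, r2 = pair
    resolved = _resolve_assignment(index.match_end(r1.bases), index.match_end(r2.bases))
    if isinstance(resolved, str):
        return Rejection(resolved, r1.name)
    name, mate1_side = resolved
    amp = index.references[name]
    L = len(amp.sequence)
    left, right = (r1, r2) if mate1_side == "left" else (r2, r1)

    left.bases = left.bases[:L]
    left.quality_string = left.quality_string[:L]
    left.start, left.anchor = 0, "left"
    right.bases, right.quality_string, right.start = _normalize_right(
        right.bases, right.quality_string, L
    )
    right.anchor = "right"

    orientation = "forward" if mate1_side == "left" else "reverse"
    key = left.index + right.index
    for r in (r1, r2):
        r.amplicon_name = name
        r.orientation = orientation
        r.family_index = key
    return r1, r2


def directional_collapse(
    key_counts: dict[str, int], min_ratio: float = 10.0
) -> dict[str, str]:
    """Optional merge of sequencing errors in the index itself.

    A family key is absorbed by a 1-mismatch neighbor whose read count is at
    least ``min_ratio`` times its own.  Returns a mapping key -> canonical
    key (identity for keys that stand alone).  Off by default in the
    pipeline: exact index matching is the baseline behavior.
    """
    order = sorted(key_counts, key=lambda k: (-key_counts[k], k))
    canonical: dict[str, str] = {}
    for key in order:
        best = None
        for pos in range(len(key)):
            for base in "ACGT":
                if base == key[pos]:
                    continue
                neighbor = key[:pos] + base + key[pos + 1:]
                root = canonical.get(neighbor)
                if root is None:
                    continue
                if key_counts[root] >= min_ratio * key_counts[key]:
                    if best is None or key_counts[root] > key_counts[best]:
                        best = root
        canonical[key] = best if best is not None else key
    return canonical
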