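"""Error-corrected consensus sequences (ECCS).

Reads within a family all descend from one molecule, so positions where
they disagree are sequencing errors.  The consensus keeps the modal base at
each column when enough reads cover it (``min_depth``) and a sufficient
fraction agree (``min_agreement``); otherwise the position is masked to 'N'
— the error is *removed* rather than the whole family discarded, preserving
coverage at the remaining positions.

Column space is the family's own template: the modal read length M.  Reads
anchored at the amplicon 5' end vote from column 0; reads anchored at the
3' end vote end-anchored (columns M-len .. M-1), so substitution errors stay
positionally aligned without any within-family alignment.  A read whose
length deviates from M (an internal indel relative to the family template)
is checked by edit distance against a modal-length exemplar and excluded as
an outlier when it exceeds ``max_member_edits``; true indel molecules are
internally concordant and simply yield a template of a different length.

Qualities are deliberately ignored: the vote is a pure read count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import edlib
import numpy as np

from ._dna import CODE_N, decode, encode
from .families import ReadFamily
from .umi import TaggedRead

__all__ = [
    "ConsensusSequence",
    "build_consensus",
    "consensus_quality_filter",
    "batch_consensus_codes",
]


@dataclass
class ConsensusSequence:
    """Per-family error-corrected sequence with per-position support.

    ``support[i]`` is the number of reads agreeing with the consensus base
    at column i, ``depth[i]`` the number of reads voting there; both are
    bounded by ``n_reads`` (individual reads, counting the two mates of a
    pair separately — mates vote independently).  ``family_size`` is the
    number of read pairs.
    """

    family_index: str
    amplicon_name: str
    bases: str
    support: np.ndarray
    depth: np.ndarray
    family_size: int
    n_reads: int
    outliers: int = 0

    @property
    def n_fraction(self) -> float:
        if not self.bases:
            return 0.0
        return self.bases.count("N") / len(self.bases)

    def __len__(self) -> int:
        return len(self.bases)


def _vote(counts: np.ndarray, min_agreement: float, min_depth: int):
    """Column-wise modal vote on a (4, M) count array -> codes/support/depth.

    A column becomes 'N' when depth < min_depth, when the modal fraction is
    below min_agreement, or when two bases tie for modal (no strict winner).
    """
    depth = counts.sum(axis=0)
    top = counts.max(axis=0)
    modal = counts.argmax(axis=0).astype(np.uint8)
    tie = (counts == top[None, :]).sum(axis=0) > 1
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(depth > 0, top / np.maximum(depth, 1), 0.0)
    bad = (depth < min_depth) | (frac < min_agreement) | tie
    codes = np.where(bad, np.uint8(CODE_N), modal)
    support = np.where(bad, 0, top)
    return codes, support.astype(np.int32), depth.astype(np.int32)


def build_consensus(
    family: ReadFamily,
    min_agreement: float = 0.9,
    min_depth: int = 3,
    max_member_edits: int = 5,
) -> ConsensusSequence:
    """Build the ECCS of one read family by per-column modal voting.

    Deterministic under any member order.  Raises ``ValueError`` for an
    empty family (contract violation).
    """
    reads = family.reads()
    if not reads:
        raise ValueError("cannot build a consensus for an empty family")
    # canonical order: determinism does not depend on how members arrived
    reads = sorted(reads, key=lambda r: (r.anchor, len(r.bases), r.bases, r.mate))

    length_counts = Counter(len(r) for r in reads)
    top_count = max(length_counts.values())
    M = min(l for l, c in length_counts.items() if c == top_count)
    exemplar = next(r for r in reads if len(r) == M)

    counts = np.zeros((4, M), dtype=np.int32)
    cols = np.arange(M)
    outliers = 0
    for read in reads:
        lr = len(read)
        take = min(lr, M)
        if read.anchor == "left":
            off, segment = 0, read.bases[:take]
        else:
            off, segment = M - take, read.bases[-take:]
        if lr != M:
            d = edlib.align(segment, exemplar.bases[off: off + take], mode="NW")[
                "editDistance"
            ]
            if d > max_member_edits:
                outliers += 1
                continue
        codes = encode(segment)
        voting = codes < 4  # read 'N's do not vote
        counts[codes[voting], cols[off: off + take][voting]] += 1

    codes, support, depth = _vote(counts, min_agreement, min_depth)
    return ConsensusSequence(
        family_index=family.family_index,
        amplicon_name=family.amplicon_name,
        bases=decode(codes),
        support=support,
        depth=depth,
        family_size=family.size,
        n_reads=len(reads),
        outliers=outliers,
    )


def consensus_quality_filter(
    eccs: ConsensusSequence, max_n_fraction: float = 0.2
) -> bool:
    """True if the ECCS should be kept for calling (N fraction within limit)."""
    return eccs.n_fraction <= max_n_fraction


def batch_consensus_codes(
    read_codes: np.ndarray,
    family_starts: np.ndarray,
    min_agreement: float = 0.9,
    min_depth: int = 3,
):
    """Vectorized consensus for many same-length families at once.

    ``read_codes`` is an (n_reads, M) uint8 matrix with reads of the same
    family contiguous; ``family_starts`` are the row offsets of each family
    (as for ``np.add.reduceat``).  All reads span the full template (the
    common case for amplicon sequencing, where both mates cover the whole
    amplicon), so this is exactly :func:`build_consensus` restricted to
    equal-length members — the equivalence is asserted in the test suite.

    Returns (consensus codes (F, M), support, depth) as int32 arrays.
    """
    n_reads, M = read_codes.shape
    F = len(family_starts)
    counts = np.empty((4, F, M), dtype=np.int32)
    for b in range(4):
        eq = (read_codes == b)
        counts[b] = np.add.reduceat(eq, family_starts, axis=0)
    depth = counts.sum(axis=0)
    top = counts.max(axis=0)
    modal = counts.argmax(axis=0).astype(np.uint8)
    tie = (counts == top[None]).sum(axis=0) > 1
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(depth > 0, top / np.maximum(depth, 1), 0.0)
    bad = (depth < min_depth) | (frac < min_agreement) | tie
    codes = np.where(bad, np.uint8(CODE_N), modal)
    support = np.where(bad, 0, top).astype(np.int32)
    return codes, support, depth.astype(np.int32)
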