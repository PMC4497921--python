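"""Grouping of tagged reads into read families.

A read family is the set of reads sharing one molecular index at one
amplicon — the sequencing descendants of a single tagged molecule, and the
unit of error correction.  Families are keyed per amplicon: the same index
observed on two different amplicons is two distinct molecules (index
collision across loci is expected and harmless).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .umi import TaggedRead

__all__ = ["ReadFamily", "group_families", "filter_families", "family_size_histogram"]

Pair = tuple[TaggedRead, "TaggedRead | None"]


@dataclass
class ReadFamily:
    """All read pairs sharing one (amplicon, family index)."""

    family_index: str
    amplicon_name: str
    members: list[Pair]

    @property
    def size(self) -> int:
        """Number of read pairs in the family."""
        return len(self.members)

    def reads(self) -> list[TaggedRead]:
        return [r for pair in self.members for r in pair if r is not None]


def group_families(tagged_pairs: Iterable[Pair]) -> list[ReadFamily]:
    """Partition assigned read pairs into families.

    Key = (amplicon name, family index); every input pair appears in exactly
    one family.  Output order is deterministic: sorted by amplicon, then
    index.
    """
    buckets: dict[tuple[str, str], list[Pair]] = {}
    for pair in tagged_pairs:
        lead = pair[0]
        if lead.amplicon_name is None or lead.family_index is None:
            raise ValueError(
                f"read {lead.name!r} is not amplicon-assigned; run assign_amplicon first"
            )
        buckets.setdefault((lead.amplicon_name, lead.family_index), []).append(pair)
    return [
        ReadFamily(family_index=idx, amplicon_name=amp, members=members)
        for (amp, idx), members in sorted(buckets.items())
    ]


def filter_families(
    families: Sequence[ReadFamily], min_size: int = 3
) -> tuple[list[ReadFamily], int]:
    """Drop families with fewer than ``min_size`` read pairs.

    The default of 3 is the smallest size with majority semantics: a true
    consensus can outvote one errored read.  Returns (kept, discarded count).
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    kept = [f for f in families if f.size >= min_size]
    return kept, len(families) - len(kept)


def family_size_histogram(families: Sequence[ReadFamily]) -> pd.DataFrame:
    """Family-size histogram for the run report."""
    counts = Counter(f.size for f in families)
    return pd.DataFrame(
        {"size": sorted(counts), "n_families": [counts[s] for s in sorted(counts)]}
    )
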