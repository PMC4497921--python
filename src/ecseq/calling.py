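"""Variant calling from error-corrected consensus sequences.

Each kept ECCS is aligned globally to its amplicon reference, producing one
allele observation per reference position; at each target locus, families
are then counted as variant-supporting, reference-supporting or other, and
the variant allele fraction is

    VAF = variant families / (variant families + reference families).

Families showing 'N' or a third allele at the locus go to ``other`` and do
not enter the denominator — the reported fraction is over families with a
definite variant-or-reference observation only.

Observation encoding (per reference position):
    "A"        single base observed
    "AGT"      base observed plus an insertion left-anchored at this position
    "-"        position deleted in the ECCS
    "N"        consensus masked here
    None       position not covered by the alignment (terminal gap)
Gaps are left-normalized, so a deletion inside a homopolymer has exactly
one canonical position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib

from .consensus import ConsensusSequence
from .io import AmpliconReference, TargetLocus

__all__ = [
    "AlleleCount",
    "VariantCall",
    "align_eccs",
    "count_alleles",
    "classify_observation",
    "call_variants",
    "left_normalize_gaps",
]

Observation = "list[str | None]"


@dataclass
class AlleleCount:
    """Read-family counts at one target locus."""

    target: TargetLocus
    variant_rfs: int = 0
    reference_rfs: int = 0
    other_rfs: int = 0

    @property
    def vaf(self) -> float | None:
        """variant / (variant + reference) families; None with no coverage."""
        denom = self.variant_rfs + self.reference_rfs
        if denom == 0:
            return None
        return self.variant_rfs / denom


@dataclass
class VariantCall:
    """Detection decision for one target at a requested specificity."""

    count: AlleleCount
    threshold: float | None
    detected: bool

    @property
    def target(self) -> TargetLocus:
        return self.count.target


# ---------------------------------------------------------------------------
# alignment


def _cigar_to_aligned(cigar: str, query: str, target: str) -> tuple[str, str]:
    """Expand an edlib extended cigar into gapped query/target strings."""
    q_out, t_out = [], []
    qi = ti = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch in "=X":
            q_out.append(query[qi: qi + n])
            t_out.append(target[ti: ti + n])
            qi += n
            ti += n
        elif ch == "I":  # present in query, absent from target
            q_out.append(query[qi: qi + n])
            t_out.append("-" * n)
            qi += n
        elif ch == "D":  # absent from query
            q_out.append("-" * n)
            t_out.append(target[ti: ti + n])
            ti += n
        else:
            raise ValueError(f"unexpected cigar op {ch!r}")
    return "".join(q_out), "".join(t_out)


def left_normalize_gaps(q_aln: str, t_aln: str) -> tuple[str, str]:
    """Shift every gap block as far left as sequence identity allows.

    A deletion of target bases t[i:j] equals a deletion of t[i-1:j-1]
    whenever t[i-1] == t[j-1] (and symmetrically for insertions), which is
    the standard left-alignment used for VCF-style indel normalization.
    """
    q = list(q_aln)
    t = list(t_aln)
    n = len(q)
    changed = True
    while changed:
        changed = False
        for seq, other in ((q, t), (t, q)):
            i = 0
            while i < n:
                if seq[i] != "-" or (i > 0 and seq[i - 1] == "-"):
                    i += 1
                    continue
                j = i
                while j < n and seq[j] == "-":
                    j += 1
                while (
                    i > 0
                    and seq[i - 1] != "-"
                    and other[i - 1] != "-"
                    and other[i - 1] == other[j - 1]
                ):
                    # slide the gap block one column left
                    seq[j - 1] = seq[i - 1]
                    seq[i - 1] = "-"
                    i -= 1
                    j -= 1
                    changed = True
                i = j
    return "".join(q), "".join(t)


def align_eccs(
    eccs: ConsensusSequence,
    amplicon: AmpliconReference,
    min_identity: float = 0.8,
) -> "list[str | None] | None":
    """Globally align an ECCS to its amplicon and emit per-position
    observations (see module docstring).  Returns None when the alignment
    identity — matching bases over non-N aligned bases — falls below
    ``min_identity`` (the ECCS is unalignable and is counted, not used).
    """
    ref = amplicon.sequence
    L = len(ref)
    query = eccs.bases
    if len(query) == L:
        # fast path: positional comparison, no indels possible
        matches = sum(1 for a, b in zip(query, ref) if a == b)
        informative = sum(1 for a in query if a != "N")
        if informative and matches / informative < min_identity:
            return None
        return list(query)

    if not query:
        return None
    aln = edlib.align(query, ref, mode="NW", task="path")
    q_aln, t_aln = _cigar_to_aligned(aln["cigar"], query, ref)
    q_aln, t_aln = left_normalize_gaps(q_aln, t_aln)

    obs: list[str | None] = [None] * L
    ref_pos = -1
    matches = informative = 0
    for qc, tc in zip(q_aln, t_aln):
        if tc == "-":  # insertion in the ECCS, left-anchored
            if ref_pos >= 0 and obs[ref_pos] is not None:
                obs[ref_pos] = (obs[ref_pos] or "") + qc
            continue
        ref_pos += 1
        obs[ref_pos] = qc
        if qc not in ("-", "N"):
            informative += 1
            if qc == tc:
                matches += 1
    # terminal query gaps are lack of coverage, not deletions
    i = 0
    while i < L and obs[i] == "-":
        obs[i] = None
        i += 1
    i = L - 1
    while i >= 0 and obs[i] == "-":
        obs[i] = None
        i -= 1
    if informative == 0 or matches / informative < min_identity:
        return None
    return obs


# ---------------------------------------------------------------------------
# counting


def classify_observation(
    obs: "list[str | None]", target: TargetLocus, amplicon: AmpliconReference
) -> str | None:
    """Classify one family's observation at a target locus.

    Returns "variant", "reference", "other", or None when the alignment does
    not span the locus.  Indel matching requires the full anchored
    replacement; partially overlapping indels are "other".
    """
    anchor = amplicon.offset(target.position)
    ref, alt = target.ref_allele, target.alt_allele
    span = len(ref)
    window = obs[anchor: anchor + span]
    if any(o is None for o in window):
        return None

    if target.is_snv:
        o = window[0]
        if o == alt:
            return "variant"
        if o == ref:
            return "reference"
        return "other"

    if target.is_deletion:
        k = span - len(alt)
        # variant: anchor bases intact, exactly the k anchored bases gapped,
        # and the deletion does not run on past the target span
        variant = (
            window[: len(alt)] == list(alt)
            and all(o == "-" for o in window[len(alt):])
            and not (anchor + span < len(obs) and obs[anchor + span] == "-")
        )
        if variant:
            return "variant"
        if window == list(ref):
            return "reference"
        return "other"

    # insertion: the inserted bases ride on the anchor position's observation
    ins = alt[len(ref):]
    if window == [ref[0] + ins] + list(ref[1:]):
        return "variant"
    if window == list(ref):
        return "reference"
    return "other"


def count_alleles(
    observations: Iterable["list[str | None]"],
    target: TargetLocus,
    amplicon: AmpliconReference,
) -> AlleleCount:
    """Count variant/reference/other families at a target locus.

    Every family contributes exactly once; families whose alignment does not
    span the locus contribute nothing.  Raises ``ValueError`` if the target
    lies outside the amplicon (configuration error).
    """
    if not amplicon.contains(target.contig, target.position, len(target.ref_allele)):
        raise ValueError(
            f"target {target.label or target.position} not covered by "
            f"amplicon {amplicon.name}"
        )
    ac = AlleleCount(target=target)
    for obs in observations:
        cls = classify_observation(obs, target, amplicon)
        if cls == "variant":
            ac.variant_rfs += 1
        elif cls == "reference":
            ac.reference_rfs += 1
        elif cls == "other":
            ac.other_rfs += 1
    return ac


# ---------------------------------------------------------------------------
# detection


def call_variants(
    allele_counts: Sequence[AlleleCount],
    error_profile,
    specificity: float = 0.99,
    min_indel_variant_rfs: int = 3,
) -> list[VariantCall]:
    """Decide detection per target against the background error profile.

    SNVs are detected when their VAF exceeds the substitution-class
    threshold at the requested specificity (missing class threshold falls
    back to the global one, with a warning).  Indels are detected from a
    minimum variant-family count instead, since indel-generating errors are
    rare and an indel VAF threshold would be dominated by substitutions.
    """
    calls = []
    for ac in allele_counts:
        t = ac.target
        if t.is_snv:
            threshold = None
            if error_profile is not None:
                threshold = error_profile.threshold_for(
                    t.ref_allele, t.alt_allele, specificity=specificity
                )
            if threshold is None:
                warnings.warn(
                    f"no error-profile threshold available for {t.label or t.mut}; "
                    "variant not callable"
                )
                detected = False
            else:
                detected = ac.vaf is not None and ac.vaf > threshold
        else:
            threshold = None
            detected = ac.variant_rfs >= min_indel_variant_rfs
        calls.append(VariantCall(count=ac, threshold=threshold, detected=detected))
    return calls
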