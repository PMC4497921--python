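"""Input/output for the ECS pipeline: amplicon references, target loci,
paired FASTQ streams and the calls table.

Coordinate conventions
----------------------
All user-facing coordinates are 1-based inclusive (genomic style).  Internal
amplicon offsets are 0-based half-open; the conversion happens only here, at
the I/O boundary.

Targets file dialect
--------------------
Tab-separated with a header line ``contig  position  ref  alt  label``.
Lines starting with ``#`` are ignored.  Two equivalent notations are accepted
for indels and normalized to VCF-style anchored alleles:

* VCF-style: ``ref=AG alt=A`` (deletion of G anchored at ``position``).
* Shorthand: ``alt`` is ``del XXX`` (deletion of the bases XXX starting at
  ``position``; the ``ref`` column is ignored and may be ``.``) or
  ``ins XXX`` (insertion of XXX immediately after ``position``).

Anchored indels are left-normalized against the amplicon sequence so that a
deletion inside a homopolymer has a single canonical position.
"""

from __future__ import annotations

import gzip
import itertools
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import pysam

__all__ = [
    "AmpliconReference",
    "TargetLocus",
    "FastqRead",
    "TargetFileError",
    "PairingError",
    "read_amplicons",
    "read_targets",
    "write_targets",
    "read_fastq_pairs",
    "write_calls_table",
    "format_vaf",
    "find_amplicon",
]

VALID_BASES = frozenset("ACGT")


class TargetFileError(ValueError):
    """Malformed or invalid targets file; carries the offending line number."""


class PairingError(ValueError):
    """R1/R2 FASTQ streams disagree (names or record counts)."""


@dataclass(frozen=True)
class AmpliconReference:
    """One PCR amplicon: its sequence and 1-based inclusive genomic span."""

    name: str
    sequence: str
    contig: str
    start: int
    end: int

    def __post_init__(self):
        object.__setattr__(self, "sequence", self.sequence.upper())
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError(
                f"amplicon {self.name}: span {self.contig}:{self.start}-{self.end} "
                f"does not match sequence length {len(self.sequence)}"
            )
        if self.start < 1:
            raise ValueError(f"amplicon {self.name}: start must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)

    def offset(self, position: int) -> int:
        """0-based offset of a 1-based genomic position on this amplicon."""
        if not (self.start <= position <= self.end):
            raise ValueError(
                f"position {self.contig}:{position} outside amplicon {self.name}"
            )
        return position - self.start

    def contains(self, contig: str, position: int, span: int = 1) -> bool:
        return (
            contig == self.contig
            and self.start <= position
            and position + span - 1 <= self.end
        )


@dataclass(frozen=True)
class TargetLocus:
    """A queried variant: SNV or anchored short indel, VCF-style alleles.

    ``position`` is the 1-based genomic position of the first reference base
    of ``ref_allele``.
    """

    contig: str
    position: int
    ref_allele: str
    alt_allele: str
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "ref_allele", self.ref_allele.upper())
        object.__setattr__(self, "alt_allele", self.alt_allele.upper())
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")
        for allele, what in ((self.ref_allele, "ref"), (self.alt_allele, "alt")):
            if not allele or not set(allele) <= VALID_BASES:
                raise ValueError(f"{what} allele {allele!r} is not a DNA string")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles are identical")

    @property
    def is_snv(self) -> bool:
        return len(self.ref_allele) == 1 and len(self.alt_allele) == 1

    @property
    def is_deletion(self) -> bool:
        return len(self.ref_allele) > len(self.alt_allele)

    @property
    def is_insertion(self) -> bool:
        return len(self.alt_allele) > len(self.ref_allele)

    @property
    def mut(self) -> str:
        """Human-readable mutation string ('T to G', 'del CTT', 'ins AC')."""
        if self.is_snv:
            return f"{self.ref_allele} to {self.alt_allele}"
        if self.is_deletion:
            return f"del {self.ref_allele[len(self.alt_allele):]}"
        return f"ins {self.alt_allele[len(self.ref_allele):]}"


class FastqRead(NamedTuple):
    name: str
    sequence: str
    quality: str


# ---------------------------------------------------------------------------
# amplicon references


def _parse_header_span(comment: str):
    # "contig:start-end" somewhere in the FASTA description
    for token in comment.split():
        if ":" in token and "-" in token.split(":", 1)[1]:
            contig, span = token.split(":", 1)
            lo, hi = span.split("-", 1)
            try:
                return contig, int(lo.replace(",", "")), int(hi.replace(",", ""))
            except ValueError:
                continue
    return None


def read_amplicons(fasta_path, bed_path=None) -> list[AmpliconReference]:
    """Load amplicon references from FASTA.

    Genomic spans come either from a BED-like companion file
    (``contig <tab> 0-based start <tab> end <tab> name``) or from FASTA
    descriptions of the form ``>name contig:start-end`` (1-based inclusive).
    Amplicons on the same contig may not overlap.
    """
    spans = {}
    if bed_path is not None:
        with open(bed_path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ValueError(f"{bed_path}:{lineno}: expected 4 BED columns")
                contig, start0, end, name = parts[:4]
                spans[name] = (contig, int(start0) + 1, int(end))

    amplicons = []
    with pysam.FastxFile(str(fasta_path)) as fh:
        for entry in fh:
            name = entry.name
            if name in spans:
                contig, start, end = spans[name]
            else:
                parsed = _parse_header_span(entry.comment or "")
                if parsed is None:
                    raise ValueError(
                        f"amplicon {name}: no genomic span in BED file or FASTA header"
                    )
                contig, start, end = parsed
            amplicons.append(
                AmpliconReference(name, entry.sequence.upper(), contig, start, end)
            )

    by_contig: dict[str, list[AmpliconReference]] = {}
    for amp in amplicons:
        by_contig.setdefault(amp.contig, []).append(amp)
    for contig, group in by_contig.items():
        group = sorted(group, key=lambda a: a.start)
        for a, b in itertools.pairwise(group):
            if b.start <= a.end:
                raise ValueError(
                    f"amplicons {a.name} and {b.name} overlap on contig {contig}"
                )
    return amplicons


def find_amplicon(
    amplicons: Sequence[AmpliconReference], contig: str, position: int, span: int = 1
) -> AmpliconReference | None:
    """The unique amplicon containing [position, position+span) on contig."""
    for amp in amplicons:
        if amp.contains(contig, position, span):
            return amp
    return None


# ---------------------------------------------------------------------------
# targets


def normalize_indel(
    position: int, ref: str, alt: str, amplicon: AmpliconReference
) -> tuple[int, str, str]:
    """Left-normalize an anchored indel against the amplicon sequence.

    Standard VCF normalization: trim shared suffix bases (extending to the
    left through the reference when one allele would empty), then trim the
    shared prefix down to a single anchor base.  Gives one canonical position
    for indels inside homopolymers.
    """
    seq = amplicon.sequence
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            continue
        if ref[-1] == alt[-1] and position > amplicon.start:
            prev = seq[position - 1 - amplicon.start]
            ref, alt = prev + ref[:-1], prev + alt[:-1]
            position -= 1
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        position += 1
    return position, ref, alt


def _resolve_target(
    contig: str, position: int, ref: str, alt: str, label: str,
    amplicons: Sequence[AmpliconReference] | None,
) -> TargetLocus:
    alt_u = alt.strip().upper()
    shorthand = alt_u.startswith(("DEL ", "INS "))
    if shorthand:
        if amplicons is None:
            raise ValueError("del/ins shorthand requires loaded amplicon references")
        op, bases = alt_u.split(None, 1)
        bases = bases.replace(" ", "")
        if not set(bases) <= VALID_BASES:
            raise ValueError(f"bad {op.lower()} bases {bases!r}")
        if op == "DEL":
            amp = find_amplicon(amplicons, contig, position, len(bases))
            if amp is None:
                raise ValueError(
                    f"locus {contig}:{position} not inside any amplicon"
                )
            observed = amp.sequence[amp.offset(position): amp.offset(position) + len(bases)]
            if observed != bases:
                raise ValueError(
                    f"deleted bases {bases} do not match reference {observed} "
                    f"at {contig}:{position}"
                )
            if position == amp.start:
                raise ValueError("deletion at amplicon start cannot be left-anchored")
            anchor = amp.sequence[amp.offset(position) - 1]
            position, ref_a, alt_a = position - 1, anchor + bases, anchor
        else:  # INS, inserted immediately after `position`
            amp = find_amplicon(amplicons, contig, position)
            if amp is None:
                raise ValueError(f"locus {contig}:{position} not inside any amplicon")
            anchor = amp.sequence[amp.offset(position)]
            ref_a, alt_a = anchor, anchor + bases
        position, ref_a, alt_a = normalize_indel(position, ref_a, alt_a, amp)
        return TargetLocus(contig, position, ref_a, alt_a, label)

    locus = TargetLocus(contig, position, ref.strip().upper(), alt_u, label)
    if amplicons is not None:
        amp = find_amplicon(amplicons, contig, position, len(locus.ref_allele))
        if amp is None:
            raise ValueError(f"locus {contig}:{position} not inside any amplicon")
        observed = amp.sequence[
            amp.offset(position): amp.offset(position) + len(locus.ref_allele)
        ]
        if observed != locus.ref_allele:
            raise ValueError(
                f"ref allele {locus.ref_allele} does not match amplicon "
                f"sequence {observed} at {contig}:{position}"
            )
        if not locus.is_snv:
            pos, ref_n, alt_n = normalize_indel(
                locus.position, locus.ref_allele, locus.alt_allele, amp
            )
            locus = replace(locus, position=pos, ref_allele=ref_n, alt_allele=alt_n)
    return locus


def read_targets(path, amplicons: Sequence[AmpliconReference] | None = None) -> list[TargetLocus]:
    """Parse the targets file; see the module docstring for the dialect.

    When ``amplicons`` is given, each locus is validated to fall inside
    exactly one amplicon and its ref allele is checked against the sequence.
    """
    required = ["contig", "position", "ref", "alt", "label"]
    loci: list[TargetLocus] = []
    with open(path) as fh:
        header = None
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip().lower() for f in fields]
                missing = [c for c in required[:4] if c not in header]
                if missing:
                    raise TargetFileError(
                        f"{path}:{lineno}: missing columns {missing}"
                    )
                continue
            row = dict(zip(header, fields))
            try:
                position = int(row["position"])
                locus = _resolve_target(
                    row["contig"].strip(),
                    position,
                    row.get("ref", "."),
                    row["alt"],
                    row.get("label", "").strip(),
                    amplicons,
                )
            except (KeyError, ValueError) as exc:
                raise TargetFileError(f"{path}:{lineno}: {exc}") from exc
            loci.append(locus)
    if header is None:
        raise TargetFileError(f"{path}: empty file (header line required)")
    return loci


def write_targets(loci: Iterable[TargetLocus], path) -> None:
    """Write targets in the VCF-style dialect (round-trips read_targets)."""
    with open(path, "w") as fh:
        fh.write("contig\tposition\tref\talt\tlabel\n")
        for t in loci:
            fh.write(
                f"{t.contig}\t{t.position}\t{t.ref_allele}\t{t.alt_allele}\t{t.label}\n"
            )


# ---------------------------------------------------------------------------
# FASTQ


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _fastq_records(path) -> Iterator[FastqRead]:
    with _open_text(path) as fh:
        while True:
            head = fh.readline()
            if not head:
                return
            head = head.rstrip("\n")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not plus or not head.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"{path}: truncated or malformed FASTQ record")
            if not qual and seq:
                raise ValueError(f"{path}: truncated FASTQ record (missing qualities)")
            if len(seq) != len(qual):
                raise ValueError(
                    f"{path}: sequence/quality length mismatch in record {head}"
                )
            yield FastqRead(head[1:].split()[0], seq, qual)


def _strip_mate_suffix(name: str) -> str:
    return name[:-2] if name.endswith(("/1", "/2")) else name


def read_fastq_pairs(path_r1, path_r2) -> Iterator[tuple[FastqRead, FastqRead]]:
    """Stream matched read pairs from two FASTQ files (plain or gzip).

    Lazily yields :class:`FastqRead` tuples; raises :class:`PairingError` on
    name mismatches or unequal record counts.
    """
    sentinel = object()
    for i, (r1, r2) in enumerate(
        itertools.zip_longest(_fastq_records(path_r1), _fastq_records(path_r2),
                              fillvalue=sentinel),
        1,
    ):
        if r1 is sentinel or r2 is sentinel:
            raise PairingError(
                f"unequal record counts between {path_r1} and {path_r2} "
                f"(at record {i})"
            )
        if _strip_mate_suffix(r1.name) != _strip_mate_suffix(r2.name):
            raise PairingError(
                f"read name mismatch at record {i}: {r1.name!r} vs {r2.name!r}"
            )
        yield r1, r2


# ---------------------------------------------------------------------------
# calls table


def format_vaf(variant_rfs: int, reference_rfs: int) -> str:
    """Format a VAF the way the calls table prints it.

    Round half-up to 4 decimal places and trim trailing zeros; zero coverage
    prints ``NA`` (no data), distinct from ``0`` (no variant families).
    """
    denom = variant_rfs + reference_rfs
    if denom == 0:
        return "NA"
    q = (Decimal(variant_rfs) / Decimal(denom)).quantize(
        Decimal("0.0001"), rounding=ROUND_HALF_UP
    )
    return format(q.normalize(), "f")


def write_calls_table(allele_counts, path) -> None:
    """Write the per-target calls table (TSV).

    Columns: label, contig, position, mut, variant_RFs, reference_RFs, VAF.
    ``allele_counts`` is an iterable of objects with ``target``,
    ``variant_rfs`` and ``reference_rfs`` attributes (see calling module).
    """
    with open(path, "w") as fh:
        fh.write("label\tcontig\tposition\tmut\tvariant_RFs\treference_RFs\tVAF\n")
        for ac in allele_counts:
            t = ac.target
            fh.write(
                f"{t.label}\t{t.contig}\t{t.position}\t{t.mut}\t"
                f"{ac.variant_rfs}\t{ac.reference_rfs}\t"
                f"{format_vaf(ac.variant_rfs, ac.reference_rfs)}\n"
            )
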