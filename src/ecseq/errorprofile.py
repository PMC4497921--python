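"""Residual error characterization at wild-type positions.

After consensus correction some errors survive (chiefly molecule-level
damage such as oxidation of guanine to 8-oxo-guanine, which mispairs and
appears as strand-consistent G>T / C>A substitutions).  This module
measures the per-site VAF distribution at every position *not* expected to
carry a real variant, derives the VAF a caller must exceed to be specific
at a requested level, and breaks the distribution down by substitution
class — overall, for G>T(C>A), for C>T(G>A), and for the other eight
substitutions, which behave very differently.

"Specific at VAF t" is operationalized as the empirical quantile of the
wild-type per-site VAF records: at specificity s, the threshold is the
order statistic ``quantile(vafs, s, method="higher")``, so calling only
sites above it limits the wild-type false-positive rate to ~(1 - s) on this
distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._dna import complement_base
from .io import AmpliconReference, TargetLocus

__all__ = [
    "SUBSTITUTIONS",
    "reverse_complement_substitution",
    "collapsed_class",
    "class_group",
    "GROUP_GT_CA",
    "GROUP_CT_GA",
    "GROUP_OTHER",
    "GROUP_GLOBAL",
    "wildtype_site_vafs",
    "specificity_threshold",
    "class_profile",
    "raw_vs_corrected_cdf",
    "ErrorProfile",
]

#: the 12 ordered substitution classes (ref base -> alt base)
SUBSTITUTIONS = [(r, a) for r in "ACGT" for a in "ACGT" if r != a]

GROUP_GT_CA = "G>T(C>A)"
GROUP_CT_GA = "C>T(G>A)"
GROUP_OTHER = "other"
GROUP_GLOBAL = "global"


def reverse_complement_substitution(ref: str, alt: str) -> tuple[str, str]:
    """The substitution seen from the opposite strand (an involution)."""
    return complement_base(ref), complement_base(alt)


def collapsed_class(ref: str, alt: str) -> str:
    """Strand-collapsed label merging a class with its reverse complement.

    Exactly 6 collapsed classes; the label lists both strand readings, the
    alphabetically smaller first (e.g. 'C>A/G>T').
    """
    a = f"{ref}>{alt}"
    rr, ra = reverse_complement_substitution(ref, alt)
    b = f"{rr}>{ra}"
    lo, hi = sorted((a, b))
    return f"{lo}/{hi}"


def class_group(ref: str, alt: str) -> str:
    """The 3-way grouping used for specificity thresholds."""
    pair = {(ref, alt)}
    if pair <= {("G", "T"), ("C", "A")}:
        return GROUP_GT_CA
    if pair <= {("C", "T"), ("G", "A")}:
        return GROUP_CT_GA
    return GROUP_OTHER


def _excluded_offsets(
    amplicon: AmpliconReference, targets: "list[TargetLocus]"
) -> set[int]:
    out: set[int] = set()
    for t in targets:
        if not amplicon.contains(t.contig, t.position, 1):
            continue
        for off in range(
            amplicon.offset(t.position),
            min(amplicon.offset(t.position) + len(t.ref_allele), len(amplicon)),
        ):
            out.add(off)
    return out


def wildtype_site_vafs(
    base_counts: np.ndarray,
    coverage: np.ndarray,
    amplicon: AmpliconReference,
    targets: "list[TargetLocus]" = (),
) -> pd.DataFrame:
    """Per-site VAF records at wild-type positions of one amplicon.

    ``base_counts`` is a (L, 4) array of read-family counts per observed
    base (A,C,G,T columns) and ``coverage`` the per-position number of
    families with a definite base call.  For every position outside the
    target loci and every alt base != ref, one record
    (position, ref, alt, alt_families, coverage, vaf) is emitted; positions
    with zero coverage are omitted.
    """
    base_counts = np.asarray(base_counts)
    coverage = np.asarray(coverage)
    excluded = _excluded_offsets(amplicon, list(targets))
    rows = []
    for off, ref_base in enumerate(amplicon.sequence):
        if off in excluded or coverage[off] == 0 or ref_base not in "ACGT":
            continue
        for bi, alt_base in enumerate("ACGT"):
            if alt_base == ref_base:
                continue
            alt_n = int(base_counts[off, bi])
            rows.append(
                (
                    amplicon.name,
                    amplicon.start + off,
                    ref_base,
                    alt_base,
                    alt_n,
                    int(coverage[off]),
                    alt_n / coverage[off],
                )
            )
    return pd.DataFrame(
        rows,
        columns=["amplicon", "position", "ref", "alt", "alt_families", "coverage", "vaf"],
    )


def specificity_threshold(vafs, specificity: float = 0.99) -> float:
    """Empirical VAF quantile of wild-type site records.

    The smallest observed VAF t such that a fraction >= ``specificity`` of
    records lie below it — the order statistic
    ``quantile(vafs, specificity, method="higher")``.  Calling only above t
    is (1 - specificity)-false-positive by construction on this record set.
    Fewer than 100 records cannot resolve a 99% quantile; a warning is
    issued and the maximum observed VAF returned.
    """
    v = np.asarray(list(vafs), dtype=float)
    if v.size == 0:
        raise ValueError("no VAF records")
    if not 0.0 < specificity <= 1.0:
        raise ValueError("specificity must be in (0, 1]")
    if v.size < 100:
        warnings.warn(
            f"only {v.size} VAF records; specificity quantile poorly resolved, "
            "returning the maximum observed VAF"
        )
        return float(v.max())
    return float(np.quantile(v, specificity, method="higher"))


def class_profile(
    records: pd.DataFrame, specificity: float = 0.99
) -> tuple[dict[str, float | None], pd.DataFrame]:
    """Per-class-group thresholds and the strand-collapsed histogram.

    Records are partitioned into the three class groups; the specificity
    quantile is computed per group (None with a warning for an empty
    group).  The returned histogram has one row per collapsed class with
    total alt families, records and mean VAF (the class-bias report).
    """
    groups = records.apply(lambda r: class_group(r["ref"], r["alt"]), axis=1) if len(
        records
    ) else pd.Series(dtype=object)
    thresholds: dict[str, float | None] = {}
    for name in (GROUP_GT_CA, GROUP_CT_GA, GROUP_OTHER):
        sub = records[groups == name] if len(records) else records
        if len(sub) == 0:
            warnings.warn(f"no wild-type records in class group {name}")
            thresholds[name] = None
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                thresholds[name] = specificity_threshold(sub["vaf"], specificity)

    if len(records):
        collapsed = records.apply(
            lambda r: collapsed_class(r["ref"], r["alt"]), axis=1
        )
        hist = (
            records.assign(collapsed=collapsed)
            .groupby("collapsed", sort=True)
            .agg(
                alt_families=("alt_families", "sum"),
                records=("vaf", "size"),
                mean_vaf=("vaf", "mean"),
            )
            .reset_index()
        )
    else:
        hist = pd.DataFrame(
            columns=["collapsed", "alt_families", "records", "mean_vaf"]
        )
    return thresholds, hist


def raw_vs_corrected_cdf(
    raw_site_vafs, eccs_site_vafs, grid=None
) -> pd.DataFrame:
    """Paired cumulative VAF distributions: raw reads vs consensus families.

    Returns (vaf, F_raw, F_eccs) on a shared grid; both CDFs are monotone
    non-decreasing, and on simulated data with active error processes the
    consensus CDF dominates the raw one (errors are removed, never added).
    """
    raw = np.sort(np.asarray(list(raw_site_vafs), dtype=float))
    eccs = np.sort(np.asarray(list(eccs_site_vafs), dtype=float))
    if raw.size == 0 or eccs.size == 0:
        raise ValueError("both raw and ECCS VAF record sets must be non-empty")
    if grid is None:
        grid = np.unique(np.concatenate([raw, eccs]))
    grid = np.asarray(grid, dtype=float)
    return pd.DataFrame(
        {
            "vaf": grid,
            "F_raw": np.searchsorted(raw, grid, side="right") / raw.size,
            "F_eccs": np.searchsorted(eccs, grid, side="right") / eccs.size,
        }
    )


@dataclass
class ErrorProfile:
    """Wild-type site records plus the thresholds derived from them."""

    records: pd.DataFrame
    specificity: float = 0.99
    thresholds: dict = field(default_factory=dict)

    @classmethod
    def from_records(
        cls, records: pd.DataFrame, specificity: float = 0.99
    ) -> "ErrorProfile":
        thresholds, hist = class_profile(records, specificity)
        if len(records):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                thresholds[GROUP_GLOBAL] = specificity_threshold(
                    records["vaf"], specificity
                )
        else:
            thresholds[GROUP_GLOBAL] = None
        profile = cls(records=records, specificity=specificity, thresholds=thresholds)
        profile.class_histogram = hist
        return profile

    def threshold_for(
        self, ref: str, alt: str, specificity: float | None = None
    ) -> float | None:
        """Class-group threshold for a substitution; global fallback with a
        warning when the group threshold is unavailable."""
        if specificity is not None and specificity != self.specificity and len(
            self.records
        ):
            return ErrorProfile.from_records(self.records, specificity).threshold_for(
                ref, alt
            )
        t = self.thresholds.get(class_group(ref, alt))
        if t is None:
            t = self.thresholds.get(GROUP_GLOBAL)
            if t is not None:
                warnings.warn(
                    f"no class threshold for {ref}>{alt}; using global threshold"
                )
        return t
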