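"""End-to-end orchestration: FASTQ -> families -> ECCS -> calls -> profile.

``run_pipeline`` executes the whole method on one library.  Internally it
uses a streaming, array-based engine so that multi-million-read libraries
fit one CPU comfortably: reads are accumulated per amplicon as flat arrays,
families whose members all share one template length are consensus-called
in vectorized chunks (``consensus.batch_consensus_codes``), and only
length-discordant families fall back to the per-family object path
(``consensus.build_consensus``).  Both paths implement the same voting rule
and the test suite asserts their equivalence on complete libraries.

Conservation identities are the primary debugging surface and are recorded
in the run manifest at every stage boundary:

* assigned + too_short + unassigned + ambiguous == total read pairs
* sum of family sizes == assigned pairs
* variant + reference + other families at a target == kept, alignable
  ECCS spanning it
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter, defaultdict
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from ._dna import CODE_N, ENCODE_LUT, decode, revcomp
from .calling import (AlleleCount, VariantCall, align_eccs, call_variants,
                      classify_observation)
from .consensus import batch_consensus_codes, build_consensus, consensus_quality_filter
from .errorprofile import ErrorProfile, raw_vs_corrected_cdf, wildtype_site_vafs
from .families import ReadFamily
from .io import (AmpliconReference, TargetLocus, find_amplicon, read_amplicons,
                 read_fastq_pairs, read_targets, write_calls_table)
from .umi import AmpliconIndex, TaggedRead, _resolve_assignment, directional_collapse

__all__ = ["PipelineParams", "RunManifest", "RunResult", "run_pipeline",
           "compare_raw_vs_corrected", "longitudinal_report"]

log = logging.getLogger("ecseq")

_CHUNK_FAMILIES = 50_000


@dataclass
class PipelineParams:
    """Tunables of the computational pipeline (see methods note for units
    and rationale).  ``correction=False`` is the conventional
    deep-sequencing mode: every read is its own singleton family, so no
    error correction occurs — used for the raw-vs-corrected comparison."""

    index_length: int = 16
    min_insert: int = 30
    anchor_k: int = 20
    anchor_max_edits: int = 2
    umi_collapse: bool = False
    min_family_size: int = 3
    min_agreement: float = 0.9
    min_depth: int = 3
    max_n_fraction: float = 0.2
    max_member_edits: int = 5
    min_identity: float = 0.8
    specificity: float = 0.99
    min_indel_variant_rfs: int = 3
    correction: bool = True


@dataclass
class RunManifest:
    """Reproducibility record: version, config, input digests, stage counts."""

    version: str
    params: dict
    inputs: dict
    counts: dict = field(default_factory=dict)
    seed: int | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class RunResult:
    manifest: RunManifest
    calls: pd.DataFrame
    allele_counts: list[AlleleCount]
    variant_calls: list[VariantCall]
    profile: ErrorProfile | None
    site_records: pd.DataFrame
    family_histogram: pd.DataFrame
    out_dir: Path | None = None


def _md5(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


class _AmpliconAccumulator:
    """Flat per-amplicon storage for assigned reads (two rows per pair)."""

    __slots__ = ("keys", "sides", "seqs", "pair_counts")

    def __init__(self):
        self.keys: list[str] = []
        self.sides: list[str] = []
        self.seqs: list[str] = []
        self.pair_counts: Counter = Counter()


def _load_amplicons(amplicons, regions):
    if isinstance(amplicons, (str, Path)):
        return read_amplicons(amplicons, regions)
    return list(amplicons)


def _load_targets(targets, refs):
    if targets is None:
        return []
    if isinstance(targets, (str, Path)):
        return read_targets(targets, amplicons=refs)
    out = []
    for t in targets:
        amp = find_amplicon(refs, t.contig, t.position, len(t.ref_allele))
        if amp is None:
            raise ValueError(
                f"target {t.label or t.position} is outside all amplicons"
            )
        out.append(t)
    return out


def run_pipeline(
    r1,
    r2,
    amplicons,
    targets=None,
    out_dir=None,
    params: PipelineParams | None = None,
    regions=None,
    seed: int | None = None,
) -> RunResult:
    """Run the full ECS analysis on one paired FASTQ library.

    ``amplicons`` is a FASTA path (with ``regions`` BED, or header spans)
    or a list of :class:`AmpliconReference`; ``targets`` a targets-file
    path or a list of :class:`TargetLocus`.  All inputs are validated
    before any read is processed.  When ``out_dir`` is given the calls
    table, per-target JSON, error-profile reports, family-size histogram
    and run manifest are written there.
    """
    params = params or PipelineParams()
    refs = _load_amplicons(amplicons, regions)
    if not refs:
        raise ValueError("no amplicon references loaded")
    target_list = _load_targets(targets, refs)

    amp_index = AmpliconIndex(refs, k=params.anchor_k, max_edits=params.anchor_max_edits)
    acc: dict[str, _AmpliconAccumulator] = {a.name: _AmpliconAccumulator() for a in refs}
    counters = {"total_pairs": 0, "too_short": 0, "unassigned": 0,
                "ambiguous": 0, "assigned_pairs": 0}

    il, mi = params.index_length, params.min_insert
    serial = 0
    for rec1, rec2 in read_fastq_pairs(r1, r2):
        counters["total_pairs"] += 1
        s1, s2 = rec1.sequence, rec2.sequence
        if len(s1) < il + mi or len(s2) < il + mi:
            counters["too_short"] += 1
            continue
        t1, t2 = s1[il:].upper(), s2[il:].upper()
        resolved = _resolve_assignment(amp_index.match_end(t1), amp_index.match_end(t2))
        if isinstance(resolved, str):
            counters[resolved] += 1
            continue
        name, m1side = resolved
        amp = amp_index.references[name]
        L = len(amp.sequence)
        i1, i2 = s1[:il].upper(), s2[:il].upper()
        if m1side == "left":
            t_left, t_right_raw, key = t1, t2, i1 + i2
        else:
            t_left, t_right_raw, key = t2, t1, i2 + i1
        t_left = t_left[:L]
        t_right = revcomp(t_right_raw)
        if len(t_right) > L:
            t_right = t_right[-L:]
        if not params.correction:
            # conventional deep sequencing: one singleton family per read
            key_l, key_r = f"!{serial}.L", f"!{serial}.R"
            serial += 1
        else:
            key_l = key_r = key
        a = acc[name]
        a.keys.append(key_l)
        a.sides.append("left")
        a.seqs.append(t_left)
        a.keys.append(key_r)
        a.sides.append("right")
        a.seqs.append(t_right)
        a.pair_counts[key_l] += 1
        if key_r != key_l:
            a.pair_counts[key_r] += 1
        counters["assigned_pairs"] += 1

    # --- per-amplicon family processing ----------------------------------
    min_size = params.min_family_size if params.correction else 1
    min_depth = params.min_depth if params.correction else 1
    min_agreement = params.min_agreement if params.correction else 0.0

    counters.update(families_total=0, families_discarded=0, families_kept=0,
                    eccs_built=0, eccs_n_filtered=0, eccs_unalignable=0,
                    eccs_used=0, family_outlier_reads=0)
    hist_counter: Counter = Counter()
    all_records: list[pd.DataFrame] = []
    target_counts: dict[int, AlleleCount] = {
        i: AlleleCount(target=t) for i, t in enumerate(target_list)
    }

    for amp in sorted(refs, key=lambda a: a.name):
        a = acc[amp.name]
        L = len(amp.sequence)
        amp_targets = [
            (i, t) for i, t in enumerate(target_list)
            if amp.contains(t.contig, t.position, len(t.ref_allele))
        ]
        keys = a.keys
        if params.correction and params.umi_collapse and a.pair_counts:
            read_counts = Counter()
            for k in keys:
                read_counts[k] += 1
            mapping = directional_collapse(read_counts)
            keys = [mapping[k] for k in keys]
            pair_counts = Counter()
            for k in keys[::2]:
                pair_counts[k] += 1
            a.pair_counts = pair_counts
        if params.correction:
            hist_counter.update(a.pair_counts.values())
        counters["families_total"] += len(a.pair_counts)
        kept_keys = sorted(
            k for k, c in a.pair_counts.items() if c >= min_size
        )
        counters["families_discarded"] += len(a.pair_counts) - len(kept_keys)
        counters["families_kept"] += len(kept_keys)
        if not kept_keys:
            continue
        kept_set = set(kept_keys)
        rows_by_key: dict[str, list[int]] = defaultdict(list)
        for ridx, k in enumerate(keys):
            if k in kept_set:
                rows_by_key[k].append(ridx)

        uniform_groups: dict[int, list[tuple[str, list[int]]]] = defaultdict(list)
        generic_keys: list[str] = []
        for k in kept_keys:
            rows = rows_by_key[k]
            lens = {len(a.seqs[r]) for r in rows}
            if len(lens) == 1:
                uniform_groups[lens.pop()].append((k, rows))
            else:
                generic_keys.append(k)

        counts4 = np.zeros((L, 4), dtype=np.int64)
        n_spanning = np.zeros(L, dtype=np.int64)  # families whose alignment covers pos
        align_cache: dict[str, object] = {}

        def handle_obs_family(obs, mult=1):
            """Tally one aligned family (or `mult` identical ones)."""
            for pos, o in enumerate(obs):
                if o is None:
                    continue
                n_spanning[pos] += mult
                b = o[0] if o else ""
                if b == "A":
                    counts4[pos, 0] += mult
                elif b == "C":
                    counts4[pos, 1] += mult
                elif b == "G":
                    counts4[pos, 2] += mult
                elif b == "T":
                    counts4[pos, 3] += mult
            for i, t in amp_targets:
                cls = classify_observation(obs, t, amp)
                if cls == "variant":
                    target_counts[i].variant_rfs += mult
                elif cls == "reference":
                    target_counts[i].reference_rfs += mult
                elif cls == "other":
                    target_counts[i].other_rfs += mult

        def handle_nonref_eccs(bases: str, mult: int = 1):
            """Align-and-tally an ECCS that is not identical in length to
            the reference fast path (cached by sequence)."""
            if bases in align_cache:
                obs = align_cache[bases]
            else:
                dummy = _EccsView(bases, kept_family_index="", amp_name=amp.name)
                obs = align_eccs(dummy, amp, min_identity=params.min_identity)
                align_cache[bases] = obs
            if obs is None:
                counters["eccs_unalignable"] += mult
                return
            counters["eccs_used"] += mult
            handle_obs_family(obs, mult)

        for lc in sorted(uniform_groups):
            group = uniform_groups[lc]
            for c0 in range(0, len(group), _CHUNK_FAMILIES):
                chunk = group[c0: c0 + _CHUNK_FAMILIES]
                starts = np.empty(len(chunk), dtype=np.int64)
                rows_flat: list[int] = []
                for fi, (k, rows) in enumerate(chunk):
                    starts[fi] = len(rows_flat)
                    rows_flat.extend(rows)
                blob = "".join(a.seqs[r] for r in rows_flat).encode("ascii")
                mat = ENCODE_LUT[np.frombuffer(blob, dtype=np.uint8)].reshape(
                    len(rows_flat), lc
                )
                codes, support, depth = batch_consensus_codes(
                    mat, starts, min_agreement=min_agreement, min_depth=min_depth
                )
                counters["eccs_built"] += len(chunk)
                nfrac = (codes == CODE_N).mean(axis=1)
                keep = nfrac <= params.max_n_fraction
                counters["eccs_n_filtered"] += int((~keep).sum())
                codes = codes[keep]
                if codes.size == 0:
                    continue
                if lc == L:
                    # fully reference-length consensus: direct tallies,
                    # with the same identity filter align_eccs applies
                    ref_codes = ENCODE_LUT[
                        np.frombuffer(amp.sequence.encode(), np.uint8)
                    ]
                    informative = (codes != CODE_N).sum(axis=1)
                    matching = (codes == ref_codes[None, :]).sum(axis=1)
                    identity_ok = (informative == 0) | (
                        matching / np.maximum(informative, 1)
                        >= params.min_identity
                    )
                    counters["eccs_unalignable"] += int((~identity_ok).sum())
                    codes = codes[identity_ok]
                    if codes.size == 0:
                        continue
                    F = codes.shape[0]
                    counters["eccs_used"] += F
                    for b in range(4):
                        counts4[:, b] += (codes == b).sum(axis=0)
                    n_spanning += F
                    for i, t in amp_targets:
                        _count_target_full_length(
                            codes, t, amp, target_counts[i]
                        )
                else:
                    seen: Counter = Counter(decode(row) for row in codes)
                    for bases, mult in sorted(seen.items()):
                        handle_nonref_eccs(bases, mult)

        for k in generic_keys:
            fam = ReadFamily(
                family_index=k,
                amplicon_name=amp.name,
                members=[
                    (
                        TaggedRead(
                            bases=a.seqs[r], quality_string="", mate=1, index="",
                            family_index=k, amplicon_name=amp.name,
                            anchor=a.sides[r], start=0,
                        ),
                        None,
                    )
                    for r in rows_by_key[k]
                ],
            )
            eccs = build_consensus(
                fam,
                min_agreement=min_agreement,
                min_depth=min_depth,
                max_member_edits=params.max_member_edits,
            )
            counters["eccs_built"] += 1
            counters["family_outlier_reads"] += eccs.outliers
            if not consensus_quality_filter(eccs, params.max_n_fraction):
                counters["eccs_n_filtered"] += 1
                continue
            handle_nonref_eccs(eccs.bases)

        records = wildtype_site_vafs(
            counts4, counts4.sum(axis=1), amp, [t for _, t in amp_targets]
        )
        if len(records):
            all_records.append(records)

    site_records = (
        pd.concat(all_records, ignore_index=True)
        if all_records
        else pd.DataFrame(
            columns=["amplicon", "position", "ref", "alt", "alt_families",
                     "coverage", "vaf"]
        )
    )
    profile = ErrorProfile.from_records(site_records, specificity=params.specificity)
    allele_counts = [target_counts[i] for i in range(len(target_list))]
    variant_calls = call_variants(
        allele_counts,
        profile if len(site_records) else None,
        specificity=params.specificity,
        min_indel_variant_rfs=params.min_indel_variant_rfs,
    )

    calls = pd.DataFrame(
        {
            "label": [c.target.label for c in variant_calls],
            "contig": [c.target.contig for c in variant_calls],
            "position": [c.target.position for c in variant_calls],
            "mut": [c.target.mut for c in variant_calls],
            "variant_RFs": [c.count.variant_rfs for c in variant_calls],
            "reference_RFs": [c.count.reference_rfs for c in variant_calls],
            "other_RFs": [c.count.other_rfs for c in variant_calls],
            "VAF": [c.count.vaf for c in variant_calls],
            "threshold": [c.threshold for c in variant_calls],
            "detected": [c.detected for c in variant_calls],
        }
    )
    hist = pd.DataFrame(
        {
            "size": sorted(hist_counter),
            "n_families": [hist_counter[s] for s in sorted(hist_counter)],
        }
    )

    manifest = RunManifest(
        version=__version__,
        params=asdict(params),
        inputs={str(r1): _md5(r1), str(r2): _md5(r2)},
        counts=counters,
        seed=seed,
    )
    for stage, n in counters.items():
        log.info("%s: %d", stage, n)

    out_path = None
    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        write_calls_table(allele_counts, out_path / "calls.tsv")
        with open(out_path / "calls.json", "w") as fh:
            json.dump(
                [
                    {
                        "label": c.target.label,
                        "contig": c.target.contig,
                        "position": c.target.position,
                        "mut": c.target.mut,
                        "variant_rfs": c.count.variant_rfs,
                        "reference_rfs": c.count.reference_rfs,
                        "other_rfs": c.count.other_rfs,
                        "vaf": c.count.vaf,
                        "threshold": c.threshold,
                        "detected": c.detected,
                    }
                    for c in variant_calls
                ],
                fh,
                indent=2,
            )
        pd.DataFrame(
            [{"class_group": k, "vaf_threshold": v}
             for k, v in sorted(profile.thresholds.items())]
        ).to_csv(out_path / "thresholds.tsv", sep="\t", index=False)
        site_records.to_csv(out_path / "site_vafs.tsv", sep="\t", index=False)
        getattr(profile, "class_histogram", pd.DataFrame()).to_csv(
            out_path / "class_histogram.tsv", sep="\t", index=False
        )
        hist.to_csv(out_path / "family_sizes.tsv", sep="\t", index=False)
        (out_path / "manifest.json").write_text(manifest.to_json())

    return RunResult(
        manifest=manifest,
        calls=calls,
        allele_counts=allele_counts,
        variant_calls=variant_calls,
        profile=profile if len(site_records) else None,
        site_records=site_records,
        family_histogram=hist,
        out_dir=out_path,
    )


class _EccsView:
    """Minimal ECCS stand-in for align_eccs (bases only)."""

    def __init__(self, bases, kept_family_index="", amp_name=""):
        self.bases = bases
        self.family_index = kept_family_index
        self.amplicon_name = amp_name


def _count_target_full_length(
    codes: np.ndarray, target: TargetLocus, amp: AmpliconReference, ac: AlleleCount
) -> None:
    """Vectorized allele counting over reference-length consensus rows."""
    anchor = amp.offset(target.position)
    span = len(target.ref_allele)
    window = codes[:, anchor: anchor + span]
    ref_codes = ENCODE_LUT[np.frombuffer(target.ref_allele.encode(), np.uint8)]
    if target.is_snv:
        alt_code = ENCODE_LUT[ord(target.alt_allele)]
        col = window[:, 0]
        nv = int((col == alt_code).sum())
        nr = int((col == ref_codes[0]).sum())
        ac.variant_rfs += nv
        ac.reference_rfs += nr
        ac.other_rfs += len(col) - nv - nr
    else:
        # a reference-length consensus cannot carry the anchored indel
        is_ref = (window == ref_codes[None, :]).all(axis=1)
        ac.reference_rfs += int(is_ref.sum())
        ac.other_rfs += int((~is_ref).sum())


def compare_raw_vs_corrected(
    r1, r2, amplicons, targets=None, params: PipelineParams | None = None,
    regions=None, out_dir=None,
):
    """Run the pipeline with and without family correction and pair the
    wild-type per-site VAF CDFs (the corrected distribution should dominate
    whenever real error processes are present).  With ``out_dir`` the CDF
    table is written as ``cdf.tsv``."""
    params = params or PipelineParams()
    corrected = run_pipeline(r1, r2, amplicons, targets, params=params,
                             regions=regions)
    raw = run_pipeline(
        r1, r2, amplicons, targets,
        params=replace(params, correction=False), regions=regions,
    )
    cdf = raw_vs_corrected_cdf(
        raw.site_records["vaf"], corrected.site_records["vaf"]
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cdf.to_csv(out / "cdf.tsv", sep="\t", index=False)
    return cdf, corrected, raw


def longitudinal_report(
    call_tables: dict[str, pd.DataFrame],
    metadata: pd.DataFrame,
) -> pd.DataFrame:
    """Time course of VAFs across banked samples of one individual.

    ``call_tables`` maps sample id -> calls table (as written by
    ``run_pipeline``: columns label, contig, position, mut, VAF);
    ``metadata`` has columns ``sample_id`` and ``years_before_diagnosis``.
    Rows are targets, columns samples ordered from the earliest banked
    sample (most years before diagnosis) to the latest; a target missing
    from a timepoint prints NA.
    """
    meta = metadata.sort_values(
        ["years_before_diagnosis", "sample_id"], ascending=[False, True]
    )
    ordered = [s for s in meta["sample_id"] if s in call_tables]
    targets_seen: list[tuple] = []
    for s in ordered:
        for _, row in call_tables[s].iterrows():
            key = (row["label"], row["contig"], row["position"], row["mut"])
            if key not in targets_seen:
                targets_seen.append(key)
    out = {}
    for s in ordered:
        table = call_tables[s]
        cells = []
        for key in targets_seen:
            match = table[
                (table["label"] == key[0])
                & (table["contig"].astype(str) == str(key[1]))
                & (table["position"] == key[2])
            ]
            cells.append(match.iloc[0]["VAF"] if len(match) else "NA")
        out[s] = cells
    idx = pd.MultiIndex.from_tuples(
        targets_seen, names=["label", "contig", "position", "mut"]
    )
    return pd.DataFrame(out, index=idx)
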