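"""Synthetic indexed amplicon libraries with known molecular truth.

The generator emulates the computational substrate of a targeted ECS
experiment: a pool of input molecules (default 2.5 million per library,
matching a typical qPCR-limited loading), each drawing a variant or
reference haplotype per target, tagged with a fresh random 16 bp index on
each adapter, amplified into a read family whose size follows a truncated
Poisson (default mean 8), and sequenced as paired reads with independent
per-base substitution errors (default 0.3%).

Three molecule-level error processes survive consensus correction and give
ECS its residual error floor:

* oxidative damage — guanine converted to 8-oxo-guanine before
  amplification mispairs and yields strand-consistent G>T (or, read from
  the other strand, C>A) families (``oxo_g_rate``, default 1e-5 per G/C
  site, split evenly between the two strand readings);
* cytosine deamination during thermal cycling, the analogous C>T / G>A
  artifact (``deamination_rate``, default 3e-6);
* early-cycle PCR errors inherited by the whole family, uniform across
  substitution classes (``pcr_error``, default 1e-6 per base).

Later-cycle PCR errors are folded into ``per_read_error``.  Sequencing
errors hit the index bases too; a mis-read index founds a spurious small
family that the family-size filter removes.

Determinism: one ``numpy`` Generator seeded from ``config.seed`` drives the
whole library; for each amplicon in order, the *first* draw consumed is the
variant haplotype matrix ``rng.random((n_molecules_on_amplicon, n_targets))
< true_vafs``, so tests can re-draw it independently.  Identical configs
produce byte-identical FASTQ output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._dna import revcomp
from .io import AmpliconReference, TargetLocus, find_amplicon

__all__ = [
    "SimulationConfig",
    "SimulatedLibrary",
    "simulate_library",
    "simulate_dilution_series",
    "random_amplicon",
    "make_benchmark_config",
]

_MUT = {
    ord("A"): b"CGT",
    ord("C"): b"AGT",
    ord("G"): b"ACT",
    ord("T"): b"ACG",
}


@dataclass
class SimulationConfig:
    """Study conditions for one simulated library.

    ``targets`` pairs each queried locus with its true molecular VAF.
    ``family_size_fixed`` overrides the Poisson family-size model with a
    constant (useful for exactness tests); otherwise sizes are
    Poisson(``family_size_mean``) truncated at >= 1 (size-0 families are
    unobservable).
    """

    amplicons: Sequence[AmpliconReference]
    targets: Sequence[tuple[TargetLocus, float]] = ()
    n_molecules: int = 2_500_000
    family_size_mean: float = 8.0
    family_size_fixed: int | None = None
    per_read_error: float = 0.003
    oxo_g_rate: float = 1e-5
    deamination_rate: float = 3e-6
    pcr_error: float = 1e-6
    read_length: int = 150
    index_length: int = 16
    seed: int = 0

    def validate(self) -> None:
        if not self.amplicons:
            raise ValueError("at least one amplicon is required")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if self.family_size_fixed is not None and self.family_size_fixed < 1:
            raise ValueError("family_size_fixed must be >= 1")
        if self.family_size_mean <= 0:
            raise ValueError("family_size_mean must be > 0")
        for name, p in (
            ("per_read_error", self.per_read_error),
            ("oxo_g_rate", self.oxo_g_rate),
            ("deamination_rate", self.deamination_rate),
            ("pcr_error", self.pcr_error),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")
        if self.index_length < 0:
            raise ValueError("index_length must be >= 0")
        if self.read_length <= self.index_length:
            raise ValueError("read_length must exceed index_length")
        for locus, vaf in self.targets:
            if not 0.0 <= vaf <= 1.0:
                raise ValueError(f"true VAF for {locus.label} must be in [0,1]")
            amp = find_amplicon(
                self.amplicons, locus.contig, locus.position, len(locus.ref_allele)
            )
            if amp is None:
                raise ValueError(
                    f"target {locus.label or locus.position} is outside all amplicons"
                )
            off = amp.offset(locus.position)
            if amp.sequence[off: off + len(locus.ref_allele)] != locus.ref_allele:
                raise ValueError(
                    f"target {locus.label}: ref allele does not match amplicon"
                )


@dataclass
class SimulatedLibrary:
    """Paths and bookkeeping for one generated library."""

    name: str
    r1: Path
    r2: Path
    truth: Path
    config: SimulationConfig
    n_molecules: int
    n_read_pairs: int


def random_amplicon(
    name: str,
    length: int = 100,
    contig: str = "sim1",
    start: int = 1000,
    gc: float = 0.5,
    seed: int = 7,
) -> AmpliconReference:
    """A reproducible random amplicon sequence with a stated GC content."""
    rng = np.random.default_rng(seed)
    p_at, p_gc = (1 - gc) / 2, gc / 2
    seq = "".join(rng.choice(list("ACGT"), size=length, p=[p_at, p_gc, p_gc, p_at]))
    return AmpliconReference(name, seq, contig, start, start + length - 1)


def _apply_allele(template: str, offset: int, ref: str, alt: str) -> str:
    assert template[offset: offset + len(ref)] == ref
    return template[:offset] + alt + template[offset + len(ref):]


def _haplotype_templates(amp: AmpliconReference, targets, flags_row) -> str:
    t = amp.sequence
    # apply right-to-left so earlier offsets stay valid
    order = sorted(
        (i for i, on in enumerate(flags_row) if on),
        key=lambda i: -amp.offset(targets[i][0].position),
    )
    for i in order:
        locus = targets[i][0]
        t = _apply_allele(
            t, amp.offset(locus.position), locus.ref_allele, locus.alt_allele
        )
    return t


class _ComboCache:
    """Per-haplotype-combo precomputation: templates, site lists, quality."""

    def __init__(self, amp, targets, cap):
        self.amp = amp
        self.targets = targets
        self.cap = cap
        self._cache = {}

    def get(self, combo: tuple):
        entry = self._cache.get(combo)
        if entry is None:
            tmpl = _haplotype_templates(self.amp, self.targets, combo)
            entry = {
                "template": tmpl,
                "g_sites": np.array([i for i, b in enumerate(tmpl) if b == "G"], int),
                "c_sites": np.array([i for i, b in enumerate(tmpl) if b == "C"], int),
                "length": len(tmpl),
                "s_left": tmpl[: self.cap],
                "s_right": revcomp(tmpl)[: self.cap],
            }
            self._cache[combo] = entry
        return entry


def _draw_family_sizes(rng, config, n):
    if config.family_size_fixed is not None:
        return np.full(n, config.family_size_fixed, dtype=np.int64)
    sizes = rng.poisson(config.family_size_mean, n)
    while True:
        zero = sizes == 0
        if not zero.any():
            return sizes
        sizes[zero] = rng.poisson(config.family_size_mean, int(zero.sum()))


def _index_strings(rng, n, index_length):
    if index_length == 0:
        return [""] * (2 * n)
    codes = rng.integers(0, 4, size=(2 * n, index_length), dtype=np.uint8)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    flat = lut[codes].tobytes().decode("ascii")
    k = index_length
    return [flat[i * k: (i + 1) * k] for i in range(2 * n)]


def _mutate(seq: str, positions, shifts) -> str:
    ba = bytearray(seq, "ascii")
    for p, s in zip(positions, shifts):
        ba[p] = _MUT[ba[p]][s]
    return ba.decode("ascii")


def simulate_library(
    config: SimulationConfig, out_dir, name: str = "library"
) -> SimulatedLibrary:
    """Generate one library: paired FASTQ plus a molecular truth table.

    The truth table (TSV) has one row per molecule: its amplicon, the
    orientation-normalized family index key, orientation, read-pair count
    and one 0/1 column per target haplotype.  The number of FASTQ read
    pairs equals the sum of the truth table's family sizes.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    r1_path = out_dir / f"{name}_R1.fastq"
    r2_path = out_dir / f"{name}_R2.fastq"
    truth_path = out_dir / f"{name}_truth.tsv"

    cap = config.read_length - config.index_length
    quals: dict[int, str] = {}
    n_amp = len(config.amplicons)
    base, rem = divmod(config.n_molecules, n_amp)
    truth_rows = []
    total_pairs = 0
    mol_id = 0

    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        buf1: list[str] = []
        buf2: list[str] = []
        for ai, amp in enumerate(config.amplicons):
            n = base + (1 if ai < rem else 0)
            if n == 0:
                continue
            targets = [
                (t, v)
                for t, v in config.targets
                if amp.contains(t.contig, t.position, len(t.ref_allele))
            ]
            T = len(targets)
            vafs = np.array([v for _, v in targets], dtype=float)

            # documented draw order: haplotype flags first, per amplicon
            flags = (
                rng.random((n, T)) < vafs[None, :]
                if T
                else np.zeros((n, 0), dtype=bool)
            )
            reverse = rng.random(n) < 0.5
            sizes = _draw_family_sizes(rng, config, n)
            idx = _index_strings(rng, n, config.index_length)
            cache = _ComboCache(amp, targets, cap)

            lengths = np.empty(n, dtype=np.int64)
            combos = [tuple(bool(x) for x in flags[i]) for i in range(n)]
            for i in range(n):
                lengths[i] = cache.get(combos[i])["length"]
            ng = np.array([len(cache.get(c)["g_sites"]) for c in combos])
            nc = np.array([len(cache.get(c)["c_sites"]) for c in combos])

            # molecule-level damage, inherited by every read of the family
            k_oxo_g = rng.binomial(ng, config.oxo_g_rate / 2)
            k_oxo_c = rng.binomial(nc, config.oxo_g_rate / 2)
            k_deam_c = rng.binomial(nc, config.deamination_rate / 2)
            k_deam_g = rng.binomial(ng, config.deamination_rate / 2)
            k_pcr = rng.binomial(lengths, config.pcr_error)

            for i in range(n):
                entry = cache.get(combos[i])
                tmpl = entry["template"]
                changes: dict[int, str] = {}
                for k, sites, new in (
                    (k_oxo_g[i], entry["g_sites"], "T"),
                    (k_oxo_c[i], entry["c_sites"], "A"),
                    (k_deam_c[i], entry["c_sites"], "T"),
                    (k_deam_g[i], entry["g_sites"], "A"),
                ):
                    if k:
                        for p in rng.choice(sites, size=min(k, len(sites)),
                                            replace=False):
                            changes[int(p)] = new
                if k_pcr[i]:
                    draws = rng.integers(0, 3 * len(tmpl), size=k_pcr[i])
                    for d in draws:
                        p, s = int(d) // 3, int(d) % 3
                        changes[p] = chr(_MUT[ord(tmpl[p])][s])
                if changes:
                    ba = bytearray(tmpl, "ascii")
                    for p, b in changes.items():
                        ba[p] = ord(b)
                    tmpl = ba.decode("ascii")
                    s_left = tmpl[:cap]
                    s_right = revcomp(tmpl)[:cap]
                else:
                    s_left = entry["s_left"]
                    s_right = entry["s_right"]
                idx1, idx2 = idx[2 * i], idx[2 * i + 1]
                if reverse[i]:
                    m1, m2 = s_right, s_left
                    key = idx2 + idx1
                else:
                    m1, m2 = s_left, s_right
                    key = idx1 + idx2
                r1_full = idx1 + m1
                r2_full = idx2 + m2
                l1, l2 = len(r1_full), len(r2_full)
                for l in (l1, l2):
                    if l not in quals:
                        quals[l] = "I" * l
                size = int(sizes[i])
                errc = rng.binomial(l1, config.per_read_error, size=2 * size)
                for j in range(size):
                    rd1, rd2 = r1_full, r2_full
                    k1, k2 = int(errc[2 * j]), int(errc[2 * j + 1])
                    if k1:
                        d = rng.integers(0, 3 * l1, size=k1)
                        rd1 = _mutate(r1_full, d // 3, d % 3)
                    if k2:
                        d = rng.integers(0, 3 * l2, size=k2)
                        rd2 = _mutate(r2_full, d // 3, d % 3)
                    rname = f"{amp.name}.{mol_id}.{j}"
                    buf1.append(f"@{rname}\n{rd1}\n+\n{quals[l1]}\n")
                    buf2.append(f"@{rname}\n{rd2}\n+\n{quals[l2]}\n")
                total_pairs += size
                truth_rows.append(
                    (mol_id, amp.name, key, "reverse" if reverse[i] else "forward",
                     size, *(int(x) for x in flags[i]))
                )
                mol_id += 1
                if len(buf1) >= 100_000:
                    f1.write("".join(buf1))
                    f2.write("".join(buf2))
                    buf1.clear()
                    buf2.clear()
        f1.write("".join(buf1))
        f2.write("".join(buf2))

    target_cols = []
    seen = {}
    for t, _ in config.targets:
        label = t.label or f"{t.contig}:{t.position}"
        seen[label] = seen.get(label, 0) + 1
        target_cols.append(f"variant_{label}" if seen[label] == 1
                           else f"variant_{label}.{seen[label]}")
    truth = pd.DataFrame(
        truth_rows,
        columns=["molecule", "amplicon", "family_index", "orientation",
                 "n_read_pairs", *target_cols],
    )
    truth.to_csv(truth_path, sep="\t", index=False)
    return SimulatedLibrary(
        name=name,
        r1=r1_path,
        r2=r2_path,
        truth=truth_path,
        config=config,
        n_molecules=config.n_molecules,
        n_read_pairs=total_pairs,
    )


def simulate_dilution_series(
    base_config: SimulationConfig,
    dilutions: Sequence[float],
    replicates: int = 2,
    out_dir="dilution_series",
    tumor_vaf: float = 0.5,
) -> tuple[list[SimulatedLibrary], pd.DataFrame]:
    """The spike-in benchmark: tumor DNA serially diluted into normal DNA.

    One library per (dilution, replicate); each target's true VAF becomes
    ``tumor_vaf * dilution`` (a heterozygous clonal mutation in the
    undiluted tumor has VAF 0.5).  Per-library seeds are spawned from
    ``base_config.seed`` so libraries are independent but reproducible.
    Writes a design table pairing each library with its expected VAF.
    """
    if len(dilutions) == 0:
        raise ValueError("dilution list must not be empty")
    for d in dilutions:
        if not 0 < d <= 1:
            raise ValueError(f"dilutions must be in (0, 1], got {d}")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    children = np.random.SeedSequence(base_config.seed).spawn(
        len(dilutions) * replicates
    )
    libraries = []
    rows = []
    k = 0
    for d in dilutions:
        for rep in range(1, replicates + 1):
            seed = int(children[k].generate_state(1)[0] & 0x7FFFFFFF)
            k += 1
            cfg = replace(
                base_config,
                targets=[(t, tumor_vaf * d) for t, _ in base_config.targets],
                seed=seed,
            )
            lib_name = f"dil{d:g}_rep{rep}"
            lib = simulate_library(cfg, out_dir, name=lib_name)
            libraries.append(lib)
            rows.append(
                {
                    "library": lib_name,
                    "dilution": d,
                    "replicate": rep,
                    "expected_vaf": tumor_vaf * d,
                    "seed": seed,
                    "r1": str(lib.r1),
                    "r2": str(lib.r2),
                    "truth": str(lib.truth),
                }
            )
    design = pd.DataFrame(rows)
    design.to_csv(out_dir / "design.tsv", sep="\t", index=False)
    return libraries, design


def make_benchmark_config(
    n_molecules: int = 2_500_000,
    amplicon_length: int = 100,
    true_vaf: float = 0.5,
    seed: int = 0,
    **overrides,
) -> SimulationConfig:
    """Default single-amplicon benchmark: one clonal SNV mid-amplicon.

    The amplicon sequence is a fixed random 100-mer; the target converts
    the reference base at its midpoint to a different base (a C>G-style
    substitution when possible, avoiding the damage-prone G>T class so the
    dilution series probes counting, not the residual damage floor).
    """
    amp = random_amplicon("amp1", length=amplicon_length)
    off = amplicon_length // 2
    ref_base = amp.sequence[off]
    alt_base = {"A": "G", "C": "G", "G": "C", "T": "C"}[ref_base]
    locus = TargetLocus(
        contig=amp.contig,
        position=amp.start + off,
        ref_allele=ref_base,
        alt_allele=alt_base,
        label="benchmark_snv",
    )
    return SimulationConfig(
        amplicons=[amp],
        targets=[(locus, true_vaf)],
        n_molecules=n_molecules,
        seed=seed,
        **overrides,
    )
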