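# ecseq — targeted error-corrected sequencing

`ecseq` implements error-corrected sequencing (ECS) for quantifying
ultra-rare variants — rare leukemic subclones, minimal residual disease,
pre-leukemic clonal hematopoiesis — from targeted amplicon libraries in
which every input DNA molecule was tagged with a random 16 bp
oligonucleotide index on each adapter before amplification.

Conventional deep sequencing cannot see below a variant allele fraction
(VAF) of ~1–2% because its own substitution error rate is of that order.
ECS defeats this statistically: reads sharing an index descend from one
molecule, so they are grouped into **read families** and compared;
positions where family members disagree are sequencing errors and are
removed, yielding one **error-corrected consensus sequence (ECCS)** per
molecule.  Each consensus is aligned to its amplicon and, per target
locus,

```
VAF = variant read families / (variant read families + reference read families)
```

— a digital count of molecules, quantitative down to ~1 in 10⁴.  The
residual (consensus-surviving) error floor is dominated by molecule-level
damage and is strongly substitution-class biased (G>T/C>A from
8-oxo-guanine, then C>T/G>A), so detection thresholds are estimated per
class from the wild-type positions of the same run.

The package contains the full computational pipeline (index extraction,
amplicon assignment, family grouping, consensus, alignment/counting,
error-profile thresholds, longitudinal reporting), a thin `ecs` CLI, and
a simulator with known molecular truth that reproduces the spike-in
dilution-series benchmark.  See `docs/methods.md` for the model and all
tunables.

## Worked example

```python
import tempfile
from ecseq import make_benchmark_config, simulate_library, run_pipeline

cfg = make_benchmark_config(n_molecules=20_000, true_vaf=0.05, seed=42)
with tempfile.TemporaryDirectory() as work:
    lib = simulate_library(cfg, work)
    result = run_pipeline(lib.r1, lib.r2, cfg.amplicons,
                          [t for t, _ in cfg.targets], out_dir=f"{work}/out")
print(result.calls[["label", "mut", "variant_RFs", "reference_RFs",
                    "VAF", "detected"]].to_string(index=False))
```

prints

```
        label    mut  variant_RFs  reference_RFs      VAF  detected
benchmark_snv C to G          965          18512 0.049546      True
```

965 of 19 477 countable read families carry the variant: the molecule-level
estimate 0.0495 sits within binomial noise of the simulated truth (0.05),
and `detected` means the VAF exceeds the run's own 99%-specificity
wild-type threshold for the C>G substitution class.  The run directory
receives the calls table (TSV mirroring the per-target family counts),
a per-target JSON with thresholds and decisions, per-class threshold and
site-VAF reports, the family-size histogram and a run manifest with
stage-by-stage conservation counts.

The `examples/` directory holds one short narrative script per
capability: single-library calling, the five-decade dilution-series
benchmark (prints `r^2 = 0.99980` at 25 000 molecules/library), the
raw-vs-corrected error profile with per-class thresholds, and the
longitudinal per-patient report (a clone tracked at VAF 0.0042 → 0.0298 →
0.0897 across three yearly banked samples).

Command-line equivalents:

```bash
ecs simulate --out sim --n-molecules 20000 --true-vaf 0.05 --seed 42
ecs call --r1 sim/library_R1.fastq --r2 sim/library_R2.fastq \
         --amplicons amps.fa --regions amps.bed --targets targets.tsv --out run
ecs profile --calls run --specificity 0.99
ecs report --calls y5=run5/calls.tsv --calls y4=run4/calls.tsv --metadata meta.tsv
```

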