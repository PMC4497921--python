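# Methods

## The problem

Conventional deep sequencing cannot quantify variants much below a variant
allele fraction (VAF) of ~1–2%: the substitution error rate of the
sequencing process itself (~0.1–1% per base) drowns the signal.  Targeted
error-corrected sequencing (ECS) circumvents this by tagging every input
DNA molecule with a random oligonucleotide index (16 bp per adapter)
before amplification.  All reads descending from one molecule share that
index; comparing them identifies and removes sequencing errors, because a
true variant is present in every read of the family while an error is
private to one or a few reads.  The corrected unit of evidence is the read
family, and

```
VAF = variant read families / (variant + reference read families)
```

is a digital molecule count, not a read count.  The main clinical use case
is quantifying rare leukemic subclones — e.g. minimal residual disease or
pre-leukemic clonal hematopoiesis — from banked blood and bone marrow at
VAFs down to ~1e-4.

## Pipeline

1. **Index extraction** (`umi`).  The first `index_length` (16) bases of
   each mate are removed and recorded.  Pairs whose remaining template is
   shorter than `min_insert` (30 nt) are rejected as `too_short`.
2. **Amplicon assignment** (`umi`).  Each template start is compared with
   the `anchor_k` = 20-mer at either end of every amplicon (exact hash
   first, then edit distance ≤ `anchor_max_edits` = 2).  The mate matching
   the 5′ end is the "left" mate; the mate matching the reverse complement
   of the 3′ end is the "right" mate.  No match → `unassigned`; ties →
   `ambiguous`.  The family key is the ordered concatenation
   left-index + right-index, so a molecule sequenced in either orientation
   founds exactly one family.  Indexes are matched exactly by default; an
   optional directional collapse (merge into a 1-mismatch neighbour with
   ≥10× the read count) is available but off, since exact matching plus
   the family-size filter already absorbs index sequencing errors (a
   mis-read index founds a spurious family of size ~1).
3. **Family grouping** (`families`).  Reads are partitioned by
   (amplicon, family key).  Families smaller than `min_family_size` = 3
   read pairs are dropped: three observations is the smallest family in
   which a true base can outvote one errored read.
4. **Consensus** (`consensus`).  Per column, the modal base is kept when
   depth ≥ `min_depth` (3) and the modal fraction ≥ `min_agreement` (0.9);
   otherwise the column is masked to `N`.  Masking removes the error while
   preserving the family's evidence at other positions; families with more
   than `max_n_fraction` (20%) masked are dropped entirely.  Both mates of
   a pair vote independently (`depth` is bounded by reads, not pairs; the
   double-counting within a fragment is deliberate and documented).
   Columns live in the family's own template coordinates (the modal read
   length): left-anchored reads vote from column 0, right-anchored reads
   vote end-anchored, so substitution-only errors never shift the frame.
   A member whose length deviates from the family template and differs
   from a template-length exemplar by more than `max_member_edits` (5)
   edits is excluded as an outlier (chimera/artifact); true indel
   molecules are internally concordant and simply produce a shorter or
   longer template.  Base qualities are ignored: the vote is a pure read
   count.
5. **Alignment and counting** (`calling`).  Each kept consensus is
   globally aligned to its amplicon (edit distance; a length-matched
   consensus needs no alignment at all).  Gaps are left-normalized so an
   indel in a homopolymer has one canonical position; alignments with
   identity < `min_identity` (80%, over non-N bases) are discarded as
   unalignable.  At each target, a family counts as variant only on the
   exact anchored replacement (partial or extended indels count as
   "other"), as reference on the exact reference allele, and as "other"
   otherwise (including `N` at the locus).  "Other" families never enter
   the VAF denominator.
6. **Error profile** (`errorprofile`).  At every wild-type position
   (targets excluded) and every alt base, the per-site VAF is
   alt families / covering families.  The specificity threshold at level
   *s* is the empirical quantile `quantile(vafs, s, method="higher")` of
   these records: calling only above it is (1−s)-false-positive on the
   wild-type distribution by construction.  Thresholds are computed
   globally and for three substitution-class groups — G>T(C>A) (the
   8-oxo-guanine oxidative-damage class), C>T(G>A) (deamination-type),
   and the other eight substitutions — because molecule-level damage
   survives consensus and is heavily class-biased.  SNV detection compares
   the VAF against its class threshold; indels are instead detected from a
   minimum variant-family count (default 3), as indel-generating errors
   are rare and a substitution-derived threshold would be meaningless for
   them.

## Simulator

`simulate` generates libraries with known molecular truth.  Defaults are
the study conditions: 2.5 million indexed molecules per library, family
sizes Poisson(8) truncated at ≥1 (the qPCR loading step ensures coverage
per family; the true distribution is unpublished, so the mean is a stated
choice), 150 bp reads with 16 bp indexes per mate, and a per-read
substitution error of 0.003.

Residual (consensus-surviving) errors are modeled at the molecule level:

* `oxo_g_rate` (1e-5): 8-oxo-guanine conversion before amplification,
  producing strand-consistent G>T families (or C>A read from the other
  strand; the rate is split evenly between strand readings).
* `deamination_rate` (3e-6): cytosine deamination during thermal cycling,
  the analogous C>T/G>A artifact.  This knob exists so the simulator can
  reproduce the observed three-tier class bias
  (G>T(C>A) > C>T(G>A) > other); a uniform error model cannot produce the
  middle tier.
* `pcr_error` (1e-6): early-cycle polymerase errors inherited by the whole
  family, uniform across classes — the worst case for consensus
  correction, and the mechanism for the class-independent residual floor.

Later-cycle PCR errors are statistically indistinguishable from sequencing
errors and are folded into `per_read_error`.  Sequencing errors also hit
index bases, founding spurious small families exactly as in real data.
Molecule orientation is Bernoulli(1/2), exercising the orientation
normalization of the family key.

The dilution-series benchmark spikes a clonal heterozygous SNV
(tumor VAF 0.5) into normal DNA over five decades (1e-1 .. 1e-5), two
replicates per dilution.  The benchmark target is deliberately not a G>T
substitution so that the series probes molecule counting rather than the
oxidative residual floor.

What the simulator does **not** emulate: coverage non-uniformity and
fragmentation, quality-score structure (flat Phred 40), FFPE deamination
of old samples, polymerase slippage indel errors within reads, and sample
cross-contamination.  Tests passing on these simulations therefore
demonstrate the correctness of the counting machinery and the qualitative
structure of the residual error profile — not the numeric thresholds of
any particular instrument, which must be re-estimated from each
experiment's own wild-type sites.

## Numerical choices

* Voting uses exact integer counts; the agreement comparison is
  `support/depth >= min_agreement`, so a 9/10 column at threshold 0.9 is
  kept.  A tie for the modal base is masked to `N` (no strict winner).
* VAF printing rounds half-up to 4 decimals and trims trailing zeros
  ("0", "0.034"), distinguishing `NA` (no covered families) from `0`
  (covered, no variant families).
* The specificity quantile is the `method="higher"` order statistic;
  fewer than 100 records cannot resolve a 99% quantile and fall back to
  the maximum observed VAF, with a warning.
* Gap left-normalization follows VCF convention (shift while the flanking
  base matches), applied both to target alleles at parse time and to
  consensus alignments.
* All randomness flows from one `numpy` Generator per library seed; the
  first draw is the haplotype matrix, which is documented so tests can
  re-draw it independently.  Identical configs give byte-identical FASTQ.
* The pipeline engine vectorizes consensus for families whose members
  share one template length (the overwhelming majority) and routes mixed-
  length families through the per-family path; the two paths implement
  the identical rule and the test suite asserts their equivalence
  end-to-end.  Reads are assumed to span their amplicon (template ≈
  amplicon length); partial-coverage tiling designs are out of scope.

## Problem sizes used in the checks

The distributed checks run scaled-down versions of the benchmark, chosen
as the package's own test sizes: the in-suite dilution series uses
2.5×10⁴ molecules per library (r² ≥ 0.995), and `scripts/acceptance.py`
uses 2.5×10⁵ per library (ten libraries).  At these loadings the binomial
counting noise at the top dilution is already far below the linearity
tolerance, so the conclusion is insensitive to further scale-up; the
`--n-molecules` flag reproduces the full 2.5×10⁶ loading when desired.
Parameter recovery is checked at true VAF 1e-3 with ~120 expected variant
families per replicate, 20 seeded replicates, against the exact binomial
99% interval.

## Known limitations

* Single-strand families only: without duplex (both-strand) pairing, a
  molecule damaged before amplification is indistinguishable from a true
  variant — hence the class-biased residual floor and the per-class
  thresholds.  Duplex consensus is explicitly out of scope.
* The detection rule (class threshold for SNVs, minimum family count for
  indels) is this package's operationalization; reported specificity is
  with respect to the empirical wild-type distribution of the same run.
* Overlapping mates double-count one physical fragment in `depth`; with
  `min_family_size` = 3 pairs this never changes a call, but `depth`
  should not be read as an independent-molecule count.
* Amplicons must not overlap; loci covered by two amplicons are rejected
  at load time.
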