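"""Shared helpers for building tiny FASTQ fixtures programmatically."""

from ecseq._dna import revcomp
from ecseq.io import FastqRead


def write_fastq(path, records):
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual or 'I' * len(seq)}\n")
    return path


def molecule_pair(amp, idx1="A" * 16, idx2="C" * 16, reverse=False, name="m0",
                  template=None):
    """A perfect read pair for one molecule of an amplicon.

    Forward molecules read the amplicon 5' end on mate 1; reverse molecules
    read it on mate 2.  ``template`` overrides the molecule sequence (e.g.
    to inject variants or errors).
    """
    t = template if template is not None else amp.sequence
    left, right = idx1 + t, idx2 + revcomp(t)
    if reverse:
        left, right = idx2 + revcomp(t), idx1 + t
    return (
        FastqRead(name, left, "I" * len(left)),
        FastqRead(name, right, "I" * len(right)),
    )


def mutate_str(s, pos, base):
    return s[:pos] + base + s[pos + 1:]
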