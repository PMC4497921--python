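import numpy as np
import pytest

from ecseq.calling import (AlleleCount, align_eccs, call_variants,
                           classify_observation, count_alleles,
                           left_normalize_gaps)
from ecseq.consensus import ConsensusSequence
from ecseq.errorprofile import ErrorProfile
from ecseq.io import AmpliconReference, TargetLocus


def _eccs(bases, amp="amp1"):
    n = len(bases)
    return ConsensusSequence(
        family_index="K", amplicon_name=amp, bases=bases,
        support=np.full(n, 5), depth=np.full(n, 5), family_size=5, n_reads=5,
    )


class TestAlignEccs:
    def test_identical_sequence_reports_reference_everywhere(self, amplicon):
        obs = align_eccs(_eccs(amplicon.sequence), amplicon)
        assert obs == list(amplicon.sequence)

    def test_single_substitution_observed_at_its_offset(self, amplicon):
        seq = list(amplicon.sequence)
        seq[40] = "T" if seq[40] != "T" else "A"
        obs = align_eccs(_eccs("".join(seq)), amplicon)
        assert obs[40] == seq[40]
        assert obs[:40] == list(amplicon.sequence[:40])

    def test_deletion_recorded_as_gap_with_flanks_intact(self):
        amp = AmpliconReference("a", "GATTACACAGTGATTACACAGTGATTACAC", "1", 1, 30)
        query = amp.sequence[:10] + amp.sequence[11:]
        obs = align_eccs(_eccs(query), amp)
        gaps = [i for i, o in enumerate(obs) if o == "-"]
        assert len(gaps) == 1
        # independent oracle: leftmost single-base deletion reproducing query
        candidates = [
            i for i in range(30)
            if amp.sequence[:i] + amp.sequence[i + 1:] == query
        ]
        assert gaps[0] == min(candidates)
        for i, o in enumerate(obs):
            if o != "-":
                assert o == amp.sequence[i]

    def test_homopolymer_deletion_is_left_normalized(self):
        amp = AmpliconReference("a", "GGTCAAAATCGGTCAAAATCGGTCAAAATC", "1", 1, 30)
        # delete the *last* A of the second AAAA run (offset 17)
        query = amp.sequence[:17] + amp.sequence[18:]
        obs = align_eccs(_eccs(query), amp)
        gaps = [i for i, o in enumerate(obs) if o == "-"]
        candidates = [
            i for i in range(30)
            if amp.sequence[:i] + amp.sequence[i + 1:] == query
        ]
        assert gaps == [min(candidates)]

    def test_insertion_rides_on_left_anchor(self):
        amp = AmpliconReference("a", "GATTACACAGTGATTACACAGTGATTACAC", "1", 1, 30)
        query = amp.sequence[:12] + "TT" + amp.sequence[12:]
        obs = align_eccs(_eccs(query), amp)
        assert obs[11] == amp.sequence[11] + "TT"
        assert obs[12] == amp.sequence[12]

    def test_unalignable_junk_discarded(self, amplicon):
        obs = align_eccs(_eccs("T" * 60), amplicon)
        assert obs is None

    def test_missing_prefix_is_uncovered_not_deleted(self, amplicon):
        obs = align_eccs(_eccs(amplicon.sequence[10:]), amplicon)
        assert obs[:10] == [None] * 10
        assert obs[10:] == list(amplicon.sequence[10:])

    def test_gap_shift_helper_canonicalizes(self):
        q, t = left_normalize_gaps("AA-G", "AAAG")
        assert (q, t) == ("-AAG", "AAAG")


class TestCountAlleles:
    def _target(self, amp, off, alt=None):
        ref = amp.sequence[off]
        alt = alt or {"A": "G", "C": "G", "G": "C", "T": "C"}[ref]
        return TargetLocus(amp.contig, amp.start + off, ref, alt, "t")

    def test_each_family_contributes_exactly_once(self, amplicon):
        t = self._target(amplicon, 50)
        ref_obs = list(amplicon.sequence)
        var_obs = ref_obs.copy()
        var_obs[50] = t.alt_allele
        n_obs = ref_obs.copy()
        n_obs[50] = "N"
        third = ref_obs.copy()
        third[50] = next(b for b in "ACGT" if b not in (t.ref_allele, t.alt_allele))
        uncovered = ref_obs.copy()
        uncovered[50] = None
        obs = [var_obs] * 3 + [ref_obs] * 2 + [n_obs, third, uncovered]
        ac = count_alleles(obs, t, amplicon)
        assert (ac.variant_rfs, ac.reference_rfs, ac.other_rfs) == (3, 2, 2)
        assert ac.vaf == 3 / 5

    def test_zero_coverage_vaf_undefined(self, amplicon):
        ac = count_alleles([], self._target(amplicon, 50), amplicon)
        assert ac.vaf is None

    def test_vaf_formula_on_reported_count_scale(self, amplicon):
        """VAF = variant / (variant + reference) on large family counts."""
        t = self._target(amplicon, 50)
        ac = AlleleCount(target=t, variant_rfs=61238, reference_rfs=156986)
        assert round(ac.vaf, 4) == 0.2806
        ac2 = AlleleCount(target=t, variant_rfs=220551, reference_rfs=110047)
        assert round(ac2.vaf, 4) == 0.6671
        ac3 = AlleleCount(target=t, variant_rfs=0, reference_rfs=4187)
        assert ac3.vaf == 0.0

    def test_target_outside_amplicon_is_configuration_error(self, amplicon):
        far = TargetLocus("other", 5, "A", "C", "x")
        with pytest.raises(ValueError, match="not covered"):
            count_alleles([], far, amplicon)

    def test_anchored_deletion_matching_is_exact(self):
        amp = AmpliconReference("a", "GATTACACAGTGATTACACAGTGATTACAC", "1", 1, 30)
        # del AC at offsets 6-7, anchored on the C at offset 5 (position 6)
        t = TargetLocus("1", 6, "CAC", "C", "del")
        var = list(amp.sequence)
        var[6] = var[7] = "-"
        partial = list(amp.sequence)
        partial[6] = "-"
        longer = list(amp.sequence)
        longer[6] = longer[7] = longer[8] = "-"
        ref_obs = list(amp.sequence)
        counts = count_alleles([var, partial, longer, ref_obs], t, amp)
        assert (counts.variant_rfs, counts.reference_rfs, counts.other_rfs) == (1, 1, 2)

    def test_insertion_matching_requires_exact_inserted_bases(self):
        amp = AmpliconReference("a", "GATTACACAGTGATTACACAGTGATTACAC", "1", 1, 30)
        t = TargetLocus("1", 12, amp.sequence[11], amp.sequence[11] + "TT", "ins")
        var = list(amp.sequence)
        var[11] = amp.sequence[11] + "TT"
        wrong = list(amp.sequence)
        wrong[11] = amp.sequence[11] + "TG"
        counts = count_alleles([var, wrong, list(amp.sequence)], t, amp)
        assert (counts.variant_rfs, counts.reference_rfs, counts.other_rfs) == (1, 1, 1)


class TestDetection:
    def _profile(self):
        return ErrorProfile(
            records=None,
            specificity=0.99,
            thresholds={
                "G>T(C>A)": 0.0034,
                "C>T(G>A)": 0.0002,
                "other": 0.000079,
                "global": 0.0016,
            },
        )

    def test_rare_substitution_above_class_threshold_detected(self):
        t = TargetLocus("20", 31023112, "T", "G", "L866*")
        ac = AlleleCount(target=t, variant_rfs=3583, reference_rfs=853598)
        (call,) = call_variants([ac], self._profile())
        assert call.threshold == pytest.approx(0.000079)
        assert round(ac.vaf, 4) == 0.0042 and call.detected

    def test_damage_class_uses_its_own_higher_threshold(self):
        t = TargetLocus("21", 44524456, "G", "T", "S34Y")
        ac = AlleleCount(target=t, variant_rfs=85, reference_rfs=414613)
        (call,) = call_variants([ac], self._profile())
        assert call.threshold == pytest.approx(0.0034)
        assert round(ac.vaf, 4) == 0.0002 and not call.detected

    def test_zero_vaf_never_detected(self):
        t = TargetLocus("1", 153517192, "A", "G", "F27L")
        ac = AlleleCount(target=t, variant_rfs=0, reference_rfs=211512)
        (call,) = call_variants([ac], self._profile())
        assert not call.detected

    def test_indel_detection_by_minimum_family_count(self):
        t = TargetLocus("20", 31022441, "CG", "C", "G645fs")
        hit = AlleleCount(target=t, variant_rfs=3, reference_rfs=100)
        miss = AlleleCount(target=t, variant_rfs=2, reference_rfs=100)
        calls = call_variants([hit, miss], self._profile(),
                              min_indel_variant_rfs=3)
        assert [c.detected for c in calls] == [True, False]

    def test_missing_profile_warns_and_does_not_detect(self):
        t = TargetLocus("1", 10, "A", "G", "x")
        ac = AlleleCount(target=t, variant_rfs=50, reference_rfs=100)
        with pytest.warns(UserWarning):
            (call,) = call_variants([ac], None)
        assert not call.detected
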