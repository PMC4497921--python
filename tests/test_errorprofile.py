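import math

import numpy as np
import pandas as pd
import pytest

from ecseq.errorprofile import (GROUP_CT_GA, GROUP_GT_CA, GROUP_OTHER,
                                SUBSTITUTIONS, ErrorProfile, class_group,
                                class_profile, collapsed_class,
                                raw_vs_corrected_cdf,
                                reverse_complement_substitution,
                                specificity_threshold, wildtype_site_vafs)
from ecseq.io import AmpliconReference, TargetLocus


class TestSubstitutionClasses:
    def test_twelve_raw_classes(self):
        assert len(SUBSTITUTIONS) == 12

    def test_reverse_complement_is_involution(self):
        for r, a in SUBSTITUTIONS:
            assert reverse_complement_substitution(
                *reverse_complement_substitution(r, a)
            ) == (r, a)

    def test_collapse_merges_to_six_classes(self):
        labels = {collapsed_class(r, a) for r, a in SUBSTITUTIONS}
        assert len(labels) == 6
        assert collapsed_class("G", "T") == collapsed_class("C", "A")

    def test_group_partition_sizes(self):
        groups = [class_group(r, a) for r, a in SUBSTITUTIONS]
        assert groups.count(GROUP_GT_CA) == 2
        assert groups.count(GROUP_CT_GA) == 2
        assert groups.count(GROUP_OTHER) == 8


class TestSpecificityThreshold:
    def test_all_zero_records_give_zero_threshold(self):
        assert specificity_threshold([0.0] * 200, 0.99) == 0.0

    def test_single_outlier_sets_threshold(self):
        vafs = [0.0] * 99 + [0.5]
        assert specificity_threshold(vafs, 0.99) == 0.5

    def test_few_records_warn_and_return_max(self):
        with pytest.warns(UserWarning, match="records"):
            assert specificity_threshold([0.0, 0.1], 0.99) == 0.1

    def test_monotone_in_specificity(self):
        rng = np.random.default_rng(0)
        vafs = rng.beta(0.1, 50, size=5000)
        qs = [specificity_threshold(vafs, s) for s in (0.95, 0.99, 0.999)]
        assert qs[0] <= qs[1] <= qs[2]

    def test_matches_sort_based_oracle(self):
        rng = np.random.default_rng(1)
        vafs = np.round(rng.beta(0.2, 100, size=10_000), 5)
        for s in (0.9, 0.99, 0.995):
            v = np.sort(vafs)
            oracle = v[math.ceil(s * (len(v) - 1))]
            assert specificity_threshold(vafs, s) == pytest.approx(oracle)

    def test_empty_records_error(self):
        with pytest.raises(ValueError):
            specificity_threshold([])


class TestWildtypeSites:
    def test_records_and_target_exclusion(self):
        amp = AmpliconReference("a", "GATTG", "1", 100, 104)
        counts = np.zeros((5, 4), dtype=int)
        cov = np.array([1000, 1000, 1000, 0, 500])
        counts[0] = [0, 0, 998, 2]    # ref G: 2 T families -> vaf 0.002
        counts[1] = [1000, 0, 0, 0]
        counts[2] = [0, 0, 0, 1000]
        counts[4] = [0, 0, 500, 0]
        target = TargetLocus("1", 101, "A", "C", "t")
        rec = wildtype_site_vafs(counts, cov, amp, [target])
        assert (rec.position == 101).sum() == 0      # target excluded
        assert (rec.position == 103).sum() == 0      # zero coverage omitted
        gt = rec[(rec.position == 100) & (rec.alt == "T")]
        assert gt.iloc[0]["vaf"] == pytest.approx(0.002)
        # every covered non-target position emits 3 records
        assert len(rec) == 3 * 3


class TestClassProfile:
    def _records(self, triples):
        rows = [
            {"amplicon": "a", "position": i, "ref": r, "alt": a,
             "alt_families": int(v * 1000), "coverage": 1000, "vaf": v}
            for i, (r, a, v) in enumerate(triples)
        ]
        return pd.DataFrame(rows)

    def test_damage_class_threshold_exceeds_quiet_classes(self):
        triples = [("G", "T", 0.01)] * 50 + [("C", "A", 0.008)] * 50
        triples += [("A", "C", 0.0)] * 200 + [("T", "G", 0.0)] * 200
        thresholds, hist = class_profile(self._records(triples))
        assert thresholds[GROUP_GT_CA] > thresholds[GROUP_OTHER]

    def test_reverse_complementing_preserves_collapsed_counts(self):
        rng = np.random.default_rng(2)
        triples = [
            (r, a, float(v))
            for (r, a), v in zip(
                [SUBSTITUTIONS[i] for i in rng.integers(0, 12, 300)],
                rng.random(300) / 100,
            )
        ]
        _, hist = class_profile(self._records(triples))
        flipped = [
            (*reverse_complement_substitution(r, a), v) for r, a, v in triples
        ]
        _, hist_rc = class_profile(self._records(flipped))
        a = hist.set_index("collapsed")["records"].to_dict()
        b = hist_rc.set_index("collapsed")["records"].to_dict()
        assert a == b

    def test_strand_collapse_conserves_total_counts(self):
        triples = [("G", "T", 0.01), ("C", "A", 0.01), ("A", "G", 0.0)]
        _, hist = class_profile(self._records(triples))
        assert hist["records"].sum() == len(triples)

    def test_empty_group_warns_and_is_none(self):
        triples = [("G", "T", 0.0)] * 120
        with pytest.warns(UserWarning, match="class group"):
            thresholds, _ = class_profile(self._records(triples))
        assert thresholds[GROUP_OTHER] is None

    def test_global_fallback_warns(self):
        profile = ErrorProfile.from_records(
            self._records([("G", "T", 0.0)] * 120)
        )
        with pytest.warns(UserWarning, match="global"):
            t = profile.threshold_for("A", "C")
        assert t == profile.thresholds["global"]


class TestCdf:
    def test_identical_inputs_identical_cdfs(self):
        vafs = [0.0, 0.0, 0.001, 0.01]
        cdf = raw_vs_corrected_cdf(vafs, vafs)
        assert (cdf["F_raw"] == cdf["F_eccs"]).all()

    def test_cdfs_are_monotone(self):
        rng = np.random.default_rng(3)
        cdf = raw_vs_corrected_cdf(rng.random(500) / 10, rng.random(400) / 100)
        assert (np.diff(cdf["F_raw"]) >= 0).all()
        assert (np.diff(cdf["F_eccs"]) >= 0).all()

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            raw_vs_corrected_cdf([], [0.1])
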