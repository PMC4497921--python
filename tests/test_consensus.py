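import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecseq._dna import ENCODE_LUT, encode
from ecseq.consensus import (batch_consensus_codes, build_consensus,
                             consensus_quality_filter)
from ecseq.families import ReadFamily
from ecseq.umi import TaggedRead


def _family(seqs, anchors=None, key="K", amp="amp1"):
    anchors = anchors or ["left"] * len(seqs)
    members = [
        (
            TaggedRead(bases=s, quality_string="I" * len(s), mate=1, index="",
                       family_index=key, amplicon_name=amp, anchor=a),
            None,
        )
        for s, a in zip(seqs, anchors)
    ]
    return ReadFamily(key, amp, members)


class TestVotingRule:
    def test_unanimous_family(self):
        eccs = build_consensus(_family(["ACGT"] * 5), min_depth=3)
        assert eccs.bases == "ACGT"
        assert list(eccs.support) == [5, 5, 5, 5]
        assert list(eccs.depth) == [5, 5, 5, 5]

    def test_agreement_exactly_at_threshold_keeps_base(self):
        seqs = ["ACGT"] * 9 + ["ATGT"]  # 9/10 = 0.9 agreement at column 1
        eccs = build_consensus(_family(seqs), min_agreement=0.9, min_depth=3)
        assert eccs.bases == "ACGT"
        assert eccs.support[1] == 9

    def test_even_split_masks_to_n(self):
        eccs = build_consensus(
            _family(["ACGT", "ACGT", "ATGT", "ATGT"]), min_agreement=0.5,
            min_depth=3,
        )
        assert eccs.bases == "ANGT"

    def test_depth_below_minimum_masks(self):
        eccs = build_consensus(_family(["ACGT"] * 2), min_depth=3)
        assert eccs.bases == "NNNN"

    def test_empty_family_is_contract_violation(self):
        with pytest.raises(ValueError):
            build_consensus(ReadFamily("K", "a", []))

    def test_singleton_equals_its_read(self):
        """min_depth=1 degenerate mode: the ECCS is the read itself, i.e.
        conventional uncorrected sequencing."""
        eccs = build_consensus(_family(["AGGTCC"]), min_agreement=1.0, min_depth=1)
        assert eccs.bases == "AGGTCC"

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        seqs = ["ACGTAC", "ACGTAC", "ACCTAC", "ACGTAA", "ACGTAC"]
        ref = build_consensus(_family(seqs))
        for _ in range(5):
            perm = list(rng.permutation(seqs))
            other = build_consensus(_family(perm))
            assert other.bases == ref.bases
            assert list(other.support) == list(ref.support)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_raising_agreement_only_masks(self, seed):
        rng = np.random.default_rng(seed)
        seqs = ["".join(rng.choice(list("ACGT"), size=8)) for _ in range(5)]
        prev = build_consensus(_family(seqs), min_agreement=0.5, min_depth=1)
        for ma in (0.7, 0.9, 1.0):
            cur = build_consensus(_family(seqs), min_agreement=ma, min_depth=1)
            for a, b in zip(prev.bases, cur.bases):
                assert b == a or b == "N"
            prev = cur

    def test_length_discordant_outlier_excluded(self):
        # 4 concordant reads plus one wildly different shorter read
        seqs = ["ACGTACGTACGT"] * 4 + ["TTTTTTTTTT"]
        eccs = build_consensus(_family(seqs), min_depth=3, max_member_edits=5)
        assert eccs.outliers == 1
        assert eccs.bases == "ACGTACGTACGT"

    def test_right_anchored_reads_vote_end_anchored(self):
        # right-anchored read one base short covers the template suffix
        seqs = ["ACGTAC", "ACGTAC", "ACGTAC", "CGTAC"]
        eccs = build_consensus(
            _family(seqs, anchors=["left"] * 3 + ["right"]), min_depth=3
        )
        assert eccs.bases == "ACGTAC"
        assert list(eccs.depth) == [3, 4, 4, 4, 4, 4]


class TestQualityFilter:
    def test_clean_eccs_kept(self):
        eccs = build_consensus(_family(["ACGT"] * 4))
        assert consensus_quality_filter(eccs, max_n_fraction=0.2)

    def test_high_n_fraction_dropped(self):
        eccs = build_consensus(_family(["AAAA", "AAAA", "CCCC", "CCCC"]),
                               min_agreement=0.9, min_depth=3)
        assert eccs.bases == "NNNN"
        assert not consensus_quality_filter(eccs, max_n_fraction=0.2)

    def test_threshold_one_never_drops(self):
        eccs = build_consensus(_family(["AAAA", "CCCC"]), min_depth=3)
        assert consensus_quality_filter(eccs, max_n_fraction=1.0)


class TestBatchEquivalence:
    @pytest.mark.parametrize("min_agreement,min_depth", [(0.9, 3), (0.6, 1), (1.0, 3)])
    def test_batch_matches_per_family_path(self, min_agreement, min_depth):
        rng = np.random.default_rng(7)
        L, fams = 30, 60
        starts, rows, all_fams = [], [], []
        for fi in range(fams):
            size = int(rng.integers(1, 9))
            base = "".join(rng.choice(list("ACGT"), size=L))
            seqs = []
            for _ in range(size):
                s = list(base)
                for p in rng.integers(0, L, size=rng.integers(0, 3)):
                    s[p] = "ACGT"[rng.integers(0, 4)]
                seqs.append("".join(s))
            starts.append(len(rows))
            rows.extend(seqs)
            all_fams.append(_family(seqs, key=f"K{fi}"))
        mat = ENCODE_LUT[
            np.frombuffer("".join(rows).encode(), np.uint8)
        ].reshape(len(rows), L)
        codes, support, depth = batch_consensus_codes(
            mat, np.array(starts), min_agreement=min_agreement, min_depth=min_depth
        )
        for fi, fam in enumerate(all_fams):
            eccs = build_consensus(fam, min_agreement=min_agreement,
                                   min_depth=min_depth)
            assert encode(eccs.bases).tolist() == codes[fi].tolist()
            assert eccs.support.tolist() == support[fi].tolist()
            assert eccs.depth.tolist() == depth[fi].tolist()


class TestErrorCorrection:
    def _simulate_families(self, rng, n_families, size, L, per_read_error):
        truth = rng.integers(0, 4, size=(n_families, L))
        errors = 0
        masked = 0
        for fi in range(n_families):
            base = "".join("ACGT"[c] for c in truth[fi])
            seqs = []
            for _ in range(size):
                s = np.array(list(base))
                hit = rng.random(L) < per_read_error
                shift = rng.integers(1, 4, size=int(hit.sum()))
                idx = np.flatnonzero(hit)
                for p, sh in zip(idx, shift):
                    s[p] = "ACGT"[(truth[fi, p] + sh) % 4]
                seqs.append("".join(s))
            yield base, _family(seqs, key=f"K{fi}")

    def test_consensus_error_at_least_100x_below_read_error(self):
        """Family size 8, 1% per-read error: the consensus error rate
        collapses by orders of magnitude."""
        rng = np.random.default_rng(11)
        n, L, e = 1000, 100, 0.01
        wrong = total = 0
        for base, fam in self._simulate_families(rng, n, 8, L, e):
            eccs = build_consensus(fam, min_agreement=0.9, min_depth=3)
            for a, b in zip(eccs.bases, base):
                if a != "N":
                    total += 1
                    wrong += a != b
        assert total > 0.9 * n * L
        assert wrong / total <= e / 100

    def test_consensus_error_matches_enumeration_closed_form(self):
        """Empirical consensus miscall rate within 3x of the exact per-column
        closed form (enumeration over all read-base combinations)."""
        size, e, ma, md = 3, 0.05, 0.6, 3
        # exact: per column, reads iid: correct w.p. 1-e, each wrong base e/3
        p_base = [1 - e] + [e / 3] * 3  # index 0 = correct, 1..3 wrong
        p_wrong = 0.0
        for combo in itertools.product(range(4), repeat=size):
            counts = np.bincount(np.array(combo), minlength=4)
            depth = size
            top = counts.max()
            if (counts == top).sum() > 1 or depth < md or top / depth < ma:
                continue  # N or no winner: not a miscall
            if counts.argmax() != 0:
                p = 1.0
                for c in combo:
                    p *= p_base[c]
                p_wrong += p
        rng = np.random.default_rng(13)
        n, L = 3000, 60
        wrong = total = 0
        for base, fam in self._simulate_families(rng, n, size, L, e):
            eccs = build_consensus(fam, min_agreement=ma, min_depth=md)
            for a, b in zip(eccs.bases, base):
                if a != "N":
                    total += 1
                    wrong += a != b
        empirical = wrong / total
        assert p_wrong / 3 <= empirical <= p_wrong * 3
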