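"""CNL vocabulary, encoding, consensus spectra, feature assembly."""

from collections import Counter

import numpy as np
import pytest

from ioneff.cnl_features import (
    CNLVocabulary,
    ConsensusConfig,
    apply_consensus,
    assemble_features,
    build_consensus,
    build_vocabulary,
    encode,
)
from ioneff.spectra import CNLSet

IK = "A" * 14 + "-" + "B" * 10 + "-N"
A, B, C = 18.0106, 44.0000, 28.0313


def _set(losses, precursor=200.0, inchikey=IK):
    return CNLSet(losses=tuple(sorted(losses)), precursor_mz=precursor,
                  inchikey=inchikey)


class TestVocabulary:
    def test_counting_and_topk(self):
        vocab = build_vocabulary(
            [_set([18.01]), _set([18.012, 44.0]), _set([18.008])], top_k=1
        )
        assert vocab.bins == pytest.approx((18.01,))
        assert vocab.counts == (3,)

    def test_presence_not_multiplicity(self):
        vocab = build_vocabulary([_set([18.01, 18.012])], top_k=5)
        assert vocab.counts == (1,)

    def test_matches_brute_force_frequency_sort(self, rng):
        true_bins = np.round(rng.uniform(10, 200, size=40), 2)
        sets = []
        for _ in range(500):
            chosen = true_bins[rng.random(40) < rng.uniform(0.05, 0.6)]
            sets.append(_set(chosen.tolist()))
        vocab = build_vocabulary(sets, top_k=15)
        counter = Counter()
        for s in sets:
            counter.update({round(l, 2) for l in s.losses})
        expected = sorted(
            sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))[:15]
        )
        assert vocab.bins == pytest.approx(tuple(b for b, _ in expected))
        assert vocab.counts == tuple(c for _, c in expected)

    def test_topk_exceeding_bins_warns_and_keeps_all(self):
        with pytest.warns(UserWarning, match="keeping all"):
            vocab = build_vocabulary([_set([18.01, 44.0])], top_k=10)
        assert len(vocab) == 2

    def test_bins_strictly_increasing(self, rng):
        sets = [_set(rng.uniform(1, 100, size=5).tolist()) for _ in range(30)]
        vocab = build_vocabulary(sets, top_k=20)
        assert np.all(np.diff(vocab.bins) > 0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            build_vocabulary([])


VOCAB = CNLVocabulary(bins=(18.01, 44.00), counts=(3, 1), top_k=2)


class TestEncoding:
    def test_within_tolerance_sets_bit(self):
        assert encode(_set([18.015]), VOCAB).bits.tolist() == [1, 0]

    def test_outside_tolerance_leaves_bit(self):
        assert encode(_set([18.031]), VOCAB).bits.tolist() == [0, 0]

    def test_close_bins_both_set_by_one_loss(self):
        vocab = CNLVocabulary(bins=(18.00, 18.02), counts=(1, 1), top_k=2)
        assert encode(_set([18.01]), vocab).bits.tolist() == [1, 1]

    def test_matches_all_pairs_oracle(self, rng):
        bins = tuple(sorted(np.round(rng.uniform(10, 150, size=25), 2)))
        vocab = CNLVocabulary(bins=bins, counts=(1,) * 25, top_k=25)
        for _ in range(20):
            losses = rng.uniform(5, 160, size=6).tolist()
            bits = encode(_set(losses), vocab).bits
            expected = [
                int(any(abs(b - l) <= 0.020 for l in losses)) for b in bins
            ]
            assert bits.tolist() == expected

    def test_adding_a_loss_never_clears_a_bit(self, rng):
        bins = tuple(sorted(np.round(rng.uniform(10, 150, size=20), 2)))
        vocab = CNLVocabulary(bins=bins, counts=(1,) * 20, top_k=20)
        losses = rng.uniform(5, 160, size=4).tolist()
        before = encode(_set(losses), vocab).bits
        after = encode(_set(losses + [77.7]), vocab).bits
        assert np.all(after >= before)


class TestConsensus:
    SETS = [_set([A, B]), _set([A, C]), _set([A])]

    def test_majority_threshold(self):
        consensus = build_consensus(self.SETS, s_min=0.5)
        assert consensus.losses == pytest.approx((A,))

    def test_zero_threshold_keeps_union(self):
        consensus = build_consensus(self.SETS, s_min=0.0)
        assert consensus.losses == pytest.approx(tuple(sorted([A, B, C])))

    def test_quarter_threshold_is_inclusive(self):
        consensus = build_consensus(self.SETS, s_min=0.25)
        assert consensus.losses == pytest.approx(tuple(sorted([A, B, C])))

    def test_tolerance_groups_jittered_losses(self):
        sets = [_set([18.010]), _set([18.025]), _set([18.018])]
        consensus = build_consensus(sets, s_min=0.9)
        assert len(consensus.losses) == 1
        assert consensus.losses[0] == pytest.approx(np.mean([18.010, 18.025, 18.018]))

    def test_mixed_inchikeys_rejected(self):
        other = CNLSet(losses=(A,), precursor_mz=100.0,
                       inchikey="C" * 14 + "-" + "D" * 10 + "-N")
        with pytest.raises(ValueError, match="mixed"):
            build_consensus([self.SETS[0], other])


class TestApplyConsensus:
    # s_min is inclusive, so with only two parent spectra a threshold of
    # 0.5 keeps singletons (1/2 >= 0.5); three parents make the collapse
    # unambiguous
    def test_replace_collapses_to_single_set(self):
        out = apply_consensus(
            [_set([A, B]), _set([A, C]), _set([A])],
            ConsensusConfig(s_min=0.5, algorithm="replace"),
        )
        assert len(out) == 1
        assert out[0].losses == pytest.approx((A,))

    def test_filter_intersects_each_spectrum(self):
        out = apply_consensus(
            [_set([A, B]), _set([A, C]), _set([A])],
            ConsensusConfig(s_min=0.5, algorithm="filter"),
        )
        assert [s.losses for s in out] == [
            pytest.approx((A,)), pytest.approx((A,)), pytest.approx((A,))
        ]

    def test_cnl_min_discards_small_sets(self):
        sets = [_set(np.linspace(10, 100, n).tolist()) for n in (2, 3, 5)]
        out = apply_consensus(
            sets, ConsensusConfig(s_min=0.0, algorithm="filter", cnl_min=3)
        )
        assert sorted(len(s) for s in out) == [3, 5]

    def test_filter_output_is_subset_of_input(self, rng):
        sets = [
            _set(rng.uniform(10, 150, size=6).tolist()) for _ in range(4)
        ]
        out = apply_consensus(
            sets, ConsensusConfig(s_min=0.5, algorithm="filter")
        )
        for original, filtered in zip(sets, out):
            assert set(filtered.losses) <= set(original.losses)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ConsensusConfig(s_min=1.5)
        with pytest.raises(ValueError):
            ConsensusConfig(algorithm="other")


class TestAssemble:
    def test_scaling_of_leading_columns(self):
        vec = encode(_set([18.01], precursor=500.0), VOCAB, ph=7.0)
        X = assemble_features([vec], VOCAB)
        assert X.loc[0, "precursor_mz_scaled"] == pytest.approx(0.5)
        assert X.loc[0, "ph_scaled"] == pytest.approx(0.5)
        # scaling round-trips
        assert X.loc[0, "precursor_mz_scaled"] * 1000 == pytest.approx(500.0)

    def test_shape_with_vocabulary(self, rng):
        bins = tuple(sorted(np.round(rng.uniform(10, 150, size=400), 2)))
        vocab = CNLVocabulary(bins=bins, counts=(1,) * 400, top_k=400)
        vectors = [
            encode(_set(rng.uniform(10, 150, size=3).tolist()), vocab, ph=5.0)
            for _ in range(10)
        ]
        assert assemble_features(vectors, vocab).shape == (10, 402)

    def test_mixed_vocabularies_rejected(self):
        short = CNLVocabulary(bins=(18.01,), counts=(1,), top_k=1)
        vec = encode(_set([18.01]), short, ph=7.0)
        with pytest.raises(ValueError, match="vocabular"):
            assemble_features([vec], VOCAB)
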