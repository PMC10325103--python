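"""Membership attacks: distance oracles, ROC orientation, verdict logic."""

import numpy as np
import pytest

from pgan import PrivacyAudit, SyntheticDataset
from pgan.privacy import (ORIGINS, AttackScoreTable, CandidateSet, attack_roc,
                          build_candidate_set, candidate_synthetic_distances,
                          cutoff_analysis, distribution_attack,
                          pairwise_attack)
from conftest import independent_synthetic, memorization_synthetic


def brute_force_scores(cand_imgs, syn_imgs, percentile=1.0):
    """Oracle: per-candidate min distance and neighbour count via plain loops."""
    c = cand_imgs.reshape(len(cand_imgs), -1).astype(float)
    s = syn_imgs.reshape(len(syn_imgs), -1).astype(float)
    dists = np.array([[np.sqrt(((ci - sj) ** 2).sum()) for sj in s] for ci in c])
    thr = np.percentile(dists, percentile)
    return dists.min(axis=1), (dists <= thr).sum(axis=1), thr


def random_fixture(n_cand=12, n_syn=20, seed=0, shape=(2, 4, 4)):
    rng = np.random.default_rng(seed)
    cands = CandidateSet(
        images=rng.uniform(-1, 1, (n_cand, *shape)).astype(np.float32),
        origins=np.array(["train", "validation", "test"] * (n_cand // 3),
                         dtype=object))
    syn = SyntheticDataset(
        images=rng.uniform(-1, 1, (n_syn, *shape)).astype(np.float32),
        labels=np.ones(n_syn, dtype=np.int8))
    return cands, syn


class TestDistancesAndScores:
    @pytest.mark.parametrize("seed", range(3))
    def test_attack_scores_match_loop_oracle(self, seed):
        cands, syn = random_fixture(seed=seed)
        want_min, want_count, want_thr = brute_force_scores(cands.images,
                                                            syn.images)
        pair = pairwise_attack(cands, syn)
        dist = distribution_attack(cands, syn)
        assert np.allclose(pair.scores, want_min)
        assert np.array_equal(dist.scores, want_count)
        assert dist.threshold == pytest.approx(want_thr)

    def test_chunked_distance_matrix_matches_oracle(self):
        cands, syn = random_fixture(n_cand=9, n_syn=11, seed=5)
        got = candidate_synthetic_distances(cands, syn, chunk=4)
        c = cands.images.reshape(9, -1).astype(float)
        s = syn.images.reshape(11, -1).astype(float)
        want = np.sqrt(((c[:, None, :] - s[None, :, :]) ** 2).sum(-1))
        assert np.allclose(got, want)

    def test_exact_copy_scores_zero_distance(self):
        cands, syn = random_fixture()
        syn.images[0] = cands.images[0]
        pair = pairwise_attack(cands, syn)
        assert pair.scores[0] == 0.0

    def test_embedding_space_requires_model(self):
        cands, syn = random_fixture()
        with pytest.raises(ValueError, match="EmbeddingModel"):
            pairwise_attack(cands, syn, space="embedding")

    def test_empty_synthetic_rejected(self):
        cands, _ = random_fixture()
        empty = SyntheticDataset(images=np.zeros((0, 2, 4, 4), np.float32),
                                 labels=np.zeros(0, np.int8))
        with pytest.raises(ValueError):
            pairwise_attack(cands, empty)


class TestAttackRoc:
    def test_hand_worked_eight_candidate_example(self):
        # pairwise: smaller distance = more suspicious. Train scores
        # {1, 2, 3, 9} vs validation {4, 5, 6, 7}: correctly ordered pairs
        # = 3*4 + 0 = 12 of 16 -> AUC 0.75.
        table = AttackScoreTable(
            scores=np.array([1.0, 2, 3, 9, 4, 5, 6, 7]),
            origins=np.array(["train"] * 4 + ["validation"] * 4, dtype=object),
            attack="pairwise", space="pixel")
        assert attack_roc(table) == pytest.approx(0.75)

    def test_distribution_attack_counts_rank_positively(self):
        # larger neighbour count = more suspicious; perfectly separated
        table = AttackScoreTable(
            scores=np.array([10, 9, 1, 2]),
            origins=np.array(["train", "train", "validation", "validation"],
                             dtype=object),
            attack="distribution", space="pixel")
        assert attack_roc(table) == 1.0

    def test_missing_origin_rejected(self):
        table = AttackScoreTable(scores=np.array([1.0, 2.0]),
                                 origins=np.array(["train", "train"],
                                                  dtype=object),
                                 attack="pairwise", space="pixel")
        with pytest.raises(ValueError, match="absent"):
            attack_roc(table)


class TestCutoffs:
    def _table(self):
        return AttackScoreTable(
            scores=np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6]),
            origins=np.array(["train", "train", "validation",
                              "test", "validation", "test"], dtype=object),
            attack="pairwise", space="pixel")

    def test_top_two_are_all_train(self):
        df = cutoff_analysis(self._table(), [2, 6])
        assert df.loc[df.cutoff == 2, "train"].item() == 1.0
        row = df.loc[df.cutoff == 6].iloc[0]
        assert row["train"] == pytest.approx(1 / 3)
        assert row["train"] + row["validation"] + row["test"] == pytest.approx(1.0)

    def test_cutoff_larger_than_table_rejected(self):
        with pytest.raises(ValueError):
            cutoff_analysis(self._table(), [7])


class TestCandidateSet:
    def test_remainder_assignment_order(self, micro_phantom):
        cands = build_candidate_set(micro_phantom, n_per_origin=5, seed=0,
                                    total=16)
        assert cands.counts() == {"train": 6, "validation": 5, "test": 5}

    def test_candidates_are_actual_split_members(self, micro_phantom):
        cands = build_candidate_set(micro_phantom, n_per_origin=4, seed=1)
        for img, origin, idx in zip(cands.images, cands.origins, cands.indices):
            assert micro_phantom.split[idx] == origin
            assert np.array_equal(micro_phantom.images[idx], img)

    def test_oversubscription_rejected(self, micro_phantom):
        with pytest.raises(ValueError):
            build_candidate_set(micro_phantom, n_per_origin=10 ** 6, seed=0)

    def test_inconsistent_total_rejected(self, micro_phantom):
        with pytest.raises(ValueError):
            build_candidate_set(micro_phantom, n_per_origin=5, seed=0, total=30)


class TestVerdicts:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_memorized_synthetic_fails_the_audit(self, privacy_phantom, seed):
        """Near-copies of training images must be detected: the pairwise
        attack separates train from validation candidates almost perfectly."""
        syn = memorization_synthetic(privacy_phantom, n=150, seed=seed)
        report = PrivacyAudit(privacy_phantom, syn, n_per_origin=40,
                              total=None, seed=seed).run()
        assert report.verdict == "FAIL"
        assert report.aucs[("pairwise", "pixel", "validation")] > 0.9

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_independent_synthetic_passes_the_audit(self, privacy_phantom,
                                                    privacy_independent, seed):
        report = PrivacyAudit(privacy_phantom, privacy_independent,
                              n_per_origin=40, total=None, seed=seed).run()
        assert report.verdict == "PASS"
        for (attack, space, neg), v in report.aucs.items():
            if neg == "validation":
                assert v < 0.6

    def test_attack_auc_increases_with_memorized_fraction(
            self, privacy_phantom, privacy_independent):
        """Mixing more training copies into an otherwise independent
        synthetic set monotonically strengthens the pairwise attack."""
        n = len(privacy_independent)
        copies = memorization_synthetic(privacy_phantom, n=n, seed=3)
        cands = build_candidate_set(privacy_phantom, n_per_origin=40, seed=0)
        aucs = []
        for frac in (0.0, 0.25, 0.5, 1.0):
            k = int(frac * n)
            images = privacy_independent.images.copy()
            if k:
                images[:k] = copies.images[:k]
            syn = SyntheticDataset(images=images,
                                   labels=privacy_independent.labels)
            aucs.append(attack_roc(pairwise_attack(cands, syn)))
        assert all(a < b for a, b in zip(aucs, aucs[1:]))
        assert aucs[0] < 0.6 and aucs[-1] > 0.9

    def test_report_serialization_and_summary(self, micro_phantom, tmp_path):
        syn = memorization_synthetic(micro_phantom, n=60)
        report = PrivacyAudit(micro_phantom, syn, n_per_origin=15, total=None,
                              cutoffs=(5, 15), seed=0).run()
        assert "FAIL" in report.summary()
        report.save_json(tmp_path / "privacy.json")
        import json

        loaded = json.loads((tmp_path / "privacy.json").read_text())
        assert loaded["verdict"] == "FAIL"
        assert "pairwise/pixel/train_vs_validation" in loaded["aucs"]
        report.save_score_tables(tmp_path)
        assert (tmp_path / "scores_pairwise_pixel.csv").exists()

    def test_test_origin_auc_does_not_affect_verdict(self):
        """Only the train-vs-validation comparison drives the verdict; a
        high train-vs-test AUC alone is not treated as a leak."""
        from pgan.privacy import PrivacyReport

        table = AttackScoreTable(scores=np.zeros(3),
                                 origins=np.array(ORIGINS, dtype=object),
                                 attack="pairwise", space="pixel")
        report = PrivacyReport(
            tables={("pairwise", "pixel"): table},
            aucs={("pairwise", "pixel", "validation"): 0.5,
                  ("pairwise", "pixel", "test"): 0.95},
            cutoff_tables={}, leak_threshold=0.6)
        assert report.verdict == "PASS"
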