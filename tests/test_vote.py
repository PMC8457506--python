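import numpy as np
import pytest

from squigglevote.average import dba
from squigglevote.vote import (
    VoteTable,
    apply_votes,
    default_thresholds,
    select_final,
    tally_votes,
    vote_sweep,
)

from conftest import toy_ensemble


class TestTally:
    def test_duplicated_consensus_position_collects_votes(self):
        """Consensus [1,2,2,3] against clean voters [1,2,3]: each voter's
        warp path pairs one voter event with consensus 1..2, so position 2
        (all-but-first of the run) is voted duplicated by all three."""
        voters = toy_ensemble([[1, 2, 3]] * 3)
        table = tally_votes(np.array([1.0, 2, 2, 3]), voters)
        assert table.n_voters == 3
        assert table.dup_votes.tolist() == [0, 0, 3, 0]

    def test_identical_voters_vote_nothing(self):
        voters = toy_ensemble([[1, 2, 3]] * 3)
        table = tally_votes(np.array([1.0, 2, 3]), voters)
        assert table.dup_votes.sum() == 0
        assert table.ins_votes.sum() == 0

    def test_voter_side_stretch_feeds_insertion_votes_only(self):
        voters = toy_ensemble([[1, 2, 2, 3]] * 3)
        table = tally_votes(np.array([1.0, 2, 3]), voters)
        assert table.dup_votes.sum() == 0
        assert table.ins_votes.tolist() == [0, 3, 0]

    def test_vote_counts_bounded_by_voters(self):
        rng = np.random.default_rng(0)
        cons = rng.uniform(60, 130, 40)
        voters = toy_ensemble([list(rng.uniform(60, 130, 55)) for _ in range(5)])
        table = tally_votes(cons, voters)
        assert table.dup_votes.max() <= 5
        assert table.ins_votes.max() <= 5


class TestApply:
    table = VoteTable(n_voters=3, dup_votes=np.array([0, 0, 3, 0]), ins_votes=np.zeros(4, int))

    def test_unanimous_vote_deletes_position(self):
        voted = apply_votes(np.array([1.0, 2, 2, 3]), self.table, 1.0)
        np.testing.assert_allclose(voted, [1, 2, 3])

    def test_threshold_above_votes_leaves_consensus(self):
        table = VoteTable(3, np.array([0, 1, 0, 0]), np.zeros(4, int))
        voted = apply_votes(np.array([1.0, 2, 2, 3]), table, 0.5)
        np.testing.assert_allclose(voted, [1, 2, 2, 3])

    def test_threshold_validated(self):
        with pytest.raises(ValueError):
            apply_votes(np.array([1.0, 2]), VoteTable(1, np.zeros(2, int), np.zeros(2, int)), 0.0)

    def test_total_deletion_rejected(self):
        table = VoteTable(2, np.array([2, 2]), np.zeros(2, int))
        with pytest.raises(ValueError, match="entire"):
            apply_votes(np.array([1.0, 2]), table, 0.5)


class TestSweep:
    def test_default_grid(self):
        grid = default_thresholds()
        assert grid[0] == 1.0 and grid[-1] == pytest.approx(0.10)
        assert np.all(np.diff(grid) < 0)

    def test_lengths_monotone_non_increasing(self, small_ensemble):
        cons = dba(small_ensemble, max_iter=3)
        sweep = vote_sweep(cons, small_ensemble)
        assert np.all(np.diff(sweep.lengths) <= 0)

    def test_agreement_free_table_keeps_length(self):
        voters = toy_ensemble([[1, 2, 3]] * 3)
        sweep = vote_sweep(np.array([1.0, 2, 3]), voters, thresholds=[1.0])
        assert sweep.lengths.tolist() == [3]
        assert sweep.mean_dist[0] == pytest.approx(0.0)

    def test_ascending_thresholds_rejected(self):
        voters = toy_ensemble([[1, 2, 3]] * 3)
        with pytest.raises(ValueError):
            vote_sweep(np.array([1.0, 2, 3]), voters, thresholds=[0.5, 1.0])

    def test_gold_distance_recorded_when_gold_given(self, small_gold, small_ensemble):
        cons = dba(small_ensemble, max_iter=2)
        sweep = vote_sweep(cons, small_ensemble, thresholds=[1.0, 0.5], gold=small_gold)
        assert sweep.gold_dist is not None and sweep.gold_dist.size == 2


class TestSelect:
    def test_single_entry_sweep(self):
        voters = toy_ensemble([[1, 2, 3]] * 3)
        sweep = vote_sweep(np.array([1.0, 2, 3]), voters, thresholds=[1.0])
        threshold, final = select_final(sweep)
        assert threshold == 1.0
        np.testing.assert_allclose(final.levels, [1, 2, 3])

    def test_convex_curve_argmin(self):
        from squigglevote.vote import VotingSweep

        sweep = VotingSweep(
            thresholds=np.array([1.0, 0.8, 0.6, 0.4]),
            lengths=np.array([10, 9, 8, 7]),
            mean_dist=np.array([5.0, 3.0, 4.0, 6.0]),
            sd_dist=np.zeros(4),
            gold_dist=None,
            voted_levels=[np.arange(10 - i, dtype=float) for i in range(4)],
        )
        threshold, final = select_final(sweep)
        assert threshold == 0.8
        assert len(final) == 9

    def test_tie_prefers_larger_threshold(self):
        from squigglevote.vote import VotingSweep

        sweep = VotingSweep(
            thresholds=np.array([1.0, 0.5]),
            lengths=np.array([4, 3]),
            mean_dist=np.array([2.0, 2.0]),
            sd_dist=np.zeros(2),
            gold_dist=None,
            voted_levels=[np.zeros(4), np.zeros(3)],
        )
        threshold, _ = select_final(sweep)
        assert threshold == 1.0


class TestEndToEndRecovery:
    def test_voting_recovers_gold_length_and_similarity(self, small_gold, small_ensemble):
        """Duplication-driven inflation is removed by gold-free voting: the
        final length lands nearer the gold length than the initial consensus,
        and the gold-consensus distance shrinks."""
        from squigglevote.warp import dtw_distance

        cons = dba(small_ensemble)
        sweep = vote_sweep(cons, small_ensemble)
        threshold, final = select_final(sweep, source=cons)
        g = small_gold.levels
        assert abs(len(final) - g.size) < abs(len(cons) - g.size)
        assert dtw_distance(final.levels, g) < dtw_distance(cons.levels, g)
        assert 0.1 < threshold < 1.0  # interior selection
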