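import numpy as np
import pytest

from squigglevote import simulate
from squigglevote.clean import (
    CleaningConfig,
    EmptyEnsembleError,
    clean_pipeline,
    detect_leader,
    distortion_level,
    filter_global,
    filter_sectional,
    filter_short,
    snr_length,
    snr_ratio,
    strip_leaders,
)
from squigglevote.squiggle_io import Ensemble, Squiggle

from conftest import toy_ensemble


def homogeneous(n, length=200, mean=100.0, sd=5.0, seed=0):
    rng = np.random.default_rng(seed)
    return Ensemble(
        [Squiggle(f"h{i}", rng.normal(mean, sd, length)) for i in range(n)]
    )


class TestFilterShort:
    def test_threshold_from_input_mean(self):
        rng = np.random.default_rng(0)
        ens = Ensemble(
            [Squiggle(f"r{i}", rng.normal(100, 5, n)) for i, n in enumerate([100, 100, 100, 10])]
        )
        out = filter_short(ens, 0.2)  # threshold 0.2 * 77.5 = 15.5
        assert len(out) == 3
        assert "r3" not in out.read_ids

    def test_equal_lengths_untouched(self):
        ens = homogeneous(5)
        assert len(filter_short(ens, 0.2)) == 5

    def test_boundary_is_inclusive(self):
        ens = toy_ensemble([[1.0], [2.0]])  # length 1 >= 0.2 * 1
        assert len(filter_short(ens, 0.2)) == 2


class TestLeaderDetection:
    cfg = CleaningConfig(leader_window=10)

    def test_no_leader_gives_zero_boundary(self):
        s = homogeneous(1)[0]
        assert detect_leader(s, self.cfg) == 0

    def test_synthetic_leader_recovered_within_a_window(self):
        rng = np.random.default_rng(1)
        leader = rng.normal(150, 20, 50)
        body = rng.normal(100, 5, 400)
        s = Squiggle("x", np.concatenate([leader, body]))
        assert 40 <= detect_leader(s, self.cfg) <= 60

    def test_leader_identical_to_body_is_undetectable(self):
        rng = np.random.default_rng(2)
        s = Squiggle("x", rng.normal(100, 5, 300))
        assert detect_leader(s, self.cfg) == 0

    def test_too_short_read_warns_and_returns_zero(self):
        s = Squiggle("x", np.ones(20))
        with pytest.warns(UserWarning):
            assert detect_leader(s, self.cfg) == 0

    def test_strip_leaders_reduces_by_detected_amounts(self):
        rng = np.random.default_rng(3)
        reads = []
        for i, lead in enumerate([50, 0, 30]):
            body = rng.normal(100, 5, 400)
            leader = rng.normal(160, 25, lead) if lead else np.empty(0)
            reads.append(Squiggle(f"r{i}", np.concatenate([leader, body])))
        out = strip_leaders(Ensemble(reads), self.cfg)
        for s, lead in zip(out, [50, 0, 30]):
            assert abs(len(s) - 400) <= self.cfg.leader_window


class TestGlobalFilter:
    def test_shifted_read_removed(self):
        ens = homogeneous(20)
        sd_of_means = np.std([s.levels.mean() for s in ens], ddof=1)
        bad = Squiggle("bad", ens[0].levels + 10 * max(sd_of_means, 1.0) * 10)
        out = filter_global(Ensemble(ens.squiggles + [bad]), 3.0)
        assert "bad" not in out.read_ids
        assert len(out) == 20

    def test_identical_reads_untouched(self):
        base = np.sin(np.linspace(0, 10, 100)) + 100
        ens = Ensemble([Squiggle(f"r{i}", base.copy()) for i in range(5)])
        assert len(filter_global(ens, 3.0)) == 5  # zero spread: criteria skipped

    def test_two_reads_rejected(self):
        with pytest.raises(ValueError):
            filter_global(toy_ensemble([[1.0, 2.0], [1.0, 2.0]]), 3.0)


class TestSectionalFilter:
    def test_flat_block_read_removed(self):
        rng = np.random.default_rng(4)
        reads = [Squiggle(f"r{i}", rng.normal(100, 5, 200)) for i in range(15)]
        flat = rng.normal(100, 5, 200)
        flat[50:150] = 100.0  # sigma-0 insert over half the read
        reads.append(Squiggle("flat", flat))
        out = filter_sectional(Ensemble(reads), 10, 2.0)
        assert "flat" not in out.read_ids

    def test_identical_reads_untouched(self):
        base = np.sin(np.linspace(0, 20, 150)) + 100
        ens = Ensemble([Squiggle(f"r{i}", base.copy()) for i in range(5)])
        assert len(filter_sectional(ens, 10, 2.0)) == 5

    def test_read_shorter_than_sections_rejected(self):
        rng = np.random.default_rng(5)
        reads = [Squiggle(f"r{i}", rng.normal(100, 5, 100)) for i in range(4)]
        reads.append(Squiggle("tiny", rng.normal(100, 5, 5)))
        out = filter_sectional(Ensemble(reads), 10, 2.0)
        assert "tiny" not in out.read_ids


class TestSnrAndDistortion:
    @pytest.mark.parametrize(
        "mean,sd,expected",
        [(2950, 614, 4.8), (2286, 248, 9.2)],
    )
    def test_length_snr_from_summaries(self, mean, sd, expected):
        assert round(snr_ratio(mean, sd), 1) == expected

    def test_snr_from_raw_lengths(self):
        lengths = [90, 100, 110]
        assert snr_length(lengths) == pytest.approx(100 / 10.0)

    def test_zero_spread_flags_infinite(self):
        with pytest.warns(UserWarning):
            assert snr_length([5, 5, 5]) == float("inf")

    @pytest.mark.parametrize(
        "mean_len,gold_len,expected",
        [(2286, 1329, 1.72), (1252, 782, 1.60)],
    )
    def test_distortion_level(self, mean_len, gold_len, expected):
        assert round(distortion_level(mean_len, gold_len), 2) == expected


class TestPipeline:
    def test_already_clean_ensemble_passes_through(self):
        ens = homogeneous(10, length=300)
        cleaned, report = clean_pipeline(ens)
        assert len(cleaned) == 10
        assert report.stages[0].n_in == 10
        for prev, nxt in zip(report.stages, report.stages[1:]):
            assert prev.n_out == nxt.n_in  # counts telescope

    def test_stage_size_non_increasing_and_ids_partition(self):
        gold = simulate.simulate_gold(300, seed=2)
        ens = simulate.make_ensemble(gold, simulate.EnsembleRecipe(n_reads=40, seed=2))
        cleaned, report = clean_pipeline(ens, gold=gold)
        for s in report.stages:
            assert s.n_out <= s.n_in
        survivors = set(cleaned.read_ids)
        removed = set(report.removed_ids)
        assert survivors | removed == set(ens.read_ids)
        assert not survivors & removed

    def test_corrupted_reads_removed_with_high_precision(self):
        gold = simulate.simulate_gold(400, seed=3)
        recipe = simulate.EnsembleRecipe(
            n_reads=60, chimera_fraction=0.1, short_fraction=0.1,
            global_outlier_fraction=0.1, seed=3,
        )
        ens = simulate.make_ensemble(gold, recipe)
        truth = {s.read_id: s.truth for s in ens}
        cleaned, report = clean_pipeline(ens, gold=gold)
        removed = report.removed_ids
        tp = sum(
            truth[r].is_chimera or truth[r].is_short or truth[r].is_outlier
            for r in removed
        )
        assert removed and tp / len(removed) >= 0.8

    def test_snr_improves_on_default_recipe(self):
        gold = simulate.simulate_gold(350, seed=4)
        ens = simulate.make_ensemble(gold, simulate.EnsembleRecipe(n_reads=48, seed=4))
        _, report = clean_pipeline(ens, gold=gold)
        assert report.snr_length_after >= report.snr_length_before
        assert 1.4 <= report.distortion_level <= 2.0

    def test_minimum_ensemble_size_enforced(self):
        with pytest.raises(ValueError):
            clean_pipeline(toy_ensemble([[1.0] * 20, [1.0] * 20]))

    def test_emptying_stage_is_named(self, monkeypatch):
        import squigglevote.clean as clean_mod

        def explode(ensemble, k_sigma):
            raise EmptyEnsembleError("boom")

        monkeypatch.setattr(clean_mod, "filter_global", explode)
        ens = homogeneous(5, length=300)
        with pytest.raises(EmptyEnsembleError, match="filter_global"):
            clean_pipeline(ens)
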