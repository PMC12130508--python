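"""Shapley axioms, the permutation-average oracle, and coalition machinery."""

import itertools
import math

import numpy as np
import pytest

from airsig.errors import ConfigError, DataError, IncompleteMapError
from airsig.models import TrainConfig
from airsig.preprocess import Coalition, extract_coalition
from airsig.shapley import (
    CharacteristicMap,
    coalition_experiment_count,
    compatibility_curves,
    compute_characteristic,
    enumerate_coalitions,
    normalize_shares,
    shapley_values,
)
from airsig.synthetic import GeneratorConfig, generate_dataset


def random_map(p, rng, baseline=0.0):
    values = {c.members: float(rng.uniform(0, 1))
              for c in enumerate_coalitions(p) if len(c) > 0}
    return CharacteristicMap(p=p, values=values, baseline=baseline)


def permutation_shapley(char):
    """Average marginal contribution over all player orderings — an
    independent formulation of the Shapley value."""
    p = char.p
    phi = np.zeros(p)
    for order in itertools.permutations(range(p)):
        members = ()
        for player in order:
            before = char.value(members)
            members = tuple(sorted(members + (player,)))
            phi[player] += char.value(members) - before
    return phi / math.factorial(p)


class TestEnumeration:
    @pytest.mark.parametrize("p,expected", [(1, 2), (3, 8), (9, 512)])
    def test_counts(self, p, expected):
        assert len(enumerate_coalitions(p)) == expected

    def test_order_and_contents(self):
        cs = enumerate_coalitions(2)
        assert [c.members for c in cs] == [(), (0,), (1,), (0, 1)]

    def test_ordering_is_by_size_then_lex(self):
        sizes = [len(c) for c in enumerate_coalitions(4)]
        assert sizes == sorted(sizes)

    def test_out_of_range(self):
        with pytest.raises(ConfigError):
            enumerate_coalitions(0)
        with pytest.raises(ConfigError):
            enumerate_coalitions(21)


class TestAxioms:
    def test_dummy_player_gets_zero(self):
        rng = np.random.default_rng(0)
        p, dummy = 4, 2
        base = {c.members: float(rng.uniform(0, 1))
                for c in enumerate_coalitions(p - 1)}
        values = {}
        for c in enumerate_coalitions(p):
            if len(c) == 0:
                continue
            without = tuple(m if m < dummy else m - 1 for m in c.members if m != dummy)
            values[c.members] = base[without]
        char = CharacteristicMap(p=p, values=values, baseline=base[()])
        phi = shapley_values(char).phi
        assert phi[dummy] == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_players_get_equal_shares(self):
        rng = np.random.default_rng(1)
        p, i, j = 4, 0, 3
        values = {}
        for c in enumerate_coalitions(p):
            if len(c) == 0:
                continue
            # value depends only on the pattern with i and j interchangeable
            key = (len(c), (i in c) + (j in c),
                   tuple(m for m in c.members if m not in (i, j)))
            values[c.members] = float(np.random.default_rng(hash(key) % 2**32).uniform(0, 1))
        char = CharacteristicMap(p=p, values=values, baseline=0.1)
        phi = shapley_values(char).phi
        assert phi[i] == pytest.approx(phi[j], abs=1e-12)

    def test_additivity(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            v = random_map(5, rng, baseline=0.2)
            w = random_map(5, rng, baseline=0.3)
            vw = CharacteristicMap(
                p=5,
                values={k: v.values[k] + w.values[k] for k in v.values},
                baseline=v.baseline + w.baseline,
            )
            lhs = shapley_values(vw).phi
            rhs = shapley_values(v).phi + shapley_values(w).phi
            np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_efficiency(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            char = random_map(6, rng, baseline=float(rng.uniform(0, 0.3)))
            report = shapley_values(char)
            assert report.phi.sum() == pytest.approx(
                char.grand_value - char.baseline, abs=1e-9)

    @pytest.mark.parametrize("p", [3, 4, 5, 6])
    def test_matches_permutation_oracle(self, p):
        rng = np.random.default_rng(p)
        n_instances = 15 if p < 6 else 10
        for _ in range(n_instances):
            char = random_map(p, rng, baseline=float(rng.uniform(0, 0.2)))
            np.testing.assert_allclose(
                shapley_values(char).phi, permutation_shapley(char), atol=1e-12)

    def test_incomplete_map_rejected(self):
        char = random_map(4, np.random.default_rng(0))
        del char.values[(0, 2)]
        with pytest.raises(IncompleteMapError, match=r"\(0, 2\)"):
            shapley_values(char)


class TestNormalization:
    def test_equal_values(self):
        shares = normalize_shares(np.full(9, 0.04))
        np.testing.assert_allclose(shares, 100 / 9)

    def test_single_contributor(self):
        np.testing.assert_allclose(normalize_shares(np.array([1.0] + [0.0] * 8)),
                                   [100.0] + [0.0] * 8)

    def test_sums_to_100(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            shares = normalize_shares(rng.uniform(0, 1, 9))
            assert shares.sum() == pytest.approx(100.0, abs=1e-6)

    def test_negative_values_clipped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            shares = normalize_shares(np.array([0.5, -0.25, 0.5]))
        np.testing.assert_allclose(shares, [50.0, 0.0, 50.0])
        assert any("clipped" in r.message for r in caplog.records)

    def test_zero_total_is_error(self):
        with pytest.raises(DataError):
            normalize_shares(np.zeros(4))

    def test_degenerate_game_reports_nan_shares(self, caplog):
        """A game where no channel helps still yields phi; shares are undefined."""
        values = {c.members: 0.5 - 0.01 * len(c)
                  for c in enumerate_coalitions(3) if len(c) > 0}
        char = CharacteristicMap(p=3, values=values, baseline=0.5)
        with caplog.at_level("WARNING"):
            report = shapley_values(char)
        assert (report.phi < 0).all()
        assert np.isnan(report.shares).all()


class TestCompatibilityCurves:
    def test_include_exclude_counts_for_nine_channels(self):
        per_size_with = sum(1 for c in enumerate_coalitions(9) if 0 in c)
        per_size_without = sum(1 for c in enumerate_coalitions(9)
                               if 0 not in c and len(c) > 0)
        assert per_size_with == 256
        assert per_size_without == 255  # 256 minus the empty set

    def test_monotone_characteristic_closed_form(self):
        p = 5
        values = {c.members: len(c) / p for c in enumerate_coalitions(p) if len(c) > 0}
        char = CharacteristicMap(p=p, values=values, baseline=0.0)
        curves = compatibility_curves(char)
        inc = curves[(curves.channel == "2") & (curves.condition == "include")]
        np.testing.assert_allclose(inc.sort_values("size").mean_value,
                                   np.arange(1, p + 1) / p)

    def test_global_mean_at_full_size_is_grand_value(self):
        rng = np.random.default_rng(4)
        char = random_map(4, rng)
        curves = compatibility_curves(char)
        top = curves[(curves["size"] == 4) & (curves.channel == "all")]
        assert top.mean_value.iloc[0] == pytest.approx(char.grand_value)

    def test_exclude_absent_at_full_size(self):
        char = random_map(3, np.random.default_rng(5))
        curves = compatibility_curves(char)
        assert curves[(curves["size"] == 3) & (curves.condition == "exclude")].empty


class TestExperimentDesign:
    def test_two_device_design(self):
        counts = coalition_experiment_count(p=9, n_devices=2)
        assert counts == {"coalitions_per_device": 512, "experiments": 1024}


@pytest.fixture(scope="module")
def tiny_corpus():
    config = GeneratorConfig(n_subjects=4, n_repetitions=6, duration_steps=40,
                             dwell_steps=2, channel_informativeness=(0.9,) * 9,
                             seed=19)
    ds = generate_dataset(config, "phone")
    return extract_coalition(ds, Coalition((0, 1)))


class TestComputeCharacteristic:
    def test_complete_map_with_chance_baseline(self, tiny_corpus):
        char = compute_characteristic(
            tiny_corpus, "MLP", TrainConfig(epochs=2, seed=0),
            input_length=32, params={"hidden_units": (16, 16, 16)})
        assert char.complete
        assert len(char.values) == 3
        assert char.baseline == pytest.approx(0.25)
        assert all(0.0 <= v <= 1.0 for v in char.values.values())

    def test_cache_resumes(self, tiny_corpus, tmp_path):
        import json
        kwargs = dict(input_length=32, params={"hidden_units": (16, 16, 16)},
                      cache_dir=tmp_path)
        config = TrainConfig(epochs=2, seed=0)
        first = compute_characteristic(tiny_corpus, "MLP", config, **kwargs)
        # plant a sentinel: a rerun must reuse the cached value, not retrain
        target = tmp_path / "coalition_0.json"
        data = json.loads(target.read_text())
        data["value"] = 0.123456
        target.write_text(json.dumps(data))
        second = compute_characteristic(tiny_corpus, "MLP", config, **kwargs)
        assert second.values[(0,)] == pytest.approx(0.123456)
        assert second.values[(0, 1)] == pytest.approx(first.values[(0, 1)])

    def test_stale_cache_ignored(self, tiny_corpus, tmp_path):
        config = TrainConfig(epochs=2, seed=0)
        kwargs = dict(input_length=32, params={"hidden_units": (16, 16, 16)},
                      cache_dir=tmp_path)
        first = compute_characteristic(tiny_corpus, "MLP", config, **kwargs)
        changed = compute_characteristic(
            tiny_corpus, "MLP", TrainConfig(epochs=3, seed=0), **kwargs)
        # different config hash: values recomputed under the new epoch budget
        assert changed.provenance["config_hash"] != first.provenance["config_hash"]
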