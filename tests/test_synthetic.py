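"""Synthetic core generator: determinism, damage model, tracer, geochem."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from sedadna.stats import fisher_z_interval
from sedadna.synthetic import (
    CompositionModel,
    DamageModel,
    FragmentModel,
    GeochemModel,
    SimulationConfig,
    SimulationError,
    TracerModel,
    apply_damage,
    default_config,
    default_samples,
    simulate_core,
    simulate_fragment_length,
    simulate_geochem,
    simulate_tracer_run,
)


@pytest.fixture(scope="session")
def small_sim():
    return simulate_core(default_config(seed=3, reads_per_sample=400))


class TestDeterminism:
    def test_identical_seed_identical_output(self):
        cfg = default_config(seed=7, reads_per_sample=100)
        cfg = dataclasses.replace(cfg, samples=cfg.samples[:2])
        a = simulate_core(cfg)
        b = simulate_core(cfg)
        assert sum(len(v) for v in a.reads.values()) == 200
        for sample in a.reads:
            assert [r.sequence for r in a.reads[sample]] == [
                r.sequence for r in b.reads[sample]
            ]
        pd.testing.assert_frame_equal(a.truth, b.truth)
        pd.testing.assert_frame_equal(a.geochem, b.geochem)

    def test_total_reads_conserved(self, small_sim):
        configured = sum(s.library_size for s in small_sim.config.samples)
        assert len(small_sim.truth) == configured


class TestComposition:
    def test_diatom_step_change(self):
        """Empirical diatom fraction: <0.12 in pre-boundary samples and
        >0.40 post-boundary at 5000 reads/sample (3-sigma binomial room)."""
        sim = simulate_core(default_config(seed=5, reads_per_sample=5000))
        truth = sim.truth.merge(
            sim.sample_truth.reset_index()[["sample_id", "age_ka", "kind"]],
            on="sample_id",
        )
        truth = truth[truth["kind"] == "sample"]
        diatoms = set(sim.groups["diatoms"])
        frac = (
            truth.assign(is_diatom=truth["taxon_id"].isin(diatoms))
            .groupby("age_ka")["is_diatom"]
            .mean()
        )
        boundary = sim.config.composition.boundary_age_ka
        assert (frac[frac.index > boundary] < 0.12).all()
        assert (frac[frac.index <= boundary] > 0.40).all()

    def test_controls_contain_only_contaminants(self, small_sim):
        meta = small_sim.sample_truth
        controls = meta.index[meta["kind"] != "sample"]
        contaminants = set(small_sim.groups["contaminants"])
        truth = small_sim.truth
        ctrl_rows = truth[truth["sample_id"].isin(controls)]
        assert ctrl_rows["taxon_id"].isin(contaminants).all()
        assert ctrl_rows["is_contaminant"].all()
        assert (ctrl_rows["n_damage"] == 0).all()

    def test_zero_contaminants_empties_controls(self):
        cfg = default_config(seed=9, reads_per_sample=50)
        cfg = dataclasses.replace(
            cfg, composition=CompositionModel(contaminant_rate=0.0)
        )
        sim = simulate_core(cfg)
        for spec in cfg.samples:
            if spec.kind != "sample":
                assert sim.reads[spec.sample_id] == []

    def test_bad_proportions_rejected(self):
        with pytest.raises(SimulationError):
            CompositionModel(diatom_pre=1.4)


class TestApplyDamage:
    def test_null_damage_identity(self):
        seq, pos = apply_damage("CGCGATTACG", d5=0.0, r=0.5, seed=0)
        assert seq == "CGCGATTACG" and pos == []

    def test_certain_flip_at_position_zero(self):
        for seed in range(20):
            seq, pos = apply_damage("CCCC", d5=1.0, r=0.5, seed=seed)
            assert seq[0] == "T" and (0, "C>T") in pos

    def test_three_prime_g_to_a(self):
        seq, pos = apply_damage("AAAG", d5=1.0, r=0.5, seed=1)
        assert seq[-1] == "A" and (3, "G>A") in pos

    def test_single_stranded_mode_flips_c_at_both_ends(self):
        seq, pos = apply_damage(
            "CAAC", d5=1.0, r=0.9, seed=2, single_stranded=True
        )
        assert seq[0] == "T" and seq[-1] == "T"
        assert all(kind == "C>T" for _, kind in pos)

    def test_positional_rates_match_geometric_law(self):
        """Monte Carlo on 100k fragments starting CC...: flip rate at
        position 0 is d5 and at position 1 is d5*r (±0.005)."""
        rng = np.random.default_rng(13)
        n = 100_000
        flips = np.zeros(2)
        for _ in range(n):
            seq, _ = apply_damage("CCAA", d5=0.3, r=0.5, seed=rng)
            flips += [seq[0] == "T", seq[1] == "T"]
        assert flips[0] / n == pytest.approx(0.300, abs=0.005)
        assert flips[1] / n == pytest.approx(0.150, abs=0.005)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            apply_damage("CC", d5=1.5, r=0.5)
        with pytest.raises(ValueError):
            apply_damage("CC", d5=0.5, r=1.0)


class TestFragmentLength:
    def test_point_mass_at_mode(self):
        params = FragmentModel(mode=56, sigma=1e-9)
        lengths = {simulate_fragment_length(params, s) for s in range(50)}
        assert lengths == {56}

    def test_hard_minimum(self):
        params = FragmentModel(mode=22, sigma=0.8)
        rng = np.random.default_rng(14)
        assert min(simulate_fragment_length(params, rng) for _ in range(10_000)) >= 20

    def test_median_brackets_configured_mode(self):
        rng = np.random.default_rng(15)
        params = FragmentModel()
        lengths = [simulate_fragment_length(params, rng) for _ in range(10_000)]
        assert 40 <= np.median(lengths) <= 80

    def test_mode_below_minimum_rejected(self):
        with pytest.raises(SimulationError):
            FragmentModel(mode=10)


class TestTracerSim:
    def test_blanks_all_zero_regime(self):
        run, _ = simulate_tracer_run(TracerModel(blanks_zero=True), seed=0)
        assert all(b == 0.0 for b in run.blanks)

    def test_blank_mean_clt_bound(self):
        model = TracerModel(n_blanks=10_000, blank_mean=0.1, blank_sd=0.03)
        run, _ = simulate_tracer_run(model, seed=16)
        se = 0.03 / np.sqrt(10_000)
        assert np.mean(run.blanks) == pytest.approx(0.1, abs=3 * se)

    def test_contaminated_periphery_separation(self):
        model = TracerModel()
        run, truth = simulate_tracer_run(
            model, seed=17, scenarios={"P": "periphery", "C": "clean"}
        )
        values = {(sid, loc): v for sid, loc, v in run.measurements}
        assert values[("P", "periphery")] > 0.5
        assert values[("P", "centre")] == 0.0
        assert truth == {"P": "periphery", "C": "clean"}


class TestGeochemSim:
    def _driver(self, n, seed=18):
        rng = np.random.default_rng(seed)
        return pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])

    def test_null_correlation_bound(self):
        model = GeochemModel(targets={"x": 0.0}, marginals={"x": (0, 1)})
        table = simulate_geochem(model, self._driver(500), seed=19)
        r = np.corrcoef(table["x"], self._driver(500))[0, 1]
        assert abs(r) < 0.1

    def test_perfect_target_is_exact_copy(self):
        model = GeochemModel(targets={"x": 1.0}, marginals={"x": (5, 2)})
        driver = self._driver(50)
        table = simulate_geochem(model, driver, seed=20)
        assert np.corrcoef(table["x"], driver)[0, 1] == pytest.approx(1.0)

    def test_ammonium_target_recovered_in_fisher_interval(self):
        """The headline damage–ammonium correlation (configured 0.56)."""
        driver = self._driver(500)
        model = GeochemModel()
        table = simulate_geochem(model, driver, seed=21)
        r = np.corrcoef(table["ammonium"], driver)[0, 1]
        lo, hi = fisher_z_interval(0.56, 500)
        assert lo <= r <= hi

    def test_invalid_target_rejected(self):
        with pytest.raises(SimulationError):
            GeochemModel(targets={"x": 1.5})

    def test_constant_driver_rejected(self):
        model = GeochemModel(targets={"x": 0.5}, marginals={"x": (0, 1)})
        with pytest.raises(SimulationError):
            simulate_geochem(model, pd.Series([1.0, 1.0, 1.0]), seed=0)


class TestDamageMonotonicity:
    def test_damage_fraction_increases_with_age(self, small_sim):
        """Configured d5 rises with age, so the per-sample fraction of
        reads carrying >=1 true damage flip must rise too (3-sigma room)."""
        meta = small_sim.sample_truth
        truth = small_sim.truth.merge(
            meta.reset_index()[["sample_id", "age_ka", "kind", "true_d5"]],
            on="sample_id",
        )
        core = truth[truth["kind"] == "sample"]
        frac = core.groupby("age_ka").apply(
            lambda g: (g["n_damage"] > 0).mean(), include_groups=False
        )
        d5 = meta[meta["kind"] == "sample"].set_index("age_ka")["true_d5"]
        assert d5.sort_index().is_monotonic_increasing
        # oldest vs youngest separated well beyond sampling noise
        assert frac.sort_index().iloc[-1] > frac.sort_index().iloc[0] + 0.1
        assert frac.corr(d5.sort_index(), method="spearman") > 0.8
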