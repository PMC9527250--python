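"""Damage spectra, read classification, proportions, decay-model fitting."""

import numpy as np
import pandas as pd
import pytest

from sedadna.align import AlignmentHit
from sedadna.damage import (
    classify_read,
    damage_proportion,
    fit_decay,
    substitution_spectrum,
    DamageSpectrum,
)
from sedadna.synthetic import apply_damage

from .conftest import random_seq


def _hit(read_id, seq_len, mismatches=(), gaps=0, insertions=(), taxon=12):
    matches = seq_len - len(mismatches) - len(insertions)
    columns = matches + len(mismatches) + gaps
    return AlignmentHit(
        read_id, "ref", taxon, "+", matches - len(mismatches) - 2 * gaps,
        columns, matches, tuple(mismatches), gaps, tuple(insertions),
    )


class TestSubstitutionSpectrum:
    def test_no_mismatches_zero_frequencies(self):
        reads = {f"r{i}": "CCGGAATTCC" for i in range(4)}
        hits = [_hit(rid, 10) for rid in reads]
        spec = substitution_spectrum(hits, reads, m=5)
        assert np.nansum(spec.f5) == 0 and np.nansum(spec.f3) == 0
        assert spec.n5[0] == 4  # every read has reference C at position 0

    def test_single_ct_over_ten_reference_cs(self):
        reads = {f"r{i}": "CAAAAAAAAA" for i in range(9)}
        reads["r9"] = "TAAAAAAAAA"  # C→T at 5' position 0
        hits = [_hit(rid, 10) for rid in list(reads)[:9]]
        hits.append(_hit("r9", 10, mismatches=[(0, "C", "T")]))
        spec = substitution_spectrum(hits, reads, m=5)
        assert spec.f5[0] == pytest.approx(0.1)
        assert spec.n5[0] == 10

    def test_insertion_positions_excluded_from_denominator(self):
        reads = {"r0": "CCCC"}
        hits = [_hit("r0", 4, gaps=1, insertions=(1,))]
        spec = substitution_spectrum(hits, reads, m=4)
        assert spec.n5[1] == 0

    def test_simulated_geometric_decay_recovered(self):
        """f5[0] ≈ d5 and f5[1]/f5[0] ≈ r on simulated damaged fragments."""
        rng = np.random.default_rng(23)
        d5, r = 0.3, 0.5
        reads, hits = {}, []
        for i in range(20_000):
            template = random_seq(rng, 50)
            seq, _ = apply_damage(template, d5, r, seed=rng)
            rid = f"r{i}"
            reads[rid] = seq
            mism = tuple(
                (p, template[p], seq[p]) for p in range(50) if template[p] != seq[p]
            )
            hits.append(_hit(rid, 50, mismatches=mism))
        spec = substitution_spectrum(hits, reads)
        assert spec.f5[0] == pytest.approx(d5, abs=0.02)
        assert spec.f5[1] / spec.f5[0] == pytest.approx(r, abs=0.06)
        assert spec.f3[0] == pytest.approx(d5, abs=0.02)  # G→A mirror at 3'


class TestClassifyRead:
    def test_perfect_hit_is_default(self):
        call = classify_read(_hit("r", 50), "s1")
        assert call.call == "default" and call.evidence == ()

    def test_terminal_ct_is_ancient(self):
        call = classify_read(_hit("r", 50, mismatches=[(0, "C", "T")]), "s1")
        assert call.call == "ancient" and call.evidence == ((0, "C>T"),)

    def test_terminal_ga_at_three_prime_is_ancient(self):
        call = classify_read(_hit("r", 50, mismatches=[(48, "G", "A")]), "s1")
        assert call.call == "ancient"

    def test_non_deamination_substitution_is_default(self):
        call = classify_read(_hit("r", 50, mismatches=[(2, "A", "G")]), "s1")
        assert call.call == "default"

    def test_interior_ct_is_default(self):
        call = classify_read(_hit("r", 50, mismatches=[(25, "C", "T")]), "s1")
        assert call.call == "default"

    def test_low_identity_rejected(self):
        mism = [(i, "A", "C") for i in range(10, 14)]
        call = classify_read(_hit("r", 50, mismatches=mism), "s1")
        assert call.call == "rejected"

    def test_sensitivity_matches_closed_form(self):
        """With eps=0 the ancient rate equals 1 − Π(1 − d5·r^pos) over
        terminal C (5') and G (3') positions, within 3σ binomial bounds."""
        rng = np.random.default_rng(24)
        d5, r, k = 0.3, 0.5, 5
        n = 20_000
        expected, var, observed = 0.0, 0.0, 0
        for i in range(n):
            template = random_seq(rng, 40)
            seq, _ = apply_damage(template, d5, r, seed=rng)
            mism = tuple(
                (p, template[p], seq[p]) for p in range(40) if template[p] != seq[p]
            )
            call = classify_read(
                _hit(f"r{i}", 40, mismatches=mism), "s", min_pid=0.0
            )
            observed += call.call == "ancient"
            p_miss = 1.0
            for pos in range(k):
                if template[pos] == "C":
                    p_miss *= 1 - d5 * r**pos
            for j in range(k):
                if template[40 - 1 - j] == "G":
                    p_miss *= 1 - d5 * r**j
            p = 1 - p_miss
            expected += p
            var += p * (1 - p)
        assert abs(observed - expected) <= 3 * np.sqrt(var)

    def test_false_ancient_rate_bounded_by_background(self):
        """Undamaged reads with background flips at rate eps go ancient
        at most at the analytic bound from the terminal window."""
        rng = np.random.default_rng(25)
        eps, k, n = 0.01, 5, 20_000
        false_pos = 0
        bound = 0.0
        for i in range(n):
            template = random_seq(rng, 40)
            seq, _ = apply_damage(template, d5=0.0, r=0.5, epsilon=eps, seed=rng)
            mism = tuple(
                (p, template[p], seq[p]) for p in range(40) if template[p] != seq[p]
            )
            call = classify_read(_hit(f"r{i}", 40, mismatches=mism), "s")
            false_pos += call.call == "ancient"
            n_qualifying = sum(template[p] == "C" for p in range(k)) + sum(
                template[40 - 1 - j] == "G" for j in range(k)
            )
            bound += 1 - (1 - eps / 3) ** n_qualifying
        assert false_pos <= bound + 3 * np.sqrt(bound)


class TestDamageProportion:
    def _calls(self, n_ancient, n_default, sample="s1", taxon=12):
        calls = []
        for i in range(n_ancient):
            calls.append(
                classify_read(
                    _hit(f"a{i}", 50, mismatches=[(0, "C", "T")]), sample, taxon
                )
            )
        for i in range(n_default):
            calls.append(classify_read(_hit(f"d{i}", 50), sample, taxon))
        return calls

    def test_basic_proportion(self):
        summary = damage_proportion(self._calls(3, 7))
        row = summary.table.iloc[0]
        assert row["proportion"] == pytest.approx(0.30)
        assert row["low_confidence"]  # 10 < 50 reads

    def test_single_ancient_read_reported_low_confidence(self):
        summary = damage_proportion(self._calls(1, 0))
        row = summary.table.iloc[0]
        assert row["proportion"] == 1.0 and row["low_confidence"]

    def test_fifty_reads_not_flagged(self):
        summary = damage_proportion(self._calls(10, 40))
        assert not summary.table.iloc[0]["low_confidence"]

    def test_rejected_excluded_from_denominator(self):
        calls = self._calls(2, 3)
        mism = [(i, "A", "C") for i in range(10, 16)]
        calls.append(classify_read(_hit("x", 50, mismatches=mism), "s1", 12))
        summary = damage_proportion(calls)
        row = summary.table.iloc[0]
        assert row["proportion"] == pytest.approx(0.4)
        assert row["n_rejected"] == 1

    def test_all_rejected_proportion_undefined(self):
        mism = [(i, "A", "C") for i in range(10, 16)]
        calls = [classify_read(_hit("x", 50, mismatches=mism), "s1", 12)]
        summary = damage_proportion(calls)
        assert np.isnan(summary.table.iloc[0]["proportion"])

    def test_invariant_to_order(self):
        calls = self._calls(5, 15) + self._calls(2, 8, sample="s2")
        a = damage_proportion(calls).table
        b = damage_proportion(list(reversed(calls))).table
        pd.testing.assert_frame_equal(a, b)


class TestFitDecay:
    def _spectrum(self, f5):
        f5 = np.asarray(f5, dtype=float)
        m = len(f5)
        n = np.full(m, 1000)
        return DamageSpectrum(f5, np.zeros(m), n, n, 0.0, 1000)

    def test_noiseless_inversion(self):
        i = np.arange(20)
        spec = self._spectrum(0.3 * 0.5**i + 0.0)
        fit = fit_decay(spec)
        assert fit.d_hat == pytest.approx(0.3, abs=1e-6)
        assert fit.r_hat == pytest.approx(0.5, abs=1e-6)
        assert fit.eps_hat == pytest.approx(0.0, abs=1e-6)

    def test_flat_spectrum_is_background_only(self):
        fit = fit_decay(self._spectrum(np.full(20, 0.01)))
        assert fit.d_hat == pytest.approx(0.0, abs=1e-4)
        assert fit.eps_hat == pytest.approx(0.01, abs=1e-4)

    def test_all_zero_degenerate(self):
        fit = fit_decay(self._spectrum(np.zeros(20)))
        assert fit.d_hat == 0.0 and fit.degenerate and np.isnan(fit.r_hat)

    def test_too_few_positions_rejected(self):
        with pytest.raises(ValueError):
            fit_decay(self._spectrum([0.1, 0.05]))
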