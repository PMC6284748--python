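"""Median-effect fitting and combination-index identities."""

from __future__ import annotations

import numpy as np
import pytest

from slcombo.synergy import (
    ADDITIVITY,
    ANTAGONISM,
    SYNERGY,
    CombinationMeasurement,
    DegenerateFitError,
    DoseResponseSeries,
    InvalidFitError,
    MedianEffectFit,
    combination_index,
    fit_median_effect,
    synergy_report,
)

DOSES = [0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0]


def model_series(drug_id, dm, m, doses=None, noise=0.0, rng=None):
    # two-fold ladder centred on Dm so no fa needs clipping
    doses = np.asarray(DOSES, dtype=float) * dm if doses is None else np.asarray(doses, dtype=float)
    ratio = (doses / dm) ** m
    fa = ratio / (1.0 + ratio)
    viability = 1.0 - fa
    if noise:
        viability = viability + rng.normal(0.0, noise, size=len(doses))
    return DoseResponseSeries(drug_id, doses.tolist(), np.clip(viability, 0, 1).tolist())


class TestFitMedianEffect:
    @pytest.mark.parametrize("dm", [0.2, 1.0, 3.7])
    @pytest.mark.parametrize("m", [0.5, 1.0, 2.5])
    def test_exact_recovery_on_noiseless_model_data(self, dm, m):
        fit = fit_median_effect(model_series("d", dm, m))
        assert fit.dm == pytest.approx(dm, rel=1e-9)
        assert fit.m == pytest.approx(m, rel=1e-9)
        assert fit.r == pytest.approx(1.0, abs=1e-12)

    def test_fa_is_half_at_dm(self):
        fit = fit_median_effect(model_series("d", 1.5, 2.0))
        assert fit.fa_at(fit.dm) == pytest.approx(0.5)
        assert fit.ic50 == fit.dm

    def test_replicates_averaged_before_fitting(self):
        s = model_series("d", 1.0, 1.0)
        doubled = DoseResponseSeries("d", list(s.doses) * 2, list(s.viability) * 2)
        assert fit_median_effect(doubled).dm == pytest.approx(1.0, rel=1e-9)

    def test_extreme_fa_clipped_with_warning(self):
        s = DoseResponseSeries("d", [0.1, 1.0, 10.0], [1.0, 0.5, 0.0])
        with pytest.warns(UserWarning, match="clipped"):
            fit = fit_median_effect(s)
        assert fit.dm > 0

    def test_unnormalised_viability_flagged(self):
        with pytest.warns(UserWarning, match="vehicle control"):
            DoseResponseSeries("d", [1.0, 2.0, 4.0], [1.2, 0.5, 0.2])

    def test_too_few_distinct_doses(self):
        with pytest.raises(DegenerateFitError, match="3 distinct"):
            fit_median_effect(DoseResponseSeries("d", [1.0, 2.0], [0.6, 0.4]))

    def test_identical_fa_values_degenerate(self):
        with pytest.raises(DegenerateFitError, match="identical"):
            fit_median_effect(DoseResponseSeries("d", [1.0, 2.0, 4.0], [0.5, 0.5, 0.5]))

    def test_noisy_recovery_median_within_five_percent(self):
        """Median recovered Dm over 200 seeded replicates stays within 5% of
        truth at plate noise sigma = 0.02."""
        dms = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            s = model_series("d", 1.0, 1.0, noise=0.02, rng=rng)
            dms.append(fit_median_effect(s).dm)
        assert abs(float(np.median(dms)) - 1.0) <= 0.05


class TestCombinationIndex:
    FIT1 = MedianEffectFit("d1", dm=2.0, m=1.0, r=1.0, n_points=7)
    FIT2 = MedianEffectFit("d2", dm=4.0, m=1.0, r=1.0, n_points=7)

    def test_hand_computed_additive_point(self):
        res = combination_index(self.FIT1, self.FIT2, CombinationMeasurement(1.0, 2.0, 0.5))
        assert res.dx1 == pytest.approx(2.0)
        assert res.dx2 == pytest.approx(4.0)
        assert res.ci == pytest.approx(1.0)
        assert res.call == ADDITIVITY

    def test_halved_doses_give_synergy(self):
        res = combination_index(self.FIT1, self.FIT2, CombinationMeasurement(0.5, 1.0, 0.5))
        assert res.ci == pytest.approx(0.5)
        assert res.call == SYNERGY

    def test_doubled_doses_give_antagonism(self):
        res = combination_index(self.FIT1, self.FIT2, CombinationMeasurement(2.0, 4.0, 0.5))
        assert res.ci == pytest.approx(2.0)
        assert res.call == ANTAGONISM

    def test_symmetric_in_drug_order(self):
        obs = CombinationMeasurement(0.7, 1.3, 0.4)
        swapped = CombinationMeasurement(1.3, 0.7, 0.4)
        a = combination_index(self.FIT1, self.FIT2, obs)
        b = combination_index(self.FIT2, self.FIT1, swapped)
        assert a.ci == pytest.approx(b.ci)

    def test_ci_strictly_decreasing_in_fa(self):
        fas = np.linspace(0.1, 0.9, 9)
        cis = [
            combination_index(
                self.FIT1, self.FIT2, CombinationMeasurement(1.0, 2.0, fa)
            ).ci
            for fa in fas
        ]
        assert all(a > b for a, b in zip(cis, cis[1:]))

    def test_nonpositive_slope_rejected(self):
        bad = MedianEffectFit("d", dm=1.0, m=-0.5, r=1.0, n_points=5)
        with pytest.raises(InvalidFitError):
            combination_index(bad, self.FIT2, CombinationMeasurement(1.0, 1.0, 0.5))


class TestSynergyReport:
    def test_empty_combo_list_reports_ic50s_only(self):
        rep = synergy_report(model_series("a", 1.0, 1.0), model_series("b", 2.0, 1.5), [])
        assert rep.results == []
        assert rep.to_dict()["ic50"]["a"] == pytest.approx(1.0, rel=1e-9)
        assert rep.to_dict()["ic50"]["b"] == pytest.approx(2.0, rel=1e-9)

    def test_additive_construction_gives_unit_ci(self):
        """Dose pairs built to satisfy d1/Dx1 + d2/Dx2 = 1 come back with CI = 1."""
        s1, s2 = model_series("a", 1.0, 1.0), model_series("b", 4.0, 1.5)
        f1, f2 = fit_median_effect(s1), fit_median_effect(s2)
        combo = [
            CombinationMeasurement(0.4 * f1.dose_for_fa(fa), 0.6 * f2.dose_for_fa(fa), fa)
            for fa in (0.2, 0.5, 0.8)
        ]
        rep = synergy_report(s1, s2, combo)
        for r in rep.results:
            assert r.ci == pytest.approx(1.0, abs=1e-6)

    def test_fa_above_additive_expectation_gives_ci_below_one(self):
        s1, s2 = model_series("a", 1.0, 1.0), model_series("b", 4.0, 1.5)
        f1, f2 = fit_median_effect(s1), fit_median_effect(s2)
        combo = [
            CombinationMeasurement(
                0.5 * f1.dose_for_fa(fa), 0.5 * f2.dose_for_fa(fa), min(fa + 0.15, 0.99)
            )
            for fa in (0.2, 0.5, 0.8)
        ]
        rep = synergy_report(s1, s2, combo)
        assert all(r.ci < 1.0 for r in rep.results)

    def test_sham_combination_identity(self):
        """A drug combined with a relabelled copy of itself at half doses is
        exactly additive: CI = 1 at the observed single-agent effect."""
        s1 = model_series("a", 1.0, 1.3)
        s2 = DoseResponseSeries("a_copy", list(s1.doses), list(s1.viability))
        fit = fit_median_effect(s1)
        combo = [
            CombinationMeasurement(d / 2.0, d / 2.0, fit.fa_at(d)) for d in DOSES
        ]
        rep = synergy_report(s1, s2, combo)
        for r in rep.results:
            assert r.ci == pytest.approx(1.0, abs=1e-6)
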