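"""Raman quantification: baseline removal, normalization, band integration
against a dense-quadrature oracle, scoring, replicate statistics and
composition calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as hst

from pyrotex import raman as rq
from pyrotex import synthetic as syn
from pyrotex.exceptions import (
    BandWindowError,
    CannotNormalizeError,
    InsufficientDataError,
    SpectrumStateError,
)

W = np.arange(300.0, 1800.0, 1.0)


def _spectrum(intensity, state="raw", w=W):
    return rq.RamanSpectrum(wavenumber=w, intensity=np.asarray(intensity, float), state=state)


def _gaussian(center, sigma, w=W, area=1.0):
    return area * np.exp(-0.5 * ((w - center) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))


# ---------------------------------------------------------------------------
# baseline
# ---------------------------------------------------------------------------

class TestSubtractBaseline:
    def test_polynomial_background_removed(self):
        x = (W - 300) / 1000
        poly = 1 + 2 * x - 0.5 * x**2 + 0.2 * x**3
        out = rq.subtract_baseline(_spectrum(poly))
        assert np.max(np.abs(out.intensity)) < 0.01 * np.ptp(poly)
        assert out.state == "baseline_subtracted"
        assert out.baseline is not None

    def test_peak_area_preserved(self):
        x = (W - 300) / 1000
        poly = 1 + 2 * x - 0.5 * x**2 + 0.2 * x**3
        out = rq.subtract_baseline(_spectrum(poly + _gaussian(800, 5, area=0.5)))
        sel = (W > 770) & (W < 830)
        area = np.trapezoid(out.intensity[sel], W[sel])
        assert area == pytest.approx(0.5, rel=0.05)

    def test_zero_spectrum_stays_zero(self):
        out = rq.subtract_baseline(_spectrum(np.zeros(W.size)))
        assert np.allclose(out.intensity, 0.0, atol=1e-12)

    def test_short_spectrum_rejected(self):
        with pytest.raises(InsufficientDataError):
            rq.subtract_baseline(
                rq.RamanSpectrum(wavenumber=np.arange(10.0), intensity=np.ones(10))
            )

    def test_state_machine_enforced(self):
        done = rq.subtract_baseline(_spectrum(np.ones(W.size)))
        with pytest.raises(SpectrumStateError):
            rq.subtract_baseline(done)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

class TestNormalizeMean:
    def test_constant_becomes_unity(self):
        out = rq.normalize_mean(_spectrum(np.full(W.size, 4.2), state="baseline_subtracted"))
        assert np.allclose(out.intensity, 1.0)
        assert out.state == "normalized"

    @given(hst.floats(min_value=0.01, max_value=100.0))
    def test_gain_invariance(self, k):
        base = _gaussian(800, 10) + 0.1
        a = rq.normalize_mean(_spectrum(base, state="baseline_subtracted"))
        b = rq.normalize_mean(_spectrum(k * base, state="baseline_subtracted"))
        assert np.allclose(a.intensity, b.intensity, atol=1e-9)

    def test_mean_is_exactly_one(self):
        out = rq.normalize_mean(
            _spectrum(_gaussian(700, 8) + 0.05, state="baseline_subtracted")
        )
        assert np.mean(out.intensity) == pytest.approx(1.0, rel=1e-12)

    def test_replicates_differing_by_gain_collapse(self):
        base = _gaussian(500, 6) + _gaussian(1200, 8) + 0.2
        a = rq.normalize_mean(_spectrum(base, state="baseline_subtracted"))
        b = rq.normalize_mean(_spectrum(2.7 * base, state="baseline_subtracted"))
        assert np.max(np.abs(a.intensity - b.intensity)) < 1e-9

    def test_zero_spectrum_rejected(self):
        with pytest.raises(CannotNormalizeError):
            rq.normalize_mean(_spectrum(np.zeros(W.size), state="baseline_subtracted"))

    def test_raw_spectrum_rejected(self):
        with pytest.raises(SpectrumStateError):
            rq.normalize_mean(_spectrum(np.ones(W.size)))


# ---------------------------------------------------------------------------
# band integration
# ---------------------------------------------------------------------------

def _quadrature_oracle(center, sigma, half_width=1.0, offset=8.0, width=2.0):
    """Dense numerical quadrature of the analytic Gaussian minus its local
    linear background — fully independent of integrate_band."""
    def g(x):
        return np.exp(-0.5 * ((x - center) / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))

    fine = np.linspace(center - half_width, center + half_width, 40001)
    anchors = []
    for sgn in (-1, +1):
        xs = np.linspace(
            center + sgn * offset - width / 2, center + sgn * offset + width / 2, 4001
        )
        anchors.append(np.mean(g(xs)))
    bg = np.interp(
        fine, [center - offset, center + offset], anchors
    )
    return np.trapezoid(g(fine) - bg, fine)


class TestIntegrateBand:
    def test_flat_spectrum_zero(self):
        s = _spectrum(np.full(W.size, 3.0), state="normalized")
        assert rq.integrate_band(s, 380.0) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("sigma", [2.0, 3.0, 5.0, 7.0, 10.0])
    def test_matches_dense_quadrature(self, sigma):
        w = np.arange(300.0, 1800.0, 0.25)  # sampled finely vs the line width
        s = _spectrum(_gaussian(380, sigma, w=w), state="normalized", w=w)
        got = rq.integrate_band(s, 380.0)
        assert got == pytest.approx(_quadrature_oracle(380.0, sigma), rel=0.01)

    def test_linear_ramp_cancelled_by_local_background(self):
        base = _gaussian(380, 5)
        s0 = _spectrum(base, state="normalized")
        s1 = _spectrum(base + 0.01 * (W - 300.0), state="normalized")
        v0, v1 = rq.integrate_band(s0, 380.0), rq.integrate_band(s1, 380.0)
        assert v1 == pytest.approx(v0, rel=0.02)

    def test_out_of_range_names_band(self):
        s = _spectrum(np.ones(W.size), state="normalized")
        with pytest.raises(BandWindowError, match="305"):
            rq.integrate_band(s, 305.0)

    def test_requires_normalized_state(self):
        with pytest.raises(SpectrumStateError):
            rq.integrate_band(_spectrum(np.ones(W.size)), 380.0)


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------

class TestSpeciesScores:
    def test_cellulose_only_spectrum(self):
        table = rq.default_band_table()
        intensity = _gaussian(380, 4, area=0.5) + _gaussian(1100, 4, area=0.5)
        scores = {
            s.species: s.total_intensity
            for s in rq.species_scores(_spectrum(intensity, state="normalized"), table)
        }
        assert scores["cellulose"] > 0.01
        for sp in ("hemicellulose", "lignin", "resin"):
            assert abs(scores[sp]) < 0.1 * scores["cellulose"]

    def test_zero_spectrum_zero_scores(self):
        table = rq.default_band_table()
        for s in rq.species_scores(_spectrum(np.zeros(W.size), state="normalized"), table):
            assert s.total_intensity == pytest.approx(0.0, abs=1e-12)
            assert s.total_intensity == pytest.approx(sum(s.per_band.values()))

    def test_score_monotone_in_concentration(self):
        table = rq.default_band_table()
        prev = -np.inf
        for conc in (0.1, 0.2, 0.4, 0.6, 0.8):
            s, _ = syn.generate_spectrum(
                syn.SpectrumSpec(composition={"cellulose": conc})
            )
            s = rq.normalize_mean(rq.subtract_baseline(s))
            score = next(
                x.total_intensity
                for x in rq.species_scores(s, table)
                if x.species == "cellulose"
            )
            assert score > prev * 0.999  # degree-0 in gain, monotone ladder
            prev = score

    def test_gain_homogeneity_degree_zero(self):
        # overall acquisition gain must not change any species score
        table = rq.default_band_table()
        s, _ = syn.generate_spectrum(
            syn.SpectrumSpec(composition={"cellulose": 0.4, "lignin": 0.3})
        )
        s1 = rq.normalize_mean(rq.subtract_baseline(s))
        s2 = rq.normalize_mean(
            rq.subtract_baseline(
                rq.RamanSpectrum(wavenumber=s.wavenumber, intensity=5.0 * s.intensity)
            )
        )
        for a, b in zip(rq.species_scores(s1, table), rq.species_scores(s2, table)):
            assert a.total_intensity == pytest.approx(b.total_intensity, rel=1e-6, abs=1e-9)


class TestAggregateReplicates:
    def _scores(self, vals):
        return [
            [rq.SpeciesScore(sp, v, {}) for sp in rq.SPECIES]
            for v in vals
        ]

    def test_hand_arithmetic(self):
        agg = rq.aggregate_replicates(self._scores([2.0, 4.0, 6.0]))
        assert agg[0].total_intensity == pytest.approx(4.0)
        assert agg[0].se == pytest.approx(2.0 / np.sqrt(3))
        assert agg[0].n_replicates == 3

    def test_identical_replicates_zero_se(self):
        agg = rq.aggregate_replicates(self._scores([3.0, 3.0, 3.0, 3.0]))
        assert agg[0].se == 0.0

    def test_single_replicate_se_absent(self):
        agg = rq.aggregate_replicates(self._scores([5.0]))
        assert agg[0].total_intensity == 5.0
        assert agg[0].se is None

    def test_permutation_invariance(self):
        a = rq.aggregate_replicates(self._scores([1.0, 5.0, 2.5, 4.0]))
        b = rq.aggregate_replicates(self._scores([4.0, 1.0, 2.5, 5.0]))
        assert a[0].total_intensity == b[0].total_intensity
        assert a[0].se == b[0].se

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            rq.aggregate_replicates([])


# ---------------------------------------------------------------------------
# calibration and estimation
# ---------------------------------------------------------------------------

def _frame(rows):
    return pd.DataFrame(rows, index=pd.Index(list(rows.keys()), name="fraction")).T


class TestCalibrate:
    def test_exact_proportionality(self):
        ref = syn.REFERENCE_COMPOSITION
        scores = ref * 3.0  # score = 3 x mass fraction
        model = rq.calibrate(scores, ref)
        for sp in rq.SPECIES:
            assert model.slope[sp] == pytest.approx(1 / 3.0)
            assert model.intercept[sp] == pytest.approx(0.0, abs=1e-12)
            assert model.goodness[sp] == pytest.approx(1.0)

    def test_anticorrelated_scores_warn(self):
        ref = syn.REFERENCE_COMPOSITION
        scores = -2.0 * ref + 1.0
        with pytest.warns(UserWarning, match="anti-correlated"):
            model = rq.calibrate(scores, ref)
        assert all(v < 0 for v in model.goodness.values())

    def test_too_few_fractions_rejected(self):
        ref = syn.REFERENCE_COMPOSITION.iloc[:2]
        with pytest.raises(InsufficientDataError):
            rq.calibrate(ref * 2.0, ref)


class TestEstimateHeatedComposition:
    def _model(self):
        ref = syn.REFERENCE_COMPOSITION
        return rq.calibrate(ref * 2.0, ref), ref

    def test_ambient_score_maps_to_calibration_line(self):
        model, ref = self._model()
        est = rq.estimate_heated_composition(model, ref.loc[["cambium"]] * 2.0)
        for sp in rq.SPECIES:
            assert est.loc["cambium", sp] == pytest.approx(ref.loc["cambium", sp])

    def test_zero_score_gives_intercept(self):
        model, ref = self._model()
        zero = ref.loc[["bark"]] * 0.0
        est = rq.estimate_heated_composition(model, zero)
        for sp in rq.SPECIES:
            assert est.loc["bark", sp] == pytest.approx(model.intercept[sp])

    def test_se_propagated_with_slope(self):
        model, ref = self._model()
        se = ref.loc[["bark"]] * 0.0 + 0.1
        est = rq.estimate_heated_composition(model, ref.loc[["bark"]] * 2.0, score_se=se)
        for sp in rq.SPECIES:
            assert est.loc["bark", f"{sp}_se"] == pytest.approx(abs(model.slope[sp]) * 0.1)

    def test_missing_species_rejected(self):
        model, ref = self._model()
        del model.slope["resin"]
        with pytest.raises(KeyError):
            rq.estimate_heated_composition(model, ref * 2.0)

    def test_estimates_below_reference_not_clipped(self):
        model, ref = self._model()
        tiny = ref * 2.0 * 0.1  # heavily degraded scores
        est = rq.estimate_heated_composition(model, tiny)
        assert (est["cellulose"] < ref["cellulose"]).all()
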