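"""GC-MS fatty-acid quantification and 13C isotopologue correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as hst

import lipidhet as lh
from lipidhet.fame import FattyAcidPanel, IsotopologueVector, NATURAL_13C


def panel(counts: dict, normalizer=0.5):
    ion = pd.DataFrame(counts, index=["s1"])
    return FattyAcidPanel(
        ion_counts=ion, normalizer=pd.Series(normalizer, index=ion.index))


BASE = {"palmitate": 100.0, "palmitoleate": 50.0, "sapienate": 25.0,
        "heptadecanoate": 1000.0}


def test_desaturation_index_arithmetic():
    """Palmitoleate 50 / palmitate 100 -> SCD index 0.5; sapienate gives 0.25."""
    out = lh.desaturation_indices(panel(BASE))
    assert out.loc["s1", "scd_index"] == pytest.approx(0.5)
    assert out.loc["s1", "fads2_index"] == pytest.approx(0.25)


def test_normalized_abundance_worked_example():
    """2000 counts / 1000 IS counts / 0.5 mg protein -> 4.0 per mg."""
    counts = dict(BASE, palmitate=2000.0)
    out = lh.desaturation_indices(panel(counts, normalizer=0.5))
    assert out.loc["s1", "norm_palmitate"] == pytest.approx(4.0)


def test_ratio_identical_on_raw_and_normalized_counts():
    """IS/protein normalization cancels in the desaturation ratio."""
    out = lh.desaturation_indices(panel(BASE, normalizer=0.77))
    ratio_norm = out.loc["s1", "norm_palmitoleate"] / out.loc["s1", "norm_palmitate"]
    assert out.loc["s1", "scd_index"] == pytest.approx(ratio_norm, rel=1e-12)


def test_missing_channel_and_zero_palmitate_error():
    with pytest.raises(KeyError, match="sapienate"):
        lh.desaturation_indices(panel({k: v for k, v in BASE.items()
                                       if k != "sapienate"}))
    with pytest.raises(ValueError, match="palmitate"):
        lh.desaturation_indices(panel(dict(BASE, palmitate=0.0)))


def test_standard_curve_linear_inversion():
    """Curve through (0,0) and (10,100): response 50 -> 5 ug."""
    curve = lh.fit_standard_curve([0.0, 10.0], [0.0, 100.0])
    conc = lh.absolute_quantification(curve, 50.0, molecular_weight=1.0,
                                      extracted_volume_ul=1.0)
    assert conc == pytest.approx(5.0 * 1e6)  # 5 ug at MW 1, 1 uL


def test_unit_conversion_palmitate():
    """1 ug palmitate (MW 256.4) in 20 uL -> 195.0 uM."""
    curve = lh.fit_standard_curve([0.0, 2.0], [0.0, 2.0])
    conc = lh.absolute_quantification(curve, 1.0, molecular_weight=256.4)
    assert conc == pytest.approx(1e-6 / 256.4 / 20e-6 * 1e6, rel=1e-12)
    assert conc == pytest.approx(195.0, abs=0.05)


def test_response_at_intercept_and_below():
    curve = lh.fit_standard_curve([0.0, 1.0], [10.0, 20.0])
    assert lh.absolute_quantification(curve, 10.0, 256.4) == 0.0
    with pytest.warns(UserWarning, match="clamped"):
        assert lh.absolute_quantification(curve, 5.0, 256.4) == 0.0


def test_correction_matrix_identity_at_zero_abundance():
    M = lh.correction_matrix(4, 0.0)
    np.testing.assert_allclose(M, np.eye(5))


@given(hst.integers(min_value=1, max_value=24),
       hst.floats(min_value=0.0, max_value=0.5))
def test_correction_matrix_columns_conserve_probability(n, p):
    M = lh.correction_matrix(n, p)
    np.testing.assert_allclose(M.sum(axis=0), 1.0, atol=1e-12)
    assert (M >= 0).all()


def test_unlabeled_two_carbon_species_corrects_to_m0():
    p = 0.05
    raw = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    vec = IsotopologueVector("acetyl", 2, raw)
    x = lh.natural_abundance_correction(vec, p13c=p)
    np.testing.assert_allclose(x, [1.0, 0.0, 0.0], atol=1e-10)


def test_correction_with_p_zero_returns_raw_fractions():
    raw = np.array([3.0, 1.0, 0.0, 1.0])
    vec = IsotopologueVector("x", 3, raw)
    x = lh.natural_abundance_correction(vec, p13c=0.0)
    np.testing.assert_allclose(x, raw / raw.sum(), atol=1e-12)


def test_all_zero_spectrum_errors():
    with pytest.raises(ValueError, match="all-zero"):
        lh.natural_abundance_correction(IsotopologueVector("x", 2, [0, 0, 0]))


def test_fractional_contribution_limit_cases():
    assert lh.fractional_contribution(np.array([0.0, 0.0, 1.0])) == 1.0
    assert lh.fractional_contribution(np.array([0.5, 0.5, 0.0])) == pytest.approx(0.25)


@given(hst.floats(min_value=0.1, max_value=1000.0))
def test_fractional_contribution_scale_invariant(scale):
    x = np.array([0.2, 0.3, 0.1, 0.4])
    assert lh.fractional_contribution(x * scale) == pytest.approx(
        lh.fractional_contribution(x), rel=1e-12)


def test_noise_free_simulator_round_trip():
    """Correction inverts the simulated natural-abundance convolution."""
    fc = {"palmitate": 0.35, "sapienate": 0.6}
    carbons = {"palmitate": 16, "sapienate": 16}
    spectra, _, _, truth = lh.simulate_tracer_panel(
        fc, carbons, noise_cv=0.0, seed=0)
    for (sp, _), vec in spectra.items():
        x = lh.natural_abundance_correction(vec)
        np.testing.assert_allclose(x, truth.label_distributions[sp], atol=1e-8)
        assert lh.fractional_contribution(x) == pytest.approx(fc[sp], abs=1e-8)


def test_natural_abundance_m1_ratio_closed_form():
    """Unlabeled palmitate: M+1/M+0 = 16 p / (1 - p) by binomial construction."""
    spectra, _, _, _ = lh.simulate_tracer_panel(
        {"palmitate": 0.0}, {"palmitate": 16}, noise_cv=0.0, seed=0)
    raw = spectra[("palmitate", 0)].intensities
    p = NATURAL_13C
    assert raw[1] / raw[0] == pytest.approx(16 * p / (1 - p), rel=1e-10)


def test_fully_labeled_two_carbon_limit():
    """FC = 1 with no natural abundance: all signal in the top isotopologue."""
    spectra, _, _, _ = lh.simulate_tracer_panel(
        {"unit": 1.0}, {"unit": 2}, natural_13c=0.0, noise_cv=0.0, seed=0)
    raw = spectra[("unit", 0)].intensities
    np.testing.assert_allclose(raw / raw.sum(), [0.0, 0.0, 1.0], atol=1e-12)
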