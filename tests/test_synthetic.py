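"""Synthetic SERS generator: band placement, variability calibration,
non-linear mixing, and the split protocol."""

import numpy as np
import pytest
from scipy.signal import argrelmax

from sersmix.spectra import CATEGORIES
from sersmix.synthetic import (
    BaselineConfig,
    GeneratorConfig,
    PeakLibrary,
    component_profile,
    default_libraries,
    default_sizes,
    generate_dataset,
    generate_mixture,
    generate_pure,
    iter_dataset,
)

PARAQUAT_BANDS = [840, 1029, 1190, 1298, 1646, 1766]


def test_single_peak_profile_argmax(gen_config):
    lib = PeakLibrary("A", [(840.0, 1.0, 10.0)])
    s = component_profile(lib, gen_config)
    assert s.wavenumber[s.intensity.argmax()] == pytest.approx(840.0, abs=gen_config.axis_step)
    assert s.intensity.max() == pytest.approx(gen_config.enhancement["A"])


def test_empty_library_rejected():
    with pytest.raises(ValueError, match="empty"):
        PeakLibrary("A", [])


def test_library_invariants():
    with pytest.raises(ValueError, match="increasing"):
        PeakLibrary("A", [(900.0, 1.0, 10.0), (840.0, 0.5, 10.0)])
    with pytest.raises(ValueError, match="reference"):
        PeakLibrary("A", [(840.0, 0.5, 10.0)])
    with pytest.raises(ValueError, match="400"):
        PeakLibrary("A", [(300.0, 1.0, 10.0)])


def test_peak_outside_axis_named_in_error():
    cfg = GeneratorConfig(seed=0, axis_start=450.0)
    lib = PeakLibrary("B", [(440.0, 1.0, 10.0)], )
    # library passes global bounds but not this axis
    with pytest.raises(ValueError, match="440"):
        component_profile(lib, cfg)


def test_paraquat_profile_has_local_maxima_at_reference_bands(gen_config):
    s = component_profile(gen_config.libraries["A"], gen_config)
    peaks = s.wavenumber[argrelmax(s.intensity, order=3)[0]]
    for band in PARAQUAT_BANDS:
        assert np.min(np.abs(peaks - band)) <= gen_config.axis_step


def test_generate_pure_deterministic(gen_config):
    a = generate_pure("A", 3, gen_config)
    b = generate_pure("A", 3, gen_config)
    for s1, s2 in zip(a, b):
        np.testing.assert_array_equal(s1.intensity, s2.intensity)


def test_generate_pure_rejects_bad_args(gen_config):
    with pytest.raises(ValueError):
        generate_pure("X", 1, gen_config)
    with pytest.raises(ValueError):
        generate_pure("A", 0, gen_config)


def test_zero_jitter_pure_equals_profile():
    cfg = GeneratorConfig(
        seed=3, amplitude_jitter_rsd=0.0, shift_jitter=0.0, noise_sd=0.0,
        baseline=BaselineConfig(poly_coeff_range=0.0, hump_amplitude=(0.0, 0.0)),
    )
    profile = component_profile(cfg.libraries["B"], cfg)
    for s in generate_pure("B", 2, cfg):
        np.testing.assert_allclose(s.intensity, profile.intensity, atol=1e-12)


def test_reference_peak_rsd_calibration():
    """Over >=100 replicates the reference-band RSD tracks the configured
    amplitude jitter (8%) within +/-30% relative."""
    cfg = GeneratorConfig(
        seed=11, noise_sd=1e-4,
        baseline=BaselineConfig(poly_coeff_range=0.0, hump_amplitude=(0.0, 0.0)),
    )
    spectra = generate_pure("B", 120, cfg)
    ref = 1380.0
    window = (spectra[0].wavenumber > ref - 6) & (spectra[0].wavenumber < ref + 6)
    heights = np.array([s.intensity[window].max() for s in spectra])
    rsd = heights.std(ddof=1) / heights.mean()
    assert 0.7 * cfg.amplitude_jitter_rsd <= rsd <= 1.3 * cfg.amplitude_jitter_rsd


def test_linear_mixing_limit_exact():
    cfg = GeneratorConfig(
        seed=5, amplitude_jitter_rsd=0.0, shift_jitter=0.0, noise_sd=0.0,
        masking_strength=0.0,
        baseline=BaselineConfig(poly_coeff_range=0.0, hump_amplitude=(0.0, 0.0)),
    )
    pa = component_profile(cfg.libraries["A"], cfg).intensity
    pc = component_profile(cfg.libraries["C"], cfg).intensity
    m = generate_mixture(["A", "C"], [0.4, 0.6], cfg)
    np.testing.assert_allclose(m.intensity, 0.4 * pa + 0.6 * pc, atol=1e-12)


def test_masking_suppresses_weak_component_band():
    """With dominant paraquat and strong masking, the tricyclazole-only band
    at 988 cm^-1 drops below its linear-superposition height."""
    base = dict(
        seed=5, amplitude_jitter_rsd=0.0, shift_jitter=0.0, noise_sd=0.0,
        baseline=BaselineConfig(poly_coeff_range=0.0, hump_amplitude=(0.0, 0.0)),
    )
    lin = generate_mixture(["A", "C"], [0.5, 0.5], GeneratorConfig(masking_strength=0.0, **base))
    masked = generate_mixture(["A", "C"], [0.5, 0.5], GeneratorConfig(masking_strength=0.95, **base))
    w = lin.wavenumber
    sel = (w > 982) & (w < 994)
    assert masked.intensity[sel].max() < lin.intensity[sel].max()


def test_zero_weight_mixture_matches_pure_realisation(gen_config):
    """Weights (1, 0) over {A, B} reproduce the pure-A replicate drawn from
    the same seed path."""
    pure = generate_pure("A", 1, gen_config, start_index=7)[0]
    mix = generate_mixture(["A", "B"], [1.0, 0.0], gen_config, index=7)
    np.testing.assert_allclose(mix.intensity, pure.intensity, atol=1e-12)


def test_generate_mixture_validates_inputs(gen_config):
    with pytest.raises(ValueError):
        generate_mixture(["A"], [1.0], gen_config)
    with pytest.raises(ValueError):
        generate_mixture(["A", "B"], [0.5, -0.1], gen_config)
    with pytest.raises(ValueError):
        generate_mixture(["A", "B"], [0.0, 0.0], gen_config)


def test_default_split_sizes_match_protocol():
    sizes = default_sizes()
    assert sizes["train"] == {"A": 157, "B": 215, "C": 220}
    assert all(sizes["val"][c] == 50 for c in CATEGORIES)
    assert all(sizes["test"][c] == 53 for c in CATEGORIES)


def test_mixture_in_train_split_rejected(gen_config):
    sizes = {"train": {"A": 1, "AB": 1}}
    with pytest.raises(ValueError, match="protocol violation"):
        list(iter_dataset(gen_config, sizes))


def test_dataset_manifest_counts_and_determinism(tmp_path, gen_config):
    sizes = {"train": {"A": 3, "B": 2, "C": 2},
             "val": {c: 1 for c in CATEGORIES},
             "test": {"AB": 2}}
    m1 = generate_dataset(gen_config, tmp_path / "d1", sizes)
    assert len(m1.subset(split="train")) == 7
    assert len(m1.subset(split="val")) == 7
    assert len(m1.subset(split="test", category="AB")) == 2
    # bit-identical regeneration from the same config + seed
    first = list(iter_dataset(gen_config, sizes))
    second = list(iter_dataset(gen_config, sizes))
    for (s1, *_), (s2, *_) in zip(first, second):
        np.testing.assert_array_equal(s1.intensity, s2.intensity)


def test_libraries_match_reference_band_positions():
    libs = default_libraries(seed=0)
    assert [p[0] for p in libs["A"].peaks] == [840, 1029, 1190, 1298, 1646, 1766]
    assert [p[0] for p in libs["B"].peaks] == [560, 932, 1380, 1512]
    assert [p[0] for p in libs["C"].peaks] == [596, 988, 1000, 1090, 1193, 1303, 1403, 1420, 1589]
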