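"""Synthetic study generator: design counts, calibration, determinism, noise."""

import numpy as np
import pytest
from dataclasses import replace

from ebis.cole import FrequencyGrid
from ebis.errors import ValidationError
from ebis.features import extract_features
from ebis.simulate import (
    DamageEffect,
    GeneratorConfig,
    add_noise,
    generate_study,
    sample_subject,
)


def quiet_config(**kwargs):
    """A config with every randomness source silenced, for exact constructions."""
    base = dict(
        subject_sigma_r=0.0,
        subject_sigma_alpha=0.0,
        subject_sigma_fc=0.0,
        hemisphere_sigma=0.0,
        healthy_ratio_sigma=0.0,
        noise_sigma=0.0,
    )
    base.update(kwargs)
    return GeneratorConfig(**base)


def true_features(profile, hemisphere):
    return extract_features(
        profile.params[(hemisphere, "central")], profile.params[(hemisphere, "lateral")]
    )


class TestSubjectProfiles:
    def test_healthy_subject_with_zero_ratio_noise_is_exactly_symmetric(self):
        profile = sample_subject(quiet_config(), 0)
        for hemi in ("left", "right"):
            v = true_features(profile, hemi)
            assert (v.f1, v.f2, v.f3) == (1.0, 1.0, 1.0)
        assert profile.stroke_hemisphere is None

    def test_damage_effects_realised_exactly_without_noise(self):
        cfg = quiet_config(
            damage_effects=(DamageEffect(f1_shift=1.0, f2_shift=1.5, f3_shift=0.3),)
        )
        profile = sample_subject(cfg, cfg.n_healthy_subjects)  # first patient
        assert profile.stroke_hemisphere == "left"
        v = true_features(profile, "left")
        assert v.f2 == pytest.approx(1.5, rel=1e-12)
        assert v.f3 == pytest.approx(0.3, rel=1e-9)
        # the phase-ratio target forces an enlarged central dispersion,
        # so the realised f1 sits above its configured floor
        assert v.f1 >= 1.0
        sound = true_features(profile, "right")
        assert (sound.f1, sound.f2, sound.f3) == (1.0, 1.0, 1.0)

    def test_solvable_phase_target_without_r0_enlargement(self):
        cfg = quiet_config(
            damage_effects=(DamageEffect(f1_shift=1.0, f2_shift=1.0, f3_shift=0.9),)
        )
        v = true_features(sample_subject(cfg, cfg.n_healthy_subjects), "left")
        assert v.f1 == pytest.approx(1.0, rel=1e-12)  # alpha alone suffices
        assert v.f3 == pytest.approx(0.9, rel=1e-9)

    def test_fixed_seed_reproduces_profile(self):
        cfg = GeneratorConfig(seed=7)
        assert sample_subject(cfg, 3) == sample_subject(cfg, 3)

    def test_profiles_invariant_to_cohort_size(self):
        a = GeneratorConfig(seed=7, n_patients=3)
        b = GeneratorConfig(seed=7, n_patients=0)
        for i in range(a.n_healthy_subjects):
            assert sample_subject(a, i) == sample_subject(b, i)


class TestGenerateStudy:
    def test_default_design_counts(self, default_study):
        spectra = default_study.spectra
        assert len(spectra) == 720
        assert sum(s.meta.label == "damaged" for s in spectra) == 120
        assert sum(s.meta.label == "healthy" for s in spectra) == 600
        assert sum(s.meta.electrode_set == "central" for s in spectra) == 360
        assert all(len(s.grid) == 256 for s in spectra)
        assert len(default_study.profiles) == 9

    def test_single_repeat_gives_36_spectra(self):
        ds = generate_study(GeneratorConfig(repeats_per_set=1))
        assert len(ds.spectra) == 36

    def test_damaged_count_scales_with_patients(self):
        # 2 patients x 1 stroke hemisphere x 2 montages x 2 repeats
        ds = generate_study(GeneratorConfig(n_patients=2, repeats_per_set=2))
        assert sum(s.meta.label == "damaged" for s in ds.spectra) == 2 * 2 * 2

    def test_same_seed_is_byte_identical(self, tmp_path):
        from ebis.io import write_spectra

        cfg = GeneratorConfig(seed=11, repeats_per_set=2)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_spectra(generate_study(cfg), p1)
        write_spectra(generate_study(cfg), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seeds_differ(self):
        a = generate_study(GeneratorConfig(seed=1, repeats_per_set=1))
        b = generate_study(GeneratorConfig(seed=2, repeats_per_set=1))
        assert not np.allclose(a.spectra[0].resistance, b.spectra[0].resistance)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValidationError):
            GeneratorConfig(repeats_per_set=0)
        with pytest.raises(ValidationError):
            GeneratorConfig(noise_sigma=-0.1)


class TestNoise:
    def test_zero_sigma_is_identity(self, default_study, rng):
        s = default_study.spectra[0]
        assert add_noise(s, 0.0, rng) is s

    def test_negative_sigma_rejected(self, default_study, rng):
        with pytest.raises(ValidationError):
            add_noise(default_study.spectra[0], -0.01, rng)

    def test_empirical_sd_matches_prescription(self, rng):
        from ebis.cole import ColeParameters, ImpedanceSpectrum, cole_impedance

        grid = FrequencyGrid(np.array([3e4]))
        z = cole_impedance(ColeParameters(100.0, 50.0, 0.8, 3e4), grid)
        clean = ImpedanceSpectrum(grid, z.real, z.imag)
        sigma = 0.01
        draws = np.array(
            [add_noise(clean, sigma, rng).resistance[0] for _ in range(1000)]
        )
        expected_sd = sigma * abs(z[0])
        assert np.std(draws) == pytest.approx(expected_sd, rel=0.10)

    def test_fixed_seed_reproducible(self, default_study):
        s = default_study.spectra[0]
        a = add_noise(s, 0.01, np.random.default_rng(5))
        b = add_noise(s, 0.01, np.random.default_rng(5))
        assert np.array_equal(a.resistance, b.resistance)
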