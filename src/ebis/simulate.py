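"""Seeded synthetic EBIS study generator.

Emulates the measurement design the analysis pipeline expects: a cohort of
healthy subjects plus unilateral-stroke patients, two electrode montages
(central, lateral) per hemisphere, a fixed number of consecutive repeats per
montage, and a log-spaced frequency sweep.  Healthy hemispheres have
near-identical central and lateral Cole parameters (ratio features cluster
at one); a patient's stroke hemisphere has its central-montage parameters
shifted so the three ratio features separate from the healthy cluster.

Damage is injected at the feature-ratio level, not via a biophysical lesion
model: the r0 and r_inf ratios are set directly by multiplicative effects,
and the mid-band phase-ratio feature f3 is steered through the dispersion
exponent alpha.  Because the Cole model gives Rc/Xc =
(r0 + r_inf) / ((r0 - r_inf) * tan(alpha*pi/4)) with alpha capped at 1, a
strong downward f3 shift cannot come from alpha alone: the generator then
enlarges the central dispersion (raises r0, keeping r_inf/r0 above a
fit-stability floor) and, if even that falls short, deepens the lateral
dispersion shape (lowers the lateral alpha) until the requested ratio is
realised exactly.

All randomness flows from a single integer seed, expanded into per-subject
substreams, so a subject's data are invariant to cohort-size changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .cole import (
    ColeParameters,
    FrequencyGrid,
    ImpedanceSpectrum,
    MeasurementMeta,
    add_parallel_capacitance,
    cole_impedance,
)
from .errors import ValidationError

__all__ = [
    "DamageEffect",
    "GeneratorConfig",
    "SubjectProfile",
    "Dataset",
    "sample_subject",
    "generate_study",
    "add_noise",
]


@dataclass(frozen=True)
class DamageEffect:
    """Multiplicative feature shifts applied to a stroke hemisphere.

    ``f1_shift`` and ``f2_shift`` multiply the central/lateral r0 and r_inf
    ratios; ``f3_shift`` (optional) is the target multiplier on the Rc/Xc
    phase ratio, realised by adjusting the central alpha.  Because alpha is
    capped at 1, a strong downward phase-ratio target may additionally
    require enlarging the central dispersion — the central r0 is raised
    above ``f1_shift`` (which then acts as a floor on the realised r0
    ratio) — and, in shallow-dispersion subjects, a slight deepening of the
    lateral dispersion shape, after which the target holds exactly.
    """

    f1_shift: float = 1.0
    f2_shift: float = 1.0
    f3_shift: Optional[float] = None

    def __post_init__(self) -> None:
        if self.f1_shift <= 0 or self.f2_shift <= 0:
            raise ValidationError("feature shifts must be positive")
        if self.f3_shift is not None and self.f3_shift <= 0:
            raise ValidationError("f3_shift must be positive or None")


#: Default per-patient damage effects.  Chosen so that, under the default
#: decision tree, patients 1 and 3 exit at the phase-ratio node (f3 < 0.4)
#: and patient 2 at the final r0-ratio split (f1 < 0.9), with every patient's
#: f2 held above the first node's healthy exit — each node is exercised.
#: A collapsed phase ratio forces a much-enlarged central dispersion
#: (small r_inf/r0), so the realised r0 ratios of the f3-target patients
#: land well above their configured floors.
DEFAULT_DAMAGE_EFFECTS: Tuple[DamageEffect, ...] = (
    DamageEffect(f1_shift=1.50, f2_shift=1.15, f3_shift=0.33),
    DamageEffect(f1_shift=0.70, f2_shift=1.30, f3_shift=None),
    DamageEffect(f1_shift=1.50, f2_shift=1.20, f3_shift=0.35),
)

#: Stroke side per patient, cycling two left / one right.
STROKE_SIDES = ("left", "left", "right")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design and noise parameters of the synthetic cohort.

    The cohort defaults mirror the measurement design the pipeline targets:
    6 healthy subjects + 3 unilateral-stroke patients, 2 montages x 20
    repeats per hemisphere, 256-point log sweep (3.096 kHz - 1 MHz), for
    720 spectra in total.  The Cole template (r0 = 100 ohm, r_inf = 40 ohm,
    alpha = 0.75, fc = 35 kHz) is an arbitrary but physiologically plausible
    head-measurement scale; with alpha around 0.75 both resistance limits
    are well constrained by the sweep, so fitted ratio features resolve
    sub-percent asymmetries.
    """

    n_healthy_subjects: int = 6
    n_patients: int = 3
    repeats_per_set: int = 20
    grid: FrequencyGrid = field(default_factory=FrequencyGrid.default)
    base_r0: float = 100.0
    base_r_inf: float = 40.0
    base_alpha: float = 0.75
    base_fc: float = 35e3
    subject_sigma_r: float = 0.08  # log-sd of subject-level r0, r_inf multipliers
    subject_sigma_alpha: float = 0.05
    subject_sigma_fc: float = 0.10
    hemisphere_sigma: float = 0.02  # log-sd of left/right asymmetry
    healthy_ratio_sigma: float = 0.005  # log-sd of central/lateral ratios
    damage_effects: Tuple[DamageEffect, ...] = DEFAULT_DAMAGE_EFFECTS
    noise_sigma: float = 0.005  # relative measurement noise on R and X
    stray_capacitance: float = 0.0  # farad, applied to every spectrum
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_healthy_subjects < 1 or self.n_patients < 0:
            raise ValidationError("need >= 1 healthy subject and >= 0 patients")
        if self.repeats_per_set < 1:
            raise ValidationError("repeats_per_set must be >= 1")
        for name in (
            "subject_sigma_r",
            "subject_sigma_alpha",
            "subject_sigma_fc",
            "hemisphere_sigma",
            "healthy_ratio_sigma",
            "noise_sigma",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.stray_capacitance < 0:
            raise ValidationError("stray_capacitance must be >= 0")
        if self.n_patients > 0 and len(self.damage_effects) == 0:
            raise ValidationError("patients require at least one damage effect")

    @property
    def n_subjects(self) -> int:
        return self.n_healthy_subjects + self.n_patients


@dataclass(frozen=True)
class SubjectProfile:
    """Ground truth for one subject: role and true per-montage Cole parameters."""

    subject_id: str
    stroke_hemisphere: Optional[str]  # None for healthy subjects
    params: Dict[Tuple[str, str], ColeParameters]  # (hemisphere, set) -> truth


@dataclass(frozen=True)
class Dataset:
    """A generated study: spectra with metadata plus the generating profiles."""

    spectra: List[ImpedanceSpectrum]
    profiles: List[SubjectProfile]


def _phase_ratio(p: ColeParameters) -> float:
    """Rc/Xc of the Cole model at its characteristic frequency (closed form)."""
    return (p.r0 + p.r_inf) / (p.delta_r * math.tan(p.alpha * math.pi / 4.0))


def _alpha_for_phase_ratio(
    r0: float, r_inf: float, target_ratio: float, alpha_floor: float = 0.05
) -> float:
    """Alpha giving Rc/Xc == target_ratio for fixed r0, r_inf, clipped to range.

    Inverts Rc/Xc = (r0 + r_inf)/((r0 - r_inf) tan(alpha pi/4)); when the
    target is unreachable (it would need alpha > 1 or below the floor) the
    nearest admissible alpha is returned.
    """
    t = (r0 + r_inf) / ((r0 - r_inf) * target_ratio)
    alpha = (4.0 / math.pi) * math.atan(t)
    return min(max(alpha, alpha_floor), 1.0)


#: Smallest r_inf/r0 ratio the generator will impose when enlarging a
#: damaged central dispersion to realise a phase-ratio target.  Much below
#: this the high-frequency resistance limit is no longer well constrained
#: by the 1 MHz sweep and fitted r_inf ratios become unusably noisy.
_RHO_FLOOR = 0.06


def _alpha_for_tan(t: float) -> float:
    """Alpha whose quarter-circle tangent tan(alpha*pi/4) equals t."""
    return (4.0 / math.pi) * math.atan(t)


def _apply_phase_target(
    r0: float, r_inf: float, target_ratio: float
) -> Tuple[float, float]:
    """Realise Rc/Xc == target_ratio, returning (r0, alpha).

    First tries alpha alone; if the target needs alpha > 1, the dispersion
    is enlarged instead: with alpha pinned at 1, r0 is raised until
    (r0 + r_inf)/(r0 - r_inf) equals the target (subject to the r_inf/r0
    floor), after which the target holds by construction.
    """
    alpha = _alpha_for_phase_ratio(r0, r_inf, target_ratio)
    if (r0 + r_inf) / ((r0 - r_inf) * 1.0) > target_ratio:
        # even alpha = 1 leaves Rc/Xc above target: enlarge the dispersion
        if target_ratio > 1.0:
            rho = (target_ratio - 1.0) / (target_ratio + 1.0)
        else:
            rho = _RHO_FLOOR
        rho = max(rho, _RHO_FLOOR)
        r0 = max(r0, r_inf / rho)
        alpha = _alpha_for_phase_ratio(r0, r_inf, target_ratio)
    return r0, alpha


def _subject_rng(config: GeneratorConfig, index: int, stream: int) -> np.random.Generator:
    """Independent substream for (subject, purpose); purpose 0 = profile, 1 = noise."""
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(index, stream))
    return np.random.Generator(np.random.PCG64(ss))


def _lognormal_factor(rng: np.random.Generator, sigma: float) -> float:
    return float(np.exp(rng.normal(0.0, sigma))) if sigma > 0 else 1.0


def sample_subject(config: GeneratorConfig, index: int) -> SubjectProfile:
    """Draw the ground-truth Cole parameters of subject ``index``.

    Indices ``0 .. n_healthy_subjects-1`` are healthy (ids H01, H02, ...);
    the rest are patients (ids P01, ...) whose stroke hemisphere's central
    parameters receive the configured damage effect.  Uses a dedicated
    per-subject substream, so the profile does not depend on cohort size.
    """
    if not (0 <= index < config.n_subjects):
        raise ValidationError(f"subject index {index} out of range")
    rng = _subject_rng(config, index, stream=0)

    is_patient = index >= config.n_healthy_subjects
    if is_patient:
        k = index - config.n_healthy_subjects
        subject_id = f"P{k + 1:02d}"
        stroke = STROKE_SIDES[k % len(STROKE_SIDES)]
        effect = config.damage_effects[k % len(config.damage_effects)]
    else:
        subject_id = f"H{index + 1:02d}"
        stroke = None
        effect = None

    # subject-level Cole template
    r0_s = config.base_r0 * _lognormal_factor(rng, config.subject_sigma_r)
    rinf_s = config.base_r_inf * _lognormal_factor(rng, config.subject_sigma_r)
    alpha_s = min(
        max(config.base_alpha * _lognormal_factor(rng, config.subject_sigma_alpha), 0.05),
        0.95,
    )
    fc_s = config.base_fc * _lognormal_factor(rng, config.subject_sigma_fc)

    params: Dict[Tuple[str, str], ColeParameters] = {}
    for hemisphere in ("left", "right"):
        # mild left/right asymmetry shared by both montages of the hemisphere
        r0_h = r0_s * _lognormal_factor(rng, config.hemisphere_sigma)
        rinf_h = rinf_s * _lognormal_factor(rng, config.hemisphere_sigma)
        fc_h = fc_s * _lognormal_factor(rng, config.hemisphere_sigma)
        lateral = ColeParameters(r0=r0_h, r_inf=rinf_h, alpha=alpha_s, fc=fc_h)
        params[(hemisphere, "lateral")] = lateral

        # central montage: near-unity ratios for healthy tissue
        s = config.healthy_ratio_sigma
        r0_c = lateral.r0 * _lognormal_factor(rng, s)
        rinf_c = lateral.r_inf * _lognormal_factor(rng, s)
        alpha_c = min(max(lateral.alpha * _lognormal_factor(rng, s), 0.05), 1.0)
        fc_c = lateral.fc * _lognormal_factor(rng, s)

        if effect is not None and hemisphere == stroke:
            r0_c *= effect.f1_shift
            rinf_c *= effect.f2_shift
            if rinf_c >= 0.95 * r0_c:  # keep the ordering invariant intact
                rinf_c = 0.95 * r0_c
            if effect.f3_shift is not None:
                # a downward phase-ratio shift is only reachable while the
                # central r_inf/r0 stays above _RHO_FLOOR; when the drawn
                # lateral dispersion is too shallow for that, deepen it
                # (lower the lateral alpha, the lesion is sensed by both
                # montages) until the target is exactly realisable
                floor_c = (1.0 + _RHO_FLOOR) / (1.0 - _RHO_FLOOR)
                required = floor_c / effect.f3_shift
                if _phase_ratio(lateral) < required:
                    tan_l = (lateral.r0 + lateral.r_inf) / (
                        (lateral.r0 - lateral.r_inf) * required
                    )
                    lateral = ColeParameters(
                        r0=lateral.r0,
                        r_inf=lateral.r_inf,
                        alpha=_alpha_for_tan(tan_l),
                        fc=lateral.fc,
                    )
                    params[(hemisphere, "lateral")] = lateral
                target = effect.f3_shift * _phase_ratio(lateral)
                r0_c, alpha_c = _apply_phase_target(r0_c, rinf_c, target)
        params[(hemisphere, "central")] = ColeParameters(
            r0=r0_c, r_inf=rinf_c, alpha=alpha_c, fc=fc_c
        )
    return SubjectProfile(subject_id=subject_id, stroke_hemisphere=stroke, params=params)


def add_noise(
    spectrum: ImpedanceSpectrum, noise_sigma: float, rng: np.random.Generator
) -> ImpedanceSpectrum:
    """Perturb resistance and reactance with independent Gaussian noise.

    At each frequency the standard deviation is ``noise_sigma * |Z|``,
    emulating relative instrument noise.  ``noise_sigma = 0`` is the
    identity.
    """
    if noise_sigma < 0:
        raise ValidationError("noise_sigma must be >= 0")
    if noise_sigma == 0:
        return spectrum
    scale = noise_sigma * np.abs(spectrum.complex_impedance)
    r = spectrum.resistance + rng.normal(0.0, 1.0, size=scale.shape) * scale
    x = spectrum.reactance + rng.normal(0.0, 1.0, size=scale.shape) * scale
    return ImpedanceSpectrum(
        grid=spectrum.grid, resistance=r, reactance=x, meta=spectrum.meta
    )


def generate_study(config: GeneratorConfig = GeneratorConfig()) -> Dataset:
    """Generate the full synthetic study.

    For every (subject, hemisphere, montage, repeat) a noiseless Cole
    spectrum is synthesised on the grid, loaded with the configured stray
    capacitance, then perturbed with relative measurement noise.  A spectrum
    is labelled ``damaged`` iff it comes from a patient's stroke hemisphere
    (either montage).  The default configuration yields 9 subjects x 2
    hemispheres x 2 montages x 20 repeats = 720 spectra, 600 healthy and
    120 damaged.
    """
    spectra: List[ImpedanceSpectrum] = []
    profiles: List[SubjectProfile] = []
    for index in range(config.n_subjects):
        profile = sample_subject(config, index)
        profiles.append(profile)
        noise_rng = _subject_rng(config, index, stream=1)
        for hemisphere in ("left", "right"):
            label = "damaged" if hemisphere == profile.stroke_hemisphere else "healthy"
            for electrode_set in ("central", "lateral"):
                p = profile.params[(hemisphere, electrode_set)]
                z = cole_impedance(p, config.grid)
                clean = ImpedanceSpectrum(
                    grid=config.grid, resistance=z.real, reactance=z.imag
                )
                if config.stray_capacitance > 0:
                    clean = add_parallel_capacitance(clean, config.stray_capacitance)
                for repeat in range(config.repeats_per_set):
                    meta = MeasurementMeta(
                        subject_id=profile.subject_id,
                        hemisphere=hemisphere,
                        electrode_set=electrode_set,
                        repeat=repeat,
                        label=label,
                    )
                    noisy = add_noise(clean, config.noise_sigma, noise_rng)
                    spectra.append(
                        ImpedanceSpectrum(
                            grid=config.grid,
                            resistance=noisy.resistance,
                            reactance=noisy.reactance,
                            meta=meta,
                        )
                    )
    return Dataset(spectra=spectra, profiles=profiles)
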