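"""Synthetic circadian cortisol cohorts.

The study design being emulated: N healthy adults each complete two 24 h
admissions (rest and exercise with a high-intensity bout at 10:00), serum
sampled hourly (Q60, 25 samples) and saliva every two hours (Q120, 13
samples), concentrations in ug/dl.

The deterministic ground-truth curve is a two-harmonic cosinor (24 h
fundamental plus a 12 h harmonic) scaled by a per-subject log-normal
effect, with an additive Gaussian transient at the exercise bout.  The
salivary curve is an attenuated fraction of the circadian shape,
phase-advanced so its peak sits at the 06:00 awakening; salivary profiles
are smoother (more quadratic) than serum ones (more cubic), which is the
feature the degree-selection analysis exploits.  On top of the
deterministic curve, generated samples carry two zero-mean perturbations:
a smooth ultradian fluctuation (random phase per profile) standing in for
cortisol's pulsatile secretion, and iid Gaussian assay noise.  All values
are floored at zero.

The generator's defaults are calibrated so that 24 h trapezoidal outputs
land near 10,000-11,500 ug*min/dl (serum) and 500-650 (saliva) and so
that serum profiles plateau at polynomial degree 3 and saliva at degree 2;
see docs/methods.md for the calibration rationale.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .profiles import EXERCISE, Profile, REST, SALIVA, SERUM, WINDOW_MAX, WINDOW_MIN
from .schemes import build_scheme

HARMONIC_PERIODS = (1440.0, 720.0)


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    Times are minutes since the 06:00 admission start; concentrations ug/dl.
    """

    n_subjects: int = 8
    mesor_serum: float = 7.5
    amplitude1: float = 4.0        #: 24 h cosine amplitude
    acrophase1: float = 120.0      #: 24 h peak time (08:00)
    amplitude2: float = 1.3        #: 12 h harmonic amplitude
    acrophase2: float = 30.0       #: 12 h harmonic peak time
    exercise_bump_height: float = 5.0
    exercise_bump_center: float = 240.0  #: 10:00 exercise bout
    exercise_bump_width: float = 45.0    #: Gaussian sd of the transient
    saliva_fraction: float = 0.06
    saliva_phase_advance: float = 120.0  #: saliva circadian peak at awakening
    saliva_bump_attenuation: float = 0.3
    ultradian_amplitude: float = 1.4     #: pulsatility stand-in, serum scale
    ultradian_period: float = 240.0
    noise_sd_serum: float = 0.4
    noise_sd_saliva: float = 0.03
    between_subject_sd: float = 0.2      #: log-scale sd of the subject effect
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        nonneg = (
            self.amplitude1,
            self.amplitude2,
            self.exercise_bump_height,
            self.exercise_bump_width,
            self.ultradian_amplitude,
            self.noise_sd_serum,
            self.noise_sd_saliva,
            self.between_subject_sd,
        )
        if any(v < 0 for v in nonneg):
            raise ValueError("amplitudes, widths and sds must be >= 0")
        if not (0 < self.saliva_fraction < 1):
            raise ValueError("saliva_fraction must lie in (0, 1)")
        if not (0 <= self.saliva_bump_attenuation <= 1):
            raise ValueError("saliva_bump_attenuation must lie in [0, 1]")
        if self.ultradian_period <= 0:
            raise ValueError("ultradian_period must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


def _circadian_shape(config: CohortConfig, t: np.ndarray) -> np.ndarray:
    out = np.full_like(t, config.mesor_serum, dtype=float)
    for amp, acro, period in (
        (config.amplitude1, config.acrophase1, HARMONIC_PERIODS[0]),
        (config.amplitude2, config.acrophase2, HARMONIC_PERIODS[1]),
    ):
        out += amp * np.cos(2.0 * np.pi * (t - acro) / period)
    return out


def _exercise_bump(config: CohortConfig, t: np.ndarray) -> np.ndarray:
    w = config.exercise_bump_width
    if w == 0:
        return np.where(t == config.exercise_bump_center, config.exercise_bump_height, 0.0)
    return config.exercise_bump_height * np.exp(
        -((t - config.exercise_bump_center) ** 2) / (2.0 * w**2)
    )


def true_concentration(
    config: CohortConfig,
    subject_effect: float,
    condition: str,
    t,
    specimen: str = SERUM,
):
    """Noiseless concentration at time(s) ``t`` (minutes).

    Serum: ``subject_effect * [mesor + sum_i amp_i cos(2pi (t - acro_i)/T_i)]``
    plus the Gaussian exercise transient under the exercise condition,
    floored at zero.  Saliva: ``saliva_fraction`` times the same circadian
    shape evaluated ``saliva_phase_advance`` minutes later (peak advanced to
    the awakening) with the transient attenuated.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < WINDOW_MIN) or np.any(t > WINDOW_MAX):
        raise ValueError(f"t must lie within [{WINDOW_MIN}, {WINDOW_MAX}] minutes")
    if condition not in (REST, EXERCISE):
        raise ValueError(f"unknown condition {condition!r}")
    if specimen == SERUM:
        out = subject_effect * _circadian_shape(config, t)
        if condition == EXERCISE:
            out = out + _exercise_bump(config, t)
    elif specimen == SALIVA:
        out = subject_effect * _circadian_shape(config, t + config.saliva_phase_advance)
        if condition == EXERCISE:
            out = out + config.saliva_bump_attenuation * _exercise_bump(config, t)
        out = config.saliva_fraction * out
    else:
        raise ValueError(f"unknown specimen {specimen!r}")
    return np.maximum(out, 0.0)


def generate_cohort(config: CohortConfig) -> list[Profile]:
    """Generate the full cohort: serum on Q60 and saliva on Q120 per
    subject x condition, fully reproducible from ``config.seed``.

    Per profile, the sampled value is the noiseless curve plus a
    random-phase ultradian cosine (amplitude scaled by ``saliva_fraction``
    for saliva) plus iid Gaussian assay noise, floored at zero.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    serum_grid = build_scheme("Q60").grid_minutes
    saliva_grid = build_scheme("Q120").grid_minutes
    width = len(str(max(config.n_subjects, 1)))
    profiles: list[Profile] = []
    for i in range(config.n_subjects):
        subject_id = f"S{i + 1:0{width}d}"
        effect = float(np.exp(rng.normal(0.0, config.between_subject_sd)))
        for condition in (REST, EXERCISE):
            for specimen, grid, noise_sd in (
                (SERUM, serum_grid, config.noise_sd_serum),
                (SALIVA, saliva_grid, config.noise_sd_saliva),
            ):
                truth = true_concentration(config, effect, condition, grid, specimen)
                phase = rng.uniform(0.0, 2.0 * np.pi)
                amp = config.ultradian_amplitude * (
                    1.0 if specimen == SERUM else config.saliva_fraction
                )
                ultradian = amp * np.cos(
                    2.0 * np.pi * grid / config.ultradian_period + phase
                )
                noise = rng.normal(0.0, noise_sd, len(grid)) if noise_sd > 0 else 0.0
                values = np.maximum(truth + ultradian + noise, 0.0)
                profiles.append(
                    Profile(subject_id, condition, specimen, grid.copy(), values)
                )
    return profiles


def known_polynomial_cohort(
    coefficients, noise_sd: float, n_subjects: int, seed: int
) -> list[Profile]:
    """Serum-grid profiles following a known polynomial in scaled time.

    ``coefficients`` are ascending-power coefficients in the time basis
    scaled to [-1, 1] over [0, 1440]; the polynomial degree must be 1-6.
    Used to verify that polynomial validation recovers the generating
    degree.  Values are floored at zero, so choose coefficients with a
    comfortably positive range.
    """
    coefficients = np.asarray(coefficients, dtype=float)
    degree = len(coefficients) - 1
    if not 1 <= degree <= 6:
        raise ValueError("polynomial degree must be between 1 and 6")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    grid = build_scheme("Q60").grid_minutes
    u = (grid - 720.0) / 720.0
    truth = np.polynomial.polynomial.polyval(u, coefficients)
    width = len(str(max(n_subjects, 1)))
    profiles = []
    for i in range(n_subjects):
        noise = rng.normal(0.0, noise_sd, len(grid)) if noise_sd > 0 else 0.0
        values = np.maximum(truth + noise, 0.0)
        profiles.append(
            Profile(f"P{i + 1:0{width}d}", REST, SERUM, grid.copy(), values)
        )
    return profiles
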