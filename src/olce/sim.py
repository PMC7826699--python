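"""Seeded generator of synthetic e-nose datasets.

The study data this package targets (multichannel metal-oxide sensor
responses to plant-material headspace) are not publicly deposited, so the
simulator emulates their qualitative morphology: a rise-to-plateau response
per sensor, signed linear baseline drift (upward from slow volatilization,
downward from chamber overflow), within-class sample-to-sample gain
variability from heterogeneous material sources, and additive Gaussian
sensor noise.  Every draw is a pure function of the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .data import DEFAULT_SENSOR_NAMES, OdorDataset, ResponseSample


class SimConfigError(ValueError):
    """The simulation configuration is invalid or unsatisfiable."""


@dataclass
class SimConfig:
    """Parameters of the synthetic e-nose study.

    Defaults mirror the acquisition geometry of a 10-sensor array sampled
    at 1 Hz for 120 s, with seven odor classes of 100 samples each.
    Amplitudes are in dimensionless conductivity-ratio units; ``noise_sd``
    and drift slopes share those units (drift per time step).
    """

    n_classes: int = 7
    n_per_class: int = 100
    n_sensors: int = 10
    n_timepoints: int = 120
    sample_interval_s: float = 1.0
    rise_time_constant_s: float = 15.0
    noise_sd: float = 0.02
    gain_sd: float = 0.08          # lognormal sigma of the per-sample gain
    drift_slope_range: tuple[float, float] = (-0.002, 0.002)
    class_separation: float = 1.0  # scales between-class amplitude spread
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.n_sensors < 1:
            raise SimConfigError("n_classes and n_sensors must be >= 1")
        if self.n_per_class < 0:
            raise SimConfigError("n_per_class must be >= 0")
        if self.n_timepoints < 2:
            raise SimConfigError("n_timepoints must be >= 2")
        if self.noise_sd < 0 or self.gain_sd < 0:
            raise SimConfigError("noise_sd and gain_sd must be >= 0")
        if self.rise_time_constant_s <= 0 or self.sample_interval_s <= 0:
            raise SimConfigError("time constants must be positive")
        lo, hi = self.drift_slope_range
        if lo > hi:
            raise SimConfigError("drift_slope_range must be (low, high)")
        if self.class_separation <= 0:
            raise SimConfigError("class_separation must be positive")

    def sensor_names(self) -> tuple[str, ...]:
        if self.n_sensors == len(DEFAULT_SENSOR_NAMES):
            return DEFAULT_SENSOR_NAMES
        return tuple(f"S{i}" for i in range(self.n_sensors))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["drift_slope_range"] = list(self.drift_slope_range)
        return d


@dataclass
class ClassProfile:
    """Latent odor signature of one class: per-sensor response amplitudes,
    baseline levels and drift slopes (a stand-in for unmeasured
    odorant-sensor sensitivities)."""

    amplitude: np.ndarray  # (n_sensors,)
    drift: np.ndarray      # (n_sensors,) slope per time step
    baseline: np.ndarray   # (n_sensors,)


_MAX_PROFILE_ATTEMPTS = 1000


def make_profiles(config: SimConfig) -> list[ClassProfile]:
    """Draw ``n_classes`` class profiles, rejecting amplitude vectors closer
    (Euclidean) than ``0.5 * class_separation`` to any accepted one."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    sep = 0.5 * config.class_separation
    profiles: list[ClassProfile] = []
    amps: list[np.ndarray] = []
    for _ in range(config.n_classes):
        for attempt in range(_MAX_PROFILE_ATTEMPTS):
            a = rng.uniform(0.3, 0.3 + 1.7 * config.class_separation, config.n_sensors)
            if all(np.linalg.norm(a - prev) >= sep for prev in amps):
                break
        else:
            raise SimConfigError(
                f"could not place {config.n_classes} class profiles at "
                f"separation {sep} after {_MAX_PROFILE_ATTEMPTS} attempts"
            )
        amps.append(a)
        lo, hi = config.drift_slope_range
        profiles.append(
            ClassProfile(
                amplitude=a,
                drift=rng.uniform(lo, hi, config.n_sensors),
                baseline=rng.uniform(0.0, 0.2, config.n_sensors),
            )
        )
    return profiles


def generate_sample(
    profile: ClassProfile, config: SimConfig, sample_seed: int
) -> ResponseSample:
    """One synthetic recording.

    Sensor s follows ``b[s] + g * A[s] * (1 - exp(-t/tau)) + d[s]*k + eps``
    with t in seconds, k the time-step index, ``g`` a per-sample lognormal
    gain (sigma ``gain_sd``, shared across sensors) and ``eps`` iid Gaussian
    noise of sd ``noise_sd``.
    """
    rng = np.random.default_rng(sample_seed)
    t = np.arange(config.n_timepoints) * config.sample_interval_s
    rise = 1.0 - np.exp(-t / config.rise_time_constant_s)
    gain = float(np.exp(rng.normal(0.0, config.gain_sd))) if config.gain_sd > 0 else 1.0
    steps = np.arange(config.n_timepoints)
    values = (
        profile.baseline[:, None]
        + gain * profile.amplitude[:, None] * rise[None, :]
        + profile.drift[:, None] * steps[None, :]
    )
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, values.shape)
    return ResponseSample(
        values=values,
        sensor_names=config.sensor_names(),
        sample_interval_s=config.sample_interval_s,
    )


def sample_seed_for(config: SimConfig, class_index: int, sample_index: int) -> int:
    """Stable per-sample seed derived from (root seed, class, counter)."""
    ss = np.random.SeedSequence([config.seed, 1 + class_index, sample_index])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_dataset(config: SimConfig) -> OdorDataset:
    """Full synthetic dataset: ``n_classes x n_per_class`` labeled samples,
    class names ``class_0 ...``, reproducible from the config alone."""
    profiles = make_profiles(config)
    class_names = [f"class_{c}" for c in range(config.n_classes)]
    samples: list[ResponseSample] = []
    for c, profile in enumerate(profiles):
        for j in range(config.n_per_class):
            s = generate_sample(profile, config, sample_seed_for(config, c, j))
            s.label = class_names[c]
            samples.append(s)
    return OdorDataset(samples=samples, class_names=class_names)
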