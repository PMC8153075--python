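"""Generator parameters for the synthetic Ternus datasets.

The psychometric defaults are the pooled Experiment 1-3 condition means
(PSE 180.1 / 100.2 ms, JND 37.9 / 42.6 ms); the microsaccade, pupil and
reaction-time process parameters are the package's own choices, documented
in docs/methods.md, picked so that the synthetic data carry the
qualitative structure the analysis pipeline is meant to recover: a
stimulus-locked oculomotor inhibition that is deepened/prolonged by sound
in the late (750-1000 ms) window, a main-sequence amplitude/peak-velocity
relation, and a sound-enhanced pupil dilation response.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class PsychometricParams:
    """True logistic parameters of the simulated observers (ms)."""
    pse_baseline_ms: float = 180.1
    pse_sound_ms: float = 100.2
    jnd_baseline_ms: float = 37.9
    jnd_sound_ms: float = 42.6

    def validate(self) -> None:
        if self.jnd_baseline_ms <= 0 or self.jnd_sound_ms <= 0:
            raise ValueError("jnd must be > 0")


@dataclass
class MicrosaccadeParams:
    """Inhomogeneous point process + waveform model for microsaccades."""
    base_rate_hz: float = 1.5
    # per-frame inhibition dip (multiplicative gain, Gaussian bump)
    inhib_depth: float = 0.9
    inhib_latency_ms: float = 120.0
    inhib_width_ms: float = 80.0
    # rebound overshoot after the presentation
    rebound_gain: float = 0.8
    rebound_latency_ms: float = 450.0
    rebound_width_ms: float = 150.0
    # extra late suppression when sound is present (relative to frame1):
    # deepens and prolongs the inhibition in the response phase
    sound_late_depth: float = 0.6
    sound_late_center_ms: float = 860.0
    sound_late_width_ms: float = 130.0
    # amplitude distribution: lognormal, clipped
    amplitude_median_deg: float = 0.35
    amplitude_sigma: float = 0.40
    amplitude_min_deg: float = 0.12
    amplitude_max_deg: float = 1.5
    # main sequence: peak velocity = slope * amplitude * lognormal noise
    main_sequence_slope: float = 100.0  # (deg/s) per deg
    main_sequence_noise_sigma: float = 0.22
    min_gap_ms: float = 20.0
    # fixational drift (Ornstein-Uhlenbeck velocity) + measurement noise
    drift_velocity_sd: float = 0.10   # deg/s
    drift_timescale_ms: float = 100.0
    position_noise_sd_deg: float = 0.001

    def validate(self) -> None:
        if self.base_rate_hz < 0:
            raise ValueError("base_rate_hz must be >= 0")
        if not (0 <= self.inhib_depth <= 1 and 0 <= self.sound_late_depth <= 1):
            raise ValueError("inhibition depths must be in [0, 1]")
        if self.position_noise_sd_deg < 0 or self.drift_velocity_sd < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass
class PupilParams:
    """Gamma-shaped impulse response pupil model (arbitrary units)."""
    baseline_au: float = 3000.0
    response_gain_au: float = 150.0     # per visual frame
    sound_gain_au: float = 120.0        # extra, per beep, when sound=true
    time_to_peak_ms: float = 600.0
    shape_n: float = 6.0
    noise_sd_au: float = 30.0
    blink_rate_hz: float = 0.10
    blink_duration_ms: float = 120.0

    def validate(self) -> None:
        if self.noise_sd_au < 0:
            raise ValueError("noise_sd_au must be >= 0")
        if self.blink_rate_hz < 0:
            raise ValueError("blink_rate_hz must be >= 0")


@dataclass
class RTParams:
    """Truncated-normal reaction times for the E4 localization task (ms)."""
    mean_sound_ms: float = 537.0
    mean_baseline_ms: float = 603.0
    sd_ms: float = 110.0
    lower_bound_ms: float = 150.0


@dataclass
class GeneratorParams:
    psychometric: PsychometricParams = field(default_factory=PsychometricParams)
    ms_process: MicrosaccadeParams = field(default_factory=MicrosaccadeParams)
    pupil: PupilParams = field(default_factory=PupilParams)
    rt: RTParams = field(default_factory=RTParams)
    sampling_rate_hz: float = 500.0
    seed: int = 0

    def validate(self) -> None:
        self.psychometric.validate()
        self.ms_process.validate()
        self.pupil.validate()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorParams":
        return cls(
            psychometric=PsychometricParams(**d.get("psychometric", {})),
            ms_process=MicrosaccadeParams(**d.get("ms_process", {})),
            pupil=PupilParams(**d.get("pupil", {})),
            rt=RTParams(**d.get("rt", {})),
            sampling_rate_hz=d.get("sampling_rate_hz", 500.0),
            seed=d.get("seed", 0),
        )
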