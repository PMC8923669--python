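"""Parameter specifications for the synthetic session generator.

Defaults reproduce the study protocol: a 2 kHz, 10 s conditioned tone
paired 7 times with a 0.5 s footshock at tone offset (delay paradigm; the
trace variant inserts a 1 s stimulus-free interval), followed by a 35-trial
extinction session organised in five blocks of seven tones.  Unit, LFP and
behaviour specs parameterise generative stand-ins for the recorded data;
``muscimol_like`` presets emulate the qualitative effect of cerebellar
nucleus inactivation (temporally dispersed multi-peak tone-offset
responses, longer freezing bouts) without asserting measured magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from fearpeth.core import ValidationError

UNIT_TEMPLATES = (
    "type1_onset",
    "type1_offset",
    "type1_both",
    "type2",
    "type3_biphasic",
    "type4_onset_dec",
    "type4_offset_dec",
)

#: templates whose transients suppress rather than elevate firing
_SUPPRESSIVE = {"type4_onset_dec", "type4_offset_dec"}


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class ProtocolSpec:
    """Trial structure of one conditioning + extinction session."""

    paradigm: str = "delay"
    tone_duration_s: float = 10.0
    n_habituation_trials: int = 0
    n_acquisition_trials: int = 7
    us_duration_s: float = 0.5
    trace_interval_s: float = 0.0
    n_extinction_trials: int = 35
    block_size: int = 7
    iti_range_s: tuple[float, float] = (60.0, 120.0)

    def __post_init__(self) -> None:
        _check(self.paradigm in ("delay", "trace"), f"unknown paradigm {self.paradigm!r}")
        _check(self.tone_duration_s > 0, "tone_duration_s must be > 0")
        _check(self.trace_interval_s >= 0, "trace_interval_s must be >= 0")
        if self.paradigm == "delay":
            _check(self.trace_interval_s == 0, "delay paradigm requires trace_interval_s = 0")
        else:
            _check(self.trace_interval_s > 0, "trace paradigm requires trace_interval_s > 0")
        _check(self.n_habituation_trials >= 0, "n_habituation_trials must be >= 0")
        _check(self.n_acquisition_trials >= 0, "n_acquisition_trials must be >= 0")
        _check(self.us_duration_s > 0, "us_duration_s must be > 0")
        _check(self.block_size > 0, "block_size must be > 0")
        _check(
            self.n_extinction_trials % self.block_size == 0,
            "n_extinction_trials must be an integer number of blocks",
        )
        lo, hi = self.iti_range_s
        _check(0 < lo < hi, "iti_range_s must satisfy 0 < min < max")

    @property
    def n_blocks(self) -> int:
        return self.n_extinction_trials // self.block_size


@dataclass(frozen=True)
class UnitSpec:
    """Generative model of one unit: baseline Poisson firing plus
    rectangular event-locked rate transients.

    Excitatory templates multiply the baseline rate by ``1 + gain`` inside
    the transient window; suppressive (type 4) templates multiply it by
    ``gain`` (a fraction in (0, 1)).  ``n_subpeaks > 1`` spreads the offset
    transient into that many separated sub-transients, emulating the
    temporally dispersed multi-peak offset pattern seen after cerebellar
    inactivation.
    """

    template: str = "type1_both"
    baseline_rate_hz: float = 5.0
    onset_gain: float = 6.0
    offset_gain: float = 6.0
    response_latency_s: float = 0.04
    response_width_s: float = 0.12
    latency_jitter_sd_s: float = 0.0
    extinction_decay_per_block: float = 0.35
    n_subpeaks: int = 1
    #: absolute refractory dead time; a pure Poisson train violates the
    #: 2 ms single-unit purity bound ~1% of the time, which no accepted
    #: sorted unit would
    refractory_s: float = 0.0025

    def __post_init__(self) -> None:
        _check(self.template in UNIT_TEMPLATES, f"unknown template {self.template!r}")
        _check(self.baseline_rate_hz > 0, "baseline_rate_hz must be > 0")
        for name, gain in (("onset_gain", self.onset_gain), ("offset_gain", self.offset_gain)):
            _check(gain > 0, f"{name} must be > 0")
        if self.template in _SUPPRESSIVE:
            gain = self.onset_gain if self.template == "type4_onset_dec" else self.offset_gain
            _check(0 < gain < 1, "suppressive templates need the active gain in (0, 1)")
        if self.template == "type3_biphasic":
            _check(0 < self.offset_gain < 1, "type3_biphasic uses a suppressive offset gain in (0, 1)")
        _check(self.response_latency_s >= 0, "response_latency_s must be >= 0")
        _check(self.response_width_s > 0, "response_width_s must be > 0")
        _check(self.latency_jitter_sd_s >= 0, "latency_jitter_sd_s must be >= 0")
        _check(
            0 <= self.extinction_decay_per_block <= 1,
            "extinction_decay_per_block must lie in [0, 1]",
        )
        _check(self.n_subpeaks >= 1, "n_subpeaks must be >= 1")
        _check(self.refractory_s >= 0, "refractory_s must be >= 0")


@dataclass(frozen=True)
class BehaviorSpec:
    """Two-state (freeze/move) semi-Markov behaviour with CS-modulated
    hazards and Poisson rear / USV events during movement.

    ``freeze_hazard_baseline`` is the move→freeze transition hazard,
    ``move_hazard_baseline`` the freeze→move hazard (both per second).
    During the conditioned tone the entry hazard is multiplied, and the
    exit hazard divided, by ``cs_freeze_modulation`` (which decays over
    extinction blocks).  ``epoch_duration_scale > 1`` lengthens both
    freeze and move bouts, as seen after cerebellar inactivation.
    """

    freeze_hazard_baseline: float = 0.08
    move_hazard_baseline: float = 0.25
    cs_freeze_modulation: float = 3.0
    modulation_decay_per_block: float = 0.35
    epoch_duration_scale: float = 1.0
    rear_rate_hz: float = 0.02
    usv_rate_hz: float = 0.01

    def __post_init__(self) -> None:
        for name in ("freeze_hazard_baseline", "move_hazard_baseline", "rear_rate_hz", "usv_rate_hz"):
            _check(getattr(self, name) >= 0, f"{name} must be >= 0")
        _check(self.cs_freeze_modulation >= 0, "cs_freeze_modulation must be >= 0")
        _check(
            0 <= self.modulation_decay_per_block <= 1,
            "modulation_decay_per_block must lie in [0, 1]",
        )
        _check(self.epoch_duration_scale > 0, "epoch_duration_scale must be > 0")


@dataclass(frozen=True)
class LfpSpec:
    """Event-locked ERP kernels plus Gaussian noise, per channel.

    Each kernel is one full sine cycle of peak-to-peak ``amplitude_uV``
    starting ``latency_s`` after the aligned event and reaching its first
    (positive) peak at ``peak_latency_s``, so injected onset and peak
    latencies are exactly recoverable on noiseless traces.
    """

    sample_rate_hz: float = 1000.0
    onset_kernel: tuple[float, float, float] = (0.006, 0.058, 500.0)
    offset_kernel: tuple[float, float, float] = (0.032, 0.099, 500.0)
    kernel_decay_per_block: float = 0.15
    noise_sd_uV: float = 20.0
    n_channels: int = 4
    channel_gains: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        _check(self.sample_rate_hz > 0, "sample_rate_hz must be > 0")
        for name, kern in (("onset_kernel", self.onset_kernel), ("offset_kernel", self.offset_kernel)):
            lat, peak, amp = kern
            _check(0 <= lat < peak, f"{name}: need 0 <= latency < peak latency")
            _check(amp >= 0, f"{name}: amplitude must be >= 0")
        _check(0 <= self.kernel_decay_per_block <= 1, "kernel_decay_per_block must lie in [0, 1]")
        _check(self.noise_sd_uV >= 0, "noise_sd_uV must be >= 0")
        _check(self.n_channels >= 1, "n_channels must be >= 1")
        if self.channel_gains is not None:
            _check(
                len(self.channel_gains) == self.n_channels,
                "channel_gains must have one entry per channel",
            )
            _check(all(g >= 0 for g in self.channel_gains), "channel_gains must be >= 0")


@dataclass(frozen=True)
class ClusterSpec:
    """Gaussian feature clusters plus broad background spikes, the fixture
    source for the cluster-quality metrics."""

    cluster_means: tuple[tuple[float, ...], ...]
    cluster_covariances: Optional[tuple] = None
    cluster_sizes: tuple[int, ...] = ()
    n_noise_spikes: int = 200
    noise_spread: float = 10.0

    def __post_init__(self) -> None:
        _check(len(self.cluster_means) >= 1, "at least one cluster required")
        n_features = len(self.cluster_means[0])
        _check(
            all(len(m) == n_features for m in self.cluster_means),
            "all cluster means must share one dimensionality",
        )
        sizes = self.cluster_sizes or tuple(50 for _ in self.cluster_means)
        object.__setattr__(self, "cluster_sizes", tuple(int(s) for s in sizes))
        _check(len(self.cluster_sizes) == len(self.cluster_means), "one size per cluster required")
        _check(
            all(s > n_features for s in self.cluster_sizes),
            "cluster sizes must exceed the feature count",
        )
        covs = self.cluster_covariances
        if covs is None:
            covs = tuple(np.eye(n_features) for _ in self.cluster_means)
        covs = tuple(np.asarray(c, dtype=float) for c in covs)
        for c in covs:
            _check(c.shape == (n_features, n_features), "covariance shape mismatch")
            eig = np.linalg.eigvalsh(c)
            _check(bool(np.all(eig > 0)), "cluster covariances must be positive definite")
        object.__setattr__(self, "cluster_covariances", covs)
        _check(self.n_noise_spikes >= 0, "n_noise_spikes must be >= 0")
        _check(self.noise_spread > 0, "noise_spread must be > 0")

    @property
    def n_features(self) -> int:
        return len(self.cluster_means[0])


def muscimol_like(unit: UnitSpec) -> UnitSpec:
    """Muscimol-like unit preset: temporally dispersed multi-peak offset
    responses (three narrow sub-peaks spread over the first 500 ms, with
    per-trial latency jitter)."""
    return replace(unit, latency_jitter_sd_s=0.03, n_subpeaks=3, response_width_s=0.08)


def muscimol_like_behavior(spec: BehaviorSpec) -> BehaviorSpec:
    """Muscimol-like behaviour preset: threefold longer freeze/move bouts."""
    return replace(spec, epoch_duration_scale=3.0)
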