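"""Synthetic motor-imagery EEG sessions.

Generates multichannel recordings that follow the clench-speed / clench-force
motor-imagery paradigm: each trial is a baseline period, a cue period, a task
(imagery) period and a rest period, with an event marker at task onset.  The
signal model is deliberately simple and fully controllable:

* background activity = 1/f ("pink") noise plus white noise, independent per
  channel;
* sensorimotor rhythms = amplitude-modulated sinusoids whose instantaneous
  frequency drifts slowly inside the mu (8-12 Hz) or beta (18-25 Hz) band;
* class differences are injected only during the task period, into the band
  power, the envelope shape, or the phase dynamics of a rhythm on a chosen
  channel subset.

The three effect kinds expose the three feature axes (power, amplitude
envelope, phase) independently, so downstream feature types can be validated
against a known ground truth.  ``phase_dynamics`` resets the rhythm phase at
task onset to a class-specific angle (plus trial-to-trial jitter), which
leaves band power untouched; ``power_shift`` multiplies the task-period
envelope and leaves phase untouched; ``envelope_shape`` modulates the
envelope trajectory while preserving its mean square, so mean band power is
(approximately) class-invariant but the amplitude dynamics are not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import ndimage

from .errors import EffectSpecError, MontageError, UnknownPresetError

__all__ = [
    "MontageSpec",
    "TrialTimingSpec",
    "RhythmSpec",
    "ClassEffectSpec",
    "Event",
    "Recording",
    "DEFAULT_RHYTHMS",
    "make_montage",
    "simulate_session",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MontageSpec:
    """Electrode layout and neighbourhood relation for the surface Laplacian.

    ``neighbours`` maps each channel label to the set of adjacent channels
    (the surrounding set used by the small-Laplacian re-reference).  The
    relation must be symmetric; channels with no neighbours are tolerated but
    flagged as edge channels and passed through the Laplacian unchanged.
    """

    channel_labels: tuple[str, ...]
    neighbours: Mapping[str, frozenset[str]]
    reference_label: str = "A1"

    def __post_init__(self) -> None:
        labels = self.channel_labels
        if len(set(labels)) != len(labels):
            raise MontageError("channel labels must be unique")
        for ch, nbrs in self.neighbours.items():
            if ch not in labels:
                raise MontageError(f"neighbour map references unknown channel {ch!r}")
            for other in nbrs:
                if other not in labels:
                    raise MontageError(f"{ch!r} lists unknown neighbour {other!r}")
                if ch not in self.neighbours.get(other, frozenset()):
                    raise MontageError(
                        f"neighbour relation not symmetric: {ch!r} -> {other!r}"
                    )

    @property
    def n_channels(self) -> int:
        return len(self.channel_labels)

    def edge_channels(self) -> tuple[str, ...]:
        """Channels with an empty neighbour set (Laplacian passthrough)."""
        return tuple(
            ch for ch in self.channel_labels if not self.neighbours.get(ch, frozenset())
        )


@dataclass(frozen=True)
class TrialTimingSpec:
    """Single-trial timing of the motor-imagery paradigm, in seconds.

    Defaults follow the long-trial protocol: 10 s baseline, 2 s cue, 10 s
    task, and a rest period drawn uniformly from 10-12 s, sampled at 1000 Hz.
    """

    baseline_s: float = 10.0
    cue_s: float = 2.0
    task_s: float = 10.0
    rest_s: tuple[float, float] = (10.0, 12.0)
    fs_hz: float = 1000.0

    def __post_init__(self) -> None:
        lo, hi = self.rest_s
        if min(self.baseline_s, self.cue_s, self.task_s, lo) <= 0:
            raise ValueError("all trial durations must be positive")
        if hi < lo:
            raise ValueError("rest_s range must be (lo, hi) with hi >= lo")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")

    @property
    def task_onset_s(self) -> float:
        return self.baseline_s + self.cue_s


@dataclass(frozen=True)
class RhythmSpec:
    """One narrow-band oscillation of the background signal model.

    ``amp_uv`` is the nominal envelope amplitude in microvolts,
    ``drift_sd_hz`` the standard deviation of the slow instantaneous-frequency
    drift around ``center_hz`` (clipped to stay inside ``band_hz``), and
    ``am_depth`` the relative depth of the slow random amplitude modulation.
    """

    name: str
    band_hz: tuple[float, float]
    center_hz: float
    amp_uv: float = 4.0
    drift_sd_hz: float = 0.4
    am_depth: float = 0.25

    def __post_init__(self) -> None:
        lo, hi = self.band_hz
        if not (0 < lo < hi):
            raise ValueError("band_hz must satisfy 0 < lo < hi")
        if not (lo <= self.center_hz <= hi):
            raise ValueError("center_hz must lie inside band_hz")


#: Default mu and beta rhythms: amplitudes typical of sensorimotor rhythms
#: relative to the ~6 uV pink background, with a slow intra-band frequency
#: drift (slower for mu so post-onset phase stays coherent across trials).
DEFAULT_RHYTHMS: tuple[RhythmSpec, ...] = (
    RhythmSpec("mu", (8.0, 12.0), 10.0, amp_uv=6.0, drift_sd_hz=0.2, am_depth=0.25),
    RhythmSpec("beta", (18.0, 25.0), 21.0, amp_uv=3.0, drift_sd_hz=0.8, am_depth=0.25),
)

_EFFECT_KINDS = ("power_shift", "envelope_shape", "phase_dynamics")


@dataclass(frozen=True)
class ClassEffectSpec:
    """Task-period class difference injected into one rhythm.

    ``effect_size`` is a dimensionless envelope multiplier for
    ``power_shift``, a dimensionless modulation depth for ``envelope_shape``,
    and a radian phase offset at task onset for ``phase_dynamics``.
    ``noise_sd`` is the trial-to-trial jitter of the effect in its own units
    (log-multiplier units for the two amplitude effects, radians for the
    phase effect).  ``affected_channels = None`` means all channels.
    """

    band: str = "mu"
    effect_kind: str = "power_shift"
    effect_size: float = 1.0
    affected_channels: tuple[str, ...] | None = None
    noise_sd: float = 0.0
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.effect_kind not in _EFFECT_KINDS:
            raise EffectSpecError(
                f"effect_kind must be one of {_EFFECT_KINDS}, got {self.effect_kind!r}"
            )
        if not np.isfinite(self.effect_size):
            raise EffectSpecError("effect_size must be finite")
        if self.noise_sd < 0:
            raise EffectSpecError("noise_sd must be non-negative")


class Event(NamedTuple):
    """Task-onset marker: sample index, class label, trial id."""

    sample_index: int
    label: str
    trial_id: int


@dataclass
class Recording:
    """Continuous multichannel recording with task-onset event markers.

    ``samples`` is channels x time in microvolts; ``events`` are sorted by
    sample index and every index lies inside the signal.
    """

    samples: np.ndarray
    fs_hz: float
    channel_labels: tuple[str, ...]
    events: tuple[Event, ...] = ()

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time array")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError("samples row count must match channel_labels")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain NaN or Inf")
        self.channel_labels = tuple(self.channel_labels)
        self.events = tuple(Event(*e) for e in self.events)
        n = self.samples.shape[1]
        last = -1
        for ev in self.events:
            if not (0 <= ev.sample_index < n):
                raise ValueError(f"event at sample {ev.sample_index} outside signal")
            if ev.sample_index < last:
                raise ValueError("events must be sorted by sample_index")
            last = ev.sample_index

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def copy_with(self, **kw) -> "Recording":
        args = dict(
            samples=self.samples,
            fs_hz=self.fs_hz,
            channel_labels=self.channel_labels,
            events=self.events,
        )
        args.update(kw)
        return Recording(**args)


# ---------------------------------------------------------------------------
# montages
# ---------------------------------------------------------------------------

# 3 x 7 cap grid over sensorimotor cortex (frontocentral / central /
# centroparietal rows); 21-electrode motor-cortex layout with 4-adjacency.
_PAPER21_ROWS = (
    ("FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6"),
    ("C5", "C3", "C1", "Cz", "C2", "C4", "C6"),
    ("CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6"),
)


def _grid_montage(labels_2d: Sequence[Sequence[str]], reference: str) -> MontageSpec:
    n_rows, n_cols = len(labels_2d), len(labels_2d[0])
    neighbours: dict[str, frozenset[str]] = {}
    for r in range(n_rows):
        for c in range(n_cols):
            nbrs = []
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols:
                    nbrs.append(labels_2d[rr][cc])
            neighbours[labels_2d[r][c]] = frozenset(nbrs)
    flat = tuple(lab for row in labels_2d for lab in row)
    return MontageSpec(flat, neighbours, reference)


def make_montage(preset: str) -> MontageSpec:
    """Build a montage from a preset name.

    ``"paper21"`` is the 21-electrode sensorimotor cap approximated as a
    3 x 7 grid (FC / C / CP rows) with 4-adjacency; ``"grid_<r>x<c>"`` is a
    parametric rectangular grid with generic ``E<r>_<c>`` labels.  A 1 x 1
    grid is rejected because no channel could have a neighbour.
    """
    if preset == "paper21":
        return _grid_montage(_PAPER21_ROWS, "A1")
    if preset.startswith("grid_"):
        try:
            r_s, c_s = preset[len("grid_"):].split("x")
            n_rows, n_cols = int(r_s), int(c_s)
        except ValueError as exc:
            raise UnknownPresetError(f"malformed grid preset {preset!r}") from exc
        if n_rows < 1 or n_cols < 1:
            raise UnknownPresetError(f"grid dimensions must be >= 1 in {preset!r}")
        if n_rows * n_cols < 2:
            raise MontageError("a 1x1 grid has no possible neighbours")
        labels = [
            [f"E{r + 1}_{c + 1}" for c in range(n_cols)] for r in range(n_rows)
        ]
        return _grid_montage(labels, "REF")
    raise UnknownPresetError(f"unknown montage preset {preset!r}")


# ---------------------------------------------------------------------------
# signal model helpers
# ---------------------------------------------------------------------------


def _pink_noise(rng: np.random.Generator, n_ch: int, n: int) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise, independent per channel."""
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n)
    gain = np.zeros_like(freqs)
    gain[1:] = 1.0 / np.sqrt(freqs[1:])
    spec *= gain
    out = np.fft.irfft(spec, n=n, axis=1)
    sd = out.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


_SLOW_RATE_HZ = 25.0


def _smooth_noise(
    rng: np.random.Generator, shape: int | tuple, fs: float, tau_s: float
) -> np.ndarray:
    """Unit-variance Gaussian noise low-passed to a ~tau_s correlation time.

    The slow modulation is synthesized at a 25 Hz internal rate and linearly
    interpolated up to ``fs`` (a ~tau_s-correlated process has no content
    anywhere near 25 Hz, so this is equivalent and much cheaper than
    smoothing at the acquisition rate).  Smoothing runs along the last axis;
    a (channels, time) shape yields independent series per channel.
    """
    if isinstance(shape, int):
        shape = (shape,)
    n = shape[-1]
    n_slow = max(int(np.ceil(n * _SLOW_RATE_HZ / fs)) + 2, 4)
    x = rng.standard_normal(shape[:-1] + (n_slow,))
    sigma = max(tau_s * _SLOW_RATE_HZ, 1.0)
    y = ndimage.gaussian_filter1d(x, sigma, axis=-1, mode="reflect")
    sd = y.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    y = y / sd
    t_fast = np.arange(n) * (_SLOW_RATE_HZ / fs)
    t_slow = np.arange(n_slow)
    out = np.empty(shape)
    flat_y = y.reshape(-1, n_slow)
    flat_out = out.reshape(-1, n)
    for i in range(flat_y.shape[0]):
        flat_out[i] = np.interp(t_fast, t_slow, flat_y[i])
    return out


def _raised_cosine_gate(n: int, on: int, off: int, ramp: int) -> np.ndarray:
    """0/1 gate over [on, off) with raised-cosine ramps of ``ramp`` samples."""
    gate = np.zeros(n)
    on = max(on, 0)
    off = min(off, n)
    if off <= on:
        return gate
    gate[on:off] = 1.0
    ramp = min(ramp, (off - on) // 2)
    if ramp > 1:
        edge = 0.5 * (1 - np.cos(np.linspace(0, np.pi, ramp)))
        gate[on:on + ramp] = edge
        gate[off - ramp:off] = edge[::-1]
    return gate


def _validate_effects(
    effects: Mapping[str, Sequence[ClassEffectSpec]],
    montage: MontageSpec,
    rhythm_names: set[str],
) -> None:
    if not effects:
        raise EffectSpecError("effects mapping must contain at least one class")
    for cls, specs in effects.items():
        for spec in specs:
            if spec.band not in rhythm_names:
                raise EffectSpecError(
                    f"class {cls!r}: effect band {spec.band!r} matches no rhythm"
                )
            if spec.affected_channels is not None:
                unknown = set(spec.affected_channels) - set(montage.channel_labels)
                if unknown:
                    raise EffectSpecError(
                        f"class {cls!r}: unknown affected channels {sorted(unknown)}"
                    )


# ---------------------------------------------------------------------------
# session simulation
# ---------------------------------------------------------------------------


def simulate_session(
    montage: MontageSpec,
    timing: TrialTimingSpec,
    effects: Mapping[str, Sequence[ClassEffectSpec]],
    n_trials: int = 60,
    rng_seed: int = 0,
    *,
    rhythms: Sequence[RhythmSpec] = DEFAULT_RHYTHMS,
    pink_sd_uv: float = 6.0,
    white_sd_uv: float = 2.0,
    effect_ramp_s: float = 0.2,
) -> Recording:
    """Simulate one session of balanced two-class (or k-class) trials.

    Trials are concatenated in a class order shuffled once per session; class
    counts are balanced to within one trial.  Each trial's task onset is
    marked with an :class:`Event`.  The same ``rng_seed`` yields a
    bit-identical :class:`Recording`.

    ``effects`` maps each class label to the list of
    :class:`ClassEffectSpec` applied during that class's task periods; pass
    identical specs for all classes to simulate a null (no-difference)
    session.
    """
    rhythm_by_name = {r.name: r for r in rhythms}
    _validate_effects(effects, montage, set(rhythm_by_name))
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    nyq = timing.fs_hz / 2
    top = max(r.band_hz[1] for r in rhythms)
    if nyq <= top:
        raise ValueError(f"fs_hz={timing.fs_hz} cannot represent {top} Hz rhythms")

    rng = np.random.default_rng(rng_seed)
    fs = timing.fs_hz
    n_ch = montage.n_channels
    classes = list(effects)

    # balanced labels (+-1), shuffled once per session
    labels = [classes[i % len(classes)] for i in range(n_trials)]
    rng.shuffle(labels)

    # per-channel rhythm gains and phase offsets, fixed for the session; the
    # fixed offsets keep neighbouring channels desynchronized even when a
    # phase_dynamics effect resets the phase at task onset
    gains = {r.name: rng.uniform(0.7, 1.3, size=n_ch) for r in rhythms}
    chan_phase = {r.name: rng.uniform(0, 2 * np.pi, size=n_ch) for r in rhythms}

    ch_index = {lab: i for i, lab in enumerate(montage.channel_labels)}
    onset_s = timing.task_onset_s
    ramp_n = int(round(effect_ramp_s * fs))

    trial_blocks: list[np.ndarray] = []
    events: list[Event] = []
    cursor = 0
    for trial_id, cls in enumerate(labels):
        rest = rng.uniform(*timing.rest_s)
        dur_s = timing.baseline_s + timing.cue_s + timing.task_s + rest
        n = int(round(dur_s * fs))
        onset = int(round(onset_s * fs))
        task_end = int(round((onset_s + timing.task_s) * fs))

        x = _pink_noise(rng, n_ch, n) * pink_sd_uv
        if white_sd_uv > 0:
            x += rng.standard_normal((n_ch, n)) * white_sd_uv

        cls_effects = effects[cls]
        for rhythm in rhythms:
            x += _synth_rhythm(
                rng, rhythm, gains[rhythm.name], chan_phase[rhythm.name],
                n, fs, onset, task_end, ramp_n,
                [e for e in cls_effects if e.band == rhythm.name], ch_index,
            )

        events.append(Event(cursor + onset, cls, trial_id))
        trial_blocks.append(x)
        cursor += n

    samples = np.concatenate(trial_blocks, axis=1)
    return Recording(samples, fs, montage.channel_labels, tuple(events))


def _synth_rhythm(
    rng: np.random.Generator,
    rhythm: RhythmSpec,
    gains: np.ndarray,
    chan_phase: np.ndarray,
    n: int,
    fs: float,
    onset: int,
    task_end: int,
    ramp_n: int,
    specs: Sequence[ClassEffectSpec],
    ch_index: Mapping[str, int],
) -> np.ndarray:
    """One trial's narrow-band rhythm on all channels, with task effects."""
    n_ch = len(gains)
    lo, hi = rhythm.band_hz

    # independent oscillator per channel: own slow frequency drift, own
    # initial phase, own slow amplitude modulation.  (A single shared
    # oscillator would make every trial's rhythm rank-2 across channels,
    # a degenerate covariance structure real EEG does not have.)
    phi0 = rng.uniform(0, 2 * np.pi, size=n_ch)
    drift = _smooth_noise(rng, (n_ch, n), fs, tau_s=0.5) * rhythm.drift_sd_hz
    f_inst = np.clip(rhythm.center_hz + drift, lo + 0.25, hi - 0.25)
    theta = 2 * np.pi * np.cumsum(f_inst, axis=1) / fs + phi0[:, None]
    am = _smooth_noise(rng, (n_ch, n), fs, tau_s=0.5) * rhythm.am_depth
    env = np.clip(1.0 + am, 0.1, None)
    env *= (gains * rhythm.amp_uv)[:, None]

    gate = _raised_cosine_gate(n, onset, task_end, ramp_n)
    for spec in specs:
        if spec.affected_channels is None:
            rows = np.arange(n_ch)
        else:
            rows = np.array(sorted(ch_index[c] for c in spec.affected_channels))
        if spec.effect_kind == "power_shift":
            mult = spec.effect_size * np.exp(spec.noise_sd * rng.standard_normal())
            env[rows] *= 1.0 + gate * (mult - 1.0)
        elif spec.effect_kind == "envelope_shape":
            depth = np.clip(
                spec.effect_size + spec.noise_sd * rng.standard_normal(), 0.0, 0.95
            )
            t_rel = (np.arange(n) - onset) / fs
            shape = 1.0 + depth * np.sin(2 * np.pi * 1.0 * t_rel)
            # preserve mean-square amplitude so band power stays class-neutral
            shape /= np.sqrt(1.0 + depth**2 / 2.0)
            env[rows] *= 1.0 + gate * (shape - 1.0)
        elif spec.effect_kind == "phase_dynamics":
            # reset phase at task onset to a class-specific angle (+ jitter)
            # plus each channel's session-fixed offset; band power untouched
            target = spec.effect_size + spec.noise_sd * rng.standard_normal()
            if onset < n:
                for j in rows:
                    jump = (target + chan_phase[j]) - theta[j, onset]
                    theta[j, onset:] += jump
    return env * np.cos(theta)
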