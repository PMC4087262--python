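"""Time-frequency-phase feature extraction via the Hilbert transform.

For each band-limited channel the discrete analytic signal
``z(t) = x(t) + i y(t) = A(t) exp(i theta(t))`` yields

* instantaneous amplitude  ``IA = A(t) = sqrt(x^2 + y^2)``,
* instantaneous phase      ``IP = theta(t)`` (four-quadrant, in [-pi, pi]),
* instantaneous frequency  ``IF = d/dt unwrap(theta) / 2 pi`` in Hz,
* band power               ``power = x(t)^2`` per sample.

Features are averaged in a 0.5 s moving window stepped by 0.125 s over the
[-0.5, +0.5] s range around task onset (five windows at the defaults), then
concatenated over channels, bands and windows into one row per trial.  IP is
averaged circularly (angle of the mean unit phasor) because arithmetic means
of wrapped angles are discontinuous at +-pi; the literal arithmetic mean is
available via ``ip_mean="arithmetic"``.

Min-max scaling maps each column's training-set range onto [-1, 1]:
``((v - min) / (max - min) - 0.5) * 2``.  The min and max come from the
training rows only, so test rows may fall slightly outside [-1, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy.signal import hilbert

from .errors import FeatureError
from .preprocess import DEFAULT_BANDS, TrialEpoch, bandpass_array

__all__ = [
    "FEATURE_TYPES",
    "FEATURE_SETS",
    "AnalyticFeatures",
    "WindowSpec",
    "ColumnMeta",
    "FeatureMatrix",
    "analytic_signal",
    "window_average",
    "assemble",
    "scale",
]

#: Canonical feature-type order used when assembling combined vectors.
FEATURE_TYPES = ("power", "IA", "IP", "IF")

#: The eight supported feature sets: the four single types and the four
#: studied combinations (power-IP, IA-IP, IA-IP-IF, power-IA-IP-IF).
FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "power": ("power",),
    "IA": ("IA",),
    "IP": ("IP",),
    "IF": ("IF",),
    "power-IP": ("power", "IP"),
    "IA-IP": ("IA", "IP"),
    "IA-IP-IF": ("IA", "IP", "IF"),
    "power-IA-IP-IF": ("power", "IA", "IP", "IF"),
}


@dataclass
class AnalyticFeatures:
    """Per-sample analytic features of one band-limited channel."""

    power: np.ndarray
    ia: np.ndarray
    ip: np.ndarray
    if_hz: np.ndarray
    fs_hz: float

    def series(self, feature_type: str) -> np.ndarray:
        try:
            return {"power": self.power, "IA": self.ia, "IP": self.ip,
                    "IF": self.if_hz}[feature_type]
        except KeyError:
            raise FeatureError(f"unknown feature type {feature_type!r}") from None


@dataclass(frozen=True)
class WindowSpec:
    """Moving-average window: 0.5 s windows stepped 0.125 s over [-0.5, 0.5] s."""

    win_len_s: float = 0.5
    step_s: float = 0.125
    range_s: tuple[float, float] = (-0.5, 0.5)

    def __post_init__(self) -> None:
        lo, hi = self.range_s
        if self.step_s <= 0:
            raise FeatureError("step_s must be positive")
        if self.win_len_s > hi - lo:
            raise FeatureError("win_len_s exceeds the feature range")

    def starts_s(self) -> np.ndarray:
        """Window start times: left-aligned grid of fully contained windows."""
        lo, hi = self.range_s
        n = int(np.floor((hi - lo - self.win_len_s) / self.step_s + 1e-9)) + 1
        return lo + self.step_s * np.arange(n)

    @property
    def n_windows(self) -> int:
        return len(self.starts_s())


class ColumnMeta(NamedTuple):
    """Provenance of one feature column."""

    channel: str
    band: str
    feature_type: str
    window_index: int


@dataclass
class FeatureMatrix:
    """Trials x features matrix with per-column provenance and trial labels."""

    values: np.ndarray
    column_meta: tuple[ColumnMeta, ...]
    labels: np.ndarray
    scaled: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise FeatureError("values must be 2-D (trials x features)")
        if self.values.shape[1] != len(self.column_meta):
            raise FeatureError("column_meta length must equal feature count")
        if self.values.shape[0] != len(self.labels):
            raise FeatureError("labels length must equal trial count")
        if not np.all(np.isfinite(self.values)):
            raise FeatureError("feature matrix contains NaN or Inf")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def select_types(self, feature_types: Sequence[str]) -> "FeatureMatrix":
        """Column subset containing only the given feature types."""
        wanted = set(feature_types)
        cols = [i for i, m in enumerate(self.column_meta) if m.feature_type in wanted]
        if not cols:
            raise FeatureError(f"no columns of types {sorted(wanted)}")
        return FeatureMatrix(
            self.values[:, cols],
            tuple(self.column_meta[i] for i in cols),
            self.labels,
            self.scaled,
        )

    def subset_rows(self, rows: Sequence[int]) -> "FeatureMatrix":
        rows = np.asarray(rows)
        return FeatureMatrix(
            self.values[rows], self.column_meta, self.labels[rows], self.scaled
        )


# ---------------------------------------------------------------------------
# analytic signal
# ---------------------------------------------------------------------------


def analytic_signal(x: np.ndarray, fs: float) -> AnalyticFeatures:
    """Hilbert-transform features of one band-limited series.

    Instantaneous frequency uses the central-difference derivative of the
    unwrapped phase (phase jumps larger than pi are corrected by +-2 pi
    before differentiation).  IF is unreliable on the first/last couple of
    samples; callers keep an epoch margin so those never enter a feature
    window.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1:
        raise FeatureError("analytic_signal expects a 1-D series")
    if x.size < 8:
        raise FeatureError("series too short for the analytic signal")
    if not np.all(np.isfinite(x)):
        raise FeatureError("series contains NaN or Inf")
    z = hilbert(x)
    ia = np.abs(z)
    ip = np.angle(z)
    unwrapped = np.unwrap(ip)
    if_hz = np.gradient(unwrapped) * fs / (2 * np.pi)
    return AnalyticFeatures(power=x**2, ia=ia, ip=ip, if_hz=if_hz, fs_hz=fs)


def _circular_mean(theta: np.ndarray) -> float:
    """Angle of the mean unit phasor, mapped back to [-pi, pi]."""
    return float(np.angle(np.mean(np.exp(1j * theta))))


def window_average(
    series: np.ndarray,
    fs: float,
    t0_index: int,
    spec: WindowSpec = WindowSpec(),
    *,
    circular: bool = False,
) -> np.ndarray:
    """Average a per-sample series in the moving windows of ``spec``.

    ``t0_index`` is the sample index of t = 0 (task onset).  Returns one
    value per window; ``circular=True`` uses the circular mean (for IP).
    """
    series = np.asarray(series, dtype=np.float64)
    n = series.shape[-1]
    lo, hi = spec.range_s
    first = t0_index + int(round(lo * fs))
    last = t0_index + int(round(hi * fs))
    if first < 0 or last > n:
        raise FeatureError(
            f"series covers [{-t0_index / fs:.3f}, {(n - t0_index) / fs:.3f}] s, "
            f"needs [{lo}, {hi}] s"
        )
    win_n = int(round(spec.win_len_s * fs))
    out = []
    for start_s in spec.starts_s():
        a = t0_index + int(round(start_s * fs))
        chunk = series[..., a:a + win_n]
        out.append(_circular_mean(chunk) if circular else float(np.mean(chunk)))
    return np.array(out)


def assemble(
    epochs: Sequence[TrialEpoch],
    bands: Mapping[str, tuple[float, float]] | None = None,
    feature_types: Sequence[str] = FEATURE_TYPES,
    spec: WindowSpec = WindowSpec(),
    *,
    ip_mean: str = "circular",
) -> FeatureMatrix:
    """Build the trials x features matrix from broadband epochs.

    Each epoch is band-passed per rhythm band, analytic features are
    computed per channel, then window-averaged.  Columns are ordered
    feature-type-major, then channel, band, window: with 21 channels, two
    bands and five windows each type contributes 210 columns, so the full
    four-type combination has 840.
    """
    if not epochs:
        raise FeatureError("no epochs given")
    if not feature_types:
        raise FeatureError("feature_types must be non-empty")
    unknown = set(feature_types) - set(FEATURE_TYPES)
    if unknown:
        raise FeatureError(f"unknown feature types {sorted(unknown)}")
    if ip_mean not in ("circular", "arithmetic"):
        raise FeatureError("ip_mean must be 'circular' or 'arithmetic'")
    bands = dict(DEFAULT_BANDS) if bands is None else dict(bands)
    fs = epochs[0].fs_hz
    chans = epochs[0].channel_labels
    n_t = epochs[0].samples.shape[1]
    for ep in epochs:
        if ep.channel_labels != chans or ep.samples.shape[1] != n_t or ep.fs_hz != fs:
            raise FeatureError("all epochs must share montage, length and fs")

    # order feature types canonically
    types = tuple(t for t in FEATURE_TYPES if t in feature_types)
    meta: list[ColumnMeta] = []
    for ftype in types:
        for ch in chans:
            for band in bands:
                for w in range(spec.n_windows):
                    meta.append(ColumnMeta(ch, band, ftype, w))

    rows = np.empty((len(epochs), len(meta)))
    labels = np.empty(len(epochs), dtype=int)
    for r, ep in enumerate(epochs):
        per_band = {
            band: bandpass_array(ep.samples, edges, fs)
            for band, edges in bands.items()
        }
        col = 0
        cache: dict[tuple[str, int], AnalyticFeatures] = {}
        for ftype in types:
            for ci in range(len(chans)):
                for band in bands:
                    key = (band, ci)
                    if key not in cache:
                        cache[key] = analytic_signal(per_band[band][ci], fs)
                    circ = ftype == "IP" and ip_mean == "circular"
                    vals = window_average(
                        cache[key].series(ftype), fs, ep.t0_index, spec,
                        circular=circ,
                    )
                    rows[r, col:col + spec.n_windows] = vals
                    col += spec.n_windows
        labels[r] = ep.label
    return FeatureMatrix(rows, tuple(meta), labels, scaled=False)


def scale(fm: FeatureMatrix, fit_rows: Sequence[int] | None = None) -> FeatureMatrix:
    """Min-max scale each column to [-1, 1] using ``fit_rows`` statistics.

    ``fit_rows`` defaults to all rows.  Columns that are constant on the
    fitted rows are mapped to zero with a warning.  Rows outside
    ``fit_rows`` are transformed with the fitted min/max and may land
    outside [-1, 1].
    """
    if fit_rows is None:
        fit_rows = np.arange(fm.n_trials)
    fit_rows = np.asarray(fit_rows)
    if fit_rows.size == 0:
        raise FeatureError("fit_rows must be non-empty")
    sub = fm.values[fit_rows]
    cmin = sub.min(axis=0)
    cmax = sub.max(axis=0)
    span = cmax - cmin
    flat = span == 0
    if np.any(flat):
        warnings.warn(
            f"{int(flat.sum())} constant feature columns scaled to 0", stacklevel=2
        )
    safe = np.where(flat, 1.0, span)
    vals = ((fm.values - cmin) / safe - 0.5) * 2.0
    vals[:, flat] = 0.0
    return FeatureMatrix(vals, fm.column_meta, fm.labels, scaled=True)
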