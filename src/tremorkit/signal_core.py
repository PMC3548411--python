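"""Ingestion and conditioning of acceleration time series.

Recordings are uniformly sampled, 1-3 axis acceleration traces in m/s².
The conditioning chain used throughout the package is: extract the trailing
analysis window, demean, optionally convert to band-limited displacement
(mm), and optionally downsample a fine reference channel onto the coarse
device grid with an anti-aliasing moving average.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "TremorRecording",
    "DisplacementSeries",
    "VALID_TASKS",
    "G_TO_MS2",
    "read_recording",
    "write_recording",
    "extract_analysis_window",
    "demean",
    "downsample_moving_average",
    "to_displacement",
    "passes_amplitude_threshold",
]

VALID_TASKS = ("rest", "postural", "kinetic", "intention")

#: Standard gravity, used to convert g-unit input to m/s².
G_TO_MS2 = 9.80665

#: Default trial length (s) and retained analysis window (s).
DEFAULT_TOTAL_S = 10.0
DEFAULT_KEEP_S = 8.5

#: Band (Hz) used for displacement reconstruction and spectral analysis.
DEFAULT_BAND = (1.0, 20.0)

#: Displacement-amplitude exclusion threshold (mm).
DEFAULT_THRESHOLD_MM = 1.0


@dataclass(frozen=True)
class TremorRecording:
    """A uniformly sampled multi-axis acceleration trial.

    Parameters
    ----------
    samples : ndarray, shape (n_samples, n_axes)
        Acceleration in m/s², one column per axis.
    rate : float
        Sampling rate in Hz (> 0).
    axes : tuple of str
        Ordered axis labels, 1-3 of ``{"x", "y", "z"}``.
    task : str
        One of :data:`VALID_TASKS`.
    trial_id : str
        Opaque identifier.
    t0 : float
        Start-time offset in seconds.
    """

    samples: np.ndarray
    rate: float
    axes: tuple[str, ...] = ("x",)
    task: str = "rest"
    trial_id: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        if arr.ndim != 2:
            raise ValueError("samples must be 1-D or 2-D (n_samples, n_axes)")
        object.__setattr__(self, "samples", arr)
        object.__setattr__(self, "axes", tuple(self.axes))
        if not (1 <= len(self.axes) <= 3):
            raise ValueError(f"expected 1-3 axes, got {len(self.axes)}")
        if arr.shape[1] != len(self.axes):
            raise ValueError(
                f"{arr.shape[1]} sample columns but {len(self.axes)} axis labels"
            )
        if arr.shape[0] < 1:
            raise ValueError("recording must contain at least one sample")
        if not np.isfinite(arr).all():
            raise ValueError("recording contains non-finite values")
        if not (self.rate > 0):
            raise ValueError(f"sampling rate must be > 0, got {self.rate}")
        if self.task not in VALID_TASKS:
            raise ValueError(
                f"unknown task {self.task!r}; expected one of {VALID_TASKS}"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.n_samples / self.rate

    def axis(self, label: str) -> np.ndarray:
        """Return the 1-D trace for one axis label."""
        try:
            idx = self.axes.index(label)
        except ValueError:
            raise KeyError(f"axis {label!r} not in {self.axes}") from None
        return self.samples[:, idx]


@dataclass(frozen=True)
class DisplacementSeries:
    """Band-limited displacement (mm) reconstructed from acceleration."""

    values: np.ndarray
    rate: float
    band: tuple[float, float] = DEFAULT_BAND
    source_axis: str = "x"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))


# ---------------------------------------------------------------------------
# Text I/O
# ---------------------------------------------------------------------------

_HEADER_KV = re.compile(r"(\w+)\s*=\s*([^\s]+)")
_SPLIT = re.compile(r"[,;\t ]+")


def read_recording(
    path: str | Path,
    rate: float | None = None,
    task: str | None = None,
    trial_id: str | None = None,
    unit: str = "m/s2",
    time_column: bool | None = None,
) -> TremorRecording:
    """Read a delimited-text acceleration recording.

    The file holds 1-3 numeric acceleration columns, optionally preceded by
    a time column, with optional ``# rate=<Hz> task=<label> axes=<x,y,z>``
    header lines.  Explicit arguments override header metadata.  An explicit
    time column must be uniform to within 1% of the sample period.

    Parameters
    ----------
    unit : {"m/s2", "g"}
        Unit of the stored values; ``g`` is converted with 9.80665.
    time_column : bool, optional
        Force interpretation of the first column.  When ``None`` the first
        column is treated as time if it is strictly increasing and uniformly
        spaced and at least one more column follows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such recording file: {path}")
    if unit not in ("m/s2", "g"):
        raise ValueError(f"unit must be 'm/s2' or 'g', got {unit!r}")

    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    row_numbers: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                meta.update(_HEADER_KV.findall(line))
                continue
            fields = [f for f in _SPLIT.split(line) if f]
            try:
                values = [float(f) for f in fields]
            except ValueError:
                if rows:
                    raise ValueError(
                        f"{path}: non-numeric data in row {lineno}: {line!r}"
                    ) from None
                # tolerate a single column-name header row
                continue
            if any(not math.isfinite(v) for v in values):
                raise ValueError(f"{path}: non-finite value in row {lineno}")
            rows.append(values)
            row_numbers.append(lineno)

    if not rows:
        raise ValueError(f"{path}: no numeric data rows")
    width = len(rows[0])
    for lineno, r in zip(row_numbers, rows):
        if len(r) != width:
            raise ValueError(
                f"{path}: row {lineno} has {len(r)} columns, expected {width}"
            )
    data = np.asarray(rows, dtype=float)

    if rate is None and "rate" in meta:
        rate = float(meta["rate"])
    if task is None:
        task = meta.get("task", "rest")

    if time_column is None:
        col0 = data[:, 0]
        dt = np.diff(col0)
        time_column = (
            data.shape[1] >= 2
            and data.shape[0] >= 3
            and bool(np.all(dt > 0))
            and float(np.ptp(dt)) <= 0.01 * float(np.median(dt))
        )

    if time_column:
        if data.shape[1] < 2:
            raise ValueError(f"{path}: time column present but no data columns")
        t = data[:, 0]
        data = data[:, 1:]
        dt = np.diff(t)
        if np.any(dt <= 0):
            bad = int(np.argmax(dt <= 0))
            raise ValueError(
                f"{path}: non-increasing timestamp at row {row_numbers[bad + 1]}"
            )
        period = 1.0 / rate if rate is not None else float(np.median(dt))
        off = np.abs(dt - period) > 0.01 * period
        if np.any(off):
            bad = int(np.argmax(off))
            raise ValueError(
                f"{path}: non-uniform timestamps (first offence at row "
                f"{row_numbers[bad + 1]}: dt={dt[bad]:.6g}, expected {period:.6g})"
            )
        if rate is None:
            rate = 1.0 / period

    if rate is None:
        raise ValueError(f"{path}: sampling rate not given and not in header")

    n_chan = data.shape[1]
    if not (1 <= n_chan <= 3):
        raise ValueError(
            f"{path}: expected 1-3 acceleration channels, found {n_chan}"
        )

    if "axes" in meta:
        axes = tuple(a for a in meta["axes"].split(",") if a)
    else:
        axes = ("x", "y", "z")[:n_chan]
    if len(axes) != n_chan:
        raise ValueError(
            f"{path}: header declares axes {axes} but file has {n_chan} channels"
        )

    if unit == "g":
        data = data * G_TO_MS2

    return TremorRecording(
        samples=data,
        rate=float(rate),
        axes=axes,
        task=task,
        trial_id=trial_id if trial_id is not None else path.stem,
    )


def write_recording(rec: TremorRecording, path: str | Path) -> Path:
    """Write a recording as delimited text with a metadata header.

    Values are written at 9 significant digits, which round-trips through
    :func:`read_recording` bit-identically for values representable at that
    precision.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(
            f"# rate={rec.rate:.9g} task={rec.task} axes={','.join(rec.axes)}\n"
        )
        for row in rec.samples:
            fh.write(",".join(f"{v:.9g}" for v in row) + "\n")
    return path


# ---------------------------------------------------------------------------
# Conditioning
# ---------------------------------------------------------------------------


def extract_analysis_window(
    rec: TremorRecording,
    total_s: float = DEFAULT_TOTAL_S,
    keep_s: float = DEFAULT_KEEP_S,
) -> TremorRecording:
    """Return the trailing ``keep_s`` seconds of a recording.

    The retained length is ``floor(keep_s * rate)`` samples taken from the
    end (510 samples for 8.5 s at 60 Hz); all metadata is preserved.
    """
    n_keep = int(math.floor(keep_s * rec.rate))
    if n_keep < 1:
        raise ValueError(f"keep_s={keep_s} retains no samples at {rec.rate} Hz")
    if rec.n_samples < n_keep:
        raise ValueError(
            f"recording too short: need {keep_s} s ({n_keep} samples) but only "
            f"{rec.duration:.6g} s ({rec.n_samples} samples) available"
        )
    return replace(rec, samples=rec.samples[-n_keep:])


def demean(series: np.ndarray) -> np.ndarray:
    """Subtract the mean (removes the gravity component)."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("cannot demean an empty series")
    return x - x.mean(axis=0)


def downsample_moving_average(
    series: np.ndarray, rate_in: float, rate_out: float
) -> np.ndarray:
    """Anti-aliased downsampling: centered moving average + grid resampling.

    A centered moving average of ``round(rate_in / rate_out)`` samples is
    applied (edge-replicated so constants are preserved), then the smoothed
    series is linearly interpolated onto the uniform ``rate_out`` grid.  The
    output holds ``floor(n * rate_out / rate_in)`` samples, i.e. duration is
    preserved to within one output sample.
    """
    if rate_out >= rate_in:
        raise ValueError(
            f"rate_out ({rate_out}) must be below rate_in ({rate_in})"
        )
    if rate_out <= 0:
        raise ValueError("rate_out must be positive")
    x = np.asarray(series, dtype=float)
    n = x.shape[0]
    w = max(1, int(round(rate_in / rate_out)))
    if w > 1:
        pad_lo = w // 2
        pad_hi = w - 1 - pad_lo
        padded = np.pad(x, (pad_lo, pad_hi), mode="edge")
        smooth = np.convolve(padded, np.full(w, 1.0 / w), mode="valid")
    else:
        smooth = x
    n_out = int(math.floor(n * rate_out / rate_in))
    if n_out < 1:
        raise ValueError("input too short to produce any output sample")
    t_in = np.arange(n) / rate_in
    t_out = np.arange(n_out) / rate_out
    return np.interp(t_out, t_in, smooth)


def to_displacement(
    rec_axis: np.ndarray,
    rate: float,
    band: tuple[float, float] = DEFAULT_BAND,
    source_axis: str = "x",
) -> DisplacementSeries:
    """Band-limited double integration, m/s² → mm.

    Equivalent to dividing each in-band Fourier component by
    ``(2*pi*f)**2`` and zeroing everything else, but conditioned for finite
    windows: naive spectral division amplifies window-edge leakage of the
    (large, ~f² scaled) acceleration onto the low-frequency bins.  Instead
    the acceleration is double-integrated in the time domain (trapezoid,
    locally exact, no wraparound), integration constants and drift are
    removed as a quadratic trend, and only then is the mm-scale
    displacement band-limited spectrally — with the trapezoid integrator's
    frequency response ``(sin(x)/x``-like) corrected analytically in-band.
    Worst-case RMS error for a pure in-band sinusoid is < 0.5% across
    2-15 Hz at 60 Hz over an 8.5 s window.
    """
    low, high = band
    if low <= 0:
        raise ValueError("band lower edge must be > 0 for double integration")
    if high <= low:
        raise ValueError(f"invalid band {band}")
    x = np.asarray(rec_axis, dtype=float)
    n = x.shape[0]
    if n < 2.0 * rate / low:
        raise ValueError(
            f"window of {n} samples too short for the {low} Hz band edge"
        )
    period = 1.0 / rate
    idx = np.arange(n)
    vel = cumulative_trapezoid(x, dx=period, initial=0.0)
    vel -= np.polyval(np.polyfit(idx, vel, 1), idx)
    disp = cumulative_trapezoid(vel, dx=period, initial=0.0)
    disp -= np.polyval(np.polyfit(idx, disp, 2), idx)
    spectrum = np.fft.rfft(disp)
    freqs = np.fft.rfftfreq(n, d=period)
    out = np.zeros_like(spectrum)
    mask = (freqs >= low) & (freqs <= high)
    half_angle = np.pi * freqs[mask] * period  # omega * T / 2
    out[mask] = spectrum[mask] * (np.tan(half_angle) / half_angle) ** 2
    disp_m = np.fft.irfft(out, n)
    return DisplacementSeries(
        values=disp_m * 1000.0, rate=rate, band=(low, high), source_axis=source_axis
    )


def passes_amplitude_threshold(
    metrics_rms: float, threshold: float = DEFAULT_THRESHOLD_MM
) -> bool:
    """True iff the displacement RMS (mm) reaches the exclusion threshold.

    Amplitudes *below* the threshold are excluded; an RMS exactly equal to
    the threshold passes.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return metrics_rms >= threshold
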