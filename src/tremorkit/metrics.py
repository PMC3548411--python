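"""Time- and frequency-domain tremor characteristics.

One analysis window yields eight numbers: RMS amplitude, regularity
(epoch-amplitude stability), the percentage of spectral power in the 3-7 Hz
band, median power frequency, peak power frequency, two 68%-power
dispersion bandwidths (median- and peak-centered), and the harmonic index.

Spectra are one-sided FFT power restricted to the 1-20 Hz band.  The
window is zero-padded to the next power of two (512 for the standard
510-sample window, giving a bin width of ~0.117 Hz) and no taper is
applied, so leakage behaviour is deterministic.

Power within each retained bin is treated as uniformly distributed over
the bin's frequency interval (clipped at the band edges); the median power
frequency and its inverse integral share this convention, so integrating
the spectrum below the MPF recovers exactly half the total power.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .signal_core import (
    DEFAULT_BAND,
    DEFAULT_KEEP_S,
    TremorRecording,
    demean,
    downsample_moving_average,
    extract_analysis_window,
    to_displacement,
)

__all__ = [
    "PowerSpectrum",
    "TremorMetrics",
    "power_spectrum",
    "power_distribution",
    "median_power_frequency",
    "peak_power_frequency",
    "power_dispersion",
    "power_dispersion_band",
    "harmonic_index",
    "rms_amplitude",
    "regularity",
    "characterize",
    "metrics_frame",
    "write_metrics_csv",
    "read_metrics_csv",
]

#: Pathological-tremor band (Hz) for the power-distribution metric.
DEFAULT_DIST_BAND = (3.0, 7.0)

#: Power fraction captured by the dispersion bandwidth.
DEFAULT_DISPERSION_FRACTION = 0.68

METRIC_NAMES = (
    "rms",
    "regularity",
    "pow_dist",
    "mpf",
    "peak",
    "disp",
    "disp_peak",
    "hi",
)


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided power spectrum restricted to the analysis band."""

    freqs: np.ndarray
    power: np.ndarray
    df: float
    band: tuple[float, float] = DEFAULT_BAND

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        power = np.asarray(self.power, dtype=float)
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "power", power)
        if freqs.shape != power.shape or freqs.ndim != 1:
            raise ValueError("freqs and power must be matching 1-D arrays")
        if freqs.size == 0:
            raise ValueError("empty spectrum")
        if np.any(np.diff(freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(power < 0):
            raise ValueError("spectral power must be nonnegative")
        if freqs[0] < self.band[0] - 1e-12 or freqs[-1] > self.band[1] + 1e-12:
            raise ValueError(f"freqs outside the declared band {self.band}")

    @property
    def total_power(self) -> float:
        return float(self.power.sum())

    def bin_edges(self) -> tuple[np.ndarray, np.ndarray]:
        """Lower/upper frequency edges of each bin, clipped at the band."""
        half = self.df / 2.0
        lo = np.clip(self.freqs - half, self.band[0], self.band[1])
        hi = np.clip(self.freqs + half, self.band[0], self.band[1])
        return lo, hi


def power_spectrum(
    window: np.ndarray,
    rate: float,
    band: tuple[float, float] = DEFAULT_BAND,
    nfft: int | None = None,
) -> PowerSpectrum:
    """One-sided FFT power of a demeaned window, keeping bins in ``band``.

    ``nfft`` defaults to the next power of two above the window length.
    """
    x = np.asarray(window, dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples for a spectrum")
    if rate <= 2.0 * band[1]:
        raise ValueError(
            f"rate {rate} Hz puts the Nyquist frequency below the "
            f"{band[1]} Hz band edge"
        )
    if nfft is None:
        nfft = 1 << (n - 1).bit_length()
    spec = np.fft.rfft(x, nfft)
    power = (2.0 / (n * n)) * np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0 / rate)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    return PowerSpectrum(
        freqs=freqs[mask], power=power[mask], df=rate / nfft, band=band
    )


def power_distribution(
    spec: PowerSpectrum, band: tuple[float, float] = DEFAULT_DIST_BAND
) -> float:
    """Percentage of total power inside ``band`` (default 3-7 Hz)."""
    total = spec.total_power
    if total <= 0:
        raise ValueError("zero total power")
    mask = (spec.freqs >= band[0]) & (spec.freqs <= band[1])
    return 100.0 * float(spec.power[mask].sum()) / total


def median_power_frequency(spec: PowerSpectrum) -> float:
    """Frequency splitting the spectral power into equal halves.

    Interpolates linearly within the crossing bin under the uniform
    bin-density convention, so the result is continuous in the power values.
    """
    total = spec.total_power
    if total <= 0:
        raise ValueError("zero total power")
    target = 0.5 * total
    cum = np.cumsum(spec.power)
    k = int(np.searchsorted(cum, target))
    k = min(k, spec.power.size - 1)
    lo, hi = spec.bin_edges()
    before = cum[k] - spec.power[k]
    width = hi[k] - lo[k]
    if spec.power[k] <= 0 or width <= 0:
        return float(spec.freqs[k])
    return float(lo[k] + width * (target - before) / spec.power[k])


def power_below(spec: PowerSpectrum, freq: float) -> float:
    """Fraction of total power below ``freq`` (same bin-density convention).

    Inverse of :func:`median_power_frequency`: for ``freq`` equal to the MPF
    this returns 0.5 up to float rounding.
    """
    total = spec.total_power
    if total <= 0:
        raise ValueError("zero total power")
    lo, hi = spec.bin_edges()
    width = np.where(hi > lo, hi - lo, 1.0)
    frac = np.clip((freq - lo) / width, 0.0, 1.0)
    frac = np.where(hi > lo, frac, np.where(spec.freqs < freq, 1.0, 0.0))
    return float(np.sum(spec.power * frac)) / total


def peak_power_frequency(spec: PowerSpectrum) -> float:
    """Frequency of the maximum-power bin; ties break to the lowest."""
    if spec.total_power <= 0:
        raise ValueError("zero total power")
    return float(spec.freqs[int(np.argmax(spec.power))])


def power_dispersion_band(
    spec: PowerSpectrum,
    center: float,
    fraction: float = DEFAULT_DISPERSION_FRACTION,
) -> tuple[float, float]:
    """Frequency band about ``center`` holding ``fraction`` of the power.

    Starting from the bin nearest ``center``, the band grows one bin at a
    time, alternating sides beginning with the lower side, clipping at the
    spectrum edges, until the contained power reaches
    ``fraction * total_power``.  Returns the outer edges of the included
    bins.
    """
    total = spec.total_power
    if total <= 0:
        raise ValueError("zero total power")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    k = int(np.argmin(np.abs(spec.freqs - center)))
    i_lo = i_hi = k
    contained = float(spec.power[k])
    target = fraction * total * (1.0 - 1e-12)
    grow_low = True
    n = spec.power.size
    while contained < target and (i_lo > 0 or i_hi < n - 1):
        if grow_low and i_lo > 0:
            i_lo -= 1
            contained += float(spec.power[i_lo])
        elif i_hi < n - 1:
            i_hi += 1
            contained += float(spec.power[i_hi])
        elif i_lo > 0:
            i_lo -= 1
            contained += float(spec.power[i_lo])
        grow_low = not grow_low
    lo, hi = spec.bin_edges()
    return float(lo[i_lo]), float(hi[i_hi])


def power_dispersion(
    spec: PowerSpectrum,
    center: float,
    fraction: float = DEFAULT_DISPERSION_FRACTION,
) -> float:
    """Width (Hz) of :func:`power_dispersion_band` about ``center``."""
    lo, hi = power_dispersion_band(spec, center, fraction)
    return hi - lo


def harmonic_index(spec: PowerSpectrum) -> float:
    """Sharpness of the spectrum: 1 - (spectral area / peak rectangle area).

    The rectangle spans the retained band horizontally and the highest peak
    vertically; with uniform bins this reduces to ``1 - mean / max`` of the
    bin powers.  A flat spectrum gives 0; a single pure line approaches 1.
    """
    total = spec.total_power
    if total <= 0:
        raise ValueError("zero total power")
    peak = float(spec.power.max())
    return 1.0 - float(spec.power.mean()) / peak


def rms_amplitude(window: np.ndarray) -> float:
    """Root mean square of a demeaned window."""
    x = np.asarray(window, dtype=float)
    if x.size == 0:
        raise ValueError("empty window")
    return float(np.sqrt(np.mean(x**2)))


def regularity(window: np.ndarray, rate: float) -> float:
    """Amplitude stability: SD of per-1-s-epoch RMS of the normalized window.

    The window is z-normalized, split into consecutive non-overlapping 1-s
    epochs (the trailing partial epoch is dropped), RMS is computed per
    epoch, and the sample SD across epoch RMS values is returned.  Lower
    values mean a steadier tremor.  A zero-variance window yields 0 with a
    warning.
    """
    x = np.asarray(window, dtype=float)
    if x.size / rate < 2.0:
        raise ValueError("regularity needs a window of at least 2 s")
    sd = float(x.std())
    if sd == 0.0:
        warnings.warn("zero-variance window: regularity defined as 0")
        return 0.0
    z = (x - x.mean()) / sd
    spe = int(round(rate))
    n_epochs = z.size // spe
    epochs = z[: n_epochs * spe].reshape(n_epochs, spe)
    epoch_rms = np.sqrt(np.mean(epochs**2, axis=1))
    return float(np.std(epoch_rms, ddof=1))


@dataclass(frozen=True)
class TremorMetrics:
    """The eight-number characterization of one trial axis.

    ``rms`` is in mm on the displacement pathway and m/s² on the
    acceleration pathway; frequencies are in Hz; ``pow_dist`` is a
    percentage; ``hi`` lies in [0, 1].
    """

    rms: float
    regularity: float
    pow_dist: float
    mpf: float
    peak: float
    disp: float
    disp_peak: float
    hi: float
    axis: str = "x"

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def characterize(
    rec: TremorRecording,
    pathway: str = "displacement",
    keep_s: float = DEFAULT_KEEP_S,
    band: tuple[float, float] = DEFAULT_BAND,
    dist_band: tuple[float, float] = DEFAULT_DIST_BAND,
    fraction: float = DEFAULT_DISPERSION_FRACTION,
    target_rate: float | None = None,
) -> list[TremorMetrics]:
    """Run the full per-axis chain and return all eight metrics per axis.

    Chain: [moving-average downsample to ``target_rate`` if the recording is
    finer] → trailing ``keep_s`` window → demean → [band-limited
    displacement, mm, if ``pathway == "displacement"``] → metrics.
    """
    if pathway not in ("acceleration", "displacement"):
        raise ValueError(f"unknown pathway {pathway!r}")
    rate = rec.rate
    series = {}
    for label in rec.axes:
        x = rec.axis(label)
        if target_rate is not None and rec.rate > target_rate:
            x = downsample_moving_average(x, rec.rate, target_rate)
            rate = target_rate
        series[label] = x

    n_keep = int(np.floor(keep_s * rate))
    out: list[TremorMetrics] = []
    for label, x in series.items():
        if x.shape[0] < n_keep:
            raise ValueError(
                f"axis {label!r}: recording shorter than the {keep_s} s window"
            )
        w = demean(x[-n_keep:])
        if pathway == "displacement":
            w = to_displacement(w, rate, band=band, source_axis=label).values
        spec = power_spectrum(w, rate, band=band)
        if spec.total_power <= 0:
            raise ValueError(f"axis {label!r}: zero total power in {band} Hz")
        mpf = median_power_frequency(spec)
        peak = peak_power_frequency(spec)
        out.append(
            TremorMetrics(
                rms=rms_amplitude(w),
                regularity=regularity(w, rate),
                pow_dist=power_distribution(spec, band=dist_band),
                mpf=mpf,
                peak=peak,
                disp=power_dispersion(spec, mpf, fraction),
                disp_peak=power_dispersion(spec, peak, fraction),
                hi=harmonic_index(spec),
                axis=label,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["trial_id", "task", "channel", "axis", *METRIC_NAMES]


def metrics_frame(
    records: list[tuple[str, str, str, TremorMetrics]]
) -> pd.DataFrame:
    """Build the canonical metrics table from (trial_id, task, channel, m)."""
    rows = []
    for trial_id, task, channel, m in records:
        rows.append(
            {
                "trial_id": trial_id,
                "task": task,
                "channel": channel,
                "axis": m.axis,
                **m.as_dict(),
            }
        )
    df = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    return df.sort_values(["channel", "task", "trial_id", "axis"]).reset_index(
        drop=True
    )


def write_metrics_csv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.9g")
    return path


def read_metrics_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metric columns {missing}")
    return df
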