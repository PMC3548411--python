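"""Seeded synthetic tremor generator with paired coarse/fine channels.

A trial is a sum of displacement sinusoids (carrier, amplitude-modulation
sidebands, an optional second harmonic, and — for the kinetic task — a slow
high-amplitude voluntary component), converted term-wise to acceleration
and rendered through two simultaneous sensor models: a coarse, quantized
60 Hz "phone" channel and a fine 2048 Hz "lab" channel.  Phases come from
the trial seed so the two channels sample the same underlying movement;
sensor-noise draws are independent per channel.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical
from .metrics import TremorMetrics, characterize, metrics_frame
from .signal_core import VALID_TASKS, TremorRecording, write_recording

__all__ = [
    "SimulationSpec",
    "ChannelModel",
    "PairedTrial",
    "PHONE_CHANNEL",
    "LAB_CHANNEL",
    "DEFAULT_RANGES",
    "synth_trial",
    "synth_battery",
    "synth_rater",
    "analyze_battery",
    "write_battery",
    "read_battery_manifest",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Generative parameters of one synthetic trial.

    ``displacement_amp`` is the target displacement RMS of the tremor
    component in mm; ``voluntary_amp`` (kinetic task) is the RMS of the
    slow voluntary component.  ``harmonic_frac`` is the power at twice the
    tremor frequency as a fraction of the carrier power.
    """

    tremor_freq: float = 5.0
    displacement_amp: float = 3.0
    mod_depth: float = 0.0
    mod_rate: float = 0.0
    harmonic_frac: float = 0.0
    noise_sd: float = 0.0
    voluntary_amp: float = 0.0
    voluntary_freq: float = 1.0
    duration_s: float = 10.0
    task: str = "rest"
    seed: int = 0
    trial_id: str = ""

    def __post_init__(self) -> None:
        if not (1.0 < self.tremor_freq < 20.0):
            raise ValueError("tremor_freq must lie in (1, 20) Hz")
        if not (0.0 < self.voluntary_freq < 3.0):
            raise ValueError("voluntary_freq must lie below 3 Hz")
        for name in ("displacement_amp", "mod_depth", "harmonic_frac",
                     "noise_sd", "voluntary_amp", "mod_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mod_rate >= 1.0:
            raise ValueError("mod_rate must be below 1 Hz")
        if self.harmonic_frac >= 1.0:
            raise ValueError("harmonic_frac must be below 1")
        if self.duration_s < 10.0:
            raise ValueError("duration must be >= 10 s")
        if self.task not in VALID_TASKS:
            raise ValueError(f"unknown task {self.task!r}")


@dataclass(frozen=True)
class ChannelModel:
    """Sensor model: rate, acceleration resolution, noise floor, crosstalk.

    ``crosstalk`` is the fraction of the voluntary-movement amplitude that
    bleeds into the recorded axis as slowly modulated sidebands — a
    stand-in for inter-axis coupling of a hand-held multi-axis sensor
    whose orientation drifts during transport movements.  The single-axis
    reference sensor has no such coupling.
    """

    rate: float
    quant_step: float = 0.0
    noise_sd: float = 0.0
    label: str = "phone"
    crosstalk: float = 0.0

    def __post_init__(self) -> None:
        if self.rate <= 40.0:
            raise ValueError("channel rate must exceed 40 Hz")
        if self.quant_step < 0 or self.noise_sd < 0 or self.crosstalk < 0:
            raise ValueError("quant_step, noise_sd and crosstalk must be >= 0")


# Phone quantization/noise chosen so sub-millimetre trials fall into the
# quantization floor while >= 1 mm trials keep their spectral shape
# (calibrated against the thresholding-improves-agreement property).
PHONE_CHANNEL = ChannelModel(
    rate=60.0, quant_step=0.153, noise_sd=0.02, label="phone", crosstalk=0.35
)
LAB_CHANNEL = ChannelModel(rate=2048.0, quant_step=0.0, noise_sd=0.002, label="lab")


@dataclass(frozen=True)
class PairedTrial:
    """One movement rendered through both channels."""

    spec: SimulationSpec
    phone: TremorRecording
    lab: TremorRecording


def _tremor_components(
    spec: SimulationSpec, phases: np.ndarray
) -> list[tuple[float, float, float]]:
    """Displacement sinusoids (amp_mm, freq_hz, phase) for the tremor part.

    Amplitude modulation of the carrier is expanded analytically into
    sidebands at f ± mod_rate, so every term has an exact second
    derivative.
    """
    phi, phi2, phim = phases
    f = spec.tremor_freq
    comps = [(1.0, f, phi)]
    if spec.harmonic_frac > 0:
        # power fraction hf of the tremor total lies at 2f:
        # amplitude ratio sqrt(hf / (1 - hf)) relative to the carrier
        comps.append(
            (math.sqrt(spec.harmonic_frac / (1.0 - spec.harmonic_frac)),
             2.0 * f, phi2)
        )
    if spec.mod_depth > 0 and spec.mod_rate > 0:
        m = spec.mod_depth
        g = spec.mod_rate
        # (1 + m sin(2πgt+φm)) sin(2πft+φ): product-to-sum expansion
        comps.append((m / 2.0, f - g, phi - phim + math.pi / 2.0))
        comps.append((m / 2.0, f + g, phi + phim - math.pi / 2.0))
    rms_unit = math.sqrt(sum(a * a for a, _, _ in comps) / 2.0)
    scale = spec.displacement_amp / rms_unit if rms_unit > 0 else 0.0
    return [(a * scale, fr, ph) for a, fr, ph in comps]


def _phase_rng(spec: SimulationSpec) -> np.random.Generator:
    return np.random.default_rng([spec.seed, 0x7F42])


def _noise_rng(spec: SimulationSpec, channel: ChannelModel) -> np.random.Generator:
    return np.random.default_rng([spec.seed, zlib.crc32(channel.label.encode())])


def trial_components(spec: SimulationSpec) -> list[tuple[float, float, float]]:
    """All displacement components (amp_mm, freq_hz, phase) of a trial."""
    rng = _phase_rng(spec)
    phases = rng.uniform(0.0, 2.0 * math.pi, size=4)
    comps = _tremor_components(spec, phases[:3])
    if spec.voluntary_amp > 0:
        comps.append(
            (spec.voluntary_amp * math.sqrt(2.0), spec.voluntary_freq, phases[3])
        )
    return comps


def _crosstalk_components(
    spec: SimulationSpec, crosstalk: float
) -> list[tuple[float, float, float]]:
    """Inter-axis bleed of the voluntary movement: two sidebands around
    the voluntary frequency, as produced by a slow orientation drift of a
    hand-held multi-axis sensor.  Deterministic per trial seed."""
    rng = np.random.default_rng([spec.seed, 0x51DE])
    delta = float(rng.uniform(0.15, 0.5))
    ph1, ph2 = rng.uniform(0.0, 2.0 * math.pi, size=2)
    amp = crosstalk * spec.voluntary_amp * math.sqrt(2.0)
    return [
        (amp, max(spec.voluntary_freq - delta, 0.05), ph1),
        (amp, spec.voluntary_freq + delta, ph2),
    ]


def synth_trial(spec: SimulationSpec, channel: ChannelModel) -> TremorRecording:
    """Render one trial through a sensor model; deterministic per seed.

    The displacement components are differentiated analytically (each
    sinusoid scaled by -(2πf)²), sampled on the channel grid, corrupted
    with Gaussian sensor noise, and quantized to ``channel.quant_step``.
    """
    n = int(round(spec.duration_s * channel.rate))
    t = np.arange(n) / channel.rate
    comps = trial_components(spec)
    if channel.crosstalk > 0 and spec.voluntary_amp > 0:
        comps = comps + _crosstalk_components(spec, channel.crosstalk)
    accel = np.zeros(n)
    for amp_mm, f, ph in comps:
        # displacement mm → acceleration m/s²
        accel -= (amp_mm / 1000.0) * (2.0 * math.pi * f) ** 2 * np.sin(
            2.0 * math.pi * f * t + ph
        )
    sd = math.hypot(spec.noise_sd, channel.noise_sd)
    if sd > 0:
        accel = accel + _noise_rng(spec, channel).normal(0.0, sd, size=n)
    if channel.quant_step > 0:
        accel = np.round(accel / channel.quant_step) * channel.quant_step
    return TremorRecording(
        samples=accel,
        rate=channel.rate,
        axes=("x",),
        task=spec.task,
        trial_id=spec.trial_id or f"trial-{spec.seed}",
    )


# Parameter ranges for the battery draw; amplitudes are log-uniform so the
# battery straddles the 1 mm visibility threshold and reaches the
# excursion ceiling of the clinical scale (~21 mm RMS = 6 cm peak-to-peak).
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "tremor_freq": (3.0, 10.0),
    "displacement_amp": (0.15, 30.0),
    "mod_depth": (0.0, 0.3),
    "mod_rate": (0.1, 0.8),
    "harmonic_frac": (0.0, 0.2),
    "noise_sd": (0.005, 0.02),
    "voluntary_amp": (10.0, 40.0),
    "voluntary_freq": (0.3, 2.0),
}


def _draw_spec(
    rng: np.random.Generator,
    task: str,
    trial_id: str,
    ranges: dict[str, tuple[float, float]],
) -> SimulationSpec:
    def u(key: str) -> float:
        lo, hi = ranges[key]
        return float(rng.uniform(lo, hi))

    lo, hi = ranges["displacement_amp"]
    if lo <= 0 or hi <= lo:
        raise ValueError("degenerate displacement_amp range")
    amp = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    kinetic = task == "kinetic"
    return SimulationSpec(
        tremor_freq=u("tremor_freq"),
        displacement_amp=amp,
        mod_depth=u("mod_depth"),
        mod_rate=u("mod_rate"),
        harmonic_frac=u("harmonic_frac"),
        noise_sd=u("noise_sd"),
        voluntary_amp=u("voluntary_amp") if kinetic else 0.0,
        voluntary_freq=u("voluntary_freq") if kinetic else 1.0,
        duration_s=10.0,
        task=task,
        seed=int(rng.integers(0, 2**31 - 1)),
        trial_id=trial_id,
    )


def synth_battery(
    n_per_task: int = 48,
    seed: int = 0,
    ranges: dict[str, tuple[float, float]] | None = None,
    phone: ChannelModel = PHONE_CHANNEL,
    lab: ChannelModel = LAB_CHANNEL,
    tasks: tuple[str, ...] = VALID_TASKS,
) -> list[PairedTrial]:
    """Draw and render the full experimental battery (default 4 x 48 trials)."""
    if n_per_task < 1:
        raise ValueError("n_per_task must be >= 1")
    eff = dict(DEFAULT_RANGES)
    if ranges:
        eff.update(ranges)
    master = np.random.default_rng(seed)
    trials = []
    for task in tasks:
        for i in range(n_per_task):
            spec = _draw_spec(master, task, f"{task}-{i:03d}", eff)
            trials.append(
                PairedTrial(
                    spec=spec,
                    phone=synth_trial(spec, phone),
                    lab=synth_trial(spec, lab),
                )
            )
    return trials


def synth_rater(
    true_excursion_cm: float,
    noise_sd_steps: float,
    rng: np.random.Generator | int = 0,
    scale: clinical.ClinicalScale = clinical.DEFAULT_SCALE,
    visibility_cm: float = clinical.PEAK_TO_PEAK_PER_RMS * 0.1,
) -> int:
    """Noisy clinical rating of a known excursion.

    The excursion is perturbed by seeded Gaussian noise expressed in scale
    steps (1 step = the first bin width); perturbed excursions below the
    visibility floor (the 1 mm RMS equivalent by default) score 0.
    """
    if noise_sd_steps < 0:
        raise ValueError("noise must be >= 0")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    step_cm = scale.boundaries[0]
    seen = true_excursion_cm + rng.normal(0.0, noise_sd_steps * step_cm)
    if seen < visibility_cm:
        return 0
    return min(clinical.score_from_amplitude(seen, scale), scale.max_score)


# ---------------------------------------------------------------------------
# Battery analysis and persistence
# ---------------------------------------------------------------------------


def analyze_battery(
    trials: list[PairedTrial],
    pathway: str = "displacement",
    target_rate: float = 60.0,
) -> pd.DataFrame:
    """Metrics table for both channels of every trial.

    The lab channel is moving-average downsampled to ``target_rate`` before
    analysis, mirroring the reference-processing chain; the phone channel
    is analyzed at its native rate.  The default displacement pathway
    reports ``rms`` in mm — the quantity the visibility threshold is
    defined on.  ``"mixed"`` keeps the displacement RMS but computes the
    spectral metrics and regularity from the recorded acceleration.
    """
    import dataclasses

    records = []
    for trial in trials:
        for channel, rec in (("phone", trial.phone), ("lab", trial.lab)):
            tr = target_rate if rec.rate > target_rate else None
            if pathway == "mixed":
                accel = characterize(rec, pathway="acceleration", target_rate=tr)
                disp = characterize(rec, pathway="displacement", target_rate=tr)
                ms = [
                    dataclasses.replace(a, rms=d.rms)
                    for a, d in zip(accel, disp)
                ]
            else:
                ms = characterize(rec, pathway=pathway, target_rate=tr)
            for m in ms:
                records.append((trial.spec.trial_id, trial.spec.task, channel, m))
    return metrics_frame(records)


_MANIFEST_FIELDS = (
    "trial_id",
    "task",
    "tremor_freq",
    "displacement_amp",
    "mod_depth",
    "mod_rate",
    "harmonic_frac",
    "noise_sd",
    "voluntary_amp",
    "voluntary_freq",
    "duration_s",
    "seed",
)


def write_battery(trials: list[PairedTrial], outdir: str | Path) -> Path:
    """Write per-trial phone/lab CSV pairs plus a ground-truth manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for trial in trials:
        phone_path = outdir / f"{trial.spec.trial_id}_phone.csv"
        lab_path = outdir / f"{trial.spec.trial_id}_lab.csv"
        write_recording(trial.phone, phone_path)
        write_recording(trial.lab, lab_path)
        row = {k: getattr(trial.spec, k) for k in _MANIFEST_FIELDS}
        row["phone_path"] = phone_path.name
        row["lab_path"] = lab_path.name
        rows.append(row)
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False, float_format="%.9g")
    return manifest


def read_battery_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _MANIFEST_FIELDS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing columns {missing}")
    return df
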