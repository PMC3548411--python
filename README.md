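# tremorkit

Quantification of pathological tremor from accelerometer recordings:
time- and frequency-domain tremor metrics, method-agreement statistics, an
amplitude-anchored 0–5 clinical scale, and a seeded simulator that renders
the same synthetic tremor through a coarse, quantized 60 Hz "phone"
channel and a fine 2048 Hz "laboratory" channel.

## What it computes

From each trial (10 s recording, last 8.5 s analyzed, demeaned):

| metric | meaning |
|---|---|
| `rms` | RMS amplitude (mm on the displacement pathway, m/s² on acceleration) |
| `regularity` | SD of per-1-s-epoch RMS of the z-normalized window (lower = steadier) |
| `pow_dist` | % of 1–20 Hz spectral power inside 3–7 Hz |
| `mpf` | median power frequency (within-bin interpolated) |
| `peak` | peak power frequency (ties break low) |
| `disp` | width of the 68%-power band centered at the MPF |
| `disp_peak` | same, centered at the peak frequency |
| `hi` | harmonic index: 1 − spectral area / peak rectangle (1 = pure line) |

Spectra are one-sided FFT power on the 1–20 Hz band, rectangular window,
zero-padded to the next power of two (bin width ≈ 0.117 Hz at 60 Hz).
Acceleration is converted to band-limited displacement (mm) by a
conditioned double integration (time-domain integration, quadratic
detrend, in-band spectral masking with trapezoid-response correction).
Trials with displacement RMS below 1 mm can be excluded — the amplitude
at which tremor becomes clinically visible.

The `agreement` module supplies Pearson r/p, Bland–Altman bias/SD/limits
of agreement, Lin's concordance correlation coefficient, ICC(2,1) with a
95% CI, and adjacent-group t-tests with Holm step-down adjustment and
noncentral-t post-hoc power.  The `clinical` module maps visible tremor
excursion (cm) onto the 0–5 scale (0 = no visible tremor, 1 = up to
1.5 cm, …, 5 = 6 cm and above), bridges recorded RMS to excursion via the
sinusoidal peak-to-peak factor 2√2, and correlates scores with the
task-appropriate severity marker (RMS, or the 3–7 Hz power fraction on
the kinetic task).

## CLI

```sh
# 4 tasks x 48 paired trials (phone + lab channel CSVs + manifest)
tremorkit --seed 1 simulate --n-per-task 48 --out battery/

# eight metrics per trial x channel x axis
tremorkit analyze battery/ --out metrics.csv

# phone-vs-lab agreement table (with and without the 1 mm threshold)
tremorkit agree --phone phone.csv --lab lab.csv --out agreement.csv

# clinical-score correlations + contiguous-score t-test report
tremorkit scale scored.csv --out clinical.csv
```

Global flags: `--config <yaml>`, `--seed`, `--threshold-mm`,
`--no-threshold`, `--log-level`.  All analysis constants live in
`RunConfig` (rates 60/2048 Hz, 8.5 s window, 1–20 Hz band, 3–7 Hz
distribution band, 0.68 dispersion fraction, 1 mm threshold, 1.5 cm scale
steps); any override is echoed to the log and dumped as `config.yaml`
beside every output.

## Layout

- `src/tremorkit/signal_core.py` — recording I/O, windowing, demeaning, moving-average downsampling, displacement conversion, amplitude threshold
- `src/tremorkit/metrics.py` — the eight tremor metrics and the spectrum type
- `src/tremorkit/agreement.py` — paired-method and group-comparison statistics
- `src/tremorkit/clinical.py` — 0–5 scale, score/amplitude bridging, per-task correlations
- `src/tremorkit/simulator.py` — seeded trial/battery/rater generators, paired-channel rendering
- `src/tremorkit/cli.py` — `simulate` / `analyze` / `agree` / `scale` commands and `RunConfig`
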