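"""Synthesis of artificial courtship-song stimuli.

Pulse songs are trains of brief sine pulses at a fixed inter-pulse interval
(IPI, onset-to-onset); sine songs are continuous carrier tones.  The
intrapulse (carrier) frequency is 167 Hz for D. melanogaster stimuli and
333 Hz for D. simulans.  The intermittent design inserts 2 s of silence
between 1-s bursts; the continuous design plays an uninterrupted train.

Each pulse spans two carrier cycles (~12 ms at 167 Hz) with a 10% cosine
taper at each end.  Under the rule that every pulse must end within its
burst, this pulse length reproduces the printed per-burst counts for all
three standard IPIs simultaneously: 66 pulses at 15-ms IPI, 29 at 35 ms and
10 at 105 ms in a 1-s burst.

An oscillating-IPI song modulates the IPI sinusoidally over a 58-s period
between 29 and 40 ms, mimicking the natural rhythm of the species song.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal.windows import tukey

__all__ = [
    "StimulusSpec",
    "Waveform",
    "make_pulse",
    "count_pulses_per_burst",
    "make_song",
    "make_oscillating_ipi",
    "write_wav",
    "read_wav",
]

MELANOGASTER_CARRIER_HZ = 167.0
SIMULANS_CARRIER_HZ = 333.0


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class IPIOscillation:
    """Sinusoidal IPI modulation: period 58 s, IPI swinging 29-40 ms."""

    period_s: float = 58.0
    ipi_min_ms: float = 29.0
    ipi_max_ms: float = 40.0

    def __post_init__(self) -> None:
        if self.ipi_min_ms >= self.ipi_max_ms:
            raise ParameterError("ipi_min must be below ipi_max")
        if self.period_s <= 0:
            raise ParameterError("oscillation period must be positive")


@dataclass
class StimulusSpec:
    """Parametric description of an artificial song.

    ``silence_s = 0`` yields the continuous song; ``fixed_pulse_count``
    overrides the per-burst count and lets the burst stretch to fit (e.g.
    29 pulses at 105-ms IPI span a burst that rounds to 3 s).
    """

    kind: str = "pulse"  # "pulse" | "sine"
    ipi_ms: float = 35.0
    carrier_hz: float = MELANOGASTER_CARRIER_HZ
    pulse_cycles: int = 2
    burst_s: float = 1.0
    silence_s: float = 2.0
    total_s: float = 60.0
    oscillation: IPIOscillation | None = None
    fixed_pulse_count: int | None = None
    amplitude: float = 1.0
    sample_rate: float = 8000.0

    def __post_init__(self) -> None:
        if self.kind not in ("pulse", "sine"):
            raise ParameterError(f"unknown stimulus kind {self.kind!r}")
        if min(self.burst_s, self.total_s, self.sample_rate) <= 0 or self.silence_s < 0:
            raise ParameterError("durations and sample rate must be positive")
        if self.kind == "pulse" and self.oscillation is None:
            if self.ipi_ms < self.pulse_duration_ms:
                raise ParameterError(
                    f"ipi {self.ipi_ms} ms shorter than pulse "
                    f"({self.pulse_duration_ms:.2f} ms): pulses would overlap"
                )

    @property
    def pulse_duration_ms(self) -> float:
        return 1000.0 * self.pulse_cycles / self.carrier_hz


@dataclass
class Waveform:
    """Rendered audio samples."""

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


def make_pulse(
    carrier_hz: float, cycles: int = 2, sample_rate: float = 8000.0
) -> Waveform:
    """One song pulse: ``cycles`` carrier cycles, 10% cosine taper per end.

    Duration is ``cycles / carrier_hz`` seconds (~11.98 ms for two 167-Hz
    cycles); peak amplitude 1.
    """
    if cycles < 1:
        raise ParameterError("cycles must be >= 1")
    if sample_rate < 4 * carrier_hz:
        raise ParameterError("sample_rate must be at least 4x the carrier")
    duration = cycles / carrier_hz
    n = max(int(round(duration * sample_rate)), 2)
    t = np.arange(n) / sample_rate
    wave = np.sin(2 * math.pi * carrier_hz * t)
    # tukey alpha=0.2 -> 10% cosine ramp at each end, flat in between
    return Waveform(samples=wave * tukey(n, alpha=0.2), sample_rate=sample_rate)


def count_pulses_per_burst(
    ipi_ms: float, burst_s: float = 1.0, pulse_duration_ms: float | None = None
) -> int:
    """Pulses fitting in one burst: onsets at multiples of the IPI, first at
    the burst start, and every pulse must end within the burst.

    With the default 2-cycle 167-Hz pulse (11.98 ms) this gives 66 pulses at
    15-ms IPI, 29 at 35 ms and 10 at 105 ms for a 1-s burst.
    """
    if pulse_duration_ms is None:
        pulse_duration_ms = 1000.0 * 2 / MELANOGASTER_CARRIER_HZ
    if ipi_ms < pulse_duration_ms:
        raise ParameterError("ipi shorter than the pulse: pulses would overlap")
    burst_ms = burst_s * 1000.0
    if pulse_duration_ms > burst_ms:
        return 0
    return int(math.floor((burst_ms - pulse_duration_ms) / ipi_ms)) + 1


def _place_pulses(
    out: np.ndarray, onsets_s: np.ndarray, pulse: np.ndarray, sr: float
) -> None:
    for t0 in onsets_s:
        i0 = int(round(t0 * sr))
        i1 = min(i0 + len(pulse), len(out))
        if i0 >= len(out):
            break
        out[i0:i1] = pulse[: i1 - i0]


def make_song(spec: StimulusSpec) -> Waveform:
    """Render a full stimulus waveform from its spec.

    Pulse kind: bursts of pulses (count per ``count_pulses_per_burst``, or
    ``fixed_pulse_count`` with the burst stretched to fit) separated by
    ``silence_s``; ``silence_s = 0`` gives the uninterrupted continuous
    train.  Sine kind: carrier tone during bursts.  Oscillating IPI replaces
    the fixed IPI by the sinusoidal schedule and implies a continuous train.
    """
    sr = spec.sample_rate
    n_total = int(round(spec.total_s * sr))
    out = np.zeros(n_total)

    if spec.kind == "sine":
        t = np.arange(n_total) / sr
        tone = np.sin(2 * math.pi * spec.carrier_hz * t)
        if spec.silence_s == 0:
            out = tone
        else:
            period = spec.burst_s + spec.silence_s
            phase = np.mod(t, period)
            out = np.where(phase < spec.burst_s, tone, 0.0)
        return Waveform(samples=spec.amplitude * out, sample_rate=sr)

    pulse = make_pulse(spec.carrier_hz, spec.pulse_cycles, sr).samples
    pulse_dur_s = spec.pulse_duration_ms / 1000.0

    if spec.oscillation is not None:
        ipis_ms = make_oscillating_ipi(
            spec.oscillation.period_s,
            spec.oscillation.ipi_min_ms,
            spec.oscillation.ipi_max_ms,
            spec.total_s,
        )
        onsets = np.concatenate([[0.0], np.cumsum(ipis_ms) / 1000.0])
        onsets = onsets[onsets + pulse_dur_s <= spec.total_s]
        _place_pulses(out, onsets, pulse, sr)
        return Waveform(samples=spec.amplitude * out, sample_rate=sr)

    ipi_s = spec.ipi_ms / 1000.0
    if spec.silence_s == 0:
        onsets = np.arange(0.0, spec.total_s, ipi_s)
        onsets = onsets[onsets + pulse_dur_s <= spec.total_s]
        _place_pulses(out, onsets, pulse, sr)
        return Waveform(samples=spec.amplitude * out, sample_rate=sr)

    if spec.fixed_pulse_count is not None:
        n_pulses = spec.fixed_pulse_count
        burst_len = (n_pulses - 1) * ipi_s + pulse_dur_s
    else:
        n_pulses = count_pulses_per_burst(
            spec.ipi_ms, spec.burst_s, spec.pulse_duration_ms
        )
        burst_len = spec.burst_s
    period = burst_len + spec.silence_s
    burst_start = 0.0
    while burst_start + pulse_dur_s <= spec.total_s:
        onsets = burst_start + np.arange(n_pulses) * ipi_s
        onsets = onsets[onsets + pulse_dur_s <= spec.total_s]
        _place_pulses(out, onsets, pulse, sr)
        burst_start += period
    return Waveform(samples=spec.amplitude * out, sample_rate=sr)


def burst_duration_s(spec: StimulusSpec) -> float:
    """Length of one burst: ``burst_s`` normally, stretched in
    fixed-pulse-count mode (29 pulses at 105-ms IPI span ~2.95 s, i.e. 3 s
    rounded)."""
    if spec.fixed_pulse_count is None:
        return spec.burst_s
    return (spec.fixed_pulse_count - 1) * spec.ipi_ms / 1000.0 + (
        spec.pulse_duration_ms / 1000.0
    )


def make_oscillating_ipi(
    period_s: float = 58.0,
    ipi_min_ms: float = 29.0,
    ipi_max_ms: float = 40.0,
    total_s: float = 60.0,
) -> np.ndarray:
    """IPI schedule (ms) of an oscillating-IPI song.

    Each successive IPI is the sinusoid ``mean + half_range *
    sin(2*pi*t/period)`` evaluated at the current pulse time, so the phase
    is continuous across the whole song.
    """
    if total_s <= 0:
        raise ParameterError("total_s must be positive")
    if ipi_min_ms >= ipi_max_ms:
        raise ParameterError("ipi_min must be below ipi_max")
    mean = (ipi_min_ms + ipi_max_ms) / 2.0
    half = (ipi_max_ms - ipi_min_ms) / 2.0
    ipis = []
    t = 0.0
    while True:
        ipi = mean + half * math.sin(2 * math.pi * t / period_s)
        if t + ipi / 1000.0 > total_s:
            break
        ipis.append(ipi)
        t += ipi / 1000.0
    return np.asarray(ipis)


def write_wav(w: Waveform, path) -> None:
    """Write a waveform as 16-bit PCM WAV."""
    peak = np.abs(w.samples).max()
    scaled = w.samples / peak if peak > 1.0 else w.samples
    data = np.clip(np.round(scaled * 32767.0), -32768, 32767).astype(np.int16)
    wavfile.write(str(path), int(round(w.sample_rate)), data)


def read_wav(path) -> Waveform:
    """Read a PCM WAV back to a float waveform in [-1, 1]."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    sr, data = wavfile.read(str(path))
    if data.dtype == np.int16:
        samples = data.astype(np.float64) / 32767.0
    elif data.dtype == np.int32:
        samples = data.astype(np.float64) / 2147483647.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 127.0
    else:
        samples = data.astype(np.float64)
    return Waveform(samples=samples, sample_rate=float(sr))
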