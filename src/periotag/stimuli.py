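"""Rhythm stimuli: symbolic drum patterns, rendered envelopes, and audio fixtures.

The stimulus grammar is an eight-pulse kick/snare pattern at a given tempo.
With eighth-note pulses (two pulses per beat) one cycle spans four beats, so a
cycle lasts ``4 * 60 / tempo_bpm`` seconds: 2.0 s at 120 bpm, ~1.714 s at
140 bpm.  Envelopes are rendered cycle-by-cycle and tiled, which makes them
exactly circularly periodic — the property the circular-autocorrelation
analysis downstream relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import signal as sps
from scipy.io import wavfile

__all__ = [
    "RhythmPattern",
    "StimulusBlock",
    "Envelope",
    "OnsetShape",
    "parse_pattern",
    "block_duration",
    "render_envelope",
    "render_cycle_envelope",
    "synth_audio",
    "spectral_peak",
    "write_wav",
    "read_wav",
    "load_pattern_file",
    "UNSYNCOPATED",
    "SYNCOPATED",
]

VALID_TOKENS = frozenset("KSx")

#: internal seed for the snare's noise component, so the fixture is a fixture
_SNARE_NOISE_SEED = 217


@dataclass(frozen=True)
class RhythmPattern:
    """An eight-pulse drum pattern with tempo.

    ``symbols`` is a string over {K, S, x}: K a sounded kick, S a sounded
    snare, x a silent pulse.  ``pulses_per_beat=2`` means eighth-note pulses,
    so the 8-pulse cycle covers 4 beats.
    """

    symbols: str
    tempo_bpm: float
    pulses_per_beat: int = 2

    def __post_init__(self) -> None:
        if len(self.symbols) != 8:
            raise ValueError(
                f"pattern must have exactly 8 symbols, got {len(self.symbols)}"
            )
        for i, tok in enumerate(self.symbols):
            if tok not in VALID_TOKENS:
                raise ValueError(
                    f"illegal token {tok!r} at position {i}; expected K, S or x"
                )
        if not self.tempo_bpm > 0:
            raise ValueError(f"tempo_bpm must be positive, got {self.tempo_bpm}")
        if self.pulses_per_beat < 1:
            raise ValueError("pulses_per_beat must be >= 1")

    @property
    def n_pulses(self) -> int:
        return len(self.symbols)

    @property
    def n_sounded(self) -> int:
        return sum(1 for s in self.symbols if s in "KS")

    @property
    def cycle_duration_s(self) -> float:
        """One cycle = n_pulses / pulses_per_beat beats."""
        return (self.n_pulses / self.pulses_per_beat) * 60.0 / self.tempo_bpm

    @property
    def pulse_duration_s(self) -> float:
        return self.cycle_duration_s / self.n_pulses


@dataclass(frozen=True)
class StimulusBlock:
    """One condition-block: a pattern looped for a number of repetitions."""

    pattern: RhythmPattern
    repetitions: int
    audio_condition: Literal["listen", "imagine"] = "listen"
    signal_type: Literal["rhythm", "white_noise"] = "rhythm"
    presentation: int = 1

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if self.audio_condition not in ("listen", "imagine"):
            raise ValueError(f"unknown audio_condition {self.audio_condition!r}")
        if self.signal_type not in ("rhythm", "white_noise"):
            raise ValueError(f"unknown signal_type {self.signal_type!r}")
        if self.presentation not in (1, 2):
            raise ValueError("presentation must be 1 or 2")

    @property
    def duration_s(self) -> float:
        return self.repetitions * self.pattern.cycle_duration_s


@dataclass
class Envelope:
    """A uniformly sampled nonnegative amplitude series."""

    values: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("envelope must be 1-D")
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be positive")
        if self.values.size and self.values.min() < 0:
            raise ValueError("envelope values must be nonnegative")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class OnsetShape:
    """Shape of the amplitude burst contributed by one sounded pulse.

    Attack/decay are time constants of the rising and falling exponentials.
    Kick and snare differ in amplitude and decay; values are configurable
    because the envelope-extraction of the original audio is not prescribed.
    """

    attack_s: float = 0.005
    kick_decay_s: float = 0.060
    snare_decay_s: float = 0.120
    kick_amp: float = 1.0
    snare_amp: float = 0.8


def parse_pattern(text: str, tempo_bpm: float, pulses_per_beat: int = 2) -> RhythmPattern:
    """Parse a symbol string like ``"KxSxKxSx"`` into a :class:`RhythmPattern`.

    Case-insensitive; whitespace is ignored.  Raises ``ValueError`` naming the
    offending position for an illegal token or a non-8 length.
    """
    stripped = "".join(text.split())
    canonical = []
    for i, ch in enumerate(stripped):
        up = ch.upper()
        if up == "X":
            canonical.append("x")
        elif up in ("K", "S"):
            canonical.append(up)
        else:
            raise ValueError(f"illegal token {ch!r} at position {i}; expected K, S or x")
    return RhythmPattern("".join(canonical), tempo_bpm, pulses_per_beat)


#: The two rhythms of the study: an unsyncopated and a syncopated
#: kick/snare pattern, each with four sounded events over eight pulses.
UNSYNCOPATED = "KxSxKxSx"
SYNCOPATED = "KxSKxSxx"


def block_duration(block: StimulusBlock) -> float:
    """Duration of a block in seconds: repetitions x cycle duration."""
    return block.duration_s


def render_cycle_envelope(
    pattern: RhythmPattern, rate_hz: float, onset: OnsetShape | None = None
) -> np.ndarray:
    """Render the envelope of a single rhythm cycle.

    The cycle is ``round(cycle_duration_s * rate_hz)`` samples.  Each sounded
    pulse contributes an attack/decay burst; tails wrap circularly around the
    cycle so that tiling R copies is exactly periodic.
    """
    onset = onset or OnsetShape()
    cycle_n = int(round(pattern.cycle_duration_s * rate_hz))
    pulse_n = cycle_n / pattern.n_pulses
    if pulse_n < 4:
        raise ValueError(
            f"rate {rate_hz} Hz too low: one pulse spans {pulse_n:.1f} samples (< 4)"
        )
    t = np.arange(cycle_n) / rate_hz
    env = np.zeros(cycle_n)
    for i, tok in enumerate(pattern.symbols):
        if tok == "x":
            continue
        amp = onset.kick_amp if tok == "K" else onset.snare_amp
        decay = onset.kick_decay_s if tok == "K" else onset.snare_decay_s
        onset_t = i * pattern.pulse_duration_s
        # time since onset, wrapped to [0, cycle) so tails cross the seam
        dt = np.mod(t - onset_t, pattern.cycle_duration_s)
        burst = amp * (1.0 - np.exp(-dt / onset.attack_s)) * np.exp(-dt / decay)
        env += burst
    return env


def render_envelope(
    block: StimulusBlock, rate_hz: float, onset: OnsetShape | None = None
) -> Envelope:
    """Render the looped rhythm envelope for a block.

    The result is ``repetitions`` exact circular tilings of the one-cycle
    envelope.  For imagine blocks the *audio* is silent, but the reference
    envelope used by the downstream correlation analysis is still the rhythm
    envelope (the rhythm the listener is imagining); callers that want the
    audible signal should use :func:`synth_audio`, which renders silence for
    imagine blocks.
    """
    cycle = render_cycle_envelope(block.pattern, rate_hz, onset)
    return Envelope(np.tile(cycle, block.repetitions), rate_hz)


def _kick_waveform(t: np.ndarray) -> np.ndarray:
    # Decaying tone complex: fundamental at 63 Hz plus a weak third partial
    # at 189 Hz; both outside the 70-170 Hz critical band.
    env = (1.0 - np.exp(-t / 0.002)) * np.exp(-t / 0.12)
    return env * (np.sin(2 * np.pi * 63.0 * t) + 0.25 * np.sin(2 * np.pi * 189.0 * t))


def _snare_waveform(t: np.ndarray, rate_hz: float) -> np.ndarray:
    # Tone burst at 217 Hz plus band-limited noise (180-400 Hz), so the
    # dominant spectral peak sits at 217 Hz; the filter skirt leaves some
    # energy, but no local maximum, inside 70-170 Hz.
    env = (1.0 - np.exp(-t / 0.001)) * np.exp(-t / 0.08)
    tone = np.sin(2 * np.pi * 217.0 * t)
    rng = np.random.default_rng(_SNARE_NOISE_SEED)
    noise = rng.standard_normal(t.size)
    sos = sps.butter(4, [180.0, 400.0], btype="bandpass", fs=rate_hz, output="sos")
    noise = sps.sosfiltfilt(sos, noise)
    noise /= np.max(np.abs(noise)) + 1e-30
    return env * (tone + 0.5 * noise)


def synth_audio(
    pattern: RhythmPattern,
    repetitions: int = 1,
    rate_hz: float = 44100.0,
    silent: bool = False,
) -> np.ndarray:
    """Synthesize the drum-pattern waveform (kick + snare fixtures).

    The kick is a decaying tone complex with its fundamental at 63 Hz; the
    snare is a tone-plus-filtered-noise burst peaking at 217 Hz.  Neither has
    a spectral peak inside the 70-170 Hz band, though (as with the natural
    sounds they emulate) some energy is present there.  ``silent=True``
    renders the imagine-condition audio: zeros of the correct length.
    """
    if rate_hz < 8000:
        raise ValueError("audio rate must be >= 8000 Hz")
    cycle_n = int(round(pattern.cycle_duration_s * rate_hz))
    total_n = cycle_n * repetitions
    if silent:
        return np.zeros(total_n)
    hit_len = min(cycle_n, int(round(0.5 * rate_hz)))
    t_hit = np.arange(hit_len) / rate_hz
    kick = _kick_waveform(t_hit)
    snare = _snare_waveform(t_hit, rate_hz)
    out = np.zeros(total_n + hit_len)
    for rep in range(repetitions):
        for i, tok in enumerate(pattern.symbols):
            if tok == "x":
                continue
            start = rep * cycle_n + int(round(i * pattern.pulse_duration_s * rate_hz))
            out[start : start + hit_len] += kick if tok == "K" else snare
    # fold the overhanging tail back circularly
    wave = out[:total_n].copy()
    wave[:hit_len] += out[total_n:]
    peak = np.max(np.abs(wave))
    if peak > 0:
        wave /= peak
    return wave


def kick_fixture(rate_hz: float = 44100.0, duration_s: float = 0.5) -> np.ndarray:
    """The isolated kick-drum sound used in the stimuli."""
    t = np.arange(int(round(duration_s * rate_hz))) / rate_hz
    return _kick_waveform(t)


def snare_fixture(rate_hz: float = 44100.0, duration_s: float = 0.5) -> np.ndarray:
    """The isolated snare sound used in the stimuli."""
    t = np.arange(int(round(duration_s * rate_hz))) / rate_hz
    return _snare_waveform(t, rate_hz)


def spectral_peak(
    waveform: np.ndarray,
    rate_hz: float,
    smooth_hz: float = 2.0,
    fmin_hz: float = 20.0,
) -> float:
    """Frequency of the global maximum of a smoothed magnitude spectrum.

    The magnitude spectrum is computed on a zero-padded FFT (bin spacing
    <= 0.25 Hz) and smoothed with a moving average of width ``smooth_hz``.
    Frequencies below ``fmin_hz`` are excluded so DC leakage cannot win.
    """
    x = np.asarray(waveform, dtype=float)
    if x.size < 0.25 * rate_hz:
        raise ValueError("need at least 0.25 s of signal")
    if not np.any(x):
        raise ValueError("spectral peak of an all-zero signal is undefined")
    nfft = int(2 ** np.ceil(np.log2(max(x.size, 4 * rate_hz))))
    mag = np.abs(np.fft.rfft(x * np.hanning(x.size), nfft))
    freqs = np.fft.rfftfreq(nfft, 1.0 / rate_hz)
    df = freqs[1] - freqs[0]
    win = max(1, int(round(smooth_hz / df)))
    if win > 1:
        mag = np.convolve(mag, np.ones(win) / win, mode="same")
    valid = freqs >= fmin_hz
    return float(freqs[valid][np.argmax(mag[valid])])


def has_band_peak(
    waveform: np.ndarray,
    rate_hz: float,
    low_hz: float = 70.0,
    high_hz: float = 170.0,
    smooth_hz: float = 4.0,
    rel_prominence: float = 0.01,
) -> bool:
    """Whether the smoothed magnitude spectrum has a local maximum in a band.

    A local maximum counts only if its prominence exceeds ``rel_prominence``
    of the global spectral maximum, so numerical ripple does not register.
    """
    x = np.asarray(waveform, dtype=float)
    nfft = int(2 ** np.ceil(np.log2(max(x.size, 4 * rate_hz))))
    mag = np.abs(np.fft.rfft(x * np.hanning(x.size), nfft))
    freqs = np.fft.rfftfreq(nfft, 1.0 / rate_hz)
    df = freqs[1] - freqs[0]
    win = max(1, int(round(smooth_hz / df)))
    if win > 1:
        mag = np.convolve(mag, np.ones(win) / win, mode="same")
    peaks, props = sps.find_peaks(mag, prominence=rel_prominence * mag.max())
    pk_freqs = freqs[peaks]
    return bool(np.any((pk_freqs >= low_hz) & (pk_freqs <= high_hz)))


def write_wav(path, waveform: np.ndarray, rate_hz: float) -> None:
    """Write a float32 PCM WAV file."""
    wavfile.write(path, int(rate_hz), np.asarray(waveform, dtype=np.float32))


def read_wav(path) -> tuple[np.ndarray, float]:
    """Read a WAV file; returns (samples as float, rate)."""
    rate, data = wavfile.read(path)
    if np.issubdtype(data.dtype, np.integer):
        data = data / np.iinfo(data.dtype).max
    return np.asarray(data, dtype=float), float(rate)


def load_pattern_file(path) -> dict[str, RhythmPattern]:
    """Read patterns from tab-separated lines ``<name>\\t<symbols>\\t<bpm>``."""
    patterns: dict[str, RhythmPattern] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"line {ln + 1}: expected name<TAB>symbols<TAB>bpm")
            name, symbols, bpm = parts
            patterns[name] = parse_pattern(symbols, float(bpm))
    return patterns
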