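"""Circular autocorrelation and the autocorrelation-correlation (ACC) statistic.

The core quantity is the circular autocorrelation of a uniformly sampled
series, computed in the frequency domain:

    r = Re(IDFT(DFT(x) * conj(DFT(x))))

max-normalized (the maximum is the zero-lag element, by Cauchy-Schwarz) and
truncated to the non-redundant half, lags 0..floor(N/2).  No mean is
subtracted before the DFT; the Pearson correlation applied at the next stage
centres the two autocorrelation vectors anyway.

The ACC of a neural envelope against a stimulus envelope is the Pearson
correlation between their two autocorrelation vectors.  Because a circular
shift of a series leaves its circular autocorrelation unchanged, the ACC is
invariant to any temporal delay between stimulus and response — the property
that distinguishes periodicity tagging from direct envelope correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

from .stimuli import Envelope
from .preprocess import BandEnvelope

__all__ = [
    "AcfVector",
    "AccRecord",
    "AccConfig",
    "circular_acf",
    "match_rates",
    "acc",
    "acc_for_trial",
    "stimulus_acf",
    "records_to_frame",
]


@dataclass
class AcfVector:
    """Max-normalized circular autocorrelation over lags 0..floor(N/2)."""

    values: np.ndarray
    source_rate_hz: float
    source_n: int
    normalization: str = "max"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_lags(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class AccConfig:
    """Choices the original description leaves open, surfaced as switches.

    ``exclude_lag0`` drops lag 0 (identically 1 in both vectors after
    max-normalization, which inflates the Pearson r) before correlating.
    ``full_lags`` keeps the whole symmetric autocorrelation instead of the
    non-redundant half.  ``subtract_mean`` removes the series mean before the
    DFT.  ``method`` selects Pearson (default) or Spearman correlation.
    """

    exclude_lag0: bool = False
    full_lags: bool = False
    subtract_mean: bool = False
    method: str = "pearson"


@dataclass(frozen=True)
class AccRecord:
    """One ACC value with its full condition key."""

    acc: float
    participant: str
    electrode: str
    rhythm: str
    tempo_bpm: float
    audio_condition: str
    signal_type: str
    presentation: int
    band: str
    n_lags: int
    ground_truth_tracking: bool = False
    hemisphere: str = ""
    talairach_xyz: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not -1.0 <= self.acc <= 1.0 + 1e-12:
            raise ValueError(f"ACC {self.acc} outside [-1, 1]")


def circular_acf(
    x: np.ndarray, rate_hz: float = 1.0, cfg: AccConfig = AccConfig()
) -> AcfVector:
    """FFT-based circular autocorrelation, max-normalized and half-truncated.

    Raises on all-zero input (max-normalization is undefined) and on series
    shorter than 4 samples.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("circular_acf expects a 1-D series")
    n = x.size
    if n < 4:
        raise ValueError(f"series too short for autocorrelation (N = {n} < 4)")
    if not np.any(x):
        raise ValueError("circular autocorrelation of all-zero input is undefined")
    if cfg.subtract_mean:
        x = x - x.mean()
        if not np.any(x):
            raise ValueError("series is constant; mean-subtracted ACF undefined")
    spec = np.fft.rfft(x)
    r = np.fft.irfft(spec * np.conj(spec), n=n)
    r = r / r.max()
    if not cfg.full_lags:
        r = r[: n // 2 + 1]
    return AcfVector(r, rate_hz, n)


def _acf_matrix(x: np.ndarray, cfg: AccConfig) -> np.ndarray:
    """Vectorized circular ACF over rows of a channels x samples matrix."""
    n = x.shape[1]
    if cfg.subtract_mean:
        x = x - x.mean(axis=1, keepdims=True)
    spec = np.fft.rfft(x, axis=1)
    r = np.fft.irfft(spec * np.conj(spec), n=n, axis=1)
    peak = r.max(axis=1, keepdims=True)
    if np.any(peak == 0):
        raise ValueError("all-zero channel: circular autocorrelation undefined")
    r = r / peak
    if not cfg.full_lags:
        r = r[:, : n // 2 + 1]
    return r


def match_rates(
    stim_env: Envelope, neural_env: Envelope, n_cycles: Optional[int] = None
) -> tuple[Envelope, Envelope]:
    """Resample the stimulus envelope to the neural rate and length.

    Both envelopes must cover the same number of rhythm cycles; if
    ``n_cycles`` is given, the cycle counts implied by the length ratio are
    checked against it.  Resampling uses the Fourier method, which is
    circular (appropriate for whole-period segments) and acts as an ideal
    anti-alias filter when downsampling.
    """
    if stim_env.rate_hz == neural_env.rate_hz:
        if stim_env.n != neural_env.n:
            raise ValueError(
                f"equal rates but different lengths ({stim_env.n} vs "
                f"{neural_env.n}): cycle counts differ"
            )
        return stim_env, neural_env
    dur_stim = stim_env.n / stim_env.rate_hz
    dur_neur = neural_env.n / neural_env.rate_hz
    if abs(dur_stim - dur_neur) * min(stim_env.rate_hz, neural_env.rate_hz) > 1.5:
        raise ValueError(
            f"envelopes cover different spans ({dur_stim:.4f} s vs "
            f"{dur_neur:.4f} s): cycle-count mismatch"
        )
    resampled = sps.resample(stim_env.values, neural_env.n)
    # Fourier resampling can produce tiny negative excursions on a
    # nonnegative envelope; clip them rather than fail the invariant.
    resampled = np.maximum(resampled, 0.0)
    return Envelope(resampled, neural_env.rate_hz), neural_env


def acc(a: AcfVector, b: AcfVector, cfg: AccConfig = AccConfig()) -> float:
    """Correlation between two autocorrelation vectors (the ACC)."""
    if a.n_lags != b.n_lags:
        raise ValueError(f"lag-vector lengths differ: {a.n_lags} vs {b.n_lags}")
    va, vb = a.values, b.values
    if cfg.exclude_lag0:
        va, vb = va[1:], vb[1:]
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("zero variance in an autocorrelation vector; "
                         "correlation undefined")
    if cfg.method == "spearman":
        from scipy.stats import spearmanr

        return float(spearmanr(va, vb).statistic)
    return float(np.corrcoef(va, vb)[0, 1])


def stimulus_acf(stim_env: Envelope, cfg: AccConfig = AccConfig()) -> AcfVector:
    """Circular ACF of a stimulus envelope (convenience wrapper)."""
    return circular_acf(stim_env.values, stim_env.rate_hz, cfg)


def acc_for_trial(
    band_env: BandEnvelope,
    stim_env: Envelope,
    cfg: AccConfig = AccConfig(),
) -> list[AccRecord]:
    """One ACC record per channel of a trial.

    The stimulus envelope is rate-matched to the neural envelopes, both are
    circularly autocorrelated, and each channel's autocorrelation is
    correlated with the stimulus autocorrelation.
    """
    neural_ref = Envelope(band_env.envelopes[0], band_env.rate_hz)
    stim_matched, _ = match_rates(stim_env, neural_ref)
    ref_acf = circular_acf(stim_matched.values, band_env.rate_hz, cfg)
    neural_acfs = _acf_matrix(band_env.envelopes, cfg)
    trial = band_env.trial
    block = trial.block
    records = []
    for i, meta in enumerate(trial.channels):
        value = acc(
            AcfVector(neural_acfs[i], band_env.rate_hz, band_env.n_samples),
            ref_acf,
            cfg,
        )
        records.append(
            AccRecord(
                acc=value,
                participant=trial.participant,
                electrode=meta.id,
                rhythm=block.pattern.symbols,
                tempo_bpm=block.pattern.tempo_bpm,
                audio_condition=block.audio_condition,
                signal_type=block.signal_type,
                presentation=block.presentation,
                band=band_env.band.name,
                n_lags=ref_acf.n_lags,
                ground_truth_tracking=meta.ground_truth_tracking,
                hemisphere=meta.hemisphere,
                talairach_xyz=meta.talairach_xyz,
            )
        )
    return records


def records_to_frame(records: list[AccRecord]):
    """AccRecords as a tidy DataFrame (one row per electrode x condition)."""
    import pandas as pd

    rows = []
    for r in records:
        d = {
            "participant": r.participant,
            "electrode": r.electrode,
            "rhythm": r.rhythm,
            "tempo_bpm": r.tempo_bpm,
            "audio_condition": r.audio_condition,
            "signal_type": r.signal_type,
            "presentation": r.presentation,
            "band": r.band,
            "acc": r.acc,
            "n_lags": r.n_lags,
            "ground_truth_tracking": r.ground_truth_tracking,
            "hemisphere": r.hemisphere,
            "x": r.talairach_xyz[0],
            "y": r.talairach_xyz[1],
            "z": r.talairach_xyz[2],
        }
        rows.append(d)
    return pd.DataFrame(rows)
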