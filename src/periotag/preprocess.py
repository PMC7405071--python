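"""Band-limiting and amplitude-envelope extraction.

Each channel is bandpass filtered (elliptic IIR high-pass + low-pass in
cascade, applied forward-backward for zero phase), optionally notch filtered
at the first harmonic of the 60 Hz line noise (120 Hz, the component that
falls inside the 70-170 Hz high-gamma band), and its amplitude envelope is
taken as the magnitude of the analytic signal.  The envelope is then trimmed
to an exact integer number of rhythm cycles, because the circular
autocorrelation downstream assumes whole periods.

Zero-phase filtering matters here: the analysis correlates *autocorrelations*,
which are phase-invariant, but a phase-distorting filter would smear the
envelope's periodic structure itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .stimuli import StimulusBlock
from .synth_ecog import EcogTrial

__all__ = [
    "BandSpec",
    "FilterConfig",
    "BandEnvelope",
    "HIGH_GAMMA",
    "BETA",
    "bandpass",
    "notch",
    "hilbert_envelope",
    "extract_band_envelope",
    "BandEnvelopeExtractor",
]


@dataclass(frozen=True)
class BandSpec:
    """A frequency band, with an optional in-band notch frequency."""

    low_hz: float
    high_hz: float
    notch_hz: Optional[float] = None
    name: str = "custom"

    def validate(self, rate_hz: float) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(f"need 0 < low < high, got {self.low_hz}, {self.high_hz}")
        if self.high_hz >= rate_hz / 2:
            raise ValueError(
                f"band edge {self.high_hz} Hz at or above Nyquist ({rate_hz / 2} Hz)"
            )
        if self.notch_hz is not None and not (
            self.low_hz < self.notch_hz < self.high_hz
        ):
            raise ValueError(
                f"notch {self.notch_hz} Hz outside band ({self.low_hz}-{self.high_hz})"
            )


#: High-gamma band with a notch at 120 Hz — the first harmonic of the 60 Hz
#: line noise, and the only line component inside the band.
HIGH_GAMMA = BandSpec(70.0, 170.0, notch_hz=120.0, name="high_gamma")

#: Beta band; no line component falls inside it, so no notch.
BETA = BandSpec(12.0, 30.0, notch_hz=None, name="beta")


@dataclass(frozen=True)
class FilterConfig:
    """Elliptic IIR design parameters.

    ``order`` is per high-pass/low-pass section; forward-backward application
    doubles the effective order and cancels the phase response.  The defaults
    (order 4, 0.5 dB passband ripple, 50 dB stopband) give sharp transitions
    at modest order.
    """

    order: int = 4
    ripple_db: float = 0.5
    stop_db: float = 50.0
    notch_bw_hz: float = 4.0
    notch_order: int = 3
    zero_phase: bool = True


def _check_stable(sos: np.ndarray, what: str) -> np.ndarray:
    _, poles, _ = sps.sos2zpk(sos)
    if np.any(np.abs(poles) >= 1.0):
        raise ValueError(f"unstable {what} design: pole magnitudes "
                         f"{np.abs(poles).max():.6f} >= 1")
    return sos


def _bandpass_sos(rate_hz: float, band: BandSpec, cfg: FilterConfig) -> np.ndarray:
    try:
        hp = sps.ellip(cfg.order, cfg.ripple_db, cfg.stop_db, band.low_hz,
                       btype="highpass", fs=rate_hz, output="sos")
        lp = sps.ellip(cfg.order, cfg.ripple_db, cfg.stop_db, band.high_hz,
                       btype="lowpass", fs=rate_hz, output="sos")
    except Exception as exc:  # pragma: no cover - scipy raises on bad params
        raise ValueError(
            f"filter design failed for band {band.low_hz}-{band.high_hz} Hz "
            f"at {rate_hz} Hz: {exc}"
        ) from exc
    return _check_stable(np.vstack([hp, lp]),
                         f"bandpass {band.low_hz}-{band.high_hz} Hz")


def _apply(sos: np.ndarray, x: np.ndarray, zero_phase: bool) -> np.ndarray:
    if zero_phase:
        return sps.sosfiltfilt(sos, x, axis=-1)
    return sps.sosfilt(sos, x, axis=-1)


def bandpass(
    signal: np.ndarray,
    rate_hz: float,
    band: BandSpec,
    cfg: FilterConfig = FilterConfig(),
) -> np.ndarray:
    """Elliptic bandpass (high-pass + low-pass cascade), zero phase by default."""
    band.validate(rate_hz)
    x = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    return _apply(_bandpass_sos(rate_hz, band, cfg), x, cfg.zero_phase)


def notch(
    signal: np.ndarray,
    rate_hz: float,
    f0_hz: float,
    cfg: FilterConfig = FilterConfig(),
) -> np.ndarray:
    """Elliptic band-stop notch of width ``cfg.notch_bw_hz`` centred on f0."""
    if not 0 < f0_hz < rate_hz / 2:
        raise ValueError(f"notch frequency {f0_hz} Hz outside (0, Nyquist)")
    x = np.asarray(signal, dtype=float)
    half_bw = cfg.notch_bw_hz / 2.0
    try:
        sos = sps.ellip(cfg.notch_order, cfg.ripple_db, cfg.stop_db,
                        [f0_hz - half_bw, f0_hz + half_bw],
                        btype="bandstop", fs=rate_hz, output="sos")
    except Exception as exc:  # pragma: no cover
        raise ValueError(f"notch design failed at {f0_hz} Hz / {rate_hz} Hz: "
                         f"{exc}") from exc
    _check_stable(sos, f"notch at {f0_hz} Hz")
    return _apply(sos, x, cfg.zero_phase)


def hilbert_envelope(signal: np.ndarray) -> np.ndarray:
    """Magnitude of the analytic signal (instantaneous amplitude)."""
    x = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    return np.abs(sps.hilbert(x, axis=-1))


@dataclass
class BandEnvelope:
    """Per-channel amplitude envelopes of one trial in one band."""

    envelopes: np.ndarray  # channels x samples, nonnegative
    rate_hz: float
    band: BandSpec
    trial: EcogTrial
    n_cycles: int
    cycle_samples: int
    provenance: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.envelopes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.envelopes.shape[1]


def extract_band_envelope(
    trial: EcogTrial,
    band: BandSpec = HIGH_GAMMA,
    cfg: FilterConfig = FilterConfig(),
) -> BandEnvelope:
    """Bandpass -> notch (if set) -> Hilbert envelope -> whole-cycle trim.

    The output covers ``n_cycles * cycle_samples`` samples exactly, where the
    cycle length is rounded to the nearest sample at the recording rate.
    Raises if the trial is shorter than one rhythm cycle.
    """
    band.validate(trial.rate_hz)
    cycle_samples = int(round(trial.block.pattern.cycle_duration_s * trial.rate_hz))
    n_cycles = trial.n_samples // cycle_samples
    if n_cycles < 1:
        raise ValueError(
            f"trial has {trial.n_samples} samples, shorter than one rhythm "
            f"cycle ({cycle_samples} samples)"
        )
    x = bandpass(trial.data, trial.rate_hz, band, cfg)
    if band.notch_hz is not None:
        x = notch(x, trial.rate_hz, band.notch_hz, cfg)
    env = hilbert_envelope(x)[:, : n_cycles * cycle_samples]
    return BandEnvelope(
        env, trial.rate_hz, band, trial, n_cycles, cycle_samples,
        provenance={
            "filter": {
                "order": cfg.order, "ripple_db": cfg.ripple_db,
                "stop_db": cfg.stop_db, "zero_phase": cfg.zero_phase,
            },
            "trial_id": trial.trial_id,
        },
    )


class BandEnvelopeExtractor(TransformerMixin, BaseEstimator):
    """sklearn-style transformer wrapping :func:`extract_band_envelope`.

    Stateless: ``fit`` only validates parameters.  ``transform`` accepts an
    :class:`~periotag.synth_ecog.EcogTrial` or a list of them.
    """

    def __init__(self, band: BandSpec = HIGH_GAMMA, cfg: FilterConfig = FilterConfig()):
        self.band = band
        self.cfg = cfg

    def fit(self, X=None, y=None):
        if not isinstance(self.band, BandSpec):
            raise TypeError("band must be a BandSpec")
        self.n_features_in_ = 0  # sklearn convention; no tabular features
        return self

    def transform(self, X):
        self.fit()
        if isinstance(X, EcogTrial):
            return extract_band_envelope(X, self.band, self.cfg)
        return [extract_band_envelope(t, self.band, self.cfg) for t in X]
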