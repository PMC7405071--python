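"""Seeded synthetic multichannel ECoG with known ground-truth tracking channels.

No intracranial data accompany the original study, so this module generates
recordings whose statistics emulate it: per-channel 1/f background plus 60 Hz
line noise (and its 120 Hz harmonic), sampled at 1200 Hz, with a designated
subset of "tracking" channels whose 70-170 Hz band-limited activity is
amplitude-modulated by (a possibly lagged or nonlinearly transformed version
of) the rhythm envelope.  Modulation depth is the ground-truth effect size:
0 is a null channel, 1 is full modulation.

Everything is deterministic given (seed, config); a trial's RNG stream is
derived from the study seed and the trial's condition keys, so any single
trial can be regenerated in isolation.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import signal as sps

from .stimuli import (
    Envelope,
    OnsetShape,
    RhythmPattern,
    StimulusBlock,
    parse_pattern,
    render_envelope,
    UNSYNCOPATED,
    SYNCOPATED,
)

__all__ = [
    "ElectrodeMeta",
    "ElectrodeTruth",
    "GroundTruth",
    "NoiseConfig",
    "EcogTrial",
    "StudyDesign",
    "generate_trial",
    "generate_white_noise_trial",
    "generate_study",
    "pink_noise",
    "save_trial",
    "load_trial",
    "electrodes_to_tsv",
    "electrodes_from_tsv",
    "read_edf",
]

Transform = Literal["identity", "rectified_derivative", "lagged", "none"]


@dataclass(frozen=True)
class ElectrodeMeta:
    """Electrode identity and location.

    Talairach convention: x < 0 is the left hemisphere, x > 0 the right;
    the ``hemisphere`` label must agree with the sign of x.
    """

    id: str
    hemisphere: Literal["L", "R"]
    talairach_xyz: tuple[float, float, float]
    ground_truth_tracking: bool = False
    region_label: str = ""

    def __post_init__(self) -> None:
        x = self.talairach_xyz[0]
        if self.hemisphere == "L" and x > 0:
            raise ValueError(f"electrode {self.id}: hemisphere L but x = {x} > 0")
        if self.hemisphere == "R" and x < 0:
            raise ValueError(f"electrode {self.id}: hemisphere R but x = {x} < 0")


@dataclass(frozen=True)
class ElectrodeTruth:
    """Ground-truth modulation for one electrode.

    ``transform`` selects how the rhythm envelope drives the high-gamma
    amplitude: ``identity`` uses the envelope itself, ``rectified_derivative``
    uses the positive part of its circular derivative (an onset-like code
    with the same periodicities but different waveform), ``lagged`` is the
    identity shifted by ``lag_ms``, ``none`` disables modulation.
    """

    modulation_depth: float = 0.0
    lag_ms: float = 0.0
    transform: Transform = "identity"

    def __post_init__(self) -> None:
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ValueError(
                f"modulation_depth must lie in [0, 1], got {self.modulation_depth}"
            )


class GroundTruth:
    """Per-electrode ground truth, with an optional imagine-condition override.

    Tracking channels keep modulating by the rhythm envelope during imagined
    (silent) repetitions — that is the hypothesis under test, made literal.
    """

    def __init__(
        self,
        per_electrode: dict[str, ElectrodeTruth],
        imagine_depth_scale: float = 1.0,
    ):
        self.per_electrode = dict(per_electrode)
        self.imagine_depth_scale = imagine_depth_scale

    def for_electrode(self, electrode_id: str, audio_condition: str) -> ElectrodeTruth:
        truth = self.per_electrode.get(electrode_id, ElectrodeTruth())
        if audio_condition == "imagine" and self.imagine_depth_scale != 1.0:
            return ElectrodeTruth(
                truth.modulation_depth * self.imagine_depth_scale,
                truth.lag_ms,
                truth.transform,
            )
        return truth

    @classmethod
    def uniform(
        cls,
        electrodes: list[ElectrodeMeta],
        depth: float,
        lag_ms: float = 0.0,
        transform: Transform = "identity",
    ) -> "GroundTruth":
        """Assign ``depth`` to every electrode flagged ``ground_truth_tracking``."""
        return cls(
            {
                e.id: ElectrodeTruth(depth, lag_ms, transform)
                for e in electrodes
                if e.ground_truth_tracking
            }
        )


@dataclass(frozen=True)
class NoiseConfig:
    """Background-noise model for one channel.

    ``pink_slope`` is the exponent of the power spectral density (PSD ~ f^slope);
    -1 is classic pink noise.  ``line_amp`` is the amplitude of the 60 Hz line
    component relative to a unit-variance background (its 120 Hz harmonic gets
    half that amplitude).  ``carrier_rms`` sets the RMS of the 70-170 Hz
    band-limited carrier on tracking channels; 0.4 makes the carrier roughly as
    strong as the background's own in-band energy for pink noise at 1200 Hz.
    ``gain_jitter`` multiplies each channel by ``exp(gain_jitter * z)``.
    """

    pink_slope: float = -1.0
    line_amp: float = 0.5
    line_hz: float = 60.0
    carrier_rms: float = 0.4
    carrier_low_hz: float = 70.0
    carrier_high_hz: float = 170.0
    gain_jitter: float = 0.1


@dataclass
class EcogTrial:
    """One condition-block of multichannel signal plus its metadata."""

    data: np.ndarray  # channels x samples
    rate_hz: float
    channels: list[ElectrodeMeta]
    block: StimulusBlock
    participant: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("trial data must be channels x samples")
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.channels)} channel metadata"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def trial_id(self) -> str:
        b = self.block
        return (
            f"{self.participant}_{b.pattern.symbols}_{int(round(b.pattern.tempo_bpm))}"
            f"_{b.audio_condition}_{b.signal_type}_p{b.presentation}"
        )


def _derive_seed(seed: int, *keys) -> int:
    """Stable per-trial seed from the study seed and condition keys."""
    tag = "|".join(str(k) for k in keys)
    return (int(seed) * 1_000_003 + zlib.crc32(tag.encode())) % (2**31 - 1)


def pink_noise(
    n_samples: int, n_channels: int, slope: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian noise with PSD ~ f^slope, unit variance per channel."""
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (slope / 2.0)
    scale[0] = 0.0  # no DC
    spec = rng.standard_normal((n_channels, freqs.size)) + 1j * rng.standard_normal(
        (n_channels, freqs.size)
    )
    x = np.fft.irfft(spec * scale, n=n_samples, axis=1)
    x /= x.std(axis=1, keepdims=True)
    return x


def _band_carrier(
    n_samples: int,
    n_channels: int,
    rate_hz: float,
    cfg: NoiseConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Band-limited Gaussian carrier, unit RMS per channel."""
    sos = sps.butter(
        4, [cfg.carrier_low_hz, cfg.carrier_high_hz], btype="bandpass",
        fs=rate_hz, output="sos",
    )
    x = sps.sosfiltfilt(sos, rng.standard_normal((n_channels, n_samples)), axis=1)
    x /= x.std(axis=1, keepdims=True)
    return x


#: Decay constant of the onset-response kernel used by the
#: rectified-derivative code (ms).  Auditory onset responses decay over tens
#: of milliseconds; 50 ms is a standard mid-range choice.
ONSET_KERNEL_MS = 50.0


def rectified_derivative_code(
    values: np.ndarray, rate_hz: float, tau_ms: float = ONSET_KERNEL_MS
) -> np.ndarray:
    """An onset code: positive part of the circular envelope derivative,
    convolved (circularly) with an exponential response kernel.

    This emulates an onset-detector population — firing rises where the
    stimulus envelope rises and relaxes with time constant ``tau_ms``.  The
    result differs pointwise from the envelope but shares its periodicity
    structure, which is exactly the kind of non-envelope-matching code the
    autocorrelation analysis is meant to detect.
    """
    d = np.maximum(values - np.roll(values, 1), 0.0)
    if tau_ms > 0:
        n_k = int(round(6 * tau_ms * 1e-3 * rate_hz))
        kernel = np.exp(-np.arange(n_k) / (tau_ms * 1e-3 * rate_hz))
        spec = np.fft.rfft(d) * np.fft.rfft(kernel, n=d.size)
        d = np.fft.irfft(spec, n=d.size)
        d = np.maximum(d, 0.0)
    return d


def modulation_signal(
    env: Envelope, truth: ElectrodeTruth, rate_hz: float
) -> np.ndarray:
    """Normalized (max = 1) modulator derived from the rhythm envelope."""
    v = env.values
    if truth.transform == "none":
        return np.zeros_like(v)
    if truth.transform == "rectified_derivative":
        v = rectified_derivative_code(v, rate_hz)
    peak = v.max()
    return v / peak if peak > 0 else v


def _background(
    n_samples: int,
    n_channels: int,
    rate_hz: float,
    cfg: NoiseConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    bg = pink_noise(n_samples, n_channels, cfg.pink_slope, rng)
    if cfg.line_amp > 0:
        t = np.arange(n_samples) / rate_hz
        phases = rng.uniform(0, 2 * np.pi, size=(n_channels, 2))
        bg = bg + cfg.line_amp * np.sin(
            2 * np.pi * cfg.line_hz * t[None, :] + phases[:, :1]
        )
        bg = bg + 0.5 * cfg.line_amp * np.sin(
            2 * np.pi * 2 * cfg.line_hz * t[None, :] + phases[:, 1:]
        )
    if cfg.gain_jitter > 0:
        bg *= np.exp(cfg.gain_jitter * rng.standard_normal((n_channels, 1)))
    return bg


def generate_trial(
    block: StimulusBlock,
    electrodes: list[ElectrodeMeta],
    ground_truth: GroundTruth,
    noise_cfg: NoiseConfig = NoiseConfig(),
    seed: int = 0,
    rate_hz: float = 1200.0,
    participant: str = "P01",
    onset: OnsetShape | None = None,
) -> EcogTrial:
    """Generate one condition-block of synthetic ECoG.

    Non-tracking channels are pink noise + line noise.  Tracking channels
    additionally carry a 70-170 Hz band-limited carrier whose instantaneous
    amplitude is ``1 + depth * m(t)``, where ``m`` is the (transformed,
    lagged, max-normalized) rhythm envelope.  White-noise blocks get no
    modulation regardless of ground truth: the participant is hearing noise.
    """
    rng = np.random.default_rng(
        _derive_seed(seed, participant, block.pattern.symbols,
                     block.pattern.tempo_bpm, block.audio_condition,
                     block.signal_type, block.presentation)
    )
    env = render_envelope(block, rate_hz, onset)
    n = env.n
    n_ch = len(electrodes)
    data = _background(n, n_ch, rate_hz, noise_cfg, rng)
    # every channel carries ongoing in-band activity; tracking channels in
    # rhythm blocks have it amplitude-modulated by the stimulus envelope.
    # Null channels and white-noise blocks get the identical unmodulated
    # carrier, so their high-gamma statistics match by construction.
    carriers = _band_carrier(n, n_ch, rate_hz, noise_cfg, rng)
    gains = np.ones((n_ch, n))
    lags = np.zeros(n_ch, dtype=int)
    if block.signal_type == "rhythm":
        for i, e in enumerate(electrodes):
            truth = ground_truth.for_electrode(e.id, block.audio_condition)
            if truth.modulation_depth > 0:
                m = modulation_signal(env, truth, rate_hz)
                gains[i] += truth.modulation_depth * m
                lags[i] = int(round(truth.lag_ms * 1e-3 * rate_hz))
    data += noise_cfg.carrier_rms * carriers * gains
    # a response lag is a circular shift of the whole channel; circular
    # autocorrelation (hence the ACC) is exactly invariant to it
    for i in np.nonzero(lags)[0]:
        data[i] = np.roll(data[i], lags[i])
    return EcogTrial(data, rate_hz, list(electrodes), block, participant)


def generate_white_noise_trial(
    block: StimulusBlock,
    electrodes: list[ElectrodeMeta],
    noise_cfg: NoiseConfig = NoiseConfig(),
    seed: int = 0,
    rate_hz: float = 1200.0,
    participant: str = "P01",
) -> EcogTrial:
    """White-noise control twin of ``block``: same length, no modulation."""
    wn_block = StimulusBlock(
        block.pattern,
        block.repetitions,
        audio_condition=block.audio_condition,
        signal_type="white_noise",
        presentation=block.presentation,
    )
    return generate_trial(
        wn_block, electrodes, GroundTruth({}), noise_cfg, seed, rate_hz, participant
    )


# ---------------------------------------------------------------------------
# study-level generation


@dataclass
class StudyDesign:
    """The factorial design: rhythms x tempi x presentations x audio conditions.

    Defaults mirror the original protocol: two rhythms (unsyncopated
    K x S x K x S x and syncopated K x S K x S x x), tempi 120 and 140 bpm,
    listen blocks of six repetitions at 120 bpm and eight at 140 bpm, imagine
    blocks of two repetitions, each condition presented twice, with a
    length-matched white-noise control twin for every block.  Electrode counts
    are desk-scale by default; :meth:`paper_coverage` reproduces the original
    coverage imbalance (151 left, 286 right across eight participants).
    """

    n_participants: int = 8
    electrodes_left: int = 6
    electrodes_right: int = 10
    n_tracking: int = 3
    modulation_depth: float = 0.5
    tracking_lag_ms: float = 0.0
    tracking_transform: Transform = "identity"
    rhythms: tuple[str, ...] = (UNSYNCOPATED, SYNCOPATED)
    tempi: tuple[float, ...] = (120.0, 140.0)
    listen_reps: dict[float, int] = field(
        default_factory=lambda: {120.0: 6, 140.0: 8}
    )
    imagine_reps: int = 2
    presentations: tuple[int, ...] = (1, 2)
    include_white_noise: bool = True
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    rate_hz: float = 1200.0

    @classmethod
    def paper_coverage(cls, **kw) -> "StudyDesign":
        """Eight participants, 151 left / 286 right electrodes in total."""
        # 151 = 8*18 + 7, 286 = 8*35 + 6: distribute the remainders below
        d = cls(electrodes_left=18, electrodes_right=35, **kw)
        d._left_extra = 7  # type: ignore[attr-defined]
        d._right_extra = 6  # type: ignore[attr-defined]
        return d

    def electrodes_for(self, p_idx: int, rng: np.random.Generator) -> list[ElectrodeMeta]:
        """Electrode montage for participant ``p_idx``.

        Tracking electrodes are planted as a right-prefrontal cluster
        (x > 20, y > 30) mirroring the study's qualitative topography; the
        rest scatter over both hemispheres.
        """
        n_l = self.electrodes_left + (1 if p_idx < getattr(self, "_left_extra", 0) else 0)
        n_r = self.electrodes_right + (1 if p_idx < getattr(self, "_right_extra", 0) else 0)
        metas: list[ElectrodeMeta] = []
        n_track = min(self.n_tracking, n_r)
        for j in range(n_r):
            tracking = j < n_track
            if tracking:
                xyz = (
                    float(rng.uniform(25, 55)),
                    float(rng.uniform(30, 55)),
                    float(rng.uniform(5, 35)),
                )
                label = "R prefrontal"
            else:
                xyz = (
                    float(rng.uniform(15, 65)),
                    float(rng.uniform(-70, 20)),
                    float(rng.uniform(-20, 60)),
                )
                label = "R other"
            metas.append(
                ElectrodeMeta(f"R{j:03d}", "R", xyz, tracking, label)
            )
        for j in range(n_l):
            xyz = (
                float(rng.uniform(-65, -15)),
                float(rng.uniform(-70, 40)),
                float(rng.uniform(-20, 60)),
            )
            metas.append(ElectrodeMeta(f"L{j:03d}", "L", xyz, False, "L other"))
        return metas

    def blocks(self) -> list[StimulusBlock]:
        """All stimulus blocks of the design (per participant)."""
        out: list[StimulusBlock] = []
        for symbols in self.rhythms:
            for tempo in self.tempi:
                pattern = parse_pattern(symbols, tempo)
                for pres in self.presentations:
                    for cond, reps in (
                        ("listen", self.listen_reps[tempo]),
                        ("imagine", self.imagine_reps),
                    ):
                        out.append(
                            StimulusBlock(pattern, reps, cond, "rhythm", pres)
                        )
        return out


def generate_study(
    design: StudyDesign, seed: int
) -> tuple[list[EcogTrial], dict[str, GroundTruth], dict[str, list[ElectrodeMeta]]]:
    """Generate the full factorial set of trials for every participant.

    Returns ``(trials, ground_truth_by_participant, electrodes_by_participant)``.
    White-noise control twins (when enabled) are included for every block.
    Regeneration with the same seed and design is bit-identical.
    """
    trials: list[EcogTrial] = []
    truths: dict[str, GroundTruth] = {}
    montages: dict[str, list[ElectrodeMeta]] = {}
    for p_idx in range(design.n_participants):
        participant = f"P{p_idx + 1:02d}"
        mrng = np.random.default_rng(_derive_seed(seed, participant, "montage"))
        electrodes = design.electrodes_for(p_idx, mrng)
        truth = GroundTruth.uniform(
            electrodes,
            design.modulation_depth,
            design.tracking_lag_ms,
            design.tracking_transform,
        )
        truths[participant] = truth
        montages[participant] = electrodes
        for block in design.blocks():
            trials.append(
                generate_trial(
                    block, electrodes, truth, design.noise, seed,
                    design.rate_hz, participant,
                )
            )
            if design.include_white_noise:
                trials.append(
                    generate_white_noise_trial(
                        block, electrodes, design.noise, seed,
                        design.rate_hz, participant,
                    )
                )
    return trials, truths, montages


# ---------------------------------------------------------------------------
# I/O: binary matrix + JSON sidecar, electrode TSV, EDF reading


def save_trial(trial: EcogTrial, out_dir) -> Path:
    """Write ``<id>.npy`` (channels x samples, float64) + ``<id>.json`` sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = out_dir / trial.trial_id
    np.save(base.with_suffix(".npy"), trial.data)
    sidecar = {
        "rate_hz": trial.rate_hz,
        "participant": trial.participant,
        "block": {
            "symbols": trial.block.pattern.symbols,
            "tempo_bpm": trial.block.pattern.tempo_bpm,
            "pulses_per_beat": trial.block.pattern.pulses_per_beat,
            "repetitions": trial.block.repetitions,
            "audio_condition": trial.block.audio_condition,
            "signal_type": trial.block.signal_type,
            "presentation": trial.block.presentation,
        },
        "channels": [
            {
                "id": e.id,
                "hemisphere": e.hemisphere,
                "talairach_xyz": list(e.talairach_xyz),
                "ground_truth_tracking": e.ground_truth_tracking,
                "region_label": e.region_label,
            }
            for e in trial.channels
        ],
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return base.with_suffix(".npy")


def load_trial(npy_path) -> EcogTrial:
    """Load a trial written by :func:`save_trial`."""
    npy_path = Path(npy_path)
    meta = json.loads(npy_path.with_suffix(".json").read_text())
    b = meta["block"]
    block = StimulusBlock(
        RhythmPattern(b["symbols"], b["tempo_bpm"], b["pulses_per_beat"]),
        b["repetitions"],
        b["audio_condition"],
        b["signal_type"],
        b["presentation"],
    )
    channels = [
        ElectrodeMeta(
            c["id"], c["hemisphere"], tuple(c["talairach_xyz"]),
            c["ground_truth_tracking"], c["region_label"],
        )
        for c in meta["channels"]
    ]
    return EcogTrial(np.load(npy_path), meta["rate_hz"], channels, block,
                     meta["participant"])


def electrodes_to_tsv(electrodes: list[ElectrodeMeta], path) -> None:
    pd.DataFrame(
        [
            {
                "id": e.id,
                "hemisphere": e.hemisphere,
                "x": e.talairach_xyz[0],
                "y": e.talairach_xyz[1],
                "z": e.talairach_xyz[2],
                "ground_truth": int(e.ground_truth_tracking),
                "region": e.region_label,
            }
            for e in electrodes
        ]
    ).to_csv(path, sep="\t", index=False)


def electrodes_from_tsv(path) -> list[ElectrodeMeta]:
    df = pd.read_csv(path, sep="\t")
    return [
        ElectrodeMeta(
            str(r.id), str(r.hemisphere), (float(r.x), float(r.y), float(r.z)),
            bool(r.ground_truth), str(getattr(r, "region", "")),
        )
        for r in df.itertuples()
    ]


def read_edf(path, block: StimulusBlock, participant: str = "unknown") -> EcogTrial:
    """Read a multichannel EDF recording into an :class:`EcogTrial`.

    Requires ``mne``; electrode locations default to (0, 0, 0) on the right
    and should be supplied separately via :func:`electrodes_from_tsv`.
    """
    import mne  # deferred: EDF support is optional

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data()
    channels = [
        ElectrodeMeta(name, "R", (0.0, 0.0, 0.0)) for name in raw.ch_names
    ]
    return EcogTrial(data, float(raw.info["sfreq"]), channels, block, participant)
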