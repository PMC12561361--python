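"""Synthetic study data: glyph corpora, simulated sessions, raw recordings.

Everything the decoding pipeline consumes can be generated here with a
seed: a packaged corpus of 26 block-capital letter templates (polygonal
letterforms in [0, 1]^2, written in natural stroke order), random
multi-stroke glyphs for scaling the recognition library, simulated feature
sessions (velocity-tuned linear encoding with optional timeline
misalignment and per-day drift), and raw 30 kHz multichannel recordings
with ground-truth spike times for exercising the feature-extraction
recipes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kinematics as kin
from . import simulation as sim
from .kinematics import KinematicSeries, StrokeTemplate, connect_strokes

__all__ = [
    "GlyphCorpus",
    "SessionSpec",
    "TuningSpec",
    "Trial",
    "Session",
    "letter_corpus",
    "random_glyph",
    "simulate_session",
    "simulate_raw_recording",
]

# Block-capital letterforms: pen-down strokes as polylines, x right / y up,
# inside [0, 1]^2, in natural writing order.  Pen lifts are inserted
# automatically wherever consecutive strokes do not connect.
_LETTER_STROKES: dict[str, list[list[tuple[float, float]]]] = {
    "A": [[(0.0, 0.0), (0.5, 1.0)], [(0.5, 1.0), (1.0, 0.0)],
          [(0.2, 0.4), (0.8, 0.4)]],
    "B": [[(0.0, 1.0), (0.0, 0.0)],
          [(0.0, 1.0), (0.7, 1.0), (0.8, 0.75), (0.7, 0.5), (0.0, 0.5)],
          [(0.0, 0.5), (0.8, 0.5), (0.9, 0.25), (0.8, 0.0), (0.0, 0.0)]],
    "C": [[(1.0, 0.85), (0.6, 1.0), (0.2, 0.85), (0.0, 0.5), (0.2, 0.15),
           (0.6, 0.0), (1.0, 0.15)]],
    "D": [[(0.0, 1.0), (0.0, 0.0)],
          [(0.0, 1.0), (0.6, 1.0), (0.9, 0.6), (0.9, 0.4), (0.6, 0.0), (0.0, 0.0)]],
    "E": [[(1.0, 1.0), (0.0, 1.0), (0.0, 0.0), (1.0, 0.0)],
          [(0.0, 0.5), (0.7, 0.5)]],
    "F": [[(1.0, 1.0), (0.0, 1.0), (0.0, 0.0)], [(0.0, 0.5), (0.7, 0.5)]],
    "G": [[(1.0, 0.85), (0.6, 1.0), (0.2, 0.85), (0.0, 0.5), (0.2, 0.15),
           (0.6, 0.0), (1.0, 0.15), (1.0, 0.45), (0.6, 0.45)]],
    "H": [[(0.0, 1.0), (0.0, 0.0)], [(1.0, 1.0), (1.0, 0.0)],
          [(0.0, 0.5), (1.0, 0.5)]],
    "I": [[(0.3, 1.0), (0.7, 1.0)], [(0.5, 1.0), (0.5, 0.0)],
          [(0.3, 0.0), (0.7, 0.0)]],
    "J": [[(0.3, 1.0), (0.9, 1.0)],
          [(0.7, 1.0), (0.7, 0.2), (0.5, 0.0), (0.2, 0.1), (0.1, 0.3)]],
    "K": [[(0.0, 1.0), (0.0, 0.0)], [(0.9, 1.0), (0.0, 0.45)],
          [(0.3, 0.6), (0.9, 0.0)]],
    "L": [[(0.0, 1.0), (0.0, 0.0), (0.9, 0.0)]],
    "M": [[(0.0, 0.0), (0.0, 1.0), (0.5, 0.4), (1.0, 1.0), (1.0, 0.0)]],
    "N": [[(0.0, 0.0), (0.0, 1.0), (1.0, 0.0), (1.0, 1.0)]],
    "O": [[(0.5, 1.0), (0.1, 0.8), (0.0, 0.5), (0.1, 0.2), (0.5, 0.0),
           (0.9, 0.2), (1.0, 0.5), (0.9, 0.8), (0.5, 1.0)]],
    "P": [[(0.0, 0.0), (0.0, 1.0)],
          [(0.0, 1.0), (0.7, 1.0), (0.85, 0.75), (0.7, 0.5), (0.0, 0.5)]],
    "Q": [[(0.5, 1.0), (0.1, 0.8), (0.0, 0.5), (0.1, 0.2), (0.5, 0.0),
           (0.9, 0.2), (1.0, 0.5), (0.9, 0.8), (0.5, 1.0)],
          [(0.65, 0.3), (0.95, 0.02)]],
    "R": [[(0.0, 0.0), (0.0, 1.0)],
          [(0.0, 1.0), (0.7, 1.0), (0.85, 0.75), (0.7, 0.5), (0.0, 0.5)],
          [(0.35, 0.5), (0.9, 0.0)]],
    "S": [[(0.9, 0.85), (0.5, 1.0), (0.1, 0.85), (0.1, 0.6), (0.9, 0.4),
           (0.9, 0.15), (0.5, 0.0), (0.1, 0.15)]],
    "T": [[(0.0, 1.0), (1.0, 1.0)], [(0.5, 1.0), (0.5, 0.0)]],
    "U": [[(0.0, 1.0), (0.0, 0.25), (0.25, 0.0), (0.75, 0.0), (1.0, 0.25),
           (1.0, 1.0)]],
    "V": [[(0.0, 1.0), (0.5, 0.0), (1.0, 1.0)]],
    "W": [[(0.0, 1.0), (0.25, 0.0), (0.5, 0.6), (0.75, 0.0), (1.0, 1.0)]],
    "X": [[(0.0, 1.0), (1.0, 0.0)], [(1.0, 1.0), (0.0, 0.0)]],
    "Y": [[(0.0, 1.0), (0.5, 0.5)], [(1.0, 1.0), (0.5, 0.5)],
          [(0.5, 0.5), (0.5, 0.0)]],
    "Z": [[(0.0, 1.0), (1.0, 1.0), (0.0, 0.0), (1.0, 0.0)]],
}


@dataclass
class GlyphCorpus:
    templates: list[StrokeTemplate]

    def __len__(self) -> int:
        return len(self.templates)

    @property
    def ids(self) -> list[str]:
        return [t.id for t in self.templates]

    def __getitem__(self, glyph_id: str) -> StrokeTemplate:
        for t in self.templates:
            if t.id == glyph_id:
                return t
        raise KeyError(glyph_id)


def letter_corpus() -> GlyphCorpus:
    """The packaged 26-letter block-capital corpus (deterministic)."""
    templates = [
        connect_strokes(letter, [np.asarray(s, float) for s in strokes])
        for letter, strokes in _LETTER_STROKES.items()
    ]
    for t in templates:
        t.validate_connectivity()
    return GlyphCorpus(templates=templates)


def random_glyph(seed_or_rng, n_strokes: int, glyph_id: str | None = None) -> StrokeTemplate:
    """A connected random multi-stroke glyph inside [0, 1]^2.

    Each stroke is a 2-4 point polyline; pen lifts join consecutive strokes.
    Used to scale the recognition library beyond the packaged letters.
    """
    rng = (
        np.random.default_rng(seed_or_rng)
        if isinstance(seed_or_rng, (int, np.integer))
        else seed_or_rng
    )
    if n_strokes < 1:
        raise ValueError("n_strokes must be >= 1")
    strokes = []
    for _ in range(n_strokes):
        n_pts = int(rng.integers(2, 5))
        pts = [rng.uniform(0.05, 0.95, size=2)]
        while len(pts) < n_pts:
            step = rng.uniform(-0.45, 0.45, size=2)
            nxt = np.clip(pts[-1] + step, 0.0, 1.0)
            if np.linalg.norm(nxt - pts[-1]) > 0.05:
                pts.append(nxt)
        strokes.append(np.asarray(pts))
    gid = glyph_id if glyph_id is not None else f"glyph_{rng.integers(1 << 31)}"
    tmpl = connect_strokes(gid, strokes)
    tmpl.validate_connectivity()
    return tmpl


# ---------------------------------------------------------------------------
# Simulated feature sessions.
# ---------------------------------------------------------------------------


@dataclass
class SessionSpec:
    """Conditions for one simulated recording session.

    ``misalignment`` applies the uniform timeline resampling to each trial
    independently; ``noise_sd`` is the observation-noise SD as a fraction of
    each channel's noiseless feature SD (default 1.0 — single channels carry
    weak kinematic signal, as in cortical recordings).  ``day`` selects the
    per-day multiplicative gain / additive offset drift; the encoder weights
    are shared across days and trials.
    """

    repetitions: int = 3
    n_channels: int = 96
    misalignment: bool = True
    day: int = 0
    drift: bool = True
    noise_sd: float = 1.0
    seed: int = 0
    encoder_seed: int = 12345
    fs: float = 20.0


@dataclass
class Trial:
    char_id: str
    rep: int
    day: int
    features: np.ndarray  # (channels, bins)
    label: KinematicSeries  # prompted kinematics (un-resampled)
    true_velocity: np.ndarray  # resampled ("actual") velocity V', (bins, 2)


@dataclass
class Session:
    trials: list[Trial]
    encoder: "sim.LinearEncoder"
    spec: SessionSpec

    def __len__(self) -> int:
        return len(self.trials)


def simulate_session(corpus: GlyphCorpus, spec: SessionSpec) -> Session:
    """Generate feature/label trials for a glyph corpus under ``spec``.

    Features are the fixed linear encoding of the (optionally resampled)
    velocity, with per-day gain/offset drift and per-channel Gaussian
    observation noise.  Labels are the prompted kinematics; the resampled
    velocity V' is retained as ground truth for evaluation.
    """
    rng = np.random.default_rng(spec.seed)
    encoder = sim.LinearEncoder.create(spec.n_channels, seed=spec.encoder_seed)
    labels = {t.id: kin.synthesize_kinematics(t, fs=spec.fs) for t in corpus.templates}

    # Per-day drift, fixed given the day index (independent of trial seed).
    drift_rng = np.random.default_rng(spec.encoder_seed + 1000 + spec.day)
    if spec.drift and spec.day > 0:
        gain = np.exp(drift_rng.normal(0.0, 0.1, size=spec.n_channels))
    else:
        gain = np.ones(spec.n_channels)

    # Channel SDs of the noiseless encoding, for scaling noise and offsets.
    clean = np.vstack([encoder.encode(labels[g].velocity) for g in corpus.ids])
    ch_sd = clean.std(axis=0)
    if spec.drift and spec.day > 0:
        offset = drift_rng.normal(0.0, 0.1 * ch_sd)
    else:
        offset = np.zeros(spec.n_channels)

    trials = []
    for char_id in corpus.ids:
        label = labels[char_id]
        for rep in range(spec.repetitions):
            if spec.misalignment:
                _, v_true = sim.resample_timeline(
                    label.position, rng, origin=label.origin, fs=label.fs
                )
            else:
                v_true = label.velocity.copy()
            feats = encoder.encode(v_true)  # (bins, channels)
            feats = feats * gain[None, :] + offset[None, :]
            feats = feats + rng.normal(0.0, spec.noise_sd * ch_sd, size=feats.shape)
            trials.append(
                Trial(
                    char_id=char_id,
                    rep=rep,
                    day=spec.day,
                    features=feats.T,
                    label=label,
                    true_velocity=v_true,
                )
            )
    return Session(trials=trials, encoder=encoder, spec=spec)


# ---------------------------------------------------------------------------
# Raw 30 kHz recordings with ground-truth spikes.
# ---------------------------------------------------------------------------


@dataclass
class TuningSpec:
    """Velocity tuning and waveform parameters for simulated channels.

    Firing rate per channel: baseline + depth * (velocity . preferred
    direction), clipped at zero.  Spike waveforms are biphasic (sharp
    negative peak, slower positive rebound) on a pink-plus-white background.
    """

    baseline_hz: float = 30.0
    depth_hz: float = 80.0
    spike_amp_uv: float = 100.0
    noise_sd_uv: float = 20.0
    refractory_ms: float = 1.5


def _spike_waveform(fs: float = 30000.0) -> np.ndarray:
    """Biphasic extracellular waveform, ~1.2 ms, peak normalized to -1."""
    t = np.arange(int(1.2e-3 * fs)) / fs
    w = -np.exp(-(((t - 2.0e-4) / 1.2e-4) ** 2)) + 0.35 * np.exp(
        -(((t - 6.0e-4) / 2.5e-4) ** 2)
    )
    return w / np.abs(w).max()


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Approximate 1/f noise via FFT shaping, unit variance."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    shaped = np.fft.irfft(spec * scale, n=n)
    return shaped / shaped.std()


@dataclass
class RawSimResult:
    recording: "object"  # neural_features.RawRecording
    spike_times: list[np.ndarray]  # per channel, sample indices
    rate_hz: np.ndarray  # (channels, samples) underlying rate
    preferred_directions: np.ndarray  # (channels, 2)


def simulate_raw_recording(
    kin_series: KinematicSeries,
    tuning: TuningSpec,
    seed: int,
    n_channels: int = 4,
    fs: float = 30000.0,
    pad_s: float = 0.6,
) -> RawSimResult:
    """Simulate a 30 kHz multichannel recording driven by a kinematic trial.

    Spikes are an inhomogeneous Bernoulli-per-sample point process with rate
    baseline + depth * (v . preferred direction), clipped at zero, with an
    absolute refractory lockout; waveforms ride on a pink+white background.
    ``pad_s`` seconds of baseline-rate signal are prepended and appended so
    binning with the standard lag has warm-up material.
    """
    from .neural_features import RawRecording  # local import to avoid cycle

    rng = np.random.default_rng(seed)
    v = kin_series.velocity
    n_kin = v.shape[0]
    n_pad = int(pad_s * fs)
    n_trial = int(round(n_kin / kin_series.fs * fs))
    n_total = n_trial + 2 * n_pad

    # Upsample velocity to the raw clock by sample-and-hold.
    idx = np.clip((np.arange(n_trial) / fs * kin_series.fs).astype(int), 0, n_kin - 1)
    pd = rng.normal(size=(n_channels, 2))
    pd /= np.linalg.norm(pd, axis=1, keepdims=True)

    wave = _spike_waveform(fs) * tuning.spike_amp_uv  # negative peak -amp
    refr = int(tuning.refractory_ms * 1e-3 * fs)

    data = np.empty((n_channels, n_total))
    rates = np.empty((n_channels, n_total))
    spike_times = []
    for c in range(n_channels):
        rate = np.full(n_total, tuning.baseline_hz)
        drive = tuning.baseline_hz + tuning.depth_hz * (v[idx] @ pd[c])
        rate[n_pad : n_pad + n_trial] = np.clip(drive, 0.0, None)
        rates[c] = rate
        p = rate / fs
        events = np.flatnonzero(rng.random(n_total) < p)
        # Absolute refractory lockout.
        kept = []
        last = -refr - 1
        for e in events:
            if e - last > refr:
                kept.append(e)
                last = e
        kept = np.asarray(kept, dtype=int)
        spike_times.append(kept)
        trace = (
            tuning.noise_sd_uv * 0.7 * rng.normal(size=n_total)
            + tuning.noise_sd_uv * 0.7 * _pink_noise(n_total, rng)
        )
        for e in kept:
            seg = trace[e : e + len(wave)]
            seg += wave[: len(seg)]
        data[c] = trace

    rec = RawRecording(data=data, fs=fs, channel_ids=list(range(n_channels)))
    return RawSimResult(
        recording=rec, spike_times=spike_times, rate_hz=rates, preferred_directions=pd
    )
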