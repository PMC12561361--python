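"""Glyph stroke templates and their conversion to 20 Hz handwriting kinematics.

A glyph is written as an ordered list of *segments* — polylines labeled
``stroke`` (pen down) or ``pen_lift`` (straight inter-stroke transit).  The
video-guided paradigm writes each straight piece at a triangular velocity
profile

    v(t) = a t            for 0 <= t < T/2
    v(t) = a T - a t      for T/2 <= t <= T

per axis, where T is the piece duration (allocated proportionally to the
piece's share of the total path length) and the scaling factor
a = 4 * displacement / T**2 makes the profile integrate to the piece's
displacement.  The concatenated profile, sampled at 20 Hz and 5-point
smoothed, gives the bell-shaped per-segment speed lobes characteristic of
guided handwriting.

Coordinates are glyph units with x rightward and y upward, nominally in
[0, 1]^2; sources using screen-down y must be flipped at import.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Segment",
    "StrokeTemplate",
    "KinematicSeries",
    "connect_strokes",
    "segment_durations",
    "triangular_profile",
    "synthesize_kinematics",
    "integrate_velocity",
    "differentiate_positions",
    "zscore_per_dim",
    "load_template_json",
    "save_template_json",
    "total_duration_policy",
]

STROKE = "stroke"
PEN_LIFT = "pen_lift"


@dataclass
class Segment:
    points: np.ndarray  # (N, 2), N >= 2
    label: str = STROKE

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[0] < 2 or self.points.shape[1] != 2:
            raise ValueError("segment polyline must have shape (>=2, 2)")
        if self.label not in (STROKE, PEN_LIFT):
            raise ValueError(f"unknown segment label {self.label!r}")

    @property
    def arclength(self) -> float:
        return float(np.sum(np.linalg.norm(np.diff(self.points, axis=0), axis=1)))


@dataclass
class StrokeTemplate:
    """Ordered, connected writing path for one character."""

    id: str
    segments: list[Segment]

    def __post_init__(self):
        if not self.segments:
            raise ValueError("template needs at least one segment")

    def validate_connectivity(self, atol: float = 1e-9) -> None:
        for prev, nxt in zip(self.segments, self.segments[1:]):
            if not np.allclose(prev.points[-1], nxt.points[0], atol=atol):
                raise ValueError(
                    f"template {self.id!r}: segment does not start where the "
                    f"previous one ends ({prev.points[-1]} vs {nxt.points[0]})"
                )

    @property
    def arclength(self) -> float:
        return float(sum(s.arclength for s in self.segments))

    @property
    def start(self) -> np.ndarray:
        return self.segments[0].points[0].copy()

    @property
    def end(self) -> np.ndarray:
        return self.segments[-1].points[-1].copy()

    def bounding_box_diagonal(self) -> float:
        pts = np.vstack([s.points for s in self.segments])
        return float(np.linalg.norm(pts.max(axis=0) - pts.min(axis=0)))


def connect_strokes(id: str, strokes, atol: float = 1e-9) -> StrokeTemplate:
    """Build a template from pen-down polylines, inserting straight pen lifts
    wherever consecutive strokes do not connect."""
    segments: list[Segment] = []
    for pts in strokes:
        pts = np.asarray(pts, dtype=float)
        if segments and not np.allclose(segments[-1].points[-1], pts[0], atol=atol):
            lift = np.vstack([segments[-1].points[-1], pts[0]])
            segments.append(Segment(lift, PEN_LIFT))
        segments.append(Segment(pts, STROKE))
    return StrokeTemplate(id=id, segments=segments)


@dataclass
class KinematicSeries:
    """20 Hz velocity/position series for one trial.

    ``position[k]`` is the integral of velocity up to and including sample k,
    starting from ``origin``, i.e. position = origin + cumsum(velocity) / fs.
    """

    velocity: np.ndarray  # (T, 2) units/s
    origin: np.ndarray  # (2,)
    fs: float = 20.0
    position: np.ndarray = field(default=None)  # (T, 2)

    def __post_init__(self):
        self.velocity = np.asarray(self.velocity, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.position is None:
            self.position = integrate_velocity(self.velocity, self.origin, self.fs)

    def __len__(self) -> int:
        return self.velocity.shape[0]

    @property
    def speed(self) -> np.ndarray:
        return np.linalg.norm(self.velocity, axis=1)


# ---------------------------------------------------------------------------


def _pieces(template: StrokeTemplate):
    """Straight pieces (start, end, length, segment index) of the whole path."""
    out = []
    for si, seg in enumerate(template.segments):
        for a, b in zip(seg.points[:-1], seg.points[1:]):
            length = float(np.linalg.norm(b - a))
            if length <= 0:
                raise ValueError(
                    f"template {template.id!r}: zero-length piece in segment {si}"
                )
            out.append((a, b, length, si))
    return out


def segment_durations(template: StrokeTemplate, total_T: float) -> list[float]:
    """Per-segment durations, proportional to segment arclength; sums to total_T."""
    if total_T <= 0:
        raise ValueError("total_T must be > 0")
    lengths = [s.arclength for s in template.segments]
    if min(lengths) <= 0:
        raise ValueError("zero-length segment")
    total = sum(lengths)
    return [total_T * L / total for L in lengths]


def triangular_profile(displacement: float, T: float, fs: float) -> np.ndarray:
    """Sampled per-axis triangular velocity profile over [0, T].

    The continuous profile rises linearly to a peak 2*displacement/T at T/2
    and falls back to zero at T; it integrates to ``displacement``.
    """
    if T <= 0 or fs <= 0:
        raise ValueError("T and fs must be > 0")
    n = int(np.ceil(T * fs))
    if n < 2:
        raise ValueError("profile too short: need at least 2 samples (T*fs >= 2)")
    t = np.arange(n) / fs
    a = 4.0 * displacement / T**2
    return np.where(t < T / 2, a * t, a * T - a * t)


def total_duration_policy(arclength: float, t_min: float = 4.0, t_max: float = 8.0) -> float:
    """Writing duration by path length: 4 s up to length 1, 8 s at length 4."""
    frac = (arclength - 1.0) / 3.0
    return float(np.clip(t_min + (t_max - t_min) * frac, t_min, t_max))


def _position_at(template: StrokeTemplate, total_T: float, t: np.ndarray) -> np.ndarray:
    """Closed-form position along the path at times t (clamped to [0, total_T]).

    Within each straight piece, the triangular velocity profile gives the
    fractional progress f(tau) = 2 tau^2 for tau <= 1/2 and 1 - 2 (1-tau)^2
    for tau > 1/2, tau the normalized time within the piece.
    """
    pieces = _pieces(template)
    total_len = sum(p[2] for p in pieces)
    starts = np.cumsum([0.0] + [p[2] / total_len * total_T for p in pieces])
    t = np.clip(np.asarray(t, dtype=float), 0.0, total_T)
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(pieces) - 1)
    out = np.empty((len(t), 2))
    for k, (ti, pi) in enumerate(zip(t, idx)):
        a, b, _, _ = pieces[pi]
        T_p = starts[pi + 1] - starts[pi]
        tau = (ti - starts[pi]) / T_p
        if tau <= 0.5:
            f = 2.0 * tau * tau
        else:
            f = 1.0 - 2.0 * (1.0 - tau) ** 2
        out[k] = a + (b - a) * f
    return out


def _smooth(v: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge-replicated padding."""
    if window <= 1:
        return v
    half = window // 2
    padded = np.concatenate(
        [np.repeat(v[:1], half, axis=0), v, np.repeat(v[-1:], half, axis=0)], axis=0
    )
    kernel = np.ones(window) / window
    return np.column_stack(
        [np.convolve(padded[:, d], kernel, mode="valid") for d in range(v.shape[1])]
    )


def synthesize_kinematics(
    template: StrokeTemplate,
    total_duration: float | None = None,
    fs: float = 20.0,
    smooth: int = 5,
) -> KinematicSeries:
    """Render a stroke template as a smoothed 20 Hz velocity/position series.

    Each straight piece of the path gets a duration proportional to its share
    of the total arclength and a per-axis triangular velocity profile.  The
    velocity at sample k is the exact mean path velocity over
    [k/fs, (k+1)/fs), so pre-smoothing integration reproduces the template
    endpoint exactly; the 5-point smoothing perturbs it by under 2 % of the
    glyph bounding-box diagonal.
    """
    template.validate_connectivity()
    if total_duration is None:
        total_duration = total_duration_policy(template.arclength)
    if total_duration < 0.5:
        raise ValueError("total duration below 0.5 s")
    n = int(np.ceil(total_duration * fs))
    grid = np.arange(n + 1) / fs
    pos = _position_at(template, total_duration, grid)
    vel = np.diff(pos, axis=0) * fs
    vel = _smooth(vel, smooth)
    return KinematicSeries(velocity=vel, origin=template.start, fs=fs)


def integrate_velocity(velocity: np.ndarray, origin, fs: float) -> np.ndarray:
    """Positions as the cumulative integral of velocity from ``origin``."""
    velocity = np.asarray(velocity, dtype=float)
    if not np.all(np.isfinite(velocity)):
        raise ValueError("non-finite velocities")
    return np.asarray(origin, dtype=float) + np.cumsum(velocity, axis=0) / fs


def differentiate_positions(position: np.ndarray, origin, fs: float) -> np.ndarray:
    """Inverse of :func:`integrate_velocity` (first sample relative to origin)."""
    position = np.asarray(position, dtype=float)
    prev = np.vstack([np.asarray(origin, dtype=float)[None, :], position[:-1]])
    return (position - prev) * fs


def zscore_per_dim(series: np.ndarray) -> np.ndarray:
    """Z-score each dimension; zero-variance dimensions map to zeros."""
    x = np.asarray(series, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    out = np.zeros_like(x)
    ok = sd > 0
    out[:, ok] = (x[:, ok] - mu[ok]) / sd[ok]
    return out[:, 0] if squeeze else out


# ---------------------------------------------------------------------------
# Template I/O: JSON with id + labeled segment polylines.
# ---------------------------------------------------------------------------


def template_to_dict(template: StrokeTemplate) -> dict:
    return {
        "id": template.id,
        "segments": [
            {"label": s.label, "points": s.points.tolist()} for s in template.segments
        ],
    }


def template_from_dict(d: dict) -> StrokeTemplate:
    tmpl = StrokeTemplate(
        id=d["id"],
        segments=[Segment(np.asarray(s["points"], float), s["label"]) for s in d["segments"]],
    )
    tmpl.validate_connectivity()
    return tmpl


def save_template_json(templates, path) -> None:
    data = [template_to_dict(t) for t in templates]
    Path(path).write_text(json.dumps(data, indent=1))


def load_template_json(path) -> list[StrokeTemplate]:
    data = json.loads(Path(path).read_text())
    if isinstance(data, dict):
        data = [data]
    return [template_from_dict(d) for d in data]


def save_template_csv(templates, path) -> None:
    """CSV alternative: one row per point (id, segment index, label, x, y)."""
    lines = ["id,segment,label,x,y"]
    for t in templates:
        for si, seg in enumerate(t.segments):
            for x, y in seg.points:
                lines.append(f"{t.id},{si},{seg.label},{float(x)!r},{float(y)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_template_csv(path) -> list[StrokeTemplate]:
    import csv

    groups: dict[str, dict[int, tuple[str, list]]] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            gid = row["id"]
            if gid not in groups:
                groups[gid] = {}
                order.append(gid)
            seg = groups[gid].setdefault(int(row["segment"]), (row["label"], []))
            seg[1].append((float(row["x"]), float(row["y"])))
    out = []
    for gid in order:
        segs = [
            Segment(np.asarray(pts, float), label)
            for _, (label, pts) in sorted(groups[gid].items())
        ]
        tmpl = StrokeTemplate(id=gid, segments=segs)
        tmpl.validate_connectivity()
        out.append(tmpl)
    return out
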