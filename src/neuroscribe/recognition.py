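"""Trajectory-to-text recognition by template matching of velocity profiles.

Decoded trajectories are translated to characters by comparing their
z-scored velocity profiles against a library of standard-character velocity
templates, either with (fast)DTW distance — which tolerates the temporal
stretch and delay typical of decoded output — or with plain Pearson
correlation after resampling to a common length.  Recognition-rate curves
versus library size follow the constrained-resampling protocol: every
random subset must contain all characters actually used as queries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import alignment as al
from .kinematics import KinematicSeries, synthesize_kinematics, zscore_per_dim

__all__ = [
    "TemplateLibrary",
    "RecognitionResult",
    "build_library",
    "match",
    "recognition_curve",
    "confusion_matrix",
]


@dataclass
class TemplateLibrary:
    """Character id -> z-scored 2-D velocity template."""

    entries: dict[str, np.ndarray]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def ids(self) -> list[str]:
        return sorted(self.entries)


@dataclass
class RecognitionResult:
    query_id: str | None
    ranked_ids: list[str]
    scores: np.ndarray  # DTW distances (ascending) or correlations (descending)
    metric: str

    @property
    def top1(self) -> str:
        return self.ranked_ids[0]

    @property
    def top1_correct(self) -> bool:
        return self.query_id is not None and self.top1 == self.query_id


def build_library(templates, total_duration=None, fs: float = 20.0) -> TemplateLibrary:
    """Synthesize and z-score velocity templates for a set of glyphs.

    ``templates`` is an iterable of StrokeTemplate (or a GlyphCorpus).
    Duplicate ids raise; the per-glyph duration policy is the standard
    arclength-proportional one unless ``total_duration`` overrides it.
    """
    tmpls = list(getattr(templates, "templates", templates))
    if len(tmpls) < 2:
        raise ValueError("library needs at least 2 templates")
    entries: dict[str, np.ndarray] = {}
    for t in tmpls:
        if t.id in entries:
            raise ValueError(f"duplicate template id {t.id!r}")
        series = synthesize_kinematics(t, total_duration=total_duration, fs=fs)
        entries[t.id] = zscore_per_dim(series.velocity)
    return TemplateLibrary(entries=entries, provenance={"n": len(entries), "fs": fs})


def _resample_to(x: np.ndarray, n: int) -> np.ndarray:
    t_old = np.linspace(0.0, 1.0, x.shape[0])
    t_new = np.linspace(0.0, 1.0, n)
    return np.column_stack([np.interp(t_new, t_old, x[:, d]) for d in range(x.shape[1])])


def match(
    query,
    library: TemplateLibrary,
    metric: str = "dtw",
    query_id: str | None = None,
    radius: int = 2,
    subset: list | None = None,
) -> RecognitionResult:
    """Rank library characters by similarity to a decoded velocity profile.

    The query is z-scored per dimension first.  ``dtw`` ranks by ascending
    fastDTW distance; ``cc`` by descending Pearson correlation after linear
    resampling of both sequences to the query length (dimensions
    concatenated).  Ties break lexicographically by id.
    """
    if len(library) == 0:
        raise ValueError("empty template library")
    if metric not in ("dtw", "cc"):
        raise ValueError(f"unknown metric {metric!r}")
    v = query.velocity if isinstance(query, KinematicSeries) else np.asarray(query, float)
    if v.shape[0] == 0:
        raise ValueError("empty query")
    q = zscore_per_dim(v)
    ids = library.ids if subset is None else sorted(subset)
    scores = []
    for cid in ids:
        tmpl = library.entries[cid]
        if metric == "dtw":
            dist, _ = al.fast_dtw(q, tmpl, radius=radius)
            scores.append(dist)
        else:
            a = q.reshape(-1, order="F")
            b = _resample_to(tmpl, q.shape[0]).reshape(-1, order="F")
            sa, sb = a.std(), b.std()
            cc = 0.0 if sa == 0 or sb == 0 else float(np.corrcoef(a, b)[0, 1])
            scores.append(cc)
    scores = np.asarray(scores)
    order = np.argsort(scores if metric == "dtw" else -scores, kind="stable")
    return RecognitionResult(
        query_id=query_id,
        ranked_ids=[ids[k] for k in order],
        scores=scores[order],
        metric=metric,
    )


def recognition_rate(queries, library: TemplateLibrary, metric: str = "dtw",
                     subset: list | None = None) -> float:
    """Fraction of (query, truth-id) pairs whose top-1 match is correct."""
    hits = 0
    for q, truth in queries:
        res = match(q, library, metric=metric, query_id=truth, subset=subset)
        hits += res.top1_correct
    return hits / len(queries)


def recognition_curve(
    queries,
    library: TemplateLibrary,
    sizes,
    n_resamples: int = 1000,
    seed: int = 0,
    metric: str = "dtw",
) -> pd.DataFrame:
    """Mean +- SD recognition rate versus library size.

    ``queries`` is a sequence of (velocity, truth_id) pairs.  For each size,
    random library subsets always include every truth id; at the full
    library size the subset is unique, so the SD is zero.
    """
    truth_ids = sorted({t for _, t in queries})
    missing = [t for t in truth_ids if t not in library.entries]
    if missing:
        raise ValueError(f"query ids missing from library: {missing}")
    pool = [i for i in library.ids if i not in set(truth_ids)]
    rng = np.random.default_rng(seed)
    rows = []
    # Cache per-query scores against the FULL library once; subset ranking
    # then only needs a restriction of the score table.
    full_scores = []
    for q, truth in queries:
        res = match(q, library, metric=metric, query_id=truth)
        full_scores.append((dict(zip(res.ranked_ids, res.scores)), truth))
    for size in sizes:
        if size < len(truth_ids):
            raise ValueError(f"size {size} smaller than the query character set")
        if size > len(library):
            raise ValueError(f"size {size} exceeds the library")
        n_extra = size - len(truth_ids)
        n_rep = 1 if (n_extra == 0 or n_extra == len(pool)) else n_resamples
        rates = []
        for _ in range(n_rep):
            extra = list(rng.choice(pool, size=n_extra, replace=False)) if pool else []
            sub = set(truth_ids) | set(extra)
            hits = 0
            for table, truth in full_scores:
                pairs = [(table[i], i) for i in sub]
                if metric == "dtw":
                    best = min(pairs)
                else:
                    best = min((-s, i) for s, i in pairs)
                hits += best[1] == truth
            rates.append(hits / len(full_scores))
        rates = np.asarray(rates)
        rows.append({"size": size, "mean_rate": rates.mean(), "sd_rate": rates.std()})
    return pd.DataFrame(rows)


def results_to_frame(results: list[RecognitionResult], k: int = 5) -> pd.DataFrame:
    """Tabulate recognition results (query, top-k candidates and scores)."""
    rows = []
    for r in results:
        row = {"query": r.query_id, "metric": r.metric, "correct": r.top1_correct}
        for rank in range(min(k, len(r.ranked_ids))):
            row[f"rank{rank + 1}"] = r.ranked_ids[rank]
            row[f"score{rank + 1}"] = r.scores[rank]
        rows.append(row)
    return pd.DataFrame(rows)


def confusion_matrix(results: list[RecognitionResult]) -> pd.DataFrame:
    """Truth x top-1 prediction counts; row sums equal per-truth query counts."""
    ids = sorted({r.query_id for r in results} | {r.top1 for r in results})
    mat = pd.DataFrame(0, index=ids, columns=ids)
    for r in results:
        mat.loc[r.query_id, r.top1] += 1
    return mat
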