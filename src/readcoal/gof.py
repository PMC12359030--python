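"""Goodness of fit of read-depth Markov models to per-site depth tracks.

The fit statistic compares doublet frequencies: f_xy is the observed relative
frequency of adjacent site pairs with depths (x, y); under a depth model the
same quantity is e_xy = p_x * p_xy with p_x the stationary depth distribution
and p_xy the transition matrix.  The deviation

    Q = sum_x sum_y e_xy * (e_xy - f_xy)^2

weights squared discrepancies by the model probabilities.  Model doublet
frequencies are estimated from one long simulated track (the rounded-beta
chain has no tractable closed-form stationary law).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .depth import DepthParams, sample_depth_track

__all__ = [
    "GofTables",
    "DepthTrackInfo",
    "read_depth_tsv",
    "count_doublets",
    "model_doublet_freqs",
    "deviation_Q",
    "scan_p",
]


@dataclass
class GofTables:
    """Doublet statistics over the depth support [depth_min, depth_max].

    ``f`` is the doublet frequency matrix (rows = depth at the current site,
    columns = depth at the next site, summing to 1 over all entries), ``p_x``
    the first-position marginal and ``p_xy`` the row-normalized transition
    matrix (rows with no observations are left at zero).
    """

    depth_min: int
    depth_max: int
    f: np.ndarray
    n_doublets: int = 0

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.depth_min, self.depth_max + 1)

    @property
    def p_x(self) -> np.ndarray:
        return self.f.sum(axis=1)

    @property
    def p_xy(self) -> np.ndarray:
        row = self.p_x
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(row[:, None] > 0, self.f / row[:, None], 0.0)
        return t

    def to_frame(self) -> pd.DataFrame:
        s = self.support
        return pd.DataFrame(self.f, index=s, columns=s)


def count_doublets(tracks, depth_min: int = 2, depth_max: int = 100) -> GofTables:
    """Tally adjacent-depth doublets over a list of tracks.

    Adjacency never spans track boundaries; every track must contribute at
    least one doublet (length >= 2).
    """
    tracks = [np.asarray(t, dtype=np.int64) for t in tracks]
    if not tracks:
        raise ValueError("no depth tracks given")
    size = depth_max - depth_min + 1
    counts = np.zeros((size, size), dtype=np.int64)
    for t in tracks:
        if t.size < 2:
            raise ValueError("each track needs at least 2 sites")
        if t.min() < depth_min or t.max() > depth_max:
            raise ValueError("track depth outside [depth_min, depth_max]")
        a = t[:-1] - depth_min
        b = t[1:] - depth_min
        np.add.at(counts, (a, b), 1)
    n = int(counts.sum())
    return GofTables(depth_min=depth_min, depth_max=depth_max,
                     f=counts / n, n_doublets=n)


def model_doublet_freqs(
    params: DepthParams,
    chain_sites: int = 10_000_000,
    rng: np.random.Generator | None = None,
    burn_in: int = 1000,
) -> GofTables:
    """Model doublet frequencies e_xy estimated from one long simulated track
    (no species-level noise: the chain runs at the scaled mean depth)."""
    if rng is None:
        rng = np.random.default_rng()
    if chain_sites <= burn_in + 1:
        raise ValueError("chain_sites must exceed burn_in + 1")
    track = sample_depth_track(params.mean_scaled, chain_sites, params, rng)
    return count_doublets([track[burn_in:]], params.depth_min, params.depth_max)


def deviation_Q(e, f) -> float:
    """The deviation Q = sum e_xy (e_xy - f_xy)^2 between model and data.

    ``e`` and ``f`` may be matrices or :class:`GofTables` over the same
    support.  Q >= 0 with equality iff the tables agree wherever e > 0.
    """
    e_mat, e_support = _as_matrix(e)
    f_mat, f_support = _as_matrix(f)
    if e_mat.shape != f_mat.shape or (
        e_support is not None and f_support is not None
        and not np.array_equal(e_support, f_support)
    ):
        raise ValueError("model and observed tables are on different supports")
    for name, m in (("e", e_mat), ("f", f_mat)):
        if not np.isclose(m.sum(), 1.0, atol=1e-6):
            raise ValueError(f"{name} table must sum to 1")
    return float(np.sum(e_mat * (e_mat - f_mat) ** 2))


def _as_matrix(obj):
    if isinstance(obj, GofTables):
        return obj.f, obj.support
    return np.asarray(obj, dtype=float), None


def scan_p(
    tracks,
    params_base: DepthParams,
    p_grid,
    models=("conditional-mean", "copy"),
    chain_sites: int = 2_000_000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Q of each depth model against empirical tracks over a grid of p.

    The empirical doublet table is computed once; for each (model, p) a model
    table is simulated at the empirical mean depth with the base parameters'
    bounds and concentration.  Returns a DataFrame indexed by p with one Q
    column per model.
    """
    if rng is None:
        rng = np.random.default_rng()
    p_grid = [float(p) for p in p_grid]
    if any(not 0.0 <= p < 1.0 for p in p_grid):
        raise ValueError("p values must lie in [0, 1)")
    obs = count_doublets(tracks, params_base.depth_min, params_base.depth_max)
    mean_depth = float(np.average(obs.support, weights=obs.p_x))
    out: dict[str, list[float]] = {m: [] for m in models}
    for p in p_grid:
        shared_e = None  # at p = 0 both variants are the same i.i.d. model
        for model in models:
            if p == 0.0 and shared_e is not None:
                e = shared_e
            else:
                params = DepthParams(
                    mean_depth=mean_depth,
                    a_samples=params_base.a_samples,
                    a_positions=params_base.a_positions,
                    corr_p=p,
                    depth_min=params_base.depth_min,
                    depth_max=params_base.depth_max,
                    model=model,
                )
                e = model_doublet_freqs(params, chain_sites=chain_sites, rng=rng)
                if p == 0.0:
                    shared_e = e
            out[model].append(deviation_Q(e, obs))
    return pd.DataFrame(out, index=pd.Index(p_grid, name="p"))


# ---------------------------------------------------------------------------
# samtools-depth I/O
# ---------------------------------------------------------------------------

@dataclass
class DepthTrackInfo:
    """Bookkeeping from reading an empirical depth file."""

    n_sites: int = 0
    n_dropped_low: int = 0
    n_clipped_high: int = 0
    n_tracks: int = 0


def read_depth_tsv(
    path: str | Path,
    depth_min: int = 2,
    depth_max: int = 100,
) -> tuple[list[np.ndarray], DepthTrackInfo]:
    """Read per-site depths in the samtools-depth dialect (chrom, 1-based
    position, depth; tab-separated, optionally gzipped).

    Sites with depth below ``depth_min`` (0 and 1 under the defaults) are
    dropped, depths above ``depth_max`` are clipped to ``depth_max``, and
    tracks are split at every chromosome change or position gap so that no
    doublet spans a gap.  Tracks shorter than 2 sites are discarded.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "pos", "depth"],
        dtype={"chrom": str, "pos": np.int64, "depth": np.int64},
    )
    info = DepthTrackInfo(n_sites=len(df))
    low = df["depth"] < depth_min
    info.n_dropped_low = int(low.sum())
    df = df[~low]
    info.n_clipped_high = int((df["depth"] > depth_max).sum())
    tracks: list[np.ndarray] = []
    for _, group in df.groupby("chrom", sort=False):
        pos = group["pos"].to_numpy()
        depth = np.minimum(group["depth"].to_numpy(), depth_max)
        breaks = np.flatnonzero(np.diff(pos) != 1) + 1
        for seg in np.split(depth, breaks):
            if seg.size >= 2:
                tracks.append(seg)
    info.n_tracks = len(tracks)
    return tracks, info
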