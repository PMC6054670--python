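"""Tile counts -> normalized log-ratios -> segments -> integer copy number.

The expected tumor/normal depth ratio at a locus of integer copy number
``c`` in a tumor of purity ``rho`` is ``(rho * c + 2 * (1 - rho)) / 2``
(stroma contributes diploid signal), so on the log2 scale a segment mean
``r`` maps back to the integer ``c`` minimizing
``|r - log2((rho * c + 2 (1 - rho)) / 2)|``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .segmentation import segment_signal

TILE_COLUMNS = ["chrom", "start", "end", "count"]


class TilingError(ValueError):
    """Tumor and normal tracks do not share a tiling."""


def expected_log_ratio(rho: float, c) -> float | np.ndarray:
    """Expected log2 tumor/normal depth ratio for copy number ``c`` at purity ``rho``."""
    c = np.asarray(c, dtype=float)
    mix = (rho * c + 2.0 * (1.0 - rho)) / 2.0
    with np.errstate(divide="ignore"):
        r = np.log2(mix)
    return r if r.ndim else float(r)


def tile_log_ratio(
    tumor: pd.DataFrame,
    normal: pd.DataFrame,
    loess_frac: float = 0.3,
    min_normal: int = 10,
    blacklist: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Normalized per-tile log2 tumor/normal ratio.

    Steps: (1) scale tumor counts to the normal library size; (2) raw
    ratio ``log2((t + 0.5) / (n + 0.5))``; (3) loess of the raw ratio on
    log2 normal count (intensity bias removal), keeping residuals; (4)
    recenter so the genome-wide median is 0.  Tiles with normal count below
    ``min_normal`` (or overlapping the blacklist) are masked and excluded
    from loess, recentering and segmentation.

    Returns the tile frame with ``normal_count, tumor_count, lr, masked``.
    """
    for df in (tumor, normal):
        missing = [c for c in TILE_COLUMNS if c not in df.columns]
        if missing:
            raise TilingError(f"tile track missing columns {missing}")
    if len(tumor) != len(normal) or not (
        tumor[["chrom", "start", "end"]].reset_index(drop=True)
        .equals(normal[["chrom", "start", "end"]].reset_index(drop=True))
    ):
        raise TilingError("tumor and normal tile tracks must share a tiling")

    out = normal[["chrom", "start", "end"]].reset_index(drop=True).copy()
    n_cnt = normal["count"].to_numpy(dtype=float)
    t_cnt = tumor["count"].to_numpy(dtype=float)
    masked = n_cnt < min_normal
    if blacklist is not None and len(blacklist):
        masked = masked | _overlaps_blacklist(out, blacklist)
    if masked.all():
        raise TilingError("all tiles masked; cannot normalize")
    if (~masked).sum() < 100:
        raise TilingError("need >= 100 unmasked tiles for loess normalization")

    scale = n_cnt[~masked].sum() / max(t_cnt[~masked].sum(), 1.0)
    raw = np.log2((t_cnt * scale + 0.5) / (n_cnt + 0.5))
    xg = np.log2(n_cnt + 0.5)
    fit = np.zeros_like(raw)
    xs = xg[~masked]
    delta = 0.01 * (xs.max() - xs.min())
    fitted = lowess(raw[~masked], xs, frac=loess_frac, delta=delta,
                    return_sorted=False)
    fit[~masked] = fitted
    lr = raw - fit
    # Anchor the diploid state at 0 via a two-stage median: per-chromosome
    # medians first, then the median across chromosomes.  A plain genome-wide
    # tile median drifts into the gap between CN clusters in heavily
    # aneuploid genomes because per-tile noise blurs the clusters together.
    chrom_arr = out["chrom"].to_numpy()
    chrom_medians = [np.median(lr[(chrom_arr == c) & ~masked])
                     for c in pd.unique(chrom_arr)
                     if ((chrom_arr == c) & ~masked).any()]
    lr = lr - np.median(chrom_medians)
    out["normal_count"] = n_cnt
    out["tumor_count"] = t_cnt
    out["lr"] = np.where(masked, np.nan, lr)
    out["masked"] = masked
    return out


def _overlaps_blacklist(tiles: pd.DataFrame, blacklist: pd.DataFrame) -> np.ndarray:
    """Boolean mask of tiles overlapping any blacklist interval (both BED half-open)."""
    mask = np.zeros(len(tiles), dtype=bool)
    for chrom, sub in blacklist.groupby("chrom"):
        sel = tiles["chrom"] == chrom
        if not sel.any():
            continue
        starts = np.sort(sub["start"].to_numpy())
        ends = sub["end"].to_numpy()[np.argsort(sub["start"].to_numpy())]
        ts = tiles.loc[sel, "start"].to_numpy()
        te = tiles.loc[sel, "end"].to_numpy()
        # overlap iff some interval with start < tile_end and end > tile_start
        idx = np.searchsorted(starts, te, side="left") - 1
        hit = np.zeros(ts.size, dtype=bool)
        ok = idx >= 0
        hit[ok] = ends[idx[ok]] > ts[ok]
        mask[np.flatnonzero(sel)] = hit
    return mask


def smooth_outliers(track: pd.DataFrame, window: int = 5, z_cap: float = 3.0) -> pd.DataFrame:
    """Shrink isolated single-tile spikes to their window median.

    A tile is an outlier iff it deviates from its rolling-window median by
    more than ``z_cap`` robust SDs (MAD-based, per chromosome) *and* it
    differs from both immediate unmasked neighbours by the same margin —
    so two adjacent shifted tiles (a real micro-segment) are preserved.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    out = track.copy()
    lr = out["lr"].to_numpy(dtype=float).copy()
    for chrom, sub in out.groupby("chrom", sort=False):
        idx = sub.index[~sub["masked"]].to_numpy()
        x = lr[idx]
        if x.size < window:
            continue
        med = pd.Series(x).rolling(window, center=True, min_periods=1).median().to_numpy()
        mad = np.median(np.abs(x - np.median(x)))
        scale = 1.4826 * mad if mad > 0 else np.std(x)
        if scale == 0:
            continue
        cap = z_cap * scale
        dev = np.abs(x - med) > cap
        left = np.abs(np.diff(x, prepend=x[0])) > cap
        right = np.abs(np.diff(x, append=x[-1])) > cap
        left[0] = True    # edge tiles only need the single neighbour
        right[-1] = True
        spike = dev & left & right
        x[spike] = med[spike]
        lr[idx] = x
    out["lr"] = lr
    return out


def cbs_segment(
    track: pd.DataFrame,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_width: int = 3,
    merge_tol: float = 0.05,
    undo_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Circular-binary-segment each chromosome of a log-ratio track.

    Returns one row per segment: ``chrom, start, end, first_tile,
    last_tile, n_tiles, mean_lr`` (bp bounds span from the first to the
    last unmasked tile of the segment; masked tiles interleaved within a
    segment count toward its bp extent but not its mean).  Deterministic
    given ``seed``.
    """
    rows = []
    for ci, (chrom, sub) in enumerate(track.groupby("chrom", sort=False)):
        sub = sub.reset_index(drop=True)
        un = sub.loc[~sub["masked"]]
        if un.empty:
            continue
        x = un["lr"].to_numpy(dtype=float)
        chrom_seed = int(np.random.SeedSequence(
            entropy=seed, spawn_key=(ci,)).generate_state(1)[0] % (2 ** 31))
        if x.size < min_width:
            pieces = [(0, x.size)]
        else:
            pieces = segment_signal(x, alpha=alpha, n_perm=n_perm,
                                    min_width=min_width, merge_tol=merge_tol,
                                    undo_sd=undo_sd, seed=chrom_seed)
        starts = un["start"].to_numpy()
        ends = un["end"].to_numpy()
        for a, b in pieces:
            rows.append({
                "chrom": chrom,
                "start": int(starts[a]),
                "end": int(ends[b - 1]),
                "first_tile": int(a),
                "last_tile": int(b),
                "n_tiles": int(b - a),
                "mean_lr": float(np.mean(x[a:b])),
            })
    return pd.DataFrame(rows)


def assign_segment_cn(
    segments: pd.DataFrame, rho: float, max_cn: int = 8
) -> pd.DataFrame:
    """Assign the integer copy number nearest each segment's mean log-ratio.

    Ties (equidistant states) break toward the diploid state c=2.
    """
    if not (0.0 < rho <= 1.0):
        raise ValueError("purity must be in (0, 1]")
    states = np.arange(0, max_cn + 1)
    expect = expected_log_ratio(rho, states)
    out = segments.copy()
    r = out["mean_lr"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        dist = np.abs(r[:, None] - expect[None, :])
    dist = np.nan_to_num(dist, nan=0.0)  # r = expect = -inf: exact match
    # stable tie-break toward 2: tiny preference for the diploid column
    dist[:, 2] -= 1e-12
    out["cn"] = states[np.argmin(dist, axis=1)]
    return out
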