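"""Genomic windowing: mean single-read vs bulk statistics per window.

The genome is tiled with fixed-width non-overlapping windows (the terminal
window of each chromosome may be shorter). Two views of methylation
heterogeneity are computed per window and compared:

* single-read: unweighted means (mu_s, cv_s, rho_s, rts) of the per-read
  statistics over reads aligned entirely within the window;
* bulk: the same statistics (mu_b, cv_b, rho_b) applied to the ordered
  series of per-CpG methylation levels m_i, where m_i is the methylated
  fraction of assigned calls at site i (coverage-filtered).

A shuffled null replaces each window's reads with reads drawn at random from
the global pool, removing any genomic localisation of heterogeneity. The
per-site statistic d_i = |m_i − 0.5| quantifies inter-molecular agreement
(0 = maximal molecule-to-molecule disagreement, 0.5 = uniform state).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import METH, UNMETH
from .readstats import coefficient_of_variation, neighbour_correlation

DEFAULT_WIDTH = 100_000
DEFAULT_MIN_COVERAGE = 10
DEFAULT_MIN_BULK_SITES = 100


def make_windows(chrom_sizes: dict[str, int], width: int = DEFAULT_WIDTH) -> pd.DataFrame:
    """Tile each chromosome with half-open windows of ``width`` bp."""
    if width <= 0:
        raise ValueError("window width must be positive")
    rows = []
    for chrom in sorted(chrom_sizes):
        size = chrom_sizes[chrom]
        for start in range(0, size, width):
            rows.append((chrom, start, min(start + width, size)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df.index.name = "window_id"
    return df


def _window_index(windows: pd.DataFrame) -> dict[tuple[str, int], int]:
    return {(c, s): i for i, (c, s) in enumerate(zip(windows["chrom"], windows["start"]))}


def assign_reads_to_windows(read_stats: pd.DataFrame, windows: pd.DataFrame) -> pd.Series:
    """Window id per read, or −1 for reads spanning a window boundary.

    A read belongs to a window iff its span is fully contained in the
    half-open window interval.
    """
    width = int((windows["end"] - windows["start"]).max())
    index = _window_index(windows)
    first = read_stats["span_start"].to_numpy() // width
    last = (read_stats["span_end"].to_numpy() - 1) // width
    out = np.full(len(read_stats), -1, dtype=np.int64)
    contained = first == last
    for i in np.flatnonzero(contained):
        key = (read_stats["chrom"].iat[i], int(first[i]) * width)
        wid = index.get(key)
        if wid is not None and read_stats["span_end"].iat[i] <= windows["end"].iat[wid]:
            out[i] = wid
    return pd.Series(out, index=read_stats.index, name="window_id")


def window_single_read_stats(
    read_stats: pd.DataFrame, windows: pd.DataFrame
) -> pd.DataFrame:
    """Mean per-read statistics per window (undefined values excluded).

    ``read_stats`` must carry a ``window_id`` column; reads with id −1 are
    ignored. Windows without any contained read are omitted.
    """
    assigned = read_stats[read_stats["window_id"] >= 0]
    agg = assigned.groupby("window_id").agg(
        n_reads=("read_id", "size"),
        mu_s=("mu", "mean"),
        cv_s=("cv", "mean"),
        rho_s=("rho", "mean"),
        rts=("rts", "mean"),
        n_rho=("rho", "count"),
    )
    out = windows.join(agg, how="inner")
    return out


def shuffled_window_stats(
    read_stats: pd.DataFrame,
    windows: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Null window means from randomly reassigned reads.

    Each window with N_w contained reads receives N_w reads sampled without
    replacement from the global retained pool (pool restored between
    windows), and the mean rho / rts are recomputed. Windows are processed in
    ascending id order so a fixed seed gives identical output.
    """
    assigned = read_stats[read_stats["window_id"] >= 0]
    counts = assigned.groupby("window_id").size().sort_index()
    pool_rho = read_stats["rho"].to_numpy()
    pool_rts = read_stats["rts"].to_numpy()
    n_pool = len(pool_rho)
    rows = []
    for wid, n_w in counts.items():
        take = rng.choice(n_pool, size=int(n_w), replace=False)
        rho = pool_rho[take]
        rts = pool_rts[take]
        rows.append((wid, int(n_w), np.nanmean(rho) if np.any(~np.isnan(rho)) else np.nan, np.nanmean(rts)))
    return pd.DataFrame(rows, columns=["window_id", "n_reads", "rho_shuffled", "rts_shuffled"]).set_index(
        "window_id"
    )


def site_bulk_levels(
    sites: pd.DataFrame,
    windows: pd.DataFrame,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> pd.DataFrame:
    """Per-site bulk methylation levels m_i and heterogeneity d_i.

    Only assigned calls count towards coverage; sites with fewer than
    ``min_coverage`` calls, or whose CpG straddles a window boundary (C and G
    in different windows), are removed. Output columns: chrom, pos, n_meth,
    n_unmeth, m, d, window_id.
    """
    assigned = sites[sites["state"].isin((UNMETH, METH))]
    grp = assigned.groupby(["chrom", "pos"])["state"]
    tab = grp.agg(n_meth="sum", coverage="size").reset_index()
    tab["n_unmeth"] = tab["coverage"] - tab["n_meth"]
    tab = tab[tab["coverage"] >= min_coverage].copy()
    width = int((windows["end"] - windows["start"]).max())
    # boundary straddle: C at pos, G at pos+1 in the next window
    tab = tab[(tab["pos"] // width) == ((tab["pos"] + 1) // width)].copy()
    index = _window_index(windows)
    tab["window_id"] = [
        index.get((c, (p // width) * width), -1) for c, p in zip(tab["chrom"], tab["pos"])
    ]
    tab = tab[tab["window_id"] >= 0].copy()
    tab["m"] = tab["n_meth"] / tab["coverage"]
    tab["d"] = (tab["m"] - 0.5).abs()
    return tab[["chrom", "pos", "n_meth", "n_unmeth", "coverage", "m", "d", "window_id"]].reset_index(
        drop=True
    )


def window_bulk_stats(
    site_bulk: pd.DataFrame,
    windows: pd.DataFrame,
    min_sites: int = DEFAULT_MIN_BULK_SITES,
) -> pd.DataFrame:
    """Bulk window statistics from the ordered per-site m_i series.

    Windows with fewer than ``min_sites`` retained CpGs are dropped. The
    statistics kernel is shared with the per-read module, so a bulk series
    equal to a binary read vector yields identical numbers.
    """
    rows = []
    for wid, grp in site_bulk.groupby("window_id"):
        if len(grp) < min_sites:
            continue
        m = grp.sort_values("pos")["m"].to_numpy()
        rows.append(
            (
                wid,
                len(m),
                float(np.mean(m)),
                coefficient_of_variation(m),
                neighbour_correlation(m),
                float(grp["d"].mean()),
            )
        )
    df = pd.DataFrame(rows, columns=["window_id", "n_cpgs", "mu_b", "cv_b", "rho_b", "mean_d"]).set_index(
        "window_id"
    )
    return windows.join(df, how="inner")


def compare_single_vs_bulk(ws: pd.DataFrame, wb: pd.DataFrame) -> pd.DataFrame:
    """Per-statistic comparison of single-read means against bulk values.

    For each of mean methylation, CV and neighbour correlation over the
    windows present in both tables: Spearman correlation, two-sided paired
    t-test, OLS linear fit (bulk on single), and the mean absolute relative
    difference mean(|bulk − single| / single).
    """
    merged = ws.join(wb[["mu_b", "cv_b", "rho_b"]], how="inner")
    if len(merged) < 3:
        raise ValueError("need at least 3 windows common to both tables")
    rows = []
    for stat, scol, bcol in (("mu", "mu_s", "mu_b"), ("cv", "cv_s", "cv_b"), ("rho", "rho_s", "rho_b")):
        sub = merged[[scol, bcol]].dropna()
        s = sub[scol].to_numpy()
        b = sub[bcol].to_numpy()
        spear, spear_p = stats.spearmanr(s, b)
        t, t_p = stats.ttest_rel(b, s)
        slope, intercept = np.polyfit(s, b, 1)
        rel = float(np.mean(np.abs(b - s) / np.abs(s)))
        rows.append((stat, len(sub), spear, spear_p, t, t_p, slope, intercept, rel))
    return pd.DataFrame(
        rows,
        columns=[
            "statistic",
            "n_windows",
            "spearman",
            "spearman_p",
            "t",
            "t_p",
            "slope",
            "intercept",
            "mean_abs_rel_diff",
        ],
    )


def shuffled_vs_real_ks(ws: pd.DataFrame, shuffled: pd.DataFrame, column: str = "rho_s") -> tuple[float, float]:
    """Two-sided KS test of real window means against the shuffled null."""
    real = ws[column].dropna().to_numpy()
    null = shuffled[column.replace("_s", "_shuffled")].dropna().to_numpy()
    res = stats.ks_2samp(real, null)
    return float(res.statistic), float(res.pvalue)


def d_i_extreme_analysis(
    site_bulk: pd.DataFrame,
    ws: pd.DataFrame,
    fraction: float = 0.10,
    background: str = "rest",
) -> dict:
    """Compare inter-molecular heterogeneity d_i in extreme windows.

    Windows are ranked by mean single-read correlation rho_s; the d_i values
    of CpGs inside the bottom/top ``fraction`` of windows are compared
    against the background (``"rest"`` of the genome, or ``"all"`` windows)
    with two-sided KS tests. Also reports the Spearman correlation between
    per-window mean d_i and rho_s.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    ranked = ws.dropna(subset=["rho_s"]).sort_values(["rho_s", "chrom", "start"])
    k = max(1, int(round(fraction * len(ranked))))
    bottom_ids = set(ranked.index[:k])
    top_ids = set(ranked.index[-k:])
    d = site_bulk["d"].to_numpy()
    wid = site_bulk["window_id"].to_numpy()
    in_bottom = np.isin(wid, list(bottom_ids))
    in_top = np.isin(wid, list(top_ids))
    usable = np.isin(wid, list(ranked.index))

    def _ks(mask):
        bg = usable & (~mask if background == "rest" else np.ones_like(mask))
        if mask.sum() == 0 or bg.sum() == 0:
            return float("nan"), float("nan")
        res = stats.ks_2samp(d[mask], d[bg])
        return float(res.statistic), float(res.pvalue)

    ks_bottom, p_bottom = _ks(in_bottom)
    ks_top, p_top = _ks(in_top)
    mean_d = pd.Series(d[usable]).groupby(pd.Series(wid[usable])).mean()
    joined = pd.concat([mean_d.rename("mean_d"), ranked["rho_s"]], axis=1).dropna()
    if len(joined) >= 3:
        rho, rho_p = stats.spearmanr(joined["mean_d"], joined["rho_s"])
    else:
        rho, rho_p = float("nan"), float("nan")
    return {
        "n_windows_per_side": k,
        "ks_bottom": ks_bottom,
        "p_bottom": p_bottom,
        "ks_top": ks_top,
        "p_top": p_top,
        "mean_d_bottom": float(d[in_bottom].mean()) if in_bottom.any() else float("nan"),
        "mean_d_top": float(d[in_top].mean()) if in_top.any() else float("nan"),
        "spearman_mean_d_vs_rho": float(rho),
        "spearman_p": float(rho_p),
    }
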