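"""Read classification by mixture modelling and annotation enrichment.

The distribution of per-read nearest-neighbour correlations rho_r over a
mammalian genome is bimodal: an ordered (high-correlation) mode and a
disordered (low-correlation) mode. A two-component Gaussian mixture is
fitted to the rho distribution and reads within one standard deviation of
the lower component mean form the *high-heterogeneity* (low-correlation)
group, those within one s.d. of the upper mean the *low-heterogeneity*
group; remaining reads are discarded.

Enrichment of window or read subsets in genomic annotations (chromHMM-like
states, partially methylated domains, CpG islands, genes) is measured as a
ratio of base-overlap proportions, with a two-sided Wilcoxon rank-sum test
on per-window overlap fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .io import AnnotationTrack
from . import intervals as iv

HIGH_HET = "HIGH_HET"  # low-correlation group
LOW_HET = "LOW_HET"  # high-correlation group
DISCARDED = "DISCARDED"


@dataclass
class MixtureFit:
    """Two-Gaussian fit to the read correlation distribution (mu1 < mu2)."""

    mu1: float
    sigma1: float
    w1: float
    mu2: float
    sigma2: float
    w2: float
    loglik: float

    @property
    def separation(self) -> float:
        """|mu2 − mu1| in units of the pooled s.d.; small values flag an
        unreliable (effectively unimodal) grouping."""
        return abs(self.mu2 - self.mu1) / np.sqrt(0.5 * (self.sigma1**2 + self.sigma2**2))


def fit_two_gaussian_mixture(
    rhos: np.ndarray, seed: int = 0, max_retries: int = 5
) -> MixtureFit:
    """Maximum-likelihood two-component Gaussian mixture of rho values.

    EM with k-means initialisation (seeded, so refits are identical);
    degenerate fits (vanishing component s.d.) are retried with a fresh
    initialisation.
    """
    x = np.asarray(rhos, dtype=np.float64)
    x = x[~np.isnan(x)].reshape(-1, 1)
    if len(x) < 10:
        raise ValueError("too few defined rho values for a mixture fit")
    last_err = None
    for attempt in range(max_retries):
        gm = GaussianMixture(
            n_components=2,
            covariance_type="full",
            random_state=seed + attempt,
            n_init=1,
            reg_covar=1e-8,
        ).fit(x)
        sig = np.sqrt(gm.covariances_.ravel())
        if np.all(sig > 1e-6):
            order = np.argsort(gm.means_.ravel())
            mu = gm.means_.ravel()[order]
            sg = sig[order]
            w = gm.weights_[order]
            return MixtureFit(
                mu1=float(mu[0]),
                sigma1=float(sg[0]),
                w1=float(w[0]),
                mu2=float(mu[1]),
                sigma2=float(sg[1]),
                w2=float(w[1]),
                loglik=float(gm.score(x) * len(x)),
            )
        last_err = f"degenerate component s.d. {sig}"
    raise RuntimeError(f"mixture fit failed after {max_retries} attempts: {last_err}")


def assign_read_groups(read_stats: pd.DataFrame, fit: MixtureFit) -> pd.Series:
    """Label each read HIGH_HET / LOW_HET / DISCARDED from its rho.

    A read joins a group when its rho lies within one s.d. of that
    component's mean. Reads eligible for both groups (overlapping bands) go
    to the component with the smaller standardised distance; reads eligible
    for neither, or with undefined rho, are discarded.
    """
    rho = read_stats["rho"].to_numpy()
    z1 = np.abs(rho - fit.mu1) / fit.sigma1
    z2 = np.abs(rho - fit.mu2) / fit.sigma2
    in1 = z1 <= 1.0
    in2 = z2 <= 1.0
    out = np.full(len(rho), DISCARDED, dtype=object)
    out[in1 & ~in2] = HIGH_HET
    out[in2 & ~in1] = LOW_HET
    both = in1 & in2
    out[both & (z1 <= z2)] = HIGH_HET
    out[both & (z1 > z2)] = LOW_HET
    out[np.isnan(rho)] = DISCARDED
    return pd.Series(out, index=read_stats.index, name="group")


def extreme_windows(ws: pd.DataFrame, fraction: float = 0.10) -> tuple[pd.Index, pd.Index]:
    """Bottom/top ``fraction`` of windows ranked by mean correlation rho_s.

    The bottom set (lowest rho_s) holds the most intra-molecularly
    heterogeneous windows. Ties break deterministically by coordinate.
    """
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must be in (0, 0.5]")
    ranked = ws.dropna(subset=["rho_s"]).sort_values(["rho_s", "chrom", "start"])
    k = max(1, int(round(fraction * len(ranked))))
    return ranked.index[:k], ranked.index[-k:]


def overlap_fraction(windows: pd.DataFrame, track: AnnotationTrack) -> pd.Series:
    """Fraction of each window's bases covered by the annotation track."""
    fracs = [
        track.overlap_length(c, s, e) / (e - s)
        for c, s, e in zip(windows["chrom"], windows["start"], windows["end"])
    ]
    return pd.Series(fracs, index=windows.index, name=f"overlap_{track.name}")


def enrichment_test(
    subset: pd.Index, all_windows: pd.DataFrame, track: AnnotationTrack
) -> dict:
    """Base-proportion fold enrichment of a window subset in an annotation.

    fold = P_sub / P_all where P is (overlapping bases) / (total bases) of
    the respective window set. Significance from a two-sided Wilcoxon
    rank-sum test on per-window overlap fractions, subset vs the full set
    (the subset windows remain part of the background).
    """
    sub = all_windows.loc[subset]
    lengths_all = (all_windows["end"] - all_windows["start"]).to_numpy()
    lengths_sub = (sub["end"] - sub["start"]).to_numpy()
    frac_all = overlap_fraction(all_windows, track)
    frac_sub = frac_all.loc[subset]
    p_all = float((frac_all.to_numpy() * lengths_all).sum() / lengths_all.sum())
    p_sub = float((frac_sub.to_numpy() * lengths_sub).sum() / lengths_sub.sum())
    fold = p_sub / p_all if p_all > 0 else float("nan")
    if frac_sub.nunique() == 1 and frac_all.nunique() == 1:
        w, p = float("nan"), 1.0
    else:
        w, p = stats.ranksums(frac_sub, frac_all)
    return {
        "annotation": track.name,
        "n_subset": len(sub),
        "n_all": len(all_windows),
        "P_all": p_all,
        "P_sub": p_sub,
        "fold": fold,
        "wilcoxon_stat": float(w),
        "p_value": float(p),
    }


def continuous_association(
    ws: pd.DataFrame, track: AnnotationTrack, n_groups: int = 5
) -> dict:
    """Enrichment along the full heterogeneity gradient.

    Windows are split into ``n_groups`` equal-size groups by ranked rho_s
    (group 1 = lowest correlation / most heterogeneous); per-group fold
    enrichments are reported, plus the Spearman correlation between rho_s
    and the per-window overlap fraction.
    """
    ranked = ws.dropna(subset=["rho_s"]).sort_values(["rho_s", "chrom", "start"])
    n = len(ranked)
    bounds = [int(np.ceil(n * k / n_groups)) for k in range(n_groups + 1)]
    folds = []
    for k in range(n_groups):
        ids = ranked.index[bounds[k] : bounds[k + 1]]
        folds.append(enrichment_test(ids, ws, track)["fold"])
    frac = overlap_fraction(ranked, track)
    rho, p = stats.spearmanr(ranked["rho_s"], frac)
    return {
        "annotation": track.name,
        "group_folds": folds,
        "spearman_rho_vs_overlap": float(rho),
        "spearman_p": float(p),
    }


def read_overlap_association(read_stats: pd.DataFrame, track: AnnotationTrack) -> dict:
    """Spearman correlation of per-read rho against per-read annotation overlap."""
    sub = read_stats.dropna(subset=["rho"])
    frac = np.array(
        [
            track.overlap_length(c, s, e) / max(e - s, 1)
            for c, s, e in zip(sub["chrom"], sub["span_start"], sub["span_end"])
        ]
    )
    rho, p = stats.spearmanr(sub["rho"], frac)
    return {"annotation": track.name, "spearman": float(rho), "p": float(p), "n_reads": len(sub)}


def jaccard(a: AnnotationTrack, b: AnnotationTrack) -> float:
    """Base-level Jaccard index |A ∩ B| / |A ∪ B| of two merged tracks."""
    inter = 0
    for chrom in set(a.by_chrom) | set(b.by_chrom):
        ia = a.by_chrom.get(chrom)
        ib = b.by_chrom.get(chrom)
        if ia is not None and ib is not None:
            inter += iv.total_length(iv.intersect(ia, ib))
    union = a.total_length() + b.total_length() - inter
    if union == 0:
        return float("nan")
    return inter / union
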