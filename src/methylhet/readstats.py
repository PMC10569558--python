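"""Single-read methylation vectors and their summary statistics.

Each retained read is reduced to an ordered binary vector v (0 unmethylated,
1 methylated) over its assigned CpG (or GpC) sites. Four statistics are
computed per read:

* mu     — mean methylation level,
* cv     — coefficient of variation, sd/mean with the unbiased (N−1) sample
           standard deviation; undefined when the mean is 0,
* rho    — correlation between nearest-neighbour site states: the Pearson
           coefficient of (v_1..v_{N−1}) against (v_2..v_N); undefined when
           either lagged subvector is constant,
* rts    — read transition score, the fraction of adjacent site pairs with
           differing states (0 for uniform reads, 1 for perfectly
           alternating reads).

Low rho / high rts indicate a disordered (heterogeneous) methylation pattern
along the molecule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import METH, UNMETH

#: Minimum assigned sites for a read to enter the analysis.
DEFAULT_MIN_SITES = 100


@dataclass
class ReadMethVector:
    """Ordered binary methylation states of one read's assigned sites."""

    read_id: str
    chrom: str
    span_start: int
    span_end: int
    positions: np.ndarray  # sorted site positions, bp
    states: np.ndarray  # uint8 0/1, same length

    @property
    def n_sites(self) -> int:
        return len(self.positions)


def build_read_vectors(
    sites: pd.DataFrame, min_sites: int = DEFAULT_MIN_SITES
) -> list[ReadMethVector]:
    """Assemble per-read vectors from a site-call table.

    Unassigned sites are dropped first; reads with fewer than ``min_sites``
    remaining sites are discarded. The read span is taken as the extent of
    its called sites (first C to one past the last C's G).
    """
    assigned = sites[sites["state"].isin((UNMETH, METH))]
    out: list[ReadMethVector] = []
    for (read_id, chrom), grp in assigned.groupby(["read_id", "chrom"], sort=False):
        if len(grp) < min_sites:
            continue
        order = np.argsort(grp["pos"].to_numpy())
        pos = grp["pos"].to_numpy()[order]
        states = grp["state"].to_numpy()[order].astype(np.uint8)
        out.append(
            ReadMethVector(
                read_id=read_id,
                chrom=chrom,
                span_start=int(pos[0]),
                span_end=int(pos[-1]) + 2,
                positions=pos.astype(np.int64),
                states=states,
            )
        )
    return out


def mean_methylation(states: np.ndarray) -> float:
    if len(states) == 0:
        raise ValueError("empty methylation vector")
    return float(np.mean(states))


def coefficient_of_variation(states: np.ndarray) -> float:
    """Sample s.d. (N−1 denominator) over mean; NaN when the mean is 0."""
    if len(states) < 2:
        raise ValueError("need at least 2 sites")
    mu = np.mean(states)
    if mu == 0:
        return float("nan")
    return float(np.std(states, ddof=1) / mu)


def neighbour_correlation(states: np.ndarray) -> float:
    """Pearson correlation of the two lag-1 subvectors; NaN if either is constant."""
    v = np.asarray(states, dtype=np.float64)
    if len(v) < 3:
        raise ValueError("need at least 3 sites")
    x, y = v[:-1], v[1:]
    xd, yd = x - x.mean(), y - y.mean()
    denom = np.sqrt((xd**2).sum() * (yd**2).sum())
    if denom == 0:
        return float("nan")
    return float((xd * yd).sum() / denom)


def read_transition_score(states: np.ndarray) -> float:
    v = np.asarray(states, dtype=np.int64)
    if len(v) < 2:
        raise ValueError("need at least 2 sites")
    return float(np.abs(np.diff(v)).mean())


def simulate_random_read(vec: ReadMethVector, rng: np.random.Generator) -> ReadMethVector:
    """Positionally matched read with i.i.d. Bernoulli(mu) states.

    The null for intra-read ordering: simulated reads keep each real read's
    sites and mean methylation but carry no correlation between sites.
    """
    mu = mean_methylation(vec.states)
    states = (rng.random(vec.n_sites) < mu).astype(np.uint8)
    return ReadMethVector(
        read_id=vec.read_id,
        chrom=vec.chrom,
        span_start=vec.span_start,
        span_end=vec.span_end,
        positions=vec.positions,
        states=states,
    )


def compute_read_stats(vectors: list[ReadMethVector]) -> pd.DataFrame:
    """Per-read statistics table (NaN marks undefined cv/rho)."""
    rows = []
    for v in vectors:
        rows.append(
            (
                v.read_id,
                v.chrom,
                v.span_start,
                v.span_end,
                v.n_sites,
                mean_methylation(v.states),
                coefficient_of_variation(v.states),
                neighbour_correlation(v.states),
                read_transition_score(v.states),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["read_id", "chrom", "span_start", "span_end", "n_sites", "mu", "cv", "rho", "rts"],
    )
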