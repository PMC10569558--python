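"""Synthetic nanopore-style methylation call data with ground truth.

Generates per-read methylation call tables in the nanopolish
``call-methylation`` TSV dialect over a small artificial genome, with the
statistical structure the analysis pipeline assumes:

* ORDERED (euchromatin-like) regions: high methylation propensity with
  strong within-read persistence, giving reads with high nearest-neighbour
  correlation;
* HETEROGENEOUS (PMD-like) regions: methylation driven by a nucleosome
  occupancy model (147 bp footprint, uniform random linkers), giving
  disordered reads with a ~(footprint + mean linker) bp periodicity and
  intermediate mean methylation. A phasing probability phi controls the
  fraction of molecules sharing the region's reference occupancy track.

LLR values are emitted from two Gaussians at ±mu_llr whose spread is
calibrated so the configured fraction of calls falls inside the unassigned
band (|LLR| < 2). Sites within 10 bp are grouped into a single call row
sharing one LLR, reproducing the caller's motif-group artifact. Matching
ground truth (per-read regimes, PMD-like and chromatin-state BED tracks,
chromosome sizes) is produced alongside.

NOMe mode additionally emits GpC accessibility calls driven by the same
occupancy tracks: linker (accessible) GpCs are methylated with high
probability, nucleosome-bound GpCs with low probability.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import AnnotationTrack

ORDERED = "ORDERED"
HETEROGENEOUS = "HETEROGENEOUS"

_GROUP_GAP = 10  # caller groups motifs within this many bp into one call


@dataclass
class OrderedParams:
    """Euchromatin-like regime: persistent, highly methylated reads."""

    propensity: float = 0.9  # stationary methylation probability
    # copy probability per site; 0.9 keeps the population lag-1 correlation
    # high while redrawing often enough that reads retain a minority class
    # (higher values degenerate many reads to constant vectors with
    # undefined or zero correlation)
    persistence: float = 0.9


@dataclass
class HeterogeneousParams:
    """PMD-like regime: occupancy-driven, disordered reads.

    Linker/nucleosome methylation probabilities are asymmetric so the
    regime's mean methylation lands at a PMD-like intermediate level
    (~0.6 with the defaults and ~75% occupancy).
    """

    nuc_len: int = 147
    linker_min: int = 10
    linker_max: int = 90
    p_linker_meth: float = 0.95
    p_nuc_meth: float = 0.5
    phi: float = 0.5  # fraction of molecules sharing the reference track
    gpc_p_linker_meth: float = 0.9  # NOMe accessibility conversion in linkers
    gpc_p_nuc_meth: float = 0.1

    @property
    def expected_period(self) -> float:
        return self.nuc_len + 0.5 * (self.linker_min + self.linker_max)


@dataclass
class ReadSpec:
    """Read length / depth / LLR emission parameters."""

    length_median: int = 25_000
    length_sigma: float = 0.25  # lognormal shape
    min_length: int = 2_000
    depth: float = 30.0
    llr_mu: float = 4.0  # confident-call LLR magnitude
    llr_sigma_confident: float = 1.5
    llr_sigma_ambiguous: float = 1.0
    unassigned_target: float = 0.24
    threshold: float = 2.0

    def ambiguous_weight(self) -> float:
        """Fraction of calls drawn from the near-zero ambiguous LLR component.

        The caller's LLR distribution is modelled as a mixture of confident
        calls at N(±mu, sd_c²) and ambiguous calls at N(0, sd_a²); the
        ambiguous weight w solves
        w·P(|N(0,sd_a)| < t) + (1−w)·P(N(mu,sd_c) in (−t, t)) = target,
        keeping the sign-flip (miscall) rate low regardless of the target.
        """
        t, mu = self.threshold, self.llr_mu
        band_amb = stats.norm.cdf(t / self.llr_sigma_ambiguous) - stats.norm.cdf(
            -t / self.llr_sigma_ambiguous
        )
        band_conf = stats.norm.cdf((t - mu) / self.llr_sigma_confident) - stats.norm.cdf(
            (-t - mu) / self.llr_sigma_confident
        )
        if not band_conf <= self.unassigned_target <= band_amb:
            raise ValueError(
                f"unassigned target {self.unassigned_target} outside achievable "
                f"range [{band_conf:.3f}, {band_amb:.3f}]"
            )
        return (self.unassigned_target - band_conf) / (band_amb - band_conf)


@dataclass
class GenomeSpec:
    """Layout of the artificial genome."""

    chromosomes: list[tuple[str, int]] = field(
        default_factory=lambda: [("chrS1", 5_000_000), ("chrS2", 5_000_000)]
    )
    cpg_spacing: float = 100.0  # mean bp between CpG sites
    gpc_spacing: float | None = None  # set (e.g. 40.0) for NOMe mode
    region_min: int = 200_000
    region_max: int = 500_000


@dataclass
class RealisedGenome:
    chrom_sizes: dict[str, int]
    cpg_positions: dict[str, np.ndarray]
    gpc_positions: dict[str, np.ndarray]
    regions: dict[str, list[tuple[int, int, str]]]  # (start, end, regime)

    def regime_at(self, chrom: str, pos: int) -> str:
        for s, e, reg in self.regions[chrom]:
            if s <= pos < e:
                return reg
        return self.regions[chrom][-1][2]

    def pmd_track(self) -> AnnotationTrack:
        items = [
            (c, s, e)
            for c, regs in self.regions.items()
            for s, e, reg in regs
            if reg == HETEROGENEOUS
        ]
        return AnnotationTrack.from_intervals("pmd", items)

    def state_track(self, regime: str, name: str | None = None) -> AnnotationTrack:
        items = [
            (c, s, e) for c, regs in self.regions.items() for s, e, r in regs if r == regime
        ]
        return AnnotationTrack.from_intervals(name or regime.lower(), items)


def _site_positions(length: int, spacing: float, rng: np.random.Generator) -> np.ndarray:
    """Strictly increasing site positions with geometric gaps (min 2 bp)."""
    n_est = int(length / spacing * 1.3) + 10
    gaps = 1 + rng.geometric(1.0 / (spacing - 1.0), size=n_est)
    pos = np.cumsum(gaps) + 3
    return pos[pos < length - 5]


def generate_genome(spec: GenomeSpec, rng: np.random.Generator) -> RealisedGenome:
    """Materialise site positions and an alternating regime map."""
    sizes, cpg, gpc, regions = {}, {}, {}, {}
    for ci, (name, length) in enumerate(spec.chromosomes):
        sizes[name] = length
        cpg[name] = _site_positions(length, spec.cpg_spacing, rng)
        if spec.gpc_spacing is not None:
            g = _site_positions(length, spec.gpc_spacing, rng)
            # a GpC whose C coincides with a CpG C sits in a GCG context
            g = g[~np.isin(g, cpg[name])]
            gpc[name] = g
        else:
            gpc[name] = np.empty(0, dtype=np.int64)
        regs = []
        pos = 0
        regime = ORDERED if ci % 2 == 0 else HETEROGENEOUS
        while pos < length:
            rlen = int(rng.integers(spec.region_min, spec.region_max + 1))
            end = min(pos + rlen, length)
            regs.append((pos, end, regime))
            regime = HETEROGENEOUS if regime == ORDERED else ORDERED
            pos = end
        regions[name] = regs
    return RealisedGenome(sizes, cpg, gpc, regions)


def _occupancy_span(
    start: int, end: int, het: HeterogeneousParams, rng: np.random.Generator, phase_anchor: int
) -> np.ndarray:
    """Occupancy over [start, end) from a renewal process anchored upstream."""
    span = end - start
    occ = np.zeros(span, dtype=np.uint8)
    pos = phase_anchor
    period = het.nuc_len + het.linker_max
    while pos + het.nuc_len <= start:
        pos += het.nuc_len + int(rng.integers(het.linker_min, het.linker_max + 1))
    # pos may still be far behind if anchor was distant; fast-forward safeguard
    while pos < end:
        s = max(pos, start) - start
        e = min(pos + het.nuc_len, end) - start
        if e > s:
            occ[s:e] = 1
        pos += het.nuc_len + int(rng.integers(het.linker_min, het.linker_max + 1))
        if pos < start - 2 * period:
            pos = start - 2 * period
    return occ


class _RegionTracks:
    """Lazy per-region reference occupancy tracks (for phased molecules)."""

    def __init__(self, het: HeterogeneousParams, seed: int):
        self.het = het
        self.seed = seed
        self._tracks: dict[tuple[str, int], np.ndarray] = {}

    def get(self, chrom: str, start: int, end: int) -> np.ndarray:
        key = (chrom, start)
        if key not in self._tracks:
            chrom_tag = zlib.crc32(chrom.encode())
            rng = np.random.default_rng((self.seed, chrom_tag, start))
            anchor = start - int(rng.integers(0, self.het.linker_max))
            self._tracks[key] = _occupancy_span(start, end, self.het, rng, anchor)
        return self._tracks[key]


def _ordered_states(n: int, p: OrderedParams, rng: np.random.Generator) -> np.ndarray:
    """Copy-or-redraw chain: stationary Bernoulli(propensity), lag-1
    correlation equal to the persistence."""
    fresh = rng.random(n) >= p.persistence
    fresh[0] = True
    draws = (rng.random(n) < p.propensity).astype(np.uint8)
    fresh_idx = np.flatnonzero(fresh)
    seg = np.searchsorted(fresh_idx, np.arange(n), side="right") - 1
    return draws[fresh_idx[seg]]


def _read_states(
    chrom: str,
    read_start: int,
    read_end: int,
    positions: np.ndarray,
    genome: RealisedGenome,
    ordered: OrderedParams,
    het: HeterogeneousParams,
    tracks: _RegionTracks,
    rng: np.random.Generator,
    gpc: bool = False,
) -> np.ndarray:
    """True binary states for one read's sites, region by region."""
    states = np.zeros(len(positions), dtype=np.uint8)
    for rs, re_, regime in genome.regions[chrom]:
        if re_ <= read_start or rs >= read_end:
            continue
        mask = (positions >= rs) & (positions < re_)
        if not mask.any():
            continue
        if regime == ORDERED and not gpc:
            states[mask] = _ordered_states(int(mask.sum()), ordered, rng)
            continue
        # occupancy-driven (heterogeneous CpG, or any GpC accessibility)
        if regime == HETEROGENEOUS and rng.random() < het.phi:
            ref = tracks.get(chrom, rs, re_)
            occ = ref[positions[mask] - rs]
        else:
            lo = max(rs, read_start)
            hi = min(re_, read_end)
            anchor = lo - int(rng.integers(0, het.nuc_len + het.linker_max))
            span = _occupancy_span(lo, hi, het, rng, anchor)
            occ = span[positions[mask] - lo]
        if gpc:
            p1, p0 = het.gpc_p_nuc_meth, het.gpc_p_linker_meth
        else:
            p1, p0 = het.p_nuc_meth, het.p_linker_meth
        prob = np.where(occ == 1, p1, p0)
        states[mask] = (rng.random(int(mask.sum())) < prob).astype(np.uint8)
    return states


_SINGLE_SEQ = {"CpG": "A" * 5 + "CG" + "A" * 5, "GpC": "A" * 3 + "GC" + "A" * 7}


class _RowBuffer:
    """Column-wise accumulator for nanopolish-dialect rows.

    Numeric columns collect per-read numpy chunks; repeated string columns
    (chromosome, read id) collect run-length pairs, so building the final
    frame avoids list-to-array conversion of millions of Python objects.
    """

    def __init__(self):
        self.runs: list[tuple[str, str, int]] = []  # (chrom, read_id, n_rows)
        self.start: list[np.ndarray] = []
        self.end: list[np.ndarray] = []
        self.llr: list[np.ndarray] = []
        self.n_motifs: list[np.ndarray] = []
        self.seq: list[str] = []

    def __len__(self):
        return sum(n for _, _, n in self.runs)

    def to_frame(self) -> pd.DataFrame:
        if not self.runs:
            arr = np.empty(0, dtype=np.int64)
            return pd.DataFrame(
                {
                    "chromosome": np.empty(0, dtype=object),
                    "strand": np.empty(0, dtype=object),
                    "start": arr,
                    "end": arr,
                    "read_name": np.empty(0, dtype=object),
                    "log_lik_ratio": np.empty(0, dtype=np.float64),
                    "log_lik_methylated": np.empty(0, dtype=np.float64),
                    "log_lik_unmethylated": np.empty(0, dtype=np.float64),
                    "num_calling_strands": arr,
                    "num_motifs": arr,
                    "sequence": np.empty(0, dtype=object),
                }
            )
        counts = np.array([n for _, _, n in self.runs])
        chrom = np.repeat(np.array([c for c, _, _ in self.runs], dtype=object), counts)
        read = np.repeat(np.array([r for _, r, _ in self.runs], dtype=object), counts)
        n = int(counts.sum())
        return pd.DataFrame(
            {
                "chromosome": chrom,
                "strand": np.full(n, "+", dtype=object),
                "start": np.concatenate(self.start),
                "end": np.concatenate(self.end),
                "read_name": read,
                "log_lik_ratio": np.round(np.concatenate(self.llr), 2),
                "log_lik_methylated": np.zeros(n),
                "log_lik_unmethylated": np.zeros(n),
                "num_calling_strands": np.ones(n, dtype=np.int64),
                "num_motifs": np.concatenate(self.n_motifs),
                "sequence": np.array(self.seq, dtype=object),
            }
        )


def _emit_rows(
    buf: _RowBuffer,
    chrom: str,
    read_id: str,
    positions: np.ndarray,
    states: np.ndarray,
    motif: str,
    readspec: ReadSpec,
    w_amb: float,
    rng: np.random.Generator,
) -> None:
    """Group sites within 10 bp and append nanopolish-dialect rows.

    Each group carries one LLR drawn from the confident component centred at
    ±llr_mu according to the group's (first site's) true state, or — with
    probability ``w_amb`` — from the ambiguous near-zero component.
    """
    c_off = 0 if motif == "CpG" else 1
    brk = np.flatnonzero(np.diff(positions) > _GROUP_GAP) + 1
    g_start = np.concatenate(([0], brk))
    g_end = np.concatenate((brk, [len(positions)]))
    n_g = len(g_start)
    g_state = states[g_start]
    centre = np.where(g_state == 1, readspec.llr_mu, -readspec.llr_mu)
    amb = rng.random(n_g) < w_amb
    llr = rng.normal(centre, readspec.llr_sigma_confident)
    llr[amb] = rng.normal(0.0, readspec.llr_sigma_ambiguous, int(amb.sum()))
    first = positions[g_start]
    last = positions[g_end - 1]
    buf.runs.append((chrom, read_id, n_g))
    buf.start.append(first.astype(np.int64))
    buf.end.append((last + 1).astype(np.int64))
    buf.llr.append(llr)
    buf.n_motifs.append((g_end - g_start).astype(np.int64))
    single_seq = _SINGLE_SEQ[motif]
    for k in range(n_g):
        if g_end[k] - g_start[k] == 1:
            buf.seq.append(single_seq)
            continue
        group = positions[g_start[k] : g_end[k]]
        flank = 5
        seq_start = int(group[0]) - flank + c_off
        seq = bytearray(b"A" * (int(group[-1]) - int(group[0]) + 2 + 2 * flank))
        for p in group:
            off = int(p) - seq_start - c_off
            seq[off : off + 2] = b"GC" if c_off else b"CG"
        buf.seq.append(seq.decode())


def generate_reads(
    genome: RealisedGenome,
    readspec: ReadSpec,
    rng: np.random.Generator,
    ordered: OrderedParams | None = None,
    het: HeterogeneousParams | None = None,
    nome: bool = False,
    seed_for_tracks: int = 0,
) -> dict:
    """Simulate reads and emit nanopolish-dialect call tables.

    Returns a dict with ``calls_cpg`` (DataFrame in TSV column order),
    ``calls_gpc`` (NOMe mode only, else empty), and ``truth_reads``
    (read_id, chrom, start, end, regime at read midpoint).
    """
    ordered = ordered or OrderedParams()
    het = het or HeterogeneousParams()
    w_amb = readspec.ambiguous_weight()
    tracks = _RegionTracks(het, seed_for_tracks)
    buf_cpg = _RowBuffer()
    buf_gpc = _RowBuffer()
    truth = []
    read_no = 0
    for chrom, size in genome.chrom_sizes.items():
        n_reads = int(round(size * readspec.depth / readspec.length_median))
        lengths = np.maximum(
            readspec.min_length,
            rng.lognormal(np.log(readspec.length_median), readspec.length_sigma, n_reads).astype(
                np.int64
            ),
        )
        starts = rng.integers(0, np.maximum(1, size - lengths))
        for length, start in zip(lengths, starts):
            end = int(start + length)
            read_id = f"read{read_no:06d}"
            read_no += 1
            cpg = genome.cpg_positions[chrom]
            pos = cpg[(cpg >= start) & (cpg < end)]
            if len(pos) == 0:
                continue
            states = _read_states(
                chrom, int(start), end, pos, genome, ordered, het, tracks, rng
            )
            _emit_rows(buf_cpg, chrom, read_id, pos, states, "CpG", readspec, w_amb, rng)
            if nome:
                gp = genome.gpc_positions[chrom]
                gpos = gp[(gp >= start) & (gp < end)]
                if len(gpos):
                    gstates = _read_states(
                        chrom, int(start), end, gpos, genome, ordered, het, tracks, rng, gpc=True
                    )
                    _emit_rows(buf_gpc, chrom, read_id, gpos, gstates, "GpC", readspec, w_amb, rng)
            mid = int(start) + int(length) // 2
            truth.append((read_id, chrom, int(start), end, genome.regime_at(chrom, mid)))
    return {
        "calls_cpg": buf_cpg.to_frame(),
        "calls_gpc": buf_gpc.to_frame(),
        "truth_reads": pd.DataFrame(
            truth, columns=["read_id", "chrom", "start", "end", "regime"]
        ),
    }


def generate_nome_reads(
    genome: RealisedGenome,
    readspec: ReadSpec,
    rng: np.random.Generator,
    ordered: OrderedParams | None = None,
    het: HeterogeneousParams | None = None,
) -> dict:
    """NOMe-style generation: CpG methylation plus GpC accessibility calls."""
    return generate_reads(genome, readspec, rng, ordered, het, nome=True)


def write_fixture(
    outdir,
    genome: RealisedGenome,
    data: dict,
) -> dict[str, Path]:
    """Write calls, truth tables and ground-truth annotation files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["calls_cpg"] = outdir / "calls_cpg.tsv"
    data["calls_cpg"].to_csv(paths["calls_cpg"], sep="\t", index=False)
    if len(data["calls_gpc"]):
        paths["calls_gpc"] = outdir / "calls_gpc.tsv"
        data["calls_gpc"].to_csv(paths["calls_gpc"], sep="\t", index=False)
    paths["truth_reads"] = outdir / "truth_reads.tsv"
    data["truth_reads"].to_csv(paths["truth_reads"], sep="\t", index=False)
    paths["chrom_sizes"] = outdir / "chrom.sizes"
    with open(paths["chrom_sizes"], "w") as fh:
        for name, size in genome.chrom_sizes.items():
            fh.write(f"{name}\t{size}\n")
    paths["pmd_bed"] = outdir / "pmd.bed"
    genome.pmd_track().to_bed(paths["pmd_bed"])
    paths["ordered_bed"] = outdir / "ordered.bed"
    genome.state_track(ORDERED).to_bed(paths["ordered_bed"])
    return paths
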