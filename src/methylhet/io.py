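"""Input handling for per-read methylation calls and genome annotations.

Consumes the TSV dialect written by ``nanopolish call-methylation``: one row
per called motif group per read, carrying a log-likelihood ratio (LLR) of
methylated vs unmethylated. Rows are expanded to per-site ternary states
(unmethylated / methylated / unassigned) using a symmetric LLR threshold;
no LLR values escape this module.

Coordinates are 0-based half-open throughout; a CpG or GpC site is identified
by the position of its C on the forward strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from . import intervals as iv

logger = logging.getLogger(__name__)

# Ternary per-site state codes (int8 in tables).
UNMETH = 0
METH = 1
UNASSIGNED = -1

STATE_NAMES = {UNMETH: "UNMETH", METH: "METH", UNASSIGNED: "UNASSIGNED"}

#: Default symmetric LLR threshold for state assignment.
DEFAULT_LLR_THRESHOLD = 2.0

_REQUIRED_COLUMNS = (
    "chromosome",
    "strand",
    "start",
    "end",
    "read_name",
    "log_lik_ratio",
    "num_motifs",
    "sequence",
)

_MOTIF_SEARCH = {"CpG": "CG", "GpC": "GC"}
# Offset of the C within the searched dinucleotide.
_MOTIF_C_OFFSET = {"CpG": 0, "GpC": 1}


@dataclass
class MethCallRecord:
    """One called motif group on one read (one Nanopolish TSV row)."""

    chrom: str
    strand: str
    start: int
    end: int
    read_id: str
    llr: float
    n_motifs: int
    sequence: str


@dataclass
class ParseReport:
    """Row-level accounting from a parse run."""

    n_rows: int = 0
    n_malformed: int = 0
    n_motif_mismatch: int = 0
    n_duplicate_sites: int = 0


def call_state(llr: float, threshold: float = DEFAULT_LLR_THRESHOLD) -> int:
    """Ternary state from a log-likelihood ratio.

    Methylated if ``llr >= threshold``, unmethylated if ``llr <= -threshold``,
    otherwise unassigned. ``threshold`` must be positive.
    """
    if threshold <= 0:
        raise ValueError("LLR threshold must be positive")
    if llr >= threshold:
        return METH
    if llr <= -threshold:
        return UNMETH
    return UNASSIGNED


def parse_nanopolish_tsv(
    path, report: ParseReport | None = None
) -> Iterator[MethCallRecord]:
    """Stream records from a nanopolish ``call-methylation`` TSV.

    Malformed rows (wrong field count, non-numeric coordinates or LLR) are
    skipped and counted in ``report``; a header missing a required column is
    fatal.
    """
    if report is None:
        report = ParseReport()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in _REQUIRED_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"missing required column(s): {', '.join(missing)}")
        idx = {c: header.index(c) for c in _REQUIRED_COLUMNS}
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            report.n_rows += 1
            try:
                rec = MethCallRecord(
                    chrom=fields[idx["chromosome"]],
                    strand=fields[idx["strand"]],
                    start=int(fields[idx["start"]]),
                    end=int(fields[idx["end"]]),
                    read_id=fields[idx["read_name"]],
                    llr=float(fields[idx["log_lik_ratio"]]),
                    n_motifs=int(fields[idx["num_motifs"]]),
                    sequence=fields[idx["sequence"]],
                )
            except (IndexError, ValueError):
                report.n_malformed += 1
                continue
            yield rec


def expand_motif_groups(
    record: MethCallRecord,
    motif: str = "CpG",
    threshold: float = DEFAULT_LLR_THRESHOLD,
) -> list[tuple[str, int, str, int, float]]:
    """Expand one grouped call into per-site tuples.

    Nanopolish reports one row per group of motifs within 10 bp, all sharing
    the group's LLR; every expanded site therefore inherits the same ternary
    state. Site positions are located via motif offsets in the reference
    context ``sequence``, anchored so the first motif's C maps to
    ``record.start``.

    Returns tuples ``(chrom, pos, read_id, state, llr)``; raises
    ``ValueError`` when the motif count in the sequence disagrees with
    ``num_motifs``.
    """
    search = _MOTIF_SEARCH[motif]
    c_off = _MOTIF_C_OFFSET[motif]
    offsets = []
    start = 0
    while True:
        i = record.sequence.find(search, start)
        if i < 0:
            break
        offsets.append(i)
        start = i + 1
    if len(offsets) != record.n_motifs:
        raise ValueError(
            f"sequence contains {len(offsets)} {motif} motifs, expected {record.n_motifs}"
        )
    state = call_state(record.llr, threshold)
    anchor = offsets[0] + c_off
    return [
        (record.chrom, record.start + (o + c_off) - anchor, record.read_id, state, record.llr)
        for o in offsets
    ]


def read_site_calls(
    path,
    motif: str = "CpG",
    threshold: float = DEFAULT_LLR_THRESHOLD,
    report: ParseReport | None = None,
) -> pd.DataFrame:
    """Parse a nanopolish TSV into a per-site call table.

    Returns a DataFrame with columns ``chrom, pos, read_id, motif, state``
    (state int8: 0 unmethylated, 1 methylated, −1 unassigned). Duplicate
    calls for one (read, site) are resolved by keeping the call with the
    largest ``|llr|``. Groups whose sequence context disagrees with
    ``num_motifs`` are dropped and counted.
    """
    if report is None:
        report = ParseReport()
    header = pd.read_csv(path, sep="\t", nrows=0)
    missing = [c for c in _REQUIRED_COLUMNS if c not in header.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    try:
        raw = pd.read_csv(path, sep="\t", usecols=list(_REQUIRED_COLUMNS), engine="pyarrow")
    except Exception:  # malformed rows: fall back to permissive string parsing
        raw = pd.read_csv(
            path, sep="\t", dtype=str, keep_default_na=False, usecols=list(_REQUIRED_COLUMNS)
        )
    report.n_rows = len(raw)
    start = pd.to_numeric(raw["start"], errors="coerce")
    llr = pd.to_numeric(raw["log_lik_ratio"], errors="coerce")
    n_motifs = pd.to_numeric(raw["num_motifs"], errors="coerce")
    ok = (start.notna() & llr.notna() & n_motifs.notna()).to_numpy()
    report.n_malformed = int((~ok).sum())
    search = _MOTIF_SEARCH[motif]
    c_off = _MOTIF_C_OFFSET[motif]
    _count = np.frompyfunc(lambda s: s.count(search) if isinstance(s, str) else -1, 1, 1)
    n_found = _count(raw["sequence"].to_numpy()).astype(np.int64)
    match = ok & (n_found == n_motifs.to_numpy())
    report.n_motif_mismatch = int((ok & ~match).sum())
    match_idx = np.flatnonzero(match)
    start_v = start.to_numpy()[match_idx].astype(np.int64)
    llr_v = llr.to_numpy()[match_idx]
    nm_v = n_motifs.to_numpy()[match_idx].astype(np.int64)
    state_v = np.full(len(match_idx), UNASSIGNED, dtype=np.int8)
    state_v[llr_v >= threshold] = METH
    state_v[llr_v <= -threshold] = UNMETH

    chrom_v = raw["chromosome"].to_numpy()[match_idx]
    read_v = raw["read_name"].to_numpy()[match_idx]
    seq_v = raw["sequence"].to_numpy()[match_idx]
    single = nm_v == 1
    # multi-motif groups expand via motif offsets in the sequence context
    multi_row: list[int] = []
    multi_pos: list[int] = []
    for i in np.flatnonzero(~single):
        seq = seq_v[i]
        offsets = []
        j = 0
        while True:
            j = seq.find(search, j)
            if j < 0:
                break
            offsets.append(j)
            j += 1
        anchor = offsets[0] + c_off
        for o in offsets:
            multi_row.append(i)
            multi_pos.append(start_v[i] + (o + c_off) - anchor)
    m_row = np.array(multi_row, dtype=np.int64)
    row_idx = np.concatenate([np.flatnonzero(single), m_row])
    pos_all = np.concatenate([start_v[single], np.array(multi_pos, dtype=np.int64)])
    chrom_all = chrom_v[row_idx]
    read_all = read_v[row_idx]
    state_all = state_v[row_idx]
    llr_all = llr_v[row_idx]
    n_expanded = len(pos_all)
    if n_expanded == 0:
        return pd.DataFrame(
            {
                "chrom": pd.Series(dtype=str),
                "pos": pd.Series(dtype=np.int64),
                "read_id": pd.Series(dtype=str),
                "motif": pd.Series(dtype=str),
                "state": pd.Series(dtype=np.int8),
            }
        )
    # duplicate (read, site) calls: keep the largest |llr|
    read_codes = pd.factorize(read_all)[0].astype(np.int64)
    chrom_codes = pd.factorize(chrom_all)[0].astype(np.int64)
    key = (read_codes << 40) | (chrom_codes << 32) | pos_all
    key_sorted_view = np.sort(key)
    if np.any(key_sorted_view[1:] == key_sorted_view[:-1]):
        order = np.lexsort((np.abs(llr_all), key))
        key_sorted = key[order]
        last_of_group = np.r_[key_sorted[1:] != key_sorted[:-1], True]
        keep = np.sort(order[last_of_group])
    else:
        keep = np.arange(n_expanded)
    # restore file order (singles were gathered before multi-motif groups)
    file_order = np.lexsort((pos_all[keep], row_idx[keep]))
    keep = keep[file_order]
    df = pd.DataFrame(
        {
            "chrom": chrom_all[keep],
            "pos": pos_all[keep],
            "read_id": read_all[keep],
            "motif": motif,
            "state": state_all[keep],
        }
    )
    report.n_duplicate_sites = n_expanded - len(df)
    if report.n_malformed or report.n_motif_mismatch or report.n_duplicate_sites:
        logger.info(
            "parsed %d rows: %d malformed, %d motif-count mismatches, %d duplicate sites",
            report.n_rows,
            report.n_malformed,
            report.n_motif_mismatch,
            report.n_duplicate_sites,
        )
    return df


def filter_gcg(sites: pd.DataFrame, contexts: dict[tuple[str, int], str]) -> pd.DataFrame:
    """Drop sites whose C lies inside a GCG trinucleotide (NOMe mode only).

    In a GCG context the C belongs to both a CpG and a GpC, so native and
    exogenous methylation cannot be distinguished. ``contexts`` maps
    ``(chrom, pos)`` to the trinucleotide centred on the C; sites with an
    unknown context are retained and counted.
    """
    if len(sites) == 0:
        return sites
    keys = list(zip(sites["chrom"], sites["pos"]))
    ctx = [contexts.get(k) for k in keys]
    is_gcg = np.array([c is not None and c.upper() == "GCG" for c in ctx])
    unknown = sum(c is None for c in ctx)
    if unknown:
        logger.info("filter_gcg: %d sites with unknown context retained", unknown)
    return sites.loc[~is_gcg].reset_index(drop=True)


@dataclass
class AnnotationTrack:
    """A named set of merged genomic intervals, one array per chromosome."""

    name: str
    by_chrom: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, name: str, items: Iterable[tuple[str, int, int]]) -> "AnnotationTrack":
        grouped: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in items:
            grouped.setdefault(chrom, []).append((s, e))
        return cls(name, {c: iv.merge(v) for c, v in grouped.items()})

    def total_length(self) -> int:
        return sum(iv.total_length(a) for a in self.by_chrom.values())

    def overlap_length(self, chrom: str, start: int, end: int) -> int:
        arr = self.by_chrom.get(chrom)
        if arr is None:
            return 0
        return iv.overlap_length(start, end, arr)

    def subtract(self, other: "AnnotationTrack") -> "AnnotationTrack":
        out = {}
        for chrom, arr in self.by_chrom.items():
            rem = iv.subtract(arr, other.by_chrom.get(chrom, np.empty((0, 2), dtype=np.int64)))
            if len(rem):
                out[chrom] = rem
        return AnnotationTrack(self.name, out)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.by_chrom):
                for s, e in self.by_chrom[chrom]:
                    fh.write(f"{chrom}\t{s}\t{e}\n")


def load_bed(path, name: str | None = None, chrom_sizes: dict[str, int] | None = None) -> AnnotationTrack:
    """Load a BED3+ file into a merged :class:`AnnotationTrack`.

    Intervals beyond a chromosome end are clipped; intervals on chromosomes
    absent from ``chrom_sizes`` (when given) are dropped. Both events warn.
    """
    items = []
    n_clipped = n_dropped = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, s, e = f[0], int(f[1]), int(f[2])
            if chrom_sizes is not None:
                size = chrom_sizes.get(chrom)
                if size is None:
                    n_dropped += 1
                    continue
                if e > size:
                    e = size
                    n_clipped += 1
            if s < e:
                items.append((chrom, s, e))
    if n_clipped or n_dropped:
        logger.warning(
            "load_bed %s: %d intervals clipped, %d on unknown chromosomes dropped",
            path,
            n_clipped,
            n_dropped,
        )
    return AnnotationTrack.from_intervals(name or Path(path).stem, items)


def load_chrom_sizes(path) -> dict[str, int]:
    """Load a two-column ``chrom<TAB>length`` table."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            name, length = line.split("\t")[:2]
            sizes[name] = int(length)
    return sizes


def write_site_calls(sites: pd.DataFrame, path) -> None:
    sites.to_csv(path, sep="\t", index=False)
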