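"""End-to-end orchestration of the heterogeneity analysis.

A single :class:`RunConfig` drives every stage with one seed: parse calls →
per-read statistics → window statistics (single-read, bulk, shuffled null) →
mixture classification → annotation enrichment → distance-dependent
correlation and spectrum of the high-heterogeneity group. Tables are written
as TSV, summary statistics as JSON, and a manifest records the
configuration so a rerun with the same config and seed is reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import distcorr, heterogeneity, io, readstats, windows

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    calls: str
    chrom_sizes: str
    outdir: str
    annotations: dict[str, str] = field(default_factory=dict)  # name -> BED path
    window_width: int = 100_000
    llr_threshold: float = 2.0
    min_sites: int = 100
    min_coverage: int = 10
    extreme_fraction: float = 0.10
    d_min: int = 2
    d_max: int = 600
    epsilon: float = 0.06
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the result bundle and writes artifacts."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    stage = "parse"
    try:
        sizes = io.load_chrom_sizes(config.chrom_sizes)
        sites = io.read_site_calls(config.calls, threshold=config.llr_threshold)
        logger.info("parsed %d site calls", len(sites))

        stage = "read-stats"
        vectors = readstats.build_read_vectors(sites, min_sites=config.min_sites)
        reads = readstats.compute_read_stats(vectors)
        reads.to_csv(out / "reads.tsv", sep="\t", index=False)
        logger.info("retained %d reads with >=%d sites", len(reads), config.min_sites)

        stage = "window-stats"
        win = windows.make_windows(sizes, config.window_width)
        reads["window_id"] = windows.assign_reads_to_windows(reads, win)
        ws = windows.window_single_read_stats(reads, win)
        shuffled = windows.shuffled_window_stats(reads, win, rng)
        sb = windows.site_bulk_levels(sites, win, min_coverage=config.min_coverage)
        wb = windows.window_bulk_stats(sb, win)
        comparison = windows.compare_single_vs_bulk(ws, wb)
        ks_stat, ks_p = windows.shuffled_vs_real_ks(ws, shuffled)
        d_report = windows.d_i_extreme_analysis(sb, ws, fraction=config.extreme_fraction)
        ws.join(shuffled[["rho_shuffled", "rts_shuffled"]]).to_csv(
            out / "windows_single.tsv", sep="\t"
        )
        wb.to_csv(out / "windows_bulk.tsv", sep="\t")
        comparison.to_csv(out / "bulk_comparison.tsv", sep="\t", index=False)

        stage = "classify"
        fit = heterogeneity.fit_two_gaussian_mixture(reads["rho"].to_numpy(), seed=config.seed)
        reads["group"] = heterogeneity.assign_read_groups(reads, fit)
        reads[["read_id", "group"]].to_csv(out / "read_groups.tsv", sep="\t", index=False)

        stage = "enrich"
        bottom, top = heterogeneity.extreme_windows(ws, config.extreme_fraction)
        enrichments = []
        for name, path in config.annotations.items():
            track = io.load_bed(path, name=name, chrom_sizes=sizes)
            for label, subset in (("most_heterogeneous", bottom), ("least_heterogeneous", top)):
                res = heterogeneity.enrichment_test(subset, ws, track)
                res["subset"] = label
                enrichments.append(res)
        if enrichments:
            pd.DataFrame(enrichments).to_csv(out / "enrichment.tsv", sep="\t", index=False)

        stage = "distcorr"
        high_ids = set(reads.loc[reads["group"] == heterogeneity.HIGH_HET, "read_id"])
        high_vectors = [v for v in vectors if v.read_id in high_ids]
        profile = distcorr.mean_distance_correlation(
            high_vectors, d_min=config.d_min, d_max=config.d_max
        )
        profile.to_csv(out / "distcorr_high_het.tsv", sep="\t", index=False)

        stage = "spectrum"
        spec = distcorr.power_spectrum(profile)

        stage = "recurrence"
        probs = distcorr.bulk_site_probabilities(sites)
        synth_sites = distcorr.synthesize_reads_from_bulk(sites, probs, rng)
        synth_vectors = readstats.build_read_vectors(synth_sites, min_sites=config.min_sites)
        synth_high = [v for v in synth_vectors if v.read_id in high_ids]
        synth_profile = distcorr.mean_distance_correlation(
            synth_high, d_min=config.d_min, d_max=config.d_max
        )
        rec_real = distcorr.recurrence_matrix(profile["mean_rho"].to_numpy(), config.epsilon)
        rec_synth = distcorr.recurrence_matrix(
            synth_profile["mean_rho"].to_numpy(), config.epsilon
        )
        _, rec_distance = distcorr.recurrence_difference(rec_real, rec_synth)
    except Exception as exc:  # noqa: BLE001 - stage-tagged reraise
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    summary = {
        "n_site_calls": int(len(sites)),
        "n_reads_retained": int(len(reads)),
        "n_windows_single": int(len(ws)),
        "n_windows_bulk": int(len(wb)),
        "bulk_comparison": comparison.to_dict(orient="records"),
        "shuffled_ks": {"statistic": ks_stat, "p": ks_p},
        "d_i": d_report,
        "mixture": asdict(fit),
        "group_sizes": reads["group"].value_counts().to_dict(),
        "enrichment": enrichments,
        "spectrum": {
            "omega_peak": spec.omega_peak,
            "lambda_peak": spec.lambda_peak if spec.significant else None,
            "lambda_range": list(spec.lambda_range) if spec.significant else None,
            "significant": bool(spec.significant),
        },
        "recurrence_distance_real_vs_bulk_synthetic": rec_distance,
        "config": asdict(config),
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return {
        "summary": summary,
        "reads": reads,
        "vectors": vectors,
        "windows_single": ws,
        "windows_bulk": wb,
        "shuffled": shuffled,
        "site_bulk": sb,
        "mixture": fit,
        "profile_high_het": profile,
        "profile_synth": synth_profile,
    }
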