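# methylhet

Single-molecule DNA methylation heterogeneity analysis for nanopore long
reads.

Bulk bisulfite-style summaries average methylation over molecules and hide
how disordered the methylation pattern is *along* each molecule. Long
nanopore reads carry the CpG methylation states of a single DNA molecule
over tens of kilobases, so intra-molecular disorder can be measured
directly. `methylhet` implements that analysis for epigenomics researchers
working with `nanopolish call-methylation` output (or NOMe-style data with
additional GpC accessibility calls): it quantifies per-read heterogeneity,
contrasts it with bulk-level statistics, maps where in the genome
heterogeneous molecules live (heterochromatin, partially methylated
domains), and characterises the ~190 bp nucleosome-scale periodicity of
heterogeneous methylation patterns.

## The statistics

For each read *r* with assigned states v₁…v_N (0 = unmethylated,
1 = methylated; |LLR| < 2 calls are dropped; N ≥ 100):

- mean methylation μ_r = (1/N) Σ vᵢ
- coefficient of variation CV_r = σ_r/μ_r (sample s.d.)
- nearest-neighbour correlation ρ_r = Pearson(v₁…v_{N−1}, v₂…v_N) —
  low ρ_r means a disordered, heterogeneous pattern
- read transition score RTS_r = (1/(N−1)) Σ |v_{i+1} − v_i| ∈ [0, 1]

Windows (100 kb by default) receive the unweighted means of these per-read
statistics over fully contained reads, alongside the same statistics
applied to the bulk per-CpG methylation levels m_i (coverage ≥ 10), a
shuffled-read null, and the inter-molecular agreement score
d_i = |m_i − 0.5|. Reads are split into a high-heterogeneity
(low-correlation) and a low-heterogeneity group by a two-Gaussian mixture
fit to the ρ_r distribution, keeping reads within one s.d. of a component
mean. Distance-dependent correlations ρ_{r,d} (all within-read site pairs
exactly d bp apart) are averaged per group; the dominant oscillation
wavelength λ = 2π/ω_peak and its half-maximum range come from the profile's
power spectrum. Recurrence plots (entry (x, y) similar iff
|ρ_x − ρ_y| ≤ ε, ε = 0.06) compare real against bulk-derived synthetic
reads, and two nucleosome-occupancy models (perfectly phased vs unphased,
147 bp footprint, 10–90 bp uniform linkers, methylation fidelity p = 0.8)
show how nucleosome phasing controls whether the periodicity survives bulk
averaging.

A `simulate` module generates nanopore-style call TSVs over a synthetic
genome with ordered (euchromatin-like) and heterogeneous (PMD-like,
nucleosome-driven) regions plus ground-truth annotations, so the entire
pipeline is testable without any downloads.

## Worked example

```python
import numpy as np
from methylhet import simulate, io, readstats, heterogeneity, distcorr

rng = np.random.default_rng(7)
genome = simulate.generate_genome(simulate.GenomeSpec(), rng)
data = simulate.generate_reads(genome, simulate.ReadSpec(), rng, seed_for_tracks=7)
paths = simulate.write_fixture("fixture/", genome, data)

sites = io.read_site_calls(paths["calls_cpg"])       # per-site ternary states
vectors = readstats.build_read_vectors(sites)        # reads with >=100 sites
reads = readstats.compute_read_stats(vectors)

fit = heterogeneity.fit_two_gaussian_mixture(reads["rho"].to_numpy(), seed=7)
print(f"rho modes: {fit.mu1:.2f} / {fit.mu2:.2f}")
reads["group"] = heterogeneity.assign_read_groups(reads, fit)

high = set(reads.loc[reads["group"] == "HIGH_HET", "read_id"])
profile = distcorr.mean_distance_correlation(
    [v for v in vectors if v.read_id in high], 2, 600)
spec = distcorr.power_spectrum(profile)
print(f"dominant wavelength: {spec.lambda_peak:.1f} bp")
```

Output:

```
rho modes: 0.09 / 0.77
dominant wavelength: 197.3 bp
```

The two correlation modes are the disordered (PMD-like) and ordered
(euchromatin-like) read populations; the ~197 bp wavelength recovered from
the high-heterogeneity group equals the generator's nucleosome repeat
length (147 bp footprint + 50 bp mean linker).

The same stages are available from the shell:

```bash
methylhet simulate --seed 7 --out fixture/
methylhet read-stats --calls fixture/calls_cpg.tsv --out reads.tsv
methylhet nucmodel --phasing unphased --seed 7
```

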