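# areclip

Downstream analysis of PAR-CLIP binding sites for AU-rich-element (ARE)
binding proteins — the ZFP36/tristetraprolin and ELAVL1/HuR class of
post-transcriptional regulators.

PAR-CLIP experiments yield clusters ("binding sites"): short genomic
intervals with aligned-read counts and diagnostic T-to-C conversions. The
scientific questions downstream are the same across studies of this
protein family, and this package implements them as a tested, reusable
pipeline:

- **Where does the protein bind?** Region annotation (3′UTR / 5′UTR / CDS /
  intron), per-cluster conversion quality
  (specificity = log₁₀(#T-to-C reads / (1 + #other-conversion reads))),
  gene-level summaries, and depth matching between libraries of unequal
  sequencing depth.
- **What does it bind?** Motif enrichment as a signal-to-noise ratio,
  SNR(m) = (occurrences of m per nucleotide of site sequence) /
  (occurrences per nucleotide of background sequence), with the background
  taken as the longest annotated 3′UTR per gene; classification of sites by
  the canonical ZFP36 recognition elements (nonamer UUAUUUAUU, octamer
  UAUUUAUU, half-site UAUU, pentamer AUUUA).
- **How tightly?** A power-curve calibration K_d = a·(1/SNR)^b fitted by
  least squares in log–log space against in-vitro probe affinities, enabling
  in-silico experiments such as disrupting the octamer's tandem half-sites
  with uridylate or non-uridylate spacers.
- **Does binding change expression, directly?** Spearman partial
  correlations ρ_XY·Z computed three interchangeable ways (regression
  residuals on ranks, the recursive order-reduction formula, and the
  correlation-matrix inverse), correlation networks, 2×2 contingency
  enrichment, stratified CDFs with KS statistics, two-sample Hotelling T²,
  and a simple per-gene Welch-t differential test.
- **Where within the 3′UTR?** Permutation-based positional statistics:
  density bands from re-drawing each site uniformly within its own segment,
  distal-end (last 100 nt) enrichment with permutation p values, intra-UTR
  inter-site spacing, and cross-RBP proximity/overlap.

Because the analyses are usually run on deposited tables that are not
bundled here, the package ships a first-class synthetic-data generator
(`areclip.synthetic`) that emulates the statistical structure the analyses
assume — a transcriptome with segment layouts, sites with planted motifs
and negative-binomial read counts, a second RBP's site set with controlled
overlap, and expression changes that are a stated linear function of 3′UTR
site count and length — so every stage is testable end to end.

## Worked example

```python
import pandas as pd
from areclip import (SyntheticConfig, simulate, compute_snr,
                     partial_correlation)
from areclip.motifs import background_utr3_sequences, site_sequences

ds = simulate(SyntheticConfig(seed=1))          # 2000 genes, 3000 sites
utr3 = [s for s in ds.sites if s.region == "utr3"]
bg = background_utr3_sequences(ds.transcriptome)
snr = compute_snr(site_sequences(utr3), bg, "UUAUUUAUU")
print(f"nonamer SNR: {snr.snr:.1f} "
      f"({snr.site_occurrences} hits in {snr.site_nt} site nt)")

fm = pd.DataFrame({
    "n_sites": [g.n_sites_utr3 for g in ds.gene_summaries],
    "utr3_len": [g.utr3_length for g in ds.gene_summaries],
    "log2fc": ds.expression["log2fc"]})
raw = partial_correlation(fm, "n_sites", "log2fc", ())
ctl = partial_correlation(fm, "n_sites", "log2fc", ["utr3_len"])
print(f"Spearman(sites, log2FC)            = {raw.rho_xy:+.3f}")
print(f"partial(sites, log2FC | UTR length) = {ctl.rho_xy_given_z:+.3f}")
```

prints

```
nonamer SNR: 25.9 (194 hits in 52540 site nt)
Spearman(sites, log2FC)            = -0.735
partial(sites, log2FC | UTR length) = -0.655
```

The nonamer occurs ~26× more often per nucleotide inside binding sites
than in the 3′UTR background, and the negative association between site
count and expression change survives controlling for 3′UTR length — the
relation is mostly direct, not a transcript-length artifact.

A CLI mirrors the library: `areclip simulate`, `areclip annotate`,
`areclip snr`, `areclip affinity`, `areclip pcor`, `areclip spatial`
(see `areclip --help`).

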