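"""Synthetic transcriptomes, binding sites, probe tables and expression data.

The generator emulates the statistical structure the downstream analyses
assume: a transcriptome of single-isoform genes with 5'UTR / CDS / intron /
3'UTR segments, PAR-CLIP-like binding-site clusters with planted AU-rich
motifs, negative-binomial read counts and binomial conversion counts, a
second RBP's site set with controlled overlap, and per-gene log2 expression
changes generated as a stated linear function of 3'UTR site count and 3'UTR
length plus Gaussian noise.

All randomness flows through ``numpy.random.default_rng`` seeded from
``SyntheticConfig.seed``; each operation derives an independent child stream
so a fixed seed gives bit-identical output regardless of which subset of
operations is called.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .models import BindingSite, Segment, TranscriptModel, to_rna

_BASES = np.frombuffer(b"ACGU", dtype="S1")

# stream labels for child RNGs, so each operation is independently reproducible
_STREAM = {"transcriptome": 1, "sites": 2, "expression": 3, "probes": 4, "overlap": 5}


class ConfigurationError(ValueError):
    """Raised when a SyntheticConfig (or derived request) is invalid."""


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    Segment lengths are drawn log-normally with the configured mean and
    coefficient of variation (``cv``); ``cv = 0`` gives the mean exactly.
    The CDS length parameter applies per coding exon (``n_introns`` introns
    yield ``n_introns + 1`` coding exons).

    ``beta_sites`` (log2FC units per 3'UTR site) and ``beta_len`` (log2FC
    units per kilobase of 3'UTR) define the linear expression model
    ``log2FC = beta_sites * n_sites_utr3 + beta_len * utr3_len/1000 + eps``
    with ``eps ~ Normal(0, noise_sd^2)``.
    """

    n_genes: int = 2000
    n_sites: int = 3000
    n_introns: int = 2
    # region -> (mean length nt, coefficient of variation)
    segment_length_params: dict = field(default_factory=lambda: {
        "utr5": (200.0, 0.5),
        "cds": (400.0, 0.4),      # per coding exon
        "intron": (1500.0, 0.8),
        "utr3": (800.0, 0.7),
    })
    min_segment_length: int = 30
    # motif -> probability of planting one instance into a site
    motif_mix: dict = field(default_factory=lambda: {
        "UUAUUUAUU": 0.08,
        "UAUUUAUU": 0.06,
        "AUUUA": 0.25,
        "UAUU": 0.45,
    })
    region_probs: dict = field(default_factory=lambda: {
        "utr3": 0.70, "intron": 0.25, "cds": 0.03, "utr5": 0.02,
    })
    positional_bias: Optional[Callable[[np.ndarray], np.ndarray]] = None
    site_length_mean: float = 25.0   # cluster mean length
    site_length_cv: float = 0.25
    site_length_min: int = 12
    site_length_max: int = 60
    # background base composition (A, C, G, U); mildly AU-rich like 3'UTRs
    base_probs: tuple = (0.3, 0.2, 0.2, 0.3)
    # read-count model: negative binomial mean and size (inverse dispersion)
    read_mean: float = 40.0
    read_size: float = 1.2
    p_t2c: float = 0.7            # per-read probability of a T-to-C conversion
    p_other_conv: float = 0.05    # per remaining read, non-T-to-C conversion
    # expression model
    beta_sites: float = -0.5
    beta_len: float = -0.3
    noise_sd: float = 0.5
    n_replicates: int = 5
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    replicate_sd: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if self.n_sites < 0:
            raise ConfigurationError("n_sites must be nonnegative")
        if self.n_introns < 0:
            raise ConfigurationError("n_introns must be nonnegative")
        for region, (mean, cv) in self.segment_length_params.items():
            if mean <= 0 or cv < 0:
                raise ConfigurationError(f"invalid length params for {region}")
        total = sum(self.region_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"region_probs sum to {total}, expected 1")
        for region, p in self.region_probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"region_probs[{region}] outside [0,1]")
        for motif, p in self.motif_mix.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"motif_mix[{motif}] outside [0,1]")
            if len(to_rna(motif)) > self.site_length_min:
                raise ConfigurationError(
                    f"motif {motif} longer than minimum site length "
                    f"{self.site_length_min}")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if self.replicate_sd < 0 or self.baseline_sd < 0:
            raise ConfigurationError("replicate noise must be nonnegative")
        if self.site_length_min <= 0 or self.site_length_max < self.site_length_min:
            raise ConfigurationError("invalid site length bounds")
        if abs(sum(self.base_probs) - 1.0) > 1e-9:
            raise ConfigurationError("base_probs must sum to 1")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAM[stream]])

    def manifest(self) -> dict:
        """JSON-serializable record of the generating parameters."""
        d = dataclasses.asdict(self)
        d["positional_bias"] = (None if self.positional_bias is None
                                else getattr(self.positional_bias, "__name__",
                                             repr(self.positional_bias)))
        return d


def _lognormal_lengths(rng, mean, cv, n, floor):
    """Integer lengths with the requested mean/CV; cv=0 is deterministic."""
    if cv == 0:
        out = np.full(n, round(mean), dtype=int)
    else:
        sigma = np.sqrt(np.log1p(cv * cv))
        mu = np.log(mean) - sigma * sigma / 2.0
        out = np.rint(rng.lognormal(mu, sigma, size=n)).astype(int)
    return np.maximum(out, floor)


def _random_rna(rng, total, base_probs):
    idx = rng.choice(4, size=int(total), p=np.asarray(base_probs, float))
    return _BASES[idx].tobytes().decode()


def generate_transcriptome(config: SyntheticConfig) -> list[TranscriptModel]:
    """Generate one transcript per gene with contiguous non-overlapping
    segments in transcript order 5'UTR, coding exons interleaved with
    introns, 3'UTR.

    Genes alternate strands and are laid out left to right on synthetic
    chromosomes of 100 genes each, separated by 1 kb gaps. Coordinates are
    0-based half-open; segment sequences are RNA, transcript orientation.
    """
    config.validate()
    rng = config.rng("transcriptome")
    n = config.n_genes
    n_cds_exons = config.n_introns + 1

    lengths = {}
    for region in ("utr5", "cds", "intron", "utr3"):
        mean, cv = config.segment_length_params[region]
        count = n * (n_cds_exons if region == "cds"
                     else config.n_introns if region == "intron" else 1)
        lengths[region] = _lognormal_lengths(rng, mean, cv, count,
                                             config.min_segment_length)

    # transcript-order region layout, identical for every gene
    layout = ["utr5"]
    for k in range(n_cds_exons):
        layout.append("cds")
        if k < config.n_introns:
            layout.append("intron")
    layout.append("utr3")

    # assemble per-gene segment lengths in transcript order
    idx = {"utr5": 0, "cds": 0, "intron": 0, "utr3": 0}
    per_gene: list[list[tuple[str, int]]] = []
    for g in range(n):
        segs = []
        for region in layout:
            segs.append((region, int(lengths[region][idx[region]])))
            idx[region] += 1
        per_gene.append(segs)

    total_nt = int(sum(sum(l for _, l in segs) for segs in per_gene))
    big = _random_rna(rng, total_nt, config.base_probs)

    transcripts = []
    cursor_seq = 0
    chrom_pos: dict[str, int] = {}
    genes_per_chrom = 100
    for g, segs in enumerate(per_gene):
        chrom = f"chr{g // genes_per_chrom + 1}"
        strand = "+" if g % 2 == 0 else "-"
        gstart = chrom_pos.get(chrom, 0)
        span = sum(l for _, l in segs)
        chrom_pos[chrom] = gstart + span + 1000

        # genomic order: transcript order on '+', reversed on '-'
        genomic_order = segs if strand == "+" else segs[::-1]
        bounds = np.concatenate([[0], np.cumsum([l for _, l in genomic_order])])
        genomic_iv = {}
        for j, (region, _) in enumerate(genomic_order):
            key = (region, j if strand == "+" else len(segs) - 1 - j)
            genomic_iv[key] = (gstart + int(bounds[j]), gstart + int(bounds[j + 1]))

        built = []
        for t_idx, (region, length) in enumerate(segs):
            seq = big[cursor_seq:cursor_seq + length]
            cursor_seq += length
            s0, s1 = genomic_iv[(region, t_idx)]
            built.append(Segment(region, s0, s1, seq))
        transcripts.append(TranscriptModel(
            gene_id=f"G{g:05d}", chrom=chrom, strand=strand,
            segments=tuple(built)))
    return transcripts


def _segment_candidates(transcriptome, region, min_len):
    out = []
    for ti, tr in enumerate(transcriptome):
        for si, seg in enumerate(tr.segments):
            if seg.region == region and seg.length >= min_len:
                out.append((ti, si))
    return out


def _sample_offset(rng, free, bias):
    """Start offset in [0, free]; optionally weighted by a positional bias
    evaluated at the relative start position."""
    if free == 0:
        return 0
    if bias is None:
        return int(rng.integers(0, free + 1))
    grid = np.arange(free + 1)
    w = np.asarray(bias(grid / free), dtype=float)
    w = np.clip(w, 0, None)
    if w.sum() <= 0:
        return int(rng.integers(0, free + 1))
    return int(rng.choice(free + 1, p=w / w.sum()))


def generate_sites(transcriptome: Sequence[TranscriptModel],
                   config: SyntheticConfig) -> list[BindingSite]:
    """Generate binding-site clusters on a transcriptome.

    Each site falls wholly within one segment: the region comes from
    ``region_probs`` and the segment is drawn with probability proportional
    to its length (uniform per nucleotide), so longer 3'UTRs host more
    sites, as in real CLIP libraries.
    The site's sequence is the segment sequence at that location after motif
    planting (each motif in ``motif_mix`` fires independently with its
    configured probability and overwrites a random stretch of the site).
    Read counts are negative binomial; conversion counts binomial, recorded
    per site together with planting metadata.
    """
    config.validate()
    if not transcriptome:
        raise ConfigurationError("transcriptome is empty")
    rng = config.rng("sites")

    regions = sorted(config.region_probs)
    probs = np.array([config.region_probs[r] for r in regions], float)
    candidates = {r: _segment_candidates(transcriptome, r, config.site_length_min)
                  for r in regions}
    cand_weights = {}
    for r, p in zip(regions, probs):
        if p > 0 and not candidates[r]:
            raise ConfigurationError(
                f"region_probs assigns mass to {r} but no segment can host a site")
        w = np.array([transcriptome[ti].segments[si].length
                      for ti, si in candidates[r]], float)
        cand_weights[r] = w / w.sum() if w.size else w

    # mutable sequence buffers so planted motifs become part of the segment
    buffers = {(ti, si): bytearray(seg.sequence, "ascii")
               for ti, tr in enumerate(transcriptome)
               for si, seg in enumerate(tr.segments)}

    site_lengths = _lognormal_lengths(rng, config.site_length_mean,
                                      config.site_length_cv, config.n_sites,
                                      config.site_length_min)
    site_lengths = np.minimum(site_lengths, config.site_length_max)
    region_draw = rng.choice(len(regions), size=config.n_sites, p=probs)
    motifs = [(to_rna(m), p) for m, p in config.motif_mix.items()]

    sites = []
    nb_p = config.read_size / (config.read_size + config.read_mean)
    for i in range(config.n_sites):
        region = regions[region_draw[i]]
        cand = candidates[region]
        ti, si = cand[int(rng.choice(len(cand), p=cand_weights[region]))]
        tr = transcriptome[ti]
        seg = tr.segments[si]
        length = int(min(site_lengths[i], seg.length))

        bias = config.positional_bias if region == "utr3" else None
        offset = _sample_offset(rng, seg.length - length, bias)

        buf = buffers[(ti, si)]
        planted = []
        for motif, p in motifs:
            if rng.random() < p:
                mo = int(rng.integers(0, length - len(motif) + 1))
                buf[offset + mo:offset + mo + len(motif)] = motif.encode()
                planted.append(motif)
        seq = buf[offset:offset + length].decode()

        # transcript-orientation offset -> genomic interval
        if tr.strand == "+":
            gstart = seg.start + offset
        else:
            gstart = seg.end - offset - length
        gend = gstart + length

        reads = max(1, int(rng.negative_binomial(config.read_size, nb_p)))
        t2c = int(rng.binomial(reads, config.p_t2c))
        other = int(rng.binomial(reads - t2c, config.p_other_conv))

        sites.append(BindingSite(
            chrom=tr.chrom, start=gstart, end=gend, strand=tr.strand,
            read_count=reads, t2c_read_count=t2c, other_conv_read_count=other,
            sequence=seq, gene_id=tr.gene_id, region=region,
            name=f"site{i:05d}",
            meta={"planted": planted, "segment_index": si,
                  "count_model": {"family": "negative_binomial",
                                  "mean": config.read_mean,
                                  "size": config.read_size,
                                  "p_t2c": config.p_t2c,
                                  "p_other_conv": config.p_other_conv}}))

    return sites


def plant_into_transcriptome(transcriptome, sites):
    """Return a transcriptome whose segment sequences carry each site's
    final sequence at its location (so FASTA output matches the site table)."""
    buffers = {(ti, si): bytearray(seg.sequence, "ascii")
               for ti, tr in enumerate(transcriptome)
               for si, seg in enumerate(tr.segments)}
    by_gene = {tr.gene_id: ti for ti, tr in enumerate(transcriptome)}
    for s in sites:
        if s.gene_id not in by_gene or s.sequence is None:
            continue
        ti = by_gene[s.gene_id]
        tr = transcriptome[ti]
        si = s.meta.get("segment_index")
        if si is None:
            continue
        seg = tr.segments[si]
        offset = (s.start - seg.start) if tr.strand == "+" else (seg.end - s.end)
        buffers[(ti, si)][offset:offset + s.length] = s.sequence.encode()
    out = []
    for ti, tr in enumerate(transcriptome):
        segs = tuple(dataclasses.replace(seg, sequence=buffers[(ti, si)].decode())
                     for si, seg in enumerate(tr.segments))
        out.append(dataclasses.replace(tr, segments=segs))
    return out


def generate_expression(gene_summaries, config: SyntheticConfig):
    """Per-gene log2 fold changes from the linear site-count / UTR-length
    model, plus per-replicate log2 intensities for two groups.

    Returns a DataFrame with columns ``gene_id``, ``log2fc``,
    ``ctrl_1..ctrl_R`` and ``treat_1..treat_R``; generating parameters are
    attached in ``.attrs['params']``.
    """
    import pandas as pd

    config.validate()
    rng = config.rng("expression")
    genes = [g.gene_id for g in gene_summaries]
    n_sites = np.array([g.n_sites_utr3 for g in gene_summaries], float)
    utr3_kb = np.array([g.utr3_length for g in gene_summaries], float) / 1000.0

    eps = rng.normal(0.0, config.noise_sd, size=len(genes)) if config.noise_sd > 0 \
        else np.zeros(len(genes))
    log2fc = config.beta_sites * n_sites + config.beta_len * utr3_kb + eps

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, len(genes))
    R = config.n_replicates
    ctrl = baseline[:, None] + rng.normal(0, config.replicate_sd, (len(genes), R))
    treat = (baseline + log2fc)[:, None] + rng.normal(
        0, config.replicate_sd, (len(genes), R))

    df = pd.DataFrame({"gene_id": genes, "log2fc": log2fc})
    for r in range(R):
        df[f"ctrl_{r + 1}"] = ctrl[:, r]
    for r in range(R):
        df[f"treat_{r + 1}"] = treat[:, r]
    df.attrs["params"] = {
        "beta_sites": config.beta_sites, "beta_len": config.beta_len,
        "noise_sd": config.noise_sd, "replicate_sd": config.replicate_sd,
        "baseline_mean": config.baseline_mean, "baseline_sd": config.baseline_sd,
    }
    return df


def generate_affinity_probes(a: float, b: float, noise_sd_log: float,
                             n: int, seed: int = 0):
    """Probe table (sequence, snr, K, kd_nM) on a power-law SNR–Kd relation.

    ``Kd_i = a * (1/SNR_i)^b * 10^eta_i`` with ``eta ~ Normal(0,
    noise_sd_log^2)``; SNR values are log-uniform over 2.5 decades spanning
    depleted (SNR < 1) to strongly enriched sequences, as a probe panel with
    non-binding controls would. ``K`` is reported as ``1/Kd``.
    """
    import pandas as pd

    if a <= 0:
        raise ConfigurationError("scale a must be positive")
    if n < 3:
        raise ConfigurationError("need at least 3 probes to support a fit")
    if noise_sd_log < 0:
        raise ConfigurationError("noise_sd_log must be nonnegative")
    rng = np.random.default_rng([int(seed), _STREAM["probes"]])
    snr = 10.0 ** rng.uniform(-1.0, 1.5, size=n)
    eta = rng.normal(0.0, noise_sd_log, size=n) if noise_sd_log > 0 else np.zeros(n)
    kd = a * (1.0 / snr) ** b * 10.0 ** eta
    seqs = ["".join(rng.choice(list("ACGU"), size=13)) for _ in range(n)]
    return pd.DataFrame({"sequence": seqs, "snr": snr, "K": 1.0 / kd,
                         "kd_nM": kd})


def generate_overlapping_sites(sites, overlap_fraction: float,
                               transcriptome, config: SyntheticConfig,
                               jitter: int = 5):
    """A second RBP's site set with a controlled fraction of sites placed
    overlapping the first set (small jitter), the rest placed uniformly in
    random 3'UTRs. Emulates a co-binding factor such as ELAVL1."""
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ConfigurationError("overlap_fraction outside [0,1]")
    rng = config.rng("overlap")
    by_gene = {tr.gene_id: tr for tr in transcriptome}
    utr3_sites = [s for s in sites if s.region == "utr3" and s.gene_id in by_gene]
    cand = _segment_candidates(transcriptome, "utr3", config.site_length_min)
    out = []
    for i, base in enumerate(utr3_sites):
        length = base.length
        if rng.random() < overlap_fraction:
            shift = int(rng.integers(-jitter, jitter + 1))
            start = max(0, base.start + shift)
            tr = by_gene[base.gene_id]
            seg = tr.segments[base.meta.get("segment_index", 0)]
            start = min(max(start, seg.start), seg.end - length)
            chrom, strand, gene = base.chrom, base.strand, base.gene_id
            si = base.meta.get("segment_index")
        else:
            ti, si = cand[int(rng.integers(len(cand)))]
            tr = transcriptome[ti]
            seg = tr.segments[si]
            L = min(length, seg.length)
            offset = int(rng.integers(0, seg.length - L + 1))
            start = seg.start + offset
            length = L
            chrom, strand, gene = tr.chrom, tr.strand, tr.gene_id
        reads = max(1, int(rng.negative_binomial(
            config.read_size,
            config.read_size / (config.read_size + config.read_mean))))
        t2c = int(rng.binomial(reads, config.p_t2c))
        out.append(BindingSite(
            chrom=chrom, start=start, end=start + length, strand=strand,
            read_count=reads, t2c_read_count=t2c,
            other_conv_read_count=int(rng.binomial(reads - t2c,
                                                   config.p_other_conv)),
            gene_id=gene, region="utr3", name=f"rbp2_{i:05d}",
            meta={"segment_index": si}))
    return out


def generate_confounded_features(n_genes: int, beta_direct: float = 0.4,
                                 noise_sd: float = 0.5, seed: int = 0):
    """Three-variable confound scenario: a direct regulator's site counts
    drive the expression response; a second factor's counts correlate with
    the first (shared sequence preference) but have no direct effect.

    Returns a DataFrame with columns ``n_sites_direct``, ``n_sites_confounded``
    and ``log2fc``. Raw correlation of the confounded counts with log2fc is
    nonzero; the partial correlation given the direct counts is ~0.
    """
    if n_genes < 10:
        raise ConfigurationError("n_genes too small for the scenario")
    import pandas as pd

    rng = np.random.default_rng([int(seed), 6])
    direct = rng.negative_binomial(2.0, 2.0 / (2.0 + 2.5), size=n_genes)
    confounded = rng.poisson(0.3 + 0.8 * direct)
    log2fc = beta_direct * direct + rng.normal(0.0, noise_sd, size=n_genes)
    return pd.DataFrame({"n_sites_direct": direct,
                         "n_sites_confounded": confounded,
                         "log2fc": log2fc})


# ---------------------------------------------------------------------------
# file output

def write_gtf(transcriptome, path) -> None:
    """Write transcript models as GTF (1-based closed, per convention)."""
    feature_of = {"utr5": "five_prime_utr", "cds": "CDS",
                  "intron": "intron", "utr3": "three_prime_utr"}
    with open(path, "w") as fh:
        for tr in transcriptome:
            attrs = f'gene_id "{tr.gene_id}"; transcript_id "{tr.gene_id}.1";'
            fh.write("\t".join([tr.chrom, "areclip", "transcript",
                                str(tr.start + 1), str(tr.end), ".",
                                tr.strand, ".", attrs]) + "\n")
            for seg in tr.segments:
                fh.write("\t".join([tr.chrom, "areclip",
                                    feature_of[seg.region],
                                    str(seg.start + 1), str(seg.end), ".",
                                    tr.strand, ".", attrs]) + "\n")


def write_segment_fasta(transcriptome, path) -> None:
    """Write segment sequences (RNA, transcript orientation) as FASTA."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = []
    for tr in transcriptome:
        for i, seg in enumerate(tr.segments):
            if seg.sequence is None:
                continue
            records.append(SeqRecord(
                Seq(seg.sequence),
                id=f"{tr.gene_id}|{seg.region}|{i}",
                description=f"{tr.chrom}:{seg.start}-{seg.end}({tr.strand})"))
    SeqIO.write(records, path, "fasta")


@dataclass
class SyntheticDataset:
    transcriptome: list
    sites: list
    gene_summaries: list
    expression: "object"
    config: SyntheticConfig


def simulate(config: SyntheticConfig) -> SyntheticDataset:
    """Run the whole generator: transcriptome, sites (with motifs planted
    back into the segment sequences), gene summaries and expression."""
    from .sites import summarize_genes

    transcriptome = generate_transcriptome(config)
    sites = generate_sites(transcriptome, config)
    transcriptome = plant_into_transcriptome(transcriptome, sites)
    # every gene is measured, siteless genes with zero counts
    summaries = summarize_genes(sites, transcriptome, include_siteless=True)
    expression = generate_expression(summaries, config)
    return SyntheticDataset(transcriptome, sites, summaries, expression, config)


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    from pathlib import Path

    from .sites import write_site_table, write_gene_summaries

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_gtf(ds.transcriptome, outdir / "transcripts.gtf")
    write_segment_fasta(ds.transcriptome, outdir / "segments.fa")
    write_site_table(ds.sites, outdir / "sites.csv")
    write_gene_summaries(ds.gene_summaries, ds.expression,
                         outdir / "gene_summaries.tsv")
    ds.expression.to_csv(outdir / "expression.tsv", sep="\t", index=False)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(ds.config.manifest(), fh, indent=2, default=str)
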