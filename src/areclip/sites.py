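"""Binding-site table IO, transcript-region annotation and gene summaries.

Internal coordinates are 0-based half-open. BED input is already 0-based;
the cluster-CSV dialect and GTF are 1-based closed and converted on read.
DNA sequences (T) are normalized to RNA (U) on ingest.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

from .models import (REGION_PRECEDENCE, BindingSite, GeneSummary, Segment,
                     TranscriptModel, group_by_gene)

CSV_COLUMNS = ["chrom", "start", "end", "strand", "gene_id", "region",
               "read_count", "t2c_read_count", "other_conv_read_count",
               "sequence"]


class SiteTableError(ValueError):
    """Malformed site table: unknown dialect/columns or invalid rows."""


# ---------------------------------------------------------------------------
# reading and writing site tables

def read_site_table(path, dialect: str = "csv_clusters") -> list[BindingSite]:
    """Read a binding-site table.

    ``csv_clusters`` is a headered CSV with 1-based closed coordinates
    (columns: chrom,start,end,strand,gene_id,region,read_count,
    t2c_read_count,other_conv_read_count,sequence); ``bed6`` is standard
    0-based BED with the score column taken as the read count.
    Rows violating site invariants abort the read with a row-numbered report.
    """
    if dialect not in ("csv_clusters", "bed6"):
        raise SiteTableError(f"unknown dialect {dialect!r}")
    sites: list[BindingSite] = []
    bad: list[str] = []
    with open(path, newline="") as fh:
        if dialect == "bed6":
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split()
                if len(f) < 6:
                    bad.append(f"line {lineno}: expected >=6 BED fields")
                    continue
                try:
                    sites.append(BindingSite(
                        chrom=f[0], start=int(f[1]), end=int(f[2]),
                        name=f[3], read_count=int(float(f[4])), strand=f[5]))
                except (ValueError, TypeError) as e:
                    bad.append(f"line {lineno}: {e}")
        else:
            reader = csv.DictReader(fh)
            missing = set(CSV_COLUMNS) - set(reader.fieldnames or [])
            if missing:
                raise SiteTableError(
                    f"cluster CSV missing columns: {sorted(missing)}")
            for lineno, row in enumerate(reader, start=2):
                try:
                    start1, end1 = int(row["start"]), int(row["end"])
                    sites.append(BindingSite(
                        chrom=row["chrom"], start=start1 - 1, end=end1,
                        strand=row["strand"],
                        gene_id=row["gene_id"] or None,
                        region=row["region"] or "unannotated",
                        read_count=int(row["read_count"] or 0),
                        t2c_read_count=int(row["t2c_read_count"] or 0),
                        other_conv_read_count=int(
                            row["other_conv_read_count"] or 0),
                        sequence=row["sequence"] or None,
                        name=row.get("name") or None))
                except (ValueError, TypeError) as e:
                    bad.append(f"row {lineno}: {e}")
    if bad:
        raise SiteTableError("invalid rows:\n  " + "\n  ".join(bad))
    return sites


def write_site_table(sites: Iterable[BindingSite], path) -> None:
    """Write the cluster-CSV dialect (1-based closed coordinates)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["name"] + CSV_COLUMNS)
        for s in sites:
            w.writerow([s.name or "", s.chrom, s.start + 1, s.end, s.strand,
                        s.gene_id or "", s.region, s.read_count,
                        s.t2c_read_count, s.other_conv_read_count,
                        s.sequence or ""])


# ---------------------------------------------------------------------------
# GTF input

_REGION_OF_FEATURE = {"three_prime_utr": "utr3", "3utr": "utr3",
                      "five_prime_utr": "utr5", "5utr": "utr5",
                      "cds": "cds", "intron": "intron"}


def read_gtf(path) -> list[TranscriptModel]:
    """Read transcript models from GTF/GFF3 (1-based closed, converted).

    Recognizes five_prime_utr/CDS/intron/three_prime_utr features grouped by
    gene_id; segments are ordered in transcript orientation. One transcript
    per gene (the package's per-gene reduction keeps a single isoform).
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique",
                            disable_infer_transcripts=True,
                            disable_infer_genes=True)
    genes: dict[str, dict] = {}
    for feat in db.all_features():
        region = _REGION_OF_FEATURE.get(feat.featuretype.lower())
        if region is None:
            continue
        gid = feat.attributes.get("gene_id", [feat.id])[0]
        rec = genes.setdefault(gid, {"chrom": feat.seqid, "strand": feat.strand,
                                     "segments": []})
        rec["segments"].append(Segment(region, feat.start - 1, feat.end))
    out = []
    for gid, rec in genes.items():
        segs = sorted(rec["segments"], key=lambda s: s.start,
                      reverse=(rec["strand"] == "-"))
        out.append(TranscriptModel(gene_id=gid, chrom=rec["chrom"],
                                   strand=rec["strand"], segments=tuple(segs)))
    out.sort(key=lambda t: t.gene_id)
    return out


def attach_segment_sequences(transcriptome: Sequence[TranscriptModel],
                             fasta_path) -> list[TranscriptModel]:
    """Attach sequences from a segment FASTA (ids ``gene|region|index``,
    RNA alphabet, transcript orientation) to transcript models."""
    import dataclasses

    from Bio import SeqIO

    from .models import to_rna

    seqs = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        gene_id, region, idx = rec.id.split("|")
        seqs[(gene_id, int(idx))] = to_rna(str(rec.seq))
    out = []
    for tr in transcriptome:
        segs = tuple(
            dataclasses.replace(seg, sequence=seqs.get((tr.gene_id, i),
                                                       seg.sequence))
            for i, seg in enumerate(tr.segments))
        out.append(dataclasses.replace(tr, segments=segs))
    return out


# ---------------------------------------------------------------------------
# annotation

def _build_index(transcriptome):
    trees: dict[tuple[str, str], IntervalTree] = {}
    for tr in transcriptome:
        tree = trees.setdefault((tr.chrom, tr.strand), IntervalTree())
        for seg in tr.segments:
            tree[seg.start:seg.end] = (tr.gene_id, seg.region)
    return trees


def annotate_sites(sites: Iterable[BindingSite],
                   transcriptome: Sequence[TranscriptModel]) -> list[BindingSite]:
    """Assign each site at most one gene and exactly one region label.

    Strand-aware interval overlap; the host gene is the one with the largest
    total overlap (exact tie -> unannotated, to avoid double counting); the
    region is the label with majority overlap within that gene, ties broken
    by precedence utr3 > utr5 > cds > intron. Deterministic and independent
    of input order.
    """
    trees = _build_index(transcriptome)
    out = []
    for s in sites:
        tree = trees.get((s.chrom, s.strand))
        if tree is None:
            out.append(s.with_annotation(None, "unannotated"))
            continue
        per_gene: dict[str, dict[str, int]] = {}
        for iv in tree.overlap(s.start, s.end):
            gene_id, region = iv.data
            ov = min(s.end, iv.end) - max(s.start, iv.begin)
            if ov > 0:
                per_gene.setdefault(gene_id, {}).setdefault(region, 0)
                per_gene[gene_id][region] += ov
        if not per_gene:
            out.append(s.with_annotation(None, "unannotated"))
            continue
        totals = {g: sum(r.values()) for g, r in per_gene.items()}
        best = max(totals.values())
        winners = sorted(g for g, t in totals.items() if t == best)
        if len(winners) > 1:
            out.append(s.with_annotation(None, "unannotated"))
            continue
        gene = winners[0]
        regions = per_gene[gene]
        best_ov = max(regions.values())
        tied = [r for r, ov in regions.items() if ov == best_ov]
        region = min(tied, key=REGION_PRECEDENCE.index)
        out.append(s.with_annotation(gene, region))
    return out


# ---------------------------------------------------------------------------
# conversion metrics

@dataclass(frozen=True)
class ConversionMetrics:
    """Per-cluster cross-link quality: the fraction of reads carrying a
    T-to-C conversion, and the conversion specificity
    log10(t2c / (1 + other_conversions)). When no read carries a T-to-C
    conversion the specificity is NaN (a "no-signal" sentinel), never -inf.
    """

    conversion_fraction: float
    conversion_specificity: float

    @property
    def has_signal(self) -> bool:
        return not math.isnan(self.conversion_specificity)


def conversion_metrics(site: BindingSite) -> ConversionMetrics:
    if site.read_count <= 0:
        raise ValueError("conversion metrics require read_count > 0")
    frac = site.t2c_read_count / site.read_count
    if site.t2c_read_count == 0:
        spec = math.nan
    else:
        spec = math.log10(site.t2c_read_count
                          / (1 + site.other_conv_read_count))
    return ConversionMetrics(frac, spec)


# ---------------------------------------------------------------------------
# gene summaries and depth matching

def summarize_genes(sites: Iterable[BindingSite],
                    transcriptome: Sequence[TranscriptModel],
                    expression=None,
                    include_siteless: bool = False) -> list[GeneSummary]:
    """One summary per gene with at least one annotated site (or per every
    annotated gene when ``include_siteless`` is set, with zero counts).

    ``utr3_length`` comes from the gene's (longest) annotated 3'UTR. An
    optional expression table (columns ``gene_id``, ``log2fc``, optionally
    ``significant``) attaches log2 fold change and a significance flag;
    duplicate gene ids in it are an error.
    """
    utr3_len = {tr.gene_id: tr.utr3_length for tr in transcriptome}
    expr: dict[str, tuple] = {}
    if expression is not None:
        if expression["gene_id"].duplicated().any():
            dups = expression.loc[expression["gene_id"].duplicated(),
                                  "gene_id"].tolist()
            raise ValueError(f"duplicate gene ids in expression table: {dups[:5]}")
        has_sig = "significant" in expression.columns
        for row in expression.itertuples(index=False):
            expr[row.gene_id] = (float(row.log2fc),
                                 bool(row.significant) if has_sig else None)

    grouped = group_by_gene(sites)
    if include_siteless:
        for tr in transcriptome:
            grouped.setdefault(tr.gene_id, [])
    out = []
    for gene_id, gsites in sorted(grouped.items()):
        counts = {"utr3": 0, "utr5": 0, "cds": 0, "intron": 0}
        for s in gsites:
            if s.region in counts:
                counts[s.region] += 1
        log2fc, sig = expr.get(gene_id, (None, None))
        out.append(GeneSummary(
            gene_id=gene_id,
            n_sites_utr3=counts["utr3"], n_sites_utr5=counts["utr5"],
            n_sites_cds=counts["cds"], n_sites_intron=counts["intron"],
            utr3_length=utr3_len.get(gene_id, 0),
            log2fc=log2fc, significant=sig))
    return out


def write_gene_summaries(summaries: Sequence[GeneSummary], expression=None,
                         path=None) -> None:
    import pandas as pd

    rows = []
    for g in summaries:
        rows.append({
            "gene_id": g.gene_id, "n_sites_utr3": g.n_sites_utr3,
            "n_sites_utr5": g.n_sites_utr5, "n_sites_cds": g.n_sites_cds,
            "n_sites_intron": g.n_sites_intron, "utr3_length": g.utr3_length,
            "region_category": g.region_category,
            "log2fc": g.log2fc, "significant": g.significant})
    df = pd.DataFrame(rows)
    if expression is not None and df["log2fc"].isna().all():
        df = df.drop(columns=["log2fc", "significant"]).merge(
            expression[["gene_id", "log2fc"]], on="gene_id", how="left")
    df.to_csv(path, sep="\t", index=False)


def depth_match(sites: Sequence[BindingSite], target_n: int) -> list[BindingSite]:
    """The ``target_n`` sites with the highest read counts (library-size
    matching, as for a deeper second library). Ties are broken by
    (chrom, start) so the subset is deterministic."""
    sites = list(sites)
    if target_n > len(sites):
        raise ValueError(f"target_n {target_n} exceeds {len(sites)} sites")
    ordered = sorted(sites, key=lambda s: (-s.read_count, s.chrom, s.start))
    return ordered[:target_n]
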