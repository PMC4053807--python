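"""Positional analysis of binding sites along transcript segments.

Permutation backgrounds follow one scheme throughout: every site keeps its
host segment and the segment keeps its length; only the site's position is
redrawn uniformly along the segment, repeated ``n_perm`` times. Site
position is represented by the interval midpoint (center nucleotide),
measured in transcript orientation (strand-aware).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .models import BindingSite, TranscriptModel

POSITION_MODES = ("normalized", "from_3prime_end")


def _host_segment(tr: TranscriptModel, site: BindingSite):
    if site.chrom != tr.chrom or site.strand != tr.strand:
        return None, None
    for si, seg in enumerate(tr.segments):
        if seg.region == site.region and seg.start <= site.start \
                and site.end <= seg.end:
            return si, seg
    return None, None


def _midpoint_index(site: BindingSite) -> int:
    # center nucleotide (left-center for even lengths), genomic index
    return (site.start + site.end - 1) // 2


def site_positions(sites: Sequence[BindingSite],
                   transcriptome: Sequence[TranscriptModel],
                   mode: str = "normalized") -> pd.DataFrame:
    """Project each annotated site's midpoint onto its host segment.

    ``normalized`` divides the transcript-orientation position by the
    segment length (0 = segment 5' end, ->1 = 3' end);
    ``from_3prime_end`` reports nucleotides from the segment 3' end (0 =
    final nucleotide). Sites not contained in a matching segment are
    skipped; the count is in ``.attrs['n_skipped']``.
    """
    if mode not in POSITION_MODES:
        raise ValueError(f"unknown mode {mode!r}")
    by_gene = {tr.gene_id: tr for tr in transcriptome}
    rows, skipped = [], 0
    for s in sites:
        tr = by_gene.get(s.gene_id)
        if tr is None:
            skipped += 1
            continue
        si, seg = _host_segment(tr, s)
        if seg is None:
            skipped += 1
            continue
        mid = _midpoint_index(s)
        pos = (mid - seg.start) if tr.strand == "+" else (seg.end - 1 - mid)
        value = pos / seg.length if mode == "normalized" \
            else seg.length - 1 - pos
        rows.append({"name": s.name, "gene_id": s.gene_id,
                     "region": s.region, "segment_length": seg.length,
                     "position": float(value)})
    df = pd.DataFrame(rows,
                      columns=["name", "gene_id", "region",
                               "segment_length", "position"])
    df.attrs["n_skipped"] = skipped
    df.attrs["mode"] = mode
    return df


@dataclass
class PositionalDensity:
    """Observed positional density with permutation quantile bands."""

    mode: str
    grid: np.ndarray
    observed: np.ndarray
    q10: np.ndarray
    q25: np.ndarray
    median: np.ndarray
    q75: np.ndarray
    q90: np.ndarray
    n_perm: int
    seed: int

    def band_coverage(self) -> float:
        """Fraction of grid points where the observed density falls inside
        the interdecile band."""
        inside = (self.observed >= self.q10) & (self.observed <= self.q90)
        return float(inside.mean())


def _kde(values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    if np.std(values) == 0:
        # degenerate: all positions equal; represent as a narrow bump
        values = values + np.linspace(-1e-9, 1e-9, len(values))
    return stats.gaussian_kde(values, bw_method="silverman")(grid)


def density_with_bands(positions: Sequence[float],
                       segment_lengths: Sequence[float],
                       mode: str = "normalized",
                       n_perm: int = 100, seed: int = 0,
                       grid_size: int = 512) -> PositionalDensity:
    """Kernel density of observed positions with permutation bands.

    Each permutation redraws every site uniformly within its own segment;
    pointwise 10/25/50/75/90 percent quantiles of the permuted densities
    form the bands (quantile-nested by construction).
    """
    positions = np.asarray(positions, float)
    lengths = np.asarray(segment_lengths, float)
    if len(positions) < 20:
        raise ValueError("need at least 20 positions for a stable density")
    if len(positions) != len(lengths):
        raise ValueError("positions and segment_lengths must align")
    if n_perm < 2:
        raise ValueError("need at least 2 permutations")
    if n_perm < 20:
        warnings.warn("fewer than 20 permutations: bands are unstable",
                      stacklevel=2)
    if mode not in POSITION_MODES:
        raise ValueError(f"unknown mode {mode!r}")

    rng = np.random.default_rng(seed)
    if mode == "normalized":
        grid = np.linspace(0.0, 1.0, grid_size)
    else:
        grid = np.linspace(0.0, float(lengths.max()), grid_size)
    observed = _kde(positions, grid)

    perm = np.empty((n_perm, grid_size))
    for k in range(n_perm):
        if mode == "normalized":
            draw = rng.uniform(0.0, 1.0, size=len(positions))
        else:
            draw = rng.uniform(0.0, lengths, size=len(positions))
        perm[k] = _kde(draw, grid)
    q10, q25, q50, q75, q90 = np.quantile(perm, [.1, .25, .5, .75, .9], axis=0)
    return PositionalDensity(mode=mode, grid=grid, observed=observed,
                             q10=q10, q25=q25, median=q50, q75=q75, q90=q90,
                             n_perm=n_perm, seed=seed)


@dataclass(frozen=True)
class TerminalEnrichment:
    ratio: float
    p_value: float
    observed: int
    expected: float
    n_sites: int
    window_nt: int
    n_perm: int
    background: str


def terminal_enrichment(sites: Sequence[BindingSite],
                        transcriptome: Sequence[TranscriptModel],
                        window_nt: int = 100, n_perm: int = 1000,
                        seed: int = 0,
                        background: str = "permutation") -> TerminalEnrichment:
    """Over-representation of 3'UTR sites in the last ``window_nt``
    nucleotides of the 3'UTR.

    ratio = observed count / mean background count;
    p = (1 + #{background >= observed}) / (1 + n_perm) for the permutation
    background, or a normal approximation of the sum of per-site Bernoulli
    indicators for the ``analytic`` uniform background.
    """
    if background not in ("permutation", "analytic"):
        raise ValueError(f"unknown background {background!r}")
    by_gene = {tr.gene_id: tr for tr in transcriptome}
    dist, seg_len, site_len = [], [], []
    for s in sites:
        if s.region != "utr3":
            continue
        tr = by_gene.get(s.gene_id)
        if tr is None:
            continue
        _, seg = _host_segment(tr, s)
        if seg is None:
            continue
        mid = _midpoint_index(s)
        pos = (mid - seg.start) if tr.strand == "+" else (seg.end - 1 - mid)
        dist.append(seg.length - 1 - pos)
        seg_len.append(seg.length)
        site_len.append(min(s.length, seg.length))
    if not dist:
        raise ValueError("no annotated 3'UTR sites")
    dist = np.asarray(dist, float)
    L = np.asarray(seg_len, float)
    sl = np.asarray(site_len, float)
    if np.all(L < window_nt):
        raise ValueError(f"all 3'UTRs shorter than the {window_nt} nt window")
    observed = int(np.sum(dist < window_nt))

    # a redrawn site starts at u ~ Uniform{0..L-l}; its midpoint sits at
    # u + (l-1)//2 and the 3'-end distance is L - 1 - midpoint
    half = (sl - 1) // 2
    n_starts = L - sl + 1
    n_hit = np.clip(n_starts - np.maximum(0.0, L - window_nt - half), 0,
                    n_starts)
    p_site = n_hit / n_starts

    if background == "analytic":
        expected = float(p_site.sum())
        var = float((p_site * (1 - p_site)).sum())
        if var == 0:
            p = 1.0 if observed <= expected else 0.0
        else:
            z = (observed - 0.5 - expected) / np.sqrt(var)
            p = float(stats.norm.sf(z))
        ratio = observed / expected if expected > 0 else float("nan")
        return TerminalEnrichment(ratio, p, observed, expected, len(dist),
                                  window_nt, 0, background)

    rng = np.random.default_rng(seed)
    u = rng.integers(0, n_starts.astype(int),
                     size=(n_perm, len(dist)))
    perm_dist = L - 1 - (u + half)
    perm_counts = (perm_dist < window_nt).sum(axis=1)
    expected = float(perm_counts.mean())
    ratio = observed / expected if expected > 0 else float("nan")
    p = float((1 + np.sum(perm_counts >= observed)) / (1 + n_perm))
    return TerminalEnrichment(ratio, p, observed, expected, len(dist),
                              window_nt, n_perm, background)


@dataclass
class IntersiteDistances:
    distances: dict        # gene_id -> list of pairwise midpoint distances
    n_transcripts_multi: int      # 3'UTRs with >=2 sites
    n_transcripts_within: int     # 3'UTRs with >=1 pair within max_gap
    max_gap: int

    @property
    def all_distances(self) -> np.ndarray:
        if not self.distances:
            return np.array([])
        return np.concatenate([np.asarray(v, float)
                               for v in self.distances.values()])


def intersite_distances(sites: Sequence[BindingSite],
                        max_gap: int = 70) -> IntersiteDistances:
    """Pairwise midpoint-to-midpoint distances between 3'UTR sites of the
    same gene; a transcript is counted once toward ``n_transcripts_within``
    no matter how many of its pairs fall within ``max_gap``."""
    by_gene: dict[str, list[int]] = {}
    for s in sites:
        if s.region == "utr3" and s.gene_id is not None:
            by_gene.setdefault(s.gene_id, []).append(_midpoint_index(s))
    distances: dict[str, list[float]] = {}
    n_multi = n_within = 0
    for gene, mids in by_gene.items():
        if len(mids) < 2:
            continue
        n_multi += 1
        mids = sorted(mids)
        d = [float(abs(mids[j] - mids[i]))
             for i in range(len(mids)) for j in range(i + 1, len(mids))]
        distances[gene] = d
        if any(x <= max_gap for x in d):
            n_within += 1
    return IntersiteDistances(distances=distances,
                              n_transcripts_multi=n_multi,
                              n_transcripts_within=n_within,
                              max_gap=max_gap)


@dataclass
class ProximityProfile:
    query_set: str
    target_set: str
    nearest_distances: np.ndarray     # per query site with a target in window
    window: int
    n_in_window: int
    n_shared_utr3: int
    background_distances: np.ndarray  # pooled over permutations
    n_perm: int
    seed: int


def _gap(a_start, a_end, b_start, b_end) -> int:
    # edge-to-edge gap; 0 if the intervals overlap
    return max(0, max(a_start, b_start) - min(a_end, b_end))


def proximity_profile(query_sites: Sequence[BindingSite],
                      target_sites: Sequence[BindingSite],
                      transcriptome: Sequence[TranscriptModel],
                      window: int = 200, n_perm: int = 100, seed: int = 0,
                      query_name: str = "query",
                      target_name: str = "target") -> ProximityProfile:
    """Nearest-target distances for query sites sharing a 3'UTR with the
    target set, with a permutation background.

    Distance is the minimum edge-to-edge gap to any same-3'UTR target
    (0 for overlapping intervals); only distances within ``window`` are
    kept. The background redraws each query site's position uniformly
    within its own 3'UTR, ``n_perm`` times.
    """
    by_gene_t: dict[str, list[BindingSite]] = {}
    for t in target_sites:
        if t.region == "utr3" and t.gene_id is not None:
            by_gene_t.setdefault(t.gene_id, []).append(t)
    queries = [q for q in query_sites
               if q.region == "utr3" and q.gene_id in by_gene_t]
    shared = {q.gene_id for q in queries}
    if not shared:
        warnings.warn("query and target sets share no 3'UTRs", stacklevel=2)
        return ProximityProfile(query_name, target_name, np.array([]),
                                window, 0, 0, np.array([]), n_perm, seed)

    tr_by_gene = {tr.gene_id: tr for tr in transcriptome}
    rng = np.random.default_rng(seed)

    nearest, bg = [], []
    for q in queries:
        targets = by_gene_t[q.gene_id]
        d = min(_gap(q.start, q.end, t.start, t.end) for t in targets)
        if d <= window:
            nearest.append(float(d))
        tr = tr_by_gene.get(q.gene_id)
        seg = None
        if tr is not None:
            _, seg = _host_segment(tr, q)
        if seg is None:
            continue
        L = q.length
        free = max(0, seg.length - L)
        starts = seg.start + rng.integers(0, free + 1, size=n_perm)
        for s0 in starts:
            db = min(_gap(int(s0), int(s0) + L, t.start, t.end)
                     for t in targets)
            if db <= window:
                bg.append(float(db))
    return ProximityProfile(
        query_set=query_name, target_set=target_name,
        nearest_distances=np.asarray(nearest), window=window,
        n_in_window=len(nearest), n_shared_utr3=len(shared),
        background_distances=np.asarray(bg), n_perm=n_perm, seed=seed)


def overlap_fraction(query_sites: Sequence[BindingSite],
                     target_sites: Sequence[BindingSite]) -> float:
    """Fraction of query sites sharing >=1 nt with any target site
    (same chromosome and strand)."""
    query_sites = list(query_sites)
    if not query_sites:
        return 0.0
    trees: dict[tuple, IntervalTree] = {}
    for t in target_sites:
        trees.setdefault((t.chrom, t.strand), IntervalTree())[t.start:t.end] = True
    hit = 0
    for q in query_sites:
        tree = trees.get((q.chrom, q.strand))
        if tree is not None and tree.overlap(q.start, q.end):
            hit += 1
    return hit / len(query_sites)
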