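"""Motif occurrence statistics: per-nucleotide rates, signal-to-noise
enrichment and the ZFP36 RNA-regulatory-element (RRE) taxonomy.

The SNR of a motif is the number of instances per nucleotide in a set of
binding-site sequences divided by the number of instances per nucleotide in
a background set — here, by default, the longest annotated 3'UTR sequence
per gene. Occurrences are counted at every start position (overlapping
matches), since tandem AU-rich elements overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .models import BindingSite, TranscriptModel, to_rna

NONAMER = "UUAUUUAUU"
OCTAMER = "UAUUUAUU"
HALFSITE = "UAUU"
PENTAMER = "AUUUA"

#: canonical ZFP36 recognition elements, largest first
RRE_MOTIFS = {"nonamer": NONAMER, "octamer": OCTAMER,
              "pentamer": PENTAMER, "halfsite": HALFSITE}


@dataclass(frozen=True)
class MotifSpec:
    motif: str
    count_mode: str = "overlapping"

    def __post_init__(self):
        object.__setattr__(self, "motif", to_rna(self.motif))
        if len(self.motif) < 2:
            raise ValueError("motif must be at least 2 nt")
        if set(self.motif) - set("ACGU"):
            raise ValueError("motif must be over the RNA alphabet A/C/G/U")
        if self.count_mode not in ("overlapping", "non_overlapping"):
            raise ValueError(f"unknown count_mode {self.count_mode!r}")


@dataclass(frozen=True)
class SnrResult:
    """Motif rate in sites vs background and their ratio (SNR)."""

    motif: str
    site_occurrences: int
    site_nt: int
    bg_occurrences: int
    bg_nt: int

    @property
    def site_rate(self) -> float:
        return self.site_occurrences / self.site_nt

    @property
    def bg_rate(self) -> float:
        return self.bg_occurrences / self.bg_nt

    @property
    def defined(self) -> bool:
        return self.bg_occurrences > 0

    @property
    def snr(self) -> float:
        """Undefined SNRs (no background occurrence) are NaN — no
        pseudocount is applied."""
        if not self.defined:
            return float("nan")
        return self.site_rate / self.bg_rate


def _as_spec(motif) -> MotifSpec:
    return motif if isinstance(motif, MotifSpec) else MotifSpec(str(motif))


def _count_in(seq: str, motif: str, mode: str) -> int:
    if mode == "non_overlapping":
        return seq.count(motif)
    n, start = 0, seq.find(motif)
    while start != -1:
        n += 1
        start = seq.find(motif, start + 1)
    return n


def count_motif(sequences: Iterable[str], motif) -> tuple[int, int]:
    """Count motif occurrences over a sequence set.

    Returns ``(occurrences, total_nt)`` where overlapping mode counts every
    start position of a match and ``total_nt`` is the summed sequence length.
    """
    spec = _as_spec(motif)
    occ = total = 0
    n_seqs = 0
    for seq in sequences:
        seq = to_rna(seq)
        occ += _count_in(seq, spec.motif, spec.count_mode)
        total += len(seq)
        n_seqs += 1
    if n_seqs == 0 or total == 0:
        raise ValueError("empty sequence set (zero total length)")
    return occ, total


def compute_snr(site_seqs: Sequence[str], background_seqs: Sequence[str],
                motif) -> SnrResult:
    spec = _as_spec(motif)
    s_occ, s_nt = count_motif(site_seqs, spec)
    b_occ, b_nt = count_motif(background_seqs, spec)
    return SnrResult(spec.motif, s_occ, s_nt, b_occ, b_nt)


def background_utr3_sequences(transcriptome: Sequence[TranscriptModel]) -> list[str]:
    """The background set: the longest annotated 3'UTR sequence per gene."""
    out = []
    for tr in transcriptome:
        seq = tr.utr3_sequence()
        if seq:
            out.append(seq)
    return out


# ---------------------------------------------------------------------------
# RRE taxonomy

@dataclass(frozen=True)
class RreFlags:
    """Non-exclusive containment flags for the canonical ZFP36 elements.

    Nesting holds by construction: the nonamer contains the octamer, the
    octamer contains the half-site and the pentamer contains no half-site
    but the nonamer contains a pentamer.
    """

    has_nonamer: bool
    has_octamer: bool
    has_halfsite: bool
    has_pentamer: bool

    @property
    def has_any(self) -> bool:
        return (self.has_nonamer or self.has_octamer
                or self.has_halfsite or self.has_pentamer)


def classify_rre(site_sequence: str) -> RreFlags:
    seq = to_rna(site_sequence)
    return RreFlags(
        has_nonamer=NONAMER in seq,
        has_octamer=OCTAMER in seq,
        has_halfsite=HALFSITE in seq,
        has_pentamer=PENTAMER in seq)


def rre_composition(sites: Sequence[BindingSite],
                    region: Optional[str] = None):
    """Fractions of sites containing each RRE (and any), with counts.

    Returns a DataFrame indexed by flag name with columns ``count``,
    ``fraction`` and ``n_sites``; ``region`` restricts to one region label.
    An empty subset yields NaN fractions (flagged by n_sites = 0).
    """
    import pandas as pd

    subset = [s for s in sites if region is None or s.region == region]
    missing = [s.name or f"{s.chrom}:{s.start}-{s.end}"
               for s in subset if s.sequence is None]
    if missing:
        raise ValueError(f"sites lacking sequences: {missing[:5]}")
    n = len(subset)
    counts = {"nonamer": 0, "octamer": 0, "halfsite": 0, "pentamer": 0,
              "any": 0}
    for s in subset:
        flags = classify_rre(s.sequence)
        counts["nonamer"] += flags.has_nonamer
        counts["octamer"] += flags.has_octamer
        counts["halfsite"] += flags.has_halfsite
        counts["pentamer"] += flags.has_pentamer
        counts["any"] += flags.has_any
    return pd.DataFrame({
        "count": pd.Series(counts),
        "fraction": pd.Series({k: (v / n if n else float("nan"))
                               for k, v in counts.items()}),
        "n_sites": n})


def compare_snr_profiles(site_sets: Mapping[str, Sequence[str]],
                         background_seqs: Sequence[str],
                         motifs: Sequence) -> "object":
    """SNR matrix over named site sets x motifs, sharing one background.

    ``site_sets`` maps set name to site sequences (e.g. a full library and a
    depth-matched subset of a deeper one). Returns a DataFrame of SNR values
    (rows: set names, columns: motifs).
    """
    import pandas as pd

    if len(site_sets) < 2:
        raise ValueError("need at least two site sets to compare")
    if not background_seqs:
        raise ValueError("background sequence set is missing")
    specs = [_as_spec(m) for m in motifs]
    data = {}
    for name, seqs in site_sets.items():
        data[name] = [compute_snr(seqs, background_seqs, sp).snr
                      for sp in specs]
    return pd.DataFrame.from_dict(
        data, orient="index", columns=[sp.motif for sp in specs])


def site_sequences(sites: Iterable[BindingSite],
                   region: Optional[str] = None) -> list[str]:
    """Convenience: extract (optionally region-restricted) site sequences."""
    return [s.sequence for s in sites
            if s.sequence is not None and (region is None or s.region == region)]
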