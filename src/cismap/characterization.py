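"""Promoter characterisation of map targets and region-set overlap.

Map-target TSSs are contrasted with the background of all TSSs
considered for mapping on two promoter features: GC content of the
500 bp upstream of the TSS, and the positional frequency of the literal
TATA tetramer in the 40 bp upstream (a proxy for TATA-box dependence).
Maps can also be intersected with externally defined region sets such
as genomic regulatory blocks (GRBs) or super enhancers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .intervals_io import CRM, TSS, GenomicInterval, ValidationError
from .map_builder import CisMap

__all__ = [
    "PromoterProfile",
    "promoter_sequence",
    "gc_content_distribution",
    "tata_positional_scan",
    "region_overlap_stats",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PromoterProfile:
    """GC histogram and TATA positional fractions for one TSS set."""

    set_label: str
    gc_bin_edges: np.ndarray | None = None
    gc_distribution: np.ndarray | None = None
    gc_values: np.ndarray | None = None
    tata_offsets: np.ndarray | None = None
    tata_positional: np.ndarray | None = None


class GenomeSource:
    """Uniform access to chromosome sequences.

    Accepts a plain ``{chrom: sequence}`` mapping or any object with
    pyfaidx-style ``obj[chrom][start:end]`` indexing (e.g.
    ``pyfaidx.Fasta`` with ``as_raw=True`` or not).
    """

    def __init__(self, genome):
        self._genome = genome

    def fetch(self, chrom: str, start: int, end: int) -> str:
        try:
            record = self._genome[chrom]
        except KeyError as exc:
            raise ValidationError(f"unknown chromosome {chrom!r}") from exc
        start = max(start, 0)
        piece = record[start:end]
        return str(piece).upper()

    def __contains__(self, chrom: str) -> bool:
        try:
            self._genome[chrom]
            return True
        except KeyError:
            return False


def promoter_sequence(
    tss: TSS, genome, upstream_bp: int
) -> str:
    """The upstream_bp bases 5' of a TSS in transcription orientation.

    For '+'-strand TSSs this is ``[pos-upstream, pos)``; for '-'-strand
    TSSs the reverse complement of ``[pos+1, pos+1+upstream)``.  Windows
    running off the chromosome start are truncated with a warning.
    """
    src = genome if isinstance(genome, GenomeSource) else GenomeSource(genome)
    if tss.strand == "+":
        start = tss.position - upstream_bp
        if start < 0:
            warnings.warn(
                f"TSS {tss.tss_id}: upstream window truncated at chromosome start",
                stacklevel=2,
            )
        return src.fetch(tss.chrom, max(start, 0), tss.position)
    seq = src.fetch(tss.chrom, tss.position + 1, tss.position + 1 + upstream_bp)
    return _reverse_complement(seq)


def gc_content_distribution(
    tss_set: Iterable[TSS],
    genome,
    upstream_bp: int = 500,
    n_bins: int = 20,
    set_label: str = "background",
) -> PromoterProfile:
    """Histogram over promoters of GC fraction in the upstream window.

    Ambiguous bases are excluded from both numerator and denominator;
    promoters that are entirely ambiguous are dropped with a warning.
    The histogram is normalised to sum to 1.
    """
    tss_set = sorted(set(tss_set))
    if not tss_set:
        raise ValidationError("empty TSS set")
    src = GenomeSource(genome) if not isinstance(genome, GenomeSource) else genome
    fractions = []
    for t in tss_set:
        seq = promoter_sequence(t, src, upstream_bp)
        gc = seq.count("G") + seq.count("C")
        at = seq.count("A") + seq.count("T")
        if gc + at == 0:
            warnings.warn(
                f"TSS {t.tss_id}: promoter entirely ambiguous; excluded",
                stacklevel=2,
            )
            continue
        fractions.append(gc / (gc + at))
    values = np.array(fractions)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    dist = counts / counts.sum() if counts.sum() else counts.astype(float)
    return PromoterProfile(
        set_label=set_label,
        gc_bin_edges=edges,
        gc_distribution=dist,
        gc_values=values,
    )


def tata_positional_scan(
    tss_set: Iterable[TSS],
    genome,
    upstream_bp: int = 40,
    motif: str = "TATA",
    set_label: str = "background",
) -> PromoterProfile:
    """Fraction of promoters with the motif ending at each upstream offset.

    Offset d means the motif's 3'-most base sits d bases 5' of the TSS
    (transcription orientation); d runs from 1 to
    upstream_bp - len(motif) + 1 so the whole motif fits in the window.
    A promoter shorter than the motif contributes zero everywhere.
    """
    motif = motif.upper()
    if len(motif) > upstream_bp:
        raise ValidationError("motif longer than scanned window")
    tss_set = sorted(set(tss_set))
    if not tss_set:
        raise ValidationError("empty TSS set")
    src = GenomeSource(genome) if not isinstance(genome, GenomeSource) else genome
    m = len(motif)
    offsets = np.arange(1, upstream_bp - m + 2)
    hits = np.zeros(len(offsets))
    for t in tss_set:
        seq = promoter_sequence(t, src, upstream_bp).upper()
        # seq[-1] is 1 base upstream of the TSS; a motif whose 3'-most base
        # is d upstream occupies seq[L-d-m+1 : L-d+1]
        L = len(seq)
        for i, d in enumerate(offsets):
            s = L - d - m + 1
            if s < 0:
                continue
            if seq[s : s + m] == motif:
                hits[i] += 1
    return PromoterProfile(
        set_label=set_label,
        tata_offsets=offsets,
        tata_positional=hits / len(tss_set),
    )


def region_overlap_stats(
    cis_map: CisMap,
    tss_set: Iterable[TSS],
    crms: Iterable[CRM],
    regions: Iterable[GenomicInterval],
) -> dict:
    """Containment of map links in a region set, and vice versa.

    A link is "in" a region when the full CRM interval and the TSS
    position both fall inside that single region.  Reports the fraction
    of links so contained and the fraction of regions containing at
    least one link, plus the raw counts.
    """
    regions = sorted(set(regions))
    tss_by_id = {t.tss_id: t for t in tss_set}
    crm_by_id = {c.crm_id: c for c in crms}
    n_links = len(cis_map.links)
    links_in_region = 0
    regions_hit: set[GenomicInterval] = set()
    for l in cis_map.links:
        t = tss_by_id.get(l.tss_id)
        c = crm_by_id.get(l.crm_id)
        if t is None or c is None:
            raise ValidationError(f"link {l.pair} not covered by tss_set/crms")
        contained = False
        for reg in regions:
            if reg.contains_interval(c.interval) and reg.contains_point(
                t.chrom, t.position
            ):
                contained = True
                regions_hit.add(reg)
        if contained:
            links_in_region += 1
    return {
        "n_links": n_links,
        "n_regions": len(regions),
        "links_in_region": links_in_region,
        "regions_with_link": len(regions_hit),
        "frac_links_in_region": links_in_region / n_links if n_links else 0.0,
        "frac_regions_with_link": len(regions_hit) / len(regions) if regions else 0.0,
    }
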