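"""Nearest-neighbor CRM→TSS maps and map set algebra.

The nearest-neighbor heuristic — assign each TSS its k closest CRMs —
is the field's default when no linking evidence exists.  Building such
maps over the same TSS universe and window as a correlation-based map
lets the two be compared link-for-link: intersections, unions and
differences of the two link sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .intervals_io import CRM, TSS, ValidationError, signed_relative_position
from .map_builder import CisMap, Link

__all__ = [
    "MapAlgebraResult",
    "nearest_neighbor_map",
    "map_algebra",
    "nn_fraction_in_map",
]

ALGEBRA_LABELS = (
    "nn_only_map",
    "union",
    "intersection",
    "correlation_minus_nn",
    "nn_minus_correlation",
    "correlation_only_map",
)


@dataclass
class MapAlgebraResult:
    label: str
    links: list[Link]
    tss_universe: frozenset[str]

    @property
    def link_pairs(self) -> set[tuple[str, str]]:
        return {l.pair for l in self.links}

    def __len__(self) -> int:
        return len(self.links)


def _ranked_candidates(tss: TSS, crms: Iterable[CRM], window_bp: int) -> list[tuple[int, CRM]]:
    """In-window CRMs sorted by |distance|, ties by (start, crm_id)."""
    out = []
    for c in crms:
        if c.chrom != tss.chrom:
            continue
        rel = signed_relative_position(tss, c)
        if abs(rel) <= window_bp:
            out.append((rel, c))
    out.sort(key=lambda rc: (abs(rc[0]), rc[1].interval.start, rc[1].crm_id))
    return out


def nearest_neighbor_map(
    tss_set: Iterable[TSS],
    crms: Iterable[CRM],
    k: int = 1,
    window_bp: int = 1_000_000,
) -> CisMap:
    """Link each TSS to its k nearest CRMs (midpoint distance) in-window.

    Ties in distance are broken by smaller genomic start, then by
    lexicographic CRM id.  A TSS with fewer than k in-window candidates
    gets all of them; one with none gets no link.  NN links carry no
    correlation statistics.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    tss_set = set(tss_set)
    crms = set(crms)
    links: list[Link] = []
    for t in sorted(tss_set):
        for rel, c in _ranked_candidates(t, crms, window_bp)[:k]:
            links.append(Link(c.crm_id, t.tss_id, rel))
    return CisMap(
        links=links,
        tss_universe=frozenset(t.tss_id for t in tss_set),
        crm_universe=frozenset(c.crm_id for c in crms),
        config=None,
        provenance={"method": "nearest_neighbor", "k": k, "window_bp": window_bp},
    )


def map_algebra(correlation_map: CisMap, nn_map: CisMap) -> dict[str, MapAlgebraResult]:
    """All six labelled link-set combinations of two maps.

    Link identity is the (crm_id, tss_id) pair; link statistics are taken
    from the correlation map where available, else from the NN map.
    """
    if correlation_map.tss_universe != nn_map.tss_universe:
        raise ValidationError("map_algebra requires maps sharing a tss_universe")
    corr_by_pair = {l.pair: l for l in correlation_map.links}
    nn_by_pair = {l.pair: l for l in nn_map.links}
    corr_pairs = set(corr_by_pair)
    nn_pairs = set(nn_by_pair)

    def _pick(pairs: set[tuple[str, str]]) -> list[Link]:
        return sorted(
            corr_by_pair[p] if p in corr_by_pair else nn_by_pair[p] for p in pairs
        )

    sets = {
        "correlation_only_map": corr_pairs,
        "nn_only_map": nn_pairs,
        "union": corr_pairs | nn_pairs,
        "intersection": corr_pairs & nn_pairs,
        "correlation_minus_nn": corr_pairs - nn_pairs,
        "nn_minus_correlation": nn_pairs - corr_pairs,
    }
    universe = correlation_map.tss_universe
    return {
        label: MapAlgebraResult(label, _pick(pairs), universe)
        for label, pairs in sets.items()
    }


def nn_fraction_in_map(
    correlation_map: CisMap,
    tss_set: Iterable[TSS],
    crms: Iterable[CRM],
    k: int,
    window_bp: int = 1_000_000,
) -> float:
    """Fraction of correlation links whose CRM is among the k nearest to its TSS."""
    if not correlation_map.links:
        return 0.0
    tss_by_id = {t.tss_id: t for t in tss_set}
    crms = set(crms)
    nn_pairs: set[tuple[str, str]] = set()
    for tss_id in correlation_map.linked_tss:
        t = tss_by_id[tss_id]
        for _, c in _ranked_candidates(t, crms, window_bp)[:k]:
            nn_pairs.add((c.crm_id, tss_id))
    hits = sum(1 for l in correlation_map.links if l.pair in nn_pairs)
    return hits / len(correlation_map.links)
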