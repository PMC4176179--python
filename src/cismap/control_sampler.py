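"""Sampled control maps matched to a correlation-based map.

A control map keeps five properties of the real map fixed — TSS set,
total link count, per-TSS connectivity, the distribution of link
positions relative to the TSS, and the CRM universe — while replacing
the actual links with randomly sampled ones.  Expression models fit on
such controls isolate the contribution of the specific links chosen by
cross-tissue correlation from everything else about the map's shape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .map_builder import CandidatePair, CisMap, Link

__all__ = [
    "SampleConfig",
    "InfeasibleControl",
    "relative_position_histogram",
    "sample_control_map",
    "sample_control_ensemble",
]


class InfeasibleControl(ValueError):
    """A TSS's real-map degree exceeds its candidate count."""


@dataclass(frozen=True)
class SampleConfig:
    """Control-sampling parameters.

    Per-TSS degree is preserved exactly; candidate CRMs are drawn without
    replacement with probability proportional to the real map's
    relative-position histogram weight of the candidate's bin
    (bin_width_bp wide), so the control's distance/direction profile
    tracks the real map's.
    """

    seed: int
    n_maps: int = 10
    bin_width_bp: int = 50_000
    max_retries: int = 100

    def __post_init__(self) -> None:
        if self.n_maps < 1:
            raise ValueError("n_maps must be >= 1")
        if self.bin_width_bp <= 0:
            raise ValueError("bin_width_bp must be positive")


def _bin_edges(window_bp: int, bin_width_bp: int) -> np.ndarray:
    """Signed-position bin edges over [-window, +window].

    The last bin is truncated at +window when bin_width_bp does not divide
    2*window exactly.
    """
    edges = np.arange(-window_bp, window_bp, bin_width_bp, dtype=float)
    return np.append(edges, float(window_bp))


def relative_position_histogram(
    cis_map: CisMap, bin_width_bp: int, window_bp: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Counts of link rel_pos per signed bin; returns (counts, edges)."""
    if window_bp is None:
        window_bp = cis_map.config.window_bp if cis_map.config else 1_000_000
    edges = _bin_edges(window_bp, bin_width_bp)
    rel = np.array([l.rel_pos for l in cis_map.links], dtype=float)
    counts, _ = np.histogram(rel, bins=edges) if rel.size else (
        np.zeros(len(edges) - 1, dtype=int),
        edges,
    )
    return counts, edges


def _replicate_rng(seed: int, replicate_index: int) -> np.random.Generator:
    # deterministic substream per replicate: stable under parallel generation
    return np.random.default_rng([seed, replicate_index])


def sample_control_map(
    real_map: CisMap,
    candidates: set[CandidatePair],
    config: SampleConfig,
    replicate_index: int,
) -> CisMap:
    """Draw one control map matched to ``real_map`` on all five properties.

    For each linked TSS, its real degree d links are drawn without
    replacement from the TSS's candidate CRMs with probabilities
    proportional to the real map's rel_pos histogram weight of each
    candidate's bin.  If fewer than d candidates fall in bins with
    positive weight, probabilities relax to uniform over the remaining
    candidates for that TSS and the event is counted in diagnostics.
    """
    window_bp = real_map.config.window_bp if real_map.config else 1_000_000
    counts, edges = relative_position_histogram(
        real_map, config.bin_width_bp, window_bp
    )
    weights = counts.astype(float)
    total = weights.sum()
    if total > 0:
        weights = weights / total

    by_tss: dict[str, list[CandidatePair]] = {}
    for p in candidates:
        by_tss.setdefault(p.tss_id, []).append(p)
    for lst in by_tss.values():
        lst.sort()

    rng = _replicate_rng(config.seed, replicate_index)
    degrees = real_map.degree_by_tss()
    links: list[Link] = []
    relaxed_tss: list[str] = []
    for tss_id in sorted(degrees):
        d = degrees[tss_id]
        cands = by_tss.get(tss_id, [])
        if len(cands) < d:
            raise InfeasibleControl(
                f"TSS {tss_id}: degree {d} exceeds {len(cands)} candidates"
            )
        rel = np.array([c.rel_pos for c in cands], dtype=float)
        bins = np.clip(np.searchsorted(edges, rel, side="right") - 1, 0, len(weights) - 1)
        w = weights[bins]
        n_positive = int((w > 0).sum())
        if n_positive < d:
            # target bin weights unrealisable for this TSS: fall back to uniform
            w = np.ones(len(cands))
            relaxed_tss.append(tss_id)
        w = w / w.sum()
        chosen = rng.choice(len(cands), size=d, replace=False, p=w)
        for idx in sorted(chosen):
            c = cands[idx]
            links.append(Link(c.crm_id, c.tss_id, c.rel_pos))

    return CisMap(
        links=links,
        tss_universe=real_map.tss_universe,
        crm_universe=real_map.crm_universe,
        config=real_map.config,
        provenance={
            **real_map.provenance,
            "control_replicate": replicate_index,
            "control_seed": config.seed,
        },
        diagnostics={
            "relaxed_tss": relaxed_tss,
            "n_relaxed": len(relaxed_tss),
        },
    )


def sample_control_ensemble(
    real_map: CisMap,
    candidates: set[CandidatePair],
    config: SampleConfig,
) -> list[CisMap]:
    """``config.n_maps`` independent control maps (replicates 0..n-1)."""
    return [
        sample_control_map(real_map, candidates, config, r)
        for r in range(config.n_maps)
    ]
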