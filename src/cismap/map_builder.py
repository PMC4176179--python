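"""Build correlation-based cis-regulatory maps.

A map links CRMs to candidate target TSSs within ±1 Mbp whenever the
cross-tissue Pearson correlation between the histone-modification level
at the CRM and the expression level at the TSS is significant at a
chosen stringency θ (a raw p-value threshold).  The tissue in which the
map will be used ("test tissue") is held out of the correlation panel so
that downstream validation on that tissue is free of circularity.
"""

from __future__ import annotations

import bisect
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .intervals_io import (
    CRM,
    TSS,
    ExpressionMatrix,
    SignalMatrix,
    ValidationError,
    signed_relative_position,
)

__all__ = [
    "MapBuildConfig",
    "CandidatePair",
    "Link",
    "CisMap",
    "ConfigError",
    "select_nonoverlapping_crms",
    "enumerate_candidates",
    "pearson_r",
    "correlation_p_value",
    "build_map",
    "map_summary",
    "write_links",
    "read_links",
]

_TINY_P = np.nextafter(0.0, 1.0)


class ConfigError(ValueError):
    """Inconsistent map-building configuration or input panels."""


@dataclass(frozen=True)
class MapBuildConfig:
    """Parameters of one map-building run.

    theta is the link stringency: a raw p-value threshold in (0, 1).
    window_bp bounds the TSS-to-CRM-midpoint distance (default 1 Mbp).
    test_tissue names the held-out tissue ("" = no hold-out).
    min_tissues is the minimum panel size for a correlation to be computed.
    """

    theta: float
    window_bp: int = 1_000_000
    test_tissue: str = ""
    min_tissues: int = 6

    def __post_init__(self) -> None:
        if not 0 < self.theta < 1:
            raise ConfigError(f"theta must be in (0,1), got {self.theta}")
        if self.window_bp <= 0:
            raise ConfigError("window_bp must be positive")
        if self.min_tissues < 3:
            raise ConfigError("min_tissues must be >= 3")


@dataclass(frozen=True, order=True)
class CandidatePair:
    crm_id: str
    tss_id: str
    rel_pos: int


@dataclass(frozen=True, order=True)
class Link:
    crm_id: str
    tss_id: str
    rel_pos: int
    r: float = math.nan
    p_value: float = math.nan
    n_tissues: int = 0

    @property
    def pair(self) -> tuple[str, str]:
        return (self.crm_id, self.tss_id)


@dataclass
class CisMap:
    """A set of CRM→TSS links plus the universes they were drawn from."""

    links: list[Link]
    tss_universe: frozenset[str]
    crm_universe: frozenset[str]
    config: MapBuildConfig | None = None
    provenance: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pairs = [l.pair for l in self.links]
        if len(set(pairs)) != len(pairs):
            raise ValidationError("duplicate (crm_id, tss_id) link")
        for l in self.links:
            if l.tss_id not in self.tss_universe:
                raise ValidationError(f"link TSS {l.tss_id} outside tss_universe")
            if l.crm_id not in self.crm_universe:
                raise ValidationError(f"link CRM {l.crm_id} outside crm_universe")

    @property
    def link_pairs(self) -> set[tuple[str, str]]:
        return {l.pair for l in self.links}

    @property
    def linked_tss(self) -> set[str]:
        return {l.tss_id for l in self.links}

    @property
    def linked_crms(self) -> set[str]:
        return {l.crm_id for l in self.links}

    def degree_by_tss(self) -> dict[str, int]:
        deg: dict[str, int] = {}
        for l in self.links:
            deg[l.tss_id] = deg.get(l.tss_id, 0) + 1
        return deg

    def __len__(self) -> int:
        return len(self.links)


def select_nonoverlapping_crms(crms: Iterable[CRM]) -> set[CRM]:
    """Greedily keep a non-overlapping subset of CRMs, best score first.

    CRMs predicted in different tissues may overlap; rather than merging
    them into tissue-nonspecific amalgams, one representative per
    overlapping cluster is kept.  Selection order is descending score,
    ties broken by leftmost start then lexicographic id, so the result is
    deterministic and every discarded CRM overlaps a kept CRM of
    equal-or-higher priority.
    """
    ordered = sorted(
        crms, key=lambda c: (-c.score, c.interval.start, c.crm_id)
    )
    kept: set[CRM] = set()
    # per-chromosome sorted list of kept (start, end)
    occupied: dict[str, list[tuple[int, int]]] = {}
    for c in ordered:
        spans = occupied.setdefault(c.chrom, [])
        i = bisect.bisect_left(spans, (c.interval.start, c.interval.start))
        clash = False
        if i < len(spans) and spans[i][0] < c.interval.end:
            clash = True
        if i > 0 and spans[i - 1][1] > c.interval.start:
            clash = True
        if not clash:
            spans.insert(i, (c.interval.start, c.interval.end))
            kept.add(c)
    return kept


def enumerate_candidates(
    tss_set: Iterable[TSS],
    crms: Iterable[CRM],
    config: MapBuildConfig,
) -> set[CandidatePair]:
    """All same-chromosome CRM–TSS pairs with |rel_pos| <= window_bp."""
    by_chrom: dict[str, list[tuple[int, str, CRM]]] = {}
    for c in crms:
        by_chrom.setdefault(c.chrom, []).append((c.midpoint, c.crm_id, c))
    for entries in by_chrom.values():
        entries.sort()
    out: set[CandidatePair] = set()
    for t in tss_set:
        entries = by_chrom.get(t.chrom, [])
        mids = [e[0] for e in entries]
        lo = bisect.bisect_left(mids, t.position - config.window_bp)
        hi = bisect.bisect_right(mids, t.position + config.window_bp)
        for mid, crm_id, crm in entries[lo:hi]:
            out.add(CandidatePair(crm_id, t.tss_id, signed_relative_position(t, crm)))
    return out


class UndefinedCorrelation(ValueError):
    """Raised when a correlation is undefined (constant input vector)."""


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation of two equal-length vectors (n >= 3)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson_r requires two equal-length vectors")
    if x.size < 3:
        raise ValueError("pearson_r requires n >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        raise UndefinedCorrelation("constant input vector")
    r = float(xc @ yc) / denom
    return max(-1.0, min(1.0, r))


def correlation_p_value(r: float, n: int) -> float:
    """Two-sided p-value for a sample Pearson correlation.

    Uses the exact t-test: t = r * sqrt((n-2) / (1-r^2)) with n-2 degrees
    of freedom.  |r| = 1 maps to the smallest positive float.
    """
    if n < 3:
        raise ValueError("correlation p-value requires n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation {r} outside [-1, 1]")
    if abs(r) == 1.0:
        return _TINY_P
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return min(max(p, _TINY_P), 1.0)


def _reference_tissues(
    histone: SignalMatrix, expr: ExpressionMatrix, config: MapBuildConfig
) -> list[str]:
    h_tissues = list(histone.tissue_ids)
    e_tissues = set(expr.tissue_ids)
    shared = [t for t in h_tissues if t in e_tissues]
    if config.test_tissue:
        if config.test_tissue not in histone.tissue_ids:
            raise ConfigError(
                f"test tissue {config.test_tissue!r} absent from histone panel"
            )
        if config.test_tissue not in expr.tissue_ids:
            raise ConfigError(
                f"test tissue {config.test_tissue!r} absent from expression panel"
            )
        shared = [t for t in shared if t != config.test_tissue]
    if len(shared) < config.min_tissues:
        raise ConfigError(
            f"only {len(shared)} shared reference tissues; "
            f"min_tissues is {config.min_tissues}"
        )
    return shared


def build_map(
    tss_set: Iterable[TSS],
    crms: Iterable[CRM],
    histone: SignalMatrix,
    expr: ExpressionMatrix,
    config: MapBuildConfig,
    candidates: set[CandidatePair] | None = None,
    provenance: dict | None = None,
) -> CisMap:
    """Score every in-window CRM–TSS pair and keep links with p <= theta.

    The held-out test tissue (if named) is removed from both panels before
    any correlation is computed.  Pairs whose histone or expression vector
    is constant over the reference panel are skipped and counted in
    ``diagnostics['skipped_constant']``.
    """
    tss_set = set(tss_set)
    crms = set(crms)
    tissues = _reference_tissues(histone, expr, config)
    n = len(tissues)

    missing_crm = {c.crm_id for c in crms} - set(histone.row_ids)
    if missing_crm:
        raise ConfigError(
            f"{len(missing_crm)} CRMs missing from histone matrix "
            f"(e.g. {sorted(missing_crm)[:3]})"
        )
    missing_tss = {t.tss_id for t in tss_set} - set(expr.row_ids)
    if missing_tss:
        raise ConfigError(
            f"{len(missing_tss)} TSSs missing from expression matrix "
            f"(e.g. {sorted(missing_tss)[:3]})"
        )

    if candidates is None:
        candidates = enumerate_candidates(tss_set, crms, config)

    # centre/normalise each referenced row once; correlations are dot products
    h_ref = histone.df.loc[:, tissues]
    e_ref = expr.df.loc[:, tissues]
    h_arr = h_ref.to_numpy()
    e_arr = e_ref.to_numpy()
    h_index = {rid: i for i, rid in enumerate(h_ref.index)}
    e_index = {rid: i for i, rid in enumerate(e_ref.index)}

    def _normalise(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        centred = arr - arr.mean(axis=1, keepdims=True)
        norms = np.sqrt((centred**2).sum(axis=1))
        ok = norms > 0
        safe = np.where(ok, norms, 1.0)
        return centred / safe[:, None], ok

    h_z, h_ok = _normalise(h_arr)
    e_z, e_ok = _normalise(e_arr)

    links: list[Link] = []
    skipped_constant = 0
    perfect = 0
    ordered = sorted(candidates)
    ci = np.fromiter((h_index[p.crm_id] for p in ordered), dtype=int, count=len(ordered))
    ti = np.fromiter((e_index[p.tss_id] for p in ordered), dtype=int, count=len(ordered))
    if len(ordered):
        valid = h_ok[ci] & e_ok[ti]
        r_all = np.einsum("ij,ij->i", h_z[ci], e_z[ti])
        r_all = np.clip(r_all, -1.0, 1.0)
        skipped_constant = int((~valid).sum())
        with np.errstate(divide="ignore"):
            tstat = r_all * np.sqrt((n - 2) / np.maximum(1.0 - r_all**2, 0.0))
        p_all = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
        exact = np.abs(r_all) >= 1.0
        p_all[exact] = _TINY_P
        perfect = int((exact & valid).sum())
        p_all = np.clip(p_all, _TINY_P, 1.0)
        keep = valid & (p_all <= config.theta)
        for idx in np.nonzero(keep)[0]:
            pair = ordered[idx]
            links.append(
                Link(
                    pair.crm_id,
                    pair.tss_id,
                    pair.rel_pos,
                    float(r_all[idx]),
                    float(p_all[idx]),
                    n,
                )
            )

    prov = dict(provenance or {})
    prov.setdefault("reference_tissues", tissues)
    prov.setdefault("test_tissue", config.test_tissue)
    return CisMap(
        links=links,
        tss_universe=frozenset(t.tss_id for t in tss_set),
        crm_universe=frozenset(c.crm_id for c in crms),
        config=config,
        provenance=prov,
        diagnostics={
            "n_candidates": len(candidates),
            "skipped_constant": skipped_constant,
            "perfect_correlations": perfect,
            "n_reference_tissues": n,
        },
    )


def map_summary(cis_map: CisMap, tss_set: Iterable[TSS] | None = None) -> dict:
    """Counts of links, linked CRMs/TSSs/genes and links per linked TSS."""
    deg = cis_map.degree_by_tss()
    n_links = len(cis_map.links)
    genes = 0
    if tss_set is not None:
        gene_by_tss = {t.tss_id: t.gene_id for t in tss_set}
        genes = len({gene_by_tss[t] for t in deg if t in gene_by_tss})
    per_tss = sorted(deg.values())
    return {
        "links": n_links,
        "crms": len(cis_map.linked_crms),
        "tsss": len(deg),
        "genes": genes,
        "mean_links_per_tss": float(np.mean(per_tss)) if per_tss else 0.0,
        "median_links_per_tss": float(np.median(per_tss)) if per_tss else 0.0,
    }


# ---------------------------------------------------------------------------
# Map serialisation: tab-delimited links + JSON sidecar
# ---------------------------------------------------------------------------

_LINK_COLUMNS = ["crm_id", "tss_id", "rel_pos", "r", "p_value", "n_tissues"]


def write_links(prefix: str | Path, cis_map: CisMap) -> tuple[Path, Path]:
    """Write ``<prefix>.links.tsv`` and ``<prefix>.map.json``."""
    prefix = Path(prefix)
    links_path = Path(str(prefix) + ".links.tsv")
    sidecar_path = Path(str(prefix) + ".map.json")
    with open(links_path, "w") as fh:
        fh.write("\t".join(_LINK_COLUMNS) + "\n")
        for l in sorted(cis_map.links):
            r = "" if math.isnan(l.r) else f"{l.r:.10g}"
            p = "" if math.isnan(l.p_value) else f"{l.p_value:.10g}"
            fh.write(
                f"{l.crm_id}\t{l.tss_id}\t{l.rel_pos}\t{r}\t{p}\t{l.n_tissues}\n"
            )
    sidecar = {
        "tss_universe": sorted(cis_map.tss_universe),
        "crm_universe": sorted(cis_map.crm_universe),
        "config": None
        if cis_map.config is None
        else {
            "theta": cis_map.config.theta,
            "window_bp": cis_map.config.window_bp,
            "test_tissue": cis_map.config.test_tissue,
            "min_tissues": cis_map.config.min_tissues,
        },
        "provenance": cis_map.provenance,
        "diagnostics": cis_map.diagnostics,
    }
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return links_path, sidecar_path


def read_links(prefix: str | Path) -> CisMap:
    """Read a map written by :func:`write_links`."""
    prefix = Path(prefix)
    links_path = Path(str(prefix) + ".links.tsv")
    sidecar_path = Path(str(prefix) + ".map.json")
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    links: list[Link] = []
    with open(links_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _LINK_COLUMNS:
            raise ValidationError(f"{links_path}: unexpected header {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            links.append(
                Link(
                    f[0],
                    f[1],
                    int(f[2]),
                    float(f[3]) if f[3] else math.nan,
                    float(f[4]) if f[4] else math.nan,
                    int(f[5]),
                )
            )
    cfg = None
    if sidecar.get("config"):
        c = sidecar["config"]
        cfg = MapBuildConfig(
            theta=c["theta"],
            window_bp=c["window_bp"],
            test_tissue=c["test_tissue"],
            min_tissues=c["min_tissues"],
        )
    return CisMap(
        links=links,
        tss_universe=frozenset(sidecar["tss_universe"]),
        crm_universe=frozenset(sidecar["crm_universe"]),
        config=cfg,
        provenance=sidecar.get("provenance", {}),
        diagnostics=sidecar.get("diagnostics", {}),
    )
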