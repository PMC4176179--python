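"""Seeded multi-tissue panels with planted CRM→TSS regulation.

The generator emulates the data regime the mapping method is designed
for: a panel of reference tissues in which the histone level at a CRM
and the expression at its target TSS co-vary because both read out a
shared, tissue-specific regulatory activity; plus a held-out test
tissue in which TF binding at a CRM drives expression only through the
planted links.  All randomness flows from a single seed.

Generative model, per planted link group ("regulon" = a TSS and its
parent CRMs):

* latent activity ``a[tissue] ~ LogNormal(0, activity_sigma)`` across
  reference tissues — tissue-specific and right-skewed like real
  enhancer activity;
* histone(parent CRM) = a + e_h and expression(TSS) = a + e_e, where
  the noise terms are mean-centred gamma variates scaled so the
  population Pearson correlation between histone and expression equals
  ``link_correlation`` (noise sd = sd(a) * sqrt((1-rho)/rho) per side);
* unlinked CRMs and TSSs carry independent gamma(shape=4) signal, whose
  mild skew keeps the correlation t-test well calibrated under the null;
* in the test tissue each CRM is independently active with probability
  ``test_active_frac``; TF binding at a CRM is a TF-specific loading
  times its test activity plus noise, and test expression at a TSS is
  the sum of its parent CRMs' test activities plus noise.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals_io import (
    CRM,
    TSS,
    ExpressionMatrix,
    GenomicInterval,
    SignalMatrix,
    TFBindingMatrix,
    write_crms_bed,
    write_matrix,
    write_tss_table,
)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "SimulatedPanel",
    "simulate_panel",
    "write_fixture",
    "fantom5_like_config",
]

TEST_TISSUE = "TEST"
CHROM = "chrS"
_GAMMA_SHAPE = 4.0  # skewness 1: realistic signal, calibrated null correlations


@dataclass(frozen=True)
class SimulationConfig:
    """Panel dimensions and effect sizes.

    Defaults mirror an ENCODE-like regime: 15 reference tissues, TF panel
    sized like the GM12878 validation set (53 TFs), planted links at
    cross-tissue correlation 0.95, and half of the true links distal to
    (not the nearest CRM of) their target TSS.
    """

    seed: int
    n_tissues: int = 15
    n_tss: int = 50
    n_crms: int = 500
    n_true_links: int = 100
    link_correlation: float = 0.95
    noise_sd: float = 1.0
    n_tfs: int = 53
    window_bp: int = 1_000_000
    frac_distal: float = 0.5
    activity_sigma: float = 0.5
    crm_spacing_bp: int = 20_000
    test_active_frac: float = 0.5
    gc_background: float = 0.45
    gc_target: float | None = None
    plant_tata_at: int | None = None
    make_genome: bool = True

    def __post_init__(self) -> None:
        if self.n_true_links > self.n_crms:
            raise ValueError("n_true_links may not exceed n_crms")
        if not 0 < self.link_correlation < 1:
            raise ValueError("link_correlation must be in (0, 1)")
        if min(self.n_tissues, self.n_tss, self.n_crms, self.n_tfs) <= 0:
            raise ValueError("all counts must be positive")
        if not 0.0 <= self.frac_distal <= 1.0:
            raise ValueError("frac_distal must be in [0, 1]")


def fantom5_like_config(seed: int, **overrides) -> SimulationConfig:
    """A 50-tissue preset mirroring the many-tissue (FANTOM5-like) regime
    in which extreme link stringencies become reachable."""
    params = dict(
        seed=seed,
        n_tissues=50,
        n_tss=100,
        n_crms=1000,
        n_true_links=200,
        link_correlation=0.95,
    )
    params.update(overrides)
    return SimulationConfig(**params)


@dataclass
class SimulationTruth:
    """Planted links and the generative parameters that produced them."""

    true_links: set[tuple[str, str]]
    active_in_test: set[str]
    nearest_neighbor_links: set[tuple[str, str]]
    config: SimulationConfig


@dataclass
class SimulatedPanel:
    tss_set: set[TSS]
    crms: set[CRM]
    histone: SignalMatrix
    expression: ExpressionMatrix
    tf_binding: TFBindingMatrix
    tf_binding_promoter: TFBindingMatrix
    test_expression: pd.Series
    genome: dict[str, str] | None
    truth: SimulationTruth


def _centered_gamma(rng: np.random.Generator, sd: np.ndarray | float, size) -> np.ndarray:
    """Mean-zero, right-skewed noise with the requested standard deviation."""
    g = rng.gamma(_GAMMA_SHAPE, 1.0, size=size)
    return (g - _GAMMA_SHAPE) / math.sqrt(_GAMMA_SHAPE) * sd


def _background_signal(rng: np.random.Generator, scale: float, size) -> np.ndarray:
    return rng.gamma(_GAMMA_SHAPE, scale / math.sqrt(_GAMMA_SHAPE), size=size)


def _place_elements(rng: np.random.Generator, config: SimulationConfig):
    """Non-overlapping CRMs on a regular jittered grid, TSSs in between."""
    spacing = config.crm_spacing_bp
    margin = 2_000
    starts = margin + np.arange(config.n_crms) * spacing
    starts = starts + rng.integers(0, spacing // 4, size=config.n_crms)
    lengths = rng.integers(300, 1200, size=config.n_crms)
    crms = [
        CRM(
            f"crm{i:05d}",
            GenomicInterval(CHROM, int(s), int(s + l)),
            "simulated",
            round(float(rng.uniform(1, 10)), 3),
        )
        for i, (s, l) in enumerate(zip(starts, lengths))
    ]
    chrom_len = int(starts[-1] + lengths[-1] + spacing + margin)
    tss_pos = rng.integers(margin, chrom_len - margin, size=config.n_tss)
    strands = rng.choice(["+", "-"], size=config.n_tss)
    tss = [
        TSS(f"tss{i:04d}", CHROM, int(p), str(s), f"gene{i:04d}")
        for i, (p, s) in enumerate(zip(tss_pos, strands))
    ]
    return tss, crms, chrom_len


def _assign_links(
    rng: np.random.Generator,
    tss: list[TSS],
    crms: list[CRM],
    config: SimulationConfig,
):
    """Plant links respecting the window and the distal fraction.

    Links are spread round-robin over a shuffled TSS order; a chosen
    number of linked TSSs receive their globally nearest CRM as first
    parent, every other planted link is drawn uniformly from the
    remaining in-window CRMs that are not the TSS's nearest.
    """
    mids = np.array([c.midpoint for c in crms])
    order = np.argsort(mids)
    sorted_mids = mids[order]

    def in_window(t: TSS) -> list[int]:
        lo = np.searchsorted(sorted_mids, t.position - config.window_bp, "left")
        hi = np.searchsorted(sorted_mids, t.position + config.window_bp, "right")
        return [int(order[i]) for i in range(lo, hi)]

    def nearest_idx(t: TSS) -> int | None:
        cand = in_window(t)
        if not cand:
            return None
        return min(
            cand,
            key=lambda i: (
                abs(crms[i].midpoint - t.position),
                crms[i].interval.start,
                crms[i].crm_id,
            ),
        )

    tss_order = list(rng.permutation(len(tss)))
    # round-robin: degree differs by at most one across linked TSSs
    targets: list[int] = []
    while len(targets) < config.n_true_links:
        take = min(len(tss_order), config.n_true_links - len(targets))
        targets.extend(tss_order[:take])
    link_tss_ids = sorted(set(targets))
    n_proximal = round((1.0 - config.frac_distal) * config.n_true_links)
    n_proximal = min(n_proximal, len(link_tss_ids))
    proximal_tss = set(
        rng.choice(np.array(link_tss_ids), size=n_proximal, replace=False).tolist()
    )

    assigned: set[int] = set()
    parents: dict[int, list[int]] = {i: [] for i in link_tss_ids}
    nn_links: set[tuple[str, str]] = set()
    # first parents: nearest CRM for the proximal TSSs
    for ti in sorted(proximal_tss):
        ni = nearest_idx(tss[ti])
        if ni is None or ni in assigned:
            continue
        parents[ti].append(ni)
        assigned.add(ni)
        nn_links.add((crms[ni].crm_id, tss[ti].tss_id))
    # remaining links: distal draws
    remaining = config.n_true_links - sum(len(v) for v in parents.values())
    queue = [t for t in targets]
    for ti in queue:
        if remaining <= 0:
            break
        want = targets.count(ti)
        if len(parents[ti]) >= want:
            continue
        cand = [i for i in in_window(tss[ti]) if i not in assigned]
        ni = nearest_idx(tss[ti])
        distal_cand = [i for i in cand if i != ni]
        pool = distal_cand if distal_cand else cand
        if not pool:
            raise ValueError(
                f"window too sparse to place a link for {tss[ti].tss_id}"
            )
        pick = int(rng.choice(np.array(pool)))
        parents[ti].append(pick)
        assigned.add(pick)
        remaining -= 1
    true_links = {
        (crms[ci].crm_id, tss[ti].tss_id)
        for ti, cis in parents.items()
        for ci in cis
    }
    return parents, true_links, nn_links


def _random_genome(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=p)


def _plant_promoter_features(
    seq: np.ndarray,
    rng: np.random.Generator,
    tss: TSS,
    config: SimulationConfig,
) -> None:
    """Rewrite a map-target promoter with target GC and/or a TATA tetramer."""
    if config.gc_target is not None:
        u = 500
        if tss.strand == "+":
            lo, hi = max(tss.position - u, 0), tss.position
        else:
            lo, hi = tss.position + 1, min(tss.position + 1 + u, len(seq))
        if hi > lo:
            seq[lo:hi] = _random_genome(rng, hi - lo, config.gc_target)
    if config.plant_tata_at is not None:
        d = config.plant_tata_at
        motif = np.frombuffer(b"TATA", dtype="S1")
        if tss.strand == "+":
            lo = tss.position - d - 3
            if lo >= 0:
                seq[lo : lo + 4] = motif
        else:
            lo = tss.position + d
            if lo + 4 <= len(seq):
                seq[lo : lo + 4] = motif  # TATA is its own reverse complement


def simulate_panel(config: SimulationConfig) -> SimulatedPanel:
    """Generate a complete, reproducible panel (see module docstring)."""
    rng = np.random.default_rng(config.seed)
    tss, crms, chrom_len = _place_elements(rng, config)
    parents, true_links, nn_links = _assign_links(rng, tss, crms, config)

    ref_tissues = [f"R{i:02d}" for i in range(1, config.n_tissues + 1)]
    tissues = ref_tissues + [TEST_TISSUE]
    n_ref = config.n_tissues
    rho = config.link_correlation

    histone = _background_signal(
        rng, config.noise_sd, (config.n_crms, len(tissues))
    )
    expr = _background_signal(rng, config.noise_sd, (config.n_tss, len(tissues)))

    # test-tissue activity per CRM: active subset only
    active = rng.random(config.n_crms) < config.test_active_frac
    test_activity = np.where(active, rng.lognormal(0.0, 1.0, config.n_crms), 0.0)

    noise_factor = math.sqrt((1.0 - rho) / rho)
    for ti, cis in parents.items():
        a = rng.lognormal(0.0, config.activity_sigma, n_ref)
        sd_a = float(a.std())
        e_e = _centered_gamma(rng, noise_factor * sd_a, n_ref)
        expr[ti, :n_ref] = np.clip(a + e_e, 0.0, None)
        for ci in cis:
            e_h = _centered_gamma(rng, noise_factor * sd_a, n_ref)
            histone[ci, :n_ref] = np.clip(a + e_h, 0.0, None)

    # held-out test column: histone tracks test activity, expression is the
    # sum of parent activities plus noise
    histone[:, n_ref] = np.clip(
        test_activity + _centered_gamma(rng, 0.3 * config.noise_sd, config.n_crms),
        0.0,
        None,
    )
    test_expr = _background_signal(rng, 0.3 * config.noise_sd, config.n_tss)
    for ti, cis in parents.items():
        test_expr[ti] = max(
            sum(test_activity[ci] for ci in cis)
            + float(_centered_gamma(rng, 0.3 * config.noise_sd, 1)[0]),
            0.0,
        )
    expr[:, n_ref] = test_expr

    crm_ids = [c.crm_id for c in crms]
    tss_ids = [t.tss_id for t in tss]
    histone_m = SignalMatrix(histone, crm_ids, tissues)
    expr_m = ExpressionMatrix(expr, tss_ids, tissues)

    # TF binding in the test tissue: loading x activity where the TF binds
    tf_ids = [f"TF{j:02d}" for j in range(1, config.n_tfs + 1)]
    loadings = rng.uniform(0.3, 1.0, config.n_tfs)
    gates = rng.random((config.n_crms, config.n_tfs)) < 0.5
    tf_noise = np.abs(
        _centered_gamma(rng, 0.2 * config.noise_sd, (config.n_crms, config.n_tfs))
    )
    tf_binding = gates * np.outer(test_activity, loadings) + tf_noise
    tf_binding_m = TFBindingMatrix(tf_binding, crm_ids, tf_ids)

    # promoter binding tracks test expression directly
    prom_gates = rng.random((config.n_tss, config.n_tfs)) < 0.5
    prom_noise = np.abs(
        _centered_gamma(rng, 0.2 * config.noise_sd, (config.n_tss, config.n_tfs))
    )
    tf_promoter = prom_gates * np.outer(test_expr, loadings) + prom_noise
    tf_promoter_m = TFBindingMatrix(tf_promoter, tss_ids, tf_ids)

    genome = None
    if config.make_genome:
        seq = _random_genome(rng, chrom_len, config.gc_background)
        target_ids = {t for _, t in true_links}
        for t in tss:
            if t.tss_id in target_ids:
                _plant_promoter_features(seq, rng, t, config)
        genome = {CHROM: seq.tobytes().decode("ascii")}

    truth = SimulationTruth(
        true_links=true_links,
        active_in_test={crm_ids[i] for i in np.nonzero(active)[0]},
        nearest_neighbor_links=nn_links,
        config=config,
    )
    return SimulatedPanel(
        tss_set=set(tss),
        crms=set(crms),
        histone=histone_m,
        expression=expr_m,
        tf_binding=tf_binding_m,
        tf_binding_promoter=tf_promoter_m,
        test_expression=pd.Series(test_expr, index=tss_ids),
        genome=genome,
        truth=truth,
    )


def write_fixture(prefix: str | Path, panel: SimulatedPanel) -> dict:
    """Write the panel in the formats the readers consume; return a manifest.

    Emits ``crms.bed``, ``tss.tsv``, ``histone.tsv``, ``expression.tsv``,
    ``tf_binding.tsv``, ``tf_promoter.tsv``, ``truth.json`` and (when a
    genome was generated) ``genome.fa`` under the prefix directory, plus
    ``manifest.json`` listing each file with its SHA-256 checksum.
    """
    out = Path(prefix)
    out.mkdir(parents=True, exist_ok=True)
    write_crms_bed(out / "crms.bed", panel.crms)
    write_tss_table(out / "tss.tsv", panel.tss_set)
    write_matrix(out / "histone.tsv", panel.histone)
    write_matrix(out / "expression.tsv", panel.expression)
    write_matrix(out / "tf_binding.tsv", panel.tf_binding)
    write_matrix(out / "tf_promoter.tsv", panel.tf_binding_promoter)
    truth = {
        "true_links": sorted(map(list, panel.truth.true_links)),
        "active_in_test": sorted(panel.truth.active_in_test),
        "nearest_neighbor_links": sorted(map(list, panel.truth.nearest_neighbor_links)),
        "config": asdict(panel.truth.config),
        "test_tissue": TEST_TISSUE,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    files = [
        "crms.bed",
        "tss.tsv",
        "histone.tsv",
        "expression.tsv",
        "tf_binding.tsv",
        "tf_promoter.tsv",
        "truth.json",
    ]
    if panel.genome is not None:
        with open(out / "genome.fa", "w") as fh:
            for chrom, seq in panel.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        files.append("genome.fa")
    manifest = {"files": {}, "omitted": []}
    for name in files:
        digest = hashlib.sha256((out / name).read_bytes()).hexdigest()
        manifest["files"][name] = digest
    if panel.genome is None:
        manifest["omitted"].append("genome.fa")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
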