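"""Cross-validated LASSO models of test-tissue expression from TF binding.

A cis-regulatory map is validated by how well TF binding in its linked
CRMs predicts expression at its TSSs in the held-out test tissue — data
that played no part in building the map.  For each TSS the features are
the per-TF binding signals summed over its map-linked CRMs (or taken
from its promoter region), log-transformed; the response is the
log-transformed test-tissue expression.  Accuracy is the mean and
standard error of held-out R² over outer cross-validation folds, with
the LASSO penalty chosen by inner cross-validation inside each training
fold so no test information leaks into the fit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold
from sklearn.preprocessing import StandardScaler

from .intervals_io import TSS, GenomicInterval, TFBindingMatrix, ValidationError
from .map_builder import CisMap

__all__ = [
    "TFBindingMatrix",
    "RegressionConfig",
    "RegressionResult",
    "promoter_interval",
    "build_features_from_map",
    "build_features_from_promoter",
    "fit_lasso_cv",
    "validate_map",
]

_TRANSFORMS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "log1p": np.log1p,
    "identity": lambda x: np.asarray(x, dtype=float),
}

_AGGREGATIONS = {"sum": np.sum, "mean": np.mean, "max": np.max}


@dataclass(frozen=True)
class RegressionConfig:
    """Cross-validation and feature-construction parameters.

    n_folds outer folds give the reported R² distribution; the penalty is
    tuned by inner CV over a lambda_grid_size-point path within each
    training fold.  transform is applied to aggregated features and to
    the response; aggregation combines binding over a TSS's linked CRMs.
    max_features caps the TFs retained per fold (ranked by |coefficient|
    at the chosen penalty); 0 means no cap.
    """

    seed: int
    n_folds: int = 10
    max_features: int = 0
    lambda_grid_size: int = 100
    transform: str = "log1p"
    aggregation: str = "sum"
    inner_folds: int = 5

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.transform not in _TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.aggregation not in _AGGREGATIONS:
            raise ValueError(f"unknown aggregation {self.aggregation!r}")


@dataclass
class RegressionResult:
    """Held-out R² per outer fold, with mean, standard error and the TFs
    the LASSO selected in each fold."""

    model_label: str
    fold_r2: list[float]
    selected_tfs: list[list[str]]
    n_obs: int

    @property
    def mean_r2(self) -> float:
        return float(np.mean(self.fold_r2)) if self.fold_r2 else math.nan

    @property
    def se_r2(self) -> float:
        if len(self.fold_r2) < 2:
            return 0.0
        return float(np.std(self.fold_r2, ddof=1) / math.sqrt(len(self.fold_r2)))


def build_features_from_map(
    cis_map: CisMap | object,
    tf_binding: TFBindingMatrix,
    transform: str = "log1p",
    aggregation: str = "sum",
) -> pd.DataFrame:
    """TSS-by-TF feature table: transform(aggregate binding over linked CRMs).

    Rows cover the map's full tss_universe; a TSS with no links gets
    all-zero features (transform(0) must be 0, true of log1p and
    identity).
    """
    links = cis_map.links
    universe = sorted(cis_map.tss_universe)
    tf_ids = tf_binding.tf_ids
    missing = {l.crm_id for l in links} - set(tf_binding.region_ids)
    if missing:
        raise ValidationError(
            f"linked CRMs missing from TF-binding matrix: {sorted(missing)[:5]}"
        )
    agg = _AGGREGATIONS[aggregation]
    tfm = _TRANSFORMS[transform]
    crm_rows = tf_binding.df
    by_tss: dict[str, list[str]] = {}
    for l in links:
        by_tss.setdefault(l.tss_id, []).append(l.crm_id)
    out = np.zeros((len(universe), len(tf_ids)))
    for i, tss_id in enumerate(universe):
        crm_ids = by_tss.get(tss_id)
        if crm_ids:
            out[i] = agg(crm_rows.loc[crm_ids].to_numpy(), axis=0)
    return pd.DataFrame(tfm(out), index=universe, columns=tf_ids)


def promoter_interval(tss: TSS, upstream: int = 500, downstream: int = 200) -> GenomicInterval:
    """Strand-oriented promoter window (default −500..+200 around the TSS)."""
    if tss.strand == "+":
        start, end = tss.position - upstream, tss.position + downstream
    else:
        start, end = tss.position - downstream, tss.position + upstream
    return GenomicInterval(tss.chrom, max(start, 0), end, tss.strand)


def build_features_from_promoter(
    tss_set: Iterable[TSS],
    tf_binding_promoter: TFBindingMatrix,
    transform: str = "log1p",
) -> pd.DataFrame:
    """TSS-by-TF features from promoter-region binding (rows keyed by tss_id)."""
    universe = sorted(t.tss_id for t in tss_set)
    missing = set(universe) - set(tf_binding_promoter.region_ids)
    if missing:
        raise ValidationError(
            f"TSSs missing from promoter TF-binding matrix: {sorted(missing)[:5]}"
        )
    tfm = _TRANSFORMS[transform]
    vals = tf_binding_promoter.df.loc[universe].to_numpy()
    return pd.DataFrame(
        tfm(vals), index=universe, columns=tf_binding_promoter.tf_ids
    )


def _fit_fold(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_test: np.ndarray,
    config: RegressionConfig,
    tf_ids: Sequence[str],
) -> tuple[np.ndarray, list[str]]:
    """Fit a penalty-tuned LASSO on one training fold; predict the test fold.

    Standardisation parameters and the penalty path are estimated from
    the training fold only.
    """
    scaler = StandardScaler()
    xt = scaler.fit_transform(x_train)
    xs = scaler.transform(x_test)
    inner = KFold(
        n_splits=min(config.inner_folds, len(y_train)),
        shuffle=True,
        random_state=config.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model = LassoCV(
            alphas=config.lambda_grid_size,
            cv=inner,
            max_iter=5000,
            random_state=config.seed,
        )
        model.fit(xt, y_train)
        coef = model.coef_.copy()
        nonzero = np.nonzero(coef)[0]
        if config.max_features and len(nonzero) > config.max_features:
            order = nonzero[np.argsort(-np.abs(coef[nonzero]))]
            keep = np.sort(order[: config.max_features])
            capped = Lasso(alpha=model.alpha_, max_iter=5000)
            capped.fit(xt[:, keep], y_train)
            pred = capped.predict(xs[:, keep])
            selected = [tf_ids[i] for i in keep[np.nonzero(capped.coef_)[0]]]
            return pred, selected
        pred = model.predict(xs)
    selected = [tf_ids[i] for i in nonzero]
    return pred, selected


def fit_lasso_cv(
    features: pd.DataFrame,
    response: Mapping[str, float] | pd.Series,
    config: RegressionConfig,
    model_label: str = "crm_map",
) -> RegressionResult:
    """Outer-CV LASSO: held-out R² per fold on transformed expression.

    The response is aligned to the feature rows on tss_id and transformed
    by ``config.transform`` before fitting.  Held-out R² is
    1 − SS_res/SS_tot with SS_tot about the held-out fold's own mean; a
    fold whose response is constant is skipped with a warning.
    """
    y_raw = pd.Series(response)
    if not set(features.index) <= set(y_raw.index):
        raise ValidationError("response does not cover all feature rows")
    y = _TRANSFORMS[config.transform](y_raw.loc[features.index].to_numpy(dtype=float))
    x = features.to_numpy(dtype=float)
    n = len(y)
    if n < 5 * config.n_folds:
        raise ValidationError(
            f"{n} observations < 5 x n_folds ({config.n_folds}); "
            "reduce n_folds or enlarge the TSS set"
        )
    outer = KFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    fold_r2: list[float] = []
    selected: list[list[str]] = []
    tf_ids = list(features.columns)
    for train_idx, test_idx in outer.split(x):
        y_test = y[test_idx]
        ss_tot = float(((y_test - y_test.mean()) ** 2).sum())
        if ss_tot == 0.0:
            warnings.warn(
                f"{model_label}: zero-variance response fold skipped", stacklevel=2
            )
            continue
        pred, sel = _fit_fold(x[train_idx], y[train_idx], x[test_idx], config, tf_ids)
        ss_res = float(((y_test - pred) ** 2).sum())
        fold_r2.append(1.0 - ss_res / ss_tot)
        selected.append(sel)
    return RegressionResult(model_label, fold_r2, selected, n)


def validate_map(
    cis_map: CisMap,
    control_maps: Sequence[CisMap],
    tf_binding: TFBindingMatrix,
    tf_binding_promoter: TFBindingMatrix | None,
    expression: Mapping[str, float] | pd.Series,
    tss_set: Iterable[TSS],
    config: RegressionConfig,
) -> dict:
    """Three-way comparison: map model vs promoter model vs control ensemble.

    All models are fit on the map's linked TSS set (identical for every
    control by construction) with the identical LASSO protocol, so
    differences in held-out R² reflect only which CRMs each map ties to
    each TSS.
    """
    tss_set = set(tss_set)
    linked = sorted(cis_map.linked_tss)
    if not linked:
        raise ValidationError("map has no links; nothing to validate")

    def _restrict(df: pd.DataFrame) -> pd.DataFrame:
        return df.loc[linked]

    feats_map = _restrict(
        build_features_from_map(
            cis_map, tf_binding, config.transform, config.aggregation
        )
    )
    results: dict = {}
    results["crm_map"] = fit_lasso_cv(feats_map, expression, config, "crm_map")

    if tf_binding_promoter is not None:
        linked_tss = [t for t in tss_set if t.tss_id in set(linked)]
        feats_prom = build_features_from_promoter(
            linked_tss, tf_binding_promoter, config.transform
        )
        results["promoter"] = fit_lasso_cv(
            feats_prom, expression, config, "promoter"
        )

    control_results: list[RegressionResult] = []
    for i, cmap in enumerate(control_maps):
        if cmap.linked_tss != cis_map.linked_tss:
            raise ValidationError(
                f"control map {i} does not share the real map's linked TSS set"
            )
        feats_c = _restrict(
            build_features_from_map(
                cmap, tf_binding, config.transform, config.aggregation
            )
        )
        control_results.append(
            fit_lasso_cv(feats_c, expression, config, f"control_replicate_{i}")
        )
    results["controls"] = control_results
    if control_results:
        means = [r.mean_r2 for r in control_results]
        results["control_mean_r2"] = float(np.mean(means))
        results["control_se_r2"] = (
            float(np.std(means, ddof=1) / math.sqrt(len(means)))
            if len(means) > 1
            else 0.0
        )
    return results
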