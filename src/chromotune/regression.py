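"""Spectral-tuning regression: feature tables, best subsets, BIC, LOO.

The statistical core of the pipeline.  Each pigment is summarised by
seven covariates extracted from its trajectory — the circular medians of
Torsions 1, 4, 14, 15 and Angle 3 (degrees) and the areas under the
RMSF profiles of the beta-ionone ring and of the full LYS+RET moiety
(nm*atom-index) — and the peak spectral sensitivity λ_max (nm) is
modelled as an ordinary least-squares linear function of a subset of
them.  Subsets are chosen by exhaustive best-subsets enumeration: for
each cardinality 1..7 the best models by residual sum of squares are
retained, and the pooled candidates are ranked by the Bayesian
Information Criterion

    BIC = n * ln(RSS / n) + (k + 1) * ln(n)

(Gaussian likelihood, additive constants dropped; k = number of
slopes).  The selected model is stress-tested by leave-one-out
cross-validation: each pigment is predicted by a model refitted without
it, and the pooled R² is the squared Pearson correlation between the
held-out predictions and the experimental values.

Two frozen reference models are shipped: the primary two-term model

    λ_max = 475.628 − 8.720 · median(Torsion 15) + 34.925 · AUC(RMSF_LYS+RET)

fitted on all 14 teleost Rh2 pigments, and a secondary model

    λ_max = 1190.6208 − 4.9097 · median(Torsion 4) + 2.9445 · median(Torsion 14)

fitted on the 11 non-cichlid pigments.  Torsion covariates are in
degrees and RMSF areas in nm*atom-index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fluctuation import kabsch_superpose, rmsf, rmsf_auc
from .geometry import circular_median, extract_angle_series
from .topology import ChromophoreTopology, Trajectory, default_topology

__all__ = [
    "COVARIATE_COLUMNS",
    "RegressionModel",
    "LooResult",
    "SingularDesignError",
    "FROZEN_PRIMARY",
    "FROZEN_SECONDARY",
    "build_feature_table",
    "ols_fit",
    "bic",
    "best_subsets",
    "loo_validate",
    "predict_lambda_max",
]

#: The seven default covariates, in canonical column order.
COVARIATE_COLUMNS: tuple[str, ...] = (
    "median_torsion1",
    "median_torsion4",
    "median_torsion14",
    "median_torsion15",
    "median_angle3",
    "auc_rmsf_ring",
    "auc_rmsf_lysret",
)

#: Descriptor medians entering the covariate set, mapped to column names.
_MEDIAN_DESCRIPTORS: dict[str, str] = {
    "Torsion 1": "median_torsion1",
    "Torsion 4": "median_torsion4",
    "Torsion 14": "median_torsion14",
    "Torsion 15": "median_torsion15",
    "Angle 3": "median_angle3",
}

_DEFAULT_UNITS: dict[str, str] = {
    "median_torsion1": "degree",
    "median_torsion4": "degree",
    "median_torsion14": "degree",
    "median_torsion15": "degree",
    "median_angle3": "degree",
    "auc_rmsf_ring": "nm*atom",
    "auc_rmsf_lysret": "nm*atom",
}


class SingularDesignError(ValueError):
    """Raised when an OLS design matrix is rank-deficient."""


class MissingFeatureError(KeyError):
    """Raised when a prediction lacks a covariate the model needs."""


@dataclass(frozen=True)
class RegressionModel:
    """Linear model λ_max = intercept + Σ coefficient_j · covariate_j."""

    intercept: float
    coefficients: Mapping[str, float]
    units: Mapping[str, str] = field(default_factory=dict)
    fit_stats: Mapping[str, float] | None = None
    provenance: str = "fitted"

    def __post_init__(self) -> None:
        object.__setattr__(self, "coefficients", dict(self.coefficients))
        object.__setattr__(self, "units", dict(self.units))
        if self.fit_stats is not None:
            object.__setattr__(self, "fit_stats", dict(self.fit_stats))

    @property
    def covariates(self) -> tuple[str, ...]:
        return tuple(self.coefficients)

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "units": dict(self.units),
            "fit_stats": dict(self.fit_stats) if self.fit_stats else None,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RegressionModel":
        return cls(
            intercept=float(d["intercept"]),
            coefficients=d["coefficients"],
            units=d.get("units", {}),
            fit_stats=d.get("fit_stats"),
            provenance=d.get("provenance", "fitted"),
        )


FROZEN_PRIMARY = RegressionModel(
    intercept=475.628,
    coefficients={"median_torsion15": -8.720, "auc_rmsf_lysret": 34.925},
    units={"median_torsion15": "degree", "auc_rmsf_lysret": "nm*atom"},
    provenance="frozen-paper-primary",
)

FROZEN_SECONDARY = RegressionModel(
    intercept=1190.6208,
    coefficients={"median_torsion4": -4.9097, "median_torsion14": 2.9445},
    units={"median_torsion4": "degree", "median_torsion14": "degree"},
    provenance="frozen-paper-secondary",
)


@dataclass
class LooResult:
    """Leave-one-out validation summary.

    ``predictions`` holds one held-out prediction per pigment (NaN for
    failed folds); ``pooled_r2`` is the squared Pearson correlation of
    held-out predictions vs experimental values; ``press_r2`` the
    alternative 1 − PRESS/TSS summary; ``fold_models`` the per-fold
    refitted models keyed by held-out pigment_id.
    """

    predictions: pd.Series
    pooled_r2: float
    press_r2: float
    fold_models: dict[str, RegressionModel]


def build_feature_table(
    trajectories: Iterable[Trajectory],
    topology: ChromophoreTopology | None = None,
    lambda_max: Mapping[str, float] | pd.Series | None = None,
    superpose: bool = True,
) -> pd.DataFrame:
    """Extract the seven-covariate feature row for each trajectory.

    Angle covariates are circular medians of the extracted series; RMSF
    areas are computed on the (optionally) superposed trajectory, over
    the topology's ``profile_order`` and its ring subset.  Pigments whose
    descriptor extraction fails are excluded with a warning.  If
    ``lambda_max`` is given, a ``lambda_max_nm`` column is joined on
    ``pigment_id``.
    """
    topology = topology or default_topology()
    rows = []
    for traj in trajectories:
        try:
            series = extract_angle_series(traj, topology)
            row: dict[str, float | str] = {"pigment_id": traj.pigment_id}
            for desc, col in _MEDIAN_DESCRIPTORS.items():
                row[col] = circular_median(series[desc])
            fitted = kabsch_superpose(traj) if superpose else traj
            profile = rmsf(fitted, topology.profile_order)
            row["auc_rmsf_lysret"] = rmsf_auc(profile)
            ring = [a for a in topology.profile_order if a in topology.ring_atoms]
            row["auc_rmsf_ring"] = rmsf_auc(profile.restrict(ring))
        except Exception as exc:  # noqa: BLE001 - flag and continue the batch
            warnings.warn(
                f"feature extraction failed for {traj.pigment_id!r}: {exc}"
            )
            continue
        rows.append(row)
    table = pd.DataFrame(
        rows, columns=["pigment_id", *COVARIATE_COLUMNS]
    )
    if lambda_max is not None:
        lam = pd.Series(dict(lambda_max)) if not isinstance(lambda_max, pd.Series) else lambda_max
        table["lambda_max_nm"] = table["pigment_id"].map(lam)
    return table


def _design(table: pd.DataFrame, subset: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    missing = [c for c in subset if c not in table.columns]
    if missing:
        raise KeyError(f"feature table lacks column(s) {missing}")
    x = np.column_stack(
        [np.ones(len(table))] + [table[c].to_numpy(dtype=float) for c in subset]
    )
    y = table["lambda_max_nm"].to_numpy(dtype=float)
    return x, y


def ols_fit(
    table: pd.DataFrame,
    subset: Sequence[str],
    response: str = "lambda_max_nm",
) -> RegressionModel:
    """Ordinary least squares of λ_max on a covariate subset.

    Solved by singular-value decomposition (``numpy.linalg.lstsq``)
    rather than the normal equations, for conditioning.  Records n, RSS,
    R² (defined as 0 when the response is constant) and BIC in
    ``fit_stats``.

    Raises
    ------
    SingularDesignError
        If the design matrix (intercept plus subset columns) is
        rank-deficient; the error names the offending columns.
    """
    subset = list(subset)
    if response != "lambda_max_nm":
        table = table.rename(columns={response: "lambda_max_nm"})
    x, y = _design(table, subset)
    n, p = x.shape
    if n < p + 1:
        raise SingularDesignError(
            f"{n} rows cannot identify {p} parameters plus residual variance"
        )
    rank = np.linalg.matrix_rank(x)
    if rank < p:
        raise SingularDesignError(
            f"design matrix is rank-deficient (rank {rank} < {p}); "
            f"check collinearity among {['intercept', *subset]}"
        )
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if tss == 0.0 else 1.0 - rss / tss
    k = len(subset)
    stats = {
        "n": n,
        "rss": rss,
        "r_squared": r2,
        "bic": _bic_value(n, rss, k),
    }
    return RegressionModel(
        intercept=float(beta[0]),
        coefficients={c: float(b) for c, b in zip(subset, beta[1:])},
        units={c: _DEFAULT_UNITS.get(c, "") for c in subset},
        fit_stats=stats,
        provenance="fitted",
    )


def _bic_value(n: int, rss: float, k: int) -> float:
    if rss <= 0.0:
        warnings.warn("RSS is zero (perfect fit); BIC reported as -inf")
        return float("-inf")
    return n * np.log(rss / n) + (k + 1) * np.log(n)


def bic(model: RegressionModel) -> float:
    """Bayesian Information Criterion of a fitted model.

    ``BIC = n·ln(RSS/n) + (k+1)·ln(n)`` with k the number of slopes;
    Gaussian likelihood, additive constants dropped (only differences
    matter for ranking).  Returns −inf with a warning when RSS = 0.
    """
    if model.fit_stats is None or "rss" not in model.fit_stats:
        raise ValueError("model has no fit statistics; fit it first")
    return _bic_value(
        int(model.fit_stats["n"]), float(model.fit_stats["rss"]), len(model.coefficients)
    )


def best_subsets(
    table: pd.DataFrame,
    nbest: int = 7,
    covariates: Sequence[str] | None = None,
) -> list[RegressionModel]:
    """Exhaustive best-subsets selection ranked by BIC.

    All covariate subsets of each cardinality 1..p are fitted; per
    cardinality the ``min(nbest, available)`` best models by RSS are
    retained; the retained pool is ranked by BIC ascending, ties broken
    lexicographically on the subset's covariate names.  Singular subsets
    are skipped with a warning, never aborting the enumeration.
    """
    covariates = list(covariates) if covariates is not None else list(COVARIATE_COLUMNS)
    if not covariates:
        raise ValueError("at least one covariate required")
    pool: list[RegressionModel] = []
    for k in range(1, len(covariates) + 1):
        fits = []
        for subset in combinations(covariates, k):
            try:
                fits.append(ols_fit(table, subset))
            except SingularDesignError as exc:
                warnings.warn(f"skipping subset {subset}: {exc}")
        fits.sort(key=lambda m: (m.fit_stats["rss"], m.covariates))
        pool.extend(fits[:nbest])
    pool.sort(key=lambda m: (m.fit_stats["bic"], m.covariates))
    return pool


def loo_validate(table: pd.DataFrame, subset: Sequence[str]) -> LooResult:
    """Leave-one-out validation of a covariate subset.

    For each pigment the model is refitted on the remaining rows and the
    held-out λ_max predicted; folds are ordered by pigment_id.  The
    pooled R² is the squared Pearson correlation between held-out
    predictions and experimental values over completed folds; the
    1 − PRESS/TSS variant is reported alongside.
    """
    subset = list(subset)
    ordered = table.sort_values("pigment_id").reset_index(drop=True)
    preds: dict[str, float] = {}
    fold_models: dict[str, RegressionModel] = {}
    for i in range(len(ordered)):
        pid = str(ordered.loc[i, "pigment_id"])
        train = ordered.drop(index=i)
        try:
            model = ols_fit(train, subset)
        except SingularDesignError as exc:
            warnings.warn(f"LOO fold for {pid!r} failed: {exc}")
            preds[pid] = float("nan")
            continue
        fold_models[pid] = model
        preds[pid] = predict_lambda_max(model, ordered.loc[i])
    pred = pd.Series(preds, name="loo_prediction_nm")
    obs = ordered.set_index("pigment_id")["lambda_max_nm"].astype(float)
    ok = pred.notna()
    if ok.sum() < 2:
        pooled = float("nan")
        press_r2 = float("nan")
    else:
        r = np.corrcoef(pred[ok], obs[pred[ok].index])[0, 1]
        pooled = float(r * r)
        press = float(((pred[ok] - obs[pred[ok].index]) ** 2).sum())
        tss = float(((obs[pred[ok].index] - obs[pred[ok].index].mean()) ** 2).sum())
        press_r2 = 0.0 if tss == 0.0 else 1.0 - press / tss
    return LooResult(
        predictions=pred, pooled_r2=pooled, press_r2=press_r2, fold_models=fold_models
    )


def predict_lambda_max(model: RegressionModel, features) -> float | pd.Series:
    """Predicted λ_max (nm) of a model on one feature row or a table.

    ``features`` may be a mapping, a pandas Series, or a DataFrame (in
    which case a Series of predictions is returned).  No clamping is
    applied.

    Raises
    ------
    MissingFeatureError
        If a covariate the model requires is absent.
    """
    if isinstance(features, pd.DataFrame):
        missing = [c for c in model.covariates if c not in features.columns]
        if missing:
            raise MissingFeatureError(f"feature table lacks covariate(s) {missing}")
        out = pd.Series(model.intercept, index=features.index, dtype=float)
        for c, b in model.coefficients.items():
            out = out + b * features[c].astype(float)
        return out.rename("lambda_max_pred_nm")
    value = float(model.intercept)
    for c, b in model.coefficients.items():
        try:
            v = features[c]
        except (KeyError, IndexError) as exc:
            raise MissingFeatureError(f"missing covariate {c!r}") from exc
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise MissingFeatureError(f"missing covariate {c!r}")
        value += b * float(v)
    return value
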