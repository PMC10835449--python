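"""LASSO decomposition of selection scores into codon-level predictors.

The unit of observation is the substitution class: one distinct
ref_codon -> alt_codon change (optionally stratified by mutational-context
class), whose response is the class's TRAPS score and whose predictors are
the induced ΔtAI, ΔCSC and ΔGC, the amino-acid degeneracy and the class's
mean transformed mutability.  Rows are weighted by class variant count;
predictors are standardised (zero weighted mean, unit weighted variance)
before the L1 fit, so selection is invariant to affine rescaling of any
predictor.  The penalty is chosen by cross-validation: the λ_min fit is
used for estimation and variance explained, the λ_min + 1SE fit for the
which-predictors-survive statements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold

from .calibration import CalibrationResult, _transform

PREDICTORS = ["delta_tai", "delta_csc", "delta_gc", "degeneracy", "mean_t_mu"]


def build_design_matrix(
    variants: pd.DataFrame,
    result: CalibrationResult,
    min_n: int = 20,
    stratify_context: bool = False,
) -> pd.DataFrame:
    """One row per substitution class with its TRAPS response and predictors.

    Classes with fewer than ``min_n`` variants are excluded (logged via the
    returned frame's ``n_excluded`` attr).
    """
    keys = ["ref_codon", "alt_codon"] + (["class_label"] if stratify_context else [])
    rows = []
    n_excluded = 0
    for key, sub in variants.groupby(keys, sort=True):
        if len(sub) < min_n:
            n_excluded += 1
            continue
        s = result.score_subset(sub)
        key = key if isinstance(key, tuple) else (key,)
        rows.append(
            {
                **dict(zip(keys, key)),
                "n": len(sub),
                "response": s.score,
                "delta_tai": float(sub["delta_tai"].iloc[0]),
                "delta_csc": float(sub["delta_csc"].iloc[0]),
                "delta_gc": float(sub["delta_gc"].iloc[0]),
                "degeneracy": float(sub["degeneracy"].iloc[0]),
                "mean_t_mu": float(
                    _transform(sub["mu"].to_numpy(), result.transform).mean()
                ),
            }
        )
    if len(rows) < 10:
        raise ValueError(f"only {len(rows)} usable substitution classes (need >= 10)")
    out = pd.DataFrame(rows)
    out.attrs["n_excluded"] = n_excluded
    return out


@dataclass
class LassoFit:
    """A cross-validated L1 fit: λ path, coefficients and selected set."""

    alphas: np.ndarray
    alpha_min: float
    alpha_1se: float
    coef_min: dict[str, float]
    coef_1se: dict[str, float]
    intercept_min: float
    r_squared: float
    cv_folds: int
    seed: int
    predictors: list[str] = field(default_factory=lambda: list(PREDICTORS))

    @property
    def selected(self) -> list[str]:
        """Predictors surviving at the λ_min + 1SE penalty."""
        return [p for p in self.predictors if self.coef_1se[p] != 0.0]

    @property
    def selected_at_min(self) -> list[str]:
        return [p for p in self.predictors if self.coef_min[p] != 0.0]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "alphas": self.alphas.tolist(),
                    "alpha_min": self.alpha_min,
                    "alpha_1se": self.alpha_1se,
                    "coef_min": self.coef_min,
                    "coef_1se": self.coef_1se,
                    "intercept_min": self.intercept_min,
                    "r_squared": self.r_squared,
                    "cv_folds": self.cv_folds,
                    "seed": self.seed,
                    "selected": self.selected,
                },
                fh,
                indent=1,
            )


def _standardize(
    X: np.ndarray, w: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    wn = w / w.sum()
    mean = wn @ X
    var = wn @ (X - mean) ** 2
    sd = np.sqrt(var)
    if (sd == 0).any():
        raise ValueError("constant predictor column")
    return (X - mean) / sd, mean, sd


def fit_lasso(
    matrix: pd.DataFrame,
    cv_folds: int = 10,
    seed: int = 0,
    predictors: list[str] | None = None,
) -> LassoFit:
    """Weighted cross-validated LASSO of the class TRAPS scores.

    Coefficients are reported on the standardised predictor scale.
    """
    preds = predictors or PREDICTORS
    if len(preds) < 2:
        raise ValueError("need at least 2 predictors")
    if cv_folds < 3:
        raise ValueError("need at least 3 CV folds")
    y = matrix["response"].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant response")
    w = matrix["n"].to_numpy(dtype=float)
    X, _, _ = _standardize(matrix[preds].to_numpy(dtype=float), w)

    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    lcv = LassoCV(cv=cv, alphas=100, max_iter=50_000)
    lcv.fit(X, y, sample_weight=w)
    alphas = lcv.alphas_
    mse = lcv.mse_path_.mean(axis=1)
    se = lcv.mse_path_.std(axis=1, ddof=1) / np.sqrt(cv_folds)
    i_min = int(np.argmin(mse))
    threshold = mse[i_min] + se[i_min]
    # largest penalty whose CV error is within one SE of the minimum
    i_1se = int(np.min(np.nonzero(mse <= threshold)[0]))
    alpha_min = float(alphas[i_min])
    alpha_1se = float(alphas[i_1se])

    def _fit(alpha: float) -> Lasso:
        m = Lasso(alpha=alpha, max_iter=50_000)
        m.fit(X, y, sample_weight=w)
        return m

    m_min = _fit(alpha_min)
    m_1se = _fit(alpha_1se)
    fit = LassoFit(
        alphas=alphas,
        alpha_min=alpha_min,
        alpha_1se=alpha_1se,
        coef_min=dict(zip(preds, (float(c) for c in m_min.coef_))),
        coef_1se=dict(zip(preds, (float(c) for c in m_1se.coef_))),
        intercept_min=float(m_min.intercept_),
        r_squared=0.0,
        cv_folds=cv_folds,
        seed=seed,
        predictors=list(preds),
    )
    fit.r_squared = variance_explained(fit, matrix)
    return fit


def variance_explained(fit: LassoFit, matrix: pd.DataFrame) -> float:
    """Weighted R^2 of the λ_min fit on the full design matrix."""
    preds = fit.predictors
    missing = [p for p in preds if p not in matrix.columns]
    if missing:
        raise ValueError(f"matrix lacks predictor column(s) {missing}")
    y = matrix["response"].to_numpy(dtype=float)
    w = matrix["n"].to_numpy(dtype=float)
    X, _, _ = _standardize(matrix[preds].to_numpy(dtype=float), w)
    yhat = fit.intercept_min + X @ np.array([fit.coef_min[p] for p in preds])
    wn = w / w.sum()
    ybar = wn @ y
    ss_res = wn @ (y - yhat) ** 2
    ss_tot = wn @ (y - ybar) ** 2
    if ss_tot == 0:
        raise ValueError("constant response")
    return float(max(0.0, 1.0 - ss_res / ss_tot))


def fit_at_alpha(
    matrix: pd.DataFrame, alpha: float, predictors: list[str] | None = None
) -> dict[str, float]:
    """Single weighted L1 fit at a fixed penalty (standardised coefficients)."""
    preds = predictors or PREDICTORS
    y = matrix["response"].to_numpy(dtype=float)
    w = matrix["n"].to_numpy(dtype=float)
    X, _, _ = _standardize(matrix[preds].to_numpy(dtype=float), w)
    m = Lasso(alpha=alpha, max_iter=200_000, tol=1e-10)
    m.fit(X, y, sample_weight=w)
    return dict(zip(preds, (float(c) for c in m.coef_)))
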