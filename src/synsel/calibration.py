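"""Singleton-proportion calibration and selection scores (MAPS / TRAPS).

The mutability-adjusted proportion of singletons (MAPS) measures purifying
selection on a class of variants as the excess of singletons (allele count
1) over a neutral expectation.  The expectation comes from a weighted
linear model fitted on a neutral calibration set: per mutational context c
the observed proportion of singletons ps_c is regressed on the context's
relative mutability mu_c with weights n_c (the number of variants in the
context).  The score of a variant subset S is then

    score(S) = (observed singletons - expected singletons) / |S|

where the expectation sums the fitted per-context proportions over the
subset's context composition.  TRAPS is the same model with the regressor
sqrt(mu) instead of mu, which removes the bias against low-mutability
(transversion) contexts that the identity-regressor fit exhibits once
mutational recurrence saturates the most mutable contexts.

The public surface follows the statsmodels idiom: build a
:class:`SingletonCalibration` model from a variant table, ``fit()`` it and
use the returned :class:`CalibrationResult` for scoring, group scores,
Welch contrasts and the mutability-quartile diagnostic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.proportion import proportion_confint

from .mutability import MutabilityTable

TRANSFORMS = ("identity", "sqrt")

CONTEXT_KEY = ["context3", "alt", "methylation_bin"]


def _transform(mu: np.ndarray, transform: str) -> np.ndarray:
    if transform == "identity":
        return np.asarray(mu, dtype=float)
    if transform == "sqrt":
        return np.sqrt(np.asarray(mu, dtype=float))
    raise ValueError(f"unknown transform {transform!r}; expected one of {TRANSFORMS}")


def aggregate_contexts(
    variants: pd.DataFrame, mut_table: MutabilityTable | None = None
) -> pd.DataFrame:
    """Collapse a variant table to one row per mutational context.

    Returns columns context3, alt, methylation_bin, n_variants, n_singletons,
    ps, mu (and class_label when available).  ``mu`` is taken from the
    variant table's own ``mu`` column if present, else looked up.
    """
    if len(variants) == 0:
        raise ValueError("cannot aggregate an empty variant table")
    df = variants
    if "mu" not in df.columns:
        if mut_table is None:
            raise ValueError("variants carry no 'mu' column and no table was given")
        df = df.copy()
        df["mu"] = mut_table.lookup(
            df["context3"].to_numpy(), df["alt"].to_numpy(),
            df["methylation_bin"].to_numpy(),
        )
    g = df.groupby(CONTEXT_KEY, sort=True, observed=True)
    agg = g.agg(
        n_variants=("is_singleton", "size"),
        n_singletons=("is_singleton", "sum"),
        mu=("mu", "first"),
    ).reset_index()
    if "class_label" in df.columns:
        agg = agg.merge(
            df[CONTEXT_KEY + ["class_label"]].drop_duplicates(CONTEXT_KEY),
            on=CONTEXT_KEY,
            how="left",
        )
    agg["n_singletons"] = agg["n_singletons"].astype(int)
    agg["ps"] = agg["n_singletons"] / agg["n_variants"]
    return agg


@dataclass(frozen=True)
class SelectionScore:
    """A MAPS/TRAPS value with its Wilson confidence interval and counts."""

    score: float
    ci_low: float
    ci_high: float
    n_variants: int
    n_singletons: int
    expected_singletons: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ContrastResult:
    """A Welch (or rank) two-group comparison of selection scores."""

    diff: float
    statistic: float
    p: float
    p_adjusted: float
    method: str
    ci_low: float = np.nan
    ci_high: float = np.nan

    def to_dict(self) -> dict:
        return asdict(self)


def wilson_interval(count: int, nobs: int, alpha: float = 0.05) -> tuple[float, float]:
    """95% Wilson score interval for a binomial proportion."""
    lo, hi = proportion_confint(count, nobs, alpha=alpha, method="wilson")
    return float(lo), float(hi)


class SingletonCalibration:
    """Weighted linear model of per-context singleton proportion on mutability.

    Parameters
    ----------
    variants
        Variant table with context keys, an ``is_singleton`` column and
        either a ``mu`` column or a mutability table to look it up from.
    transform
        ``"identity"`` gives the classic MAPS calibration, ``"sqrt"`` the
        recalibrated TRAPS model.
    mut_table
        Optional :class:`~synsel.mutability.MutabilityTable`.
    """

    def __init__(
        self,
        variants: pd.DataFrame,
        transform: str = "sqrt",
        mut_table: MutabilityTable | None = None,
    ) -> None:
        if transform not in TRANSFORMS:
            raise ValueError(f"transform must be one of {TRANSFORMS}")
        self.transform = transform
        if {"n_variants", "n_singletons"} <= set(variants.columns):
            # already aggregated per context
            agg = variants.copy()
            if "ps" not in agg.columns:
                agg["ps"] = agg["n_singletons"] / agg["n_variants"]
            self.aggregates = agg
        else:
            self.aggregates = aggregate_contexts(variants, mut_table)
        if (self.aggregates["mu"] <= 0).any():
            raise ValueError("mutabilities must be positive")

    def fit(self) -> "CalibrationResult":
        agg = self.aggregates
        t_mu = _transform(agg["mu"].to_numpy(), self.transform)
        if len(np.unique(t_mu)) < 2:
            raise ValueError("calibration needs >=2 distinct mutability values")
        X = sm.add_constant(t_mu)
        wls = sm.WLS(agg["ps"].to_numpy(), X, weights=agg["n_variants"].to_numpy())
        res = wls.fit()
        alpha, beta = float(res.params[0]), float(res.params[1])
        fitted = np.clip(alpha + beta * t_mu, 0.0, 1.0)
        return CalibrationResult(
            transform=self.transform,
            intercept=alpha,
            slope=beta,
            aggregates=agg.assign(p_hat=fitted, residual=agg["ps"] - fitted),
            model=self,
        )


@dataclass
class CalibrationResult:
    """Fitted calibration: coefficients plus scoring and contrast methods."""

    transform: str
    intercept: float
    slope: float
    aggregates: pd.DataFrame
    model: SingletonCalibration | None = field(default=None, repr=False)
    min_context_n: int = 20  # contexts below this are dropped from Welch tests

    # ------------------------------------------------------------------ predict
    def predict(self, mu: np.ndarray | float) -> np.ndarray:
        """Expected singleton proportion for mutability ``mu`` (clamped to [0,1])."""
        t = _transform(np.atleast_1d(np.asarray(mu, dtype=float)), self.transform)
        return np.clip(self.intercept + self.slope * t, 0.0, 1.0)

    # ------------------------------------------------------------------ scoring
    def score_subset(self, variants: pd.DataFrame) -> SelectionScore:
        """MAPS/TRAPS of a variant subset: scaled singleton excess with Wilson CI.

        The expected singleton count treats the calibration as fixed; the
        confidence interval is the Wilson interval of the observed singleton
        proportion shifted by the expected proportion.
        """
        if len(variants) == 0:
            raise ValueError("cannot score an empty subset")
        n = int(len(variants))
        obs = int(variants["is_singleton"].sum())
        expected = float(self.predict(variants["mu"].to_numpy()).sum())
        score = (obs - expected) / n
        lo, hi = wilson_interval(obs, n)
        shift = expected / n
        return SelectionScore(
            score=float(score),
            ci_low=float(lo - shift),
            ci_high=float(hi - shift),
            n_variants=n,
            n_singletons=obs,
            expected_singletons=expected,
        )

    def score_by_group(
        self, variants: pd.DataFrame, by: str, min_group_n: int = 20
    ) -> pd.DataFrame:
        """One SelectionScore row per level of column ``by``.

        Rows with a missing grouping key are dropped (and counted in the
        ``n_dropped`` attribute of the returned frame); groups smaller than
        ``min_group_n`` are flagged, not removed.
        """
        keyed = variants[variants[by].notna()]
        n_dropped = len(variants) - len(keyed)
        if len(keyed) == 0:
            raise ValueError(f"no rows with a defined {by!r} key")
        rows = []
        for name, sub in keyed.groupby(by, sort=True, observed=True):
            s = self.score_subset(sub)
            rows.append({by: name, **s.to_dict(), "flagged_small": s.n_variants < min_group_n})
        out = pd.DataFrame(rows)
        out.attrs["n_dropped"] = n_dropped
        return out

    # ---------------------------------------------------------------- contrasts
    def _context_residuals(self, variants: pd.DataFrame) -> pd.DataFrame:
        agg = aggregate_contexts(variants)
        agg["p_hat"] = self.predict(agg["mu"].to_numpy())
        agg["residual"] = agg["ps"] - agg["p_hat"]
        return agg

    def contrast(
        self,
        group_a: pd.DataFrame,
        group_b: pd.DataFrame,
        family_size: int = 1,
        min_context_n: int | None = None,
    ) -> ContrastResult:
        """Welch two-sample t test between two variant groups.

        The observation unit is the per-context residual singleton proportion
        (observed minus calibrated), restricted to contexts with at least
        ``min_context_n`` variants (default ``self.min_context_n``); p is
        Bonferroni-adjusted by ``family_size``.
        """
        if len(group_a) == 0 or len(group_b) == 0:
            raise ValueError("both groups must be non-empty")
        min_n = self.min_context_n if min_context_n is None else min_context_n
        res_a = self._context_residuals(group_a)
        res_b = self._context_residuals(group_b)
        ra = res_a.loc[res_a["n_variants"] >= min_n, "residual"]
        rb = res_b.loc[res_b["n_variants"] >= min_n, "residual"]
        if len(ra) < 2 or len(rb) < 2:
            raise ValueError(
                f"need >=2 contexts with n >= {min_n} in each group"
            )
        t, p = stats.ttest_ind(ra, rb, equal_var=False)
        sa, sb = self.score_subset(group_a), self.score_subset(group_b)
        diff = sa.score - sb.score
        hw = np.hypot(
            (sa.ci_high - sa.ci_low) / 2.0, (sb.ci_high - sb.ci_low) / 2.0
        )
        return ContrastResult(
            diff=float(diff),
            statistic=float(t),
            p=float(p),
            p_adjusted=float(min(1.0, p * family_size)),
            method="welch-t (per-context residuals)",
            ci_low=float(diff - hw),
            ci_high=float(diff + hw),
        )

    # -------------------------------------------------------------- diagnostics
    def mutability_quartile_diagnostic(self, variants: pd.DataFrame) -> pd.DataFrame:
        """Selection score per variant-weighted mutability quartile.

        Quartile boundaries are computed on the per-variant mu distribution so
        each quartile holds ~25% of variants; on data used for calibration all
        four scores should sit at zero when the calibration transform matches
        the saturation law of the data.
        """
        mu = variants["mu"].to_numpy()
        if len(np.unique(mu)) < 2:
            raise ValueError("degenerate mutability distribution")
        edges = np.quantile(mu, [0.25, 0.5, 0.75])
        labels = ["lowest", "lower", "higher", "highest"]
        idx = np.searchsorted(edges, mu, side="right")
        rows = []
        for q, label in enumerate(labels):
            sub = variants[idx == q]
            if len(sub) == 0:
                continue
            s = self.score_subset(sub)
            rows.append({"quartile": label, **s.to_dict()})
        return pd.DataFrame(rows)

    # ------------------------------------------------------------------ summary
    def summary(self) -> str:
        agg = self.aggregates
        name = "TRAPS" if self.transform == "sqrt" else "MAPS"
        lines = [
            f"Singleton-proportion calibration ({name})",
            "=" * 46,
            f"transform:        {self.transform}",
            f"intercept (a0):   {self.intercept: .6f}",
            f"slope (a1):       {self.slope: .6f}",
            f"contexts:         {len(agg)}",
            f"variants:         {int(agg['n_variants'].sum())}",
            f"singletons:       {int(agg['n_singletons'].sum())}",
            f"weighted resid.:  {self.weighted_residual_sum(): .3e}",
        ]
        return "\n".join(lines)

    def weighted_residual_sum(self) -> float:
        agg = self.aggregates
        return float((agg["n_variants"] * agg["residual"]).sum())

    # -------------------------------------------------------------- persistence
    def to_json(self, path) -> None:
        payload = {
            "format_version": 1,
            "transform": self.transform,
            "intercept": self.intercept,
            "slope": self.slope,
            "aggregates": self.aggregates.drop(
                columns=[c for c in ("class_label",) if c not in self.aggregates],
                errors="ignore",
            ).to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CalibrationResult":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            transform=payload["transform"],
            intercept=float(payload["intercept"]),
            slope=float(payload["slope"]),
            aggregates=pd.DataFrame(payload["aggregates"]),
        )


def fit_calibration(
    variants_or_aggregates: pd.DataFrame,
    transform: str = "sqrt",
    mut_table: MutabilityTable | None = None,
) -> CalibrationResult:
    """Functional wrapper: fit the calibration on a variant table."""
    return SingletonCalibration(
        variants_or_aggregates, transform=transform, mut_table=mut_table
    ).fit()
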