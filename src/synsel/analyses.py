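"""Comparative analyses on annotated synonymous variants.

Each function is a pure function of (variant table, fitted calibration)
returning a tidy DataFrame: optimality contrasts per amino acid, GERP
rank tests, saturation of optimality-reducing variants, constrained-gene
scores, SpliceAI splice classes, predictor quartiles and ClinVar-like
group differences.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import CalibrationResult, wilson_interval

log = logging.getLogger(__name__)

SPLICE_CLASSES = {
    "donor_loss": "spliceai_donor_loss",
    "donor_gain": "spliceai_donor_gain",
    "acceptor_loss": "spliceai_acceptor_loss",
    "acceptor_gain": "spliceai_acceptor_gain",
}


def _two_sided(variants: pd.DataFrame) -> pd.DataFrame:
    return variants[variants["optimality_label"].isin(["reducing", "increasing"])]


def optimality_contrast_by_aa(
    variants: pd.DataFrame, result: CalibrationResult
) -> pd.DataFrame:
    """Score(reducing) - score(increasing) per amino acid, with Welch tests.

    Neutral-labelled variants (ΔCSC = 0) are excluded; amino acids with an
    empty side are skipped.  The Bonferroni family is the set of amino
    acids reported.
    """
    df = _two_sided(variants)
    rows = []
    for aa, sub in df.groupby("amino_acid", sort=True):
        red = sub[sub["optimality_label"] == "reducing"]
        inc = sub[sub["optimality_label"] == "increasing"]
        if len(red) == 0 or len(inc) == 0:
            log.info("skipping %s: one optimality side empty", aa)
            continue
        rows.append((aa, red, inc))
    out = []
    for aa, red, inc in rows:
        try:
            # per-amino-acid groups are small; keep contexts with >=5 variants
            c = result.contrast(red, inc, family_size=len(rows), min_context_n=5)
        except ValueError as exc:
            log.info("skipping %s: %s", aa, exc)
            continue
        sr, si = result.score_subset(red), result.score_subset(inc)
        out.append(
            {
                "amino_acid": aa,
                "n_reducing": len(red),
                "n_increasing": len(inc),
                "score_reducing": sr.score,
                "score_increasing": si.score,
                **c.to_dict(),
            }
        )
    return pd.DataFrame(out)


def gerp_contrast(
    variants: pd.DataFrame, two_codon_only: bool = True
) -> pd.DataFrame:
    """One-sided Mann-Whitney U test of GERP: reducing > increasing, per amino acid.

    Optionally restricted to two-codon amino acids (the cleanest dichotomy);
    p values are Bonferroni-adjusted across the amino acids tested.
    """
    df = _two_sided(variants)
    df = df[df["gerp"].notna()]
    if len(df) == 0:
        raise ValueError("no rows carry a GERP score")
    if two_codon_only:
        df = df[df["degeneracy"] == 2]
    groups = []
    for aa, sub in df.groupby("amino_acid", sort=True):
        g_red = sub.loc[sub["optimality_label"] == "reducing", "gerp"]
        g_inc = sub.loc[sub["optimality_label"] == "increasing", "gerp"]
        if len(g_red) == 0 or len(g_inc) == 0:
            continue
        groups.append((aa, g_red, g_inc))
    out = []
    for aa, g_red, g_inc in groups:
        u, p = stats.mannwhitneyu(g_red, g_inc, alternative="greater")
        out.append(
            {
                "amino_acid": aa,
                "n_reducing": len(g_red),
                "n_increasing": len(g_inc),
                "median_reducing": float(g_red.median()),
                "median_increasing": float(g_inc.median()),
                "statistic": float(u),
                "p": float(p),
                "p_adjusted": float(min(1.0, p * len(groups))),
                "method": "mann-whitney-u one-sided (reducing > increasing)",
            }
        )
    return pd.DataFrame(out)


def saturation_by_aa(
    variants: pd.DataFrame, change_universe: pd.DataFrame
) -> pd.DataFrame:
    """Observed vs expected fraction of optimality-reducing variants.

    Restricted to two-codon amino acids.  The observed fraction is
    reducing / (reducing + increasing) among observed variants, with a
    Wilson CI; the expected baseline is the mutability-weighted share of
    optimality-reducing opportunities among all possible synonymous changes
    for that amino acid in the sequence universe (``change_universe`` must
    carry amino_acid, optimality_label and mu columns, one row per possible
    change).
    """
    obs = _two_sided(variants)
    obs = obs[obs["degeneracy"] == 2]
    uni = change_universe[
        change_universe["optimality_label"].isin(["reducing", "increasing"])
    ]
    out = []
    for aa, sub in obs.groupby("amino_acid", sort=True):
        n_red = int((sub["optimality_label"] == "reducing").sum())
        n_tot = len(sub)
        if n_tot == 0:
            continue
        lo, hi = wilson_interval(n_red, n_tot)
        u = uni[uni["amino_acid"] == aa]
        w_red = u.loc[u["optimality_label"] == "reducing", "mu"].sum()
        w_all = u["mu"].sum()
        out.append(
            {
                "amino_acid": aa,
                "n_reducing": n_red,
                "n_total": n_tot,
                "observed_fraction": n_red / n_tot,
                "ci_low": lo,
                "ci_high": hi,
                "expected_fraction": float(w_red / w_all) if w_all > 0 else np.nan,
            }
        )
    return pd.DataFrame(out)


def constrained_gene_scores(
    variants: pd.DataFrame,
    result: CalibrationResult,
    loeuf_column: str = "loeuf",
    constrained_frac: float = 0.30,
) -> pd.DataFrame:
    """Selection scores in the most constrained genes vs all genes.

    Constrained genes are those in the lowest ``constrained_frac`` of the
    per-gene LOEUF distribution; scores are reported per optimality label
    for both the constrained set and the full set.
    """
    df = variants[variants[loeuf_column].notna()]
    if len(df) == 0:
        raise ValueError("no rows carry a LOEUF value")
    per_gene = df.groupby("gene_id")[loeuf_column].first().sort_values(kind="stable")
    n_sel = int(np.ceil(constrained_frac * len(per_gene)))
    constrained_genes = set(per_gene.index[:n_sel])
    rows = []
    for label in ("reducing", "increasing", "all"):
        sub = df if label == "all" else df[df["optimality_label"] == label]
        if len(sub) == 0:
            continue
        con = sub[sub["gene_id"].isin(constrained_genes)]
        for gene_set, d in (("constrained", con), ("all_genes", sub)):
            if len(d) == 0:
                continue
            s = result.score_subset(d)
            rows.append({"optimality_label": label, "gene_set": gene_set, **s.to_dict()})
    return pd.DataFrame(rows)


def splice_class_scores(
    variants: pd.DataFrame,
    result: CalibrationResult,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Selection scores for high- vs low-SpliceAI variants in each class.

    For each of donor/acceptor x loss/gain independently, variants with a
    delta score >= ``threshold`` are compared against those below it, with
    a Welch contrast; rows with no SpliceAI annotation are excluded.
    """
    cols = list(SPLICE_CLASSES.values())
    annotated = variants[variants[cols].notna().all(axis=1)]
    if len(annotated) == 0:
        raise ValueError("no rows carry SpliceAI annotations")
    rows = []
    for cls, col in SPLICE_CLASSES.items():
        high = annotated[annotated[col] >= threshold]
        low = annotated[annotated[col] < threshold]
        if len(high) == 0 or len(low) == 0:
            log.info("splice class %s has an empty side", cls)
            continue
        # high-score groups are small; keep every context with >=3 variants
        c = result.contrast(high, low, min_context_n=3)
        for side, d in (("high", high), ("low", low)):
            s = result.score_subset(d)
            rows.append(
                {
                    "splice_class": cls,
                    "side": side,
                    **s.to_dict(),
                    "p": c.p if side == "high" else np.nan,
                    "p_adjusted": c.p_adjusted if side == "high" else np.nan,
                }
            )
    return pd.DataFrame(rows)


def predictor_quartile_scores(
    variants: pd.DataFrame,
    result: CalibrationResult,
    score_column: str,
) -> pd.DataFrame:
    """Selection score per quartile of an external pathogenicity score.

    Quartiles are computed on the annotated subset only; ties are broken by
    stable rank so the four bins are as equal as the data allow.
    """
    df = variants[variants[score_column].notna()]
    if len(df) == 0:
        raise ValueError(f"all rows are missing {score_column!r}")
    if df[score_column].nunique() < 4:
        raise ValueError(f"fewer than 4 distinct {score_column!r} values")
    ranks = df[score_column].rank(method="first")
    q = np.minimum((4 * (ranks - 1) / len(df)).astype(int), 3)
    out = []
    for i, name in enumerate(["Q1", "Q2", "Q3", "Q4"]):
        sub = df[q == i]
        s = result.score_subset(sub)
        out.append(
            {
                "quartile": name,
                "score_min": float(sub[score_column].min()),
                "score_max": float(sub[score_column].max()),
                **s.to_dict(),
            }
        )
    return pd.DataFrame(out)


def clinvar_group_scores(
    variants: pd.DataFrame, result: CalibrationResult
) -> pd.DataFrame:
    """Score differences of ClinVar-like groups relative to benign-like.

    Pathogenic and likely-pathogenic merge into "pathogenic-like", benign
    and likely-benign into "benign-like"; differences use benign-like as
    the reference.
    """
    merge = {
        "pathogenic": "pathogenic-like", "likely pathogenic": "pathogenic-like",
        "pathogenic-like": "pathogenic-like",
        "benign": "benign-like", "likely benign": "benign-like",
        "benign-like": "benign-like",
        "VUS": "VUS", "none": "none",
    }
    df = variants.copy()
    df["clinvar_group"] = df["clinvar_label"].map(lambda x: merge.get(x, "none"))
    bench = df[df["clinvar_group"] == "benign-like"]
    if len(bench) == 0:
        raise ValueError("benign-like reference group is empty")
    s_ref = result.score_subset(bench)
    rows = []
    for grp in ("benign-like", "VUS", "pathogenic-like"):
        sub = df[df["clinvar_group"] == grp]
        if len(sub) == 0:
            continue
        s = result.score_subset(sub)
        rows.append(
            {
                "clinvar_group": grp,
                **s.to_dict(),
                "diff_vs_benign": s.score - s_ref.score,
            }
        )
    return pd.DataFrame(rows)
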