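"""Synthetic gnomAD-like data with known ground truth.

The generator emulates, at desk scale, the inputs of a singleton-based
constraint analysis: coding genes drawn from a codon-usage law, planted
per-codon CSC/tAI tables, a trinucleotide mutability table whose CpG
transitions are ~100-fold more mutable than other changes, and a variant
table in which every possible synonymous change is observed with a
mutability-dependent (saturating) probability and is a singleton with
probability

    P(singleton) = clamp(a0 + a1 * sqrt(mu) + delta(class))

The affine-in-sqrt(mu) neutral curve mimics the saturation/recurrence
regime of a large exome cohort: the sqrt-regressor calibration (TRAPS) is
then correctly specified while the identity-regressor calibration (MAPS)
is misspecified and shows the classic low-mutability bias.  ``delta``
plants class-specific selection: weights on -ΔtAI, -ΔCSC and -ΔGC plus
offsets for high SpliceAI classes, ClinVar labels, constrained (low
LOEUF) genes and an optional random planted subset.  All quantities are
deterministic functions of the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .codons import (
    STANDARD_TABLE,
    CodonTable,
    CodonMetricSet,
    compute_tai,
    enumerate_synonymous_changes,
    revcomp,
)
from .mutability import MutabilityTable, all_context_keys, CPG_TRANSITION
from . import ingest

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; the seed fully determines the output."""

    seed: int = 0
    n_genes: int = 200
    codons_per_gene: int = 300

    # mutability law (relative rates, log-uniform per class; CpG transitions
    # are ~100x the non-CpG centre, as in human germline data)
    mu_transversion: tuple[float, float] = (0.2, 0.6)
    mu_transition: tuple[float, float] = (0.6, 2.0)
    mu_cpg: tuple[float, float] = (30.0, 120.0)
    meth_scale: tuple[float, float, float] = (0.25, 0.55, 1.0)
    meth_probs: tuple[float, float, float] = (0.15, 0.25, 0.60)

    # neutral singleton curve P = a0 + a1 * sqrt(mu)
    a0: float = 0.62
    a1: float = -0.045
    eps: float = 0.01

    # saturating observation model: P(observed) = 1 - exp(-rate * mu)
    sampling_rate: float = 1.0

    # selection weights on (-delta) of each codon metric
    w_tai: float = 0.03
    w_csc: float = 0.05
    w_gc: float = 0.015

    # splice classes (SpliceAI-like delta scores)
    splice_high_frac: float = 0.01      # per class, fraction with score >= 0.5
    splice_loss_offset: float = 0.10
    splice_gain_offset: float = 0.03
    spliceai_missing_frac: float = 0.10

    # ClinVar-like labels
    clinvar_fracs: tuple[float, float, float] = (0.02, 0.01, 0.002)  # benign-like, VUS, pathogenic-like
    clinvar_offsets: tuple[float, float, float] = (0.0, 0.02, 0.06)

    # constrained genes
    loeuf_constrained_frac: float = 0.30
    loeuf_boost: float = 0.02

    # optional random planted subset (for offset-recovery experiments)
    planted_frac: float = 0.0
    planted_delta: float = 0.0

    # external score columns
    gerp_reducing_shift: float = 1.0
    gerp_sd: float = 1.0
    cadd_slope: float = 100.0
    cadd_sd: float = 3.0
    synvep_slope: float = 4.0
    synvep_sd: float = 0.15

    # mRNA half-life / codon frequency matrix for CSC
    n_transcripts: int = 500

    # non-synonymous decoy rows written to fixtures to exercise filtering
    decoy_frac: float = 0.05

    an_total: int = 251496

    def neutral(self, **overrides) -> "SimulationConfig":
        """Copy of this config with every planted selection effect zeroed."""
        zeroed = dict(
            w_tai=0.0, w_csc=0.0, w_gc=0.0,
            splice_loss_offset=0.0, splice_gain_offset=0.0,
            clinvar_offsets=(0.0, 0.0, 0.0), loeuf_boost=0.0,
            planted_frac=0.0, planted_delta=0.0, gerp_reducing_shift=0.0,
        )
        zeroed.update(overrides)
        return dataclasses.replace(self, **zeroed)

    def validate(self) -> None:
        if self.n_genes < 1 or self.codons_per_gene < 1:
            raise ValueError("genes must have positive length")
        if not 0 < self.eps < 0.5:
            raise ValueError("eps must be in (0, 0.5)")
        if self.n_transcripts < 3:
            raise ValueError("need at least 3 transcripts for CSC")


@dataclass
class GroundTruth:
    """Planted quantities every recovery test checks against."""

    config: SimulationConfig
    csc: pd.Series
    tai: pd.Series
    class_offsets: dict
    planted_index: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))


@dataclass
class SimulatedReference:
    codon_idx: np.ndarray  # (n_genes, codons_per_gene) indices into sense_codons
    gene_ids: list[str]
    usage: pd.Series       # genome-wide per-codon counts

    @property
    def n_codons(self) -> int:
        return int(self.codon_idx.size)


@dataclass
class SimulatedMetrics:
    metrics: CodonMetricSet
    trna_copies: dict[str, int]
    half_lives: pd.Series
    freq_matrix: pd.DataFrame
    usage: pd.Series


def default_usage_weights(table: CodonTable = STANDARD_TABLE) -> pd.Series:
    """Per-codon sampling weights with a within-amino-acid usage bias.

    Amino-acid mass is proportional to degeneracy (uniform over codons
    before bias); within each amino acid the fractions are skewed, with
    glutamine given an extreme bias to emulate its outlier usage in the
    human genome.
    """
    frac = {
        1: [1.0],
        2: [0.67, 0.33],
        3: [0.50, 0.30, 0.20],
        4: [0.40, 0.30, 0.20, 0.10],
        6: [0.30, 0.25, 0.18, 0.12, 0.09, 0.06],
    }
    weights: dict[str, float] = {}
    for aa, codons in table.aa_to_codons.items():
        cs = sorted(codons)
        fr = [0.86, 0.14] if aa == "Q" else frac[len(cs)]
        for c, f in zip(cs, fr):
            weights[c] = len(cs) * f
    w = pd.Series(weights).reindex(table.sense_codons)
    return w / w.sum()


def simulate_reference(
    config: SimulationConfig, table: CodonTable = STANDARD_TABLE
) -> SimulatedReference:
    """Draw coding sequences (as codon indices) from the usage weights."""
    config.validate()
    rng = np.random.default_rng([config.seed, 11])
    weights = default_usage_weights(table)
    codon_idx = rng.choice(
        len(table.sense_codons),
        size=(config.n_genes, config.codons_per_gene),
        p=weights.to_numpy(),
    )
    counts = np.bincount(codon_idx.ravel(), minlength=len(table.sense_codons))
    usage = pd.Series(counts, index=table.sense_codons, name="count")
    gene_ids = [f"G{i:04d}" for i in range(config.n_genes)]
    return SimulatedReference(codon_idx=codon_idx, gene_ids=gene_ids, usage=usage)


def _planted_csc(rng: np.random.Generator, table: CodonTable) -> pd.Series:
    """Per-codon CSC values with a clear within-amino-acid spread."""
    values: dict[str, float] = {}
    for aa in sorted(table.aa_to_codons):
        codons = sorted(table.aa_to_codons[aa])
        k = len(codons)
        offset = rng.uniform(-0.1, 0.1)
        if k == 1:
            values[codons[0]] = offset
            continue
        half_spread = 0.2 + 0.15 * rng.random()
        spaced = np.linspace(half_spread, -half_spread, k)
        order = rng.permutation(k)
        for c, v in zip(codons, spaced[order]):
            values[c] = float(np.clip(v + offset, -0.95, 0.95))
    return pd.Series(values).reindex(table.sense_codons)


def simulate_metrics(
    config: SimulationConfig, table: CodonTable = STANDARD_TABLE
) -> SimulatedMetrics:
    """Planted CSC/tAI tables plus half-lives and codon frequencies.

    The codon-frequency matrix is constructed with the residual component
    orthogonalised against the half-life in-sample, so the empirical
    Pearson correlation per codon equals the planted CSC essentially
    exactly; tRNA gene copies are assigned so that within each amino acid
    the higher-CSC codon has the better-supplied Watson-Crick anticodon.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 13])
    csc = _planted_csc(rng, table)
    if (csc.abs() > 1).any():
        raise ValueError("planted CSC outside [-1, 1]")

    copies_rank = [10, 5, 3, 2, 1, 1]
    trna_copies: dict[str, int] = {}
    for aa, codons in table.aa_to_codons.items():
        ranked = sorted(codons, key=lambda c: -csc[c])
        for i, c in enumerate(ranked):
            trna_copies[revcomp(c)] = copies_rank[i]
    tai = compute_tai(trna_copies, table=table)

    n = config.n_transcripts
    half_lives = pd.Series(
        rng.lognormal(mean=1.0, sigma=0.6, size=n),
        index=[f"T{i:05d}" for i in range(n)],
        name="half_life_hours",
    )
    z = (half_lives - half_lives.mean()) / half_lives.std(ddof=0)
    z = z.to_numpy()
    cols = {}
    for codon in table.sense_codons:
        rho = float(csc[codon])
        e = rng.standard_normal(n)
        e = e - e.mean()
        e = e - (e @ z) / (z @ z) * z
        sd = e.std(ddof=0)
        e = e / sd if sd > 0 else e
        f = 1000.0 / 61.0 + 3.0 * (rho * z + np.sqrt(1.0 - rho**2) * e)
        cols[codon] = np.clip(f, 0.0, None)
    freq = pd.DataFrame(cols, index=half_lives.index)

    metrics = CodonMetricSet(csc=csc.to_dict(), tai=tai.to_dict())
    return SimulatedMetrics(
        metrics=metrics,
        trna_copies=trna_copies,
        half_lives=half_lives,
        freq_matrix=freq,
        usage=default_usage_weights(table),
    )


def build_mutability_table(config: SimulationConfig) -> MutabilityTable:
    """Relative mutation rates for every pyrimidine-centred context key."""
    rng = np.random.default_rng([config.seed, 17])
    keys = all_context_keys()
    ranges = {
        "transversion": config.mu_transversion,
        "non-CpG transition": config.mu_transition,
        CPG_TRANSITION: config.mu_cpg,
    }
    mus = []
    base_draw: dict[tuple[str, str], float] = {}
    for ctx, alt, mbin, cls in zip(
        keys["context3"], keys["alt"], keys["methylation_bin"], keys["class_label"]
    ):
        key = (ctx, alt)
        if key not in base_draw:
            lo, hi = ranges[cls]
            base_draw[key] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        mu = base_draw[key]
        if cls == CPG_TRANSITION:
            mu *= config.meth_scale[int(mbin)]
        mus.append(mu)
    return MutabilityTable(keys.assign(mu=mus))


def _mu_lut(mut: MutabilityTable) -> np.ndarray:
    """Dense lookup array mu[left, mid, right, alt, bin] over base indices."""
    lut = np.full((4, 4, 4, 4, 3), np.nan)
    for ctx, alt, mbin, mu in zip(
        mut.table["context3"], mut.table["alt"],
        mut.table["methylation_bin"], mut.table["mu"],
    ):
        l, m, r = (_BASE_IDX[b] for b in ctx)
        lut[l, m, r, _BASE_IDX[alt], int(mbin)] = mu
    return lut


def _change_arrays(metrics: CodonMetricSet, table: CodonTable) -> pd.DataFrame:
    """Per-ref-codon synonymous change table with deltas, indexed by codon idx."""
    codon_index = {c: i for i, c in enumerate(table.sense_codons)}
    rows = []
    for ref, pos, alt, altc in enumerate_synonymous_changes(table):
        rows.append(
            {
                "ref_idx": codon_index[ref],
                "pos": pos,
                "alt_base": _BASE_IDX[alt],
                "alt_idx": codon_index[altc],
                "delta_csc": metrics.csc[altc] - metrics.csc[ref],
                "delta_tai": metrics.tai[altc] - metrics.tai[ref],
                "delta_gc": sum(b in "GC" for b in altc) - sum(b in "GC" for b in ref),
                "degeneracy": table.degeneracy(ref),
                "amino_acid": table.codon_to_aa[ref],
            }
        )
    return pd.DataFrame(rows)


def simulate_variant_table(
    config: SimulationConfig,
    reference: SimulatedReference,
    metrics: SimulatedMetrics,
    mut_table: MutabilityTable | None = None,
    table: CodonTable = STANDARD_TABLE,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Observed synonymous variants with planted selection and ground truth.

    Every possible synonymous single-base change in the reference is
    observed with probability 1 - exp(-rate * mu); singleton status is
    Bernoulli with the neutral sqrt(mu) curve plus the class offsets.
    """
    config.validate()
    if mut_table is None:
        mut_table = build_mutability_table(config)
    rng = np.random.default_rng([config.seed, 19])

    codon_bases = np.array(
        [[_BASE_IDX[b] for b in c] for c in table.sense_codons], dtype=np.int8
    )
    n_genes, cpg = reference.codon_idx.shape
    seq = codon_bases[reference.codon_idx].reshape(n_genes, cpg * 3)
    # pad with 'A' so edge positions have a context
    seqp = np.pad(seq, ((0, 0), (1, 1)), constant_values=_BASE_IDX["A"])

    changes = _change_arrays(metrics.metrics, table)
    flat_codon = reference.codon_idx.ravel()
    site_gene, site_codon = np.divmod(np.arange(flat_codon.size), cpg)

    # expand: one row per (codon site, synonymous change of that codon)
    parts = []
    grouped = changes.groupby("ref_idx")
    for ref_idx, chg in grouped:
        sites = np.nonzero(flat_codon == ref_idx)[0]
        if sites.size == 0:
            continue
        n_s, n_c = sites.size, len(chg)
        parts.append(
            pd.DataFrame(
                {
                    "site": np.repeat(sites, n_c),
                    "pos_in_codon": np.tile(chg["pos"].to_numpy(), n_s),
                    "alt_b": np.tile(chg["alt_base"].to_numpy(), n_s),
                    "alt_idx": np.tile(chg["alt_idx"].to_numpy(), n_s),
                    "ref_idx": ref_idx,
                    "delta_csc": np.tile(chg["delta_csc"].to_numpy(), n_s),
                    "delta_tai": np.tile(chg["delta_tai"].to_numpy(), n_s),
                    "delta_gc": np.tile(chg["delta_gc"].to_numpy(), n_s),
                    "degeneracy": np.tile(chg["degeneracy"].to_numpy(), n_s),
                    "amino_acid": np.tile(chg["amino_acid"].to_numpy(), n_s),
                }
            )
        )
    opp = pd.concat(parts, ignore_index=True).sort_values(
        ["site", "pos_in_codon", "alt_b"], kind="stable", ignore_index=True
    )

    g = site_gene[opp["site"]]
    base_pos = (site_codon[opp["site"]] * 3 + opp["pos_in_codon"]).to_numpy()
    left = seqp[g, base_pos]
    mid = seqp[g, base_pos + 1]
    right = seqp[g, base_pos + 2]
    alt = opp["alt_b"].to_numpy()

    # strand-normalise so the middle base is a pyrimidine (C=1, T=3)
    flip = (mid == 0) | (mid == 2)  # A or G
    l_n = np.where(flip, 3 - right, left)
    m_n = np.where(flip, 3 - mid, mid)
    r_n = np.where(flip, 3 - left, right)
    a_n = np.where(flip, 3 - alt, alt)

    # methylation bin per CpG site (ref C followed by G after normalisation)
    cpg_site = (m_n == 1) & (r_n == 2)
    mbin = np.zeros(len(opp), dtype=np.int8)
    mbin[cpg_site] = rng.choice(3, size=int(cpg_site.sum()), p=config.meth_probs)

    lut = _mu_lut(mut_table)
    mu = lut[l_n, m_n, r_n, a_n, mbin]

    # saturating, mutability-dependent observation
    p_obs = 1.0 - np.exp(-config.sampling_rate * mu)
    observed = rng.random(len(opp)) < p_obs
    v = opp[observed].reset_index(drop=True)
    nv = len(v)
    mu = mu[observed]
    mbin_v = mbin[observed]
    g_v = g[observed]
    base_pos_v = base_pos[observed]
    ctx_coding = (
        np.array(list(_BASES))[left[observed]].astype(object)
        + np.array(list(_BASES))[mid[observed]]
        + np.array(list(_BASES))[right[observed]]
    )

    # ---- planted selection -------------------------------------------------
    delta = (
        config.w_tai * (-v["delta_tai"].to_numpy())
        + config.w_csc * (-v["delta_csc"].to_numpy())
        + config.w_gc * (-v["delta_gc"].to_numpy())
    )

    # splice classes: each variant may be "high" in one of the four classes
    u = rng.random(nv)
    f = config.splice_high_frac
    splice_class = np.full(nv, -1)  # 0=dl 1=dg 2=al 3=ag
    for k in range(4):
        splice_class[(u >= k * f) & (u < (k + 1) * f)] = k
    sai = rng.uniform(0.0, 0.25, size=(nv, 4))
    for k in range(4):
        hit = splice_class == k
        sai[hit, k] = rng.uniform(0.5, 1.0, size=int(hit.sum()))
    delta = delta + np.where(
        (splice_class == 0) | (splice_class == 2), config.splice_loss_offset, 0.0
    )
    delta = delta + np.where(
        (splice_class == 1) | (splice_class == 3), config.splice_gain_offset, 0.0
    )
    sai_missing = rng.random(nv) < config.spliceai_missing_frac
    sai[sai_missing] = np.nan

    # ClinVar-like labels
    fb, fv, fp = config.clinvar_fracs
    uc = rng.random(nv)
    clinvar = np.full(nv, "none", dtype=object)
    clinvar[uc < fb] = "benign-like"
    clinvar[(uc >= fb) & (uc < fb + fv)] = "VUS"
    clinvar[(uc >= fb + fv) & (uc < fb + fv + fp)] = "pathogenic-like"
    ob, ov, op_ = config.clinvar_offsets
    delta = delta + np.select(
        [clinvar == "benign-like", clinvar == "VUS", clinvar == "pathogenic-like"],
        [ob, ov, op_],
        default=0.0,
    )

    # constrained genes (low LOEUF)
    loeuf_gene = rng.uniform(0.0, 2.0, size=n_genes)
    thresh = np.quantile(loeuf_gene, config.loeuf_constrained_frac)
    constrained = loeuf_gene[g_v] <= thresh
    delta = delta + np.where(constrained, config.loeuf_boost, 0.0)

    # random planted subset
    planted = np.zeros(nv, dtype=bool)
    if config.planted_frac > 0:
        planted = rng.random(nv) < config.planted_frac
        delta = delta + np.where(planted, config.planted_delta, 0.0)

    # ---- singleton draw ----------------------------------------------------
    p_raw = config.a0 + config.a1 * np.sqrt(mu) + delta
    n_out = int(((p_raw <= 0) | (p_raw >= 1)).sum())
    if n_out:
        import warnings

        warnings.warn(f"{n_out} singleton probabilities clamped to [eps, 1-eps]")
    p_single = np.clip(p_raw, config.eps, 1.0 - config.eps)
    is_singleton = rng.random(nv) < p_single
    ac = np.where(is_singleton, 1, 2 + rng.geometric(0.3, size=nv) - 1)
    an = config.an_total - rng.integers(0, config.an_total // 10, size=nv)

    # ---- external score columns -------------------------------------------
    reducing = v["delta_csc"].to_numpy() < 0
    gerp = rng.normal(0.0, config.gerp_sd, size=nv) + np.where(
        reducing, config.gerp_reducing_shift, 0.0
    )
    cadd = 10.0 + config.cadd_slope * delta + rng.normal(0.0, config.cadd_sd, size=nv)
    synvep = np.clip(
        0.3 + config.synvep_slope * delta + rng.normal(0.0, config.synvep_sd, size=nv),
        0.0,
        1.0,
    )

    sense = np.array(table.sense_codons)
    gene_ids = np.array(reference.gene_ids)
    variants = pd.DataFrame(
        {
            "chrom": gene_ids[g_v],
            "pos": base_pos_v + 1,
            "ref": np.array(list(_BASES))[mid[observed]],
            "alt": np.array(list(_BASES))[alt[observed]],
            "ac": ac.astype(int),
            "an": an.astype(int),
            "gene_id": gene_ids[g_v],
            "transcript_id": np.char.add(gene_ids[g_v].astype(str), ".t1"),
            "most_severe_consequence": "synonymous_variant",
            "strand": "+",
            "context3": ctx_coding.astype(str),
            "methylation_bin": mbin_v.astype(int),
            "ref_codon": sense[v["ref_idx"].to_numpy()],
            "alt_codon": sense[v["alt_idx"].to_numpy()],
            "codon_index": site_codon[v["site"]].astype(int),
            "gerp": gerp,
            "spliceai_donor_loss": sai[:, 0],
            "spliceai_donor_gain": sai[:, 1],
            "spliceai_acceptor_loss": sai[:, 2],
            "spliceai_acceptor_gain": sai[:, 3],
            "cadd": cadd,
            "synvep": synvep,
            "loeuf": loeuf_gene[g_v],
            "clinvar_label": clinvar,
            "is_singleton": is_singleton,
            "mu": mu,
            "delta_true": delta,
            "is_planted": planted,
        }
    )

    # non-synonymous decoy rows so ingest filtering has something to remove
    n_decoy = int(round(config.decoy_frac * nv))
    if n_decoy:
        variants = pd.concat(
            [variants, _decoy_rows(config, variants, rng, n_decoy, table)],
            ignore_index=True,
        )

    gt = GroundTruth(
        config=config,
        csc=pd.Series(metrics.metrics.csc),
        tai=pd.Series(metrics.metrics.tai),
        class_offsets={
            "splice_loss": config.splice_loss_offset,
            "splice_gain": config.splice_gain_offset,
            "clinvar": dict(
                zip(("benign-like", "VUS", "pathogenic-like"), config.clinvar_offsets)
            ),
            "loeuf_boost": config.loeuf_boost,
            "planted_delta": config.planted_delta,
            "weights": {"w_tai": config.w_tai, "w_csc": config.w_csc, "w_gc": config.w_gc},
            "neutral_curve": {"a0": config.a0, "a1": config.a1},
        },
        planted_index=np.nonzero(planted)[0],
    )
    return variants, gt


def _decoy_rows(
    config: SimulationConfig,
    variants: pd.DataFrame,
    rng: np.random.Generator,
    n_decoy: int,
    table: CodonTable,
) -> pd.DataFrame:
    """Non-synonymous rows derived from observed sites (filtered out at ingest)."""
    picks = rng.choice(len(variants), size=n_decoy, replace=False)
    rows = variants.iloc[picks].copy().reset_index(drop=True)
    keep = np.ones(n_decoy, dtype=bool)
    new_alt, new_codon = [], []
    for i, (refc, altc) in enumerate(zip(rows["ref_codon"], rows["alt_codon"])):
        p = next(j for j in range(3) if refc[j] != altc[j])
        new = None
        for b in _BASES:
            if b in (refc[p], altc[p]):
                continue
            cand = refc[:p] + b + refc[p + 1 :]
            if cand in table.stop_codons:
                continue
            if table.codon_to_aa[cand] != table.codon_to_aa[refc]:
                new = (b, cand)
                break
        if new is None:
            keep[i] = False
            new_alt.append(None)
            new_codon.append(None)
        else:
            new_alt.append(new[0])
            new_codon.append(new[1])
    rows["alt"] = new_alt
    rows["alt_codon"] = new_codon
    rows = rows[keep].reset_index(drop=True)
    n = len(rows)
    rows["most_severe_consequence"] = np.where(
        rng.random(n) < 0.8, "missense_variant", "splice_region_variant"
    )
    rows["is_singleton"] = rng.random(n) < 0.7
    rows["ac"] = np.where(rows["is_singleton"], 1, 2 + rng.geometric(0.3, size=n) - 1)
    rows["mu"] = np.nan
    rows["delta_true"] = np.nan
    rows["is_planted"] = False
    return rows


@dataclass
class SimulatedDataset:
    """Everything one end-to-end run needs, ready for analysis."""

    config: SimulationConfig
    reference: SimulatedReference
    metrics: SimulatedMetrics
    mutability: MutabilityTable
    raw: pd.DataFrame          # coding-strand table incl. non-synonymous decoys
    variants: pd.DataFrame     # annotated synonymous variants (mu, deltas attached)
    ground_truth: GroundTruth


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the full generator and annotate the variant table for analysis."""
    reference = simulate_reference(config)
    metrics = simulate_metrics(config)
    mut = build_mutability_table(config)
    raw, gt = simulate_variant_table(config, reference, metrics, mut)
    synonymous = ingest.filter_synonymous(raw)
    annotated = ingest.attach_codon_annotations(
        ingest.assign_context(synonymous, mut), metrics.metrics
    )
    return SimulatedDataset(
        config=config,
        reference=reference,
        metrics=metrics,
        mutability=mut,
        raw=raw,
        variants=annotated,
        ground_truth=gt,
    )


# --------------------------------------------------------------------------
# fixture writing
# --------------------------------------------------------------------------

_GT_COLUMNS = ("mu", "delta_true", "is_planted", "is_singleton")

_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=AC,Number=A,Type=Integer,Description="Allele count">
##INFO=<ID=AN,Number=1,Type=Integer,Description="Allele number">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">
##INFO=<ID=TRANSCRIPT,Number=1,Type=String,Description="Transcript id">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Most severe consequence">
##INFO=<ID=STRAND,Number=1,Type=String,Description="Coding strand">
##INFO=<ID=CONTEXT,Number=1,Type=String,Description="Coding-strand trinucleotide context">
##INFO=<ID=METH,Number=1,Type=Integer,Description="Methylation bin">
##INFO=<ID=REF_CODON,Number=1,Type=String,Description="Reference codon">
##INFO=<ID=ALT_CODON,Number=1,Type=String,Description="Alternate codon">
##INFO=<ID=CODON_INDEX,Number=1,Type=Integer,Description="Codon index in transcript">
##INFO=<ID=GERP,Number=1,Type=Float,Description="GERP score">
##INFO=<ID=SAI_DL,Number=1,Type=Float,Description="SpliceAI donor loss">
##INFO=<ID=SAI_DG,Number=1,Type=Float,Description="SpliceAI donor gain">
##INFO=<ID=SAI_AL,Number=1,Type=Float,Description="SpliceAI acceptor loss">
##INFO=<ID=SAI_AG,Number=1,Type=Float,Description="SpliceAI acceptor gain">
##INFO=<ID=CADD,Number=1,Type=Float,Description="CADD score">
##INFO=<ID=SYNVEP,Number=1,Type=Float,Description="synVep score">
##INFO=<ID=LOEUF,Number=1,Type=Float,Description="Gene LOEUF">
##INFO=<ID=CLNSIG,Number=1,Type=String,Description="ClinVar-like label">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def _fixture_table(variants: pd.DataFrame) -> pd.DataFrame:
    return variants.drop(columns=[c for c in _GT_COLUMNS if c in variants.columns])


def write_variants_tsv(variants: pd.DataFrame, path) -> None:
    _fixture_table(variants).to_csv(path, sep="\t", index=False)


def write_variants_vcf(variants: pd.DataFrame, path) -> None:
    df = _fixture_table(variants)
    info_keys = [(k, c) for k, c in ingest._VCF_INFO_MAP.items() if c in df.columns]
    header, columns_line = _VCF_HEADER.rsplit("#CHROM", 1)
    contigs = "".join(
        f"##contig=<ID={c}>\n" for c in pd.unique(df["chrom"])
    )
    with open(path, "w") as fh:
        fh.write(header + contigs + "#CHROM" + columns_line)
        for row in df.itertuples(index=False):
            d = row._asdict()
            fields = []
            for key, col in info_keys:
                val = d[col]
                if isinstance(val, float):
                    if np.isnan(val):
                        continue
                    val = f"{val:.6g}"
                fields.append(f"{key}={val}")
            fh.write(
                f"{d['chrom']}\t{d['pos']}\t.\t{d['ref']}\t{d['alt']}\t.\tPASS\t"
                + ";".join(fields)
                + "\n"
            )


def write_fixtures(dataset: SimulatedDataset, outdir) -> dict:
    """Write the full fixture set (TSV + VCF variants, all metric tables).

    Returns the manifest (also written as ``manifest.json``).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    variants = dataset.raw
    write_variants_tsv(variants, out / "variants.tsv")
    write_variants_vcf(variants, out / "variants.vcf")
    dataset.mutability.to_tsv(out / "mutability.tsv")
    pd.DataFrame(
        {"codon": list(dataset.metrics.metrics.csc), "csc": list(dataset.metrics.metrics.csc.values())}
    ).to_csv(out / "csc.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"anticodon": list(dataset.metrics.trna_copies), "copies": list(dataset.metrics.trna_copies.values())}
    ).to_csv(out / "trna_copies.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"codon": dataset.reference.usage.index, "count": dataset.reference.usage.to_numpy()}
    ).to_csv(out / "usage.tsv", sep="\t", index=False)

    gt = dataset.ground_truth
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(
            {
                "config": dataclasses.asdict(gt.config),
                "class_offsets": gt.class_offsets,
                "csc": gt.csc.to_dict(),
                "tai": gt.tai.to_dict(),
                "planted_index": gt.planted_index.tolist(),
            },
            fh,
            indent=1,
        )
    manifest = {
        name: {"rows": int(n)}
        for name, n in [
            ("variants.tsv", len(variants)),
            ("variants.vcf", len(variants)),
            ("mutability.tsv", len(dataset.mutability.table)),
            ("csc.tsv", len(dataset.metrics.metrics.csc)),
            ("trna_copies.tsv", len(dataset.metrics.trna_copies)),
            ("usage.tsv", len(dataset.reference.usage)),
        ]
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
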