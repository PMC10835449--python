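"""Reading and filtering annotated variant tables.

Input is a pre-annotated table of single-nucleotide variants (flat TSV or
VCF with the same fields in INFO): allele counts, VEP-style most-severe
consequence, coding-strand ref/alt codons, the trinucleotide context and a
methylation bin.  The analyses operate on the subset whose most severe
consequence is ``synonymous_variant`` — this removes missense and pLoF
SNVs, including those disrupting canonical splice sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

from .codons import CodonTable, STANDARD_TABLE, CodonMetricSet, delta_table
from .mutability import MutabilityTable, normalize_context, classify_context

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = [
    "chrom", "pos", "ref", "alt", "ac", "an",
    "most_severe_consequence", "context3", "methylation_bin",
    "ref_codon", "alt_codon",
]
OPTIONAL_COLUMNS = [
    "gene_id", "transcript_id", "strand", "codon_index",
    "gerp", "spliceai_donor_loss", "spliceai_donor_gain",
    "spliceai_acceptor_loss", "spliceai_acceptor_gain",
    "cadd", "synvep", "loeuf", "clinvar_label",
]

#: VEP consequence terms from most to least severe (abridged to the terms
#: that occur for coding SNVs).  Used only to validate consequence strings;
#: the filter itself keys on the already-computed most-severe term.
SEVERITY_ORDER = [
    "transcript_ablation", "splice_acceptor_variant", "splice_donor_variant",
    "stop_gained", "frameshift_variant", "stop_lost", "start_lost",
    "missense_variant", "splice_region_variant", "incomplete_terminal_codon_variant",
    "start_retained_variant", "stop_retained_variant", "synonymous_variant",
    "coding_sequence_variant", "5_prime_UTR_variant", "3_prime_UTR_variant",
    "intron_variant", "intergenic_variant",
]

_VCF_INFO_MAP = {
    "AC": "ac", "AN": "an", "GENE": "gene_id", "TRANSCRIPT": "transcript_id",
    "CSQ": "most_severe_consequence", "STRAND": "strand", "CONTEXT": "context3",
    "METH": "methylation_bin", "REF_CODON": "ref_codon", "ALT_CODON": "alt_codon",
    "CODON_INDEX": "codon_index", "GERP": "gerp",
    "SAI_DL": "spliceai_donor_loss", "SAI_DG": "spliceai_donor_gain",
    "SAI_AL": "spliceai_acceptor_loss", "SAI_AG": "spliceai_acceptor_gain",
    "CADD": "cadd", "SYNVEP": "synvep", "LOEUF": "loeuf", "CLNSIG": "clinvar_label",
}


@dataclass
class IngestReport:
    """Counts of rows rejected at each validation step."""

    n_read: int = 0
    n_rejected: dict = field(default_factory=dict)

    def reject(self, reason: str, count: int) -> None:
        if count:
            self.n_rejected[reason] = self.n_rejected.get(reason, 0) + int(count)
            log.info("rejected %d rows: %s", count, reason)


def _validate(df: pd.DataFrame, report: IngestReport) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {missing}")
    report.n_read = len(df)
    df = df.copy()
    df["ac"] = pd.to_numeric(df["ac"], errors="coerce")
    df["an"] = pd.to_numeric(df["an"], errors="coerce")
    bad_num = df["ac"].isna() | df["an"].isna()
    report.reject("non-numeric AC/AN", bad_num.sum())
    df = df[~bad_num]
    mono = df["ac"] < 1
    report.reject("monomorphic (AC < 1)", mono.sum())
    df = df[~mono]
    over = df["ac"] > df["an"]
    report.reject("AC > AN", over.sum())
    df = df[~over]
    not_snv = (df["ref"].str.len() != 1) | (df["alt"].str.len() != 1)
    report.reject("not a SNV", not_snv.sum())
    df = df[~not_snv]
    df["ac"] = df["ac"].astype(int)
    df["an"] = df["an"].astype(int)
    df["methylation_bin"] = df["methylation_bin"].astype(int)
    df["is_singleton"] = df["ac"] == 1
    return df.reset_index(drop=True)


def read_variant_table(
    path, format: str = "tsv", an_fraction: float | None = 0.5
) -> tuple[pd.DataFrame, IngestReport]:
    """Read a variant table from TSV or VCF.

    ``an_fraction`` applies an optional coverage filter keeping rows with
    AN >= an_fraction * max(AN); pass None to disable.  Returns the table
    and an :class:`IngestReport` of rejected-row counts.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t")
    elif format == "vcf":
        df = _read_vcf(path)
    else:
        raise ValueError(f"unknown format {format!r}; expected 'vcf' or 'tsv'")
    report = IngestReport()
    df = _validate(df, report)
    if an_fraction is not None and len(df):
        thresh = an_fraction * df["an"].max()
        low = df["an"] < thresh
        report.reject(f"AN below {an_fraction:.0%} of max", low.sum())
        df = df[~low].reset_index(drop=True)
    return df, report


def _read_vcf(path) -> pd.DataFrame:
    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            info = dict(rec.info)
            row = {"chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref,
                   "alt": rec.alts[0] if rec.alts else None}
            for key, col in _VCF_INFO_MAP.items():
                if key in info:
                    val = info[key]
                    if isinstance(val, tuple):
                        val = val[0]
                    row[col] = val
            rows.append(row)
    df = pd.DataFrame(rows)
    for col in ("gerp", "spliceai_donor_loss", "spliceai_donor_gain",
                "spliceai_acceptor_loss", "spliceai_acceptor_gain",
                "cadd", "synvep", "loeuf"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def filter_synonymous(
    variants: pd.DataFrame,
    severity_order: list[str] | None = None,
    strict: bool = True,
) -> pd.DataFrame:
    """Keep variants whose most severe consequence is ``synonymous_variant``.

    Unknown consequence strings raise in strict mode and are dropped with a
    warning otherwise.  The filter is idempotent and order-independent.
    """
    order = severity_order or SEVERITY_ORDER
    known = set(order)
    csq = variants["most_severe_consequence"]
    unknown = ~csq.isin(known)
    if unknown.any():
        bad = sorted(csq[unknown].unique())
        if strict:
            raise ValueError(f"unknown consequence string(s): {bad}")
        log.warning("dropping %d rows with unknown consequences %s", unknown.sum(), bad)
        variants = variants[~unknown]
        csq = variants["most_severe_consequence"]
    return variants[csq == "synonymous_variant"].reset_index(drop=True)


def assign_context(
    variants: pd.DataFrame, mut_table: MutabilityTable
) -> pd.DataFrame:
    """Attach the normalised context key, mutational class and mu per row."""
    # only 192 (context, alt) combinations exist; precompute and map
    combo = {}
    for left in "ACGT":
        for m in "ACGT":
            for right in "ACGT":
                ctx = left + m + right
                for a in "ACGT":
                    if a == m:
                        continue
                    nc, na = normalize_context(ctx, a)
                    combo[ctx + a] = (nc, na, classify_context(nc, na))
    keys = variants["context3"].astype(str) + variants["alt"].astype(str)
    mapped = keys.map(combo)
    if mapped.isna().any():
        bad = keys[mapped.isna()].unique()[:5]
        raise ValueError(f"invalid context/alt combination(s): {list(bad)}")
    out = variants.copy()
    out["context3"] = [t[0] for t in mapped]
    out["alt_norm"] = [t[1] for t in mapped]
    out["class_label"] = [t[2] for t in mapped]
    out["mu"] = mut_table.lookup(
        out["context3"].to_numpy(), out["alt_norm"].to_numpy(),
        out["methylation_bin"].to_numpy(),
    )
    # the calibration keys contexts on the normalised alternate allele
    out = out.rename(columns={"alt": "alt_coding", "alt_norm": "alt"})
    return out


def attach_codon_annotations(
    variants: pd.DataFrame,
    metrics: CodonMetricSet,
    table: CodonTable = STANDARD_TABLE,
) -> pd.DataFrame:
    """Join per-substitution deltas (ΔCSC, ΔtAI, ΔGC, degeneracy, label).

    Rows whose codon pair is not a single-base synonymous change are
    rejected and logged.  Idempotent: re-annotation overwrites the same
    columns with the same values.
    """
    deltas = delta_table(metrics, table)
    keep = variants.drop(
        columns=[c for c in deltas.columns if c not in ("ref_codon", "alt_codon")],
        errors="ignore",
    )
    merged = keep.merge(deltas, on=["ref_codon", "alt_codon"], how="left")
    bad = merged["optimality_label"].isna()
    if bad.any():
        log.info("rejected %d rows with non-synonymous codon pairs", bad.sum())
    return merged[~bad].reset_index(drop=True)
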