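"""Genetic code, codon-optimality metrics (CSC, tAI, GC) and per-substitution deltas.

Codon optimality is quantified two ways: the codon stability coefficient
(CSC), the Pearson correlation across transcripts between a codon's
frequency and the transcript's mRNA half-life, and the tRNA adaptation
index (tAI), the relative availability of decoding tRNAs approximated from
tRNA gene copy numbers with wobble-pairing penalties.  A synonymous
single-nucleotide change is *optimality reducing* when the created codon
has a lower CSC than the reference codon (ΔCSC < 0) and *optimality
increasing* when ΔCSC > 0; classifying by the sign of the delta avoids the
ambiguity of an absolute optimal/non-optimal split for amino acids such as
histidine whose codons all have negative CSC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.Data import CodonTable as _BioCodonTable

BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Default wobble-pairing penalties s for the non-Watson-Crick codon:anticodon
#: pairs at the third codon position (anticodon position 34).  These are the
#: literature-standard constrained-optimisation values for the tAI; they can be
#: overridden via the ``wobble_weights`` argument of :func:`compute_tai`.
DEFAULT_WOBBLE_WEIGHTS: dict[str, float] = {
    "G:U": 0.41,   # anticodon G34 reading codon-3 U
    "I:C": 0.28,   # anticodon A34 (read as inosine) reading codon-3 C
    "I:A": 0.9999, # anticodon A34 (inosine) reading codon-3 A
    "U:G": 0.68,   # anticodon U34 reading codon-3 G
}


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


class CodonTable:
    """The standard genetic code: 61 sense codons, 3 stops.

    Attributes
    ----------
    codon_to_aa : dict mapping each sense codon to its one-letter amino acid.
    aa_to_codons : dict mapping each amino acid to its frozen set of codons.
    """

    def __init__(self) -> None:
        std = _BioCodonTable.unambiguous_dna_by_id[1]
        self.codon_to_aa: dict[str, str] = dict(std.forward_table)
        self.stop_codons: frozenset[str] = frozenset(std.stop_codons)
        aa_map: dict[str, set[str]] = {}
        for codon, aa in self.codon_to_aa.items():
            aa_map.setdefault(aa, set()).add(codon)
        self.aa_to_codons: dict[str, frozenset[str]] = {
            aa: frozenset(cs) for aa, cs in aa_map.items()
        }
        self.sense_codons: tuple[str, ...] = tuple(sorted(self.codon_to_aa))

    def degeneracy(self, codon: str) -> int:
        """Number of codons encoding the amino acid of ``codon``."""
        return len(self.aa_to_codons[self.codon_to_aa[codon]])

    def is_synonymous_snv(self, ref_codon: str, alt_codon: str) -> bool:
        """True for a single-base change that preserves the amino acid."""
        if ref_codon == alt_codon:
            return False
        if ref_codon in self.stop_codons or alt_codon in self.stop_codons:
            return False
        diffs = sum(a != b for a, b in zip(ref_codon, alt_codon))
        return diffs == 1 and self.codon_to_aa[ref_codon] == self.codon_to_aa[alt_codon]


STANDARD_TABLE = CodonTable()


def gc_count(codon: str) -> int:
    return sum(b in "GC" for b in codon)


def enumerate_synonymous_changes(
    table: CodonTable = STANDARD_TABLE,
) -> list[tuple[str, int, str, str]]:
    """All single-base synonymous substitutions in the genetic code.

    Returns a duplicate-free list of ``(ref_codon, position, alt_base,
    alt_codon)`` tuples, excluding stop codons on either side.
    """
    out = []
    for codon in table.sense_codons:
        for pos in range(3):
            for alt in BASES:
                if alt == codon[pos]:
                    continue
                alt_codon = codon[:pos] + alt + codon[pos + 1 :]
                if table.is_synonymous_snv(codon, alt_codon):
                    out.append((codon, pos, alt, alt_codon))
    return out


@dataclass(frozen=True)
class CodonMetricSet:
    """Per-codon optimality metrics.

    ``csc`` maps codon -> codon stability coefficient in [-1, 1] (codons with
    undefined CSC are absent / NaN); ``tai`` maps codon -> tRNA adaptation
    index in (0, 1] with max 1; ``gc`` maps codon -> number of G/C bases.
    """

    csc: Mapping[str, float]
    tai: Mapping[str, float]
    gc: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.gc:
            object.__setattr__(
                self, "gc", {c: gc_count(c) for c in STANDARD_TABLE.sense_codons}
            )


@dataclass(frozen=True)
class DeltaRecord:
    """Metric changes induced by one synonymous single-base substitution."""

    ref_codon: str
    alt_codon: str
    delta_csc: float
    delta_tai: float
    delta_gc: int
    degeneracy: int
    optimality_label: str  # "reducing" | "increasing" | "neutral" | "unclassified"


def compute_csc(freq_matrix: pd.DataFrame, half_lives: pd.Series) -> pd.Series:
    """Codon stability coefficients from per-transcript codon frequencies.

    Parameters
    ----------
    freq_matrix
        Transcripts x codons frequency matrix (per-thousand codon counts
        within each transcript).
    half_lives
        Per-transcript mRNA half-life in hours, indexed like ``freq_matrix``.

    Returns
    -------
    pandas.Series mapping codon -> Pearson correlation between the codon's
    frequency and the half-life across transcripts.  Codons with zero
    frequency variance get NaN.
    """
    if len(freq_matrix) < 3:
        raise ValueError("CSC requires at least 3 transcripts")
    hl = half_lives.reindex(freq_matrix.index)
    if hl.isna().any():
        raise ValueError("half-life missing for some transcripts")
    if float(hl.std(ddof=0)) == 0.0:
        raise ValueError("half-lives have zero variance")
    # column-wise Pearson r against the half-life vector
    x = freq_matrix.to_numpy(dtype=float)
    y = hl.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc * yc[:, None]).sum(axis=0) / (sx * sy)
    r[sx == 0] = np.nan
    return pd.Series(r, index=freq_matrix.columns, name="csc")


def _decoding_anticodons(codon: str) -> list[tuple[str, str]]:
    """(anticodon, pairing-key) pairs that can decode ``codon``.

    The Watson-Crick anticodon is the reverse complement (pairing key "WC",
    penalty 0); one additional wobble anticodon is allowed at position 34
    depending on the codon's third base.
    """
    wc = revcomp(codon)
    stem = revcomp(codon[:2])  # anticodon positions 35-36
    third = codon[2]
    wobble = {
        "T": ("G" + stem, "G:U"),
        "C": ("A" + stem, "I:C"),
        "A": ("A" + stem, "I:A"),
        "G": ("T" + stem, "U:G"),
    }[third]
    return [(wc, "WC"), wobble]


def compute_tai(
    trna_copies: Mapping[str, float],
    wobble_weights: Mapping[str, float] | None = None,
    table: CodonTable = STANDARD_TABLE,
) -> pd.Series:
    """tRNA adaptation index per sense codon from tRNA gene copy numbers.

    For each codon the absolute adaptiveness is
    ``W = sum over decoding anticodons of (1 - s) * copies`` where ``s`` is
    the wobble-pairing penalty (0 for Watson-Crick pairs); tAI = W / max(W).
    Codons with W = 0 (no decoding tRNA gene) receive the geometric mean of
    the nonzero tAI values, the standard convention for the index.
    """
    weights = dict(DEFAULT_WOBBLE_WEIGHTS)
    if wobble_weights:
        weights.update(wobble_weights)
    copies = {ac: float(n) for ac, n in trna_copies.items()}
    if any(n < 0 for n in copies.values()):
        raise ValueError("tRNA copy numbers must be non-negative")
    if not any(n > 0 for n in copies.values()):
        raise ValueError("all tRNA copy numbers are zero")
    w = {}
    for codon in table.sense_codons:
        total = 0.0
        for anticodon, key in _decoding_anticodons(codon):
            s = 0.0 if key == "WC" else weights[key]
            total += (1.0 - s) * copies.get(anticodon, 0.0)
        w[codon] = total
    ser = pd.Series(w, name="tai")
    wmax = ser.max()
    if wmax <= 0:
        raise ValueError("no codon has nonzero tRNA availability")
    tai = ser / wmax
    nonzero = tai[tai > 0]
    if (tai == 0).any():
        gmean = float(np.exp(np.log(nonzero).mean()))
        tai[tai == 0] = gmean
    return tai


def delta_metrics(
    ref_codon: str,
    alt_codon: str,
    metrics: CodonMetricSet,
    table: CodonTable = STANDARD_TABLE,
) -> DeltaRecord:
    """Metric deltas (alt - ref) for one synonymous single-base substitution."""
    if not table.is_synonymous_snv(ref_codon, alt_codon):
        raise ValueError(
            f"{ref_codon}->{alt_codon} is not a single-base synonymous change"
        )
    csc_ref = metrics.csc.get(ref_codon, np.nan)
    csc_alt = metrics.csc.get(alt_codon, np.nan)
    d_csc = csc_alt - csc_ref
    rec = DeltaRecord(
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        delta_csc=float(d_csc),
        delta_tai=float(metrics.tai[alt_codon] - metrics.tai[ref_codon]),
        delta_gc=gc_count(alt_codon) - gc_count(ref_codon),
        degeneracy=table.degeneracy(ref_codon),
        optimality_label="",
    )
    return DeltaRecord(**{**rec.__dict__, "optimality_label": classify_optimality(rec)})


def classify_optimality(rec: DeltaRecord) -> str:
    """Label a substitution by the sign of its CSC change.

    ΔCSC < 0 -> "reducing", ΔCSC > 0 -> "increasing", ΔCSC == 0 -> "neutral";
    a missing CSC on either side yields "unclassified".
    """
    d = rec.delta_csc
    if np.isnan(d):
        return "unclassified"
    if d < 0:
        return "reducing"
    if d > 0:
        return "increasing"
    return "neutral"


def delta_table(
    metrics: CodonMetricSet, table: CodonTable = STANDARD_TABLE
) -> pd.DataFrame:
    """DeltaRecords for every synonymous single-base change, as a DataFrame."""
    rows = []
    for ref, _pos, _alt, alt in enumerate_synonymous_changes(table):
        rec = delta_metrics(ref, alt, metrics, table)
        rows.append(rec.__dict__)
    df = pd.DataFrame(rows).drop_duplicates(subset=["ref_codon", "alt_codon"])
    df["amino_acid"] = df["ref_codon"].map(table.codon_to_aa)
    return df.reset_index(drop=True)


def usage_bias(
    usage: pd.Series | Mapping[str, float], table: CodonTable = STANDARD_TABLE
) -> pd.Series:
    """Average codon usage bias per amino acid, rescaled to [0, 1].

    For an amino acid with k >= 2 codons whose genome-wide usage fractions
    are f_1..f_k, the bias is ``(max f - 1/k) / (1 - 1/k)``: 0 for uniform
    usage, 1 when one codon is used exclusively.  Single-codon amino acids
    (Met, Trp) are skipped.
    """
    u = pd.Series(usage, dtype=float)
    out = {}
    for aa, codons in table.aa_to_codons.items():
        k = len(codons)
        if k < 2:
            continue
        counts = u.reindex(sorted(codons)).fillna(0.0)
        total = counts.sum()
        if total <= 0:
            out[aa] = np.nan
            continue
        frac = counts / total
        out[aa] = float((frac.max() - 1.0 / k) / (1.0 - 1.0 / k))
    return pd.Series(out, name="usage_bias").sort_index()


def read_two_column_table(path, key: str, value: str) -> pd.Series:
    """Read a tab-separated two-column table (with header) as a Series."""
    df = pd.read_csv(path, sep="\t")
    if key not in df.columns or value not in df.columns:
        raise ValueError(f"expected columns {key!r} and {value!r} in {path}")
    return pd.Series(df[value].to_numpy(), index=df[key], name=value)


def write_two_column_table(series: pd.Series, path, key: str, value: str) -> None:
    pd.DataFrame({key: series.index, value: series.to_numpy()}).to_csv(
        path, sep="\t", index=False
    )
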