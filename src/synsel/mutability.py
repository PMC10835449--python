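"""Trinucleotide mutational contexts and the relative mutation-rate table.

Every single-nucleotide variant is keyed by its strand-normalised
trinucleotide context, alternate allele and (for CpG sites) a methylation
bin.  Contexts are normalised so that the middle (reference) base is a
pyrimidine; mutation rates are symmetric under reverse complement, so this
loses no information while the codon fields stay on the coding strand.
Keys fall into three exclusive classes: CpG transitions (C>T at a CG
dinucleotide, roughly 100-fold more mutable than anything else), non-CpG
transitions, and transversions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codons import revcomp

PYRIMIDINES = frozenset("CT")
TRANSITIONS = frozenset({("C", "T"), ("T", "C"), ("A", "G"), ("G", "A")})

CPG_TRANSITION = "CpG transition"
NONCPG_TRANSITION = "non-CpG transition"
TRANSVERSION = "transversion"

METHYLATION_BINS = (0, 1, 2)  # 0 = unmethylated, 2 = highly methylated


def normalize_context(context3: str, alt: str) -> tuple[str, str]:
    """Strand-normalise so the middle reference base is a pyrimidine."""
    context3 = context3.upper()
    alt = alt.upper()
    if len(context3) != 3 or any(b not in "ACGT" for b in context3 + alt):
        raise ValueError(f"invalid context/alt: {context3!r} {alt!r}")
    if context3[1] in PYRIMIDINES:
        return context3, alt
    return revcomp(context3), revcomp(alt)


def classify_context(context3: str, alt: str) -> str:
    """Mutational class of a (context, alt) pair; input need not be normalised."""
    ctx, a = normalize_context(context3, alt)
    ref = ctx[1]
    if a == ref:
        raise ValueError("alt equals the reference middle base")
    if (ref, a) in TRANSITIONS:
        if ref == "C" and a == "T" and ctx[2] == "G":
            return CPG_TRANSITION
        return NONCPG_TRANSITION
    return TRANSVERSION


def is_cpg_site(context3: str) -> bool:
    """True when the (normalised) context is a CG dinucleotide site."""
    ctx = context3.upper()
    if ctx[1] not in PYRIMIDINES:
        ctx = revcomp(ctx)
    return ctx[1] == "C" and ctx[2] == "G"


def all_context_keys() -> pd.DataFrame:
    """Every pyrimidine-centred (context3, alt, methylation_bin) key.

    Methylation bins beyond 0 exist only for CpG sites.
    """
    rows = []
    for left in "ACGT":
        for mid in "CT":
            for right in "ACGT":
                ctx = left + mid + right
                for alt in "ACGT":
                    if alt == mid:
                        continue
                    bins = METHYLATION_BINS if is_cpg_site(ctx) else (0,)
                    for b in bins:
                        rows.append(
                            {
                                "context3": ctx,
                                "alt": alt,
                                "methylation_bin": b,
                                "class_label": classify_context(ctx, alt),
                            }
                        )
    return pd.DataFrame(rows)


@dataclass
class MutabilityTable:
    """Relative per-site mutation rates keyed by (context3, alt, methylation_bin).

    ``table`` holds columns context3, alt, methylation_bin, mu (all mu > 0);
    contexts are pyrimidine-centred.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"context3", "alt", "methylation_bin", "mu"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"mutability table missing columns: {sorted(missing)}")
        if (self.table["mu"] <= 0).any():
            raise ValueError("all mutabilities must be positive")
        keys = self.table[["context3", "alt", "methylation_bin"]]
        if keys.duplicated().any():
            raise ValueError("duplicate (context, alt, methylation_bin) keys")
        if "class_label" not in self.table.columns:
            self.table = self.table.assign(
                class_label=[
                    classify_context(c, a)
                    for c, a in zip(self.table["context3"], self.table["alt"])
                ]
            )
        self._lookup = {
            (c, a, int(m)): float(mu)
            for c, a, m, mu in zip(
                self.table["context3"],
                self.table["alt"],
                self.table["methylation_bin"],
                self.table["mu"],
            )
        }

    def mu(self, context3: str, alt: str, methylation_bin: int = 0) -> float:
        ctx, a = normalize_context(context3, alt)
        key = (ctx, a, int(methylation_bin))
        try:
            return self._lookup[key]
        except KeyError:
            raise KeyError(f"context key not in mutability table: {key}") from None

    def lookup(
        self,
        context3: np.ndarray | pd.Series,
        alt: np.ndarray | pd.Series,
        methylation_bin: np.ndarray | pd.Series,
    ) -> np.ndarray:
        """Vectorised mu lookup (contexts must already be normalised)."""
        strkeys = {f"{c}{a}{m}": mu for (c, a, m), mu in self._lookup.items()}
        keys = (
            pd.Series(np.asarray(context3, dtype=object))
            + np.asarray(alt, dtype=object)
            + pd.Series(np.asarray(methylation_bin)).astype(int).astype(str)
        )
        out = keys.map(strkeys)
        if out.isna().any():
            bad = keys[out.isna()].unique()[:5]
            raise KeyError(f"context key(s) not in mutability table: {list(bad)}")
        return out.to_numpy(dtype=float)

    @classmethod
    def from_tsv(cls, path) -> "MutabilityTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)
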