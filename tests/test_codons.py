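"""Genetic code, CSC, tAI, deltas and usage bias."""

import numpy as np
import pandas as pd
import pytest

from synsel.codons import (
    BASES,
    DEFAULT_WOBBLE_WEIGHTS,
    STANDARD_TABLE,
    CodonMetricSet,
    classify_optimality,
    compute_csc,
    compute_tai,
    delta_metrics,
    enumerate_synonymous_changes,
    gc_count,
    revcomp,
    usage_bias,
)


class TestCodonTable:
    def test_code_size_and_degeneracy(self):
        t = STANDARD_TABLE
        assert len(t.sense_codons) == 61
        assert len(t.stop_codons) == 3
        assert {len(cs) for cs in t.aa_to_codons.values()} <= {1, 2, 3, 4, 6}

    def test_his_pair_is_synonymous(self):
        assert STANDARD_TABLE.is_synonymous_snv("CAT", "CAC")
        assert not STANDARD_TABLE.is_synonymous_snv("CAT", "CAA")  # His -> Gln


class TestEnumerateSynonymous:
    def test_matches_brute_force(self):
        """Exhaustive oracle: every one of the 61 x 9 single-base changes."""
        expected = set()
        for codon in STANDARD_TABLE.sense_codons:
            for pos in range(3):
                for alt in BASES:
                    if alt == codon[pos]:
                        continue
                    cand = codon[:pos] + alt + codon[pos + 1 :]
                    if (
                        cand not in STANDARD_TABLE.stop_codons
                        and STANDARD_TABLE.codon_to_aa[cand]
                        == STANDARD_TABLE.codon_to_aa[codon]
                    ):
                        expected.add((codon, pos, alt, cand))
        got = enumerate_synonymous_changes()
        assert len(got) == len(set(got)), "duplicates"
        assert set(got) == expected

    def test_his_included_met_excluded(self):
        got = set(enumerate_synonymous_changes())
        assert ("CAT", 2, "C", "CAC") in got
        assert not any(ref == "ATG" for ref, *_ in got)


class TestCSC:
    def test_perfect_correlation(self):
        hl = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0], index=list("abcde"))
        freq = pd.DataFrame({"AAA": 2 * hl + 1, "GGG": [5, 1, 4, 2, 3]}, index=hl.index)
        csc = compute_csc(freq, hl)
        assert csc["AAA"] == pytest.approx(1.0)

    def test_absent_codon_is_missing(self):
        hl = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        freq = pd.DataFrame({"AAA": [1, 2, 3], "CCC": [0, 0, 0]}, index=hl.index)
        csc = compute_csc(freq, hl)
        assert np.isnan(csc["CCC"])

    def test_toy_matrix_matches_pearson_formula(self):
        rng = np.random.default_rng(0)
        hl = pd.Series(rng.uniform(1, 10, size=5), index=[f"t{i}" for i in range(5)])
        freq = pd.DataFrame(
            rng.uniform(0, 30, size=(5, 3)), index=hl.index, columns=["AAA", "AAG", "CCC"]
        )
        csc = compute_csc(freq, hl)
        for codon in freq.columns:
            x, y = freq[codon].to_numpy(), hl.to_numpy()
            r = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
                ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
            )
            assert csc[codon] == pytest.approx(r, abs=1e-12)

    @pytest.mark.parametrize(
        "bad_hl, match",
        [
            (pd.Series([2.0, 2.0, 2.0], index=list("abc")), "zero variance"),
            (pd.Series([1.0, 2.0], index=list("ab")), "at least 3"),
        ],
    )
    def test_degenerate_inputs_raise(self, bad_hl, match):
        freq = pd.DataFrame({"AAA": np.arange(len(bad_hl))}, index=bad_hl.index)
        with pytest.raises(ValueError, match=match):
            compute_csc(freq, bad_hl)

    def test_permuted_half_lives_decorrelate(self):
        rng = np.random.default_rng(1)
        hl = pd.Series(rng.lognormal(0, 0.5, 300), index=[f"t{i}" for i in range(300)])
        freq = pd.DataFrame(
            {"AAA": 3 * hl + rng.normal(0, 0.1, 300)}, index=hl.index
        )
        hl_perm = pd.Series(rng.permutation(hl.to_numpy()), index=hl.index)
        assert compute_csc(freq, hl)["AAA"] > 0.9
        assert abs(compute_csc(freq, hl_perm)["AAA"]) < 0.15


def brute_force_tai(copies, weights=None):
    """Independent oracle: enumerate all 64 anticodons against each codon."""
    w = dict(DEFAULT_WOBBLE_WEIGHTS)
    if weights:
        w.update(weights)
    penalty = {
        ("A", "T"): 0.0, ("G", "C"): 0.0, ("T", "A"): 0.0, ("C", "G"): 0.0,
        ("G", "T"): w["G:U"], ("A", "C"): w["I:C"],
        ("A", "A"): w["I:A"], ("T", "G"): w["U:G"],
    }
    anticodons = [a + b + c for a in BASES for b in BASES for c in BASES]
    W = {}
    for codon in STANDARD_TABLE.sense_codons:
        total = 0.0
        for ac in anticodons:
            # anticodon 5'->3' pairs the codon 3'->5'; positions 35-36 must
            # be Watson-Crick with codon positions 2 and 1
            if ac[1] != revcomp(codon[1]) or ac[2] != revcomp(codon[0]):
                continue
            key = (ac[0], codon[2])
            if key not in penalty:
                continue
            total += (1.0 - penalty[key]) * copies.get(ac, 0.0)
        W[codon] = total
    ser = pd.Series(W)
    tai = ser / ser.max()
    nz = tai[tai > 0]
    gmean = np.exp(np.log(nz).mean())
    return tai.mask(tai == 0, gmean)


class TestTAI:
    def test_watson_crick_normalization(self):
        # with wobble fully penalised only Watson-Crick pairs count:
        # copies {2, 1} give tAI {1.0, 0.5}
        copies = {"AAA": 2, "GAA": 1}
        no_wobble = {"G:U": 1.0, "I:C": 1.0, "I:A": 1.0, "U:G": 1.0}
        tai = compute_tai(copies, wobble_weights=no_wobble)
        assert tai["TTT"] == pytest.approx(1.0)
        assert tai["TTC"] == pytest.approx(0.5)

    def test_wobble_contributions(self):
        copies = {"AAA": 2, "GAA": 1}
        tai = compute_tai(copies)
        # TTT: WC anticodon AAA + G:U wobble GAA; TTC: WC GAA + I:C wobble AAA
        assert tai["TTT"] == pytest.approx(1.0)  # 2 + 0.59*1 is the max W
        assert tai["TTC"] == pytest.approx((1 + (1 - 0.28) * 2) / (2 + 0.59 * 1))

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        copies = {revcomp(c): int(rng.integers(1, 10)) for c in STANDARD_TABLE.sense_codons}
        t1 = compute_tai(copies)
        t2 = compute_tai({k: 7 * v for k, v in copies.items()})
        pd.testing.assert_series_equal(t1, t2)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        copies = {
            revcomp(c): int(rng.integers(0, 12)) for c in STANDARD_TABLE.sense_codons
        }
        got = compute_tai(copies)
        expected = brute_force_tai(copies)
        for codon in STANDARD_TABLE.sense_codons:
            assert got[codon] == pytest.approx(expected[codon], abs=1e-12), codon

    def test_zero_availability_gets_geometric_mean(self):
        copies = {revcomp(c): 1 for c in STANDARD_TABLE.sense_codons}
        # removing anticodons AAA and GAA leaves both Phe codons undecodable
        copies.pop("AAA")
        copies["GAA"] = 0
        tai = compute_tai(copies)
        others = [c for c in tai.index if c not in ("TTT", "TTC")]
        expected = np.exp(np.log(tai[others]).mean())
        assert tai["TTT"] == pytest.approx(expected, abs=1e-12)
        assert tai["TTC"] == pytest.approx(expected, abs=1e-12)

    def test_all_zero_copies_raise(self):
        with pytest.raises(ValueError, match="zero"):
            compute_tai({"AAA": 0})


@pytest.fixture(scope="module")
def toy_metrics():
    rng = np.random.default_rng(4)
    csc = {c: float(rng.uniform(-0.5, 0.5)) for c in STANDARD_TABLE.sense_codons}
    copies = {revcomp(c): int(rng.integers(1, 10)) for c in STANDARD_TABLE.sense_codons}
    return CodonMetricSet(csc=csc, tai=compute_tai(copies).to_dict())


class TestDeltaMetrics:
    def test_his_gc_delta(self, toy_metrics):
        rec = delta_metrics("CAT", "CAC", toy_metrics)
        assert rec.delta_gc == 1
        assert rec.degeneracy == 2

    def test_gln_gc_delta(self, toy_metrics):
        assert delta_metrics("CAG", "CAA", toy_metrics).delta_gc == -1

    def test_antisymmetry_over_all_pairs(self, toy_metrics):
        for ref, _pos, _alt, alt in enumerate_synonymous_changes():
            fwd = delta_metrics(ref, alt, toy_metrics)
            rev = delta_metrics(alt, ref, toy_metrics)
            assert fwd.delta_csc == pytest.approx(-rev.delta_csc)
            assert fwd.delta_tai == pytest.approx(-rev.delta_tai)
            assert fwd.delta_gc == -rev.delta_gc
            assert fwd.delta_gc in (-1, 0, 1)

    def test_non_synonymous_pair_raises(self, toy_metrics):
        with pytest.raises(ValueError):
            delta_metrics("CAT", "CAA", toy_metrics)
        with pytest.raises(ValueError):
            delta_metrics("CTA", "GAT", toy_metrics)


class TestClassifyOptimality:
    @pytest.mark.parametrize(
        "dcsc, label",
        [(-0.1, "reducing"), (0.3, "increasing"), (0.0, "neutral"), (np.nan, "unclassified")],
    )
    def test_sign_rule(self, dcsc, label, toy_metrics):
        rec = delta_metrics("CAT", "CAC", toy_metrics)
        rec = type(rec)(**{**rec.__dict__, "delta_csc": dcsc})
        assert classify_optimality(rec) == label

    def test_both_negative_csc_still_classified(self):
        # histidine-like case: both codons suboptimal in absolute terms
        metrics = CodonMetricSet(
            csc={"CAT": -0.3, "CAC": -0.1, **{c: 0.0 for c in STANDARD_TABLE.sense_codons if c not in ("CAT", "CAC")}},
            tai={c: 1.0 for c in STANDARD_TABLE.sense_codons},
        )
        assert delta_metrics("CAT", "CAC", metrics).optimality_label == "increasing"
        assert delta_metrics("CAC", "CAT", metrics).optimality_label == "reducing"


class TestUsageBias:
    @pytest.mark.parametrize(
        "f_cat, expected", [(0.5, 0.0), (1.0, 1.0), (0.75, 0.5)]
    )
    def test_two_codon_bias(self, f_cat, expected):
        usage = {c: 1.0 for c in STANDARD_TABLE.sense_codons}
        usage["CAT"], usage["CAC"] = 100 * f_cat, 100 * (1 - f_cat)
        assert usage_bias(usage)["H"] == pytest.approx(expected)

    def test_single_codon_aas_skipped(self):
        bias = usage_bias({c: 1.0 for c in STANDARD_TABLE.sense_codons})
        assert "M" not in bias.index and "W" not in bias.index

    def test_gc_count(self):
        assert [gc_count(c) for c in ("ATA", "CAT", "CAC", "GGC")] == [0, 1, 2, 3]
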