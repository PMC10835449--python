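"""Downstream comparative analyses on annotated variants."""

import numpy as np
import pandas as pd
import pytest

from synsel import analyses
from synsel.calibration import SingletonCalibration
from synsel.simulate import SimulationConfig, simulate_dataset


class TestOptimalityContrast:
    def test_planted_selection_gives_positive_differences(
        self, default_dataset, traps_result
    ):
        v = default_dataset.variants
        tab = analyses.optimality_contrast_by_aa(v, traps_result)
        two_codon = tab.merge(
            v[["amino_acid", "degeneracy"]].drop_duplicates(), on="amino_acid"
        )
        assert (two_codon.loc[two_codon["degeneracy"] == 2, "diff"] > 0).all()

    def test_single_codon_aas_absent(self, default_dataset, traps_result):
        tab = analyses.optimality_contrast_by_aa(default_dataset.variants, traps_result)
        assert not set(tab["amino_acid"]) & {"M", "W"}

    def test_null_differences_cover_zero(self, neutral_dataset):
        v = neutral_dataset.variants
        res = SingletonCalibration(v, "sqrt").fit()
        tab = analyses.optimality_contrast_by_aa(v, res)
        covered = (tab["ci_low"] <= 0) & (0 <= tab["ci_high"])
        assert covered.mean() >= 0.9


class TestGerpContrast:
    def test_identical_distributions_not_significant(self, neutral_dataset):
        v = neutral_dataset.variants  # gerp shift zeroed in the neutral config
        tab = analyses.gerp_contrast(v)
        assert (tab["p"] >= 0.01).all()
        assert tab["p"].median() >= 0.2

    def test_two_codon_filter(self, default_dataset):
        v = default_dataset.variants
        tab = analyses.gerp_contrast(v, two_codon_only=True)
        deg = v.groupby("amino_acid")["degeneracy"].first()
        assert all(deg[aa] == 2 for aa in tab["amino_acid"])

    def test_missing_gerp_raises(self, default_dataset):
        v = default_dataset.variants.assign(gerp=np.nan)
        with pytest.raises(ValueError, match="GERP"):
            analyses.gerp_contrast(v)


class TestSaturation:
    def test_toy_fractions_and_wilson(self):
        obs = pd.DataFrame(
            {
                "amino_acid": "H",
                "degeneracy": 2,
                "optimality_label": ["reducing"] * 30 + ["increasing"] * 70,
            }
        )
        universe = pd.DataFrame(
            {
                "amino_acid": "H",
                "optimality_label": ["reducing", "increasing"],
                "mu": [1.0, 1.0],
            }
        )
        tab = analyses.saturation_by_aa(obs, universe)
        assert tab.loc[0, "observed_fraction"] == pytest.approx(0.30)
        assert tab.loc[0, "expected_fraction"] == pytest.approx(0.5)

    def test_asymmetric_mutability_baseline(self):
        obs = pd.DataFrame(
            {"amino_acid": "H", "degeneracy": 2, "optimality_label": ["reducing"]}
        )
        universe = pd.DataFrame(
            {
                "amino_acid": "H",
                "optimality_label": ["reducing", "increasing"],
                "mu": [3.0, 1.0],
            }
        )
        tab = analyses.saturation_by_aa(obs, universe)
        assert tab.loc[0, "expected_fraction"] == pytest.approx(0.75)

    def test_zero_successes_wilson_lower_bound(self):
        obs = pd.DataFrame(
            {
                "amino_acid": "H",
                "degeneracy": 2,
                "optimality_label": ["increasing"] * 10,
            }
        )
        universe = obs.assign(mu=1.0)
        tab = analyses.saturation_by_aa(obs, universe)
        assert tab.loc[0, "ci_low"] == 0.0


class TestConstrainedGenes:
    def test_planted_boost_elevates_constrained_scores(
        self, default_dataset, traps_result
    ):
        tab = analyses.constrained_gene_scores(default_dataset.variants, traps_result)
        piv = tab.set_index(["optimality_label", "gene_set"])["score"]
        assert piv[("all", "constrained")] > piv[("all", "all_genes")]

    def test_constrained_gene_count(self, default_dataset, traps_result):
        v = default_dataset.variants
        n_genes = v["gene_id"].nunique()
        per_gene = v.groupby("gene_id")["loeuf"].first().sort_values()
        expect = int(np.ceil(0.3 * n_genes))
        thresh_genes = set(per_gene.index[:expect])
        con = v[v["gene_id"].isin(thresh_genes)]
        tab = analyses.constrained_gene_scores(v, traps_result)
        row = tab[(tab["optimality_label"] == "all") & (tab["gene_set"] == "constrained")]
        assert int(row["n_variants"].iloc[0]) == len(con)

    def test_all_missing_loeuf_raises(self, default_dataset, traps_result):
        v = default_dataset.variants.assign(loeuf=np.nan)
        with pytest.raises(ValueError, match="LOEUF"):
            analyses.constrained_gene_scores(v, traps_result)


class TestSpliceClasses:
    def test_thresholding(self, default_dataset, traps_result):
        tab = analyses.splice_class_scores(default_dataset.variants, traps_result)
        assert set(tab["splice_class"]) == {
            "donor_loss", "donor_gain", "acceptor_loss", "acceptor_gain"
        }
        assert set(tab["side"]) == {"high", "low"}

    def test_unannotated_rows_excluded(self, default_dataset, traps_result):
        v = default_dataset.variants
        tab = analyses.splice_class_scores(v, traps_result)
        n_annot = v[
            ["spliceai_donor_loss", "spliceai_donor_gain",
             "spliceai_acceptor_loss", "spliceai_acceptor_gain"]
        ].notna().all(axis=1).sum()
        per_class = tab.groupby("splice_class")["n_variants"].sum()
        assert (per_class == n_annot).all()

    def test_loss_offset_exceeds_gain(self, default_dataset, traps_result):
        tab = analyses.splice_class_scores(default_dataset.variants, traps_result)
        s = tab.set_index(["splice_class", "side"])["score"]
        assert s[("donor_loss", "high")] > s[("donor_gain", "high")]
        assert s[("acceptor_loss", "high")] > s[("acceptor_gain", "high")]

    def test_no_annotations_raises(self, default_dataset, traps_result):
        v = default_dataset.variants.assign(
            spliceai_donor_loss=np.nan, spliceai_donor_gain=np.nan,
            spliceai_acceptor_loss=np.nan, spliceai_acceptor_gain=np.nan,
        )
        with pytest.raises(ValueError, match="SpliceAI"):
            analyses.splice_class_scores(v, traps_result)


class TestPredictorQuartiles:
    def test_equal_membership(self, traps_result):
        df = pd.DataFrame(
            {
                "cadd": np.arange(1, 101, dtype=float),
                "mu": 1.0,
                "is_singleton": True,
                "context3": "ACA", "alt": "T", "methylation_bin": 0,
            }
        )
        tab = analyses.predictor_quartile_scores(df, traps_result, "cadd")
        assert list(tab["n_variants"]) == [25, 25, 25, 25]

    def test_monotone_with_planted_selection(self, default_dataset, traps_result):
        tab = analyses.predictor_quartile_scores(
            default_dataset.variants, traps_result, "cadd"
        )
        assert np.all(np.diff(tab["score"]) > 0)

    def test_all_missing_raises(self, default_dataset, traps_result):
        v = default_dataset.variants.assign(cadd=np.nan)
        with pytest.raises(ValueError, match="cadd"):
            analyses.predictor_quartile_scores(v, traps_result, "cadd")


@pytest.fixture(scope="module")
def clinvar_rich():
    """Larger table with generous ClinVar label fractions for ordering power."""
    cfg = SimulationConfig(
        seed=23, n_genes=500, codons_per_gene=400,
        clinvar_fracs=(0.06, 0.04, 0.03),
    )
    ds = simulate_dataset(cfg)
    res = SingletonCalibration(ds.variants, "sqrt").fit()
    return ds, res


class TestClinvarGroups:
    def test_reference_identity(self, default_dataset, traps_result):
        tab = analyses.clinvar_group_scores(default_dataset.variants, traps_result)
        ref = tab[tab["clinvar_group"] == "benign-like"]
        assert ref["diff_vs_benign"].iloc[0] == pytest.approx(0.0)

    def test_planted_ordering_recovered(self, clinvar_rich):
        ds, res = clinvar_rich
        tab = analyses.clinvar_group_scores(ds.variants, res)
        d = tab.set_index("clinvar_group")["diff_vs_benign"]
        assert d["pathogenic-like"] > d["VUS"] > d["benign-like"]

    def test_raw_labels_merge(self, traps_result):
        df = pd.DataFrame(
            {
                "clinvar_label": ["pathogenic", "likely pathogenic", "benign",
                                  "likely benign", "VUS", "none"],
                "mu": 1.0, "is_singleton": True,
                "context3": "ACA", "alt": "T", "methylation_bin": 0,
            }
        )
        tab = analyses.clinvar_group_scores(df, traps_result)
        counts = tab.set_index("clinvar_group")["n_variants"]
        assert counts["pathogenic-like"] == 2
        assert counts["benign-like"] == 2

    def test_empty_reference_raises(self, default_dataset, traps_result):
        v = default_dataset.variants.assign(clinvar_label="none")
        with pytest.raises(ValueError, match="benign"):
            analyses.clinvar_group_scores(v, traps_result)


def test_reports_are_deterministic(default_dataset, traps_result):
    v = default_dataset.variants
    a = analyses.optimality_contrast_by_aa(v, traps_result)
    b = analyses.optimality_contrast_by_aa(v.copy(), traps_result)
    pd.testing.assert_frame_equal(a, b)
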