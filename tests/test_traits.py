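"""Trait augmentation, nearest-taxon assignment and gene prediction."""

import numpy as np
import pandas as pd
import pytest

from plastisphere import synthetic as syn
from plastisphere import traits as tr


def _traits(df=None, custom=None):
    if df is None:
        df = pd.DataFrame({"famA": [1, 0], "famB": [2, 3]},
                          index=["gA", "gB"])
    return tr.TraitMatrix(df, custom or set())


class TestTraitMatrix:
    def test_negative_or_fractional_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            _traits(pd.DataFrame({"f": [-1]}, index=["g"]))
        with pytest.raises(ValueError, match="integral"):
            _traits(pd.DataFrame({"f": [0.5]}, index=["g"]))


class TestAugment:
    def test_counts_appended_as_new_column(self):
        out = tr.augment_traits(_traits(), pd.Series({"gA": 2, "gB": 0}),
                                "custom")
        assert list(out.table["custom"]) == [2, 0]
        assert "custom" in out.custom_families
        # existing columns untouched
        assert list(out.table["famA"]) == [1, 0]

    def test_name_collision_needs_overwrite(self):
        traits = tr.augment_traits(_traits(), pd.Series({"gA": 1}), "custom")
        with pytest.raises(ValueError, match="already present"):
            tr.augment_traits(traits, pd.Series({"gA": 2}), "custom")
        out = tr.augment_traits(traits, pd.Series({"gA": 2}), "custom",
                                overwrite=True)
        assert out.table.loc["gA", "custom"] == 2

    def test_unknown_genomes_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = tr.augment_traits(_traits(), pd.Series({"gA": 1, "gX": 5}),
                                    "custom")
        assert "gX" in caplog.text
        assert "gX" not in out.table.index
        assert out.table.loc["gB", "custom"] == 0  # missing genomes get zero


class TestRestrict:
    def test_intersection(self):
        assert tr.restrict_to_reference({"a", "b", "c"}, {"b", "c", "d"}) == \
            ["b", "c"]

    def test_identity_when_equal(self):
        assert tr.restrict_to_reference({"a", "b"}, {"a", "b"}) == ["a", "b"]

    def test_empty_intersection_rejected(self):
        with pytest.raises(ValueError, match="no genomes"):
            tr.restrict_to_reference({"a"}, {"b"})

    def test_subset_reference_keeps_reference_size(self):
        db = {f"g{i}" for i in range(20)}
        ref = {f"g{i}" for i in range(14)}
        assert len(tr.restrict_to_reference(db, ref)) == 14


class TestAssignNearest:
    def test_identical_sequence_gets_zero_nsti(self):
        refs = {"g1": "ACGT" * 25, "g2": "TTTT" * 25}
        out = tr.assign_nearest({"asv": "ACGT" * 25}, refs)
        assert out.loc["asv", "genome"] == "g1"
        assert out.loc["asv", "nsti"] == 0.0

    def test_substitution_counting(self):
        base = "ACGT" * 25  # length 100
        two_subs = "TA" + base[2:]
        five_subs = "TATAT" + base[5:]
        refs = {"gA": two_subs, "gB": five_subs}
        out = tr.assign_nearest({"asv": base}, refs)
        assert out.loc["asv", "genome"] == "gA"
        assert out.loc["asv", "nsti"] == pytest.approx(0.02)

    def test_planted_identity_ladder_recovered(self, reference_collection):
        scn, ref = reference_collection
        out = tr.assign_nearest(ref["asv_seqs"], ref["reference_16s"])
        merged = out.join(ref["truth"])
        assert (merged.genome == merged.source_genome).all()
        ladder = merged[merged.target_identity == 0.97]
        assert (abs(ladder.nsti - 0.03) <= 0.005).all()

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty reference"):
            tr.assign_nearest({"a": "ACGT"}, {})

    def test_ties_break_lexicographically(self):
        refs = {"gB": "ACGT" * 25, "gA": "ACGT" * 25}
        out = tr.assign_nearest({"asv": "ACGT" * 25}, refs)
        assert out.loc["asv", "genome"] == "gA"


def _prediction_inputs():
    rel = pd.DataFrame({"s1": [0.5, 0.5], "s2": [1.0, 0.0]},
                       index=["asv1", "asv2"])
    assignments = pd.DataFrame(
        {"genome": ["gA", "gB"], "identity": [0.98, 0.90],
         "nsti": [0.02, 0.10]}, index=["asv1", "asv2"])
    traits = _traits(pd.DataFrame({"fam": [2, 0]}, index=["gA", "gB"]))
    return rel, assignments, traits


class TestPredictGenes:
    def test_hand_arithmetic(self):
        rel, assignments, traits = _prediction_inputs()
        pred = tr.predict_genes(rel, assignments, traits)
        # 0.5 * 2 + 0.5 * 0 = 1.0 ; 1.0 * 2 = 2.0
        assert pred.gene_abundance.loc["fam", "s1"] == pytest.approx(1.0)
        assert pred.gene_abundance.loc["fam", "s2"] == pytest.approx(2.0)

    def test_zero_copies_give_zero_abundance(self):
        rel, assignments, _ = _prediction_inputs()
        traits = _traits(pd.DataFrame({"fam": [0, 0]}, index=["gA", "gB"]))
        pred = tr.predict_genes(rel, assignments, traits)
        assert (pred.gene_abundance.values == 0).all()

    def test_weighted_nsti_closed_form(self):
        rel, assignments, traits = _prediction_inputs()
        rel = pd.DataFrame({"s": [0.75, 0.25]}, index=["asv1", "asv2"])
        pred = tr.predict_genes(rel, assignments, traits)
        # 0.75*0.02 + 0.25*0.10 = 0.04 (weights sum to 1)
        assert pred.weighted_nsti["s"] == pytest.approx(0.04, abs=1e-12)

    def test_weighted_nsti_zero_when_all_nsti_zero(self):
        rel, assignments, traits = _prediction_inputs()
        assignments["nsti"] = 0.0
        pred = tr.predict_genes(rel, assignments, traits)
        assert (pred.weighted_nsti == 0.0).all()

    def test_weighted_nsti_is_convex_combination(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = rng.integers(2, 8)
            asvs = [f"a{i}" for i in range(n)]
            rel = pd.DataFrame(rng.dirichlet(np.ones(n), size=3).T,
                               index=asvs, columns=["s1", "s2", "s3"])
            nsti = rng.uniform(0, 0.3, n)
            assignments = pd.DataFrame(
                {"genome": ["g"] * n, "identity": 1 - nsti, "nsti": nsti},
                index=asvs)
            traits = _traits(pd.DataFrame({"fam": [1]}, index=["g"]))
            pred = tr.predict_genes(rel, assignments, traits)
            assert (pred.weighted_nsti >= nsti.min() - 1e-12).all()
            assert (pred.weighted_nsti <= nsti.max() + 1e-12).all()

    def test_doubling_an_asv_doubles_its_contribution(self):
        rel, assignments, traits = _prediction_inputs()
        contrib1 = tr.taxon_contributions(rel, assignments, traits,
                                          group_threshold=0.0)
        rel2 = rel.copy()
        rel2.loc["asv1"] *= 2  # pre-normalisation scaling
        contrib2 = tr.taxon_contributions(rel2, assignments, traits,
                                          group_threshold=0.0)
        c1 = contrib1.set_index(["sample", "family", "taxon"]).contribution
        c2 = contrib2.set_index(["sample", "family", "taxon"]).contribution
        for key in c1.index:
            if key[2] == "asv1":
                assert c2[key] == pytest.approx(2 * c1[key])


class TestFoldChange:
    def _setup(self):
        gene = pd.DataFrame(
            {"c.d1.r1": [2.0], "c.d1.r2": [2.0], "t.d1.r1": [4.0],
             "t.d1.r2": [4.0], "inoc.d0.r1": [3.0]}, index=["fam"])
        meta = pd.DataFrame({
            "treatment": ["control", "control", "treated", "treated", "inoc"],
            "day": [1, 1, 1, 1, 0],
            "replicate": [1, 2, 1, 2, 1],
        }, index=gene.columns)
        return gene, meta

    def test_fold_change_arithmetic(self):
        gene, meta = self._setup()
        out = tr.fold_change_vs_control(gene, meta, "control",
                                        inoculum_label="inoc")
        fc = out.set_index(["treatment", "day"]).fold_change
        assert fc[("treated", 1)] == pytest.approx(2.0)
        assert fc[("control", 1)] == pytest.approx(1.0)

    def test_inoculum_compared_to_overall_control_mean(self):
        gene, meta = self._setup()
        out = tr.fold_change_vs_control(gene, meta, "control",
                                        inoculum_label="inoc")
        fc = out.set_index(["treatment", "day"]).fold_change
        assert fc[("inoc", 0)] == pytest.approx(3.0 / 2.0)

    def test_zero_denominator_floored_and_flagged(self):
        gene, meta = self._setup()
        gene.loc["fam", ["c.d1.r1", "c.d1.r2"]] = 0.0
        out = tr.fold_change_vs_control(gene, meta, "control",
                                        inoculum_label="inoc")
        treated = out[(out.treatment == "treated")].iloc[0]
        assert treated.floored
        assert np.isfinite(treated.fold_change)

    def test_missing_control_rejected(self):
        gene, meta = self._setup()
        with pytest.raises(ValueError, match="control"):
            tr.fold_change_vs_control(gene, meta, "no-such-treatment")


class TestContributions:
    def test_single_taxon_is_total_without_other(self):
        rel = pd.DataFrame({"s": [1.0]}, index=["asv1"])
        assignments = pd.DataFrame({"genome": ["g"], "identity": [1.0],
                                    "nsti": [0.0]}, index=["asv1"])
        traits = _traits(pd.DataFrame({"fam": [3]}, index=["g"]))
        out = tr.taxon_contributions(rel, assignments, traits)
        assert list(out.taxon) == ["asv1"]
        assert out.contribution.iloc[0] == pytest.approx(3.0)

    def test_minor_taxa_grouped_into_other(self):
        rel = pd.DataFrame({"s": [0.996, 0.004]}, index=["big", "small"])
        assignments = pd.DataFrame({"genome": ["g", "g"],
                                    "identity": [1.0, 1.0],
                                    "nsti": [0.0, 0.0]},
                                   index=["big", "small"])
        traits = _traits(pd.DataFrame({"fam": [1]}, index=["g"]))
        out = tr.taxon_contributions(rel, assignments, traits,
                                     group_threshold=0.005)
        assert set(out.taxon) == {"big", "Other"}

    def test_conservation_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n_taxa, n_samples, n_genomes = 6, 4, 3
            asvs = [f"a{i}" for i in range(n_taxa)]
            rel = pd.DataFrame(rng.dirichlet(np.ones(n_taxa), size=n_samples).T,
                               index=asvs,
                               columns=[f"s{i}" for i in range(n_samples)])
            genomes = [f"g{i}" for i in range(n_genomes)]
            assignments = pd.DataFrame({
                "genome": rng.choice(genomes, n_taxa),
                "identity": rng.uniform(0.9, 1.0, n_taxa),
                "nsti": rng.uniform(0, 0.1, n_taxa)}, index=asvs)
            traits = _traits(pd.DataFrame(
                {"fam": rng.integers(0, 5, n_genomes)}, index=genomes))
            pred = tr.predict_genes(rel, assignments, traits)
            contrib = tr.taxon_contributions(rel, assignments, traits)
            total = contrib.groupby(["sample", "family"]).contribution.sum()
            for (sample, family), value in total.items():
                assert value == pytest.approx(
                    pred.gene_abundance.loc[family, sample], abs=1e-9)


class TestClosestTraitBearer:
    def _identities(self):
        return pd.DataFrame({"gA": [0.99], "gB": [0.95], "gC": [0.90]},
                            index=["asv"])

    def test_nearest_carrier_when_nearest_overall_carries(self):
        traits = _traits(pd.DataFrame({"fam": [1, 1, 0]},
                                      index=["gA", "gB", "gC"]))
        assert tr.closest_trait_bearer("asv", self._identities(), traits,
                                       "fam") == "gA"

    def test_falls_back_to_second_nearest_carrier(self):
        traits = _traits(pd.DataFrame({"fam": [0, 1, 1]},
                                      index=["gA", "gB", "gC"]))
        assert tr.closest_trait_bearer("asv", self._identities(), traits,
                                       "fam") == "gB"

    def test_family_without_carriers_rejected(self):
        traits = _traits(pd.DataFrame({"fam": [0, 0, 0]},
                                      index=["gA", "gB", "gC"]))
        with pytest.raises(ValueError, match="no genome carries"):
            tr.closest_trait_bearer("asv", self._identities(), traits, "fam")
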