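"""Signed genetic-evidence features: encoding, conventions, tri-state integrity."""

import numpy as np
import pandas as pd
import pytest

from doepred.genetics import (bin_support_counts, build_feature_matrix, burden_features,
                              encode_association, eqtl_direction_features,
                              l2g_harmonic_features, load_feature_schema, missense_score,
                              rare_variant_features)

SCHEMA = load_feature_schema()


class TestEncodeAssociation:
    @pytest.mark.parametrize("p,sign,expected", [
        (0.01, -1, -2.0),
        (0.2, +1, 0.0),
        (0.05, +1, 0.0),  # strict threshold: boundary excluded
        (1e-4, +1, 4.0),
        (1.0, -1, 0.0),
    ])
    def test_examples(self, p, sign, expected):
        assert encode_association(p, sign) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.5, np.nan])
    def test_domain_error(self, p):
        with pytest.raises(ValueError):
            encode_association(p, 1)

    def test_monotone_in_significance(self, rng):
        ps = np.sort(rng.uniform(1e-12, 0.05 - 1e-12, size=200))
        vals = [abs(encode_association(p, 1)) for p in ps]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestMissenseScore:
    def test_proportion(self):
        calls = [("qualitative", "D")] * 15 + [("qualitative", "T")] * 15
        assert missense_score(calls) == pytest.approx(0.5)

    def test_too_few_predictions_missing(self):
        assert missense_score([("qualitative", "D")] * 7) is None

    def test_rank_score_strictly_above_threshold(self):
        assert missense_score([("quantitative", 0.95)] * 8) == 1.0
        assert missense_score([("quantitative", 0.9)] * 8) == 0.0

    def test_tools_without_prediction_not_counted(self):
        calls = [("qualitative", "D")] * 8 + [("qualitative", None)] * 22
        assert missense_score(calls) == 1.0


def _assoc(rows):
    cols = ["variant_id", "gene_id", "disease_code", "dataset", "af_bin",
            "beta_sign", "p_value", "functional_class", "missense_score"]
    df = pd.DataFrame(rows, columns=cols[: len(rows[0])] if rows else cols)
    for c in cols:
        if c not in df.columns:
            df[c] = np.nan
    return df


def _eqtl(rows):
    return pd.DataFrame(rows, columns=["variant_id", "gene_id", "eqtl_sign",
                                       "significant", "distance_to_gene"])


class TestEqtlDirection:
    def test_risk_raising_expression_supports_inhibitor(self):
        a = _assoc([("v1", "g1", "D01", "gwas", "common", +1, 1e-3, "unknown")])
        e = _eqtl([("v1", "g1", +1, True, 1000)])
        out = eqtl_direction_features(a, e)
        assert out.loc[("g1", "D01"), "eqtl_inhibitor"] == pytest.approx(3.0)
        assert out.loc[("g1", "D01"), "eqtl_activator"] == 0.0  # tested, no signal

    def test_protective_raising_expression_supports_activator(self):
        a = _assoc([("v1", "g1", "D01", "gwas", "common", -1, 1e-2, "unknown")])
        e = _eqtl([("v1", "g1", +1, True, 1000)])
        out = eqtl_direction_features(a, e)
        assert out.loc[("g1", "D01"), "eqtl_activator"] == pytest.approx(-2.0)

    def test_closest_gene_wins(self):
        a = _assoc([("v1", "gX", "D01", "gwas", "common", +1, 1e-3, "unknown")])
        e = _eqtl([("v1", "near", +1, True, 5_000), ("v1", "far", +1, True, 50_000)])
        out = eqtl_direction_features(a, e)
        assert ("near", "D01") in out.index and ("far", "D01") not in out.index

    def test_distance_tie_breaks_lexicographically(self):
        a = _assoc([("v1", "gX", "D01", "gwas", "common", +1, 1e-3, "unknown")])
        e = _eqtl([("v1", "zeta", +1, True, 5000), ("v1", "alpha", +1, True, 5000)])
        out = eqtl_direction_features(a, e)
        assert out.index.get_level_values(0).tolist() == ["alpha"]

    def test_most_significant_per_direction(self):
        a = _assoc([("v1", "g1", "D01", "gwas", "common", +1, 1e-3, "unknown"),
                    ("v2", "g1", "D01", "gwas", "common", +1, 1e-5, "unknown")])
        e = _eqtl([("v1", "g1", +1, True, 1000), ("v2", "g1", +1, True, 1000)])
        out = eqtl_direction_features(a, e)
        assert out.loc[("g1", "D01"), "eqtl_inhibitor"] == pytest.approx(5.0)

    def test_eqtl_without_association_ignored(self):
        out = eqtl_direction_features(_assoc([]), _eqtl([("v9", "g1", +1, True, 10)]))
        assert len(out) == 0


class TestL2G:
    def _l2g(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "disease_code", "mechanism", "score"])

    def test_single_score_identity(self):
        out = l2g_harmonic_features(self._l2g([("g1", "D01", "inhibitor", 0.7)]))
        assert out.loc[("g1", "D01"), "l2g_inhibitor"] == pytest.approx(0.7)

    def test_all_ones_saturate(self):
        out = l2g_harmonic_features(self._l2g([("g1", "D01", "activator", 1.0)] * 5))
        assert out.loc[("g1", "D01"), "l2g_activator"] == pytest.approx(1.0)

    def test_larger_sum_retained(self):
        out = l2g_harmonic_features(self._l2g([("g1", "D01", "activator", 0.4),
                                               ("g1", "D01", "inhibitor", 0.6)]))
        assert out.loc[("g1", "D01"), "l2g_inhibitor"] == pytest.approx(0.6)
        assert out.loc[("g1", "D01"), "l2g_activator"] == 0.0

    def test_harmonic_weighting(self):
        # H = (0.9/1 + 0.3/4) / (1 + 1/4)
        out = l2g_harmonic_features(self._l2g([("g1", "D01", "inhibitor", 0.3),
                                               ("g1", "D01", "inhibitor", 0.9)]))
        assert out.loc[("g1", "D01"), "l2g_inhibitor"] == pytest.approx(0.975 / 1.25)


class TestRareAndBurden:
    def test_gof_category_direct_encoding(self):
        a = _assoc([("v1", "g1", "D01", "finngen", "rare", +1, 1e-4, "GOF")])
        out = rare_variant_features(a)
        assert out.loc[("g1", "D01"), "rare_finngen_gof"] == pytest.approx(4.0)

    def test_most_significant_variant_wins(self):
        a = _assoc([("v1", "g1", "D01", "finngen", "rare", +1, 1e-3, "GOF"),
                    ("v2", "g1", "D01", "finngen", "rare", -1, 1e-5, "GOF")])
        out = rare_variant_features(a)
        assert out.loc[("g1", "D01"), "rare_finngen_gof"] == pytest.approx(-5.0)

    def test_family_tested_zero_vs_untested_missing(self):
        a = _assoc([("v1", "g1", "D01", "finngen", "rare", +1, 0.5, "GOF")])
        out = rare_variant_features(a)
        row = out.loc[("g1", "D01")]
        assert (row[[c for c in out.columns if "finngen" in c]] == 0).all()
        assert row[[c for c in out.columns if "genebass" in c]].isna().all()

    def test_missense_strata_split_at_half(self):
        a = _assoc([("v1", "g1", "D01", "finngen", "rare", +1, 1e-3, "missense_other", 0.8),
                    ("v2", "g1", "D01", "finngen", "rare", +1, 1e-2, "missense_other", 0.5)])
        out = rare_variant_features(a)
        assert out.loc[("g1", "D01"), "rare_finngen_missense_del"] == pytest.approx(3.0)
        assert out.loc[("g1", "D01"), "rare_finngen_missense_ben"] == pytest.approx(2.0)

    def test_unknown_functional_class_goes_to_other(self):
        a = _assoc([("v1", "g1", "D01", "finngen", "rare", +1, 1e-3, "weird_class")])
        out = rare_variant_features(a)
        assert out.loc[("g1", "D01"), "rare_finngen_other"] == pytest.approx(3.0)

    def _burden(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "disease_code", "dataset",
                                           "mask", "beta_sign", "p_value"])

    def test_burden_encoding(self):
        b = self._burden([("g1", "D01", "finngen", "plof", -1, 0.04)])
        out = burden_features(b)
        assert out.loc[("g1", "D01"), "burden_finngen_plof"] == pytest.approx(-np.log10(0.04) * -1)

    def test_burden_nonsignificant_zero_untested_missing(self):
        b = self._burden([("g1", "D01", "finngen", "plof", +1, 0.06)])
        out = burden_features(b)
        assert out.loc[("g1", "D01"), "burden_finngen_plof"] == 0.0
        assert np.isnan(out.loc[("g1", "D01"), "burden_genebass_plof"])


class TestFeatureMatrix:
    def test_shape_and_group_cardinalities(self):
        assert len(SCHEMA) == 31
        counts = SCHEMA["group"].value_counts()
        assert counts["common"] == 4 and counts["rare"] == 14
        assert counts["burden"] == 9 and counts["complementary"] == 4

    def test_matrix_follows_pairs_and_schema(self, small_cfg):
        from doepred.simulate import generate_gene_disease_labels, generate_genetic_associations

        labels = generate_gene_disease_labels(small_cfg, 300)
        d = generate_genetic_associations(small_cfg, labels)
        F = build_feature_matrix(labels, d.associations, d.eqtl_links, d.burden,
                                 d.l2g, d.complementary)
        assert F.shape == (300, 31)
        assert list(F.columns) == SCHEMA["feature_name"].tolist()

    def test_tri_state_survives_file_roundtrip(self, tmp_path, small_cfg):
        from doepred.simulate import generate_gene_disease_labels, generate_genetic_associations

        labels = generate_gene_disease_labels(small_cfg, 300)
        d = generate_genetic_associations(small_cfg, labels)
        F = build_feature_matrix(labels, d.associations, d.eqtl_links, d.burden,
                                 d.l2g, d.complementary)
        p = tmp_path / "features.tsv"
        F.to_csv(p, sep="\t")  # empty field = missing, "0.0" = observed zero
        back = pd.read_csv(p, sep="\t", index_col=[0, 1])
        assert back.isna().equals(F.isna())
        assert np.allclose(back.fillna(0).to_numpy(), F.fillna(0).to_numpy())

    def test_sign_antisymmetry_end_to_end(self, small_cfg):
        """Flipping every beta sign in the raw tables mirrors the feature matrix.

        Concordance-derived columns swap between the activator and inhibitor
        variants (a flipped beta moves the variant to the opposite concordance
        group); every signed column flips sign; Locus2gene sums swap without a
        flip (scores carry no sign); and bin-support counts swap mechanisms.
        """
        from doepred.simulate import generate_gene_disease_labels, generate_genetic_associations

        labels = generate_gene_disease_labels(small_cfg, 400)
        d = generate_genetic_associations(small_cfg, labels)
        F = build_feature_matrix(labels, d.associations, d.eqtl_links, d.burden,
                                 d.l2g, d.complementary)

        assoc = d.associations.assign(beta_sign=-d.associations["beta_sign"])
        burden = d.burden.assign(beta_sign=-d.burden["beta_sign"])
        l2g = d.l2g.assign(mechanism=d.l2g["mechanism"].map(
            {"activator": "inhibitor", "inhibitor": "activator"}))
        comp = d.complementary.copy()
        for c in ("clinical_gof", "clinical_lof", "mouse_ko_direction", "expression_direction"):
            comp[c] = -comp[c]
        F2 = build_feature_matrix(labels, assoc, d.eqtl_links, burden, l2g, comp)

        expected = -F.copy()
        expected["eqtl_inhibitor"], expected["eqtl_activator"] = \
            (-F["eqtl_activator"]).to_numpy(), (-F["eqtl_inhibitor"]).to_numpy()
        expected["l2g_inhibitor"], expected["l2g_activator"] = \
            F["l2g_activator"].to_numpy(), F["l2g_inhibitor"].to_numpy()
        pd.testing.assert_frame_equal(F2, expected, atol=1e-12)

        for m, m2 in (("inhibitor", "activator"), ("activator", "inhibitor")):
            assert bin_support_counts(F2, m).equals(bin_support_counts(F, m2))


class TestBinSupport:
    def _vec(self, **kw):
        v = pd.Series(np.nan, index=SCHEMA["feature_name"])
        for k, val in kw.items():
            v[k] = val
        return v

    def test_common_plus_rare_counts_two(self):
        v = self._vec(eqtl_inhibitor=2.5, rare_finngen_gof=3.0)
        assert bin_support_counts(v, "inhibitor") == 2
        assert bin_support_counts(v, "activator") == 0

    def test_all_zero_vector_supports_nothing(self):
        v = pd.Series(0.0, index=SCHEMA["feature_name"])
        assert bin_support_counts(v, "inhibitor") == 0
        assert bin_support_counts(v, "activator") == 0

    def test_lof_protective_supports_inhibitor(self):
        v = self._vec(rare_genebass_lof_hc=-4.0, burden_jurgens_plof=-2.0)
        assert bin_support_counts(v, "inhibitor") == 2

    def test_complementary_features_outside_bins(self):
        v = self._vec(clinical_gof=5.0)
        assert bin_support_counts(v, "inhibitor") == 0

    def test_invalid_mechanism_rejected(self):
        with pytest.raises(ValueError):
            bin_support_counts(self._vec(), "other")

    def test_vector_level_antisymmetry(self, rng):
        """Induced transform (flip signs, swap direction-paired columns) swaps counts."""
        names = SCHEMA["feature_name"].tolist()
        for _ in range(200):
            vals = rng.choice([np.nan, 0.0, 1.0], size=31, p=[0.5, 0.2, 0.3])
            vals = vals * rng.normal(size=31)
            v = pd.Series(vals, index=names)
            w = -v.copy()
            w["eqtl_inhibitor"], w["eqtl_activator"] = -v["eqtl_activator"], -v["eqtl_inhibitor"]
            w["l2g_inhibitor"], w["l2g_activator"] = v["l2g_activator"], v["l2g_inhibitor"]
            assert bin_support_counts(w, "inhibitor") == bin_support_counts(v, "activator")
            assert bin_support_counts(w, "activator") == bin_support_counts(v, "inhibitor")
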