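"""Variant filtration, consequence taxonomy, genotype classes, contrasts, PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from sibxpress import FilterCriteria, SimulationConfig, read_vcf
from sibxpress.panel import ABSENT, MISSING, GenotypePanel, VARIANT_COLUMNS
from sibxpress.simulate import simulate_founders
from sibxpress.variants import (
    breed_frequency_contrast,
    classify_consequence,
    classify_consequences,
    consequence_tally,
    filter_panel,
    genotype_class_counts,
    genotype_pca,
    table_summary,
)


def build_panel(genotypes, quals=None, gq=None, breeds=None, consequences=None):
    """genotypes: (n_var, n_samples, 2) list/array with -1 missing, -2 absent."""
    geno = np.array(genotypes, dtype=np.int8)
    n_var, n_samp, _ = geno.shape
    variants = pd.DataFrame(
        {
            "chrom": ["chr1"] * n_var,
            "pos": np.arange(1, n_var + 1) * 100,
            "ref": "C", "alt": "T",
            "qual": quals if quals is not None else [99.0] * n_var,
            "gene": [f"g{i}" for i in range(n_var)],
            "consequence": consequences if consequences is not None else [""] * n_var,
        },
        columns=VARIANT_COLUMNS,
    )
    ids = [f"s{i}" for i in range(n_samp)]
    samples = pd.DataFrame(
        {"breed": breeds if breeds is not None else [""] * n_samp,
         "sex": "M", "generation": 0, "family": ""},
        index=pd.Index(ids, name="id"),
    )
    gqa = np.array(gq, dtype=np.float32) if gq is not None else None
    return GenotypePanel(variants, samples, geno, gqa)


HOM_REF, HET, HOM_ALT, MISS = (0, 0), (0, 1), (1, 1), (-1, -1)


class TestFilterPanel:
    def test_site_quality_boundary_pass_at_equality(self):
        panel = build_panel([[HET] * 4, [HET] * 4, [HET] * 4],
                            quals=[29.9, 30.0, 31.0])
        res = filter_panel(panel, FilterCriteria())
        assert res.panel.n_variants == 2
        assert res.n_low_site_quality == 1
        assert 29.9 not in res.panel.variants["qual"].to_numpy()

    def test_missing_rate_arithmetic(self):
        # 20 samples, 5 masked genotypes = 25% missing > 20% -> dropped;
        # 4 masked = 20% -> kept (max rate passes at equality)
        drop = [MISS] * 5 + [HET] * 15
        keep = [MISS] * 4 + [HET] * 16
        panel = build_panel([drop, keep])
        res = filter_panel(panel, FilterCriteria())
        assert list(res.panel.variants["gene"]) == ["g1"]
        assert res.n_high_missing == 1

    def test_low_gq_calls_masked_then_rate_applied(self):
        gq = [[10.0, 99.0, 99.0, 99.0, 99.0]]  # 1/5 masked = 20% -> kept
        panel = build_panel([[HET] * 5], gq=gq)
        res = filter_panel(panel, FilterCriteria())
        assert res.n_calls_masked == 1
        assert res.panel.n_variants == 1
        assert (res.panel.genotypes[0, 0] == MISSING).all()

    def test_hand_enumerated_fixture(self):
        # 10 variants; 3 fail by construction: low site quality (g0),
        # missing rate 50% (g1), GQ-masking pushing rate to 50% (g2)
        genos = [[HET, HET]] * 10
        genos[1] = [MISS, HET]
        quals = [10.0] + [99.0] * 9
        gq = [[99.0, 99.0]] * 10
        gq[2] = [5.0, 99.0]
        panel = build_panel(genos, quals=quals, gq=gq)
        res = filter_panel(panel, FilterCriteria())
        assert res.n_in == 10 and res.n_out == 7
        assert set(res.panel.variants["gene"]) == {f"g{i}" for i in (3, 4, 5, 6, 7, 8, 9)}

    def test_empty_panel_warns_not_fails(self):
        panel = build_panel(np.empty((0, 3, 2)))
        with pytest.warns(UserWarning, match="empty"):
            res = filter_panel(panel, FilterCriteria())
        assert res.n_out == 0

    def test_order_independence(self):
        rng = np.random.default_rng(3)
        genos = rng.integers(0, 2, size=(12, 6, 2))
        quals = rng.uniform(20, 40, 12)
        panel = build_panel(genos, quals=quals)
        perm = rng.permutation(12)
        permuted = GenotypePanel(
            panel.variants.iloc[perm].reset_index(drop=True),
            panel.samples, panel.genotypes[perm])
        a = filter_panel(panel, FilterCriteria()).panel
        b = filter_panel(permuted, FilterCriteria()).panel
        assert set(a.variants["pos"]) == set(b.variants["pos"])


class TestConsequences:
    @pytest.mark.parametrize("raw,category,high", [
        ("stop_gained", "stop_gained", True),
        ("Stop gain", "stop_gained", True),
        ("stop_lost", "stop_lost", True),
        ("start_lost", "start_lost", True),
        ("splice_acceptor_variant", "splice_acceptor", True),
        ("splice_donor_variant&intron_variant", "splice_donor", True),
        ("frameshift_variant", "frameshift", True),
        ("INDEL frameshift", "frameshift", True),
        ("missense_deleterious", "missense_deleterious", False),
        ("synonymous_variant", "other", False),
        ("", "other", False),
    ])
    def test_taxonomy(self, raw, category, high):
        assert classify_consequence(raw) == category
        from sibxpress.variants import HIGH_IMPACT
        assert (category in HIGH_IMPACT) is high

    def test_unknown_string_warns_to_other(self):
        with pytest.warns(UserWarning, match="unknown consequence"):
            assert classify_consequence("gibberish_effect") == "other"

    def test_panel_tally(self):
        panel = build_panel([[HET]] * 4,
                            consequences=["stop_gained", "frameshift_variant",
                                          "missense_deleterious", ""])
        cls = classify_consequences(panel)
        tally = consequence_tally(cls)
        assert tally["HIGH_total"] == 2
        assert tally["HIGH_snv_only"] == 1  # frameshift reported separately


class TestGenotypeClassCounts:
    def test_table_row_pattern(self):
        # the 0 hom-alt / 1 het / 18 hom-ref pattern of a rare stop variant
        panel = build_panel([[HET] + [HOM_REF] * 18])
        counts = genotype_class_counts(panel)
        assert counts.loc[0, ["hom_alt", "het", "hom_ref", "missing"]].tolist() == \
            [0, 1, 18, 0]

    def test_all_missing(self):
        panel = build_panel([[MISS] * 7])
        counts = genotype_class_counts(panel)
        assert counts.loc[0].tolist() == [0, 0, 0, 7, 0, 0]

    def test_random_fixture_matches_brute_force(self):
        rng = np.random.default_rng(0)
        geno = rng.choice([-2, -1, 0, 1], size=(20, 50, 2), p=[0.05, 0.1, 0.5, 0.35])
        panel = build_panel(geno)
        counts = genotype_class_counts(panel)
        for vi in range(20):
            tally = dict(hom_alt=0, het=0, hom_ref=0, missing=0, hemi=0, absent=0)
            for si in range(50):
                a, b = geno[vi, si]
                present = [x for x in (a, b) if x != -2]
                if not present:
                    tally["absent"] += 1
                elif -1 in present:
                    tally["missing"] += 1
                elif len(present) == 1:
                    tally["hemi"] += 1
                else:
                    tally[["hom_ref", "het", "hom_alt"][sum(present)]] += 1
            assert counts.loc[vi].to_dict() == tally

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(arrays(np.int8, (5, 8, 2), elements=st.sampled_from([-2, -1, 0, 1])))
    def test_classes_always_partition_samples(self, geno):
        counts = genotype_class_counts(build_panel(geno))
        assert (counts.sum(axis=1) == 8).all()
        assert (counts >= 0).all().all()

    def test_hemizygous_counted_separately(self):
        panel = build_panel([[(0, ABSENT), (1, ABSENT), HET]])
        counts = genotype_class_counts(panel)
        assert counts.loc[0, "hemi"] == 2 and counts.loc[0, "het"] == 1

    def test_summary_table_shape(self):
        panel = build_panel([[HET] * 3] * 2, consequences=["stop_gained", ""])
        t = table_summary(panel)
        assert {"gene", "qual", "category", "hom_alt", "het", "hom_ref"} <= set(t.columns)
        assert len(t) == 2


class TestBreedContrast:
    def test_fixed_opposite(self):
        panel = build_panel([[HOM_ALT] * 3 + [HOM_REF] * 3],
                            breeds=["a"] * 3 + ["b"] * 3)
        t = breed_frequency_contrast(panel)
        assert t.loc[0, ["af_1", "af_2", "delta"]].tolist() == [1.0, 0.0, 1.0]
        assert bool(t.loc[0, "near_fixed_opposite"])

    def test_single_het_frequency(self):
        panel = build_panel([[HET] + [HOM_REF] * 4 + [HOM_REF] * 5],
                            breeds=["a"] * 5 + ["b"] * 5)
        t = breed_frequency_contrast(panel)
        assert t.loc[0, "af_1"] == pytest.approx(0.1)

    def test_simulator_fixed_fraction_recovered(self):
        cfg = SimulationConfig(seed=4, n_autosomal_genes=400, n_z_genes=0,
                               n_w_genes=0, breed_fixed_fraction=0.3,
                               het_null_fraction=0.0, trans_module_size=0,
                               mesenchyme_module_size=0, n_lps_induced=0,
                               n_lps_repressed=0)
        panel, _ = simulate_founders(cfg)
        t = breed_frequency_contrast(panel)
        # exclude the trans-regulator locus (always near-fixed by design)
        frac = t["near_fixed_opposite"][:-1].mean()
        assert frac == pytest.approx(0.3, abs=3 * np.sqrt(0.3 * 0.7 / 400))

    def test_all_missing_breed_flagged(self):
        panel = build_panel([[MISS, MISS, HET, HET]], breeds=["a", "a", "b", "b"])
        with pytest.warns(UserWarning, match="all-missing"):
            t = breed_frequency_contrast(panel)
        assert not t.loc[0, "defined"]
        assert np.isnan(t.loc[0, "af_1"])


class TestGenotypePCA:
    def test_identical_samples_identical_coordinates(self):
        panel = build_panel([[HET, HET, HOM_REF], [HOM_ALT, HOM_ALT, HOM_REF],
                             [HOM_REF, HOM_REF, HET]])
        coords = genotype_pca(panel, 2)
        np.testing.assert_allclose(coords.iloc[0], coords.iloc[1], atol=1e-12)

    def test_pc1_partitions_divergent_breeds(self):
        cfg = SimulationConfig(seed=9, n_founders_per_breed=5,
                               breed_fixed_fraction=1.0, het_null_fraction=0.0,
                               n_autosomal_genes=50, n_z_genes=0, n_w_genes=0,
                               trans_module_size=0, mesenchyme_module_size=0,
                               n_lps_induced=0, n_lps_repressed=0)
        panel, _ = simulate_founders(cfg)
        coords = genotype_pca(panel, 2)
        pc1 = coords["PC1"].to_numpy()
        breed = panel.samples["breed"].to_numpy()
        a, b = pc1[breed == "broiler"], pc1[breed == "layer"]
        assert a.max() < b.min() or b.max() < a.min()

    def test_constant_variant_contributes_nothing(self):
        base = [[HET, HOM_REF, HOM_ALT, HET], [HOM_ALT, HET, HOM_REF, HOM_REF]]
        with_const = base + [[HET, HET, HET, HET]]
        c1 = genotype_pca(build_panel(base), 2)
        c2 = genotype_pca(build_panel(with_const), 2)
        np.testing.assert_allclose(np.abs(c1.to_numpy()), np.abs(c2.to_numpy()),
                                   atol=1e-10)

    def test_component_reduction_warns(self):
        panel = build_panel([[HET, HOM_REF, HOM_ALT]] * 5)
        with pytest.warns(UserWarning, match="reducing"):
            coords = genotype_pca(panel, 10)
        assert coords.shape[1] == 2


class TestVcfRoundTrip:
    def test_write_read_preserves_genotypes(self, tmp_path, tiny_config):
        panel, _ = simulate_founders(tiny_config)
        path = tmp_path / "founders.vcf"
        panel.to_vcf(path)
        back = read_vcf(path)
        assert back.n_variants == panel.n_variants
        assert back.sample_ids == panel.sample_ids
        np.testing.assert_array_equal(back.genotypes, panel.genotypes)
        assert list(back.variants["consequence"]) == list(panel.variants["consequence"])

    def test_multiallelic_split(self, tmp_path):
        text = "\n".join([
            "##fileformat=VCFv4.2",
            "##contig=<ID=chr1>",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2",
            "chr1\t100\t.\tC\tT,G\t50\tPASS\t.\tGT\t0/1\t2/2",
        ]) + "\n"
        path = tmp_path / "multi.vcf"
        path.write_text(text)
        panel = read_vcf(path)
        assert panel.n_variants == 2
        # record for alt T: s2's G alleles are unusable -> missing
        t_rec = panel.genotypes[0]
        assert t_rec[0].tolist() == [0, 1]
        assert (t_rec[1] == MISSING).all()
        g_rec = panel.genotypes[1]
        assert g_rec[1].tolist() == [1, 1]
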