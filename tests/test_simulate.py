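"""The synthetic-data generator: planted structure, determinism, and
self-consistency against its own configured parameters."""

import numpy as np
import pandas as pd
import pytest

from mztenh import coverage as cov, io, regions as reg, simulate


@pytest.fixture(scope="module")
def spec():
    return simulate.default_genome_spec(n_genes=160, seed=9)


@pytest.fixture(scope="module")
def config():
    return simulate.SimulationConfig(regions_per_class=30, depth=150_000,
                                     seed=9)


class TestAnnotation:
    def test_single_gene_passthrough(self):
        g = simulate.Gene("g1", "chr1", 1_000, "+", [(1_000, 1_300)], 25,
                          "unaffected", "strictly-zygotic")
        one = simulate.SyntheticGenomeSpec([("chr1", 10_000)], [g])
        tss, exons, expr = simulate.generate_annotation(one, seed=1)
        assert len(tss) == 1
        assert tss.loc[0, "tag_count"] == 25

    def test_deterministic_given_seed(self, spec):
        a = simulate.generate_annotation(spec, seed=4)
        b = simulate.generate_annotation(spec, seed=4)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_overlapping_genes_rejected(self):
        g1 = simulate.Gene("g1", "chr1", 1_000, "+", [(1_000, 1_300)], 25,
                           "unaffected", "strictly-zygotic")
        g2 = simulate.Gene("g2", "chr1", 1_000, "+", [(1_000, 1_300)], 25,
                           "NPS-down", "strictly-zygotic")
        bad = simulate.SyntheticGenomeSpec([("chr1", 10_000)], [g1, g2])
        with pytest.raises(ValueError, match="overlapping"):
            simulate.generate_annotation(bad, seed=1)

    def test_unaffected_group_activates_earlier(self, spec):
        """At the first post-activation stage the unaffected group's
        mean log2 fold-increase exceeds the NPS-down group's (computed
        from the generator's own ramp parameters)."""
        _, _, expr = simulate.generate_annotation(spec, seed=4)
        logx = np.log2(expr[list(simulate.RNA_STAGES)] + 0.1)
        fc = logx.sub(logx["2-cell"], axis=0)
        by_group = fc.groupby(expr["expression_group"]).mean()
        assert by_group.loc["unaffected", "1K-cell"] > \
            by_group.loc["NPS-down", "1K-cell"]
        # and the NPS-down group overtakes by the last stage
        assert by_group.loc["NPS-down", "shield"] > \
            by_group.loc["unaffected", "shield"]

    def test_maternal_zygotic_cutoff_respected(self, spec):
        _, _, expr = simulate.generate_annotation(spec, seed=4)
        mz = expr.loc[expr["contribution"] == "maternal-zygotic", "2-cell"]
        sz = expr.loc[expr["contribution"] == "strictly-zygotic", "2-cell"]
        assert (mz > 0.5).all()
        assert (sz <= 0.5).all()

    def test_invariants_enforced_by_spec_type(self):
        with pytest.raises(ValueError, match="first exon"):
            simulate.SyntheticGenomeSpec(
                [("chr1", 10_000)],
                [simulate.Gene("g1", "chr1", 500, "+", [(1_000, 1_300)], 5,
                               "unaffected", "strictly-zygotic")])


class TestRegions:
    def test_class_counts_and_labels(self, spec, config):
        truth = simulate.generate_regions(spec, config)
        counts = truth["true_class"].value_counts()
        for cls in simulate.ELEMENT_CLASSES:
            assert counts[cls] == 30

    def test_distal_classes_far_from_every_tss(self, spec, config):
        truth = simulate.generate_regions(spec, config)
        tss_by_chrom = {}
        for g in spec.genes:
            tss_by_chrom.setdefault(g.chrom, []).append(g.tss)
        distal = truth[~truth["true_class"].str.endswith("promoter")]
        for _, r in distal.iterrows():
            d = reg._nearest_tss_distance(
                r["start"], r["end"],
                np.array(tss_by_chrom[r["chrom"]]))
            assert d >= 2_000

    def test_promoter_classes_overlap_a_tss(self, spec, config):
        truth = simulate.generate_regions(spec, config)
        tss = {(g.chrom, g.tss) for g in spec.genes}
        prom = truth[truth["true_class"].str.endswith("promoter")]
        for _, r in prom.iterrows():
            assert any(c == r["chrom"] and r["start"] <= t < r["end"]
                       for c, t in tss)

    def test_source_split_and_id_convention(self, spec, config):
        truth = simulate.generate_regions(spec, config)
        for src, prefix in (("L", "atac_L"), ("P", "atac_P")):
            ids = truth.loc[truth["source"] == src, "region_id"]
            assert ids.str.startswith(prefix).all()
        assert truth["region_id"].is_unique

    def test_cryptic_fraction_planted(self, spec):
        cfg = simulate.SimulationConfig(
            regions_per_class={"H3K4me2-enhancer": 100, "unmarked": 50},
            seed=9)
        truth = simulate.generate_regions(spec, cfg)
        me2 = truth[truth["true_class"] == "H3K4me2-enhancer"]
        assert me2["is_cryptic_tss"].sum() == 7
        assert not truth.loc[truth["true_class"] != "H3K4me2-enhancer",
                             "is_cryptic_tss"].any()

    def test_too_small_genome_errors(self):
        tiny = simulate.default_genome_spec(n_genes=8, n_chromosomes=1,
                                            chrom_length=60_000, seed=9)
        cfg = simulate.SimulationConfig(regions_per_class=50, seed=9)
        with pytest.raises(ValueError):
            simulate.generate_regions(tiny, cfg)

    def test_exactly_2kb_distal_boundary_classified_distal(self):
        region = pd.DataFrame({"region_id": ["r1"], "chrom": ["chr1"],
                               "start": [12_000], "end": [12_300],
                               "source": "L"})
        iso = pd.DataFrame({"chrom": ["chr1"], "pos": [10_000]})
        out = reg.classify_taxonomy(region, iso.iloc[0:0], iso, {"chr1": 1})
        assert out["taxonomy"].tolist() == ["distal"]


class TestCoverageGenerator:
    def test_deterministic_given_seed(self, spec, config):
        profiles = simulate.default_profiles()
        truth = simulate.generate_regions(spec, config)
        a, _ = simulate.simulate_coverage(truth, profiles, config,
                                          dict(spec.chromosomes))
        b, _ = simulate.simulate_coverage(truth, profiles, config,
                                          dict(spec.chromosomes))
        for key in a:
            pd.testing.assert_frame_equal(a[key], b[key])

    def test_missing_profile_errors(self, spec, config):
        profiles = simulate.default_profiles()
        del profiles["poised-enhancer"]
        truth = simulate.generate_regions(spec, config)
        with pytest.raises(ValueError, match="poised"):
            simulate.simulate_coverage(truth, profiles, config,
                                       dict(spec.chromosomes))

    def test_spike_pairs_passed_through(self, spec, config):
        profiles = simulate.default_profiles()
        truth = simulate.generate_regions(spec, config)
        _, spikes = simulate.simulate_coverage(truth, profiles, config,
                                               dict(spec.chromosomes))
        assert set(spikes.values()) == {config.spike_pairs}

    def test_library_padded_to_depth(self, spec, config):
        profiles = simulate.default_profiles()
        truth = simulate.generate_regions(spec, config)
        frags, _ = simulate.simulate_coverage(truth, profiles, config,
                                              dict(spec.chromosomes))
        for frame in frags.values():
            assert len(frame) == config.depth


def empirical_enrichment(truth, profiles, config, chrom_lengths):
    """Run the measurement chain the generator is checked against."""
    frags, _ = simulate.simulate_coverage(truth, profiles, config,
                                          chrom_lengths)
    filtered = {(m, r): cov.filter_fragments(f)
                for (s, m, r), f in frags.items()}
    regions = truth[["region_id", "chrom", "start", "end"]].copy()
    regions["taxonomy"] = "distal"
    regions = reg.build_flanks(regions, chrom_lengths)
    regions["downstream_is_right"] = truth["true_downstream_right"].to_numpy()
    raw = cov.count_coverage(filtered, regions)
    pooled = cov.pool_replicates(raw)
    return cov.enrichment_over_control(pooled)


class TestGeneratorSelfConsistency:
    def test_igg_versus_igg_null_centers_on_one(self, spec):
        cfg = simulate.SimulationConfig(regions_per_class=30, depth=200_000,
                                        seed=10)
        profiles = {c: simulate.ClassProfile(
            c, {m: 1.0 for m in simulate.MARKS},
            {"embryo": 0.5, "egg": 0.5, "sperm": 0.5},
            activity_scatter=0.0)
            for c in simulate.ELEMENT_CLASSES}
        truth = simulate.generate_regions(spec, cfg)
        enr = empirical_enrichment(truth, profiles, cfg,
                                   dict(spec.chromosomes))
        med = enr.stack().median()
        assert med == pytest.approx(1.0, abs=0.05)

    def test_planted_fold_recovered_within_band(self, spec):
        """Fold 4 planted for H3K4me2 with low dispersion and no
        biological scatter: >= 90% of regions measure within [3, 5]."""
        cfg = simulate.SimulationConfig(regions_per_class=30, depth=400_000,
                                        dispersion=0.001, seed=11,
                                        fold_scatter=1e-9)
        profiles = {c: simulate.ClassProfile(
            c, {m: 1.0 for m in simulate.MARKS},
            {"embryo": 0.5, "egg": 0.5, "sperm": 0.5},
            activity_scatter=0.0)
            for c in simulate.ELEMENT_CLASSES}
        profiles["H3K4me2-enhancer"].folds["H3K4me2"] = 4.0
        truth = simulate.generate_regions(spec, cfg)
        enr = empirical_enrichment(truth, profiles, cfg,
                                   dict(spec.chromosomes))
        me2 = enr.loc[truth.set_index("region_id")["true_class"]
                      .eq("H3K4me2-enhancer").reindex(enr.index).fillna(False),
                      "H3K4me2"]
        assert ((me2 >= 3) & (me2 <= 5)).mean() >= 0.9

    def test_convergence_to_configured_fold_at_higher_depth(self, spec):
        """Class-mean enrichment approaches the planted fold within 5%
        relative error when depth is scaled up tenfold (wide regions so
        the library-complexity ceiling stays far away)."""
        base = dict(regions_per_class=30, dispersion=0.001, seed=12,
                    fold_scatter=1e-9, in_region_fraction=0.05,
                    region_width=(3_000, 4_000))
        profiles = {c: simulate.ClassProfile(
            c, {m: 1.0 for m in simulate.MARKS},
            {"embryo": 0.5, "egg": 0.5, "sperm": 0.5},
            activity_scatter=0.0)
            for c in simulate.ELEMENT_CLASSES}
        profiles["H3K4me1-enhancer"].folds["H3K4me1"] = 3.0
        errors = {}
        for depth in (50_000, 500_000):
            cfg = simulate.SimulationConfig(depth=depth, **base)
            truth = simulate.generate_regions(spec, cfg)
            enr = empirical_enrichment(truth, profiles, cfg,
                                       dict(spec.chromosomes))
            me1 = enr.loc[
                truth.set_index("region_id")["true_class"]
                .eq("H3K4me1-enhancer").reindex(enr.index).fillna(False),
                "H3K4me1"]
            errors[depth] = abs(me1.mean() - 3.0) / 3.0
        assert errors[500_000] <= 0.05


class TestMethylationGenerator:
    def test_class_means_in_planted_ranges(self, spec, config):
        profiles = simulate.default_profiles()
        truth = simulate.generate_regions(spec, config)
        meth = simulate.simulate_methylation(truth, profiles, config)
        by_class = meth.join(truth.set_index("region_id")["true_class"])
        means = by_class.groupby("true_class")["embryo"].mean()
        assert means["H3K4me2-enhancer"] < 0.2
        assert means["H3K4me1-enhancer"] > 0.8
        assert ((meth[["embryo", "egg", "sperm"]] >= 0) &
                (meth[["embryo", "egg", "sperm"]] <= 1)).all().all()

    def test_zero_noise_gives_exact_means(self, spec):
        cfg = simulate.SimulationConfig(regions_per_class=10, seed=13,
                                        methylation_concentration=np.inf)
        profiles = simulate.default_profiles()
        profiles["unmarked"].methylation = {"embryo": 0.0, "egg": 0.0,
                                            "sperm": 0.0}
        truth = simulate.generate_regions(spec, cfg)
        meth = simulate.simulate_methylation(truth, profiles, cfg)
        un = truth.loc[truth["true_class"] == "unmarked", "region_id"]
        assert (meth.loc[un] == 0.0).all().all()

    def test_shared_gamete_fraction_recovered(self, spec):
        from mztenh.association import shared_hypomethylation

        cfg = simulate.SimulationConfig(
            regions_per_class={"H3K4me2-enhancer": 1000}, seed=14)
        profiles = simulate.default_profiles()
        truth = simulate.generate_regions(spec, cfg)
        meth = simulate.simulate_methylation(truth, profiles, cfg)
        frac, _ = shared_hypomethylation(meth)
        assert frac == pytest.approx(0.69, abs=0.04)


class TestMotifGenerator:
    def test_depletion_structure_planted(self, spec, config):
        profiles = simulate.default_profiles()
        truth = simulate.generate_regions(spec, config)
        hits = simulate.simulate_motif_counts(truth, profiles, config)
        by_class = hits.groupby(
            truth.set_index("region_id")["true_class"]).mean()
        assert by_class["H3K4me1-enhancer"] > by_class["H3K4me2-enhancer"]


class TestRoundTrip:
    def test_tables_round_trip_through_io(self, tmp_path, spec, config):
        profiles = simulate.default_profiles()
        truth = simulate.generate_regions(spec, config)
        meth = simulate.simulate_methylation(truth, profiles, config)
        ct = simulate.simulate_ct_table(config, planted_fold=1.7)

        io.write_regions_bed(truth, tmp_path / "r.bed")
        back = io.read_regions_bed(tmp_path / "r.bed")
        pd.testing.assert_frame_equal(
            back, truth[["region_id", "chrom", "start", "end"]])

        io.write_methylation(meth, tmp_path / "m.tsv")
        pd.testing.assert_frame_equal(io.read_methylation(tmp_path / "m.tsv"),
                                      meth)

        io.write_ct_table(ct, tmp_path / "ct.csv")
        pd.testing.assert_frame_equal(io.read_ct_table(tmp_path / "ct.csv"),
                                      ct)

        frag = pd.DataFrame({"chrom": ["chr1", "chr2"],
                             "start": [10, 20], "end": [180, 260]})
        io.write_fragments_bed(frag, tmp_path / "f.bed")
        pd.testing.assert_frame_equal(io.read_fragments_bed(tmp_path / "f.bed"),
                                      frag)
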