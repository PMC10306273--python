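"""RAD locus calling, filtering, depth ratios and density bootstrap."""

import numpy as np
import pandas as pd
import pytest

from lepisex import (
    FemaleLimitedParams,
    LocusFilterParams,
    call_rad_loci,
    depth_ratio,
    filter_loci,
    find_female_limited,
    locus_density_ci,
    segment_hemizygosity,
)
from lepisex.genome import Genome, Individual, make_cohort
from lepisex.raddepth import bootstrap_median_ci


def tiny_cohort():
    return [Individual("f1", "female"), Individual("f2", "female"),
            Individual("m1", "male"), Individual("m2", "male")]


def locus_row(chrom="A1", pos=100, strand="+", **depths):
    return {"chrom": chrom, "pos": pos, "strand": strand, **depths}


class TestCallLoci:
    def test_reads_stack_by_start_and_strand(self):
        df = pd.DataFrame({
            "individual": ["f1", "f1", "m1"],
            "chrom": ["A1"] * 3,
            "start": [100] * 3,
            "strand": ["+"] * 3,
        })
        loci = call_rad_loci(df, tiny_cohort())
        assert len(loci) == 1
        row = loci.iloc[0]
        assert (row["f1"], row["m1"], row["f2"], row["m2"]) == (2, 1, 0, 0)

    def test_distinct_starts_make_distinct_loci(self):
        df = pd.DataFrame({
            "individual": ["f1", "f1"],
            "chrom": ["A1", "A1"],
            "start": [100, 101],
            "strand": ["+", "+"],
        })
        assert len(call_rad_loci(df, tiny_cohort())) == 2

    def test_opposite_strands_are_distinct_loci(self):
        df = pd.DataFrame({
            "individual": ["f1", "f1"],
            "chrom": ["A1", "A1"],
            "start": [100, 100],
            "strand": ["+", "-"],
        })
        assert len(call_rad_loci(df, tiny_cohort())) == 2

    def test_unknown_individual_rejected(self):
        df = pd.DataFrame({
            "individual": ["ghost"], "chrom": ["A1"], "start": [0],
            "strand": ["+"]})
        with pytest.raises(ValueError, match="ghost"):
            call_rad_loci(df, tiny_cohort())

    def test_simulated_loci_sit_at_cut_site_flanks(self, fusion_sim,
                                                   rad_alignment, cohort):
        from lepisex.reads import digest_sites
        _, _, male, _, _ = fusion_sim
        loci = call_rad_loci(rad_alignment, cohort)
        expected = set()
        for chrom, seq in male.chromosomes.items():
            for p in digest_sites(seq):
                expected.add((chrom, p + 1, "+"))
                expected.add((chrom, p + 5 - 91, "-"))
        # every locus with substantial male depth must be an in-silico
        # cut-site flank of the male genome (female W-derived reads may
        # stack at shifted, W-homologous positions instead)
        male_cols = [i.id for i in cohort if i.sex == "male"]
        depths = loci[male_cols].sum(axis=1)
        abundant = loci.loc[depths >= 100, ["chrom", "pos", "strand"]]
        abundant = set(map(tuple, abundant.to_numpy()))
        assert abundant <= expected
        # and most expected flanks are recovered
        assert len(abundant) > 0.7 * len(expected)


class TestFilters:
    def _cohort19(self):
        return make_cohort(19)

    def _locus(self, n_f, n_m, depth_per_ind):
        cohort = self._cohort19()
        females = [i.id for i in cohort if i.sex == "female"][:n_f]
        males = [i.id for i in cohort if i.sex == "male"][:n_m]
        row = {i.id: 0 for i in cohort}
        for name in females + males:
            row[name] = depth_per_ind
        return pd.DataFrame([locus_row(**row)]), cohort

    def test_18_of_19_with_depth_900_kept(self):
        loci, cohort = self._locus(18, 19, 25)  # total 925
        params = LocusFilterParams(18, 450, 2400)
        assert len(filter_loci(loci, params, cohort)) == 1

    def test_17_of_19_females_dropped(self):
        loci, cohort = self._locus(17, 19, 25)
        params = LocusFilterParams(18, 450, 2400)
        assert len(filter_loci(loci, params, cohort)) == 0

    def test_total_depth_above_ceiling_dropped(self):
        loci, cohort = self._locus(19, 19, 80)  # total 3040
        params = LocusFilterParams(18, 450, 2400)
        assert len(filter_loci(loci, params, cohort)) == 0

    def test_total_depth_below_floor_dropped(self):
        loci, cohort = self._locus(19, 19, 10)  # total 380
        params = LocusFilterParams(18, 450, 2400)
        assert len(filter_loci(loci, params, cohort)) == 0


class TestDepthRatio:
    def test_half_and_unity_ratios(self):
        cohort = tiny_cohort()
        loci = pd.DataFrame([
            locus_row(pos=1, f1=10, f2=10, m1=20, m2=20),
            locus_row(pos=2, f1=15, f2=15, m1=15, m2=15),
        ])
        out = depth_ratio(loci, cohort)
        assert list(out["ratio"]) == [0.5, 1.0]

    def test_mean_based_arithmetic(self):
        cohort = [Individual(f"f{i}", "female") for i in range(3)] + \
                 [Individual(f"m{i}", "male") for i in range(2)]
        loci = pd.DataFrame([locus_row(f0=4, f1=6, f2=5, m0=8, m1=8)])
        out = depth_ratio(loci, cohort)
        assert out["ratio"].iloc[0] == pytest.approx(5.0 / 8.0)

    def test_zero_male_loci_excluded(self):
        cohort = tiny_cohort()
        loci = pd.DataFrame([
            locus_row(pos=1, f1=10, f2=10, m1=0, m2=0),
            locus_row(pos=2, f1=10, f2=10, m1=10, m2=10),
        ])
        out = depth_ratio(loci, cohort)
        assert list(out["pos"]) == [2]

    def test_scale_equivariance(self):
        cohort = tiny_cohort()
        rng = np.random.default_rng(0)
        depths = rng.integers(1, 50, size=(30, 4))
        loci = pd.DataFrame([
            locus_row(pos=i, f1=int(a), f2=int(b), m1=int(c), m2=int(d))
            for i, (a, b, c, d) in enumerate(depths)])
        doubled = loci.copy()
        for col in ("f1", "f2", "m1", "m2"):
            doubled[col] *= 2
        r1 = depth_ratio(loci, cohort)["ratio"]
        r2 = depth_ratio(doubled, cohort)["ratio"]
        assert np.allclose(r1, r2)


class TestSegmentation:
    def _track(self, ratios, chrom="Z"):
        return pd.DataFrame({
            "chrom": chrom, "pos": np.arange(len(ratios)) * 1_000,
            "strand": "+", "ratio": ratios})

    def test_uniform_half_ratio_single_hemizygous_segment(self):
        segs = segment_hemizygosity(self._track([0.5] * 60), window_loci=25)
        assert len(segs) == 1
        assert segs[0].label == "hemizygous"

    def test_uniform_unity_single_balanced_segment(self):
        segs = segment_hemizygosity(self._track([1.0] * 60), window_loci=25)
        assert [s.label for s in segs] == ["balanced"]

    def test_two_regime_track_splits_near_change_point(self):
        ratios = [0.5] * 40 + [1.0] * 40
        segs = segment_hemizygosity(self._track(ratios), window_loci=9)
        assert [s.label for s in segs] == ["hemizygous", "balanced"]
        # change point at locus 40 (pos 40_000), boundary at locus midpoint
        assert abs(segs[0].end - 39_500) < 5_000

    def test_sparse_chromosome_single_segment_with_warning(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            segs = segment_hemizygosity(self._track([0.4] * 5), window_loci=25)
        assert len(segs) == 1 and segs[0].label == "hemizygous"
        assert any("single segment" in r.message for r in caplog.records)

    def test_fusion_recovers_balanced_terminal_region(
            self, fusion_sim, rad_alignment, cohort):
        """The W-homologous (fused) end of the neo-Z shows balanced depth;
        the ancestral Z portion is hemizygous in females."""
        cfg, _, male, _, truth = fusion_sim
        loci = call_rad_loci(rad_alignment, cohort)
        filtered = filter_loci(loci, LocusFilterParams(), cohort)
        track = depth_ratio(filtered, cohort)
        segs = [s for s in segment_hemizygosity(track) if s.chrom == "Z"]
        z_len = len(male.chromosomes["Z"])
        balanced = [s for s in segs if s.label == "balanced"]
        hemi = [s for s in segs if s.label == "hemizygous"]
        assert balanced and hemi
        # a balanced segment overlaps the fused (W-homologous) terminal region
        from lepisex.genome import interval_overlap
        assert any(interval_overlap(s.start, s.end, cfg.z_length, z_len) > 0
                   for s in balanced)
        # hemizygous segments dominate the ancestral Z portion
        hemi_cover = sum(interval_overlap(s.start, s.end, 0, cfg.z_length)
                         for s in hemi)
        assert hemi_cover > 0.6 * cfg.z_length


class TestFemaleLimited:
    def _cohort19(self):
        return make_cohort(19)

    def _locus(self, n_f, pooled, male_depth=0):
        cohort = self._cohort19()
        females = [i.id for i in cohort if i.sex == "female"]
        males = [i.id for i in cohort if i.sex == "male"]
        row = {i.id: 0 for i in cohort}
        per = pooled // n_f
        extra = pooled - per * n_f
        for j, name in enumerate(females[:n_f]):
            row[name] = per + (1 if j < extra else 0)
        if male_depth:
            row[males[0]] = male_depth
        return pd.DataFrame([locus_row(chrom="W", **row)]), cohort

    def test_all_females_pooled_in_band_kept(self):
        loci, cohort = self._locus(19, 300)
        assert len(find_female_limited(loci, FemaleLimitedParams(), cohort)) == 1

    def test_18_of_19_females_dropped(self):
        loci, cohort = self._locus(18, 300)
        assert len(find_female_limited(loci, FemaleLimitedParams(), cohort)) == 0

    def test_pooled_depth_below_floor_dropped(self):
        loci, cohort = self._locus(19, 200)
        assert len(find_female_limited(loci, FemaleLimitedParams(), cohort)) == 0

    def test_any_male_read_disqualifies(self):
        loci, cohort = self._locus(19, 300, male_depth=1)
        assert len(find_female_limited(loci, FemaleLimitedParams(), cohort)) == 0

    def test_simulated_female_limited_only_on_w(
            self, female_genome_alignment, cohort):
        loci = call_rad_loci(female_genome_alignment, cohort)
        fl = find_female_limited(loci, FemaleLimitedParams(), cohort)
        assert len(fl) > 0
        assert set(fl["chrom"]) == {"W"}


class TestDensityBootstrap:
    def test_degenerate_bootstrap_collapses(self):
        median, lo, hi = bootstrap_median_ci(np.full(24, 7.5), 1_000, seed=0)
        assert (median, lo, hi) == (7.5, 7.5, 7.5)

    def test_matches_independent_resampling_oracle(self):
        """Same seed, same draw order, independently coded percentile CI."""
        values = np.arange(1.0, 25.0)
        n_boot, seed = 10_000, 7
        median, lo, hi = bootstrap_median_ci(values, n_boot, seed)

        rng = np.random.default_rng(seed)
        idx = rng.integers(0, len(values), size=(n_boot, len(values)))
        meds = []
        for row in idx:
            sample = sorted(values[j] for j in row)
            mid = len(sample) // 2
            meds.append((sample[mid - 1] + sample[mid]) / 2.0
                        if len(sample) % 2 == 0 else sample[mid])
        meds = np.asarray(meds)
        assert lo == pytest.approx(float(np.quantile(meds, 0.025)))
        assert hi == pytest.approx(float(np.quantile(meds, 0.975)))
        assert median == pytest.approx(float(np.median(values)))

    def test_too_few_autosomes_rejected(self):
        g = Genome(chromosomes={"A1": "A" * 1_000, "Z": "A" * 1_000})
        cohort = tiny_cohort()
        loci = pd.DataFrame([locus_row(f1=5, f2=5, m1=5, m2=5)])
        with pytest.raises(ValueError, match="autosomes"):
            locus_density_ci(loci, g, cohort, min_females=1)

    def test_repeat_rich_w_density_below_autosomal_ci(self):
        """A repeat-rich W attracts fewer unique RAD loci per Mb than the
        autosomal bootstrap interval admits: reads from its multiplied
        segments cannot be placed uniquely. Density uses females only (males
        carry no W)."""
        from lepisex import (AlignerParams, GenomeIndex, ScenarioConfig,
                             align_unique, apply_scenario,
                             simulate_ancestral_genome)
        from lepisex.reads import preprocess_records, simulate_individual_reads

        cfg = ScenarioConfig(
            autosome_lengths=[80_000] * 12, z_length=80_000,
            fused_autosome_length=80_000, n_translocations=10, seed=2)
        anc = simulate_ancestral_genome(cfg)
        _, female, _ = apply_scenario(anc, cfg)
        females = [i for i in make_cohort(19) if i.sex == "female"]
        index = GenomeIndex(female)
        params = AlignerParams(400)
        rows = []
        for idx, ind in enumerate(females):
            rng = np.random.default_rng([cfg.seed, 3, idx])
            raw = simulate_individual_reads(
                female, ind, cfg.mean_depth, cfg.error_rate, cfg.read_len,
                rng, cfg.depth_dispersion)
            for r in preprocess_records(raw, seed=cfg.seed):
                hit = align_unique(r.seq, index, params, query_id=r.name)
                if hit is not None:
                    rows.append((ind.id, hit.chrom, hit.start, hit.strand))
        align_df = pd.DataFrame(
            rows, columns=["individual", "chrom", "start", "strand"])
        loci = call_rad_loci(align_df, females)
        dci = locus_density_ci(loci, female, females, min_females=10,
                               n_boot=10_000, seed=1)
        w_density = dci.per_chrom.set_index("chrom").loc["W", "density"]
        assert w_density < dci.ci_low
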