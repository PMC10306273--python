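"""W sequence-tag extraction, density, synteny and expansion signatures."""

import numpy as np
import pandas as pd
import pytest

from lepisex import (
    AlignerParams,
    GenomeIndex,
    ScenarioConfig,
    apply_scenario,
    compute_density,
    detect_collinear_blocks,
    detect_expansion,
    extract_tags_masked,
    extract_tags_stepped,
    peripheral_enrichment,
    positional_correlation,
    simulate_ancestral_genome,
)
from lepisex.chromstats import mask_repeats_simple
from lepisex.genome import Genome, interval_overlap
from lepisex.tags import align_tags


def _align_df(source_start, start, chrom="Z", tag_len=150):
    return pd.DataFrame({
        "source_chrom": "W",
        "source_start": source_start,
        "tag_len": tag_len,
        "chrom": chrom,
        "start": start,
        "strand": "+",
        "n_mismatch": 0,
    })


class TestExtraction:
    def test_masked_run_of_450_gives_three_left_aligned_tags(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=800))
        mask = np.ones(800, dtype=bool)
        mask[200:650] = False  # 450 bp unmasked run
        tags = extract_tags_masked("W", seq, mask)
        assert [t.source_start for t in tags] == [200, 350, 500]
        assert all(t.sequence == seq[t.source_start:t.source_start + 150]
                   for t in tags)

    def test_run_of_149_gives_no_tags(self):
        seq = "A" * 149
        assert extract_tags_masked("W", seq, np.zeros(149, dtype=bool)) == []

    def test_hard_masked_sequence_implies_mask(self):
        seq = "N" * 100 + "ACGT" * 75 + "N" * 50  # 300 bp unmasked
        tags = extract_tags_masked("W", seq)
        assert [t.source_start for t in tags] == [100, 250]
        assert all("N" not in t.sequence for t in tags)

    @pytest.mark.parametrize("length,expected", [
        (1_500, [0, 500, 1_000]),
        (149, []),
        (650, [0, 500]),
        (150, [0]),
    ])
    def test_stepped_positions(self, length, expected):
        seq = "A" * length
        tags = extract_tags_stepped("W", seq)
        assert [t.source_start for t in tags] == expected

    def test_stepped_count_formula(self):
        for length in (150, 700, 1_499, 10_000, 33_333):
            n = len(extract_tags_stepped("W", "A" * length))
            assert n == (length - 150) // 500 + 1

    def test_masked_tags_avoid_masked_bases(self, masked_female):
        mask = masked_female.mask["W"]
        tags = extract_tags_masked("W", masked_female.chromosomes["W"], mask)
        assert len(tags) > 100
        for t in tags[::25]:
            assert not mask[t.source_start:t.source_start + t.length].any()


class TestDensity:
    def test_density_arithmetic(self):
        g = Genome(chromosomes={"c1": "A" * 2_000_000, "c2": "A" * 1_000_000})
        df = _align_df(np.arange(50) * 500, np.arange(50) * 500, chrom="c1")
        out = compute_density(df, g).set_index("chrom")
        assert out.loc["c1", "density"] == pytest.approx(25.0)
        assert out.loc["c2", "n_unique"] == 0
        assert out.loc["c2", "density"] == 0.0

    def test_unknown_chromosome_rejected(self):
        g = Genome(chromosomes={"c1": "A" * 1_000})
        with pytest.raises(ValueError, match="unknown"):
            compute_density(_align_df([0], [0], chrom="cX"), g)


class TestPositionalCorrelation:
    def test_collinear_gives_one(self):
        df = _align_df(np.arange(200) * 500, np.arange(200) * 480 + 7)
        out = positional_correlation(df, min_tags=120)
        assert out["r_s"].iloc[0] == pytest.approx(1.0)

    def test_reversed_gives_minus_one(self):
        df = _align_df(np.arange(200) * 500, (200 - np.arange(200)) * 500)
        out = positional_correlation(df, min_tags=120)
        assert out["r_s"].iloc[0] == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 5]
        # oracle: rank both (no ties here), then Pearson on the ranks
        r_oracle = np.corrcoef(x, y)[0, 1]  # values are their own ranks
        df = _align_df(x, y)
        out = positional_correlation(df, min_tags=5)
        assert out["r_s"].iloc[0] == pytest.approx(r_oracle)
        assert out["r_s"].iloc[0] == pytest.approx(0.8)

    def test_tie_handling_average_ranks(self):
        x = [1, 2, 2, 4, 5, 6]
        y = [10, 30, 30, 30, 50, 60]

        def avg_rank(v):
            v = np.asarray(v, dtype=float)
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2.0
                i = j
            return ranks

        r_oracle = np.corrcoef(avg_rank(x), avg_rank(y))[0, 1]
        out = positional_correlation(_align_df(x, y), min_tags=6)
        assert out["r_s"].iloc[0] == pytest.approx(r_oracle)

    def test_gate_omits_sparse_chromosomes(self):
        df = pd.concat([
            _align_df(np.arange(130) * 10, np.arange(130) * 10, chrom="Z"),
            _align_df(np.arange(30) * 10, np.arange(30) * 10, chrom="A1"),
        ])
        out = positional_correlation(df, min_tags=120)
        assert list(out["chromosome"]) == ["Z"]


class TestPeripheralEnrichment:
    def test_all_tags_in_right_window(self):
        length = 3_000_000
        df = _align_df(np.arange(40) * 100,
                       length - 1_000_000 + np.arange(40) * 100)
        left, right, either = peripheral_enrichment(df, "Z", length)
        assert (left, right, either) == (0.0, 1.0, 1.0)

    def test_uniform_placement_matches_expectation(self):
        rng = np.random.default_rng(1)
        length, window, n = 1_300_000, 100_000, 4_000
        df = _align_df(np.arange(n), rng.integers(0, length - 150, size=n))
        left, right, either = peripheral_enrichment(df, "Z", length, window)
        p = window / length
        tol = 3 * np.sqrt(p * (1 - p) / n)
        assert abs(right - p) < tol
        assert abs(left - p) < tol

    def test_short_chromosome_rejected_with_advice(self):
        df = _align_df([0], [0])
        with pytest.raises(ValueError, match="smaller window"):
            peripheral_enrichment(df, "Z", 1_500_000, window=1_000_000)


class TestCollinearBlocks:
    def test_increasing_targets_form_single_block(self):
        df = _align_df(np.arange(10) * 500, np.arange(10) * 500 + 100)
        blocks = detect_collinear_blocks(df, min_run=5, max_gap=10_000)
        assert len(blocks) == 1
        assert blocks[0].n_tags == 10 and blocks[0].direction == "+"

    def test_alternating_targets_give_no_block(self):
        tgt = [100, 5_000, 200, 5_100, 300, 5_200, 400, 5_300]
        df = _align_df(np.arange(8) * 500, tgt)
        assert detect_collinear_blocks(df, min_run=5, max_gap=10_000) == []

    def test_decreasing_direction_reported(self):
        df = _align_df(np.arange(8) * 500, (8 - np.arange(8)) * 400)
        blocks = detect_collinear_blocks(df, min_run=5, max_gap=10_000)
        assert len(blocks) == 1 and blocks[0].direction == "-"

    def test_fusion_block_overlaps_truth_remnant(self, fusion_sim, masked_female):
        _, _, male, female, truth = fusion_sim
        tags = extract_tags_masked("W", female.chromosomes["W"],
                                   masked_female.mask["W"])
        df = align_tags(tags, GenomeIndex(male), AlignerParams(600))
        blocks = detect_collinear_blocks(
            df[df["chrom"] == "Z"], min_run=5, max_gap=100_000)
        assert blocks
        remnants = truth.of_kind("remnant_homology")
        assert any(
            interval_overlap(b.w_start, b.w_end, r.w_start, r.w_end) > 0
            for b in blocks for r in remnants)


class TestExpansionDetection:
    def test_arithmetic_on_synthetic_cluster(self):
        """20 tags spanning 10 kb of W mapping into 4 kb of target: ratio 2.5."""
        src = np.round(np.linspace(0, 9_850, 20)).astype(int)
        tgt = np.round(np.linspace(0, 3_850, 20)).astype(int)
        calls = detect_expansion(_align_df(src, tgt, chrom="A1"), step=500)
        assert len(calls) == 1
        assert calls[0].span_ratio == pytest.approx(2.5, rel=1e-6)
        assert calls[0].n_tags == 20

    def test_one_to_one_block_not_called(self):
        src = np.arange(20) * 500
        calls = detect_expansion(_align_df(src, src + 3, chrom="A1"), step=500)
        assert calls == []

    def test_w_gap_splits_spurious_cluster(self):
        """Collinear anchors separated by a large W insertion are not an
        expansion: the W span is inflated but not compact."""
        src = np.concatenate([np.arange(10) * 500,
                              20_000 + np.arange(10) * 500])
        tgt = np.concatenate([np.arange(10) * 500,
                              5_200 + np.arange(10) * 500])
        calls = detect_expansion(_align_df(src, tgt, chrom="A1"), step=500)
        assert calls == []


class TestScenarioProperties:
    def test_fusion_density_peaks_on_neo_z(self, fusion_sim, masked_female):
        _, _, male, female, _ = fusion_sim
        tags = extract_tags_masked("W", female.chromosomes["W"],
                                   masked_female.mask["W"])
        df = align_tags(tags, GenomeIndex(male), AlignerParams(600))
        dens = compute_density(df, male).set_index("chrom")["density"]
        assert dens["Z"] > dens.drop("Z").max()

    def test_expansion_recovery_single_run(self, fusion_sim):
        cfg, _, male, female, truth = fusion_sim
        stepped = extract_tags_stepped("W", female.chromosomes["W"])
        df = align_tags(stepped, GenomeIndex(male), AlignerParams(600))
        calls = detect_expansion(df)
        donors = {r.source_chrom for r in truth.of_kind("translocation")}
        assert len(calls) == cfg.n_translocations
        assert {c.target_chrom for c in calls} <= donors
        for c in calls:
            assert c.span_ratio == pytest.approx(cfg.expansion_factor, rel=0.2)

    def test_robustness_long_tags_high_threshold(self):
        """300 bp tags at a doubled mismatch budget preserve the fusion vs.
        B-origin discrimination ordering."""
        for seed in (21, 22):
            results = {}
            for scenario in ("fusion", "b_origin"):
                cfg = ScenarioConfig(scenario=scenario, seed=seed)
                anc = simulate_ancestral_genome(cfg)
                male, female, _ = apply_scenario(anc, cfg)
                masked = mask_repeats_simple(female, chroms=["W"])
                tags = extract_tags_masked(
                    "W", female.chromosomes["W"], masked.mask["W"],
                    tag_len=300)
                df = align_tags(tags, GenomeIndex(male), AlignerParams(1_200))
                corr = positional_correlation(df, min_tags=120)
                corr = corr.set_index("chromosome")["r_s"]
                results[scenario] = corr
            fusion_rs = results["fusion"]
            assert "Z" in fusion_rs.index and fusion_rs["Z"] > 0.95
            autosomal = fusion_rs.drop("Z", errors="ignore")
            if len(autosomal):
                assert fusion_rs["Z"] > autosomal.max()
            b_rs = results["b_origin"]
            if "Z" in b_rs.index:
                assert b_rs["Z"] < 0.5
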