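"""End-to-end orchestration: simulate, analyze, compare.

Every intermediate is a documented on-disk artifact (FASTA, gzipped FASTQ,
BED, TSV, JSON); runs are deterministic under a fixed seed. The analyze stage
operationalizes the sex-chromosome signatures: the candidate Z is the
chromosome with the lowest median female:male RAD depth ratio, the candidate
W the chromosome attracting the female-limited loci, cross-checked by its
repeat/GC composition.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import aligner, chromstats, raddepth, reads, simulate, tags
from .config import ScenarioConfig, dataclass_from_kv, dataclass_to_kv
from .genome import Genome, Individual, TruthTable, make_cohort, read_cohort, write_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All stage parameters for a full run; round-trips through key=value."""

    # scenario / simulation
    scenario: str = "fusion"
    autosome_lengths: list[int] = field(
        default_factory=lambda: [150_000, 130_000, 110_000, 120_000])
    z_length: int = 200_000
    fused_autosome_length: int = 120_000
    gc_content: float = 0.37
    substitution_rate: float = 0.05
    indel_rate: float = 0.001
    mean_indel_len: float = 5.0
    n_translocations: int = 1
    translocation_len: int = 4_000
    expansion_factor: float = 2.45
    expansion_unit_len: int = 300
    w_gc_shift: float = 0.15
    telomere_copies: int = 30
    n_per_sex: int = 19
    mean_depth: float = 20.0
    depth_dispersion: float = 5.0
    error_rate: float = 0.002
    read_len: int = 100
    seed: int = 1
    # preprocessing / alignment
    read_cap: int = 8_000_000
    trim_len: int = 91
    read_score_threshold: int = 400
    tag_score_threshold: int = 600
    mismatch_cost: int = 30
    seed_len: int = 15
    # RAD depth
    min_per_sex: int = 18
    total_depth_min: int = 450
    total_depth_max: int = 2400
    pooled_female_min: int = 225
    pooled_female_max: int = 1200
    min_females: int = 10
    n_boot: int = 10_000
    window_loci: int = 25
    hemizygosity_boundary: float = 0.75
    # tags
    tag_len: int = 150
    tag_step: int = 500
    min_tags: int = 120
    min_run: int = 5
    max_gap: int = 100_000
    min_cluster: int = 10
    ratio_threshold: float = 1.5
    peripheral_window: int = 1_000_000
    # masker
    mask_k: int = 15
    mask_copy_threshold: int = 5

    def scenario_config(self) -> ScenarioConfig:
        names = {f.name for f in dataclasses.fields(ScenarioConfig)}
        return ScenarioConfig(**{
            f.name: getattr(self, f.name)
            for f in dataclasses.fields(self) if f.name in names})

    def read_params(self) -> aligner.AlignerParams:
        return aligner.AlignerParams(self.read_score_threshold,
                                     self.mismatch_cost, self.seed_len)

    def tag_params(self) -> aligner.AlignerParams:
        return aligner.AlignerParams(self.tag_score_threshold,
                                     self.mismatch_cost, self.seed_len)

    def to_file(self, path: str | Path) -> None:
        dataclass_to_kv(self, path)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        cfg = dataclass_from_kv(cls, path)
        cfg.scenario_config().validate()
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ------------------------------------------------------------------ simulate


def cmd_simulate(config: RunConfig, out_dir: str | Path,
                 force: bool = False) -> dict:
    """Simulate a full study to disk; returns (and writes) the manifest."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(
            f"output directory {out} exists and is not empty; use force")
    (out / "reads").mkdir(parents=True, exist_ok=True)
    scfg = config.scenario_config()
    scfg.validate()
    ancestral = simulate.simulate_ancestral_genome(scfg)
    male, female, truth = simulate.apply_scenario(ancestral, scfg)
    cohort = make_cohort(config.n_per_sex)

    male.to_fasta(out / "male.fasta")
    female.to_fasta(out / "female.fasta")
    truth.to_bed(out / "truth.bed")
    write_cohort(cohort, out / "cohort.tsv")
    config.to_file(out / "scenario.cfg")
    genomes_by_sex = {"male": male, "female": female}
    fastqs = reads.simulate_rad_reads(
        genomes_by_sex, cohort, config.mean_depth, config.error_rate,
        config.read_len, config.seed, config.depth_dispersion,
        out_dir=out / "reads")

    files = [out / "male.fasta", out / "female.fasta", out / "truth.bed",
             out / "cohort.tsv", out / "scenario.cfg"]
    files += sorted(fastqs.values())
    manifest = {
        "scenario": config.scenario,
        "seed": config.seed,
        "truth_meta": truth.meta,
        "files": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ------------------------------------------------------------------- analyze


def _preprocess_cohort(run_dir: Path, out: Path, config: RunConfig,
                       cohort: list[Individual]) -> dict[str, Path]:
    pre = out / "preprocessed"
    pre.mkdir(parents=True, exist_ok=True)
    paths = {}
    for ind in cohort:
        src = run_dir / "reads" / f"{ind.id}.fastq.gz"
        dst = pre / f"{ind.id}.fastq.gz"
        reads.preprocess_reads(src, dst, config.read_cap, config.trim_len,
                               config.seed)
        paths[ind.id] = dst
    return paths


def _align_cohort(paths: dict[str, Path], index: aligner.GenomeIndex,
                  params: aligner.AlignerParams,
                  only: set[str] | None = None) -> pd.DataFrame:
    frames = []
    for ind_id, path in paths.items():
        if only is not None and ind_id not in only:
            continue
        rows = []
        for r in reads.read_fastq(path):
            hit = aligner.align_unique(r.seq, index, params, query_id=r.name)
            if hit is not None:
                rows.append((ind_id, hit.chrom, hit.start, hit.strand,
                             hit.n_mismatch))
        frames.append(pd.DataFrame(
            rows, columns=["individual", "chrom", "start", "strand",
                           "n_mismatch"]))
    if not frames:
        return pd.DataFrame(
            columns=["individual", "chrom", "start", "strand", "n_mismatch"])
    return pd.concat(frames, ignore_index=True)


def _effective_window(requested: int, chrom_len: int) -> int:
    """Shrink the peripheral window so it is applicable to short chromosomes."""
    if chrom_len > 2 * requested:
        return requested
    return max(1, chrom_len // 4)


def cmd_analyze(run_dir: str | Path, out_dir: str | Path,
                config: RunConfig | None = None) -> dict:
    """Run preprocess -> align -> RAD depth -> W tags -> composition stats.

    ``run_dir`` must hold male.fasta, female.fasta, cohort.tsv and reads/
    (the cmd_simulate layout). Writes the stage tables plus a single
    report.json; returns the report.
    """
    run_dir = Path(run_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config is None:
        cfg_path = run_dir / "scenario.cfg"
        config = RunConfig.from_file(cfg_path) if cfg_path.exists() else RunConfig()
    for stage_file in ("male.fasta", "female.fasta", "cohort.tsv"):
        if not (run_dir / stage_file).exists():
            raise FileNotFoundError(
                f"analyze: missing input {stage_file} for stage "
                f"{'alignment' if stage_file.endswith('.fasta') else 'rad_depth'}")
    male = Genome.from_fasta(run_dir / "male.fasta")
    female = Genome.from_fasta(run_dir / "female.fasta")
    cohort = read_cohort(run_dir / "cohort.tsv")
    females = [i for i in cohort if i.sex == "female"]
    males_ = [i for i in cohort if i.sex == "male"]
    report: dict = {"stages": [], "warnings": []}

    fastqs = _preprocess_cohort(run_dir, out, config, cohort)
    report["stages"].append("preprocess")

    # ---- sex-ratio stages need both sexes
    ratio_df = None
    candidate_z = None
    if females and males_:
        male_index = aligner.GenomeIndex(male, config.seed_len)
        align_df = _align_cohort(fastqs, male_index, config.read_params())
        loci = raddepth.call_rad_loci(align_df, cohort)
        fparams = raddepth.LocusFilterParams(
            config.min_per_sex, config.total_depth_min, config.total_depth_max)
        filtered = raddepth.filter_loci(loci, fparams, cohort)
        ratio_df = raddepth.depth_ratio(filtered, cohort)
        ratio_df.to_csv(out / "ratio_track.tsv", sep="\t", index=False)
        segments = raddepth.segment_hemizygosity(
            ratio_df, config.window_loci, config.hemizygosity_boundary)
        with open(out / "segments.bed", "w") as fh:
            for s in segments:
                fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.label}\t"
                         f"{s.n_loci}\t+\n")
        medians = ratio_df.groupby("chrom")["ratio"].median()
        candidate_z = str(medians.idxmin()) if len(medians) else None
        report["candidate_z"] = {
            "chrom": candidate_z,
            "rule": "lowest genome-wide median female:male depth ratio",
            "median_ratio_by_chrom": {k: float(v) for k, v in medians.items()},
        }
        report["stages"].append("rad_depth")
    else:
        report["warnings"].append(
            "cohort lacks one sex; sex-ratio stages skipped")

    # ---- female-genome stages
    candidate_w = None
    if females:
        female_index = aligner.GenomeIndex(female, config.seed_len)
        f_align = _align_cohort(fastqs, female_index, config.read_params(),
                                only={i.id for i in females} | {i.id for i in males_})
        f_loci = raddepth.call_rad_loci(f_align, cohort)
        if males_:
            flp = raddepth.FemaleLimitedParams(
                pooled_female_min=config.pooled_female_min,
                pooled_female_max=config.pooled_female_max)
            fl = raddepth.find_female_limited(f_loci, flp, cohort)
            fl[raddepth.KEY_COLUMNS].to_csv(
                out / "female_limited.tsv", sep="\t", index=False)
            fl_counts = fl["chrom"].value_counts()
            candidate_w = str(fl_counts.idxmax()) if len(fl_counts) else None
            report["female_limited"] = {
                "n_loci": int(len(fl)),
                "by_chrom": {k: int(v) for k, v in fl_counts.items()},
            }
        try:
            dci = raddepth.locus_density_ci(
                f_loci, female, cohort, config.min_females, config.n_boot,
                config.seed)
            dci.per_chrom.to_csv(out / "rad_density.tsv", sep="\t", index=False)
            report["rad_density"] = {
                "autosomal_median": dci.autosomal_median,
                "ci_low": dci.ci_low, "ci_high": dci.ci_high,
                "n_boot": dci.n_boot,
                "per_chrom": {
                    r.chrom: r.density for r in dci.per_chrom.itertuples()},
            }
        except ValueError as exc:
            report["warnings"].append(f"locus density CI unavailable: {exc}")
        report["stages"].append("rad_density")
    else:
        report["warnings"].append("no females; W stages skipped")

    # ---- composition stats on the masked female genome
    masked = chromstats.mask_repeats_simple(
        female, config.mask_k, config.mask_copy_threshold)
    stats_df = chromstats.chrom_stats_table(masked)
    stats_df.to_csv(out / "chrom_stats.tsv", sep="\t", index=False)
    report["chrom_stats"] = stats_df.set_index("chrom").to_dict("index")
    report["stages"].append("chrom_stats")

    # composition cross-check of the candidate W
    if candidate_w is not None:
        auto_names = [n for n in female.names if n not in ("Z", "W", candidate_z,
                                                           candidate_w)]
        srow = stats_df.set_index("chrom")
        if auto_names:
            report["candidate_w"] = {
                "chrom": candidate_w,
                "rule": ("most female-limited loci; support: nonrepeat below "
                         "all autosomes, GC above autosomal median"),
                "low_nonrepeat": bool(
                    srow.loc[candidate_w, "nonrepeat"]
                    < srow.loc[auto_names, "nonrepeat"].min()),
                "high_gc": bool(
                    srow.loc[candidate_w, "gc"]
                    > srow.loc[auto_names, "gc"].median()),
            }
        else:
            report["candidate_w"] = {"chrom": candidate_w}

    # ---- W sequence-tag homology
    if candidate_w is not None:
        w_seq = female.chromosomes[candidate_w]
        w_mask = masked.mask[candidate_w]
        masked_tags = tags.extract_tags_masked(
            candidate_w, w_seq, w_mask, config.tag_len)
        stepped_tags = tags.extract_tags_stepped(
            candidate_w, w_seq, config.tag_step, config.tag_len)
        target = Genome(chromosomes={
            n: s for n, s in female.chromosomes.items() if n != candidate_w})
        tindex = aligner.GenomeIndex(target, config.seed_len)
        tparams = config.tag_params()
        tag_align = tags.align_tags(masked_tags, tindex, tparams)
        tag_align.to_csv(out / "tag_alignments.tsv", sep="\t", index=False)
        stepped_align = tags.align_tags(stepped_tags, tindex, tparams)
        density = tags.compute_density(tag_align, target)
        density.to_csv(out / "tag_density.tsv", sep="\t", index=False)
        corr = tags.positional_correlation(tag_align, config.min_tags)
        corr.to_csv(out / "tag_correlation.tsv", sep="\t", index=False)
        report["tag_homology"] = {
            "n_tags_masked": len(masked_tags),
            "n_tags_stepped": len(stepped_tags),
            "n_unique": int(len(tag_align)),
            "density": {r.chrom: r.density for r in density.itertuples()},
            "r_s": {r.chromosome: r.r_s for r in corr.itertuples()},
        }
        if candidate_z is not None and candidate_z in target.chromosomes:
            z_len = len(target.chromosomes[candidate_z])
            window = _effective_window(config.peripheral_window, z_len)
            left, right, either = tags.peripheral_enrichment(
                tag_align, candidate_z, z_len, window)
            report["peripheral_enrichment"] = {
                "chrom": candidate_z, "window": window,
                "left": left, "right": right, "either": either,
            }
            z_align = tag_align[tag_align["chrom"] == candidate_z]
            blocks = tags.detect_collinear_blocks(
                z_align, config.min_run, config.max_gap)
            tags.blocks_to_bed(blocks, out / "collinear_blocks.bed")
            report["collinear_blocks"] = len(blocks)
        calls = tags.detect_expansion(
            stepped_align, config.tag_step, config.min_cluster,
            config.ratio_threshold)
        tags.expansions_to_bed(calls, out / "expansions.bed")
        report["expansion_calls"] = [dataclasses.asdict(c) for c in calls]
        report["stages"].append("tag_homology")

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return report


# ------------------------------------------------------------------- compare


def compare_genomes(
    genome_a: Genome, genome_b: Genome,
    params: aligner.AlignerParams | None = None,
    step: int = 500, tag_len: int = 150, min_tags: int = 10,
) -> pd.DataFrame:
    """Per-chromosome cross-genome divergence summary.

    For every chromosome of A, stepped tags are aligned uniquely to the
    same-named chromosome of B; the summary reports the alignment success
    rate, the positional Spearman correlation (when at least ``min_tags``
    align), and the length difference. Missing name matches are an error.
    """
    if params is None:
        params = aligner.AlignerParams()
    missing = set(genome_a.names) - set(genome_b.names)
    if missing:
        raise ValueError(
            f"chromosomes absent from second genome: {sorted(missing)}")
    rows = []
    for name, seq in genome_a.chromosomes.items():
        tg = tags.extract_tags_stepped(name, seq, step, tag_len)
        sub = Genome(chromosomes={name: genome_b.chromosomes[name]})
        index = aligner.GenomeIndex(sub, params.seed_len)
        df = tags.align_tags(tg, index, params)
        r_s = np.nan
        if len(df) >= min_tags:
            corr = tags.positional_correlation(df, min_tags=min_tags)
            if len(corr):
                r_s = float(corr["r_s"].iloc[0])
        rows.append((name, len(tg), len(df),
                     len(df) / len(tg) if tg else 0.0, r_s,
                     len(seq), len(genome_b.chromosomes[name]),
                     len(seq) - len(genome_b.chromosomes[name])))
    return pd.DataFrame(rows, columns=[
        "chrom", "n_tags", "n_unique", "align_rate", "r_s",
        "len_a", "len_b", "len_diff"])


def cmd_compare(dir_a: str | Path, dir_b: str | Path, out_path: str | Path,
                params: aligner.AlignerParams | None = None,
                step: int = 500, tag_len: int = 150) -> pd.DataFrame:
    """Compare the female genomes of two simulated/analyzed runs."""
    a = Genome.from_fasta(Path(dir_a) / "female.fasta")
    b = Genome.from_fasta(Path(dir_b) / "female.fasta")
    df = compare_genomes(a, b, params, step, tag_len)
    df.to_csv(out_path, sep="\t", index=False)
    return df
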