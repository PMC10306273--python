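"""RAD locus calling and read-depth sex-linkage statistics.

A RAD locus is an exact read-start stack: all uniquely aligned,
residual-bearing reads sharing (chromosome, start, strand). Because females
are ZW and males ZZ, Z-specific loci show a female:male depth ratio near 0.5,
Z-W-homologous loci near 1.0, and W-specific loci are female-limited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import Genome, Individual

logger = logging.getLogger(__name__)

KEY_COLUMNS = ["chrom", "pos", "strand"]


@dataclass
class LocusFilterParams:
    """Representation and total-depth gates for high-confidence loci."""

    min_per_sex: int = 18
    total_depth_min: int = 450
    total_depth_max: int = 2400

    def __post_init__(self) -> None:
        if self.min_per_sex < 0:
            raise ValueError("min_per_sex must be >= 0")
        if self.total_depth_min > self.total_depth_max:
            raise ValueError("total_depth_min must be <= total_depth_max")


@dataclass
class FemaleLimitedParams:
    """Criteria for W-diagnostic loci: seen in every female, in no male."""

    require_all_females: bool = True
    max_male_depth: int = 0
    pooled_female_min: int = 225
    pooled_female_max: int = 1200

    def __post_init__(self) -> None:
        if self.pooled_female_min > self.pooled_female_max:
            raise ValueError("pooled_female_min must be <= pooled_female_max")


def _sex_columns(cohort: list[Individual]) -> tuple[list[str], list[str]]:
    females = [i.id for i in cohort if i.sex == "female"]
    males = [i.id for i in cohort if i.sex == "male"]
    return females, males


def call_rad_loci(alignments: pd.DataFrame, cohort: list[Individual]) -> pd.DataFrame:
    """Group per-read alignments into loci with per-individual depths.

    ``alignments`` needs columns individual, chrom, start, strand (one row per
    uniquely aligned read). The result has one row per (chrom, pos, strand)
    and one integer depth column per cohort member (0 where absent).
    """
    ids = [i.id for i in cohort]
    unknown = set(alignments["individual"]) - set(ids)
    if unknown:
        raise ValueError(f"reads from individuals not in cohort: {sorted(unknown)}")
    if len(alignments) == 0:
        return pd.DataFrame(columns=KEY_COLUMNS + ids)
    table = (
        alignments
        .rename(columns={"start": "pos"})
        .groupby(["chrom", "pos", "strand", "individual"], sort=True)
        .size()
        .unstack("individual", fill_value=0)
        .reindex(columns=ids, fill_value=0)
        .reset_index()
    )
    table.columns.name = None
    return table


def filter_loci(
    loci: pd.DataFrame, params: LocusFilterParams, cohort: list[Individual],
) -> pd.DataFrame:
    """Keep loci represented (depth >= 1) in at least ``min_per_sex``
    individuals of EACH sex, with total depth inside the configured band."""
    females, males = _sex_columns(cohort)
    f_rep = (loci[females] >= 1).sum(axis=1)
    m_rep = (loci[males] >= 1).sum(axis=1)
    total = loci[females + males].sum(axis=1)
    keep = ((f_rep >= params.min_per_sex) & (m_rep >= params.min_per_sex)
            & (total >= params.total_depth_min) & (total <= params.total_depth_max))
    return loci.loc[keep].reset_index(drop=True)


def depth_ratio(
    loci: pd.DataFrame, cohort: list[Individual], mode: str = "mean",
) -> pd.DataFrame:
    """Female:male depth ratio per locus.

    mode 'mean' (default): mean depth over all females divided by mean depth
    over all males, absent individuals counting as 0. mode 'pooled': ratio of
    pooled sums scaled by cohort sizes (identical for balanced cohorts).
    Loci with zero male depth are flagged (``male_zero``) and excluded from
    the returned ratio track.
    """
    females, males = _sex_columns(cohort)
    if not females or not males:
        raise ValueError("depth_ratio requires both sexes in the cohort")
    f_mean = loci[females].sum(axis=1) / len(females)
    m_mean = loci[males].sum(axis=1) / len(males)
    if mode not in ("mean", "pooled"):
        raise ValueError(f"unknown mode {mode!r}")
    out = loci[KEY_COLUMNS].copy()
    male_zero = m_mean == 0
    with np.errstate(divide="ignore"):
        out["ratio"] = np.where(male_zero, np.nan, f_mean / m_mean)
    out["male_zero"] = male_zero.to_numpy()
    n_excluded = int(male_zero.sum())
    if n_excluded:
        logger.info("excluded %d loci with zero male depth from ratio track",
                    n_excluded)
    return out.loc[~male_zero].drop(columns="male_zero").reset_index(drop=True)


@dataclass(frozen=True)
class HemizygositySegment:
    chrom: str
    start: int
    end: int
    label: str  # 'hemizygous' | 'balanced'
    n_loci: int
    median_ratio: float


def segment_hemizygosity(
    ratio_track: pd.DataFrame, window_loci: int = 25, boundary: float = 0.75,
) -> list[HemizygositySegment]:
    """Label chromosome segments hemizygous (female:male ratio < boundary)
    or balanced via a sliding median over ``window_loci`` loci.

    Segment bounds fall at the midpoint between flanking loci. Chromosomes
    with fewer loci than the window get a single segment labeled by the
    overall median (with a warning).
    """
    segments: list[HemizygositySegment] = []
    for chrom, grp in ratio_track.groupby("chrom", sort=False):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        ratio = grp["ratio"].to_numpy(dtype=float)
        n = len(grp)
        if n == 0:
            continue
        if n < window_loci:
            logger.warning(
                "chromosome %s has %d loci (< window of %d); single segment",
                chrom, n, window_loci)
            med = float(np.median(ratio))
            segments.append(HemizygositySegment(
                chrom, int(pos[0]), int(pos[-1]) + 1,
                "hemizygous" if med < boundary else "balanced", n, med))
            continue
        smooth = (pd.Series(ratio)
                  .rolling(window_loci, center=True, min_periods=1)
                  .median().to_numpy())
        labels = np.where(smooth < boundary, "hemizygous", "balanced")
        run_start = 0
        for i in range(1, n + 1):
            if i == n or labels[i] != labels[run_start]:
                start = (int(pos[0]) if run_start == 0
                         else (int(pos[run_start - 1]) + int(pos[run_start])) // 2)
                end = (int(pos[n - 1]) + 1 if i == n
                       else (int(pos[i - 1]) + int(pos[i])) // 2)
                segments.append(HemizygositySegment(
                    chrom, start, end, str(labels[run_start]),
                    i - run_start, float(np.median(ratio[run_start:i]))))
                run_start = i
    return segments


def find_female_limited(
    loci: pd.DataFrame, params: FemaleLimitedParams, cohort: list[Individual],
) -> pd.DataFrame:
    """Loci represented in all females, absent in all males, with pooled
    female depth inside the configured band (W-diagnostic loci)."""
    females, males = _sex_columns(cohort)
    f_rep = (loci[females] >= 1).sum(axis=1)
    m_depth = loci[males].sum(axis=1) if males else pd.Series(0, index=loci.index)
    pooled_f = loci[females].sum(axis=1)
    keep = pd.Series(True, index=loci.index)
    if params.require_all_females:
        keep &= f_rep == len(females)
    keep &= m_depth <= params.max_male_depth
    keep &= (pooled_f >= params.pooled_female_min) & (pooled_f <= params.pooled_female_max)
    return loci.loc[keep].reset_index(drop=True)


@dataclass
class DensityCI:
    per_chrom: pd.DataFrame  # chrom, n_loci, chrom_len, density
    autosomal_median: float
    ci_low: float
    ci_high: float
    n_boot: int


def bootstrap_median_ci(
    values: np.ndarray, n_boot: int, seed: int, level: float = 0.95,
) -> tuple[float, float, float]:
    """Percentile bootstrap CI for the median.

    Draw order is fixed and documented so results are reproducible at a seed:
    ``default_rng(seed)``, one ``integers(0, n, size=(n_boot, n))`` call,
    row medians, then ``quantile`` at the two tail probabilities.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    medians = np.median(values[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(medians, [alpha, 1.0 - alpha])
    return float(np.median(values)), float(lo), float(hi)


def locus_density_ci(
    loci: pd.DataFrame,
    genome: Genome,
    cohort: list[Individual],
    min_females: int = 10,
    n_boot: int = 10_000,
    seed: int = 0,
) -> DensityCI:
    """Per-chromosome density of high-quality loci (represented in at least
    ``min_females`` females), with a bootstrap CI for the autosomal median.

    The bootstrap resamples chromosomes: the units are the per-autosome
    density values, resampled with replacement ``n_boot`` times.
    """
    females, _ = _sex_columns(cohort)
    hq = loci.loc[(loci[females] >= 1).sum(axis=1) >= min_females]
    counts = hq["chrom"].value_counts()
    rows = [(name, int(counts.get(name, 0)), length,
             counts.get(name, 0) / (length / 1e6))
            for name, length in genome.lengths().items()]
    per_chrom = pd.DataFrame(rows, columns=["chrom", "n_loci", "chrom_len", "density"])
    auto = per_chrom.loc[per_chrom["chrom"].isin(genome.autosome_names()), "density"]
    if len(auto) < 2:
        raise ValueError("bootstrap CI undefined with fewer than 2 autosomes")
    median, lo, hi = bootstrap_median_ci(auto.to_numpy(), n_boot, seed)
    return DensityCI(per_chrom=per_chrom, autosomal_median=median,
                     ci_low=lo, ci_high=hi, n_boot=n_boot)
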