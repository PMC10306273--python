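"""W sequence-tag homology machinery.

Short fixed-length tags extracted from a W chromosome are aligned (uniquely)
to a W-less target genome; their per-chromosome alignment density and the
rank correlation between source and target positions quantify Z-W homology
and synteny. Additional detectors report peripheral enrichment on the Z,
collinear blocks, and translocation-plus-tandem-expansion signatures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .aligner import AlignerParams, GenomeIndex, align_unique
from .genome import Genome

logger = logging.getLogger(__name__)

TAG_LEN = 150
TAG_STEP = 500


@dataclass(frozen=True)
class SequenceTag:
    source_chrom: str
    source_start: int
    length: int
    sequence: str


def _unmasked_runs(seq: str, mask: np.ndarray | None) -> Iterable[tuple[int, int]]:
    if mask is None:
        arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        keep = arr != ord("N")
    else:
        keep = ~np.asarray(mask, dtype=bool)
    # run boundaries of True stretches
    padded = np.concatenate([[False], keep, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    return zip(starts.tolist(), ends.tolist())


def extract_tags_masked(
    chrom: str, seq: str, mask: np.ndarray | None = None, tag_len: int = TAG_LEN,
) -> list[SequenceTag]:
    """Contiguous non-overlapping tags from repeat-mask-surviving segments.

    Within each maximal unmasked run of length L, floor(L / tag_len) tags are
    emitted starting at the run's left edge. Without an explicit mask, N is
    interpreted as hard masking.
    """
    tags: list[SequenceTag] = []
    for start, end in _unmasked_runs(seq, mask):
        n = (end - start) // tag_len
        for i in range(n):
            s = start + i * tag_len
            tags.append(SequenceTag(chrom, s, tag_len, seq[s:s + tag_len].upper()))
    return tags


def extract_tags_stepped(
    chrom: str, seq: str, step: int = TAG_STEP, tag_len: int = TAG_LEN,
) -> list[SequenceTag]:
    """Tags of ``tag_len`` bp every ``step`` bp along the unmasked sequence."""
    tags = []
    pos = 0
    while pos + tag_len <= len(seq):
        tags.append(SequenceTag(chrom, pos, tag_len, seq[pos:pos + tag_len].upper()))
        pos += step
    return tags


TAG_ALIGN_COLUMNS = ["source_chrom", "source_start", "tag_len",
                     "chrom", "start", "strand", "n_mismatch"]


def align_tags(
    tags: Iterable[SequenceTag], index: GenomeIndex, params: AlignerParams,
) -> pd.DataFrame:
    """Unique placements of tags on the target; one row per aligned tag."""
    rows = []
    for t in tags:
        hit = align_unique(t.sequence, index, params,
                           query_id=f"{t.source_chrom}:{t.source_start}")
        if hit is not None:
            rows.append((t.source_chrom, t.source_start, t.length,
                         hit.chrom, hit.start, hit.strand, hit.n_mismatch))
    return pd.DataFrame(rows, columns=TAG_ALIGN_COLUMNS)


def compute_density(alignments: pd.DataFrame, genome: Genome) -> pd.DataFrame:
    """Uniquely aligned tags per Mb for every target chromosome.

    Zero-count chromosomes are included; an alignment naming a chromosome
    absent from the genome is an error.
    """
    lengths = genome.lengths()
    unknown = set(alignments["chrom"]) - set(lengths)
    if unknown:
        raise ValueError(f"alignments reference unknown chromosomes {sorted(unknown)}")
    counts = alignments["chrom"].value_counts()
    rows = [(name, int(counts.get(name, 0)), length,
             counts.get(name, 0) / (length / 1e6))
            for name, length in lengths.items()]
    return pd.DataFrame(rows, columns=["chrom", "n_unique", "chrom_len", "density"])


def positional_correlation(
    alignments: pd.DataFrame, min_tags: int = 120,
) -> pd.DataFrame:
    """Spearman r_s of (source position, target position) per target chromosome.

    Chromosomes attracting fewer than ``min_tags`` uniquely aligned tags are
    omitted (and logged); ties are handled by average ranks.
    """
    rows = []
    for chrom, grp in alignments.groupby("chrom", sort=False):
        n = len(grp)
        if n < min_tags:
            logger.info("chromosome %s under the %d-tag gate (n=%d); omitted",
                        chrom, min_tags, n)
            continue
        r_s = stats.spearmanr(grp["source_start"], grp["start"]).statistic
        rows.append((chrom, n, float(r_s)))
    return pd.DataFrame(rows, columns=["chromosome", "n_tags", "r_s"])


def peripheral_enrichment(
    alignments: pd.DataFrame, chrom: str, chrom_len: int,
    window: int = 1_000_000,
) -> tuple[float, float, float]:
    """Fraction of tags on ``chrom`` starting in the terminal windows.

    Returns (left, right, either) where left is [0, window) and right is
    [chrom_len - window, chrom_len).
    """
    if chrom_len <= 2 * window:
        raise ValueError(
            f"chromosome length {chrom_len} must exceed twice the window "
            f"({window}); choose a smaller window")
    on = alignments.loc[alignments["chrom"] == chrom, "start"]
    if len(on) == 0:
        return (0.0, 0.0, 0.0)
    left = float((on < window).mean())
    right = float((on >= chrom_len - window).mean())
    return (left, right, left + right)


@dataclass(frozen=True)
class CollinearBlock:
    target_chrom: str
    w_start: int
    w_end: int
    target_start: int
    target_end: int
    n_tags: int
    direction: str  # '+' increasing, '-' decreasing target positions


def detect_collinear_blocks(
    alignments: pd.DataFrame, min_run: int = 5, max_gap: int = 100_000,
) -> list[CollinearBlock]:
    """Maximal runs of source-consecutive tags with strictly monotone target
    positions (either direction) and inter-tag target gaps <= max_gap."""
    blocks: list[CollinearBlock] = []
    for chrom, grp in alignments.groupby("chrom", sort=False):
        grp = grp.sort_values("source_start")
        src = grp["source_start"].to_numpy()
        tgt = grp["start"].to_numpy()
        tlen = grp["tag_len"].to_numpy()
        i = 0
        n = len(grp)
        while i < n - 1:
            step = tgt[i + 1] - tgt[i]
            if step == 0 or abs(step) > max_gap:
                i += 1
                continue
            direction = 1 if step > 0 else -1
            j = i + 1
            while j < n - 1:
                nxt = tgt[j + 1] - tgt[j]
                if nxt == 0 or np.sign(nxt) != direction or abs(nxt) > max_gap:
                    break
                j += 1
            if j - i + 1 >= min_run:
                blocks.append(CollinearBlock(
                    target_chrom=chrom,
                    w_start=int(src[i]),
                    w_end=int(src[j] + tlen[j]),
                    target_start=int(tgt[i:j + 1].min()),
                    target_end=int(tgt[i:j + 1].max() + tlen[j]),
                    n_tags=j - i + 1,
                    direction="+" if direction > 0 else "-"))
            i = j
    return blocks


@dataclass(frozen=True)
class ExpansionCall:
    w_start: int
    w_end: int
    target_chrom: str
    target_start: int
    target_end: int
    n_tags: int
    span_ratio: float  # W span / target span


def detect_expansion(
    alignments: pd.DataFrame,
    step: int = TAG_STEP,
    min_cluster: int = 10,
    ratio_threshold: float = 1.5,
    max_w_gap: int | None = None,
) -> list[ExpansionCall]:
    """Tandem-expansion signatures from stepped (unmasked) W tags.

    Tags are single-linkage clustered by target position (link distance
    <= 2 * step); a cluster with >= min_cluster tags whose W-coordinate span
    exceeds its target span by >= ratio_threshold is reported: many W
    positions collapsing onto a short target interval is the footprint of a
    translocated segment multiplied in tandem on the W.

    A genuine tandem-array cluster is compact on both axes, so clusters are
    additionally split where consecutive W positions gap by more than
    ``max_w_gap`` (default 4 * step). This suppresses spurious high-ratio
    clusters whose W span merely straddles an unrelated insertion between
    two collinear anchors.
    """
    if max_w_gap is None:
        max_w_gap = 4 * step
    calls: list[ExpansionCall] = []
    for chrom, grp in alignments.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        tgt = grp["start"].to_numpy()
        src = grp["source_start"].to_numpy()
        tlen = grp["tag_len"].to_numpy()
        if len(grp) == 0:
            continue
        breaks = np.nonzero(np.diff(tgt) > 2 * step)[0]
        bounds = np.concatenate([[0], breaks + 1, [len(grp)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            order = np.argsort(src[a:b], kind="stable") + a
            w_sorted = src[order]
            w_breaks = np.nonzero(np.diff(w_sorted) > max_w_gap)[0]
            w_bounds = np.concatenate([[0], w_breaks + 1, [len(order)]])
            for wa, wb in zip(w_bounds[:-1], w_bounds[1:]):
                sel = order[wa:wb]
                n = len(sel)
                if n < min_cluster:
                    continue
                w_lo = int(src[sel].min())
                w_hi = int(src[sel].max() + tlen[sel].max())
                t_lo = int(tgt[sel].min())
                t_hi = int(tgt[sel].max() + tlen[sel].max())
                ratio = (w_hi - w_lo) / (t_hi - t_lo)
                if ratio >= ratio_threshold:
                    calls.append(ExpansionCall(
                        w_start=w_lo, w_end=w_hi, target_chrom=chrom,
                        target_start=t_lo, target_end=t_hi,
                        n_tags=n, span_ratio=float(ratio)))
    return calls


def blocks_to_bed(blocks: list[CollinearBlock], path) -> None:
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(f"{b.target_chrom}\t{b.target_start}\t{b.target_end}\t"
                     f"collinear\t{b.n_tags}\t{b.direction}\t{b.w_start}\t{b.w_end}\n")


def expansions_to_bed(calls: list[ExpansionCall], path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            fh.write(f"{c.target_chrom}\t{c.target_start}\t{c.target_end}\t"
                     f"expansion\t{c.n_tags}\t+\t{c.w_start}\t{c.w_end}\t"
                     f"{c.span_ratio:.3f}\n")
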