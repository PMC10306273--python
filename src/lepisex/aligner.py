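"""Unique-best-hit ungapped alignment of short queries to a genome.

The contract mirrors mismatch-threshold short-read mapping: every
seed-anchored ungapped placement of the query on either strand is scored as
n_mismatch * mismatch_cost, and a hit is reported iff the single best
placement is unique (no tie) and its score does not exceed score_threshold.
With the default cost of 30 per mismatch, the conventional thresholds map to
t300 -> 10, t400 -> 13, t600 -> 20 and t1200 -> 40 allowed mismatches.

N in query or target always counts as a mismatch, including N vs N.

``brute_force_align`` implements the identical contract by exhaustive scan of
every placement with no seeding; it is the verification oracle for
``align_unique`` and must stay independent of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .genome import Genome, revcomp

_N = ord("N")


@dataclass
class AlignerParams:
    score_threshold: int = 600
    mismatch_cost: int = 30
    seed_len: int = 15
    uniqueness: bool = True

    def __post_init__(self) -> None:
        if self.score_threshold < 0:
            raise ValueError("score_threshold must be >= 0")
        if self.mismatch_cost <= 0:
            raise ValueError("mismatch_cost must be > 0")
        if self.seed_len < 8:
            raise ValueError("seed_len must be >= 8")

    @property
    def max_mismatches(self) -> int:
        return self.score_threshold // self.mismatch_cost


@dataclass(frozen=True)
class TagAlignment:
    query_id: str
    chrom: str
    start: int  # 0-based leftmost target position
    strand: str  # '+' or '-'
    n_mismatch: int
    score: int
    unique: bool = True


class GenomeIndex:
    """Exact k-mer location index over the forward strand of every chromosome.

    Reverse-strand placements are found by aligning the reverse-complemented
    query against the forward index.
    """

    def __init__(self, genome: Genome, seed_len: int = 15):
        if seed_len < 8:
            raise ValueError("seed_len must be >= 8")
        self.seed_len = seed_len
        self.names: list[str] = genome.names
        self.arrays: list[np.ndarray] = [
            np.frombuffer(genome.chromosomes[n].upper().encode(), dtype=np.uint8)
            for n in self.names
        ]
        self.index: dict[bytes, list[tuple[int, int]]] = {}
        k = seed_len
        for ci, arr in enumerate(self.arrays):
            b = arr.tobytes()
            for pos in range(len(b) - k + 1):
                kmer = b[pos:pos + k]
                if b"N" in kmer:
                    continue
                self.index.setdefault(kmer, []).append((ci, pos))

    def chrom_length(self, ci: int) -> int:
        return self.arrays[ci].size


def _mismatches(target: np.ndarray, query: np.ndarray, query_has_n: bool) -> int:
    m = int(np.count_nonzero(target != query))
    if query_has_n:
        # byte-equal N vs N would count as a match; force it to mismatch
        m += int(np.count_nonzero((target == _N) & (query == _N)))
    return m


def _seed_offsets(qlen: int, k: int) -> list[int]:
    offsets = list(range(0, qlen - k + 1, k))
    if offsets[-1] != qlen - k:
        offsets.append(qlen - k)
    return offsets


def align_unique(
    query: str, index: GenomeIndex, params: AlignerParams,
    query_id: str = "query",
) -> TagAlignment | None:
    """Best unique seed-anchored placement of ``query``, or None.

    None is returned when no placement scores within threshold, or when two
    or more placements tie for the best score (the uniqueness contract).
    """
    q = query.upper()
    k = index.seed_len
    if len(q) < k:
        raise ValueError(f"query shorter than seed_len ({len(q)} < {k})")
    m = len(q)
    best: tuple[int, int, int, str] | None = None  # (mism, ci, start, strand)
    best_mism = m + 1
    ties = 0
    seen: set[tuple[int, int, str]] = set()
    for strand, qs in (("+", q), ("-", revcomp(q))):
        qb = qs.encode()
        qarr = np.frombuffer(qb, dtype=np.uint8)
        has_n = b"N" in qb
        for off in _seed_offsets(m, k):
            for ci, pos in index.index.get(qb[off:off + k], ()):
                start = pos - off
                if start < 0 or start + m > index.chrom_length(ci):
                    continue
                key = (ci, start, strand)
                if key in seen:
                    continue
                seen.add(key)
                mism = _mismatches(
                    index.arrays[ci][start:start + m], qarr, has_n)
                if mism < best_mism:
                    best_mism = mism
                    best = (mism, ci, start, strand)
                    ties = 1
                elif mism == best_mism:
                    ties += 1
    if best is None or best_mism * params.mismatch_cost > params.score_threshold:
        return None
    if params.uniqueness and ties > 1:
        return None
    mism, ci, start, strand = best
    return TagAlignment(
        query_id=query_id, chrom=index.names[ci], start=start, strand=strand,
        n_mismatch=mism, score=mism * params.mismatch_cost, unique=True)


def brute_force_align(
    query: str, genome: Genome, params: AlignerParams,
    query_id: str = "query",
) -> TagAlignment | None:
    """Oracle: identical contract to align_unique, by exhaustive scan."""
    q = query.upper()
    m = len(q)
    best: tuple[int, str, int, str] | None = None
    best_mism = m + 1
    ties = 0
    for strand, qs in (("+", q), ("-", revcomp(q))):
        qarr = np.frombuffer(qs.encode(), dtype=np.uint8)
        has_n = _N in qarr
        for name, seq in genome.chromosomes.items():
            arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
            if arr.size < m:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(arr, m)
            mism = (windows != qarr).sum(axis=1)
            if has_n:
                mism = mism + ((windows == _N) & (qarr == _N)).sum(axis=1)
            local_best = int(mism.min())
            n_local = int(np.count_nonzero(mism == local_best))
            if local_best < best_mism:
                best_mism = local_best
                best = (local_best, name, int(np.argmin(mism)), strand)
                ties = n_local
            elif local_best == best_mism:
                ties += n_local
    if best is None or best_mism * params.mismatch_cost > params.score_threshold:
        return None
    if params.uniqueness and ties > 1:
        return None
    mism, name, start, strand = best
    return TagAlignment(
        query_id=query_id, chrom=name, start=start, strand=strand,
        n_mismatch=mism, score=mism * params.mismatch_cost, unique=True)


# -------------------------------------------------------------- batch helpers

ALIGN_COLUMNS = ["query_id", "chrom", "start", "strand", "n_mismatch", "unique"]


def align_queries(
    queries: Iterable[tuple[str, str]], index: GenomeIndex, params: AlignerParams,
) -> pd.DataFrame:
    """Align (query_id, sequence) pairs; one row per uniquely placed query."""
    rows = []
    for qid, seq in queries:
        hit = align_unique(seq, index, params, query_id=qid)
        if hit is not None:
            rows.append((hit.query_id, hit.chrom, hit.start, hit.strand,
                         hit.n_mismatch, hit.unique))
    return pd.DataFrame(rows, columns=ALIGN_COLUMNS)


def alignments_to_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def alignments_from_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def alignments_to_sam(
    hits: Iterable[TagAlignment | tuple[str, str | None]],
    genome: Genome, path: str | Path,
) -> None:
    """Minimal SAM: mandatory columns only; unmapped reads get flag 4.

    ``hits`` may mix TagAlignment objects and (query_id, None) pairs for
    unaligned queries.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name, seq in genome.chromosomes.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for h in hits:
            if isinstance(h, tuple):
                qid, _ = h
                fh.write(f"{qid}\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n")
            else:
                flag = 16 if h.strand == "-" else 0
                fh.write(f"{h.query_id}\t{flag}\t{h.chrom}\t{h.start + 1}\t"
                         f"60\t*\t*\t0\t0\t*\t*\n")
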