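"""Chromosome composition diagnostics: GC, repeat content, telomeres.

A degenerate W chromosome betrays itself through an exceptionally low
proportion of non-repeated DNA and an elevated GC content relative to the
autosomes; intact chromosome builds carry (TTAGG)n telomere arrays at both
ends. A simple k-mer/tandem masker is provided for synthetic genomes so the
repeat-proportion diagnostics are computable without an external masking
step; real genomes are expected as pre-masked FASTA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import Genome, revcomp

TELOMERE_MOTIF = "TTAGG"


@dataclass(frozen=True)
class ChromStat:
    chrom: str
    length: int
    gc: float | None
    nonrepeat: float
    telomere_left: bool
    telomere_right: bool


def gc_content(seq: str) -> float | None:
    """(G+C) / (A+C+G+T); None when no unambiguous base is present."""
    s = seq.upper()
    counts = {b: s.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        return None
    return (counts["G"] + counts["C"]) / denom


def nonrepeat_proportion(seq: str, masking: str | None = None) -> float:
    """Fraction of unmasked bases. ``masking`` is 'soft' (lowercase = repeat),
    'hard' (N = repeat), or None to autodetect (soft if any lowercase)."""
    if len(seq) == 0:
        return 0.0
    if masking is None:
        masking = "soft" if any(c.islower() for c in seq) else "hard"
    if masking == "soft":
        unmasked = sum(1 for c in seq if c.isupper())
    elif masking == "hard":
        unmasked = sum(1 for c in seq.upper() if c != "N")
    else:
        raise ValueError(f"unknown masking mode {masking!r}")
    return unmasked / len(seq)


def _mismatch(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _max_tandem_run(window: str, motif: str) -> int:
    """Longest run of consecutive motif copies (stride = motif length, any
    phase) tolerating one mismatch per copy."""
    m = len(motif)
    best = 0
    for phase in range(m):
        run = 0
        for i in range(phase, len(window) - m + 1, m):
            if _mismatch(window[i:i + m], motif) <= 1:
                run += 1
                best = max(best, run)
            else:
                run = 0
    return best


def detect_telomere(
    seq: str, motif: str = TELOMERE_MOTIF, window: int = 2000,
    min_copies: int = 10,
) -> tuple[bool, bool]:
    """Telomere presence at (left, right) chromosome ends.

    Positive iff at least ``min_copies`` tandem copies of the motif (left end)
    or of its reverse complement (right end) occur within the terminal window,
    allowing one mismatch per copy.
    """
    if window > len(seq):
        window = len(seq)
    s = seq.upper()
    left = _max_tandem_run(s[:window], motif.upper()) >= min_copies
    right = _max_tandem_run(s[-window:], revcomp(motif.upper())) >= min_copies
    return left, right


def mask_repeats_simple(
    genome: Genome, k: int = 15, copy_threshold: int = 5,
    max_period: int = 500, identity: float = 0.9,
    chroms: list[str] | None = None,
) -> Genome:
    """Mask repeats in a synthetic genome by k-mer multiplicity.

    Every base covered by a k-mer whose genome-wide (forward strand) count is
    >= ``copy_threshold`` is masked; masked runs are then extended through
    tandem arrays (self-offset identity >= ``identity`` at some period
    <= ``max_period``). Nucleotides are never altered: only the mask changes.
    k-mer counts always cover the whole genome; ``chroms`` restricts which
    chromosomes receive a mask (all by default).
    """
    counts: dict[bytes, int] = {}
    encoded = {name: seq.upper().encode() for name, seq in genome.chromosomes.items()}
    for b in encoded.values():
        for pos in range(len(b) - k + 1):
            kmer = b[pos:pos + k]
            counts[kmer] = counts.get(kmer, 0) + 1
    masks: dict[str, np.ndarray] = {}
    for name, b in encoded.items():
        if chroms is not None and name not in chroms:
            continue
        mask = np.zeros(len(b), dtype=bool)
        for pos in range(len(b) - k + 1):
            if counts[b[pos:pos + k]] >= copy_threshold:
                mask[pos:pos + k] = True
        _extend_tandem(b, mask, max_period, identity)
        masks[name] = mask
    return Genome(chromosomes=dict(genome.chromosomes), mask=masks,
                  karyotype_note=genome.karyotype_note)


def _chunk_identity(a: bytes, b: bytes) -> float:
    if not a or len(a) != len(b):
        return 0.0
    arr_a = np.frombuffer(a, dtype=np.uint8)
    arr_b = np.frombuffer(b, dtype=np.uint8)
    return float((arr_a == arr_b).mean())


def _extend_tandem(b: bytes, mask: np.ndarray, max_period: int,
                   identity: float) -> None:
    """Grow each masked run outward while the flanking sequence repeats the
    run edge at some period (in place)."""
    n = len(b)
    padded = np.concatenate([[False], mask, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.nonzero(diff == 1)[0]
    ends = np.nonzero(diff == -1)[0]
    for s, e in zip(starts.tolist(), ends.tolist()):
        period = _detect_period(b, s, e, max_period, identity)
        if period is None:
            continue
        # rightward
        pos = e
        while pos + period <= n and _chunk_identity(
                b[pos:pos + period], b[pos - period:pos]) >= identity:
            mask[pos:pos + period] = True
            pos += period
        # leftward
        pos = s
        while pos - period >= 0 and _chunk_identity(
                b[pos - period:pos], b[pos:pos + period]) >= identity:
            mask[pos - period:pos] = True
            pos -= period


def _detect_period(b: bytes, s: int, e: int, max_period: int,
                   identity: float) -> int | None:
    span = e - s
    for period in range(1, min(max_period, span // 2) + 1):
        if _chunk_identity(b[s:s + period], b[s + period:s + 2 * period]) >= identity:
            return period
    return None


def chrom_stats_table(
    genome: Genome, telomere_window: int = 2000, telomere_min_copies: int = 10,
) -> pd.DataFrame:
    """Per-chromosome composition table; repeat fraction needs genome.mask."""
    rows = []
    for name, seq in genome.chromosomes.items():
        if genome.mask is not None and name in genome.mask:
            nonrep = float((~genome.mask[name]).mean()) if len(seq) else 0.0
        else:
            nonrep = nonrepeat_proportion(seq)
        tel_l, tel_r = detect_telomere(
            seq, window=telomere_window, min_copies=telomere_min_copies)
        rows.append((name, len(seq), gc_content(seq), nonrep, tel_l, tel_r))
    return pd.DataFrame(rows, columns=[
        "chrom", "length", "gc", "nonrepeat", "telomere_left", "telomere_right"])
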