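"""In-silico single-digest RAD-seq: PstI digest, read simulation, preprocessing.

PstI recognizes CTGCAG. The library model keeps only the cut-site-anchored
single-end geometry that matters for depth analysis: every read begins with
the 5' restriction residual TGCAG followed by genomic flank. For a site whose
recognition sequence starts at position p, the plus-strand read covers
[p+1, p+1+read_len) and the minus-strand read is the reverse complement of
[p+5-read_len, p+5); both begin with TGCAG.

Per-site, per-chromosome-copy, per-flank read counts are negative-binomial
(mean ``mean_depth``, dispersion ``k``), emulating the overdispersion of RAD
coverage. Copy number follows the karyotype: autosomes x2 in both sexes,
Z x2 in males and x1 in females, W x1 in females only.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .genome import Genome, Individual, revcomp

PSTI_SITE = "CTGCAG"
RESIDUAL = "TGCAG"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def digest_sites(seq: str, site: str = PSTI_SITE) -> list[int]:
    """Start positions of every exact occurrence of the recognition site."""
    out: list[int] = []
    pos = seq.find(site)
    while pos != -1:
        out.append(pos)
        pos = seq.find(site, pos + 1)
    return out


def _copies(chrom: str, sex: str) -> int:
    if chrom == "W":
        return 1 if sex == "female" else 0
    if chrom == "Z":
        return 1 if sex == "female" else 2
    return 2


@dataclass(frozen=True)
class FastqRead:
    name: str
    seq: str
    qual: str


def _inject_errors(seq: str, n_err: int, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    pos = rng.choice(arr.size, size=n_err, replace=False)
    for p in pos:
        alternatives = _BASES[_BASES != arr[p]]
        arr[p] = alternatives[rng.integers(0, alternatives.size)]
    return arr.tobytes().decode()


def simulate_individual_reads(
    genome: Genome,
    individual: Individual,
    mean_depth: float,
    error_rate: float,
    read_len: int,
    rng: np.random.Generator,
    dispersion: float = 5.0,
) -> Iterator[FastqRead]:
    """Reads for one individual over the genome copies its karyotype carries."""
    if read_len < len(RESIDUAL):
        raise ValueError("read_len shorter than the restriction residual")
    p_nb = dispersion / (dispersion + mean_depth)
    qual = "I" * read_len
    for chrom, seq in genome.chromosomes.items():
        n_copies = _copies(chrom, individual.sex)
        if n_copies == 0:
            continue
        for p in digest_sites(seq):
            for flank, ok in (("+", p + 1 + read_len <= len(seq)),
                              ("-", p + 5 - read_len >= 0)):
                if not ok:
                    continue
                count = int(rng.negative_binomial(dispersion, p_nb, size=n_copies).sum())
                if count == 0:
                    continue
                if flank == "+":
                    template = seq[p + 1:p + 1 + read_len]
                else:
                    template = revcomp(seq[p + 5 - read_len:p + 5])
                n_err = rng.binomial(read_len, error_rate, size=count)
                for i in range(count):
                    out = template if n_err[i] == 0 else _inject_errors(
                        template, int(n_err[i]), rng)
                    yield FastqRead(
                        f"{individual.id}|{chrom}|{p}|{flank}|{i}", out, qual)


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> int:
    path = Path(path)
    n = 0
    if path.suffix == ".gz":
        # mtime=0 keeps same-seed outputs byte-identical across runs
        fh = gzip.GzipFile(path, "wb", mtime=0)
    else:
        fh = open(path, "wb")
    with fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.seq}\n+\n{r.qual}\n".encode())
            n += 1
    return n


def read_fastq(path: str | Path) -> Iterator[FastqRead]:
    """Stream a (possibly gzipped) FASTQ; malformed records raise with index."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise ValueError(f"malformed FASTQ record {idx}: truncated record")
            header, seq, plus, qual = (s.rstrip("\n") for s in (header, seq, plus, qual))
            if not header.startswith("@"):
                raise ValueError(f"malformed FASTQ record {idx}: header lacks '@'")
            if not plus.startswith("+"):
                raise ValueError(f"malformed FASTQ record {idx}: separator lacks '+'")
            if len(seq) != len(qual):
                raise ValueError(
                    f"malformed FASTQ record {idx}: sequence/quality length mismatch")
            yield FastqRead(header[1:].split()[0], seq, qual)
            idx += 1


def simulate_rad_reads(
    genomes_by_sex: dict[str, Genome],
    individuals: list[Individual],
    mean_depth: float,
    error_rate: float,
    read_len: int,
    seed: int,
    dispersion: float = 5.0,
    out_dir: str | Path | None = None,
) -> dict[str, Path] | dict[str, list[FastqRead]]:
    """Simulate the sexed cohort. With ``out_dir``, write one gzipped FASTQ per
    individual and return id -> path; otherwise return id -> reads in memory.

    Each individual gets an independent, deterministic substream of ``seed``.
    """
    result_paths: dict[str, Path] = {}
    result_mem: dict[str, list[FastqRead]] = {}
    for idx, ind in enumerate(individuals):
        rng = np.random.default_rng([seed, 3, idx])
        reads = simulate_individual_reads(
            genomes_by_sex[ind.sex], ind, mean_depth, error_rate, read_len,
            rng, dispersion)
        if out_dir is not None:
            path = Path(out_dir) / f"{ind.id}.fastq.gz"
            write_fastq(reads, path)
            result_paths[ind.id] = path
        else:
            result_mem[ind.id] = list(reads)
    return result_paths if out_dir is not None else result_mem


# ---------------------------------------------------------------- preprocess


def preprocess_records(
    reads: Iterable[FastqRead],
    read_cap: int = 8_000_000,
    trim_len: int = 91,
    seed: int = 0,
) -> list[FastqRead]:
    """Keep residual-bearing reads, trim, and cap the file size.

    A read survives iff it begins with the PstI residual TGCAG; survivors are
    truncated to ``trim_len`` bp. If more than ``read_cap`` reads survive, the
    file is downsampled to exactly ``read_cap`` by seeded reservoir sampling.
    """
    rng = np.random.default_rng([seed, 4])
    reservoir: list[FastqRead] = []
    n_kept = 0
    for r in reads:
        if not r.seq.upper().startswith(RESIDUAL):
            continue
        trimmed = FastqRead(r.name, r.seq[:trim_len], r.qual[:trim_len])
        if n_kept < read_cap:
            reservoir.append(trimmed)
        else:
            j = int(rng.integers(0, n_kept + 1))
            if j < read_cap:
                reservoir[j] = trimmed
        n_kept += 1
    return reservoir


def preprocess_reads(
    in_path: str | Path,
    out_path: str | Path,
    read_cap: int = 8_000_000,
    trim_len: int = 91,
    seed: int = 0,
) -> int:
    """File-level preprocessing; returns the number of reads written."""
    kept = preprocess_records(read_fastq(in_path), read_cap, trim_len, seed)
    return write_fastq(kept, out_path)
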