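"""Core containers: genomes, simulation ground truth, and cohorts.

Coordinates are 0-based, half-open everywhere in memory and in BED output.
FASTA headers never carry coordinates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

VALID_BASES = set("ACGTN")

_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Genome:
    """An ordered set of named chromosome sequences with an optional repeat mask.

    ``mask`` maps chromosome name to a boolean array of the same length where
    True marks a repeat-masked base. Sequences are uppercase over {A,C,G,T,N}.
    """

    chromosomes: dict[str, str]
    mask: dict[str, np.ndarray] | None = None
    karyotype_note: str = ""

    def __post_init__(self) -> None:
        for name, seq in self.chromosomes.items():
            bad = set(seq.upper()) - VALID_BASES
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains invalid characters {sorted(bad)}"
                )
        if self.mask is not None:
            for name, m in self.mask.items():
                if name not in self.chromosomes:
                    raise ValueError(f"mask for unknown chromosome {name!r}")
                if len(m) != len(self.chromosomes[name]):
                    raise ValueError(
                        f"mask length {len(m)} != sequence length "
                        f"{len(self.chromosomes[name])} for {name!r}"
                    )

    @property
    def names(self) -> list[str]:
        return list(self.chromosomes)

    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def autosome_names(self) -> list[str]:
        """Chromosome names excluding the sex chromosomes Z and W."""
        return [n for n in self.chromosomes if n not in ("Z", "W")]

    # ---------------------------------------------------------------- I/O

    def to_fasta(self, path: str | Path, masking: str | None = None,
                 width: int = 80) -> None:
        """Write FASTA; masking is None, 'soft' (lowercase) or 'hard' (N)."""
        path = Path(path)
        with open(path, "w") as fh:
            for name, seq in self.chromosomes.items():
                out = seq
                if masking is not None:
                    if self.mask is None or name not in self.mask:
                        raise ValueError(f"no mask available for {name!r}")
                    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
                    m = self.mask[name]
                    if masking == "hard":
                        arr[m] = ord("N")
                    elif masking == "soft":
                        lower = np.frombuffer(seq.lower().encode(), dtype=np.uint8)
                        arr[m] = lower[m]
                    else:
                        raise ValueError(f"unknown masking mode {masking!r}")
                    out = arr.tobytes().decode()
                fh.write(f">{name}\n")
                for i in range(0, len(out), width):
                    fh.write(out[i:i + width] + "\n")

    @classmethod
    def from_fasta(cls, path: str | Path, mask_from: str | None = None) -> "Genome":
        """Read FASTA. ``mask_from`` = 'soft' derives the mask from lowercase,
        'hard' from N runs; sequences are stored uppercase either way."""
        chroms: dict[str, str] = {}
        masks: dict[str, np.ndarray] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            raw = str(rec.seq)
            if rec.id in chroms:
                raise ValueError(f"duplicate chromosome name {rec.id!r}")
            if mask_from == "soft":
                arr = np.frombuffer(raw.encode(), dtype=np.uint8)
                masks[rec.id] = (arr >= ord("a"))
            elif mask_from == "hard":
                arr = np.frombuffer(raw.upper().encode(), dtype=np.uint8)
                masks[rec.id] = (arr == ord("N"))
            chroms[rec.id] = raw.upper()
        return cls(chromosomes=chroms, mask=masks if mask_from else None)


@dataclass(frozen=True)
class TruthRecord:
    """One ground-truth homology/event interval on the simulated W.

    kind is 'remnant_homology' (surviving sequence of the fused autosome copy,
    mapping back to the neo-Z), 'translocation' (an autosomal segment copied
    into the W; the interval is the full occupied block after expansion) or
    'expansion' (the tandem-array sub-interval created by repeat multiplication).
    """

    w_start: int
    w_end: int
    source_chrom: str
    source_start: int
    source_end: int
    kind: str

    KINDS = ("remnant_homology", "translocation", "expansion")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown truth kind {self.kind!r}")
        if not (0 <= self.w_start < self.w_end):
            raise ValueError("invalid W interval")


@dataclass
class TruthTable:
    """Simulator ground truth: W intervals annotated with their origin."""

    records: list[TruthRecord] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def of_kind(self, kind: str) -> list[TruthRecord]:
        return [r for r in self.records if r.kind == kind]

    def extend(self, records: Iterable[TruthRecord]) -> None:
        self.records.extend(records)

    def hemizygous_z_intervals(self, neo_z_length: int) -> list[tuple[int, int]]:
        """Complement, on the neo-Z, of all remnant-homology source intervals.

        Loci inside these intervals have no W counterpart and are expected at a
        female:male depth ratio of 0.5; the rest of the neo-Z is Z-W balanced.
        """
        covered = sorted(
            (r.source_start, r.source_end) for r in self.of_kind("remnant_homology")
        )
        out: list[tuple[int, int]] = []
        cursor = 0
        for s, e in covered:
            if s > cursor:
                out.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < neo_z_length:
            out.append((cursor, neo_z_length))
        return out

    # BED: chrom=W, start, end, name=kind, score=0, strand=+, then source
    def to_bed(self, path: str | Path, w_name: str = "W") -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(
                    f"{w_name}\t{r.w_start}\t{r.w_end}\t{r.kind}\t0\t+\t"
                    f"{r.source_chrom}\t{r.source_start}\t{r.source_end}\n"
                )

    @classmethod
    def from_bed(cls, path: str | Path) -> "TruthTable":
        records = []
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                records.append(TruthRecord(
                    w_start=int(f[1]), w_end=int(f[2]), kind=f[3],
                    source_chrom=f[6], source_start=int(f[7]),
                    source_end=int(f[8]),
                ))
        return cls(records=records)


@dataclass(frozen=True)
class Individual:
    id: str
    sex: str  # 'male' | 'female'

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")


def make_cohort(n_per_sex: int) -> list[Individual]:
    """A balanced cohort f01..f<n>, m01..m<n>."""
    width = max(2, len(str(n_per_sex)))
    cohort = [Individual(f"f{i:0{width}d}", "female") for i in range(1, n_per_sex + 1)]
    cohort += [Individual(f"m{i:0{width}d}", "male") for i in range(1, n_per_sex + 1)]
    return cohort


def write_cohort(cohort: list[Individual], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tsex\n")
        for ind in cohort:
            fh.write(f"{ind.id}\t{ind.sex}\n")


def read_cohort(path: str | Path) -> list[Individual]:
    cohort: list[Individual] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            if not line.strip():
                continue
            ind_id, sex = line.rstrip("\n").split("\t")[:2]
            if ind_id in seen:
                raise ValueError(f"duplicate individual id {ind_id!r}")
            seen.add(ind_id)
            cohort.append(Individual(ind_id, sex))
    return cohort


def interval_overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))
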