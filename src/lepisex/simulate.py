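"""Simulation of ZW-origin scenarios with ground truth.

Two evolutionary pathways from an ancestral Z0/Z0Z0 configuration are
emulated. Under ``fusion``, the Z fuses with an autosome; the unfused copy of
that autosome becomes the W and degenerates (substitutions with a GC bias,
indels, incorporation of autosomal segments, tandem repeat multiplication).
Under ``b_origin``, the W derives from a B-like chromosome: a non-homologous
random backbone that recruits segments from the regular complement.

Every chromosome carries (TTAGG)n telomeres: the motif on the left end, its
reverse complement on the right end. The female genome carries the W; the
male genome does not; all other chromosomes are identical between sexes.

All coordinates in the returned TruthTable are final W coordinates (0-based,
half-open). Degradation is applied in a fixed order — substitutions, indels,
translocations, expansions — so truth intervals are computed once.
"""

from __future__ import annotations

import numpy as np

from .config import ScenarioConfig
from .genome import Genome, TruthRecord, TruthTable, revcomp

TELOMERE_MOTIF = "TTAGG"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = (ord(b) for b in "ACGT")


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def _telomere_arrays(copies: int) -> tuple[np.ndarray, np.ndarray]:
    left = np.frombuffer((TELOMERE_MOTIF * copies).encode(), dtype=np.uint8)
    right = np.frombuffer(
        (revcomp(TELOMERE_MOTIF) * copies).encode(), dtype=np.uint8)
    return left, right


def _random_chromosome(rng: np.random.Generator, length: int, gc: float,
                       telomere_copies: int) -> np.ndarray:
    left, right = _telomere_arrays(telomere_copies)
    interior = length - len(left) - len(right)
    if interior < 0:
        raise ValueError("chromosome shorter than its telomeres")
    return np.concatenate([left, _random_bases(rng, interior, gc), right])


def simulate_ancestral_genome(config: ScenarioConfig) -> Genome:
    """The pre-fusion state: ``n_autosomes`` autosomes (A1..An) plus the Z.

    Base composition is uniform at ``config.gc_content`` outside the telomeres.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    chroms: dict[str, str] = {}
    for i, length in enumerate(config.autosome_lengths, start=1):
        chroms[f"A{i}"] = _random_chromosome(
            rng, length, config.gc_content, config.telomere_copies
        ).tobytes().decode()
    chroms["Z"] = _random_chromosome(
        rng, config.z_length, config.gc_content, config.telomere_copies
    ).tobytes().decode()
    return Genome(chromosomes=chroms,
                  karyotype_note=f"ancestral: {config.n_autosomes} autosomes + Z")


# --------------------------------------------------------------- degradation


def _apply_substitutions(arr: np.ndarray, rate: float, gc_shift: float,
                         rng: np.random.Generator) -> int:
    """In-place substitutions; every hit changes the base.

    The replacement is drawn G/C with probability 0.5 + gc_shift, emulating
    the GC accumulation observed on degenerate W chromosomes.
    """
    if rate <= 0 or arr.size == 0:
        return 0
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    if hits.size == 0:
        return 0
    to_gc = rng.random(hits.size) < (0.5 + gc_shift)
    pick = rng.integers(0, 2, size=hits.size)
    for i, pos in enumerate(hits):
        orig = arr[pos]
        if to_gc[i]:
            pool = (_G, _C)
        else:
            pool = (_A, _T)
        new = pool[pick[i]]
        if new == orig:  # forced change: take the other base of the class
            new = pool[1 - pick[i]]
        if new == orig:  # class has only one alternative left (orig in class)
            new = pool[0] if pool[1] == orig else pool[1]
        arr[pos] = new
    return hits.size


def _apply_indels(arr: np.ndarray, src: np.ndarray, config: ScenarioConfig,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, int]:
    """Insertions (unsourced random sequence) and deletions at indel_rate.

    Returns the new sequence, the new source-position map and the net length
    delta. Geometric lengths with mean ``mean_indel_len``.
    """
    if config.indel_rate <= 0 or arr.size == 0:
        return arr, src, 0
    positions = np.nonzero(rng.random(arr.size) < config.indel_rate)[0]
    if positions.size == 0:
        return arr, src, 0
    is_ins = rng.random(positions.size) < 0.5
    lens = rng.geometric(1.0 / config.mean_indel_len, size=positions.size)
    pieces: list[np.ndarray] = []
    src_pieces: list[np.ndarray] = []
    cursor = 0
    delta = 0
    for pos, ins, length in zip(positions, is_ins, lens):
        if pos < cursor:  # swallowed by a previous deletion
            continue
        pieces.append(arr[cursor:pos])
        src_pieces.append(src[cursor:pos])
        if ins:
            insert = _random_bases(rng, int(length), config.gc_content)
            pieces.append(insert)
            src_pieces.append(np.full(int(length), -1, dtype=np.int64))
            cursor = pos
            delta += int(length)
        else:
            end = min(pos + int(length), arr.size)
            delta -= end - pos
            cursor = end
    pieces.append(arr[cursor:])
    src_pieces.append(src[cursor:])
    return np.concatenate(pieces), np.concatenate(src_pieces), delta


def _build_translocation_block(
    donor_seq: np.ndarray, donor_start: int, config: ScenarioConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, tuple[int, int, int, int] | None]:
    """A donor segment expanded in place by tandem repeat multiplication.

    The occupied block length is exactly round(expansion_factor * seg_len).
    Returns (block, expansion) where expansion = (block-relative array start,
    array length, unit offset in segment, unit length) or None if no extra
    copies were added.
    """
    tlen = config.translocation_len
    seg = donor_seq[donor_start:donor_start + tlen]
    extra = int(round((config.expansion_factor - 1.0) * tlen))
    if extra <= 0:
        return seg.copy(), None
    u = min(config.expansion_unit_len, tlen)
    o = int(rng.integers(0, tlen - u + 1))
    unit = seg[o:o + u]
    n_full, rem = divmod(extra, u)
    added = np.concatenate([np.tile(unit, n_full), unit[:rem]]) if extra else unit[:0]
    block = np.concatenate([seg[:o + u], added, seg[o + u:]])
    # the tandem array = the original unit plus all added copies
    return block, (o, u + extra, o, u)


def _apply_translocations(
    arr: np.ndarray, src: np.ndarray, donors: Genome, config: ScenarioConfig,
    rng: np.random.Generator, protect: int,
) -> tuple[np.ndarray, np.ndarray, list[TruthRecord], int]:
    """Insert expanded donor segments at random internal W positions.

    ``protect`` keeps insertions out of the terminal (telomeric) regions.
    Truth records carry final W coordinates: insertion sites are drawn in
    current coordinates, applied left to right with a running offset.
    """
    if config.n_translocations == 0:
        return arr, src, [], 0
    donor_names = donors.names
    if not donor_names:
        raise ValueError("translocations requested but no donor chromosomes")
    shortest = min(len(donors.chromosomes[n]) for n in donor_names)
    if config.translocation_len > shortest:
        raise ValueError(
            f"translocation_len {config.translocation_len} exceeds shortest "
            f"donor chromosome ({shortest} bp)")
    lo = min(protect, max(arr.size - protect, 0))
    hi = max(arr.size - protect, lo + 1)
    ins_pos = np.sort(rng.integers(lo, hi, size=config.n_translocations))
    records: list[TruthRecord] = []
    pieces: list[np.ndarray] = []
    src_pieces: list[np.ndarray] = []
    cursor = 0
    offset = 0
    added = 0
    for pos in ins_pos:
        donor = donor_names[int(rng.integers(0, len(donor_names)))]
        dseq = np.frombuffer(donors.chromosomes[donor].encode(), dtype=np.uint8)
        dstart = int(rng.integers(0, len(dseq) - config.translocation_len + 1))
        block, expansion = _build_translocation_block(dseq, dstart, config, rng)
        pieces.append(arr[cursor:pos])
        src_pieces.append(src[cursor:pos])
        pieces.append(block)
        src_pieces.append(np.full(block.size, -1, dtype=np.int64))
        w_start = int(pos) + offset
        records.append(TruthRecord(
            w_start=w_start, w_end=w_start + block.size,
            source_chrom=donor, source_start=dstart,
            source_end=dstart + config.translocation_len,
            kind="translocation"))
        if expansion is not None:
            a_start, a_len, u_off, u_len = expansion
            records.append(TruthRecord(
                w_start=w_start + a_start, w_end=w_start + a_start + a_len,
                source_chrom=donor, source_start=dstart + u_off,
                source_end=dstart + u_off + u_len,
                kind="expansion"))
        cursor = int(pos)
        offset += block.size
        added += block.size
    pieces.append(arr[cursor:])
    src_pieces.append(src[cursor:])
    return np.concatenate(pieces), np.concatenate(src_pieces), records, added


def _remnant_records(src: np.ndarray, source_chrom: str) -> list[TruthRecord]:
    """Maximal runs of consecutive source positions -> remnant_homology."""
    records: list[TruthRecord] = []
    n = src.size
    i = 0
    while i < n:
        if src[i] < 0:
            i += 1
            continue
        j = i + 1
        while j < n and src[j] == src[j - 1] + 1:
            j += 1
        records.append(TruthRecord(
            w_start=i, w_end=j, source_chrom=source_chrom,
            source_start=int(src[i]), source_end=int(src[j - 1]) + 1,
            kind="remnant_homology"))
        i = j
    return records


def degrade_w(
    w: str,
    donors: Genome,
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
    source_chrom: str | None = "Z",
    source_offset: int = 0,
    backbone_degeneration: bool = True,
) -> tuple[str, TruthTable]:
    """Degenerate a W sequence and report ground truth in final W coordinates.

    Order of events: substitutions (GC-biased by ``w_gc_shift``) -> indels ->
    translocations from random donor chromosomes -> tandem expansion of each
    translocated segment to ``expansion_factor`` times its length.

    ``source_chrom``/``source_offset`` declare where the input W is homologous
    to (the fused-autosome portion of the neo-Z); surviving homologous runs
    are reported as remnant_homology. Set ``source_chrom=None`` for a
    non-homologous backbone (B-origin), and ``backbone_degeneration=False``
    to skip substitutions/indels on an already-random backbone.
    """
    if not w:
        raise ValueError("w: empty sequence")
    config.validate()
    if rng is None:
        rng = np.random.default_rng([config.seed, 2])
    arr = np.frombuffer(w.upper().encode(), dtype=np.uint8).copy()
    if source_chrom is not None:
        src = np.arange(source_offset, source_offset + arr.size, dtype=np.int64)
    else:
        src = np.full(arr.size, -1, dtype=np.int64)
    n_sub = 0
    indel_delta = 0
    if backbone_degeneration:
        n_sub = _apply_substitutions(
            arr, config.substitution_rate, config.w_gc_shift, rng)
        arr, src, indel_delta = _apply_indels(arr, src, config, rng)
    protect = len(TELOMERE_MOTIF) * config.telomere_copies
    arr, src, event_records, transloc_added = _apply_translocations(
        arr, src, donors, config, rng, protect)
    truth = TruthTable()
    if source_chrom is not None:
        truth.extend(_remnant_records(src, source_chrom))
    truth.extend(event_records)
    truth.records.sort(key=lambda r: (r.w_start, r.w_end))
    truth.meta = {
        "n_substitutions": int(n_sub),
        "net_indel_delta": int(indel_delta),
        "translocation_added": int(transloc_added),
        "w_length": int(arr.size),
    }
    return arr.tobytes().decode(), truth


# ------------------------------------------------------------------ scenarios


def apply_scenario(
    genome: Genome, config: ScenarioConfig,
) -> tuple[Genome, Genome, TruthTable]:
    """Derive the male and female genomes plus ground truth from the ancestor.

    fusion: neo-Z = Z ++ last autosome (removed from the autosome set); the W
    is the degenerated second copy of that autosome, homologous to neo-Z
    positions [z_length, z_length + autosome length) before degeneration.

    b_origin: the W is a random backbone of ``fused_autosome_length`` bp (at
    gc_content + w_gc_shift, with telomeres) carrying ``n_translocations``
    segments recruited from the Z and autosomes; no remnant homology exists.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    note = dict(fusion="neo-Z from Z-autosome fusion; W = degenerate autosome copy",
                b_origin="W recruited from a B-like chromosome")[config.scenario]

    if config.scenario == "fusion":
        if config.n_autosomes == 0:
            raise ValueError("fusion scenario requires at least one autosome")
        fused_name = f"A{config.n_autosomes}"
        fused_seq = genome.chromosomes[fused_name]
        neo_z = genome.chromosomes["Z"] + fused_seq
        shared = {n: s for n, s in genome.chromosomes.items()
                  if n not in (fused_name, "Z")}
        donors = Genome(chromosomes=dict(shared)) if shared else Genome(chromosomes={})
        w_seq, truth = degrade_w(
            fused_seq, donors, config, rng,
            source_chrom="Z", source_offset=config.z_length)
        male = Genome(chromosomes={**shared, "Z": neo_z},
                      karyotype_note=note + " (male: ZZ)")
        female = Genome(chromosomes={**shared, "Z": neo_z, "W": w_seq},
                        karyotype_note=note + " (female: ZW)")
    else:
        backbone = _random_chromosome(
            rng, config.fused_autosome_length,
            min(config.gc_content + config.w_gc_shift, 0.95),
            config.telomere_copies,
        ).tobytes().decode()
        donors = Genome(chromosomes=dict(genome.chromosomes))
        w_seq, truth = degrade_w(
            backbone, donors, config, rng,
            source_chrom=None, backbone_degeneration=False)
        male = Genome(chromosomes=dict(genome.chromosomes),
                      karyotype_note=note + " (male: ZZ)")
        female = Genome(chromosomes={**genome.chromosomes, "W": w_seq},
                        karyotype_note=note + " (female: ZW)")
    return male, female, truth
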