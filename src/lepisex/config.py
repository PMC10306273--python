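"""Simulation scenario configuration.

A ScenarioConfig fully determines a simulated study: the karyotype, the
W-origin scenario (Z-autosome fusion vs. B-chromosome recruitment), the
degeneration process applied to the W, and the sexed RAD-seq cohort.
Identical config + seed gives bit-identical output everywhere downstream.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

SCENARIOS = ("fusion", "b_origin")


@dataclass
class ScenarioConfig:
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
    # RAD cohort
    n_per_sex: int = 19
    mean_depth: float = 20.0
    depth_dispersion: float = 5.0
    error_rate: float = 0.002
    read_len: int = 100
    seed: int = 1

    @property
    def n_autosomes(self) -> int:
        return len(self.autosome_lengths)

    def validate(self) -> None:
        """Raise ValueError naming the offending field."""
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario: must be one of {SCENARIOS}, got {self.scenario!r}")
        if not self.autosome_lengths and self.scenario == "fusion":
            raise ValueError("autosome_lengths: fusion requires at least one autosome")
        for i, length in enumerate(self.autosome_lengths):
            if length <= 0:
                raise ValueError(f"autosome_lengths[{i}]: must be > 0")
        if self.z_length <= 0:
            raise ValueError("z_length: must be > 0")
        if self.fused_autosome_length <= 0:
            raise ValueError("fused_autosome_length: must be > 0")
        if (self.scenario == "fusion"
                and self.autosome_lengths[-1] != self.fused_autosome_length):
            raise ValueError(
                "fused_autosome_length: the fusion partner is the last autosome; "
                f"autosome_lengths[-1]={self.autosome_lengths[-1]} must equal "
                f"fused_autosome_length={self.fused_autosome_length}")
        for name in ("gc_content", "substitution_rate", "indel_rate",
                     "w_gc_shift", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}: must be in [0, 1], got {v}")
        if self.gc_content / 2 + self.w_gc_shift > 1.0:
            raise ValueError("w_gc_shift: gc_content/2 + w_gc_shift exceeds 1")
        if self.mean_indel_len < 1:
            raise ValueError("mean_indel_len: must be >= 1")
        if self.n_translocations < 0:
            raise ValueError("n_translocations: must be >= 0")
        if self.translocation_len <= 0:
            raise ValueError("translocation_len: must be > 0")
        if self.expansion_factor < 1.0:
            raise ValueError("expansion_factor: must be >= 1")
        if self.expansion_unit_len <= 0:
            raise ValueError("expansion_unit_len: must be > 0")
        if self.telomere_copies < 0:
            raise ValueError("telomere_copies: must be >= 0")
        if self.telomere_copies * 10 > min(
                [self.z_length, self.fused_autosome_length] + self.autosome_lengths):
            raise ValueError("telomere_copies: telomeres longer than shortest chromosome")
        if self.n_per_sex <= 0:
            raise ValueError("n_per_sex: must be > 0")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth: must be > 0")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion: must be > 0")
        if self.read_len < 5:
            raise ValueError("read_len: must cover the 5 bp restriction residual")
        if not isinstance(self.seed, int) or self.seed < 0:
            raise ValueError("seed: must be a non-negative integer")

    # ------------------------------------------------ flat key=value round-trip

    def to_file(self, path: str | Path) -> None:
        dataclass_to_kv(self, path)

    @classmethod
    def from_file(cls, path: str | Path) -> "ScenarioConfig":
        cfg = dataclass_from_kv(cls, path)
        cfg.validate()
        return cfg


def dataclass_to_kv(obj, path: str | Path) -> None:
    """Write a flat key=value file; lists become comma-joined values."""
    with open(path, "w") as fh:
        for f in dataclasses.fields(obj):
            value = getattr(obj, f.name)
            if isinstance(value, list):
                value = ",".join(str(v) for v in value)
            fh.write(f"{f.name}={value}\n")


def dataclass_from_kv(cls, path: str | Path):
    """Read a flat key=value file into ``cls``; unknown keys are rejected."""
    known = {f.name: f for f in dataclasses.fields(cls)}
    kwargs: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"line {lineno}: expected key=value, got {line!r}")
            key, _, raw = line.partition("=")
            key = key.strip()
            raw = raw.strip()
            if key not in known:
                raise ValueError(f"unknown config key {key!r}")
            kwargs[key] = _parse(known[key].type, raw)
    return cls(**kwargs)


def _parse(typ: str | type, raw: str):
    name = typ if isinstance(typ, str) else typ.__name__
    if "list" in name:
        return [int(v) for v in raw.split(",") if v != ""]
    if name == "int":
        return int(raw)
    if name == "float":
        return float(raw)
    return raw
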