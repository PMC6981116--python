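"""Run configuration: one YAML document driving the whole pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from . import ancestor, homology, synteny


@dataclass
class RunConfig:
    genomes: dict[str, str] = field(default_factory=dict)  # id -> GFF3/BED path
    hits: str = ""
    lengths: str = ""
    tree: str | None = None
    out_dir: str = "paleokaryo_out"

    cip_min: float = homology.DEFAULT_CIP_MIN
    calp_min: float = homology.DEFAULT_CALP_MIN
    max_gap: int = synteny.DEFAULT_MAX_GAP
    min_genes: int = synteny.DEFAULT_MIN_GENES
    self_min_genes: int = synteny.DEFAULT_SELF_MIN_GENES
    merge_gap: int = synteny.DEFAULT_MERGE_GAP
    min_span: int = synteny.DEFAULT_MIN_SPAN
    coverage_frac: float = synteny.DEFAULT_COVERAGE_FRAC
    quota: int = 1
    car_support_frac: float = ancestor.DEFAULT_CAR_SUPPORT_FRAC
    proto_support_frac: float = ancestor.DEFAULT_PROTO_SUPPORT_FRAC
    telomere_frac: float = ancestor.DEFAULT_TELOMERE_FRAC
    rescue_support_frac: float = ancestor.DEFAULT_RESCUE_SUPPORT_FRAC
    rescue_telomere_max: float = ancestor.DEFAULT_RESCUE_TELOMERE_MAX
    min_support: int = ancestor.DEFAULT_MIN_SUPPORT
    small_car_min: int = ancestor.DEFAULT_SMALL_CAR_MIN
    min_family_genomes: int = 2
    copy_policy: str = "best_synteny"
    reference_genome: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def validate(self) -> None:
        if not self.genomes:
            raise ValueError("config must list at least one genome")
        for gid, path in self.genomes.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"gene-order file for {gid!r} missing: {path}")
        for name in ("hits", "lengths"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"{name} file missing: {p!r}")
        if self.tree and not Path(self.tree).exists():
            raise FileNotFoundError(f"tree file missing: {self.tree}")
        for name, lo, hi in (("cip_min", 0, 100), ("calp_min", 0, 100),
                             ("car_support_frac", 0, 1), ("proto_support_frac", 0, 1),
                             ("telomere_frac", 0, 1), ("coverage_frac", 0, 1)):
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.proto_support_frac > self.car_support_frac:
            raise ValueError("proto_support_frac must not exceed car_support_frac")
        for name in ("max_gap", "min_genes", "self_min_genes", "merge_gap", "quota"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
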