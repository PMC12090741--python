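"""Pipeline configuration: typed, defaulted, strictly validated YAML."""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Configuration for the end-to-end pipeline.

    Paths are optional because the ``simulate`` stage can generate every
    input; when given, they must exist at validation time.
    """

    # input paths (None -> produced by the simulate stage)
    counts_tsv: str | None = None
    taxonomy_tsv: str | None = None
    reference_tsv: str | None = None
    reads_fasta: str | None = None
    genes_fasta: str | None = None
    markers_tsv: str | None = None
    qpcr_csv: str | None = None
    metadata_csv: str | None = None
    tree_newick: str | None = None

    # analysis parameters
    rarefaction_depth: int = 33018
    rrn_fallback_rank: str = "phylum"
    min_matched: float = 0.5
    distance: str = "unifrac"  # "unifrac" | "braycurtis"
    nmds_k: int = 2
    nmds_restarts: int = 20
    seed: int = 0
    calib_beta0: float = 1.0
    calib_beta1: float = -2.0
    simulate: bool = True
    # synthetic scale (used when simulate is true)
    n_taxa: int = 150
    n_sites: int = 6
    samples_per_site: int = 3
    effect: float = 0.8
    site_sd: float = 0.1
    depth: int = 20000

    _PATH_FIELDS = (
        "counts_tsv",
        "taxonomy_tsv",
        "reference_tsv",
        "reads_fasta",
        "genes_fasta",
        "markers_tsv",
        "qpcr_csv",
        "metadata_csv",
        "tree_newick",
    )

    def validate(self) -> "PipelineConfig":
        if self.distance not in ("unifrac", "braycurtis"):
            raise ValueError(f"unknown distance {self.distance!r}")
        if self.rarefaction_depth <= 0:
            raise ValueError("rarefaction_depth must be positive")
        for name in self._PATH_FIELDS:
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config key {name!r}: no such file: {p}")
        if not self.simulate and self.counts_tsv is None:
            raise ValueError("config key 'counts_tsv' is required when simulate is off")
        return self

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def validate_config(path) -> PipelineConfig:
    """Load, default, and strictly validate a YAML config file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a YAML mapping")
    known = {f.name for f in fields(PipelineConfig) if not f.name.startswith("_")}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    return PipelineConfig(**raw).validate()
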