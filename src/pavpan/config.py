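"""Numeric thresholds governing every stage of the pipeline.

All cut-offs used anywhere in the package live in one :class:`Thresholds`
object that is passed explicitly to each operation; there is no global
state. Comparison semantics are deliberately literal: gene presence is
*strictly more than* 80% CDS coverage, while the reference-contig rule is
*at least* 95% identity and 95% query coverage.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["Thresholds", "load_thresholds", "write_thresholds"]

_FRACTION_FIELDS = {
    "ref_identity",
    "ref_query_coverage",
    "presence_cds_coverage",
    "hag_cds_coverage",
    "anchor_min_identity",
    "gene_contig_min_identity",
    "ins_max_repeat_fraction",
    "fdr_alpha",
    "redundancy_identity",
    "redundancy_coverage",
}

_POSITIVE_INT_FIELDS = {
    "min_contig_len",
    "anchor_flank_len",
    "anchor_min_aln_len",
    "sv_merge_max_dist",
    "sv_min_size",
}


@dataclass(frozen=True)
class Thresholds:
    """Every numeric rule of the pipeline, with its default value.

    Lengths are in bp; fractions in [0, 1]; ``placement_span_factor`` is a
    multiplier on gene length and ``or_flag_threshold`` an odds ratio.
    """

    min_contig_len: int = 500
    ref_identity: float = 0.95
    ref_query_coverage: float = 0.95
    presence_cds_coverage: float = 0.80
    hag_cds_coverage: float = 0.50
    anchor_flank_len: int = 3000
    anchor_min_aln_len: int = 1500
    anchor_min_identity: float = 0.80
    placement_span_factor: float = 2.0
    gene_contig_min_identity: float = 0.80
    sv_merge_max_dist: int = 1000
    sv_merge_min_support: int = 2
    sv_merge_type_match: bool = True
    sv_merge_strand_match: bool = True
    sv_min_size: int = 30
    ins_max_repeat_fraction: float = 0.5
    fdr_alpha: float = 0.05
    or_flag_threshold: float = 1.5
    redundancy_identity: float = 0.95
    redundancy_coverage: float = 0.95
    depth_presence_min: int = 1

    def __post_init__(self) -> None:
        for name in _FRACTION_FIELDS:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        for name in _POSITIVE_INT_FIELDS:
            v = getattr(self, name)
            if not (isinstance(v, int) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.sv_merge_min_support < 1:
            raise ValueError(
                f"sv_merge_min_support must be >= 1, got {self.sv_merge_min_support!r}"
            )
        if self.placement_span_factor <= 0:
            raise ValueError("placement_span_factor must be positive")
        if self.or_flag_threshold <= 0:
            raise ValueError("or_flag_threshold must be positive")
        if self.depth_presence_min < 1:
            raise ValueError("depth_presence_min must be >= 1")

    def replace(self, **overrides: object) -> "Thresholds":
        """Return a copy with the given fields overridden (re-validated)."""
        return dataclasses.replace(self, **overrides)


def load_thresholds(path: str | Path | None = None) -> Thresholds:
    """Load thresholds from a flat ``key: value`` YAML file.

    With no path, returns pure defaults. Unknown keys are rejected so a
    typo cannot silently leave a rule at its default.
    """
    if path is None:
        return Thresholds()
    text = Path(path).read_text()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ValueError(f"malformed config file {path}: {exc}") from exc
    if raw is None:
        return Thresholds()
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must be a flat key/value mapping")
    known = {f.name for f in dataclasses.fields(Thresholds)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
    return Thresholds(**raw)


def write_thresholds(t: Thresholds, path: str | Path) -> None:
    """Write thresholds as a flat YAML mapping; inverse of load_thresholds."""
    Path(path).write_text(
        yaml.safe_dump(dataclasses.asdict(t), sort_keys=True, default_flow_style=False)
    )
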