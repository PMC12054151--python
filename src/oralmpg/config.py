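"""Pipeline configuration and the controlled oral-site vocabulary.

The nine oral sampling sites are supragingival plaque (SUPP), buccal
mucosa (BM), tongue dorsum (TD), sub-gingival plaque (SUBP), keratinized
gingiva (KG), palatine tonsil (PT), throat (TH), saliva (SV), and hard
palate (HP).  Habitat classification runs on eight of them: HP is
excluded by default because a single hard-palate sample cannot support a
group comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any

import yaml

#: Controlled vocabulary of oral sampling-site codes.
SITE_CODES: tuple[str, ...] = (
    "SUPP", "BM", "TD", "SUBP", "KG", "PT", "TH", "SV", "HP",
)

#: Default site universe for habitat classification (HP excluded).
CLASSIFIER_SITES: tuple[str, ...] = (
    "BM", "KG", "PT", "SUBP", "SUPP", "SV", "TD", "TH",
)


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, with their defaults.

    Attributes
    ----------
    breadth_threshold:
        Minimum breadth of coverage for a genome to count as detected
        in a sample (fraction, inclusive).
    gene_cov_fraction:
        Fraction of a gene's nucleotides that must reach
        ``gene_min_depth`` for the gene to count as detected.
    gene_min_depth:
        Per-position depth (x coverage) required for a gene nucleotide
        to count as covered.
    module_completeness_threshold:
        Fraction of pathway steps present at which a metabolic module is
        scored complete (inclusive).
    q_threshold:
        Strict upper bound on the BH-adjusted p-value for a function or
        module to be called significantly enriched.
    ani_threshold:
        Maximum pairwise average nucleotide identity (percent) allowed
        between retained genomes after dereplication.
    min_completeness:
        Minimum genome completeness percent kept by QC (inclusive).
    max_contamination:
        Contamination percent at or above which QC removes a genome
        (strict "below" semantics).
    site_universe:
        Site codes over which habitat bipartitions are enumerated.
    seed:
        Root seed for every stochastic stage.
    """

    breadth_threshold: float = 0.5
    gene_cov_fraction: float = 0.9
    gene_min_depth: int = 1
    module_completeness_threshold: float = 0.75
    q_threshold: float = 0.01
    ani_threshold: float = 98.0
    min_completeness: float = 90.0
    max_contamination: float = 5.0
    site_universe: tuple[str, ...] = field(default_factory=lambda: CLASSIFIER_SITES)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.breadth_threshold <= 1:
            raise ValueError("breadth_threshold must be in (0, 1]")
        if not 0 < self.gene_cov_fraction <= 1:
            raise ValueError("gene_cov_fraction must be in (0, 1]")
        if self.gene_min_depth < 1:
            raise ValueError("gene_min_depth must be >= 1")
        if not 0 < self.module_completeness_threshold <= 1:
            raise ValueError("module_completeness_threshold must be in (0, 1]")
        if not 0 < self.q_threshold <= 1:
            raise ValueError("q_threshold must be in (0, 1]")
        if not 0 <= self.ani_threshold <= 100:
            raise ValueError("ani_threshold must be in [0, 100]")
        if not 0 <= self.min_completeness <= 100:
            raise ValueError("min_completeness must be in [0, 100]")
        if not 0 <= self.max_contamination <= 100:
            raise ValueError("max_contamination must be in [0, 100]")
        unknown = set(self.site_universe) - set(SITE_CODES)
        if unknown:
            raise ValueError(
                f"unknown site codes in site_universe: {sorted(unknown)}; "
                f"expected a subset of {SITE_CODES}"
            )
        self.site_universe = tuple(self.site_universe)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["site_universe"] = list(self.site_universe)
        return d

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        """Load a config from a YAML mapping; absent keys keep defaults."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path!r} must contain a YAML mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def validate_sites(sites) -> None:
    """Raise ValueError if any site code is outside the vocabulary."""
    unknown = set(sites) - set(SITE_CODES)
    if unknown:
        raise ValueError(
            f"unknown site code(s): {sorted(unknown)}; valid codes are {SITE_CODES}"
        )
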