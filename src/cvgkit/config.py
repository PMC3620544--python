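"""Pipeline configuration: every numeric threshold used by the analysis.

The defaults encode the published analysis settings: stem-vs-tissue
contrasts at adjusted P < 0.05, a >= 2-fold gate over the geometric mean
of tissue means, a homology E-value cutoff of 1e-50 (inclusive), GO
enrichment at FDR < 0.05, coexpression clusters of fewer than 3 nodes
removed, an HRR rank cutoff of 30, and the five GO evidence codes
treated as experimental.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

EXPERIMENTAL_CODES_DEFAULT = frozenset({"IDA", "IEP", "IPI", "IMP", "IGI"})


class ConfigError(ValueError):
    """Invalid configuration or missing required input."""


@dataclass
class PipelineConfig:
    """Numeric and policy settings shared across pipeline stages.

    Parameters
    ----------
    alpha
        Significance level for the per-contrast adjusted p-values
        (stem > tissue), strict ``<`` comparison.
    fold_threshold
        Minimum linear-scale fold of stem over the geometric mean of
        tissue means, inclusive ``>=`` comparison ("at least twice").
    evalue_cutoff
        Homology hit E-value cutoff, inclusive (a hit at exactly the
        cutoff is retained).
    fdr_threshold
        BH FDR level for GO term significance, strict ``<``.
    min_cluster_size
        Coexpression clusters with fewer members are removed.
    hrr_cutoff
        Highest-reciprocal-rank cutoff for coexpression edges.
    experimental_codes
        GO evidence codes counted as experimental annotations.
    focal_tissue
        The tissue treated as the vascular proxy ("stem").
    p_adjust
        Multiple-testing procedure across genes within each contrast:
        ``bh`` (default), ``bonferroni`` or ``none``.
    one_sided
        Directional stem > tissue contrasts when True (default).
    geomean_include_focal
        Whether the focal tissue participates in the geometric mean
        ("all tissues analysed" read literally). Default True.
    use_moderated
        Empirical-Bayes moderated t when True; ordinary pooled t when
        False.
    require_reciprocal
        Homology edges need hits in both directions when True; union
        of directions otherwise (default).
    d0_max
        Cap on the prior degrees of freedom before the prior is treated
        as effectively infinite.
    seed
        Seed for any stochastic step.
    """

    alpha: float = 0.05
    fold_threshold: float = 2.0
    evalue_cutoff: float = 1e-50
    fdr_threshold: float = 0.05
    min_cluster_size: int = 3
    hrr_cutoff: int = 30
    experimental_codes: frozenset[str] = EXPERIMENTAL_CODES_DEFAULT
    focal_tissue: str = "stem"
    p_adjust: str = "bh"
    one_sided: bool = True
    geomean_include_focal: bool = True
    use_moderated: bool = True
    require_reciprocal: bool = False
    d0_max: float = 1e6
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError(f"alpha must be in (0,1), got {self.alpha}")
        if not (0.0 < self.fdr_threshold < 1.0):
            raise ConfigError(
                f"fdr_threshold must be in (0,1), got {self.fdr_threshold}"
            )
        for name in ("fold_threshold", "evalue_cutoff", "d0_max"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.min_cluster_size < 1 or self.hrr_cutoff < 1:
            raise ConfigError("min_cluster_size and hrr_cutoff must be >= 1")
        if self.p_adjust not in ("bh", "bonferroni", "none"):
            raise ConfigError(f"unknown p_adjust method {self.p_adjust!r}")
        self.experimental_codes = frozenset(self.experimental_codes)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError(f"config file {path} is not a mapping")
        return cls.from_dict(d)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["experimental_codes"] = sorted(self.experimental_codes)
        return d
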