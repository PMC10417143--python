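"""Run configuration and seed plumbing for the end-to-end pipeline.

All pipeline stages draw their randomness from named substreams derived from
one root seed, so a stage's output is reproducible without coupling it to the
others.  Defaults equal the printed study constants: 0.7 um axial step,
selection cutoff 0.01, dichotomization cutoff 0.05, K=20 clusters, log2
fold-change threshold 1.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import numpy as np
import yaml

from .errors import ConfigurationError

#: Parameters whose defaults are the study's printed constants; the run
#: report records whether each was overridden.
PAPER_DEFAULTS = {
    "z_step": 0.7,
    "select_cutoff": 0.01,
    "dichotomize_cutoff": 0.05,
    "clusters": 20,
    "lfc_threshold": 1.0,
}

STAGES = ("stack_a", "stack_b", "profiles", "survival", "de", "mc")


@dataclass
class RunConfig:
    """Flat per-stage parameters of a full pipeline run."""

    seed: int = 0
    out_dir: str = "runs/demo"
    log_level: str = "INFO"
    # geometry / quantification
    z_step: float = 0.7
    select_cutoff: float = 0.01
    count_threshold: float = 0.0
    background: str | None = None
    background_level: float = 20.0
    median_window: int = 1
    # synthetic stacks
    n_layers: int = 60
    height: int = 64
    width: int = 64
    marker_density: float = 0.1
    noise_sd: float = 0.0
    # permutation test
    clusters: int = 20
    dichotomize_cutoff: float = 0.05
    mc_draws: int | None = None
    # survival
    n_subjects: int = 400
    true_cutoff: float = 25.0
    hazard_ratio: float = 6.0
    censor_rate: float = 0.2
    min_group_frac: float = 0.1
    # differential expression
    n_genes: int = 1000
    n_concordant: int = 922
    lfc_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.clusters < 1:
            raise ConfigurationError("clusters must be >= 1")
        if self.median_window < 1 or self.median_window % 2 == 0:
            raise ConfigurationError("median_window must be odd and >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(open(path)) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def overridden_paper_defaults(self) -> dict[str, bool]:
        """Which paper-printed defaults were changed in this run."""
        return {k: getattr(self, k) != v for k, v in PAPER_DEFAULTS.items()}


def stage_seeds(root_seed: int) -> dict[str, int]:
    """Derive one independent 31-bit seed per named pipeline stage."""
    children = np.random.SeedSequence(root_seed).spawn(len(STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(STAGES, children)
    }
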