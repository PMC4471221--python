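"""Run configuration for the command-line pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml

from .errors import InvalidInputError


@dataclass
class RunConfig:
    """Everything a pipeline run needs, with a mandatory seed.

    A missing seed is auto-generated (and logged) so that every run is
    reproducible after the fact; the config hash is stamped into every
    output file.
    """

    tree: Optional[str] = None
    species_table: Optional[str] = None
    landmark_manifest: Optional[str] = None
    fossil_table: Optional[str] = None
    output_dir: str = "results"

    run_pca: bool = True
    run_permutation: bool = True
    run_signal: bool = True
    run_allometry: bool = True
    run_ancestral: bool = True

    log_base: float = 10.0
    lambda_mode: str = "ml"          # "ml" or a fixed value as str/float
    signal_log_scale: bool = False   # signal tests on raw scale by default
    pca_scale_mode: str = "correlation"
    n_permutations: int = 10_000
    alpha_level: float = 0.05

    mcmc_iterations: int = 110_000
    mcmc_burn_in: int = 10_000
    mcmc_thinning: int = 20

    seed: Optional[int] = None
    seed_autogenerated: bool = False

    def __post_init__(self):
        if self.seed is None:
            import secrets

            self.seed = secrets.randbelow(2**31)
            self.seed_autogenerated = True

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (destination excluded)."""
        payload = self.to_dict()
        payload.pop("output_dir", None)
        payload.pop("seed_autogenerated", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
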