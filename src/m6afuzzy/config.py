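"""Run configuration: every tunable of the pipeline in one validated record.

A :class:`RunConfig` is loadable from YAML (with keyword overrides winning
over file values), hashable for provenance logging, and echoed into every
model file and report so a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields, replace
from pathlib import Path

import yaml

from .bsbl import BETA_INIT_RULES, CORRELATION_CONSTRAINTS, BsblOptions
from .psnp import PROPENSITY_MODES

LEARNERS = ("bsbl", "sbl", "ls")


@dataclass
class RunConfig:
    """Pipeline configuration with the package defaults.

    window_length / k
        Sequence window (41 nt) and k-mer order (5) of the propensity encoder.
    propensity_mode
        "difference" (positive minus negative class frequencies, default) or
        "positive" (positive-class frequencies alone).
    standardize
        Z-score the propensity features per column with training-split
        statistics before the fuzzy stage (default on).  Raw propensities
        live on very different scales than the design's intercept columns,
        which destabilizes the shared per-block prior scale.
    rules / fuzziness / h
        Number of TSK rules K, the FCM fuzziness exponent m, and the width
        scale h of the Gaussian memberships.
    learner
        "bsbl" (block-sparse Bayesian, default), "sbl" (singleton blocks) or
        "ls" (ridge least squares with ``ridge_lambda``).
    """

    window_length: int = 41
    k: int = 5
    propensity_mode: str = "difference"
    pseudocount: float = 0.0
    standardize: bool = True
    rules: int = 25
    fuzziness: float = 2.0
    h: float = 1.0
    fcm_tol: float = 1e-6
    fcm_max_iter: int = 300
    learner: str = "bsbl"
    eta: float = 1e-4
    max_iter: int = 500
    beta_init_rule: str = "signal-energy"
    correlation_constraint: str = "toeplitz"
    prune_gamma: float = 1e-2
    ridge_lambda: float = 1.0
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.window_length < 1:
            raise ValueError("window_length must be positive")
        if not 1 <= self.k <= self.window_length:
            raise ValueError("k must satisfy 1 <= k <= window_length")
        if self.propensity_mode not in PROPENSITY_MODES:
            raise ValueError(f"propensity_mode must be one of {PROPENSITY_MODES}")
        if self.rules < 1:
            raise ValueError("rules must be >= 1")
        if self.fuzziness <= 1:
            raise ValueError("fuzziness must exceed 1")
        if self.h <= 0:
            raise ValueError("h must be positive")
        if self.learner not in LEARNERS:
            raise ValueError(f"learner must be one of {LEARNERS}")
        if self.beta_init_rule not in BETA_INIT_RULES:
            raise ValueError(f"beta_init_rule must be one of {BETA_INIT_RULES}")
        if self.correlation_constraint not in CORRELATION_CONSTRAINTS:
            raise ValueError(
                f"correlation_constraint must be one of {CORRELATION_CONSTRAINTS}"
            )
        if self.ridge_lambda < 0:
            raise ValueError("ridge_lambda must be >= 0")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")

    def bsbl_options(self) -> BsblOptions:
        return BsblOptions(
            eta=self.eta,
            max_iter=self.max_iter,
            beta_init_rule=self.beta_init_rule,
            correlation_constraint=self.correlation_constraint,
            prune_gamma=self.prune_gamma,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def with_overrides(self, **changes) -> "RunConfig":
        changes = {k: v for k, v in changes.items() if v is not None}
        return replace(self, **changes)

    @classmethod
    def from_yaml(cls, path: str | Path | None = None, **overrides) -> "RunConfig":
        """Load from a YAML mapping; explicit keyword overrides win."""
        data: dict = {}
        if path is not None:
            with open(Path(path), "r", encoding="utf-8") as fh:
                loaded = yaml.safe_load(fh) or {}
            if not isinstance(loaded, dict):
                raise ValueError(f"{path}: config must be a YAML mapping")
            known = {f.name for f in fields(cls)}
            unknown = set(loaded) - known
            if unknown:
                raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
            data.update(loaded)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)
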