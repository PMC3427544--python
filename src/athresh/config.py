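"""Run configuration with the procedure's default settings.

Defaults mirror the standard analysis: FDR over clusters at q = 0.05 and
fixed forming thresholds at p = 0.001 uncorrected or p = 0.05 FWE.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import yaml

from .exceptions import InputError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    mode: str = "adaptive"          # adaptive | fixed-p | fixed-fwe
    fdr_q: float = 0.05             # FDR level over clusters
    fixed_p: float = 0.001          # uncorrected forming-threshold p
    fixed_fwe_p: float = 0.05       # FWE forming-threshold p
    em_tol: float = 1e-6            # relative log-likelihood tolerance
    em_max_iter: int = 1000
    n_boot: int = 2000              # bootstrap resamples
    bootstrap_alpha: float = 0.05
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise InputError(f"config file {path!r} must hold a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
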