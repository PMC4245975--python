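"""Run configuration: every tunable in one serializable record.

The config snapshot is embedded verbatim in every JSON report so a run can
be reproduced from its own output; deterministic stages rerun from an
embedded config byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .seedmatch import DEFAULT_ALLOWANCE_SPEC
from . import thermo
from .profiles import DEFAULT_CONTEXT_COEFFS

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    seed_span: tuple[int, int] = (2, 7)
    extended_seed_span: tuple[int, int] = (2, 8)
    include_6mer: bool = False
    gu_spec: str = DEFAULT_ALLOWANCE_SPEC
    mm_spec: str = DEFAULT_ALLOWANCE_SPEC
    thermo_flank: int = thermo.DEFAULT_FLANK
    thermo_threshold: float = thermo.DEFAULT_FUNCTIONAL_THRESHOLD
    thermo_mismatch_penalty: float = thermo.DEFAULT_MISMATCH_PENALTY
    thermo_k_terminal: int = thermo.DEFAULT_K_TERMINAL
    context_coeffs: dict = field(default_factory=lambda: dict(DEFAULT_CONTEXT_COEFFS))
    variant_positions: tuple[int, ...] = (2, 3, 4, 5, 6, 7)
    include_pos8: bool = False
    retarget_max_mismatch: int = 1
    guide_length: int = 22
    rng_seed: int = 0
    schema_version: int = SCHEMA_VERSION

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["seed_span"] = list(self.seed_span)
        d["extended_seed_span"] = list(self.extended_seed_span)
        d["variant_positions"] = list(self.variant_positions)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("seed_span", "extended_seed_span", "variant_positions"):
            if key in d:
                d[key] = tuple(d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def profile_kwargs(self) -> dict:
        """Keyword arguments for profiles.build_profile."""
        return {
            "include_6mer": self.include_6mer,
            "gu_spec": self.gu_spec,
            "mm_spec": self.mm_spec,
            "flank": self.thermo_flank,
            "functional_threshold": self.thermo_threshold,
            "mismatch_penalty": self.thermo_mismatch_penalty,
            "context_coeffs": self.context_coeffs,
        }
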