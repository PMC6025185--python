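"""Run configuration: the tunable constants of the pipeline.

Defaults follow the published protocol where it states a value — the PSD
neighbor cut 0.1 (strict <), the homolog coverage cut 0.6 (strict >), the
auto-covariance lag 10, the annotation score cutoff 0.5 (inclusive >=) and
the 0.9 train/test identity cut (strict >) — and this package's documented
choices elsewhere (10 equal-width LR bins, additive smoothing 1).

Configs load from a TOML file; explicit keyword overrides win over the
file, which wins over the defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path


@dataclass
class RunConfig:
    psd_threshold: float = 0.1      # structural neighbor cut, strict <
    coverage_threshold: float = 0.6  # homolog alignment coverage, strict >
    acc_lag: int = 10                # AC transform lag l
    bins: int = 10                   # LR bins over [0, 1]
    smoothing: float = 1.0           # additive LR smoothing
    score_cutoff: float = 0.5        # posterior cutoff, inclusive >=
    max_identity: float = 0.9        # decontamination identity cut, strict >
    min_support: int = 1             # neighbor floor for the structural scorer
    min_pos: int = 10                # PSSM per-term class floors
    min_neg: int = 10
    svm_kernel: str = "linear"
    seed: int = 0
    aspects: tuple[str, ...] = ("MF", "BP", "CC")
    chain_level: bool = False        # count PDB chains instead of entries
    drop_self_hits: bool = True      # remove query==subject homolog hits
    is_a_only: bool = False          # restrict propagation to is_a edges

    def relations(self) -> tuple[str, ...]:
        return ("is_a",) if self.is_a_only else ("is_a", "part_of")

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional TOML file plus overrides."""
    values: dict = {}
    if path is not None:
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        values.update(data)
    values.update({k: v for k, v in overrides.items() if v is not None})
    if "aspects" in values:
        values["aspects"] = tuple(values["aspects"])
    return RunConfig(**values)
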