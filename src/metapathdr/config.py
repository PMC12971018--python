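"""Shared pipeline configuration and deterministic seed derivation."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

from .metapath import CURATED_METAPATHS
from .prediction import DEFAULT_XGB_PARAMS


def derive_seed(master_seed: int, stage: str) -> int:
    """Derive a component seed from the master seed and a stage name.

    SHA-256 of ``"{master}:{stage}"``, first four bytes, reduced mod 2**31 --
    so every stage is independently reproducible from the master seed alone.
    """
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """All tunables of the build -> walk -> embed -> train -> integrate flow."""

    metapaths: tuple[str, ...] = CURATED_METAPATHS
    # random walks
    walks_per_start: int = 100
    walk_length: int = 40
    # skip-gram (dimension/window/epochs sized for desk-scale networks with
    # a few hundred embedded nodes; raise dimension for larger networks)
    dimension: int = 16
    window: int = 2
    epochs: int = 15
    negative_samples: int = 5
    min_count: int = 1
    heterogeneous: bool = True
    combine: str = "input"
    # classifier
    xgb_params: dict = field(default_factory=lambda: dict(DEFAULT_XGB_PARAMS))
    # integration / evaluation
    strategy: str = "MAX"
    threshold: float = 0.5
    k_folds: int = 5

    def __post_init__(self) -> None:
        self.metapaths = tuple(self.metapaths)
        if not self.metapaths:
            raise ValueError("metapath set must be non-empty")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["metapaths"] = list(self.metapaths)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]
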