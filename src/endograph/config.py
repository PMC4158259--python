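"""Run configuration shared by the CLI and embedded in every output file."""
from __future__ import annotations

from dataclasses import asdict, dataclass

from .exceptions import InvalidParameterError


@dataclass
class Config:
    """All tunable thresholds and rates of the pipeline.

    lam is the bracket-update weight of the connection-threshold search;
    dif_accept / dif_reject the NCC validation and subgraph-rejection
    thresholds; kl_threshold the trajectory-acceptance bound; max_features
    the per-frame feature budget; ratio the descriptor-matching ratio test;
    ransac_tol the inlier tolerance in pixels; stride the tracking
    decimation (positions recomputed every ``stride`` frames); seed governs
    every random draw.
    """

    lam: float = 0.1
    dif_accept: float = 0.8
    dif_reject: float = 0.2
    kl_threshold: float = 0.1
    max_features: int = 200
    ratio: float = 0.8
    ransac_tol: float = 3.0
    ransac_iter: int = 2000
    min_overlap: float = 0.25
    stride: int = 3
    n_samples: int = 200
    cell_size: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.lam < 1.0:
            raise InvalidParameterError("lam must lie in (0, 1)")
        for name in ("dif_accept", "dif_reject", "kl_threshold", "min_overlap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidParameterError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.ratio <= 1.0:
            raise InvalidParameterError("ratio must lie in (0, 1]")
        if self.max_features < 1 or self.stride < 1 or self.n_samples < 1:
            raise InvalidParameterError(
                "max_features, stride and n_samples must be >= 1"
            )
        if self.ransac_tol <= 0 or self.cell_size <= 0:
            raise InvalidParameterError("ransac_tol and cell_size must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, record: dict) -> "Config":
        known = {k: record[k] for k in cls.__dataclass_fields__ if k in record}
        return cls(**known)
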