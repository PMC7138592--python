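"""Declarative pipeline configuration.

A single :class:`PipelineConfig` carries every tunable of the analysis:
the KNN segmenter (training-point counts, spatial weighting, probability
threshold), the relevance vector regression (kernel, convergence controls),
and the evaluation scheme (folds, permutations, seed).  Configs load from
YAML or JSON; each run is expected to log the fully resolved config together
with the seed so results can be reproduced exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

logger = logging.getLogger(__name__)

__all__ = ["KNNParams", "RVRParams", "EvalParams", "PipelineConfig"]


@dataclass
class KNNParams:
    """KNN lesion-segmentation settings.

    Defaults follow the published BIANCA configuration: spatial weighting 1,
    no patch features, 2000 lesion / 10000 non-lesion training points
    ("fixed + unbalanced"), probability threshold 0.9 with strict inequality.
    The neighbour count k is not published; 40 is the package default.
    """

    k: int = 40
    spatial_weighting: float = 1.0
    n_lesion_points: int = 2000
    n_nonlesion_points: int = 10000
    probability_threshold: float = 0.9
    feature_channels: tuple[str, ...] = ("t1", "flair")
    sampling_policy: str = "fixed_unbalanced"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.spatial_weighting < 0:
            raise ValueError("spatial_weighting must be >= 0")
        if not 0.0 <= self.probability_threshold <= 1.0:
            raise ValueError("probability_threshold must be in [0, 1]")
        if self.sampling_policy != "fixed_unbalanced":
            raise ValueError(
                f"unsupported sampling_policy: {self.sampling_policy!r}"
            )


@dataclass
class RVRParams:
    """Relevance vector regression hyper-settings (see rvr module)."""

    kernel: str = "linear"
    max_iterations: int = 500
    convergence_tol: float = 1e-3
    prune_threshold: float = 1e9
    standardize_features: bool = False

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "precomputed"):
            raise ValueError(f"unsupported kernel: {self.kernel!r}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class EvalParams:
    """Cross-validation and permutation-test settings (7-fold, 1000 perms)."""

    n_folds: int = 7
    n_permutations: int = 1000
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass
class PipelineConfig:
    knn: KNNParams = field(default_factory=KNNParams)
    rvr: RVRParams = field(default_factory=RVRParams)
    evaluation: EvalParams = field(default_factory=EvalParams)
    atlas_path: str | None = None
    exclusion_mask_path: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        knn = KNNParams(**d.get("knn", {}))
        rvr = RVRParams(**d.get("rvr", {}))
        ev = EvalParams(**d.get("evaluation", {}))
        return cls(
            knn=knn,
            rvr=rvr,
            evaluation=ev,
            atlas_path=d.get("atlas_path"),
            exclusion_mask_path=d.get("exclusion_mask_path"),
        )

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            d = json.loads(text)
        else:
            d = yaml.safe_load(text)
        return cls.from_dict(d or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        d["knn"]["feature_channels"] = list(self.knn.feature_channels)
        return d

    def log_resolved(self) -> None:
        """Log the full resolved configuration and seed (reproducibility)."""
        logger.info("resolved pipeline config: %s",
                    json.dumps(self.to_dict(), sort_keys=True))
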