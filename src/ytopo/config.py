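"""Analysis configuration.

All tunable settings of the pipeline live in :class:`AnalysisConfig`.  The
defaults are the study settings: 5,000 permutations for pairwise genetic
distances, 9,999 permutations/bootstraps for spatial autocorrelation, a
10 km circular neighborhood for toponym density surfaces, and a 5%
informative-frequency threshold for haplogroup reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

GENERATION_LEVELS = ("proband", "father", "grandfather")
MT_METHODS = ("BH", "BY", "bonferroni")


@dataclass
class AnalysisConfig:
    """Settings shared by all pipeline stages.

    Parameters
    ----------
    generation_level : str
        Which generation's municipality is used for spatial placement:
        ``"proband"``, ``"father"`` or ``"grandfather"``.
    permutations_fst : int
        Permutations for pairwise PhiST significance testing.
    permutations_autocorr, bootstraps : int
        Resampling counts for the spatial autocorrelogram.
    density_radius_km, density_cell_km : float
        Circular-neighborhood radius and grid cell size of the toponym
        density surfaces, in km.
    informative_threshold : float
        Relative haplogroup frequency below which a haplogroup is flagged
        non-informative.
    mt_method : str
        Multiple-testing correction: ``"BH"``, ``"BY"`` or ``"bonferroni"``.
    n_distance_classes : int
        Number of even-pair-count distance classes for the correlogram.
    seed : int
        Seed for every stochastic stage.
    """

    generation_level: str = "proband"
    permutations_fst: int = 5000
    permutations_autocorr: int = 9999
    bootstraps: int = 9999
    density_radius_km: float = 10.0
    density_cell_km: float = 1.0
    informative_threshold: float = 0.05
    mt_method: str = "BY"
    n_distance_classes: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generation_level not in GENERATION_LEVELS:
            raise ValueError(
                f"generation_level must be one of {GENERATION_LEVELS}, "
                f"got {self.generation_level!r}"
            )
        if self.mt_method not in MT_METHODS:
            raise ValueError(f"mt_method must be one of {MT_METHODS}")
        for name in ("permutations_fst", "permutations_autocorr", "bootstraps",
                     "n_distance_classes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("density_radius_km", "density_cell_km"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.informative_threshold < 1.0:
            raise ValueError("informative_threshold must be in (0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load settings from a YAML key/value file; absent keys keep defaults."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must hold a key/value mapping")
        known = cls().__dict__.keys()
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
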