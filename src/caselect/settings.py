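"""Analysis-parameter grid and pipeline configuration.

A parameter *setting* is one combination of the five analysis choices that
enter the selectivity-inference pipeline: the neural datatype, the behavioral
datatype (which centroid defines arm occupancy), the temporal bin width, the
open/closed-arm sample matching rule, and the shuffling method used to build
the null distribution.  The full grid has 2 x 4 x 2 x 2 x 4 = 128 cells;
random permutation (``randperm``) does not apply lawfully to continuous
traces (there is no event train to permute), so those 8 cells are excluded,
leaving 120 valid settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from itertools import product
from typing import Iterable

import yaml

NEURAL_DATATYPES = ("events", "conv2s", "conv4s", "traces")
BEHAVIORAL_DATATYPES = ("head", "body")
BIN_WIDTHS = ("native", "one_second")
MATCHINGS = ("matched", "nonmatched")
SHUFFLES = ("randperm", "partial_ecm", "full_ecm", "circshift")

#: seconds of signal following each event onset that form a partial-ECM chunk
CHUNK_SECONDS = {"events": 3.0, "conv2s": 2.0, "conv4s": 4.0, "traces": 3.0}


@dataclass(frozen=True, order=True)
class ParameterSetting:
    """One point of the 5-dimensional analysis grid.

    ``setting_id`` is the 1-based row-major index over the grid in field
    order (neural, behavioral, bin, matching, shuffle).  Identity of a
    setting is its 5-tuple; ids are stable bookkeeping for a fixed grid
    ordering and are always reported alongside the tuple.
    """

    neural_datatype: str
    behavioral_datatype: str
    bin_width: str
    matching: str
    shuffle: str
    setting_id: int = field(compare=False, default=0)

    def __post_init__(self) -> None:
        checks = (
            (self.neural_datatype, NEURAL_DATATYPES, "neural_datatype"),
            (self.behavioral_datatype, BEHAVIORAL_DATATYPES, "behavioral_datatype"),
            (self.bin_width, BIN_WIDTHS, "bin_width"),
            (self.matching, MATCHINGS, "matching"),
            (self.shuffle, SHUFFLES, "shuffle"),
        )
        for value, allowed, name in checks:
            if value not in allowed:
                raise ValueError(f"{name}={value!r} not in {allowed}")

    @property
    def tuple(self) -> tuple[str, str, str, str, str]:
        return (
            self.neural_datatype,
            self.behavioral_datatype,
            self.bin_width,
            self.matching,
            self.shuffle,
        )

    @property
    def is_valid(self) -> bool:
        return not (self.shuffle == "randperm" and self.neural_datatype == "traces")

    @property
    def levels(self) -> tuple[str, ...]:
        """The five constituent levels, tagged by dimension (for robustness)."""
        return (
            f"neural={self.neural_datatype}",
            f"behavioral={self.behavioral_datatype}",
            f"bin={self.bin_width}",
            f"matching={self.matching}",
            f"shuffle={self.shuffle}",
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"#{self.setting_id}({','.join(self.tuple)})"


@dataclass(frozen=True)
class GridSummary:
    n_total: int
    n_excluded: int
    n_valid: int
    excluded_ids: tuple[int, ...]


def _full_grid() -> list[ParameterSetting]:
    out = []
    for i, combo in enumerate(
        product(NEURAL_DATATYPES, BEHAVIORAL_DATATYPES, BIN_WIDTHS, MATCHINGS, SHUFFLES)
    ):
        out.append(ParameterSetting(*combo, setting_id=i + 1))
    return out


def enumerate_settings() -> tuple[list[ParameterSetting], GridSummary]:
    """All valid settings in deterministic (row-major) order, plus counts."""
    grid = _full_grid()
    valid = [s for s in grid if s.is_valid]
    excluded = tuple(s.setting_id for s in grid if not s.is_valid)
    summary = GridSummary(
        n_total=len(grid),
        n_excluded=len(excluded),
        n_valid=len(valid),
        excluded_ids=excluded,
    )
    return valid, summary


def setting_from_id(setting_id: int) -> ParameterSetting:
    """Inverse of the enumeration ordering; rejects unknown and excluded ids."""
    grid = _full_grid()
    if not 1 <= setting_id <= len(grid):
        raise KeyError(f"no such setting: {setting_id}")
    s = grid[setting_id - 1]
    if not s.is_valid:
        raise ValueError(
            f"invalid setting (randperm on traces): {setting_id}"
        )
    return s


@dataclass
class PipelineConfig:
    """Iteration counts, seeds and thresholds for the whole pipeline.

    Defaults are the study-design values: 1,000 shuffle iterations, 1,000
    bootstrap resamples, 500 bootstrap-validation iterations, 200
    cross-validation iterations, alpha = 0.05, and 1,000 matched draws both
    for the true SI (``matched_draws``) and inside every null iteration
    (``matched_draws_null``; cheap, because draws are folded into coverage
    weights).
    """

    n_shuffles: int = 1000
    n_bootstrap: int = 1000
    n_validation: int = 500
    n_cv: int = 200
    cv_train_frac: float = 0.6
    alpha: float = 0.05
    matched_draws: int = 1000
    matched_draws_null: int = 1000
    tier_small: float = 0.9
    tier_medium: float = 0.8
    slope_ci: float = 0.99
    template_selective: float = 0.85
    template_nonselective: float = 0.05
    glm_permutations: int = 100
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def settings_table(settings: Iterable[ParameterSetting]):
    """Settings as a pandas DataFrame (id + the five levels)."""
    import pandas as pd

    rows = [
        {
            "setting_id": s.setting_id,
            "neural_datatype": s.neural_datatype,
            "behavioral_datatype": s.behavioral_datatype,
            "bin_width": s.bin_width,
            "matching": s.matching,
            "shuffle": s.shuffle,
        }
        for s in settings
    ]
    return pd.DataFrame(rows)
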