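"""Run configuration for the phenology pipeline."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .errors import ParameterError


@dataclass
class PipelineConfig:
    """Every tunable knob of the pipeline, with the defaults used throughout.

    Widths are in days, search ranges are inclusive DOY intervals, the
    significance level gates both driver selection and the final model
    F-test.
    """

    # NEE smoothing and transition-window search
    smooth_width: int = 15
    window_width: int = 10
    spring_range: tuple = (1, 200)
    autumn_range: tuple = (150, 365)

    # LSP retrieval
    lsp_method: str = "local_midpoint"
    lsp_method_params: dict = field(default_factory=dict)
    sg_window_points: int = 7
    sg_degree: int = 4
    sg_max_iterations: int = 10
    use_sg_filter: bool = True
    min_valid_composites: int = 15
    amplitude_floor: float = 0.05

    # climate-driver impact-window grid (offsets in days relative to the
    # LSP anchor; negative = before)
    window_starts: tuple = (-60, -50, -40, -30, -20, -10)
    window_ends: tuple = (0, 10, 20)
    min_site_years_per_window: int = 5
    #: Optional pinned impact windows, e.g. {"scu:temperature": (-20, 0)}:
    #: the grid search is skipped and the given window used directly —
    #: the regime in which windows selected on one site network are
    #: reapplied when extrapolating to new sites or regions.
    fixed_driver_windows: dict = field(default_factory=dict)

    # cohort filtering
    max_site_deviation: float = 60.0
    min_site_years_per_biome: int = 10

    # statistics
    significance_level: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.significance_level < 1.0):
            raise ParameterError("significance level must be in (0, 1)")
        for name in ("smooth_width", "window_width"):
            if int(getattr(self, name)) <= 0:
                raise ParameterError(f"{name} must be a positive integer")
        if self.smooth_width % 2 == 0:
            raise ParameterError("smooth_width must be odd")
        self.spring_range = tuple(self.spring_range)
        self.autumn_range = tuple(self.autumn_range)
        self.window_starts = tuple(self.window_starts)
        self.window_ends = tuple(self.window_ends)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ParameterError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        d = self.to_dict()
        for key in ("spring_range", "autumn_range", "window_starts", "window_ends"):
            d[key] = list(d[key])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)
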