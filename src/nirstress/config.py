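"""Pipeline configuration: every tunable of the analysis in one validated object."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .containers import ChannelLayout
from .preprocess import DEFAULT_BAND_HZ, DEFAULT_ORDER, DEFAULT_RIPPLE_DB


@dataclass
class FilterConfig:
    low_hz: float = DEFAULT_BAND_HZ[0]
    high_hz: float = DEFAULT_BAND_HZ[1]
    order: int = DEFAULT_ORDER
    ripple_db: float = DEFAULT_RIPPLE_DB


@dataclass
class EpochConfig:
    window_s: tuple[float, float] = (-1.0, 60.0)
    baseline_s: tuple[float, float] = (-1.0, 0.0)


@dataclass
class MbllConfig:
    dpf: tuple[float, float] = (6.0, 6.0)


@dataclass
class LisConfig:
    aggregation: str = "max"  # "max" | "mean"
    interval_s: tuple[float, float] = (0.0, 60.0)


@dataclass
class PipelineConfig:
    filter: FilterConfig = field(default_factory=FilterConfig)
    epoch: EpochConfig = field(default_factory=EpochConfig)
    mbll: MbllConfig = field(default_factory=MbllConfig)
    lis: LisConfig = field(default_factory=LisConfig)
    layout: ChannelLayout = field(default_factory=ChannelLayout)
    n_per_group: int = 11
    seed: int = 0
    use_forward_model: bool = False  # route synthetic data through MBLL and back

    def validate(self) -> "PipelineConfig":
        """Check every consuming module's constraints before any stage runs."""
        fs = self.layout.fs_hz
        if not (0.0 < self.filter.low_hz < self.filter.high_hz < fs / 2.0):
            raise ValueError(
                f"filter band ({self.filter.low_hz}, {self.filter.high_hz}) Hz "
                f"must satisfy 0 < low < high < fs/2 = {fs / 2:g} Hz"
            )
        if self.filter.order < 1:
            raise ValueError("filter order must be >= 1")
        w0, w1 = self.epoch.window_s
        b0, b1 = self.epoch.baseline_s
        if not w0 < 0 <= w1:
            raise ValueError("epoch window must contain t = 0")
        if not (w0 <= b0 < b1 <= 0):
            raise ValueError("baseline window must be a pre-onset subinterval")
        if self.lis.aggregation not in ("max", "mean"):
            raise ValueError("lis aggregation must be 'max' or 'mean'")
        i0, i1 = self.lis.interval_s
        if not (w0 <= i0 < i1 <= w1):
            raise ValueError("lis interval must lie within the epoch window")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if any(d <= 0 for d in self.mbll.dpf):
            raise ValueError("DPF values must be positive")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        kw = {}
        for name, sub in (("filter", FilterConfig), ("epoch", EpochConfig),
                          ("mbll", MbllConfig), ("lis", LisConfig),
                          ("layout", ChannelLayout)):
            if name in d:
                v = d.pop(name)
                kw[name] = sub(**{k: tuple(x) if isinstance(x, list) else x
                                  for k, x in v.items()}) if isinstance(v, dict) else v
        kw.update(d)
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
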