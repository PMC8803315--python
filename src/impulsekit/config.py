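"""Run configuration: analysis defaults, validation, and seed derivation.

Analysis defaults equal the protocol's stated values: 0.25 s rate bins,
1.5 s Gaussian smoothing, baseline -2..-1 s, post-onset 0..+1 s, 5000
permutation iterations, top-10% population criterion, Grubbs alpha 0.0001,
2 s LFP time bins.  One global seed expands into per-stage seeds through
``numpy.random.SeedSequence(seed).spawn`` in the fixed stage order
``cohort, sessions, spikes, lfp, nodes, analysis`` so any stage can be
re-run independently yet reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

__all__ = ["AnalysisConfig", "RunConfig", "load_config", "stage_seeds"]

STAGES = ("cohort", "sessions", "spikes", "lfp", "nodes", "analysis")


@dataclass(frozen=True)
class AnalysisConfig:
    bin_width_s: float = 0.25
    kernel_s: float = 1.5
    baseline_window: tuple[float, float] = (-2.0, -1.0)
    post_window: tuple[float, float] = (0.0, 1.0)
    peri_window: tuple[float, float] = (-5.0, 5.0)
    cluster_n_iter: int = 5000
    population_n_iter: int = 5000
    bin_alpha: float = 0.05
    alpha: float = 0.05
    criterion_q: float = 0.10
    grubbs_alpha: float = 1e-4
    split_method: str = "quartile"
    lfp_bin_s: float = 2.0
    lfp_window: tuple[float, float] = (-8.0, 8.0)
    lfp_fs_hz: float = 1000.0
    band_edges: dict = field(default_factory=lambda: {
        "theta": (4.0, 12.0), "beta": (15.0, 30.0), "gamma": (30.0, 90.0)})

    def __post_init__(self) -> None:
        if self.bin_width_s <= 0 or self.kernel_s <= 0 or self.lfp_bin_s <= 0:
            raise ValueError("bin widths and kernels must be positive")
        for name in ("bin_alpha", "alpha", "criterion_q", "grubbs_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.cluster_n_iter < 100 or self.population_n_iter < 100:
            raise ValueError("iteration counts below 100 are unstable")
        for w in (self.baseline_window, self.post_window, self.peri_window,
                  self.lfp_window):
            if not w[0] < w[1]:
                raise ValueError(f"window {w} must be increasing")
        if self.split_method not in ("quartile", "median"):
            raise ValueError("split_method must be quartile or median")
        for name, (lo, hi) in self.band_edges.items():
            if not 0 < lo < hi:
                raise ValueError(f"band {name!r}: need 0 < low < high")
            if hi > self.lfp_fs_hz / 2:
                raise ValueError(f"band {name!r} exceeds the Nyquist frequency "
                                 f"({self.lfp_fs_hz / 2} Hz)")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    n_animals: int = 10
    n_units: int = 8
    n_lfp_channels: int = 4
    n_nodes: int = 51
    treatments: tuple[str, ...] = ("vehicle", "treatment")
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    def __post_init__(self) -> None:
        if self.n_animals < 2:
            raise ValueError("n_animals must be >= 2")
        if not self.treatments:
            raise ValueError("treatments must be nonempty")


def stage_seeds(seed: int) -> dict[str, np.random.SeedSequence]:
    """Derive one SeedSequence per pipeline stage from the global seed."""
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return dict(zip(STAGES, children))


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML file; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    analysis_raw = raw.pop("analysis", {})
    known_a = set(AnalysisConfig.__dataclass_fields__)
    known_r = set(RunConfig.__dataclass_fields__) - {"analysis"}
    bad = (set(analysis_raw) - known_a) | (set(raw) - known_r)
    if bad:
        raise ValueError(f"unknown config keys: {sorted(bad)}")
    for key in ("baseline_window", "post_window", "peri_window", "lfp_window"):
        if key in analysis_raw:
            analysis_raw[key] = tuple(analysis_raw[key])
    if "band_edges" in analysis_raw:
        analysis_raw["band_edges"] = {k: tuple(v) for k, v
                                      in analysis_raw["band_edges"].items()}
    if "treatments" in raw:
        raw["treatments"] = tuple(raw["treatments"])
    return RunConfig(analysis=AnalysisConfig(**analysis_raw), **raw)


def config_to_dict(cfg: RunConfig) -> dict:
    return asdict(cfg)
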