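"""Study configuration: every analysis constant in one serializable object.

The defaults are the study conditions of the full design (67 subjects
covering four Padua bins, 120 trials per coherence level, 64 channels,
4 chains x 1,000 warmup + 3,000 sampling iterations).  Reduced-scale runs
for tests and examples override the size fields explicitly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class StudyConfig:
    # cohort / behavior
    n_subjects: int = 67
    bin_targets: tuple = (19, 18, 15, 15)
    n_trials_per_condition: int = 120
    min_rt_s: float = 0.25
    max_rt_s: float = 10.0
    # spectral analysis
    bands: tuple = ("gamma", "beta")
    window_s: float = 0.25
    smoothing_hz: float = 8.0
    baseline_ms: tuple = (-200.0, 0.0)
    power_step_ms: float = 50.0
    slope_window_ms: tuple = (300.0, 800.0)
    # MCMC
    chains: int = 4
    warmup: int = 1000
    iters: int = 3000
    target_accept: float = 0.8
    # electrode weighting / aggregation
    n_channels: int = 64
    weight_draws_applied: int = 200   # posterior draws carried through weighting
    exclude_frontal: bool = False
    # seeds
    seed: int = 0

    def to_yaml(self, path):
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as f:
            raw = yaml.safe_load(f)
        for key in ("bin_targets", "bands", "baseline_ms", "slope_window_ms"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def small(self, **overrides) -> "StudyConfig":
        """Reduced-scale copy for quick runs; study constants unchanged."""
        base = asdict(self)
        base.update(dict(n_subjects=12, bin_targets=(3, 3, 3, 3),
                         n_trials_per_condition=40, chains=4,
                         warmup=300, iters=500, weight_draws_applied=100))
        base.update(overrides)
        for key in ("bin_targets", "bands", "baseline_ms", "slope_window_ms"):
            if isinstance(base[key], list):
                base[key] = tuple(base[key])
        return StudyConfig(**base)
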