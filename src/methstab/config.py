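"""Configuration of the synthetic-cohort generator.

The generator draws per-probe M-values from the same crossed random-effects
model the ICC engine fits:

    y_it = mu_p + beta1 * monocyte_it + beta2[batch_i] + omega_i + nu_t + eps_it

so every probe class has an analytic "true" ICC, and downstream stages can be
tested against a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import yaml

from .scenarios import TIMEPOINTS, TIMEPOINT_MINUTES


@dataclass(frozen=True)
class VarianceTriple:
    """Per-class variance components on the M-scale (subject, time, residual)."""

    sigma2_subject: float
    sigma2_time: float
    sigma2_resid: float

    def __post_init__(self):
        if min(self.sigma2_subject, self.sigma2_time, self.sigma2_resid) < 0:
            raise ValueError("variance components must be non-negative")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.sigma2_subject, self.sigma2_time, self.sigma2_resid)


# Class mix chosen so the cohort spans the stability range the arrays show:
# a stable minority, a broad middle, an unstable tail, and a small group of
# time-driven (circadian-like) probes whose variance sits in the occasion term.
DEFAULT_VARIANCE_SPEC: dict[str, VarianceTriple] = {
    "high": VarianceTriple(0.95, 0.01, 0.04),
    "medium": VarianceTriple(0.55, 0.07, 0.38),
    "low": VarianceTriple(0.20, 0.15, 0.65),
    "circadian": VarianceTriple(0.10, 0.50, 0.40),
}

DEFAULT_CLASS_MIX: dict[str, float] = {
    "high": 0.15,
    "medium": 0.45,
    "low": 0.30,
    "circadian": 0.10,
}


@dataclass(frozen=True)
class CovariateSpec:
    """Monocyte-proportion and batch (array) covariate effects.

    ``monocyte_beta`` is in M-units per unit proportion; monocyte proportions
    are drawn as subject baseline + diurnal drift + per-draw noise, clipped to
    a plausible PBMC range.  Batches model the two arrays, assigned per
    subject (each subject's 8 replicates share one slide, slides alternate
    between arrays).
    """

    monocyte_beta: float = 1.5
    batch_beta: float = 0.25
    n_batches: int = 2
    monocyte_mean: float = 0.20
    monocyte_between_sd: float = 0.05
    monocyte_within_sd: float = 0.03
    monocyte_diurnal: Mapping[str, float] = field(
        default_factory=lambda: {"T1": 0.0, "T2": 0.02, "T3": 0.03, "T4": 0.05}
    )


@dataclass(frozen=True)
class StressSpec:
    """Mean shifts applied only in the Stress session.

    ``shift_by_timepoint`` maps timepoint labels to M-unit shifts; the
    responsive probes are drawn from the high-stability TSS probes so that
    the highly-stable selection pipeline can find them.
    """

    n_responsive: int = 20
    shift_by_timepoint: Mapping[str, float] = field(
        default_factory=lambda: {"T4": -0.2}
    )


@dataclass(frozen=True)
class GroupSpec:
    """Early-life-adversity effect: residual-variance inflation under stress."""

    ela_resid_multiplier: float = 2.0


@dataclass(frozen=True)
class BaselineSpec:
    """Mixture of baseline M-values: unmethylated, methylated, intermediate."""

    means: tuple[float, ...] = (-3.0, 3.0, 0.0)
    sds: tuple[float, ...] = (1.0, 1.0, 1.5)
    weights: tuple[float, ...] = (0.45, 0.45, 0.10)


@dataclass(frozen=True)
class ExpressionSpec:
    """Coupling of TSS-probe methylation to gene expression counts.

    A fraction of TSS probes drive their gene's log2 abundance with slope
    ``coupling`` (negative: promoter methylation represses); remaining genes
    are expression-null.  Library sizes are log-normal around a 3'-tag-seq
    scale depth.
    """

    coupled_fraction: float = 0.30
    coupling: float = -0.8
    noise_sd: float = 0.5
    log_library_mean: float = float(np.log(5e6))
    log_library_sd: float = 0.2
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 1.5


@dataclass(frozen=True)
class DetectionSpec:
    """Detection p-value generation; planted whole-sample failures."""

    failed_sample_fraction: float = 0.0
    pass_scale: float = 0.02   # passing cells ~ U(0, pass_scale)
    fail_scale: float = 0.20   # failing samples ~ U(0, fail_scale), mean > 0.05


@dataclass(frozen=True)
class SimConfig:
    """Full description of one synthetic cohort."""

    n_subjects_per_group: int = 15
    groups: tuple[str, str] = ("control", "ELA")
    sessions: tuple[str, str] = ("NoStress", "Stress")
    timepoints: tuple[str, ...] = TIMEPOINTS
    n_probes: int = 2000
    variance_spec: Mapping[str, VarianceTriple] = field(
        default_factory=lambda: dict(DEFAULT_VARIANCE_SPEC)
    )
    probe_class_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX)
    )
    covariate_spec: CovariateSpec = field(default_factory=CovariateSpec)
    stress_spec: StressSpec = field(default_factory=StressSpec)
    group_spec: GroupSpec = field(default_factory=GroupSpec)
    baseline_mu: BaselineSpec = field(default_factory=BaselineSpec)
    expression_spec: ExpressionSpec = field(default_factory=ExpressionSpec)
    detection_spec: DetectionSpec = field(default_factory=DetectionSpec)
    sex_probe_fraction: float = 0.02
    mqtl_fraction: float = 0.10
    feature_class_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "TSS": 0.25,
            "5UTR": 0.10,
            "Body": 0.40,
            "3UTR": 0.10,
            "undefined": 0.15,
        }
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects_per_group <= 0:
            raise ValueError("n_subjects_per_group must be positive")
        if self.n_probes <= 0:
            raise ValueError("n_probes must be positive")
        unknown = set(self.probe_class_mix) - set(self.variance_spec)
        if unknown:
            raise ValueError(f"probe classes without variance spec: {sorted(unknown)}")
        total = sum(self.probe_class_mix.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"probe_class_mix must sum to 1, got {total}")
        minutes = [TIMEPOINT_MINUTES[t] for t in self.timepoints]
        if any(b <= a for a, b in zip(minutes, minutes[1:])):
            raise ValueError("timepoint minutes must be strictly increasing")

    @property
    def n_subjects(self) -> int:
        return self.n_subjects_per_group * len(self.groups)


def config_to_yaml(config: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def config_from_yaml(path) -> SimConfig:
    """Load a SimConfig from YAML; nested specs may be partial."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    nested = {
        "covariate_spec": CovariateSpec,
        "stress_spec": StressSpec,
        "group_spec": GroupSpec,
        "baseline_mu": BaselineSpec,
        "expression_spec": ExpressionSpec,
        "detection_spec": DetectionSpec,
    }
    kwargs = {}
    for key, value in raw.items():
        if key in nested and isinstance(value, dict):
            kwargs[key] = nested[key](**{
                k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
            })
        elif key == "variance_spec":
            kwargs[key] = {
                name: VarianceTriple(**trip) if isinstance(trip, dict) else VarianceTriple(*trip)
                for name, trip in value.items()
            }
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return SimConfig(**kwargs)
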