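"""Pipeline configuration: strict key/value document validation.

Every block is validated against its module's dataclass before any stage
runs; unknown keys are rejected outright so silent typos cannot alter an
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .elasticity import ElasticityModel
from .kinetics import KineticParameters

__all__ = ["PipelineConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Invalid or inconsistent pipeline configuration."""


_SIM_KEYS = {
    "hairpin_size", "noise_sd", "sample_rate", "force_schedule",
    "initial_open_bp", "drift_nm_per_s", "n_traces", "seed",
}
_DET_KEYS = {"min_dwell", "acceptance_threshold", "max_steps"}
_FIT_KEYS = {"n_bootstrap", "noise_cv"}
_TOP_KEYS = {"elasticity", "kinetic", "simulation", "detection", "fitting", "seed", "out_dir"}


def _check_keys(d: dict, allowed: set, ctx: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {ctx}: {sorted(unknown)}")


@dataclass
class PipelineConfig:
    kinetic: KineticParameters
    elasticity: ElasticityModel = field(default_factory=ElasticityModel)
    simulation: dict = field(default_factory=dict)
    detection: dict = field(default_factory=dict)
    fitting: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "."

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        if not isinstance(raw, dict):
            raise ConfigError("config document must be a mapping")
        _check_keys(raw, _TOP_KEYS, "config")
        if "kinetic" not in raw:
            raise ConfigError("config requires a 'kinetic' block")
        try:
            kinetic = KineticParameters.from_dict(raw["kinetic"])
            elasticity = ElasticityModel.from_dict(raw.get("elasticity", {}))
        except (ValueError, TypeError) as exc:
            raise ConfigError(str(exc)) from exc
        sim = dict(raw.get("simulation", {}))
        _check_keys(sim, _SIM_KEYS, "simulation")
        det = dict(raw.get("detection", {}))
        _check_keys(det, _DET_KEYS, "detection")
        fit = dict(raw.get("fitting", {}))
        _check_keys(fit, _FIT_KEYS, "fitting")
        hairpin = sim.get("hairpin_size", 488)
        if kinetic.footprint > hairpin:
            raise ConfigError(
                f"footprint ({kinetic.footprint} bp) exceeds hairpin size ({hairpin} bp)"
            )
        sched = sim.get("force_schedule")
        if sched is not None:
            try:
                sim["force_schedule"] = [(float(d), float(F)) for d, F in sched]
            except (TypeError, ValueError) as exc:
                raise ConfigError("force_schedule must be a list of [duration_s, force_pN]") from exc
        return cls(
            kinetic=kinetic, elasticity=elasticity, simulation=sim,
            detection=det, fitting=fit, seed=int(raw.get("seed", 0)),
            out_dir=str(raw.get("out_dir", ".")),
        )


def load_config(path) -> PipelineConfig:
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    return PipelineConfig.from_dict(raw or {})
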