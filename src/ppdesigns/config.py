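"""Run configuration: schema, validation, loading, packaged case-study files."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .bayes import BetaPrior, Thresholds
from .calibration import ThresholdGrid
from .designs import DesignConfig, Scenario

__all__ = ["ConfigError", "RunSpec", "load_config", "case_study_config"]

SCHEMA_VERSION = 1

#: Priors examined in the sensitivity analysis (first entry is the default).
SENSITIVITY_PRIORS = (
    (0.5, 0.5),
    (1.0, 1.0),
    (0.0, 0.0),
    (2.0, 2.0),
    (0.75, 0.25),
    (0.25, 0.75),
)


class ConfigError(ValueError):
    """A configuration file violates the schema."""


@dataclass
class RunSpec:
    """Validated run configuration (one design + scenarios + grid)."""

    design: str
    thresholds: Thresholds
    prior: BetaPrior
    scenarios: dict[str, Scenario]
    grid: ThresholdGrid
    arm_size: int = 50
    look_interval: int = 10
    stage2_per_arm: int = 50
    stage1_bound_percentile: float = 0.8
    n_sim: int = 1000
    seed: int = 0
    sensitivity_priors: tuple[tuple[float, float], ...] = field(
        default=SENSITIVITY_PRIORS
    )

    def design_config(self, n_sim: int | None = None) -> DesignConfig:
        return DesignConfig(
            kind=self.design,
            thresholds=self.thresholds,
            prior=self.prior,
            arm_size=self.arm_size,
            look_interval=self.look_interval,
            stage2_per_arm=self.stage2_per_arm,
            stage1_bound_percentile=self.stage1_bound_percentile,
            n_sim=self.n_sim if n_sim is None else n_sim,
        )


def _require(mapping: dict, key: str, where: str):
    try:
        return mapping[key]
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"missing key {key!r} in {where}") from exc


def _parse_prior(raw) -> BetaPrior:
    try:
        if isinstance(raw, dict):
            return BetaPrior(float(raw["a0"]), float(raw["b0"]))
        a0, b0 = raw
        return BetaPrior(float(a0), float(b0))
    except (ValueError, TypeError, KeyError) as exc:
        raise ConfigError(f"invalid prior specification {raw!r}") from exc


def _parse_scenario(raw, where: str) -> Scenario:
    try:
        return Scenario(
            _require(raw, "p_ctrl", where),
            _require(raw, "p_trt", where),
            raw.get("prevalence", (1 / 3, 1 / 3, 1 / 3)),
        )
    except ValueError as exc:
        raise ConfigError(f"invalid scenario in {where}: {exc}") from exc


def parse_config(raw: dict, source: str = "<config>") -> RunSpec:
    if not isinstance(raw, dict):
        raise ConfigError(f"{source}: top level must be a mapping")
    version = raw.get("schema", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise ConfigError(f"{source}: unsupported schema version {version}")
    design = _require(raw, "design", source)
    if design not in ("pooled", "stratified", "enrichment"):
        raise ConfigError(f"{source}: unknown design {design!r}")
    thr = _require(raw, "thresholds", source)
    try:
        thresholds = Thresholds(
            float(_require(thr, "theta", "thresholds")),
            float(_require(thr, "theta_star", "thresholds")),
        )
    except ValueError as exc:
        raise ConfigError(f"{source}: {exc}") from exc
    scen_raw = _require(raw, "scenarios", source)
    scenarios = {
        name: _parse_scenario(s, f"scenarios.{name}") for name, s in scen_raw.items()
    }
    if "null" not in scenarios:
        raise ConfigError(f"{source}: scenarios must include 'null'")
    grid_raw = raw.get("grid", {})
    try:
        grid = ThresholdGrid(
            tuple(grid_raw.get("theta", ThresholdGrid().posterior_thresholds)),
            tuple(grid_raw.get("theta_star", ThresholdGrid().predictive_thresholds)),
        )
    except ValueError as exc:
        raise ConfigError(f"{source}: invalid grid: {exc}") from exc
    sens = tuple(
        tuple(map(float, p)) for p in raw.get("sensitivity_priors", SENSITIVITY_PRIORS)
    )
    try:
        spec = RunSpec(
            design=design,
            thresholds=thresholds,
            prior=_parse_prior(raw.get("prior", (0.5, 0.5))),
            scenarios=scenarios,
            grid=grid,
            arm_size=int(raw.get("arm_size", 50)),
            look_interval=int(raw.get("look_interval", 10)),
            stage2_per_arm=int(raw.get("stage2_per_arm", 50)),
            stage1_bound_percentile=float(raw.get("stage1_bound_percentile", 0.8)),
            n_sim=int(raw.get("n_sim", 1000)),
            seed=int(raw.get("seed", 0)),
            sensitivity_priors=sens,
        )
        spec.design_config()  # validates size/interval consistency
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"{source}: {exc}") from exc
    return spec


def load_config(path: str | Path) -> RunSpec:
    """Load and validate a YAML or JSON configuration file."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    return parse_config(raw, source=str(path))


def case_study_config(design: str) -> RunSpec:
    """Packaged configuration of the urothelial-carcinoma case study."""
    name = f"case_study_{design}.yaml"
    try:
        text = resources.files("ppdesigns.configs").joinpath(name).read_text()
    except FileNotFoundError as exc:
        raise ConfigError(f"no packaged config for design {design!r}") from exc
    return parse_config(yaml.safe_load(text), source=name)
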