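"""Simulation configuration for synthetic visuomotor-rotation cohorts.

A :class:`SimulationConfig` describes one experimental group: the rotation it
adapts to, whether it was instructed about the perturbation, the parameters of
the internal learning model, the localization shifts injected into the rotated
session, and the noise structure. Identical configs with identical seeds
produce bit-identical cohorts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import yaml

VALID_ROTATIONS = (30.0, 60.0)

#: Hand-localization probe centres (degrees, polar) used by the tasks.
LOCALIZATION_CENTERS = (50.0, 90.0, 130.0)

#: Reach targets (degrees), 12 cm from the start position.
REACH_TARGETS = (45.0, 90.0, 135.0)

TARGET_DISTANCE_CM = 12.0


class ConfigError(ValueError):
    """Raised when a configuration fails validation."""


@dataclass
class SimulationConfig:
    """Parameters for one simulated group.

    Angles are in degrees, counter-clockwise positive. The cursor rotation is
    applied clockwise (negative direction); compensation is therefore positive
    and the injected localization shifts are applied in the negative (CW)
    direction.

    Parameters
    ----------
    rotation_deg : float
        Magnitude of the clockwise cursor rotation; 30 or 60.
    instructed : bool
        Whether the group received instructions about the perturbation.
    n_participants : int
        Participants in the group.
    retention_A, learn_rate_B : float
        Retention factor and error-driven learning rate of the single
        implicit state, both in [0, 1].
    strategy_frac : float
        Fraction of the rotation adopted as an explicit re-aiming strategy by
        aware participants.
    afferent_shift_deg : float
        Magnitude of the proprioceptive recalibration injected into rotated-
        session localization taps (applied CW, i.e. subtracted).
    efferent_shift_deg : float
        Additional shift on active (self-generated) localization only.
    motor_noise_sd_deg, tap_noise_sd_deg : float
        Trial-to-trial angular noise on reach direction and localization taps.
    reach_bias_sd_deg, loc_bias_sd_deg : float
        SDs of idiosyncratic per-target reach biases and of the scalar
        localization bias drawn once per participant.
    loc_spread_deg : float
        Half-width of the uniform spread of chosen hand angles around each
        localization centre.
    reach_duration_s, sample_rate_hz : float
        Duration and sampling rate of materialized reach trajectories.
    aware : bool or None
        Override for awareness. ``None`` applies the default rule: instructed
        groups and the non-instructed 60 deg group are aware.
    seed : int
        Base seed for this group's random streams.
    """

    rotation_deg: float = 30.0
    instructed: bool = False
    n_participants: int = 20
    retention_A: float = 0.98
    learn_rate_B: float = 0.13
    strategy_frac: float = 0.4
    afferent_shift_deg: float = 5.6
    efferent_shift_deg: float = 2.2
    motor_noise_sd_deg: float = 3.5
    tap_noise_sd_deg: float = 6.0
    reach_bias_sd_deg: float = 2.0
    loc_bias_sd_deg: float = 3.0
    loc_spread_deg: float = 20.0
    reach_duration_s: float = 0.6
    sample_rate_hz: float = 100.0
    aware: Optional[bool] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if float(self.rotation_deg) not in VALID_ROTATIONS:
            raise ConfigError(
                f"rotation_deg must be one of {VALID_ROTATIONS}, got {self.rotation_deg!r}"
            )
        for name in ("retention_A", "learn_rate_B", "strategy_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v!r}")
        for name in (
            "motor_noise_sd_deg",
            "tap_noise_sd_deg",
            "reach_bias_sd_deg",
            "loc_bias_sd_deg",
            "loc_spread_deg",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.reach_duration_s <= 0 or self.sample_rate_hz <= 0:
            raise ConfigError("reach_duration_s and sample_rate_hz must be positive")
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")

    @property
    def is_aware(self) -> bool:
        """Whether this group carries an explicit strategy.

        Instructed groups are aware by instruction; the non-instructed 60 deg
        group becomes aware through the salience of the large rotation; the
        non-instructed 30 deg group does not.
        """
        if self.aware is not None:
            return bool(self.aware)
        return bool(self.instructed) or float(self.rotation_deg) >= 60.0

    @property
    def explicit_deg(self) -> float:
        """Explicit strategy magnitude switched on at rotation onset (deg, CCW)."""
        return self.strategy_frac * self.rotation_deg if self.is_aware else 0.0

    @property
    def group(self) -> str:
        prefix = "instr" if self.instructed else "noninstr"
        return f"{prefix}{int(self.rotation_deg)}"

    def zero_noise(self) -> "SimulationConfig":
        """Copy of this config with every stochastic component switched off."""
        return dataclasses.replace(
            self,
            motor_noise_sd_deg=0.0,
            tap_noise_sd_deg=0.0,
            reach_bias_sd_deg=0.0,
            loc_bias_sd_deg=0.0,
        )

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def default_study_configs(seed: int = 0, n_per_group: int = 20, **overrides) -> list[SimulationConfig]:
    """The four-group study design: {non-instructed, instructed} x {30, 60} deg CW.

    ``overrides`` apply to every group (e.g. ``motor_noise_sd_deg=0``).
    """
    configs = []
    for i, (rot, instructed) in enumerate(
        [(30.0, False), (30.0, True), (60.0, False), (60.0, True)]
    ):
        configs.append(
            SimulationConfig(
                rotation_deg=rot,
                instructed=instructed,
                n_participants=n_per_group,
                seed=int(seed),
                **overrides,
            )
        )
    return configs


# ---------------------------------------------------------------------------
# Pipeline configuration files
# ---------------------------------------------------------------------------

_GROUP_REQUIRED = ("rotation_deg", "instructed")

DEFAULT_ANALYSIS = {
    "kernel_sd_deg": 10.0,
    "centers": list(LOCALIZATION_CENTERS),
    "pool_blocks": True,
}


def default_pipeline_config() -> dict:
    """Default structured pipeline config (YAML-serializable)."""
    return {
        "seed": 0,
        "n_per_group": 20,
        "trajectories": False,
        "groups": [
            {"rotation_deg": 30, "instructed": False},
            {"rotation_deg": 30, "instructed": True},
            {"rotation_deg": 60, "instructed": False},
            {"rotation_deg": 60, "instructed": True},
        ],
        "simulation": {},
        "analysis": dict(DEFAULT_ANALYSIS),
    }


def validate_pipeline_config(cfg: dict) -> dict:
    """Validate a pipeline config dict; return a normalized copy.

    Raises :class:`ConfigError` naming the offending field.
    """
    if not isinstance(cfg, dict):
        raise ConfigError("pipeline config must be a mapping")
    out = dict(default_pipeline_config())
    unknown = set(cfg) - set(out)
    if unknown:
        raise ConfigError(f"unknown config fields: {sorted(unknown)}")
    out.update({k: v for k, v in cfg.items() if k not in ("analysis", "simulation")})
    out["analysis"] = {**DEFAULT_ANALYSIS, **cfg.get("analysis", {})}
    out["simulation"] = dict(cfg.get("simulation", {}))
    groups = cfg.get("groups", out["groups"])
    if not isinstance(groups, list) or not groups:
        raise ConfigError("groups: must be a non-empty list")
    for i, g in enumerate(groups):
        for req in _GROUP_REQUIRED:
            if req not in g:
                raise ConfigError(f"groups[{i}]: missing required field '{req}'")
    out["groups"] = groups
    return out


def pipeline_configs(cfg: dict, seed: int | None = None) -> list[SimulationConfig]:
    """Expand a validated pipeline config into per-group SimulationConfigs."""
    cfg = validate_pipeline_config(cfg)
    base_seed = int(cfg["seed"] if seed is None else seed)
    out = []
    for g in cfg["groups"]:
        params = {**cfg["simulation"], **g}
        params.setdefault("n_participants", cfg["n_per_group"])
        out.append(SimulationConfig(seed=base_seed, **params))
    return out


def load_pipeline_config(path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return validate_pipeline_config(raw or {})


def save_pipeline_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
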