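"""Run configuration: one human-editable YAML file drives the whole study.

The packaged ``data/default_config.yaml`` holds the published defaults;
:func:`load_run_config` deep-merges a user file (and programmatic overrides)
over those defaults and materialises the typed parameter objects the other
modules consume.  All randomness flows from the single top-level ``seed``.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Mapping, Optional

import yaml

from .costs import UnitCosts, UnitFootprints
from .profiles import SeverityProfileSpec
from .training import DeliveryRateModel, VariabilitySchedule

__all__ = ["RunConfig", "ConfigError", "load_run_config", "default_config_dict"]


class ConfigError(ValueError):
    """Raised for missing or invalid configuration fields."""


def default_config_dict() -> dict:
    """The packaged default configuration as a plain nested dict."""
    text = resources.files("inhalersim.data").joinpath("default_config.yaml").read_text()
    return yaml.safe_load(text)


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def _require(mapping: Mapping, path: str) -> Any:
    node: Any = mapping
    for part in path.split("."):
        if not isinstance(node, Mapping) or part not in node or node[part] is None:
            raise ConfigError(f"missing required config field '{path}'")
        node = node[part]
    return node


@dataclass(frozen=True)
class RunConfig:
    """Fully validated study configuration."""

    seed: int
    output_dir: str
    n_patients: float
    projection_years: tuple
    use_published_gains: bool
    learned_fractions: Optional[Mapping[str, float]]  # None -> take from simulator
    n_runs: int
    training_years: Mapping[str, tuple]
    four_year_lead_in: int
    schedule: VariabilitySchedule
    delivery: Mapping[str, DeliveryRateModel]
    profiles: Mapping[str, SeverityProfileSpec]
    costs: UnitCosts
    footprints: UnitFootprints
    raw: dict = field(repr=False, default_factory=dict)

    @property
    def config_hash(self) -> str:
        """SHA-256 of the canonical raw configuration (manifest provenance)."""
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def load_run_config(path: Optional[str] = None, overrides: Optional[Mapping] = None) -> RunConfig:
    """Load, merge and validate the run configuration.

    ``path`` points to a user YAML file layered over the packaged defaults;
    ``overrides`` is a nested dict layered on top of both (CLI flags use it).
    Missing or null required fields raise :class:`ConfigError` naming the
    field.
    """
    raw = default_config_dict()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"config file {path!r} must contain a YAML mapping")
        raw = _deep_merge(raw, user)
    if overrides:
        raw = _deep_merge(raw, overrides)

    schedule = VariabilitySchedule(
        pre_pif_cv_initial=_require(raw, "simulator.schedule.pre_pif_cv_initial"),
        pre_pif_cv_floor=_require(raw, "simulator.schedule.pre_pif_cv_floor"),
        post_pif_cv_initial=_require(raw, "simulator.schedule.post_pif_cv_initial"),
        post_pif_cv_floor=_require(raw, "simulator.schedule.post_pif_cv_floor"),
        decay_factor=_require(raw, "simulator.schedule.decay_factor"),
    )
    delivery = {
        sev: DeliveryRateModel(
            baseline_mean=_require(raw, f"simulator.delivery.{sev}.baseline_mean"),
            max_final_gain=_require(raw, f"simulator.delivery.{sev}.max_final_gain"),
            annual_increment_sd=_require(raw, f"simulator.delivery.{sev}.annual_increment_sd"),
        )
        for sev in ("moderate", "severe")
    }
    profiles = {
        sev: SeverityProfileSpec(
            severity=sev,
            pif=_require(raw, f"simulator.profiles.{sev}.pif"),
            time_to_pif=_require(raw, f"simulator.profiles.{sev}.time_to_pif"),
            total_duration=_require(raw, f"simulator.profiles.{sev}.total_duration"),
            rise_shape=_require(raw, f"simulator.profiles.{sev}.rise_shape"),
            decay_shape=_require(raw, f"simulator.profiles.{sev}.decay_shape"),
            n_points=int(_require(raw, f"simulator.profiles.{sev}.n_points")),
        )
        for sev in ("moderate", "severe")
    }
    costs = UnitCosts(
        cartridge_eur=_require(raw, "costs.cartridge_eur"),
        case_eur=_require(raw, "costs.case_eur"),
        module_eur=dict(_require(raw, "costs.module_eur")),
    )
    footprints = UnitFootprints(
        cartridge_kg=_require(raw, "footprints.cartridge_kg"),
        case_kg=_require(raw, "footprints.case_kg"),
        module_kg=dict(_require(raw, "footprints.module_kg")),
        scc_eur_per_tonne=_require(raw, "footprints.scc_eur_per_tonne"),
    )
    fractions = raw.get("projection", {}).get("learned_fractions")
    if fractions is not None:
        fractions = {k: float(v) for k, v in fractions.items()}
        for key in ("five_year", "four_year"):
            if key not in fractions:
                raise ConfigError(f"missing required config field 'projection.learned_fractions.{key}'")

    return RunConfig(
        seed=int(_require(raw, "seed")),
        output_dir=str(_require(raw, "output_dir")),
        n_patients=float(_require(raw, "cohort.n_patients")),
        projection_years=tuple(int(y) for y in _require(raw, "projection.years")),
        use_published_gains=bool(_require(raw, "projection.use_published_gains")),
        learned_fractions=fractions,
        n_runs=int(_require(raw, "simulator.n_runs")),
        training_years={
            key: tuple(int(y) for y in _require(raw, f"simulator.training_years.{key}"))
            for key in ("five_year", "four_year")
        },
        four_year_lead_in=int(_require(raw, "simulator.four_year_lead_in")),
        schedule=schedule,
        delivery=delivery,
        profiles=profiles,
        costs=costs,
        footprints=footprints,
        raw=raw,
    )
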