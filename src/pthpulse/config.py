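"""Configuration loading: units, kinetic/activity/PK parameters, scenarios.

A single YAML file with explicit unit tags defines the whole model setup.
The packaged default (``data/defaults.yaml``) carries the calibrated
parameter set; any field can be overridden by pointing the loader at a user
file of the same structure.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .activity import ActivityCoefficients, DEFAULT_TAU_A_CRITERION
from .kinetics import KineticParameters
from .stimulus import PKParameters

__all__ = ["ModelConfig", "load_config", "default_config_path"]


@dataclass(frozen=True)
class ModelConfig:
    """Fully resolved model configuration."""

    params: KineticParameters
    coeffs: ActivityCoefficients
    pk: PKParameters
    tau_a_criterion: float
    window_s: float
    target_tolerance: float
    reference_daily_dose_ug: float
    raw: dict = None  # parsed YAML, for provenance and the scenario section
    config_hash: str = ""

    @property
    def scenarios_raw(self) -> dict:
        return self.raw.get("scenarios", {})


def default_config_path() -> Path:
    return Path(resources.files("pthpulse").joinpath("data/defaults.yaml"))


def _check_units(doc: dict) -> None:
    units = doc.get("units", {})
    expected = {"concentration": "pmol/L", "time": "min", "dose": "ug"}
    for key, val in expected.items():
        got = units.get(key)
        if got is not None and got != val:
            raise ValueError(
                f"unsupported unit {got!r} for {key}; this configuration layer "
                f"works in {val} (convert at the boundary)"
            )


def load_config(path: str | Path | None = None) -> ModelConfig:
    """Parse a YAML configuration file (packaged defaults when ``path`` is None)."""
    path = Path(path) if path is not None else default_config_path()
    text = path.read_text()
    doc = yaml.safe_load(text)
    _check_units(doc)

    kin = doc["kinetics"]
    params = KineticParameters.from_dissociation_constants(
        k1=kin["k1"],
        k_minus1=kin["k_minus1"],
        k2=kin["k2"],
        k_minus2=kin["k_minus2"],
        Kr_nM=kin["Kr_nM"],
        Kd_nM=kin["Kd_nM"],
        k_minusr=kin["k_minusr"],
        k_minusd=kin["k_minusd"],
        detailed_balance=bool(kin.get("detailed_balance", True)),
    )

    act = doc["activity"]
    coeffs = ActivityCoefficients.exact_adaptation(
        act["a1"], act["a3"], act["a4"], params, scale=act.get("scale", 1.0)
    )

    pk_doc = doc.get("pk", {})
    pk = PKParameters(
        k_a=pk_doc["k_a"],
        k_e=pk_doc["k_e"],
        V_d=pk_doc["V_d"],
        F=pk_doc["F"],
        molar_mass=pk_doc.get("molar_mass_g_per_mol", 4117.8),
    )

    opt = doc.get("optimisation", {})
    return ModelConfig(
        params=params,
        coeffs=coeffs,
        pk=pk,
        tau_a_criterion=act.get("tau_a_criterion", DEFAULT_TAU_A_CRITERION),
        window_s=opt.get("window_s_min", 1440.0),
        target_tolerance=opt.get("target_tolerance", 0.01),
        reference_daily_dose_ug=pk_doc.get("reference_daily_dose_ug", 20.0),
        raw=doc,
        config_hash=hashlib.sha256(text.encode()).hexdigest()[:16],
    )
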