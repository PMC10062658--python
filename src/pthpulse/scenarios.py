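"""Scenario registry, fixture generation and table reproduction.

Each scenario is a named glandular secretion pattern: a square-wave stimulus
plus its pulsatile AUC fraction ``r`` and a provenance note pointing at the
clinical literature the state is based on.  The registry ships with a healthy
reference, a reduced-tonic variant derived from it, three osteoporosis
states (idiopathic, postmenopausal, glucocorticoid-induced), primary
hyperparathyroidism and calcium-clamp states (initial and steady-state
hypocalcemia, hypercalcemia).
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .activity import cellular_responsiveness
from .config import ModelConfig, load_config
from .errors import InfeasibilityError
from .kinetics import KineticParameters
from .optimise import (
    maximise_glandular,
    maximise_injection,
    target_glandular,
    target_injection_dose,
)
from .stimulus import (
    CombinedStimulus,
    SquareWaveStimulus,
    auc_decomposition,
    injection_square_wave,
    pk_auc,
    responsiveness_model1,
    responsiveness_model2,
)

__all__ = [
    "Scenario",
    "RunManifest",
    "load_scenarios",
    "generate_test_stimulus",
    "reproduce_table",
    "PHYSIOLOGICAL_RANGES",
]

#: sampling ranges for randomly generated test stimuli
PHYSIOLOGICAL_RANGES = {
    "gamma0": (1.0, 10.0),  # tonic level, pmol/L
    "amplitude_ratio": (1.0, 10.0),  # gamma1 / gamma0
    "tau1": (1.0, 30.0),  # on-phase, min
    "T": (None, 120.0),  # period, min; lower bound is tau1 + 1
}


@dataclass(frozen=True)
class Scenario:
    """A named glandular secretion state."""

    name: str
    stimulus: SquareWaveStimulus
    r: float  # pulsatile fraction of total AUC
    provenance: str

    def __post_init__(self) -> None:
        if not self.provenance:
            raise ValueError(f"scenario {self.name!r} must carry a provenance note")
        r_wave = auc_decomposition(self.stimulus, self.stimulus.T).r
        if abs(r_wave - self.r) > 1e-3:
            raise ValueError(
                f"scenario {self.name!r}: declared pulsatile fraction {self.r:.5f} "
                f"does not match the waveform ({r_wave:.5f})"
            )


def load_scenarios(path: str | Path | None = None) -> dict[str, Scenario]:
    """Validated scenario registry from a configuration file.

    Derived entries (``derive_from``) are produced from their parent; the
    reduced-tonic variant scales the tonic level while preserving the pulse
    amplitude, so the pulsatile AUC is unchanged and the fraction ``r`` is
    recomputed.
    """
    config = load_config(path)
    raw = config.scenarios_raw
    registry: dict[str, Scenario] = {}
    derived: list[tuple[str, dict]] = []
    for name, entry in raw.items():
        if name in registry:
            raise ValueError(f"duplicate scenario name {name!r}")
        if "derive_from" in entry:
            derived.append((name, entry))
            continue
        missing = [k for k in ("gamma0", "gamma1", "tau1", "T", "r", "provenance") if k not in entry]
        if missing:
            raise ValueError(f"scenario {name!r} is missing fields {missing}")
        stim = SquareWaveStimulus(entry["gamma0"], entry["gamma1"], entry["tau1"], entry["T"])
        registry[name] = Scenario(name, stim, entry["r"], entry["provenance"])
    for name, entry in derived:
        if name in registry:
            raise ValueError(f"duplicate scenario name {name!r}")
        parent = registry[entry["derive_from"]]
        scale = float(entry["tonic_scale"])
        shift = (1.0 - scale) * parent.stimulus.gamma0
        stim = replace(
            parent.stimulus,
            gamma0=parent.stimulus.gamma0 - shift,
            gamma1=parent.stimulus.gamma1 - shift,
        )
        registry[name] = Scenario(
            name, stim, auc_decomposition(stim, stim.T).r, entry["provenance"]
        )
    return registry


def generate_test_stimulus(
    rng: np.random.Generator | int,
    ranges: dict | None = None,
) -> SquareWaveStimulus:
    """Random physiologically plausible square wave for property tests.

    Deterministic for a fixed seed/generator state.  The period is drawn
    above ``tau1 + 1`` so every output satisfies the stimulus invariants.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    rr = dict(PHYSIOLOGICAL_RANGES)
    if ranges:
        rr.update(ranges)
    for key, (lo, hi) in rr.items():
        if lo is not None and not lo < hi:
            raise ValueError(f"empty range for {key}: {(lo, hi)}")
    gamma0 = rng.uniform(*rr["gamma0"])
    gamma1 = gamma0 * rng.uniform(*rr["amplitude_ratio"])
    tau1 = rng.uniform(*rr["tau1"])
    t_lo = rr["T"][0] if rr["T"][0] is not None else tau1 + 1.0
    t_lo = max(t_lo, tau1 + 1.0)
    T = rng.uniform(t_lo, max(rr["T"][1], t_lo + 1.0))
    return SquareWaveStimulus(gamma0=gamma0, gamma1=gamma1, tau1=tau1, T=T)


@dataclass(frozen=True)
class RunManifest:
    """Provenance record attached to every generated output."""

    config_hash: str
    software_version: str
    tau_a_criterion: float
    off_rates: tuple[float, float]
    parameters: dict
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(datetime.timezone.utc).isoformat()
    )

    @classmethod
    def from_config(cls, config: ModelConfig) -> "RunManifest":
        from . import __version__

        return cls(
            config_hash=config.config_hash,
            software_version=__version__,
            tau_a_criterion=config.tau_a_criterion,
            off_rates=(config.params.k_minusr, config.params.k_minusd),
            parameters=dataclasses.asdict(config.params),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @property
    def reference(self) -> str:
        """Short deterministic tag embedded in data outputs."""
        return f"pthpulse-{self.software_version}-config-{self.config_hash}"


def _table3(
    registry: dict[str, Scenario],
    config: ModelConfig,
    scenario_names: list[str],
) -> pd.DataFrame:
    """Baseline, maximised and healthy-targeted responsiveness per scenario."""
    params, coeffs = config.params, config.coeffs
    crit = config.tau_a_criterion
    target = cellular_responsiveness(
        registry["healthy"].stimulus, params, coeffs, crit
    ).alpha_R
    rows = {}
    for name in scenario_names:
        sc = registry[name]
        base = cellular_responsiveness(sc.stimulus, params, coeffs, crit).alpha_R
        mx = maximise_glandular(
            sc.stimulus, params, coeffs, r=sc.r, s=config.window_s, tau_a_criterion=crit
        )
        tg = target_glandular(
            sc.stimulus,
            target,
            params,
            coeffs,
            r=sc.r,
            s=config.window_s,
            tau_a_criterion=crit,
            tolerance=config.target_tolerance,
        )
        rows[name] = {
            "alpha_R": base,
            "alpha_R_max": mx.alpha_R,
            "tau1_max_min": mx.design["tau1"],
            "T_max_min": mx.design["T"],
            "gamma1_max_pmol_per_L": mx.design["gamma1"],
            "tau1_star_min": tg.design["tau1"] if tg.feasible else np.nan,
            "T_star_min": tg.design["T"] if tg.feasible else np.nan,
            "gamma1_star_pmol_per_L": tg.design["gamma1"] if tg.feasible else np.nan,
        }
    return pd.DataFrame(rows)


def _table2(
    registry: dict[str, Scenario],
    config: ModelConfig,
    scenario_names: list[str],
    doses: tuple[float, ...] = (0.0, 10.0, 20.0, 30.0),
) -> pd.DataFrame:
    """Model-1 vs model-2 responsiveness for daily injections on baseline states."""
    params, coeffs, pk = config.params, config.coeffs, config.pk
    crit = config.tau_a_criterion
    records = []
    for name in scenario_names:
        sc = registry[name]
        for dose in doses:
            inj = (
                injection_square_wave(dose, pk, sc.stimulus.gamma0, T_inj=1440.0)
                if dose > 0
                else None
            )
            m2 = responsiveness_model2(sc.stimulus, inj, params, coeffs, crit)
            m1 = responsiveness_model1(
                CombinedStimulus(sc.stimulus, inj), params, coeffs, crit
            )
            records.append(
                {
                    "scenario": name,
                    "dose_ug": dose,
                    "alpha_R_model1": m1.alpha_R_total,
                    "alpha_R_model2": m2.alpha_R_total,
                    "alpha_R_injection": m2.alpha_R_injection,
                }
            )
    return pd.DataFrame.from_records(records)


def _table4(
    registry: dict[str, Scenario],
    config: ModelConfig,
    daily_doses: tuple[float, ...] = (10.0, 20.0, 30.0),
) -> pd.DataFrame:
    """Optimal injection regimens at fixed daily drug exposure, plus the
    dose normalising an osteoporotic deficit at the once-daily period."""
    params, coeffs, pk = config.params, config.coeffs, config.pk
    crit = config.tau_a_criterion
    gamma0 = registry["OP"].stimulus.gamma0
    records = {}
    for dose in daily_doses:
        mx = maximise_injection(
            pk_auc(dose, pk), gamma0, pk, params, coeffs, s=config.window_s, tau_a_criterion=crit
        )
        records[f"{dose:g}ug_daily"] = {
            "alpha_R_max": mx.alpha_R,
            "dose_per_injection_ug": mx.design["dose_ug"],
            "tau1_min": mx.design["tau1"],
            "T_min": mx.design["T"],
            "gamma1_pmol_per_L": mx.design["gamma1"],
        }
    ref = cellular_responsiveness(registry["healthy"].stimulus, params, coeffs, crit).alpha_R
    ill = cellular_responsiveness(registry["OP"].stimulus, params, coeffs, crit).alpha_R
    tg = target_injection_dose(
        ref, ill, gamma0, pk, params, coeffs, T_inj=1440.0, tau_a_criterion=crit,
        tolerance=config.target_tolerance,
    )
    records["normalising_dose"] = {
        "alpha_R_max": tg.alpha_R,
        "dose_per_injection_ug": tg.design["dose_ug"],
        "tau1_min": tg.design["tau1"] if tg.stimulus else np.nan,
        "T_min": tg.design["T"],
        "gamma1_pmol_per_L": tg.design["gamma1"] if tg.stimulus else np.nan,
    }
    return pd.DataFrame(records)


def reproduce_table(
    table_id: str,
    registry: dict[str, Scenario] | None = None,
    config: ModelConfig | None = None,
    scenario_names: list[str] | None = None,
) -> tuple[pd.DataFrame, RunManifest]:
    """Recompute one of the summary tables from the model.

    ``table_id`` is one of ``table2`` (superposition-model comparison),
    ``table3`` (glandular baselines and pattern optimisation) or ``table4``
    (injection-regimen optimisation).  Returns the table plus the manifest
    describing the configuration that produced it.
    """
    config = config or load_config()
    registry = registry or load_scenarios()
    manifest = RunManifest.from_config(config)
    if table_id == "table3":
        names = scenario_names or list(registry)
        df = _table3(registry, config, names)
    elif table_id == "table2":
        names = scenario_names or ["healthy", "OP", "HP"]
        df = _table2(registry, config, names)
    elif table_id == "table4":
        df = _table4(registry, config)
    else:
        raise ValueError(f"unknown table id {table_id!r}; expected table2, table3 or table4")
    df.attrs["manifest"] = manifest.reference
    return df, manifest


def write_table_csv(df: pd.DataFrame, path: str | Path, manifest: RunManifest) -> None:
    """CSV output with the manifest reference embedded as a comment header."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# manifest: {manifest.reference}\n")
        df.to_csv(fh, float_format="%.12g")
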