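"""Pipeline configuration schema.

All user-facing numbers are in the units of the acquisition protocols
(milliseconds, millivolts, degrees); conversion to SI happens when the
configuration is turned into library objects.  Every pipeline run writes
its fully resolved configuration next to its outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, ValidationError

from .errors import ConfigError
from .synthetic import (DEFAULT_CONTROL_EFFECTS,
                        DEFAULT_MODULATION_EFFECTS, StudyDesign,
                        ir_mese_sequence, sese_sequence)
from .twopool import InversionState, TwoPoolParams, simulate_inversion_pulse

SCHEMA_ID = "memri-config-v1"


class TwoPoolConfig(BaseModel):
    r1_hz: float = 0.5              # assumed R1,f = R1,m
    t2m_us: float = 10.0            # macromolecular T2
    t2f_ms: float = 60.0
    pulse_ms: float = 1.0           # hard inversion pulse duration
    inversion_flip_deg: float = 180.0
    delta_f: float = -1.0           # free pool taken as fully inverted
    delta_m: float | None = None    # None -> Bloch-simulated


class SequenceConfig(BaseModel):
    sese_n_te: int = 50
    sese_te_min_ms: float = 9.5
    sese_te_max_ms: float = 290.5
    ir_n_ti: int = 25
    ir_ti_min_ms: float = 4.0
    ir_ti_max_ms: float = 10079.4
    ir_echo_spacing_ms: float = 9.5
    ir_echoes_per_ti: int = 16


class DictionaryConfig(BaseModel):
    t2_min_ms: float = 5.0
    t2_max_ms: float = 300.0
    t2_step_ms: float = 0.5
    t1_s: float = 1.8               # nominal T1; MESE is weakly T1-sensitive
    n_slice_positions: int = 64
    refocus_deg: float = 180.0


class StudyConfig(BaseModel):
    n_batches: int = 15
    batch_sd_frac: float = 0.03
    noise_sd_frac: float = 0.02
    kmf_noise_sd_frac: float = 0.14
    signal_noise_frac: float = 0.005
    fit_from_signals: bool = False


class InVivoConfig(BaseModel):
    n_modulation: int = 7
    n_control: int = 5
    n_recovery: int = 2
    rat_sd_ms: float = 0.3
    noise_sd_ms: float = 0.2
    modulation_effects_ms: tuple[float, float, float, float] = \
        DEFAULT_MODULATION_EFFECTS
    control_effects_ms: tuple[float, float, float, float] = \
        DEFAULT_CONTROL_EFFECTS


class PipelineConfig(BaseModel):
    schema_id: str = SCHEMA_ID
    seed: int = 20250703
    twopool: TwoPoolConfig = Field(default_factory=TwoPoolConfig)
    sequences: SequenceConfig = Field(default_factory=SequenceConfig)
    dictionary: DictionaryConfig = Field(default_factory=DictionaryConfig)
    study: StudyConfig = Field(default_factory=StudyConfig)
    invivo: InVivoConfig = Field(default_factory=InVivoConfig)

    # -- converters ---------------------------------------------------
    def twopool_params(self, psr: float = 0.0377,
                       kmf: float = 14.8) -> TwoPoolParams:
        tp = self.twopool
        return TwoPoolParams(r1f=tp.r1_hz, r1m=tp.r1_hz, kmf=kmf, psr=psr,
                             t2f=tp.t2f_ms / 1e3, t2m=tp.t2m_us / 1e6)

    def inversion_state(self) -> InversionState:
        """delta_f as configured; delta_m Bloch-simulated unless fixed."""
        tp = self.twopool
        if tp.delta_m is not None:
            return InversionState(delta_f=tp.delta_f, delta_m=tp.delta_m)
        sim = simulate_inversion_pulse(self.twopool_params(),
                                       tp.pulse_ms / 1e3,
                                       tp.inversion_flip_deg)
        return InversionState(delta_f=tp.delta_f, delta_m=sim.delta_m)

    def sese_sequence(self):
        s = self.sequences
        return sese_sequence(s.sese_n_te, s.sese_te_min_ms,
                             s.sese_te_max_ms)

    def ir_sequence(self):
        s = self.sequences
        return ir_mese_sequence(s.ir_n_ti, s.ir_ti_min_ms, s.ir_ti_max_ms,
                                s.ir_echo_spacing_ms, s.ir_echoes_per_ti)

    def study_design(self) -> StudyDesign:
        s = self.study
        return StudyDesign(n_batches=s.n_batches,
                           batch_sd_frac=s.batch_sd_frac,
                           noise_sd_frac=s.noise_sd_frac,
                           kmf_noise_sd_frac=s.kmf_noise_sd_frac,
                           seed=self.seed)

    def t2_grid_s(self) -> np.ndarray:
        d = self.dictionary
        n = int(round((d.t2_max_ms - d.t2_min_ms) / d.t2_step_ms)) + 1
        return np.linspace(d.t2_min_ms, d.t2_max_ms, n) / 1e3


def load_config(path: str | Path | None) -> PipelineConfig:
    """Read a JSON (or YAML, if pyyaml is available) configuration file;
    None yields the defaults."""
    if path is None:
        return PipelineConfig()
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml
            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
    except Exception as exc:
        raise ConfigError(f"could not parse configuration {path}: {exc}") \
            from exc
    try:
        return PipelineConfig.model_validate(payload)
    except ValidationError as exc:
        locs = ", ".join("/".join(str(p) for p in err["loc"])
                         for err in exc.errors())
        raise ConfigError(f"invalid configuration ({path}): {locs}") from exc


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(config.model_dump_json(indent=2) + "\n")
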