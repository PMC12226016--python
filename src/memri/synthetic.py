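"""Synthetic study generator.

Emulates the two experiments the inference layer consumes:

* an in vitro cell-pellet study — seven ionic conditions (six potassium
  concentrations plus one barium condition) applied to replicate cell
  batches, with the MR parameters tied to the measured membrane-potential
  change dVm through fractional-linear relations

      T2 (ms) = 49.7  (1 + 0.00687 dVm)
      PSR     = 0.0377 (1 - 0.00542 dVm)
      k_mf(Hz)= 14.8  (1 + 0.000648 dVm)

  with multiplicative batch random effects and residual noise, and
  optionally the raw SESE / IR-MESE signals those parameters would
  produce;

* an in vivo perfused-cortex time series — four sequential epochs
  (baseline, 40 mM K+, 80 mM K+, recovery) in a modulation arm against a
  constant-baseline control arm, with per-rat random intercepts.

Everything is driven by a single seed; two calls with the same design
produce identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DomainError
from .signals import SignalRecord
from .twopool import (InversionState, SequenceParams, TwoPoolParams,
                      biexp_recovery_signal, rates_from_twopool,
                      simulate_inversion_pulse)

__all__ = [
    "ConditionSpec", "StudyDesign", "StudyDataset", "InVivoSeries",
    "default_conditions", "generate_parameter_dataset",
    "generate_signal_dataset", "generate_invivo_series",
    "sese_sequence", "ir_mese_sequence", "invivo_mese_sequence",
    "RESPONSES",
]

RESPONSES = ("t2_ms", "psr", "kmf_hz")

#: patch-clamp anchors: [K+] (mM) -> measured dVm (mV) from control
K_ANCHORS = {0.2: -5.33, 4.2: 0.0, 80.0: 30.0}
BA_CONC_MM = 10.0
BA_DELTA_VM = 13.3
K_CONCENTRATIONS = (0.2, 1.0, 4.2, 20.0, 40.0, 80.0)

#: fractional-linear relation coefficients of the emulated study
#: (intercept, per-mV slope)
DEFAULT_INTERCEPTS = {"t2_ms": 49.7, "psr": 0.0377, "kmf_hz": 14.8}
DEFAULT_SLOPES = {"t2_ms": 0.00687, "psr": -0.00542, "kmf_hz": 0.000648}


@dataclass(frozen=True)
class ConditionSpec:
    label: str
    k_conc: float          # mM
    ba_conc: float         # mM
    delta_vm: float        # mV, change from the control condition
    group: str             # "potassium" | "barium" | "control"

    def __post_init__(self):
        if self.group not in ("potassium", "barium", "control"):
            raise DomainError(f"unknown group {self.group!r}")
        if not np.isfinite(self.delta_vm):
            raise DomainError("delta_vm must be finite")
        if self.group == "control" and self.delta_vm != 0.0:
            raise DomainError("the control condition defines delta_vm = 0")


def default_conditions() -> list[ConditionSpec]:
    """The seven ionic conditions of the pellet experiment.

    dVm at the anchored conditions (0.2, 4.2, 80 mM K+ and the barium
    condition) carries the patch-clamp values; the remaining potassium
    conditions are interpolated with a least-squares line in log10[K+]
    through the three potassium anchors, reflecting the near-log-linear
    dependence of membrane potential on extracellular potassium.
    """
    xs = np.log10(np.array(list(K_ANCHORS)))
    ys = np.array(list(K_ANCHORS.values()))
    slope, intercept = np.polyfit(xs, ys, 1)
    conditions = []
    for k in K_CONCENTRATIONS:
        if k in K_ANCHORS:
            dvm = K_ANCHORS[k]
        else:
            dvm = float(intercept + slope * np.log10(k))
        group = "control" if k == 4.2 else "potassium"
        conditions.append(ConditionSpec(label=f"K{k:g}", k_conc=k,
                                        ba_conc=0.0, delta_vm=dvm,
                                        group=group))
    conditions.append(ConditionSpec(label=f"Ba{BA_CONC_MM:g}", k_conc=4.2,
                                    ba_conc=BA_CONC_MM,
                                    delta_vm=BA_DELTA_VM, group="barium"))
    return conditions


@dataclass(frozen=True)
class StudyDesign:
    """Ground-truth relations, replication and noise of a pellet study.

    batch_sd_frac and noise_sd_frac are relative (multiplicative) SDs for
    the batch random effect and the residual; k_mf carries its own, much
    larger, residual fraction because the exchange-rate estimate is far
    noisier than T2 or PSR in practice (its condition contrasts in the
    emulated study
    are all non-significant).
    """

    conditions: tuple[ConditionSpec, ...] = None
    n_batches: int = 15
    intercepts: dict = field(default_factory=lambda: dict(DEFAULT_INTERCEPTS))
    slopes: dict = field(default_factory=lambda: dict(DEFAULT_SLOPES))
    batch_sd_frac: float = 0.03
    noise_sd_frac: float = 0.02
    kmf_noise_sd_frac: float = 0.14
    seed: int = 20250703

    def __post_init__(self):
        if self.conditions is None:
            object.__setattr__(self, "conditions",
                               tuple(default_conditions()))
        else:
            object.__setattr__(self, "conditions", tuple(self.conditions))
        if self.n_batches < 2:
            raise DomainError("need at least 2 batches")
        for frac in (self.batch_sd_frac, self.noise_sd_frac,
                     self.kmf_noise_sd_frac):
            if frac < 0:
                raise DomainError("SD fractions must be nonnegative")
        if any(v <= 0 for v in self.intercepts.values()):
            raise DomainError("intercepts must be positive")
        n_control = sum(c.group == "control" for c in self.conditions)
        if n_control != 1:
            raise DomainError("exactly one control condition is required")

    def noise_frac(self, response: str) -> float:
        return self.kmf_noise_sd_frac if response == "kmf_hz" \
            else self.noise_sd_frac


@dataclass
class StudyDataset:
    """Balanced batches x conditions table of MR parameters, optionally
    with the raw signal bundles each row would have produced."""

    params: pd.DataFrame
    signals: dict | None = None   # (batch_id, label) -> {"sese": .., "ir_mese": ..}

    def __post_init__(self):
        required = {"batch_id", "label", "k_conc", "ba_conc", "delta_vm",
                    "group"}
        missing = required - set(self.params.columns)
        if missing:
            raise DomainError(f"dataset missing columns {sorted(missing)}")
        counts = self.params.groupby(["batch_id", "label"]).size()
        if (counts != 1).any():
            raise DomainError("dataset is not balanced: every batch x "
                              "condition pair must appear exactly once")
        n_labels = self.params["label"].nunique()
        n_batches = self.params["batch_id"].nunique()
        if len(self.params) != n_labels * n_batches:
            raise DomainError("dataset is not a complete batch x "
                              "condition grid")


def generate_parameter_dataset(design: StudyDesign,
                               rng: np.random.Generator | None = None
                               ) -> StudyDataset:
    """Draw one study of per-batch, per-condition MR parameters.

    value = intercept * (1 + slope * dVm) * (1 + u_b) * (1 + eps), with
    u_b shared across a batch's conditions (one draw per batch per
    response) and eps independent per cell.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    rows = []
    batch_effects = {resp: rng.normal(0.0, design.batch_sd_frac,
                                      design.n_batches)
                     for resp in RESPONSES}
    for b in range(design.n_batches):
        for cond in design.conditions:
            row = {"batch_id": f"b{b + 1:02d}", "label": cond.label,
                   "k_conc": cond.k_conc, "ba_conc": cond.ba_conc,
                   "delta_vm": cond.delta_vm, "group": cond.group}
            for resp in RESPONSES:
                mean = (design.intercepts[resp]
                        * (1.0 + design.slopes[resp] * cond.delta_vm))
                eps = rng.normal(0.0, design.noise_frac(resp))
                row[resp] = mean * (1.0 + batch_effects[resp][b]) \
                    * (1.0 + eps)
            rows.append(row)
    return StudyDataset(params=pd.DataFrame(rows))


def sese_sequence(n_te: int = 50, te_min_ms: float = 9.5,
                  te_max_ms: float = 290.5) -> SequenceParams:
    """Single-echo spin-echo protocol: log-spaced echo times."""
    return SequenceParams(te_list=np.geomspace(te_min_ms, te_max_ms,
                                               n_te) / 1e3)


def ir_mese_sequence(n_ti: int = 25, ti_min_ms: float = 4.0,
                     ti_max_ms: float = 10079.4,
                     echo_spacing_ms: float = 9.5,
                     n_echoes_per_ti: int = 16) -> SequenceParams:
    """Inversion-recovery multi-echo spin-echo protocol; the default TI
    span matches the optimized schedule of the emulated protocol,
    log-spaced."""
    return SequenceParams(ti_list=np.geomspace(ti_min_ms, ti_max_ms,
                                               n_ti) / 1e3,
                          echo_spacing=echo_spacing_ms / 1e3,
                          n_echoes_per_ti=n_echoes_per_ti)


def invivo_mese_sequence(n_te: int = 20, echo_spacing_ms: float = 7.5
                         ) -> SequenceParams:
    """In vivo multi-echo spin-echo: 20 echoes, 7.5-150 ms."""
    te = echo_spacing_ms * np.arange(1, n_te + 1) / 1e3
    return SequenceParams(te_list=te, echo_spacing=echo_spacing_ms / 1e3,
                          n_echoes_per_ti=n_te)


def generate_signal_dataset(design: StudyDesign,
                            seq_sese: SequenceParams | None = None,
                            seq_ir: SequenceParams | None = None,
                            r1_hz: float = 0.5,
                            t2m_s: float = 10e-6,
                            signal_noise_frac: float = 0.005,
                            inversion: InversionState | None = None,
                            rng: np.random.Generator | None = None
                            ) -> StudyDataset:
    """Synthesize raw SESE decays and IR-MESE recoveries for every row.

    Per row, the SESE signal follows exp(-TE/T2) from the row's T2 and
    the IR-MESE signal follows the two-pool bi-exponential recovery from
    the row's (PSR, k_mf) with R1,f = R1,m = r1_hz, each echo in the
    post-TI train additionally decaying with the row's T2.  Gaussian
    noise of SD signal_noise_frac (fraction of the equilibrium
    magnitude) is added before taking magnitudes.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    if seq_sese is None:
        seq_sese = sese_sequence()
    if seq_ir is None:
        seq_ir = ir_mese_sequence()
    dataset = generate_parameter_dataset(design, rng=rng)
    if inversion is None:
        probe = TwoPoolParams(r1f=r1_hz, r1m=r1_hz, kmf=14.8, psr=0.0377,
                              t2m=t2m_s)
        inversion = simulate_inversion_pulse(
            probe, seq_ir.inversion_pulse_duration, seq_ir.inversion_flip)

    esp = seq_ir.echo_spacing
    n_echo = seq_ir.n_echoes_per_ti
    echo_te = esp * np.arange(1, n_echo + 1)
    signals = {}
    for row in dataset.params.itertuples():
        t2_s = row.t2_ms / 1e3
        sese_clean = np.exp(-seq_sese.te_list / t2_s)
        sese_mag = np.abs(sese_clean + rng.normal(
            0.0, signal_noise_frac, sese_clean.shape))
        sese = SignalRecord(condition_label=row.label,
                            batch_id=row.batch_id,
                            te_ms=seq_sese.te_list * 1e3,
                            magnitude=sese_mag,
                            sigma=signal_noise_frac)
        pools = TwoPoolParams(r1f=r1_hz, r1m=r1_hz, kmf=row.kmf_hz,
                              psr=row.psr, t2f=t2_s, t2m=t2m_s)
        comp = rates_from_twopool(pools, inversion)
        mz = biexp_recovery_signal(comp, seq_ir.ti_list)
        train = mz[:, None] * np.exp(-echo_te[None, :] / t2_s)
        noisy = np.abs(train + rng.normal(0.0, signal_noise_frac,
                                          train.shape))
        ir = SignalRecord(
            condition_label=row.label, batch_id=row.batch_id,
            te_ms=np.tile(echo_te * 1e3, seq_ir.ti_list.size),
            magnitude=noisy.ravel(),
            ti_ms=np.repeat(seq_ir.ti_list * 1e3, n_echo),
            sigma=signal_noise_frac)
        signals[(row.batch_id, row.label)] = {"sese": sese, "ir_mese": ir}
    dataset.signals = signals
    return dataset


#: in vivo epoch structure: epoch -> ([K+] mM in the modulation arm,
#: elapsed minutes at readout)
INVIVO_EPOCH_K = {1: 3.0, 2: 40.0, 3: 80.0, 4: 3.0}
INVIVO_ELAPSED_MIN = {1: 0.0, 2: 12.0, 3: 24.0, 4: 36.0}
#: arm-specific mean dT2 (ms) per epoch; epochs 2 and 3 carry the
#: emulated study's means, the recovery epoch is a generator choice
DEFAULT_MODULATION_EFFECTS = (0.0, 0.684, 1.10, 0.30)
DEFAULT_CONTROL_EFFECTS = (0.0, 0.104, 0.181, 0.25)


@dataclass
class InVivoSeries:
    """Tidy four-epoch dT2 series for modulation and control arms."""

    data: pd.DataFrame

    def __post_init__(self):
        required = {"rat_id", "arm", "epoch", "elapsed_min", "k_conc",
                    "delta_t2_ms"}
        missing = required - set(self.data.columns)
        if missing:
            raise DomainError(f"series missing columns {sorted(missing)}")
        for row in self.data.itertuples():
            expected = INVIVO_EPOCH_K[row.epoch] if row.arm == "modulation" \
                else 3.0
            if row.k_conc != expected:
                raise DomainError(
                    f"epoch {row.epoch} in arm {row.arm} must use "
                    f"[K+] = {expected} mM")


def generate_invivo_series(n_modulation: int = 7, n_control: int = 5,
                           modulation_effects=DEFAULT_MODULATION_EFFECTS,
                           control_effects=DEFAULT_CONTROL_EFFECTS,
                           rat_sd: float = 0.3, noise_sd: float = 0.2,
                           n_recovery: int = 2,
                           seed: int = 20250703,
                           rng: np.random.Generator | None = None
                           ) -> InVivoSeries:
    """Draw the four-epoch in vivo time series.

    delta_t2 = arm-specific epoch effect + per-rat intercept + noise (ms).
    Only `n_recovery` of the modulation rats undergo the recovery epoch;
    all control rats complete four epochs.
    """
    if n_modulation < 1 or n_control < 1:
        raise DomainError("both arms need at least one rat")
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    for arm, n_rats, effects in (("modulation", n_modulation,
                                  modulation_effects),
                                 ("control", n_control, control_effects)):
        intercepts = rng.normal(0.0, rat_sd, n_rats)
        for r in range(n_rats):
            epochs = range(1, 5)
            if arm == "modulation" and r >= n_recovery:
                epochs = range(1, 4)
            for e in epochs:
                k = INVIVO_EPOCH_K[e] if arm == "modulation" else 3.0
                rows.append({
                    "rat_id": f"{arm[:3]}{r + 1:02d}", "arm": arm,
                    "epoch": e, "elapsed_min": INVIVO_ELAPSED_MIN[e],
                    "k_conc": k,
                    "delta_t2_ms": effects[e - 1] + intercepts[r]
                    + rng.normal(0.0, noise_sd)})
    return InVivoSeries(data=pd.DataFrame(rows))
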