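"""Model parameterization: exposure conditions, perturbations, kinetic constants.

The simulator models the intracellular response of an epithelial cell to
extracellular H2O2.  Exposure is either a *bolus* (a single acute addition
that the cell clears within ~2 h) or *continuous* enzymatic production
(glucose-oxidase-like, sustained over the whole movie).  A population of
2-Cys peroxiredoxins scavenges H2O2; at high concentrations their
peroxidatic cysteine is hyperoxidized (SO2H/SO3H), which both inactivates
the peroxidase and flips a switch between two transcription-factor
programs: while the hyperoxidized fraction ``P`` is above a threshold
``theta_F``, the shuttling TF (FOXO1) is nuclear and the level TF (p53) is
blocked; below the threshold, p53 is driven by accumulated damage and by
the sulfiredoxin repair flux.  Sulfiredoxin (SRXN1) slowly repairs
hyperoxidized peroxiredoxin, so the nuclear residence time of FOXO1 grows
with dose and can be stretched by SRXN1 inhibition or shortened by SRXN1
overexpression.

All defaults below were calibrated once against reported single-cell
death fractions and timing constraints for MCF7 cells (see
``docs/methods.md``) and are meant to be used as-is; per-condition
overrides belong in the TOML config, not in edits to these values.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Literal

try:  # Python >= 3.11
    import tomllib
except ModuleNotFoundError:  # pragma: no cover
    tomllib = None

__all__ = [
    "ExposureCondition",
    "PerturbationMode",
    "KineticParams",
    "SimulationConfig",
    "InvalidConditionError",
    "load_config",
    "config_to_toml",
]

ExposureMode = Literal["bolus", "continuous", "none"]


class InvalidConditionError(ValueError):
    """Raised for physically meaningless exposure or perturbation settings."""


@dataclass(frozen=True)
class ExposureCondition:
    """How H2O2 reaches the cell.

    Parameters
    ----------
    mode:
        ``"bolus"`` (single acute addition, concentration units),
        ``"continuous"`` (enzymatic production, dose labelled in mU/mL of
        enzyme) or ``"none"`` (untreated control).
    dose:
        Bolus: the nominal extracellular concentration in uM-equivalents
        (the label "100" corresponds to a 100 uM condition by convention).
        Continuous: the enzyme activity label in mU/mL; the production rate
        is ``gox_rate * dose ** gox_exponent`` per hour (see
        :class:`KineticParams`).
    treatment_start:
        Hours after movie start at which exposure begins (default 0).
    """

    mode: ExposureMode = "none"
    dose: float = 0.0
    treatment_start: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("bolus", "continuous", "none"):
            raise InvalidConditionError(f"unknown exposure mode {self.mode!r}")
        if not math.isfinite(self.dose) or self.dose < 0:
            raise InvalidConditionError(f"dose must be finite and >= 0, got {self.dose}")
        if self.mode == "none" and self.dose != 0:
            raise InvalidConditionError("mode='none' requires dose == 0")
        if self.treatment_start < 0:
            raise InvalidConditionError("treatment_start must be >= 0")


# srxn1_multiplier, prdx_capacity_multiplier presets per genetic/chemical mode
_PERTURBATION_PRESETS: dict[str, tuple[float, float]] = {
    "control": (1.0, 1.0),
    "srxn1_oe": (4.0, 1.0),
    "srxn1_inhibited": (0.0, 1.0),
    "prdx1_ko": (1.0, 0.70),
    "prdx2_kd": (1.0, 0.85),
    "prdx_inhibited": (1.0, 0.50),
}


@dataclass(frozen=True)
class PerturbationMode:
    """Genetic or small-molecule perturbation of the PRDX/SRXN1 system.

    ``srxn1_multiplier`` scales the sulfiredoxin repair rate (0 for the J14
    inhibitor, >1 for overexpression).  ``prdx_capacity_multiplier`` < 1
    models loss of peroxiredoxin (knockout/knockdown/covalent inhibition):
    it scales both the H2O2 clearance rate and the hyperoxidation threshold
    ``theta_F`` downward, because a smaller PRDX pool scavenges less and
    needs less oxidation to be taken out.
    """

    label: str = "control"
    srxn1_multiplier: float = 1.0
    prdx_capacity_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.srxn1_multiplier < 0:
            raise InvalidConditionError("srxn1_multiplier must be >= 0")
        if not 0 < self.prdx_capacity_multiplier <= 1:
            raise InvalidConditionError("prdx_capacity_multiplier must be in (0, 1]")
        if self.label == "control" and (
            self.srxn1_multiplier != 1.0 or self.prdx_capacity_multiplier != 1.0
        ):
            raise InvalidConditionError("control perturbation must have unit multipliers")
        if self.label == "srxn1_inhibited" and self.srxn1_multiplier != 0.0:
            raise InvalidConditionError("srxn1_inhibited requires srxn1_multiplier == 0")

    @classmethod
    def from_label(cls, label: str) -> "PerturbationMode":
        """Build one of the named presets (``control``, ``srxn1_oe``, ...)."""
        try:
            srx, cap = _PERTURBATION_PRESETS[label]
        except KeyError:
            raise InvalidConditionError(
                f"unknown perturbation {label!r}; known: {sorted(_PERTURBATION_PRESETS)}"
            ) from None
        return cls(label=label, srxn1_multiplier=srx, prdx_capacity_multiplier=cap)


@dataclass(frozen=True)
class KineticParams:
    """All rate constants and thresholds of the single-cell model.

    Units: time in hours, H2O2 in bolus-dose units (uM-equivalents), the
    hyperoxidized PRDX fraction ``P`` in [0, 1], damage ``D`` in arbitrary
    units, p53 in arbitrary fluorescence units (AU).
    """

    # --- H2O2 input ---
    k_clear: float = 2.3          # /h, intracellular clearance (bolus gone < 2 h)
    gox_rate: float = 17.2        # production units/h per (mU/mL)**gox_exponent
    gox_exponent: float = 0.545   # sublinear enzyme-dose -> rate mapping
    gox_dip: float = 0.0          # fractional production drop after the first hour
    density_coupling: float = 0.0  # effective dose = dose / (1 + c * cells_plated)
    cells_plated: float = 0.0

    # --- PRDX hyperoxidation / SRXN1 repair ---
    k_hyp: float = 0.0164         # /(dose*h), hyperoxidation rate constant
    k_srx: float = 0.10           # /h, SRXN1 repair of PRDX-SO2H
    theta_F: float = 0.40         # hyperoxidized fraction gating FOXO1 and p53 block

    # --- damage and death ---
    k_dmg: float = 0.0599         # damage per (dose unit * h)
    k_pdmg: float = 1.1075        # damage per (unrepaired hyperoxidized fraction * h)
    k_srx_half: float = 0.02      # /h repair flux halving the hyperoxidation damage
    k_rep: float = 0.2497         # /h, damage repair
    lambda_d: float = 0.4957      # /h death hazard per unit excess damage
    D_c: float = 1.6498           # damage threshold for death hazard
    hazard_cap: float = 1.2238     # excess damage saturating the hazard
    death_latency: float = 3.0    # h from death commitment to execution

    # --- FOXO1 shuttling ---
    tau_f: float = 0.15           # h, nuclear/cytoplasmic relaxation time
    f_min: float = 0.10           # cytoplasmic-state nuclear fraction
    f_max: float = 0.90           # nuclear-state nuclear fraction
    k_retention: float = 2.0      # cytoplasmic retention by the active PRDX relay

    # --- p53 drive and delayed-negative-feedback oscillator ---
    theta_p: float = 0.80         # drive threshold for p53 activation
    w_relay: float = 1.0          # drive weight of the repair/relay flux (w * P)
    tau_act: float = 1.5          # h, rise time of the p53-activating signal
    tau_deact: float = 24.0       # h, persistence of the signal once activated
    tau_sig: float = 0.2          # h, latency of the damage-sensing kinase relay
    beta_p: float = 60.0          # AU/h maximal p53 production
    alpha_p: float = 0.50         # /(M*h) MDM2-mediated p53 degradation
    alpha_x: float = 0.10         # /h MDM2-independent p53 turnover
    gamma_m: float = 16.0         # M/h maximal MDM2 production
    K_m: float = 50.0             # AU, p53 half-saturation of MDM2 production
    delta_m: float = 1.0          # /h MDM2 turnover
    tau_delay: float = 1.5        # h, transcriptional delay (sets ~5.5 h period)
    p53_suppression: float = 0.12  # basal-pool suppression per hyperoxidized fraction
    d_m: float = 2.0              # damage scale weakening the MDM2 feedback
    p53_baseline: float = 100.0   # AU, unstressed nuclear p53

    # --- cell-to-cell variability and measurement ---
    cv_cell: float = 0.1982       # lognormal CV on k_hyp, k_clear, theta_F, D_c
    sigma_meas: float = 0.05      # multiplicative measurement noise SD

    # --- integration ---
    dt_int: float = 1.0 / 60.0    # h, fixed RK4 step (1 min)

    def __post_init__(self) -> None:
        for name in (
            "k_clear", "gox_rate", "k_hyp", "k_srx", "k_dmg", "k_pdmg", "k_rep",
            "lambda_d", "hazard_cap", "beta_p", "alpha_p", "alpha_x", "gamma_m",
            "delta_m", "w_relay", "cv_cell", "sigma_meas",
        ):
            if getattr(self, name) < 0:
                raise InvalidConditionError(f"{name} must be >= 0")
        if not 0 < self.theta_F < 1:
            raise InvalidConditionError("theta_F must lie in (0, 1)")
        if not 0 <= self.f_min < self.f_max <= 1:
            raise InvalidConditionError("need 0 <= f_min < f_max <= 1")
        for name in ("tau_f", "tau_act", "tau_deact", "dt_int", "K_m"):
            if getattr(self, name) <= 0:
                raise InvalidConditionError(f"{name} must be > 0")
        if self.tau_delay < 0 or self.tau_sig < 0 or self.death_latency < 0:
            raise InvalidConditionError("tau_delay, tau_sig, death_latency must be >= 0")

    def replace(self, **changes) -> "KineticParams":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class SimulationConfig:
    """Complete description of one simulated experiment."""

    condition: ExposureCondition = field(default_factory=ExposureCondition)
    perturbation: PerturbationMode = field(default_factory=PerturbationMode)
    params: KineticParams = field(default_factory=KineticParams)
    n_cells: int = 100
    t_end: float = 24.0
    dt_sample: float = 1.0 / 3.0  # 20-min imaging interval
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise InvalidConditionError("n_cells must be >= 1")
        if self.t_end <= 0 or self.dt_sample <= 0:
            raise InvalidConditionError("t_end and dt_sample must be > 0")
        ratio = self.t_end / self.dt_sample
        if abs(ratio - round(ratio)) > 1e-9:
            raise InvalidConditionError("t_end must be an integer multiple of dt_sample")
        sub = self.dt_sample / self.params.dt_int
        if abs(sub - round(sub)) > 1e-9:
            raise InvalidConditionError("dt_sample must be an integer multiple of dt_int")

    @property
    def n_samples(self) -> int:
        return int(round(self.t_end / self.dt_sample)) + 1

    def sample_times(self):
        import numpy as np

        return np.arange(self.n_samples) * self.dt_sample

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)


# ---------------------------------------------------------------------------
# TOML configuration files
# ---------------------------------------------------------------------------

def load_config(path) -> SimulationConfig:
    """Read a :class:`SimulationConfig` from a TOML file.

    Recognized sections: ``[condition]``, ``[perturbation]``, ``[params]``
    and ``[run]``; every key is optional and defaults to the shipped value.
    ``[perturbation]`` may give just ``label = "..."`` to use a preset, or
    override the multipliers explicitly.
    """
    if tomllib is None:  # pragma: no cover
        raise RuntimeError("TOML support requires Python >= 3.11")
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    unknown = set(raw) - {"condition", "perturbation", "params", "run"}
    if unknown:
        raise InvalidConditionError(f"unknown config sections: {sorted(unknown)}")

    condition = _build(ExposureCondition, raw.get("condition", {}))
    pert_raw = dict(raw.get("perturbation", {}))
    if set(pert_raw) == {"label"}:
        perturbation = PerturbationMode.from_label(pert_raw["label"])
    else:
        if "label" in pert_raw and pert_raw["label"] in _PERTURBATION_PRESETS:
            srx, cap = _PERTURBATION_PRESETS[pert_raw["label"]]
            pert_raw.setdefault("srxn1_multiplier", srx)
            pert_raw.setdefault("prdx_capacity_multiplier", cap)
        perturbation = _build(PerturbationMode, pert_raw)
    params = _build(KineticParams, raw.get("params", {}))
    run = raw.get("run", {})
    allowed = {"n_cells", "t_end", "dt_sample", "seed"}
    bad = set(run) - allowed
    if bad:
        raise InvalidConditionError(f"unknown [run] keys: {sorted(bad)}")
    return SimulationConfig(
        condition=condition, perturbation=perturbation, params=params, **run
    )


def _build(cls, section: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    bad = set(section) - names
    if bad:
        raise InvalidConditionError(f"unknown {cls.__name__} keys: {sorted(bad)}")
    return cls(**section)


def config_to_toml(config: SimulationConfig) -> str:
    """Render a config (defaults included) as a TOML document."""

    def fmt(value) -> str:
        if isinstance(value, bool):
            return "true" if value else "false"
        if isinstance(value, str):
            return f'"{value}"'
        if isinstance(value, float):
            return repr(value)
        return str(value)

    lines: list[str] = []
    for section, obj in (
        ("condition", config.condition),
        ("perturbation", config.perturbation),
        ("params", config.params),
    ):
        lines.append(f"[{section}]")
        for f in dataclasses.fields(obj):
            lines.append(f"{f.name} = {fmt(getattr(obj, f.name))}")
        lines.append("")
    lines.append("[run]")
    for key in ("n_cells", "t_end", "dt_sample", "seed"):
        lines.append(f"{key} = {fmt(getattr(config, key))}")
    lines.append("")
    return "\n".join(lines)
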