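"""Parameter containers for the FLC silencing model.

All rates are per day; temperatures in degrees Celsius; mark coverages and
state fractions are dimensionless in [0, 1].  Defaults are free/fit
quantities with documented rationales (see docs/methods.md); none is a
measured constant.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

STATES = ("U", "N", "S")          # non-nucleated, nucleated, spread
REGIONS = ("nucleation", "body")  # H3K27me3 nucleation region, gene body


class ParamError(ValueError):
    """Raised when a parameter set violates a model invariant."""


@dataclass
class AntisenseParams:
    """Antisense (COOLAIR)-mediated repression of sense transcription.

    The slow component ``a_slow`` is a first-order accumulator that rises
    toward ``a_slow_max`` below ``T_cold`` and relaxes to zero above it.
    The fast component is a step of size ``a_fast`` below ``T_fast``
    (freezing response) plus a graded Arrhenius-like term
    ``a_grad * exp(-(T - T_fast)/T_grad_scale)`` active below
    ``T_grad_on``, which lets repression track within-day temperature
    cycles that never cross the freezing threshold.
    """

    a_slow_max: float = 0.7   # maximal slow repression, dimensionless
    k_on: float = 0.25        # 1/day, slow activation in cold
    k_off: float = 1.0        # 1/day, relaxation in warm
    a_fast: float = 0.25      # step increment below T_fast
    T_fast: float = 0.0       # degC, freezing-response threshold
    a_grad: float = 0.15      # amplitude of graded fast term
    T_grad_scale: float = 3.0  # degC, e-folding scale of graded term
    T_grad_on: float = 15.0   # degC, graded term active only below this
    T_cold: float = 15.0      # degC, slow component activates below this
    disabled: bool = False    # COOLAIR-defective line
    constitutive: bool = False  # ntl8-D3-like ectopic antisense
    k_pin: float = 10.0       # 1/day, pinning rate for disabled/constitutive

    def validate(self) -> None:
        if not 0.0 <= self.a_slow_max <= 1.0:
            raise ParamError(f"a_slow_max must be in [0,1], got {self.a_slow_max}")
        if not 0.0 <= self.a_fast <= 1.0:
            raise ParamError(f"a_fast must be in [0,1], got {self.a_fast}")
        if self.k_on < 0 or self.k_off < 0:
            raise ParamError("k_on and k_off must be nonnegative")
        if self.a_grad < 0:
            raise ParamError("a_grad must be nonnegative")
        if self.T_grad_scale <= 0:
            raise ParamError("T_grad_scale must be positive")
        if self.disabled and self.constitutive:
            raise ParamError("a line cannot be both COOLAIR-defective and constitutive")

    def copy(self, **overrides) -> "AntisenseParams":
        return dataclasses.replace(self, **overrides)


def _default_k27_targets() -> dict:
    # per-state per-region H3K27me3 targets: U carries none, N nucleation
    # region only, S covers the whole locus
    return {
        "U": {"nucleation": 0.0, "body": 0.0},
        "N": {"nucleation": 0.9, "body": 0.0},
        "S": {"nucleation": 0.9, "body": 0.9},
    }


@dataclass
class ModelParams:
    """Rate constants and structural parameters of the chromatin-state ODEs."""

    # --- PRC2 nucleation / spreading ---
    k_nuc0: float = 0.15      # 1/day per unit cold memory
    v_ramp: float = 0.025     # 1/day, cold-memory accumulation
    v_decay: float = 10.0     # 1/day, warm reset of cold memory (fixed, fast)
    nuc_T_opt: float = 5.0    # degC, nucleation temperature optimum
    nuc_T_width: float = 15.0  # degC, width of nucleation efficiency
    k_spread: float = 0.2     # 1/day, N->S at full cell-cycle activity
    g_warm: float = 1.0       # relative cell-cycle activity in warm
    g_cold: float = 0.1       # relative cell-cycle activity in cold
    nucleation_enabled: bool = True
    spreading_enabled: bool = True

    # --- transcription ---
    beta_U: float = 10.0      # transcription events/day, non-nucleated
    beta_N: float = 3.0       # nucleated
    beta_S: float = 0.3       # spread
    delta_dwell: float = 1.2  # max fractional Pol II dwell-time increase
    dwell_T_on: float = 12.0  # degC, dwell slowdown starts below this
    dwell_T_sat: float = 0.0  # degC, dwell slowdown saturates at this
    dwell_body_enabled: bool = True  # slowdown also applies to gene body

    # --- histone marks ---
    alpha36_nuc: float = 0.02   # K36 added per transcription event, nucleation region
    alpha36_body: float = 0.02  # same, gene body
    gamma36: float = 0.2        # 1/day K36 removal (~3.5 d half-life)
    k27_relax: float = 5.0      # 1/day relaxation of K27 to per-state target
    K27_target: dict = field(default_factory=_default_k27_targets)
    coexistence_cap: float = 1.3  # max K36+K27 per region within a state

    # --- mRNA ---
    lambda_m: float = 2.0     # 1/day mRNA degradation

    # --- initial condition ---
    f_N0: float = 0.05        # pre-switched nucleated fraction at NV
    f_S0: float = 0.0         # pre-switched spread fraction at NV

    def validate(self) -> None:
        if not self.beta_U > self.beta_N > self.beta_S >= 0:
            raise ParamError(
                f"require beta_U > beta_N > beta_S >= 0, got "
                f"{self.beta_U}, {self.beta_N}, {self.beta_S}")
        for name in ("k_nuc0", "v_ramp", "v_decay", "k_spread", "g_warm",
                     "g_cold", "delta_dwell", "alpha36_nuc", "alpha36_body",
                     "gamma36", "k27_relax", "lambda_m"):
            if getattr(self, name) < 0:
                raise ParamError(f"{name} must be nonnegative")
        if self.f_N0 < 0 or self.f_S0 < 0 or self.f_N0 + self.f_S0 > 1:
            raise ParamError(f"need f_N0, f_S0 >= 0 and f_N0 + f_S0 <= 1")
        if not 0 < self.coexistence_cap <= 2:
            raise ParamError("coexistence_cap must be in (0, 2]")
        for s in STATES:
            for r in REGIONS:
                v = self.K27_target[s][r]
                if not 0.0 <= v <= 1.0:
                    raise ParamError(f"K27_target[{s}][{r}]={v} outside [0,1]")
        if self.nuc_T_width <= 0:
            raise ParamError("nuc_T_width must be positive")

    def copy(self, **overrides) -> "ModelParams":
        new = dataclasses.replace(self)
        # deep-copy the nested target dict so copies never alias
        new.K27_target = {s: dict(self.K27_target[s]) for s in STATES}
        for k, v in overrides.items():
            setattr(new, k, v)
        return new

    def beta(self, state: str) -> float:
        return {"U": self.beta_U, "N": self.beta_N, "S": self.beta_S}[state]

    def alpha36(self, region: str) -> float:
        return self.alpha36_nuc if region == "nucleation" else self.alpha36_body


def get_param(params: ModelParams, antisense: AntisenseParams, path: str) -> float:
    """Read a parameter by path, e.g. ``"k_nuc0"`` or ``"antisense.a_slow_max"``."""
    if path.startswith("antisense."):
        return getattr(antisense, path.split(".", 1)[1])
    if path.startswith("K27_target."):
        _, s, r = path.split(".")
        return params.K27_target[s][r]
    return getattr(params, path)


def set_param(params: ModelParams, antisense: AntisenseParams, path: str, value):
    """Set a parameter by path on the given (already copied) containers."""
    if path.startswith("antisense."):
        name = path.split(".", 1)[1]
        if not hasattr(antisense, name):
            raise ParamError(f"unknown antisense parameter {name!r}")
        setattr(antisense, name, value)
    elif path.startswith("K27_target."):
        _, s, r = path.split(".")
        params.K27_target[s][r] = value
    else:
        if not hasattr(params, path):
            raise ParamError(f"unknown parameter {path!r}")
        setattr(params, path, value)
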