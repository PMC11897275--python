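"""CYP3A4 enzyme-turnover induction model.

Relative enzyme amount E (baseline 1) follows the standard turnover ODE

    dE/dt = kdeg * (1 + emax*Cu/(ec50 + Cu)) - kdeg * E

driven by the unbound perpetrator concentration Cu (µM).  At constant
exposure the solution is ``E(t) = fold_ss - (fold_ss - 1)*exp(-kdeg*t)``
with ``fold_ss = 1 + emax*Cu/(ec50 + Cu)``, so E stays within
[1, 1 + emax] for a pure inducer started at baseline.

Induced rates: the hepatic CYP3A4 intrinsic clearance is multiplied by
the liver fold; the instantaneous intestinal availability becomes
``fg' = fg / (fg + (1 - fg)*E_gut)``, i.e. gut extraction scales with
the per-compartment gut enzyme amount.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence, Union

import numpy as np
from scipy.integrate import solve_ivp

from .data_store import InductionParams

__all__ = [
    "EnzymeState",
    "induction_fold_ss",
    "enzyme_closed_form",
    "simulate_enzyme",
    "induced_fg",
    "induced_hepatic_cl",
    "apply_induction",
    "InducedRates",
]


@dataclass
class EnzymeState:
    """Relative CYP3A4 amounts (baseline 1.0) for liver and gut compartments."""

    e_rel_liver: float = 1.0
    e_rel_gut: Union[float, np.ndarray] = 1.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.e_rel_liver)) or not np.all(
            np.isfinite(np.asarray(self.e_rel_gut))
        ):
            raise ValueError("enzyme state must be finite")


def induction_fold_ss(cu: float, induction: InductionParams) -> float:
    """Steady-state induction fold 1 + emax*Cu/(ec50 + Cu) at unbound Cu (µM)."""
    if cu < 0:
        raise ValueError("unbound concentration must be non-negative")
    return 1.0 + induction.emax * cu / (induction.ec50 + cu)


def enzyme_closed_form(
    t: np.ndarray, cu: float, induction: InductionParams, kdeg: float
) -> np.ndarray:
    """E(t) at constant exposure: fold_ss - (fold_ss - 1)*exp(-kdeg*t)."""
    fold = induction_fold_ss(cu, induction)
    return fold - (fold - 1.0) * np.exp(-kdeg * np.asarray(t, dtype=float))


def simulate_enzyme(
    cu_of_t: Callable[[float], float],
    induction: InductionParams,
    t_end: float,
    compartment: str = "liver",
    e0: float = 1.0,
    dt_out: float = 0.05,
    rtol: float = 1e-10,
    atol: float = 1e-12,
):
    """Integrate the turnover ODE for a given unbound-exposure trajectory.

    ``compartment`` selects the degradation rate constant (``"liver"`` or
    ``"gut"``).  Returns ``(times, e_rel)`` arrays with ``E(0) = e0``.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    kdeg = induction.kdeg_liver if compartment == "liver" else induction.kdeg_gut

    def rhs(t, y):
        cu = max(float(cu_of_t(t)), 0.0)
        drive = 1.0 + induction.emax * cu / (induction.ec50 + cu)
        return [kdeg * (drive - y[0])]

    times = np.arange(0.0, t_end + dt_out / 2, dt_out)
    times[-1] = min(times[-1], t_end)
    sol = solve_ivp(rhs, (0.0, t_end), [e0], t_eval=times, rtol=rtol, atol=atol, method="LSODA")
    if not sol.success:
        raise RuntimeError(f"enzyme integration failed: {sol.message}")
    return sol.t, sol.y[0]


def induced_fg(fg: float, e_rel_gut) -> Union[float, np.ndarray]:
    """Instantaneous intestinal availability under gut-enzyme fold e_rel_gut."""
    e = np.asarray(e_rel_gut, dtype=float)
    out = fg / (fg + (1.0 - fg) * e)
    return float(out) if out.ndim == 0 else out


def induced_hepatic_cl(cl_cyp3a4: float, e_rel_liver: float) -> float:
    """Hepatic CYP3A4 intrinsic clearance scaled by the liver enzyme fold."""
    return cl_cyp3a4 * e_rel_liver


@dataclass(frozen=True)
class InducedRates:
    """Snapshot of a model's induction-sensitive rates at one enzyme state."""

    cl_cyp3a4: float
    vmax: float
    fg_prime: Union[float, np.ndarray]


def apply_induction(model, enzyme: EnzymeState) -> InducedRates:
    """Evaluate a compiled model's CYP3A4-dependent rates at an enzyme state.

    With ``e_rel = 1`` everywhere the model is returned unchanged; with
    ``fg = 1`` there is no gut extraction to induce and ``fg' = 1``.
    """
    return InducedRates(
        cl_cyp3a4=induced_hepatic_cl(model.cl_cyp3a4, enzyme.e_rel_liver),
        vmax=model.vmax * enzyme.e_rel_liver,
        fg_prime=induced_fg(model.fg, enzyme.e_rel_gut),
    )
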