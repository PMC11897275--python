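"""Paired victim simulations (with/without a CYP3A4 inducer) and AUC ratios.

A DDI run is two simulations: the victim alone, and the victim co-dosed
after a rifampicin wash-in long enough for the enzyme pool to approach
its induced steady state.  The combined arm integrates perpetrator,
victim, and liver/gut enzyme turnover as one coupled ODE system; the
perpetrator's own CYP3A4 pathway autoinduces by default under multiple
dosing.

For single-dose victims AUC(0–∞) is obtained by λz extrapolation of each
arm (clinical DDI-study convention); for QD victims the AUC over one
dosing interval at steady state is used.  AUCR = AUC_combo/AUC_alone and
CmaxR likewise.

The module also carries the closed-form clearance-scaling oracle for
linear low-extraction victims at steady-state induction:

    AUCR = [fg'/fg] * 1 / ((1 - fm) + fm*fold_liver)

with ``fg' = fg/(fg + (1-fg)*fold_gut)``, which the dynamic engine must
reproduce and which is invertible for fm.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import nca
from .data_store import DrugModel
from .enzyme_induction import induced_fg
from .pk_engine import (
    CompiledModel,
    DoseEvent,
    DoseRegimen,
    ODESystem,
    Physiology,
    build_model,
)

__all__ = [
    "DDIDesign",
    "DDIResult",
    "default_design",
    "parse_dosing",
    "run_ddi",
    "aucr_analytic",
    "invert_fm",
]


class DDIDesign(BaseModel):
    """Study design for one victim/perpetrator pair.

    The perpetrator is dosed QD from t=0 for ``washin_days`` days before
    the victim starts, and continues until ``t_end``.  ``t_end`` must
    cover victim elimination (≥ 5 victim half-lives after the last dose
    for a reliable extrapolation).
    """

    model_config = ConfigDict(extra="forbid")

    perpetrator_regimen: DoseRegimen
    victim_regimen: DoseRegimen
    washin_days: int = Field(default=7, ge=0)
    t_end: float = Field(gt=0)
    steady_state_victim: bool = False

    @property
    def victim_start(self) -> float:
        return self.victim_regimen.start_time


_DOSING_RE = re.compile(
    r"^\s*([\d,.]+)\s*(mg|ug|µg)\s*,\s*(SD|QD)\s*$", re.IGNORECASE
)


def parse_dosing(dosing: str):
    """Parse a dosing string like ``"1,000 mg, SD"`` or ``"500 ug, SD"``.

    Returns ``(dose_mg, schedule)`` with schedule ``"SD"`` or ``"QD"``.
    """
    m = _DOSING_RE.match(dosing)
    if not m:
        raise ValueError(f"cannot parse dosing string {dosing!r}")
    value = float(m.group(1).replace(",", ""))
    unit = m.group(2).lower()
    if unit in ("ug", "µg"):
        value /= 1000.0
    return value, m.group(3).upper()


def default_design(
    victim_dosing: str,
    washin_days: int = 7,
    victim_window: float = 120.0,
    n_victim_ss_doses: int = 10,
    perpetrator_dose: float = 600.0,
) -> DDIDesign:
    """Standard design for a victim dosing string from the interaction table.

    Rifampicin 600 mg oral QD throughout; single-dose victims receive one
    dose with the (washin_days+1)-th rifampicin dose, QD victims are dosed
    daily to steady state and evaluated over the final interval.
    """
    dose_mg, schedule = parse_dosing(victim_dosing)
    victim_start = washin_days * 24.0
    if schedule == "SD":
        victim_regimen = DoseRegimen(
            route="oral", dose=dose_mg, n_doses=1, start_time=victim_start
        )
        t_end = victim_start + victim_window
        steady = False
    else:
        victim_regimen = DoseRegimen(
            route="oral",
            dose=dose_mg,
            n_doses=n_victim_ss_doses,
            interval=24.0,
            start_time=victim_start,
        )
        t_end = victim_start + n_victim_ss_doses * 24.0
        steady = True
    n_perp = int(np.ceil(t_end / 24.0))
    perpetrator_regimen = DoseRegimen(
        route="oral", dose=perpetrator_dose, n_doses=n_perp, interval=24.0
    )
    return DDIDesign(
        perpetrator_regimen=perpetrator_regimen,
        victim_regimen=victim_regimen,
        washin_days=washin_days,
        t_end=t_end,
        steady_state_victim=steady,
    )


@dataclass
class DDIResult:
    aucr: float
    cmaxr: float
    auc_alone: float
    auc_combo: float
    cmax_alone: float
    cmax_combo: float
    fold_liver_at_victim_dose: float
    fold_gut_at_victim_dose: float
    fold_liver_weighted: float  # victim-concentration-weighted mean liver fold
    fg_eff_alone: float  # realized intestinal availability, alone arm
    fg_eff_combo: float
    warnings: List[str] = field(default_factory=list)


def _regimen_events(regimen: DoseRegimen, drug_index: int) -> List[DoseEvent]:
    return [
        DoseEvent(
            time=t,
            drug_index=drug_index,
            route=regimen.route,
            amount=regimen.dose,
            duration=regimen.infusion_duration or 0.0,
        )
        for t in regimen.dose_times()
    ]


def _fg_eff(result, drug_index: int) -> float:
    """Realized gut availability: absorbed-to-portal / absorbed-from-lumen."""
    blk = result.system.blocks[drug_index]
    final = result.states[-1]
    gut_met = final[blk.cum_gut_met]
    dose = result.dosed_in(drug_index, np.array([result.t_end]))[0]
    unabs = final[blk.cum_unabs]
    absorbed = dose - unabs - result.states[-1, blk.gut].sum()
    if blk.gut_solid is not None:
        absorbed -= result.states[-1, blk.gut_solid].sum()
    if absorbed <= 0:
        return 1.0
    return float(np.clip((absorbed - gut_met) / absorbed, 1e-12, 1.0))


def _victim_exposure(result, design: DDIDesign, drug_index: int, dose: float):
    """AUC/Cmax of the victim in one arm, per the SD/QD convention."""
    profile = result.profile(drug_index)
    warnings = []
    if design.steady_state_victim:
        reg = design.victim_regimen
        t_last = reg.dose_times()[-1]
        t1 = min(t_last + (reg.interval or 24.0), result.t_end)
        sub = profile.slice(t_last, t1, rebase=True)
        auc = nca.auc_trapezoid(sub.times, sub.concentrations)
        cmax = float(np.max(sub.concentrations))
    else:
        sub = profile.slice(design.victim_start, rebase=True)
        res = nca.run_nca(sub, dose=dose, route="oral")
        if res.auc_inf is None:
            auc = res.auc_last
            warnings.append("lambda_z not estimable; AUC(0-t_last) used")
        else:
            auc = res.auc_inf
            if res.extrap_pct is not None and res.extrap_pct > 20.0:
                warnings.append(
                    f"extrapolated area {res.extrap_pct:.1f}% exceeds 20%"
                )
        cmax = res.cmax
    return auc, cmax, warnings


def run_ddi(
    victim: DrugModel,
    perpetrator: DrugModel,
    design: DDIDesign,
    phys: Optional[Physiology] = None,
    dt_out: float = 0.05,
    autoinduction: bool = True,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> DDIResult:
    """Simulate a victim with and without the perpetrator and form AUCR/CmaxR."""
    if perpetrator.induction is None:
        raise ValueError("perpetrator must carry induction parameters")
    phys = phys or Physiology()
    victim_model = build_model(victim, phys)
    perp_model = build_model(perpetrator, phys)

    # --- victim alone: same victim schedule, clock rebased to victim start
    alone_reg = design.victim_regimen.model_copy(update={"start_time": 0.0})
    alone_system = ODESystem([victim_model])
    alone_result = alone_system.run(
        _regimen_events(alone_reg, 0),
        t_end=design.t_end - design.victim_start,
        dt_out=dt_out,
        rtol=rtol,
        atol=atol,
    )
    alone_design = design.model_copy(
        update={
            "victim_regimen": alone_reg,
            "t_end": design.t_end - design.victim_start,
        }
    )
    auc_alone, cmax_alone, warn_a = _victim_exposure(
        alone_result, alone_design, 0, design.victim_regimen.dose
    )

    # --- combined arm: perpetrator + victim + enzyme turnover
    combo_system = ODESystem(
        [perp_model, victim_model],
        inducer_index=0,
        induced=[autoinduction, True],
    )
    events = _regimen_events(design.perpetrator_regimen, 0) + _regimen_events(
        design.victim_regimen, 1
    )
    combo_result = combo_system.run(
        events, t_end=design.t_end, dt_out=dt_out, rtol=rtol, atol=atol
    )
    auc_combo, cmax_combo, warn_c = _victim_exposure(
        combo_result, design, 1, design.victim_regimen.dose
    )

    # --- diagnostics
    times = combo_result.times
    e_liver = combo_result.enzyme_liver()
    e_gut = combo_result.enzyme_gut()
    i_dose = int(np.searchsorted(times, design.victim_start))
    fold_liver_0 = float(e_liver[i_dose])
    fold_gut_0 = float(e_gut[i_dose].mean())
    cv = combo_result.concentrations(1)
    post = times >= design.victim_start
    weight = cv[post]
    if weight.sum() > 0:
        fold_liver_w = float(np.trapezoid(e_liver[post] * weight, times[post])
                             / np.trapezoid(weight, times[post]))
    else:
        fold_liver_w = fold_liver_0

    if auc_alone <= 0:
        raise ValueError("victim alone produced zero exposure")
    return DDIResult(
        aucr=auc_combo / auc_alone,
        cmaxr=cmax_combo / cmax_alone,
        auc_alone=auc_alone,
        auc_combo=auc_combo,
        cmax_alone=cmax_alone,
        cmax_combo=cmax_combo,
        fold_liver_at_victim_dose=fold_liver_0,
        fold_gut_at_victim_dose=fold_gut_0,
        fold_liver_weighted=fold_liver_w,
        fg_eff_alone=_fg_eff(alone_result, 0),
        fg_eff_combo=_fg_eff(combo_result, 1),
        warnings=warn_a + warn_c,
    )


def aucr_analytic(fm: float, fg: float, fold_liver: float, fold_gut: float) -> float:
    """Closed-form AUCR for a linear, low-extraction victim at constant folds.

    ``AUCR = (fg'/fg) / ((1 - fm) + fm*fold_liver)`` with
    ``fg' = fg/(fg + (1-fg)*fold_gut)``.
    """
    if not (0.0 <= fm <= 1.0):
        raise ValueError("fm must lie in [0, 1]")
    if not (0.0 < fg <= 1.0):
        raise ValueError("fg must lie in (0, 1]")
    fg_prime = induced_fg(fg, fold_gut)
    return (fg_prime / fg) / ((1.0 - fm) + fm * fold_liver)


def invert_fm(
    aucr: float,
    fg: float,
    fold_liver: float,
    fold_gut: float,
    tol: float = 1e-10,
) -> float:
    """Recover fm from an observed noise-free AUCR by bisection.

    ``aucr_analytic`` is strictly decreasing in fm for fold_liver > 1, so
    the root is unique whenever the target lies in the attainable range.
    """
    lo, hi = 0.0, 1.0
    f_lo = aucr_analytic(lo, fg, fold_liver, fold_gut)
    f_hi = aucr_analytic(hi, fg, fold_liver, fold_gut)
    if not (f_hi - 1e-12 <= aucr <= f_lo + 1e-12):
        raise ValueError(
            f"target AUCR {aucr:.4g} outside attainable range [{f_hi:.4g}, {f_lo:.4g}]"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if aucr_analytic(mid, fg, fold_liver, fold_gut) >= aucr:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)
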