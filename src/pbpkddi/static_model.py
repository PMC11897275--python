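"""Mechanistic static model for induction-mediated AUC-ratio prediction.

The regulatory closed-form comparator (FDA DDI guidance convention):

    AUCR = 1/[Ag*Bg*Cg*(1 - Fg) + Fg]  *  1/[Ah*Bh*Ch*fm + (1 - fm)]

where A (reversible inhibition) and B (time-dependent inhibition) default
to 1 for a pure inducer, and the induction term is

    C = 1 + d*emax*I/(I + ec50)

evaluated at the gut concentration ``I_gut = dose/250 mL`` and the
unbound hepatic inlet concentration

    I_h = fup*(Cmax,ss + Fa*Fg*ka*Dose/(Qh*Rb)),

both converted to µM via the perpetrator's molecular weight.  The gut
factor equals the turnover model's ``fg'/fg`` when Cg equals the gut
enzyme fold, so the static and dynamic treatments of intestinal
availability agree in structure and differ only in the exposure they
plug in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .data_store import DDIRecord, DrugModel, InductionParams
from .pk_engine import DoseRegimen, Physiology, build_model, simulate

__all__ = [
    "StaticInputs",
    "gut_concentration",
    "hepatic_inlet_unbound",
    "induction_c_term",
    "static_aucr",
    "rifampicin_static_inputs",
    "invert_fm_static",
    "static_vs_table",
]


class StaticInputs(BaseModel):
    """Perpetrator exposure terms and victim fractions for the static equation.

    ``a_*``/``b_*`` are the reversible/time-dependent inhibition
    multipliers of the guidance equation, fixed at 1 for a pure inducer;
    ``d_factor`` is the induction scaling factor d (guidance default 1).
    """

    model_config = ConfigDict(extra="forbid")

    i_gut: float = Field(ge=0)  # µM
    i_h: float = Field(ge=0)  # µM, unbound hepatic inlet
    fa: float = Field(default=1.0, gt=0, le=1)
    ka: float = Field(default=0.0, ge=0)  # 1/h
    d_factor: float = Field(default=1.0, ge=0)
    fm: float = Field(ge=0, le=1)
    fg: float = Field(gt=0, le=1)
    a_gut: float = 1.0
    a_hep: float = 1.0
    b_gut: float = 1.0
    b_hep: float = 1.0


def gut_concentration(dose: float, mw: float) -> float:
    """I_gut = dose / 250 mL, in µM (guidance convention)."""
    if mw <= 0:
        raise ValueError("molecular weight must be positive")
    if dose < 0:
        raise ValueError("dose must be non-negative")
    return dose / mw / 0.25 * 1000.0


def hepatic_inlet_unbound(
    cmax: float,
    dose: float,
    fa: float,
    fg: float,
    ka: float,
    qh: float,
    rbp: float,
    fup: float,
    mw: float,
) -> float:
    """Unbound hepatic inlet concentration in µM.

    ``fup*(Cmax + Fa*Fg*ka*Dose/(Qh*Rb))`` with Cmax in mg/L, dose in mg,
    ka in 1/h, Qh in L/h (blood), Rb the blood/plasma ratio.
    """
    inlet_plasma = cmax + fa * fg * ka * dose / qh / rbp
    return fup * inlet_plasma / mw * 1000.0


def induction_c_term(i_um: float, induction: InductionParams, d_factor: float = 1.0) -> float:
    """Guidance induction term C = 1 + d*emax*I/(I + ec50)."""
    if i_um < 0:
        raise ValueError("concentration must be non-negative")
    return 1.0 + d_factor * induction.emax * i_um / (i_um + induction.ec50)


def static_aucr(inputs: StaticInputs, induction: InductionParams) -> float:
    """Predicted AUC ratio from the mechanistic static equation."""
    cg = induction_c_term(inputs.i_gut, induction, inputs.d_factor)
    ch = induction_c_term(inputs.i_h, induction, inputs.d_factor)
    gut = 1.0 / (inputs.a_gut * inputs.b_gut * cg * (1.0 - inputs.fg) + inputs.fg)
    hep = 1.0 / (inputs.a_hep * inputs.b_hep * ch * inputs.fm + (1.0 - inputs.fm))
    return gut * hep


def rifampicin_static_inputs(
    perpetrator: DrugModel,
    phys: Optional[Physiology] = None,
    fm: float = 1.0,
    fg: float = 1.0,
    cmax_ss: Optional[float] = None,
    d_factor: float = 1.0,
    n_washin_doses: int = 7,
) -> StaticInputs:
    """Assemble static-model inputs for a 600 mg QD rifampicin perpetrator.

    ``cmax_ss`` (mg/L) defaults to the simulated day-``n_washin_doses``
    peak with autoinduction on; pass the packaged table's printed steady-state value for a
    simulation-free, fully reproducible computation.
    """
    phys = phys or Physiology()
    model = build_model(perpetrator, phys)
    ab = model.absorption
    dose = 600.0
    if cmax_ss is None:
        regimen = DoseRegimen(route="oral", dose=dose, n_doses=n_washin_doses, interval=24.0)
        profile = simulate(model, regimen, t_end=n_washin_doses * 24.0)
        last = profile.slice((n_washin_doses - 1) * 24.0)
        cmax_ss = float(max(last.concentrations))
    comp = perpetrator.compound
    i_gut = gut_concentration(dose, comp.molecular_weight)
    fa = ab.fraction_absorbed_closed_form()
    i_h = hepatic_inlet_unbound(
        cmax=cmax_ss,
        dose=dose,
        fa=fa,
        fg=perpetrator.clearance.fg,
        ka=ab.ka,
        qh=phys.hepatic_blood_flow_qh,
        rbp=comp.rbp,
        fup=comp.fup,
        mw=comp.molecular_weight,
    )
    return StaticInputs(i_gut=i_gut, i_h=i_h, fa=fa, ka=ab.ka, d_factor=d_factor, fm=fm, fg=fg)


def invert_fm_static(
    target_aucr: float,
    inputs: StaticInputs,
    induction: InductionParams,
    tol: float = 1e-10,
) -> float:
    """Recover the fm that reproduces a static AUCR at fixed fg (bisection).

    The hepatic term is strictly decreasing in fm, so the solution is
    unique when the target lies between the fm=1 and fm=0 values.
    """

    def f(fm: float) -> float:
        return static_aucr(inputs.model_copy(update={"fm": fm}), induction)

    lo, hi = 0.0, 1.0
    if not (f(1.0) - 1e-12 <= target_aucr <= f(0.0) + 1e-12):
        raise ValueError(
            f"target {target_aucr:.4g} outside attainable range [{f(1.0):.4g}, {f(0.0):.4g}]"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) >= target_aucr:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def static_vs_table(
    records: Sequence[DDIRecord],
    victims: Sequence[Tuple[str, float, float]],
    inputs: StaticInputs,
    induction: InductionParams,
) -> pd.DataFrame:
    """Static AUCR predictions for user-supplied (name, fm, fg) victims,
    joined against the printed static column for qualitative comparison.

    The victims' fm/fg are supplied by the caller (the source models behind
    the printed column are not distributed), so agreement is illustrative
    rather than a reproduction.
    """
    printed = {r.victim: r.predicted_aucr_static for r in records}
    rows = []
    for name, fm, fg in victims:
        pred = static_aucr(inputs.model_copy(update={"fm": fm, "fg": fg}), induction)
        rows.append(
            {
                "victim": name,
                "fm": fm,
                "fg": fg,
                "static_aucr": pred,
                "printed_static_aucr": printed.get(name),
            }
        )
    return pd.DataFrame(rows)
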