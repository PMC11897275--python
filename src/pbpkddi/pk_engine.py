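"""Deterministic ODE simulation of drug disposition with transit-chain absorption.

Model topology
--------------
Each drug is a 1–3 compartment disposition model (central volume ``vc``,
first-order inter-compartment transfer ``k12/k21`` and optionally
``k13/k31``) fed by either intravenous input (bolus or zero-order
infusion) or a compartmental-absorption-transit (CAT) chain: ``n`` serial
gut compartments with transit rate ``kt = n / small_intestine_transit_time``
and first-order absorption ``ka = 2*Peff/intestine_radius`` from each.
Drug leaving the last transit compartment is counted as unabsorbed.

Elimination from the central compartment is partitioned into a hepatic
CYP3A4 pathway (linear clearance by default, optional Michaelis–Menten
with Vmax calibrated so the sub-Km clearance equals the configured linear
value), a lumped non-CYP3A4 hepatic clearance, and renal clearance.  All
clearances are plasma-referenced; the blood/plasma ratio is carried for
the static model's hepatic-inlet term only.

When CYP3A4 induction is active (see :mod:`pbpkddi.enzyme_induction`) the
hepatic CYP3A4 pathway scales with the relative liver enzyme amount and
drug absorbed from gut compartment *i* is subject to first-pass
extraction ``1 - fg_i'`` with ``fg_i' = fg / (fg + (1-fg)*E_gut_i)``.

Numerics: LSODA with ``rtol=1e-8`` / ``atol=1e-10`` by default, dose
events handled by integration restarts, fixed output grid (default
0.05 h).  Mass balance (dose in = amount in body + eliminated +
unabsorbed) is verified to 0.1% at every output point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.integrate import solve_ivp

from .data_store import DrugModel, DispositionParams

__all__ = [
    "Physiology",
    "DoseRegimen",
    "ConcTimeProfile",
    "CompiledModel",
    "SimulationResult",
    "DoseEvent",
    "SolverError",
    "build_model",
    "simulate",
    "analytic_two_compartment_iv",
    "oral_absorption_chain",
    "AbsorptionSubmodel",
    "fraction_absorbed",
    "fa_transit_chain_closed_form",
]

ELIMINATION_ROUTES = ("metabolic_cyp3a4", "metabolic_other", "renal", "unabsorbed")


class SolverError(RuntimeError):
    """ODE integration failed or produced an invalid state."""


class Physiology(BaseModel):
    """Subject/system parameters (standard adult defaults).

    ``hepatic_blood_flow_qh`` and ``enterocyte_blood_flow_qent`` are blood
    flows (L/h) used by the static model and the gut induction driver;
    ``gfr`` (L/h) anchors renal clearance as ``fup * GFR``.
    """

    model_config = ConfigDict(extra="forbid")

    body_weight: float = Field(default=70.0, gt=0)
    hepatic_blood_flow_qh: float = Field(default=97.0, gt=0)
    enterocyte_blood_flow_qent: float = Field(default=18.0, gt=0)
    gfr: float = Field(default=7.2, gt=0)
    n_gut_compartments: int = Field(default=7, ge=1)
    small_intestine_transit_time: float = Field(default=3.32, gt=0)
    intestine_radius: float = Field(default=1.75, gt=0)  # cm


class DoseRegimen(BaseModel):
    """Dosing schedule for one drug."""

    model_config = ConfigDict(extra="forbid")

    route: Literal["iv_bolus", "iv_infusion", "oral"]
    dose: float = Field(ge=0)  # mg
    n_doses: int = Field(default=1, ge=1)
    interval: Optional[float] = Field(default=None, gt=0)  # h
    infusion_duration: Optional[float] = Field(default=None, gt=0)  # h
    start_time: float = Field(default=0.0, ge=0)

    @model_validator(mode="after")
    def _consistent(self) -> "DoseRegimen":
        if self.n_doses > 1 and self.interval is None:
            raise ValueError("interval is required when n_doses > 1")
        if self.route == "iv_infusion" and self.infusion_duration is None:
            raise ValueError("infusion_duration is required for iv_infusion")
        return self

    def dose_times(self) -> List[float]:
        step = self.interval or 0.0
        return [self.start_time + k * step for k in range(self.n_doses)]


@dataclass
class ConcTimeProfile:
    """Central-compartment plasma concentrations on a strictly increasing grid.

    ``dose_events`` is a list of ``(time_h, amount_mg, route)``;
    ``cumulative_eliminated`` maps elimination route to the total mg
    eliminated by the end of the simulation.
    """

    times: Sequence[float]
    concentrations: Sequence[float]
    dose_events: List[Tuple[float, float, str]] = field(default_factory=list)
    cumulative_eliminated: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.shape != self.concentrations.shape:
            raise ValueError("times and concentrations must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("profile time grid must be strictly increasing")

    @property
    def total_dose(self) -> float:
        return float(sum(a for _, a, _ in self.dose_events))

    def slice(self, t0: float, t1: Optional[float] = None, rebase: bool = False) -> "ConcTimeProfile":
        """Sub-profile on [t0, t1]; optionally rebase the grid to start at 0."""
        t1 = self.times[-1] if t1 is None else t1
        mask = (self.times >= t0 - 1e-9) & (self.times <= t1 + 1e-9)
        times = self.times[mask]
        return ConcTimeProfile(
            times=times - (t0 if rebase else 0.0),
            concentrations=self.concentrations[mask],
            dose_events=[
                (t - (t0 if rebase else 0.0), a, r)
                for t, a, r in self.dose_events
                if t0 - 1e-9 <= t <= t1 + 1e-9
            ],
            cumulative_eliminated=dict(self.cumulative_eliminated),
        )


@dataclass(frozen=True)
class AbsorptionSubmodel:
    """Transit-chain absorption constants (all 1/h) for one compound."""

    n: int
    kt: float  # transit rate between gut compartments
    ka: float  # first-order absorption rate from each compartment
    dissolution_enabled: bool = False
    k_diss: float = 0.0  # first-order dissolution rate, 1/h

    def fraction_absorbed_closed_form(self) -> float:
        """Fa for the pure first-order chain (dissolution disabled)."""
        return fa_transit_chain_closed_form(self.ka, self.kt, self.n)


def fa_transit_chain_closed_form(ka: float, kt: float, n: int) -> float:
    """Fa = 1 - (kt/(kt+ka))**n for an n-compartment transit chain."""
    if ka <= 0:
        return 0.0
    return 1.0 - (kt / (kt + ka)) ** n


def oral_absorption_chain(
    compound,
    phys: Physiology,
    dissolution_enabled: bool = False,
) -> AbsorptionSubmodel:
    """Build the transit-chain absorption submodel for a compound.

    ``ka = 2*Peff/R`` converts the effective permeability (stored in units
    of 1e-4 cm/s) and intestinal radius (cm) to a first-order absorption
    rate in 1/h.  The optional dissolution limitation is a Noyes–Whitney
    style first-order rate from solubility and particle radius; it is
    disabled by default (rifampicin's 1.1 mg/mL solubility is not limiting
    at the simulated doses).
    """
    peff_cm_s = compound.peff * 1e-4
    ka = 2.0 * peff_cm_s / phys.intestine_radius * 3600.0
    kt = phys.n_gut_compartments / phys.small_intestine_transit_time
    k_diss = 0.0
    if dissolution_enabled:
        # dC/dt = -k_diss*C with k_diss = 3*D*Cs/(rho*r^2); D = 5e-6 cm^2/s,
        # rho = 1.2 g/cm^3, Cs in g/cm^3, r in cm.  Stylized sink-condition rate.
        diffusivity = 5e-6  # cm^2/s
        density = 1.2  # g/cm^3
        cs = compound.aqueous_solubility * 1e-3  # mg/mL -> g/cm^3
        r_cm = compound.particle_radius * 1e-4
        k_diss = 3.0 * diffusivity * cs / (density * r_cm**2) * 3600.0
    return AbsorptionSubmodel(
        n=phys.n_gut_compartments,
        kt=kt,
        ka=ka,
        dissolution_enabled=dissolution_enabled,
        k_diss=k_diss,
    )


@dataclass
class CompiledModel:
    """One drug's parameters scaled to absolute units (mg, L, h) and bound to
    a physiology, ready for simulation."""

    drug: DrugModel
    phys: Physiology
    vc: float  # L
    k12: float
    k21: float
    k13: float
    k31: float
    n_periph: int
    cl_cyp3a4: float  # L/h, uninduced baseline
    cl_other: float  # L/h
    cl_renal: float  # L/h
    mm_mode: bool
    vmax: float  # mg/h (MM mode; calibrated as cl_cyp3a4 * km)
    km: float  # mg/L
    fg: float
    absorption: AbsorptionSubmodel

    @property
    def cl_total_linear(self) -> float:
        """Total baseline plasma clearance in the linear regime, L/h."""
        return self.cl_cyp3a4 + self.cl_other + self.cl_renal


def build_model(
    drug: DrugModel,
    phys: Optional[Physiology] = None,
    dissolution_enabled: bool = False,
) -> CompiledModel:
    """Scale a validated :class:`DrugModel` to absolute units for a subject.

    Per-kg volumes and clearances are multiplied by body weight; the
    Michaelis–Menten Vmax (when that mode is selected) is calibrated so
    that the uninduced clearance at sub-Km concentrations equals the
    configured ``cl_cyp3a4_hepatic``.
    """
    phys = phys or Physiology()
    bw = phys.body_weight
    disp = drug.disposition
    clr = drug.clearance
    mm = clr.vmax_mode == "michaelis_menten"
    if mm and clr.km is None:
        raise ValueError("michaelis_menten mode requires km")
    cl_cyp3a4 = clr.cl_cyp3a4_hepatic * bw
    return CompiledModel(
        drug=drug,
        phys=phys,
        vc=disp.vc * bw,
        k12=disp.k12,
        k21=disp.k21,
        k13=disp.k13 or 0.0,
        k31=disp.k31 or 0.0,
        n_periph=(1 if disp.k12 > 0 or disp.k21 > 0 else 0)
        + (1 if disp.k13 is not None else 0),
        cl_cyp3a4=cl_cyp3a4,
        cl_other=clr.cl_other_hepatic * bw,
        cl_renal=clr.cl_renal * bw,
        mm_mode=mm,
        vmax=cl_cyp3a4 * (clr.km or 0.0),
        km=clr.km or 0.0,
        fg=clr.fg,
        absorption=oral_absorption_chain(drug.compound, phys, dissolution_enabled),
    )


@dataclass(frozen=True)
class DoseEvent:
    time: float
    drug_index: int
    route: str
    amount: float
    duration: float = 0.0  # infusions only


class _DrugBlock:
    """State-vector layout for one drug within the coupled ODE system."""

    def __init__(self, offset: int, n_gut: int, n_periph: int, dissolution: bool):
        self.n_gut = n_gut
        self.dissolution = dissolution
        i = offset
        self.gut = slice(i, i + n_gut)
        i += n_gut
        if dissolution:
            self.gut_solid = slice(i, i + n_gut)
            i += n_gut
        else:
            self.gut_solid = None
        self.central = i
        i += 1
        self.periph = slice(i, i + n_periph)
        i += n_periph
        self.cum_gut_met = i
        self.cum_hep_cyp3a4 = i + 1
        self.cum_other = i + 2
        self.cum_renal = i + 3
        self.cum_unabs = i + 4
        self.end = i + 5


class ODESystem:
    """Coupled ODE system for 1–2 drugs with optional CYP3A4 enzyme turnover.

    ``inducer_index`` names the drug whose unbound concentration drives
    enzyme synthesis; ``induced`` flags the drugs whose CYP3A4 pathway and
    gut extraction respond to the enzyme state (the inducer itself only
    when autoinduction is on).
    """

    def __init__(
        self,
        models: Sequence[CompiledModel],
        inducer_index: Optional[int] = None,
        induced: Optional[Sequence[bool]] = None,
    ):
        self.models = list(models)
        self.phys = self.models[0].phys
        self.inducer_index = inducer_index
        self.induced = list(induced) if induced is not None else [False] * len(models)
        if inducer_index is not None and models[inducer_index].drug.induction is None:
            raise ValueError("designated inducer has no induction parameters")
        self.n_gut = self.phys.n_gut_compartments
        self.blocks: List[_DrugBlock] = []
        offset = 0
        for m in self.models:
            blk = _DrugBlock(offset, self.n_gut, m.n_periph, m.absorption.dissolution_enabled)
            self.blocks.append(blk)
            offset = blk.end
        self.enzyme_active = inducer_index is not None and any(self.induced)
        if self.enzyme_active:
            self.e_liver = offset
            self.e_gut = slice(offset + 1, offset + 1 + self.n_gut)
            offset += 1 + self.n_gut
        self.n_states = offset

    def initial_state(self) -> np.ndarray:
        y0 = np.zeros(self.n_states)
        if self.enzyme_active:
            y0[self.e_liver] = 1.0
            y0[self.e_gut] = 1.0
        return y0

    def rhs(self, t: float, y: np.ndarray, infusion_rates: np.ndarray) -> np.ndarray:
        dy = np.zeros_like(y)
        if self.enzyme_active:
            e_liver = y[self.e_liver]
            e_gut = y[self.e_gut]
        for i, (m, blk) in enumerate(zip(self.models, self.blocks)):
            ab = m.absorption
            gut = y[blk.gut]
            a_c = y[blk.central]
            conc = a_c / m.vc
            # transit + absorption
            d_gut = -(ab.kt + ab.ka) * gut
            d_gut[1:] += ab.kt * gut[:-1]
            if blk.gut_solid is not None:
                solid = y[blk.gut_solid]
                d_solid = -(ab.kt + ab.k_diss) * solid
                d_solid[1:] += ab.kt * solid[:-1]
                d_gut += ab.k_diss * solid
                dy[blk.gut_solid] = d_solid
                unabs_flux = ab.kt * (gut[-1] + solid[-1])
            else:
                unabs_flux = ab.kt * gut[-1]
            abs_flux = ab.ka * gut
            if self.induced[i] and m.fg < 1.0:
                fg_prime = m.fg / (m.fg + (1.0 - m.fg) * e_gut)
            else:
                fg_prime = np.full(self.n_gut, 1.0) if m.fg >= 1.0 else np.full(self.n_gut, m.fg)
            to_central = float(abs_flux @ fg_prime)
            gut_met_flux = float(abs_flux.sum()) - to_central
            # hepatic + renal elimination
            e_l = e_liver if (self.induced[i] and self.enzyme_active) else 1.0
            if m.mm_mode:
                hep_cyp = m.vmax * e_l * conc / (m.km + conc) if conc > 0 else 0.0
            else:
                hep_cyp = m.cl_cyp3a4 * e_l * conc
            hep_other = m.cl_other * conc
            renal = m.cl_renal * conc
            d_central = to_central + infusion_rates[i] - hep_cyp - hep_other - renal
            # peripheral exchange
            if m.n_periph >= 1:
                a_p = y[blk.periph]
                d_p = np.empty(m.n_periph)
                d_central += -m.k12 * a_c + m.k21 * a_p[0]
                d_p[0] = m.k12 * a_c - m.k21 * a_p[0]
                if m.n_periph == 2:
                    d_central += -m.k13 * a_c + m.k31 * a_p[1]
                    d_p[1] = m.k13 * a_c - m.k31 * a_p[1]
                dy[blk.periph] = d_p
            dy[blk.gut] = d_gut
            dy[blk.central] = d_central
            dy[blk.cum_gut_met] = gut_met_flux
            dy[blk.cum_hep_cyp3a4] = hep_cyp
            dy[blk.cum_other] = hep_other
            dy[blk.cum_renal] = renal
            dy[blk.cum_unabs] = unabs_flux
        if self.enzyme_active:
            perp = self.models[self.inducer_index]
            pblk = self.blocks[self.inducer_index]
            ind = perp.drug.induction
            mw = perp.drug.compound.molecular_weight
            # liver driver: unbound central plasma concentration, µM
            cu = perp.drug.compound.fup * (y[pblk.central] / perp.vc) / mw * 1000.0
            cu = max(cu, 0.0)
            drive_l = 1.0 + ind.emax * cu / (ind.ec50 + cu)
            dy[self.e_liver] = ind.kdeg_liver * (drive_l - y[self.e_liver])
            # gut driver: enterocyte surrogate ka*A_gut_i/Qent, total, µM
            c_ent = (
                perp.absorption.ka
                * np.maximum(y[pblk.gut], 0.0)
                / self.phys.enterocyte_blood_flow_qent
                / mw
                * 1000.0
            )
            drive_g = 1.0 + ind.emax * c_ent / (ind.ec50 + c_ent)
            dy[self.e_gut] = ind.kdeg_gut * (drive_g - y[self.e_gut])
        return dy

    # ------------------------------------------------------------------
    def run(
        self,
        events: Sequence[DoseEvent],
        t_end: float,
        dt_out: float = 0.05,
        rtol: float = 1e-8,
        atol: float = 1e-10,
        method: str = "LSODA",
    ) -> "SimulationResult":
        """Integrate the system with dose-event restarts on a fixed output grid."""
        if dt_out <= 0:
            raise ValueError("dt_out must be positive")
        events = sorted(events, key=lambda e: e.time)
        for e in events:
            if e.time > t_end:
                raise ValueError("t_end does not cover all doses")
        n_grid = int(round(t_end / dt_out))
        grid = np.linspace(0.0, n_grid * dt_out, n_grid + 1)
        if grid[-1] < t_end - 1e-12:
            grid = np.append(grid, t_end)
        breaks = {0.0, float(t_end)}
        for e in events:
            breaks.add(float(e.time))
            if e.route == "iv_infusion":
                breaks.add(float(min(e.time + e.duration, t_end)))
        breaks = sorted(breaks)

        y = self.initial_state()
        times_out = [0.0]
        states_out = [y.copy()]
        for ta, tb in zip(breaks[:-1], breaks[1:]):
            # bolus/oral doses land at segment start
            for e in events:
                if abs(e.time - ta) < 1e-12 and e.route != "iv_infusion":
                    blk = self.blocks[e.drug_index]
                    if e.route == "iv_bolus":
                        y[blk.central] += e.amount
                    elif e.route == "oral":
                        if blk.gut_solid is not None:
                            y[blk.gut_solid.start] += e.amount
                        else:
                            y[blk.gut.start] += e.amount
                    else:
                        raise ValueError(f"unknown route {e.route!r}")
            if times_out and abs(times_out[-1] - ta) < 1e-12:
                # record the post-dose state at the event time (C0 convention)
                states_out[-1] = y.copy()
            rates = np.zeros(len(self.models))
            for e in events:
                if e.route == "iv_infusion" and e.time - 1e-12 <= ta < e.time + e.duration - 1e-12:
                    rates[e.drug_index] += e.amount / e.duration
            t_eval = grid[(grid > ta + 1e-12) & (grid <= tb + 1e-12)]
            if len(t_eval) == 0 or t_eval[-1] < tb - 1e-12:
                t_eval = np.append(t_eval, tb)
            sol = solve_ivp(
                self.rhs,
                (ta, tb),
                y,
                method=method,
                t_eval=t_eval,
                rtol=rtol,
                atol=atol,
                args=(rates,),
            )
            if not sol.success:
                raise SolverError(f"integration failed on [{ta}, {tb}]: {sol.message}")
            for k in range(sol.t.size):
                if sol.t[k] > times_out[-1] + 1e-12:
                    times_out.append(float(sol.t[k]))
                    states_out.append(sol.y[:, k].copy())
            y = sol.y[:, -1].copy()

        times = np.array(times_out)
        states = np.vstack(states_out)
        # solver noise below tolerance is clipped; anything larger is an error
        floor = -max(1e-6, 100.0 * atol)
        scale = max(1.0, float(np.nanmax(np.abs(states))))
        if states.min() < floor * scale:
            raise SolverError(f"negative state beyond tolerance: min={states.min():.3e}")
        np.clip(states, 0.0, None, out=states)
        return SimulationResult(times=times, states=states, system=self, events=list(events), t_end=t_end)


@dataclass
class SimulationResult:
    """Raw trajectory of a coupled simulation plus bookkeeping accessors."""

    times: np.ndarray
    states: np.ndarray  # (n_t, n_states)
    system: ODESystem
    events: List[DoseEvent]
    t_end: float

    def concentrations(self, drug_index: int = 0) -> np.ndarray:
        blk = self.system.blocks[drug_index]
        return self.states[:, blk.central] / self.system.models[drug_index].vc

    def profile(self, drug_index: int = 0) -> ConcTimeProfile:
        blk = self.system.blocks[drug_index]
        final = self.states[-1]
        return ConcTimeProfile(
            times=self.times,
            concentrations=self.concentrations(drug_index),
            dose_events=[
                (e.time, e.amount, e.route)
                for e in self.events
                if e.drug_index == drug_index
            ],
            cumulative_eliminated={
                "metabolic_cyp3a4": float(final[blk.cum_hep_cyp3a4] + final[blk.cum_gut_met]),
                "metabolic_other": float(final[blk.cum_other]),
                "renal": float(final[blk.cum_renal]),
                "unabsorbed": float(final[blk.cum_unabs]),
            },
        )

    def dosed_in(self, drug_index: int, t: np.ndarray) -> np.ndarray:
        """Cumulative administered amount (mg) at each time, infusions pro-rated."""
        total = np.zeros_like(t, dtype=float)
        for e in self.events:
            if e.drug_index != drug_index:
                continue
            if e.route == "iv_infusion":
                total += e.amount / e.duration * np.clip(t - e.time, 0.0, e.duration)
            else:
                total += np.where(t >= e.time - 1e-12, e.amount, 0.0)
        return total

    def amount_in_body(self, drug_index: int) -> np.ndarray:
        blk = self.system.blocks[drug_index]
        amount = self.states[:, blk.gut].sum(axis=1) + self.states[:, blk.central]
        if blk.gut_solid is not None:
            amount += self.states[:, blk.gut_solid].sum(axis=1)
        if self.system.models[drug_index].n_periph:
            amount += self.states[:, blk.periph].sum(axis=1)
        return amount

    def mass_balance_error(self, drug_index: int = 0) -> float:
        """Max relative mass-balance defect over the output grid."""
        blk = self.system.blocks[drug_index]
        eliminated = self.states[
            :, [blk.cum_gut_met, blk.cum_hep_cyp3a4, blk.cum_other, blk.cum_renal, blk.cum_unabs]
        ].sum(axis=1)
        accounted = self.amount_in_body(drug_index) + eliminated
        dosed = self.dosed_in(drug_index, self.times)
        ref = max(float(dosed.max()), 1e-12)
        return float(np.max(np.abs(accounted - dosed)) / ref)

    def enzyme_liver(self) -> np.ndarray:
        if not self.system.enzyme_active:
            return np.ones_like(self.times)
        return self.states[:, self.system.e_liver]

    def enzyme_gut(self) -> np.ndarray:
        if not self.system.enzyme_active:
            return np.ones((self.times.size, self.system.n_gut))
        return self.states[:, self.system.e_gut]


def _regimen_events(regimen: DoseRegimen, drug_index: int = 0) -> List[DoseEvent]:
    events = []
    for t in regimen.dose_times():
        events.append(
            DoseEvent(
                time=t,
                drug_index=drug_index,
                route=regimen.route,
                amount=regimen.dose,
                duration=regimen.infusion_duration or 0.0,
            )
        )
    return events


def simulate(
    model: CompiledModel,
    regimen: DoseRegimen,
    t_end: float,
    dt_out: float = 0.05,
    autoinduction: Optional[bool] = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    check_mass_balance: bool = True,
) -> ConcTimeProfile:
    """Simulate one drug under a dosing regimen and return its plasma profile.

    ``autoinduction`` couples the drug's own CYP3A4 pathway to the enzyme
    turnover it induces; by default it is enabled for multi-dose regimens
    of a perpetrator (an inducer accelerating its own metabolism) and
    disabled for single doses.
    """
    if autoinduction is None:
        autoinduction = model.drug.induction is not None and regimen.n_doses > 1
    if autoinduction and model.drug.induction is None:
        raise ValueError("autoinduction requested but drug has no induction parameters")
    system = ODESystem(
        [model],
        inducer_index=0 if autoinduction else None,
        induced=[autoinduction],
    )
    result = system.run(
        _regimen_events(regimen), t_end=t_end, dt_out=dt_out, rtol=rtol, atol=atol
    )
    if check_mass_balance and regimen.dose > 0:
        err = result.mass_balance_error(0)
        if err > 1e-3:
            raise SolverError(f"mass balance violated: relative error {err:.2e}")
    profile = result.profile(0)
    profile._result = result  # stash for diagnostics (fraction_absorbed etc.)
    return profile


def simulate_raw(
    model: CompiledModel,
    regimen: DoseRegimen,
    t_end: float,
    **kwargs,
) -> SimulationResult:
    """Like :func:`simulate` but returning the full :class:`SimulationResult`."""
    autoinduction = kwargs.pop("autoinduction", None)
    if autoinduction is None:
        autoinduction = model.drug.induction is not None and regimen.n_doses > 1
    system = ODESystem(
        [model], inducer_index=0 if autoinduction else None, induced=[autoinduction]
    )
    return system.run(_regimen_events(regimen), t_end=t_end, **kwargs)


def analytic_two_compartment_iv(
    disp: DispositionParams,
    cl_total: float,
    dose: float,
    bw: float,
    times: Sequence[float],
) -> ConcTimeProfile:
    """Closed-form bi-exponential solution for an IV bolus, linear clearance.

    Macro-constants from ``k10 = CL/(vc*bw)``, ``k12``, ``k21``; serves as
    an independent oracle for the ODE engine.  Degenerates exactly to the
    one-compartment mono-exponential when ``k12 = k21 = 0``.
    """
    if disp.k13 is not None:
        raise ValueError("closed form implemented for <= 2 compartments")
    times = np.asarray(times, dtype=float)
    vc = disp.vc * bw
    k10 = cl_total / vc
    k12, k21 = disp.k12, disp.k21
    c0 = dose / vc
    s = k10 + k12 + k21
    disc = math.sqrt(max(s * s - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    if alpha == beta:  # k12=k21=0 degenerate: C = C0*exp(-k10 t)
        conc = c0 * np.exp(-k10 * times)
    else:
        a = c0 * (alpha - k21) / (alpha - beta)
        b = c0 * (k21 - beta) / (alpha - beta)
        conc = a * np.exp(-alpha * times) + b * np.exp(-beta * times)
    return ConcTimeProfile(
        times=times,
        concentrations=conc,
        dose_events=[(float(times[0]), dose, "iv_bolus")],
        cumulative_eliminated={},
    )


def fraction_absorbed(profile: ConcTimeProfile) -> float:
    """Fa = 1 - unabsorbed/dose from an oral simulation's bookkeeping."""
    oral_dose = sum(a for _, a, r in profile.dose_events if r == "oral")
    if oral_dose <= 0:
        raise ValueError("fraction_absorbed requires an oral simulation")
    unabs = profile.cumulative_eliminated.get("unabsorbed")
    if unabs is None:
        raise ValueError("profile lacks unabsorbed bookkeeping")
    return float(np.clip(1.0 - unabs / oral_dose, 0.0, 1.0))
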