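"""Drug-model configuration I/O, packaged reference tables, and profile files.

This module owns the validated parameter containers that the rest of the
pipeline consumes:

* :class:`DrugModel` — one compound's physicochemical, disposition,
  clearance and (for perpetrators) CYP3A4-induction parameters.  Internal
  unit convention: amounts in mg, volumes in L, times in h; disposition
  and clearance parameters are per kg body weight and are scaled to
  absolute values at model-build time.  Induction drivers are converted
  to µM via the molecular weight at the point of use.
* Packaged tables: the rifampicin parameter set, the rifampicin PK
  validation table (predicted vs. observed, five regimens), and the
  28-victim interaction table (observed AUC ratios with static-model and
  PBPK predictions).
* Concentration–time profile CSV round-trip (``time_h, conc_mg_per_L``).
"""

from __future__ import annotations

import csv
import hashlib
import json
import math
from importlib import resources
from pathlib import Path
from typing import List, Literal, Optional, Tuple

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "CompoundProperties",
    "DispositionParams",
    "ClearanceParams",
    "InductionParams",
    "DrugModel",
    "DDIRecord",
    "PKValidationRecord",
    "FixtureIntegrityError",
    "load_drug_model",
    "load_rifampicin",
    "load_exemplar_victims",
    "load_ddi_table",
    "load_pk_validation_table",
    "write_profile",
    "read_profile",
    "fixture_checksums",
]


class CompoundProperties(BaseModel):
    """Physicochemical and distribution parameters of one compound.

    Units: ``molecular_weight`` g/mol; ``log_d`` unitless at pH 7.4;
    ``aqueous_solubility`` mg/mL at ``solubility_ref_ph``;
    ``particle_radius`` µm; ``precipitation_time`` s; ``peff`` in units of
    1e-4 cm/s (a value of 1.0 means 1e-4 cm/s); ``rbp`` blood/plasma
    concentration ratio; ``fup`` fraction unbound in plasma.
    """

    model_config = ConfigDict(extra="forbid")

    molecular_weight: float = Field(gt=0)
    log_d: float
    pka_values: List[Tuple[float, Literal["acid", "base"]]] = Field(default_factory=list)
    aqueous_solubility: float = Field(ge=0)
    solubility_ref_ph: float = 6.5
    particle_radius: float = Field(default=25.0, gt=0)
    precipitation_time: float = Field(default=900.0, gt=0)
    peff: float = Field(ge=0)
    rbp: float = Field(gt=0)
    fup: float = Field(gt=0, le=1)


class DispositionParams(BaseModel):
    """Compartmental disposition: central volume (L/kg) and inter-compartment
    first-order transfer rate constants (1/h).  ``k13``/``k31`` add a second
    peripheral compartment and must be given together."""

    model_config = ConfigDict(extra="forbid")

    vc: float = Field(gt=0)
    k12: float = Field(default=0.0, ge=0)
    k21: float = Field(default=0.0, ge=0)
    k13: Optional[float] = Field(default=None, ge=0)
    k31: Optional[float] = Field(default=None, ge=0)

    @model_validator(mode="after")
    def _paired_second_peripheral(self) -> "DispositionParams":
        if (self.k13 is None) != (self.k31 is None):
            raise ValueError("k13 and k31 must both be present or both absent")
        return self


class ClearanceParams(BaseModel):
    """Clearance partition (all L/h/kg, plasma referenced, uninduced baseline).

    ``cl_cyp3a4_hepatic`` is the CYP3A4-mediated hepatic pathway — the one
    scaled by the induction fold.  ``vmax_mode`` selects whether that pathway
    is simulated as a linear clearance or as Michaelis–Menten kinetics with
    ``km`` (mg/L) and a Vmax calibrated to match the linear clearance at
    sub-Km concentrations.  ``fm_cyp3a4`` is the fraction of total clearance
    via CYP3A4 (victims); ``fg`` the baseline intestinal availability.
    """

    model_config = ConfigDict(extra="forbid")

    cl_cyp3a4_hepatic: float = Field(default=0.0, ge=0)
    km: Optional[float] = Field(default=None, gt=0)
    vmax_mode: Literal["linear", "michaelis_menten"] = "linear"
    cl_other_hepatic: float = Field(default=0.0, ge=0)
    cl_renal: float = Field(default=0.0, ge=0)
    fm_cyp3a4: Optional[float] = Field(default=None, ge=0, le=1)
    fg: float = Field(default=1.0, gt=0, le=1)

    @model_validator(mode="after")
    def _km_required_for_mm(self) -> "ClearanceParams":
        if self.vmax_mode == "michaelis_menten" and self.km is None:
            raise ValueError("km is required when vmax_mode = michaelis_menten")
        return self


class InductionParams(BaseModel):
    """Enzyme-induction drive and turnover.

    ``ec50`` (µM, unbound) and ``emax`` parameterize the Emax synthesis
    drive ``1 + emax*Cu/(ec50 + Cu)``.  ``kdeg_liver``/``kdeg_gut`` (1/h)
    are the first-order CYP3A4 degradation rate constants that set the
    onset/offset kinetics of induction (defaults correspond to turnover
    half-lives of about 36 h and 23 h respectively).
    """

    model_config = ConfigDict(extra="forbid")

    ec50: float = Field(gt=0)
    emax: float = Field(ge=0)
    kdeg_liver: float = Field(default=0.019, gt=0)
    kdeg_gut: float = Field(default=0.030, gt=0)


class DrugModel(BaseModel):
    """Full parameterization of one compound — the unit the pipeline simulates."""

    model_config = ConfigDict(extra="forbid")

    name: str = Field(min_length=1)
    description: Optional[str] = None
    compound: CompoundProperties
    disposition: DispositionParams
    clearance: ClearanceParams
    induction: Optional[InductionParams] = None

    @property
    def is_perpetrator(self) -> bool:
        return self.induction is not None


class DDIRecord(BaseModel):
    """One victim drug's observed AUC ratio and model predictions."""

    model_config = ConfigDict(extra="forbid")

    victim: str
    dosing: str
    observed_aucr: float = Field(gt=0)
    predicted_aucr_static: float = Field(gt=0)
    predicted_aucr_pbpk: float = Field(gt=0)
    printed_ratio_static: float = Field(gt=0)
    printed_ratio_pbpk: float = Field(gt=0)

    @property
    def is_steady_state(self) -> bool:
        """Victims evaluated at steady state (QD dosing) rather than single dose."""
        return self.dosing.strip().endswith("QD")


class PKValidationRecord(BaseModel):
    """One predicted/observed PK-parameter pair for a rifampicin regimen."""

    model_config = ConfigDict(extra="forbid")

    regimen_label: str
    parameter: str
    predicted: float = Field(gt=0)
    observed: float = Field(gt=0)
    printed_error_pct: float
    units: str = ""


class FixtureIntegrityError(RuntimeError):
    """A packaged data table does not match its recorded checksum."""


# sha256 of the packaged tables, fixed at release; guards against silent edits.
_CHECKSUMS = {
    "rifampicin.json": "be96dae18873730080ecb92cc41c9ce53d0740b79e444361ff9d90be7b360628",
    "table2_pk_validation.csv": "39c00285204b18fde782c7a22db7eaeba41fa46015cbefb365f92cd9542eb63d",
    "table3_ddi.csv": "346b26fa15bc733b3195015e2fec8e20739083d352be61a635ebc8210bd3d064",
}


def _data_path(name: str) -> Path:
    return Path(str(resources.files("pbpkddi").joinpath("data", name)))


def _read_fixture_bytes(name: str, verify: bool = True) -> bytes:
    raw = _data_path(name).read_bytes()
    if verify and name in _CHECKSUMS:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != _CHECKSUMS[name]:
            raise FixtureIntegrityError(
                f"fixture {name!r} checksum mismatch: {digest} != {_CHECKSUMS[name]}"
            )
    return raw


def fixture_checksums() -> dict:
    """Current sha256 digests of the packaged tables (recomputed from disk)."""
    return {
        name: hashlib.sha256(_data_path(name).read_bytes()).hexdigest()
        for name in _CHECKSUMS
    }


def load_drug_model(path) -> DrugModel:
    """Load and validate a drug-model configuration file (JSON or YAML).

    Raises pydantic ``ValidationError`` naming the offending field on any
    missing field or invariant violation.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in (".yaml", ".yml"):
        payload = yaml.safe_load(text)
    else:
        payload = json.loads(text)
    return DrugModel.model_validate(payload)


def load_rifampicin() -> DrugModel:
    """The packaged rifampicin parameter set (perpetrator model)."""
    payload = json.loads(_read_fixture_bytes("rifampicin.json"))
    return DrugModel.model_validate(payload)


def load_exemplar_victims() -> List[DrugModel]:
    """Three packaged synthetic exemplar victims spanning fm(CYP3A4) 0.25/0.6/0.95.

    These are illustrative parameter sets, not literature models of real drugs.
    """
    names = [
        "synthetic_victim_low_fm.json",
        "synthetic_victim_mid_fm.json",
        "synthetic_victim_high_fm.json",
    ]
    return [load_drug_model(_data_path(n)) for n in names]


def load_ddi_table() -> List[DDIRecord]:
    """The packaged 28-victim interaction table, in table order."""
    raw = _read_fixture_bytes("table3_ddi.csv").decode("utf-8")
    records = []
    for row in csv.DictReader(raw.splitlines()):
        records.append(
            DDIRecord(
                victim=row["victim"],
                dosing=row["dosing"],
                observed_aucr=float(row["observed_aucr"]),
                predicted_aucr_static=float(row["predicted_aucr_static"]),
                predicted_aucr_pbpk=float(row["predicted_aucr_pbpk"]),
                printed_ratio_static=float(row["printed_ratio_static"]),
                printed_ratio_pbpk=float(row["printed_ratio_pbpk"]),
            )
        )
    if len(records) != 28:
        raise FixtureIntegrityError(f"expected 28 victim records, got {len(records)}")
    return records


def load_pk_validation_table() -> List[PKValidationRecord]:
    """The packaged rifampicin predicted-vs-observed PK parameter table."""
    raw = _read_fixture_bytes("table2_pk_validation.csv").decode("utf-8")
    records = []
    for row in csv.DictReader(raw.splitlines()):
        parameter = row["parameter"]
        if row["day"]:
            parameter = f"{parameter}-Day {row['day']}"
        records.append(
            PKValidationRecord(
                regimen_label=row["regimen_label"],
                parameter=parameter,
                predicted=float(row["predicted"]),
                observed=float(row["observed"]),
                printed_error_pct=float(row["printed_error_pct"]),
                units=row["units"],
            )
        )
    return records


def write_profile(profile, path) -> None:
    """Write a concentration–time profile to CSV.

    Columns ``time_h, conc_mg_per_L`` (dot decimal, UTF-8); dose events and
    cumulative elimination bookkeeping are preserved in ``#``-prefixed JSON
    header lines so that :func:`read_profile` restores the full object.
    """
    from .pk_engine import ConcTimeProfile  # local import avoids a cycle

    if not isinstance(profile, ConcTimeProfile):
        raise TypeError("write_profile expects a ConcTimeProfile")
    if len(profile.times) == 0:
        raise ValueError("refusing to write an empty profile")
    path = Path(path)
    meta = {
        "dose_events": [[float(t), float(a), r] for t, a, r in profile.dose_events],
        "cumulative_eliminated": {
            k: float(v) for k, v in profile.cumulative_eliminated.items()
        },
    }
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write("# pbpkddi profile v1\n")
        fh.write("# meta: " + json.dumps(meta) + "\n")
        fh.write("time_h,conc_mg_per_L\n")
        for t, c in zip(profile.times, profile.concentrations):
            fh.write(f"{t:.15g},{c:.15g}\n")


def read_profile(path):
    """Read a profile CSV written by :func:`write_profile` (or any two-column
    ``time_h, conc_mg_per_L`` file with a strictly increasing time grid)."""
    from .pk_engine import ConcTimeProfile

    path = Path(path)
    meta = {"dose_events": [], "cumulative_eliminated": {}}
    times, concs = [], []
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("meta:"):
                    meta = json.loads(body[len("meta:"):])
                continue
            if line.startswith("time_h"):
                continue
            t_str, c_str = line.split(",")
            times.append(float(t_str))
            concs.append(float(c_str))
    if not times:
        raise ValueError(f"no profile rows in {path}")
    if any(b <= a for a, b in zip(times, times[1:])) or any(
        not math.isfinite(t) for t in times
    ):
        raise ValueError("profile time grid must be strictly increasing and finite")
    return ConcTimeProfile(
        times=times,
        concentrations=concs,
        dose_events=[tuple(e) for e in meta.get("dose_events", [])],
        cumulative_eliminated=dict(meta.get("cumulative_eliminated", {})),
    )
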