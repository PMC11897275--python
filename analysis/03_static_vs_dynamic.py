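#!/usr/bin/env python
"""Static-model vs dynamic co-simulation AUCR on the packaged exemplar
victims (synthetic parameter sets spanning fm 0.25/0.6/0.95).

The static equation evaluates the induction term at steady-state
perpetrator exposures held fixed for the whole victim time course, so it
systematically predicts deeper induction (smaller AUCR) than the dynamic
model.  Writes results/static_vs_dynamic.csv."""

from pathlib import Path

import pandas as pd

from pbpkddi import data_store, static_model
from pbpkddi.ddi_simulation import default_design, run_ddi
from pbpkddi.pk_engine import Physiology

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rif = data_store.load_rifampicin()
    phys = Physiology()
    design = default_design("100 mg, SD", washin_days=7)
    rows = []
    for victim in data_store.load_exemplar_victims():
        dynamic = run_ddi(victim, rif, design, phys)
        inputs = static_model.rifampicin_static_inputs(
            rif, phys, fm=victim.clearance.fm_cyp3a4, fg=victim.clearance.fg
        )
        rows.append(
            {
                "victim": victim.name,
                "fm": victim.clearance.fm_cyp3a4,
                "fg": victim.clearance.fg,
                "aucr_dynamic": dynamic.aucr,
                "aucr_static": static_model.static_aucr(inputs, rif.induction),
                "cmaxr_dynamic": dynamic.cmaxr,
                "fold_liver_at_dose": dynamic.fold_liver_at_victim_dose,
                "i_h_uM": inputs.i_h,
                "i_gut_uM": inputs.i_gut,
            }
        )
    frame = pd.DataFrame(rows)
    frame["static_overprediction"] = frame.aucr_static <= frame.aucr_dynamic
    RESULTS.mkdir(exist_ok=True)
    frame.to_csv(RESULTS / "static_vs_dynamic.csv", index=False, float_format="%.4g")
    print(frame.to_string(index=False))
    assert frame.static_overprediction.all()
    print("\nStatic AUCR <= dynamic AUCR on every exemplar: the static model "
          "overstates induction-mediated exposure loss.")


if __name__ == "__main__":
    main()
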