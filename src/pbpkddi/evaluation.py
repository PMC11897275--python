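"""Predictive-performance evaluation: fold ratios, two-fold and Guest criteria.

The two-fold criterion accepts a prediction when predicted/observed lies
in the closed interval [0.5, 2].  The Guest criterion tightens the limit
near an observed ratio of 1:

    L = (delta + 2*(R - 1)) / R,   R = max(observed, 1/observed)

and accepts when predicted/observed lies in [1/L, L].  With delta = 1 the
limit degenerates to 1 at R = 1 and approaches 2 as the observed ratio
moves away from unity, so every Guest pass is also a two-fold pass.

``summarize`` applies a criterion over the packaged interaction table and
reports counts and the integer-rounded pass percentage; ratios can be
recomputed from the AUCR columns (``ratio_source="recomputed"``) or taken
from the printed predicted/observed column, which occasionally differs by
rounding of the unprinted source values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Literal, Sequence, Tuple

from pydantic import BaseModel, ConfigDict, Field

from .data_store import DDIRecord

__all__ = [
    "EvalConfig",
    "ConcordanceSummary",
    "fold_ratio",
    "twofold_pass",
    "guest_limit",
    "guest_pass",
    "summarize",
    "plot_concordance",
]


class EvalConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    criterion: Literal["twofold", "guest"] = "twofold"
    guest_delta: float = Field(default=1.0, ge=1.0)
    bounds_inclusive: bool = True
    ratio_source: Literal["recomputed", "printed"] = "recomputed"


@dataclass
class ConcordanceSummary:
    n: int
    n_pass: int
    pct_pass: int  # integer-rounded percentage
    per_record_flags: List[Tuple[str, float, bool]] = field(default_factory=list)


def fold_ratio(predicted: float, observed: float) -> float:
    """predicted/observed; the basic accuracy ratio."""
    if observed <= 0:
        raise ValueError("observed value must be positive")
    return predicted / observed


def twofold_pass(ratio: float, config: EvalConfig | None = None) -> bool:
    """True when the ratio lies within two-fold of unity ([0.5, 2])."""
    config = config or EvalConfig()
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if config.bounds_inclusive:
        return 0.5 <= ratio <= 2.0
    return 0.5 < ratio < 2.0


def guest_limit(observed_ratio: float, delta: float = 1.0) -> float:
    """Observed-ratio-dependent acceptance limit L = (delta + 2(R-1))/R."""
    if observed_ratio <= 0:
        raise ValueError("observed ratio must be positive")
    big_r = max(observed_ratio, 1.0 / observed_ratio)
    return (delta + 2.0 * (big_r - 1.0)) / big_r


def guest_pass(
    predicted: float, observed: float, config: EvalConfig | None = None
) -> bool:
    """Guest criterion: predicted/observed within [1/L, L] of the limit."""
    config = config or EvalConfig(criterion="guest")
    limit = guest_limit(observed, config.guest_delta)
    ratio = fold_ratio(predicted, observed)
    if config.bounds_inclusive:
        return 1.0 / limit <= ratio <= limit
    return 1.0 / limit < ratio < limit


def _record_ratio(record: DDIRecord, column: str, source: str) -> float:
    if source == "printed":
        return (
            record.printed_ratio_static
            if column == "static"
            else record.printed_ratio_pbpk
        )
    predicted = (
        record.predicted_aucr_static
        if column == "static"
        else record.predicted_aucr_pbpk
    )
    return fold_ratio(predicted, record.observed_aucr)


def summarize(
    records: Sequence[DDIRecord],
    model_column: Literal["static", "pbpk"] = "pbpk",
    config: EvalConfig | None = None,
) -> ConcordanceSummary:
    """Apply the configured criterion per record and aggregate."""
    if not records:
        raise ValueError("no records to summarize")
    config = config or EvalConfig()
    flags = []
    for record in records:
        ratio = _record_ratio(record, model_column, config.ratio_source)
        if config.criterion == "twofold":
            ok = twofold_pass(ratio, config)
        else:
            predicted = (
                record.predicted_aucr_static
                if model_column == "static"
                else record.predicted_aucr_pbpk
            )
            ok = guest_pass(predicted, record.observed_aucr, config)
        flags.append((record.victim, ratio, ok))
    n = len(flags)
    n_pass = sum(1 for _, _, ok in flags if ok)
    return ConcordanceSummary(
        n=n,
        n_pass=n_pass,
        pct_pass=round(100.0 * n_pass / n),
        per_record_flags=flags,
    )


def plot_concordance(
    records: Sequence[DDIRecord],
    out_path,
    model_column: Literal["static", "pbpk"] = "pbpk",
    guest_delta: float = 1.0,
):
    """Predicted-vs-observed scatter with unity, two-fold, and Guest bands."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    obs = np.array([r.observed_aucr for r in records])
    pred = np.array(
        [
            r.predicted_aucr_static if model_column == "static" else r.predicted_aucr_pbpk
            for r in records
        ]
    )
    grid = np.logspace(np.log10(0.005), np.log10(3.0), 200)
    limits = np.array([guest_limit(x, guest_delta) for x in grid])
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(grid, grid, "k-", lw=1, label="unity")
    ax.plot(grid, 2 * grid, "k--", lw=0.8, label="2-fold")
    ax.plot(grid, 0.5 * grid, "k--", lw=0.8)
    ax.plot(grid, grid * limits, "k:", lw=0.8, label="Guest limit")
    ax.plot(grid, grid / limits, "k:", lw=0.8)
    ax.plot(obs, pred, "o", mfc="none", color="tab:blue")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("observed AUCR")
    ax.set_ylabel(f"predicted AUCR ({model_column})")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
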