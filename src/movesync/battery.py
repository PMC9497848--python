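"""Assemble the 21-measure synchrony battery for a cohort of dyads.

One row per dyad, one column per measure, exactly the column set used by
the validity statistics. Per-measure failures (e.g. a dyad too short for a
CRQA window) are recorded as NaN and logged, never fatal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import crqa as _crqa
from .datatypes import MEASURE_COLUMNS, DyadTimeSeries
from .global_correlation import compute_cc
from .mutual_information import mutual_information
from .peak_picking import (
    peak_picking,
    sync_frequency,
    sync_mean_r2,
    wclc_rsq_matrix,
    wclr_rsq_matrix,
)
from .surrogate_synchrony import suco, susy
from .windowed_correlation import rmea_wcc, rmea_wclc, wclc_matrix

__all__ = ["BatteryConfig", "measure_battery"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BatteryConfig:
    """Every measure's parameters, at the battery's standard values."""

    rmea_window_s: float = 60.0
    rmea_lag_max_s: float = 5.0
    rmea_increment_s: float = 30.0
    susy_segment_s: float = 30.0
    susy_lag_max_s: float = 5.0
    suco_slope_window_s: float = 3.0
    suco_slope_increment_s: float = 1.0
    pp_window: int = 125
    pp_tau_max: int = 125
    pp_alpha: float = 0.001
    pp_cutoff: float = 0.25
    mi_jackknife_blocks: int = 50
    crqa: _crqa.CrqaParams = field(default_factory=_crqa.CrqaParams)


def _dyad_measures(dyad: DyadTimeSeries, cfg: BatteryConfig) -> dict[str, float]:
    out: dict[str, float] = {c: np.nan for c in MEASURE_COLUMNS}

    def attempt(label: str, fn) -> None:
        try:
            fn()
        except Exception as exc:  # failures degrade to missing values
            log.warning("dyad %s: %s failed: %s", dyad.dyad_id, label, exc)

    def cc() -> None:
        r = compute_cc(dyad)
        out.update(cc_raw=r.raw, cc_abs=r.abs, cc_z=r.z, cc_r2=r.r2)

    def rmea() -> None:
        m = wclc_matrix(dyad, cfg.rmea_window_s, cfg.rmea_lag_max_s,
                        cfg.rmea_increment_s)
        out.update(rmea_wcc=rmea_wcc(m), rmea_wclc=rmea_wclc(m))

    def susy_suco() -> None:
        s = susy(dyad, cfg.susy_segment_s, cfg.susy_lag_max_s)
        out.update(susy_es_abs=s.es_abs, susy_es_noabs=s.es_noabs)
        c = suco(dyad, cfg.suco_slope_window_s, cfg.suco_slope_increment_s,
                 cfg.susy_segment_s)
        out.update(suco_co=c.co, suco_es_abs=c.es_abs, suco_es_co=c.es_co)

    def peaks() -> None:
        for mode, builder in (("wclc", wclc_rsq_matrix), ("wclr", wclr_rsq_matrix)):
            m = builder(dyad, cfg.pp_window, cfg.pp_tau_max, cfg.pp_alpha)
            losi = peak_picking(m, cfg.pp_cutoff)
            out[f"{mode}_pp_f"] = sync_frequency(losi)
            out[f"{mode}_pp_r2"] = sync_mean_r2(losi, m)

    def mi() -> None:
        r = mutual_information(dyad, cfg.mi_jackknife_blocks)
        out.update(mi_raw=r.raw, mi_cor=r.cor, mi_z=r.z)

    def recurrence() -> None:
        r = _crqa.wincrqa(dyad, cfg.crqa)
        out.update(wincrqa_rr=r.rr, wincrqa_det=r.det, wincrqa_entr=r.entr)

    attempt("cc", cc)
    attempt("rmea", rmea)
    attempt("susy/suco", susy_suco)
    attempt("peak picking", peaks)
    attempt("mutual information", mi)
    attempt("wincrqa", recurrence)
    return out


def measure_battery(dyads: list[DyadTimeSeries],
                    cohort: pd.DataFrame | None = None,
                    config: BatteryConfig | None = None) -> pd.DataFrame:
    """Compute all 21 measures for every dyad.

    ``cohort`` (dyad_id, group, phq9, gad7, ...) is merged in when given.
    The computation is deterministic: surrogate ensembles are exhaustive and
    every stochastic step lives in the synthetic generator, not here.
    """
    cfg = config or BatteryConfig()
    rows = []
    for dyad in dyads:
        row = {"dyad_id": dyad.dyad_id}
        row.update(_dyad_measures(dyad, cfg))
        rows.append(row)
    table = pd.DataFrame(rows)
    if cohort is not None:
        table = cohort.merge(table, on="dyad_id", how="right")
    return table
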