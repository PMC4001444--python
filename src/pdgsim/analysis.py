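"""Post-processing of scenario outputs into selection statistics.

The continuous 700-1700 m gradient is split into five 200-m elevational
bands Alt1-Alt5.  For each band the module computes

* ``Cb`` — the response to selection: the change of the mean trait
  (forcing requirement, or budburst date per climatic year) between the
  first adult year of generation G0 and of the final generation, averaged
  over repetitions;
* ``Cw`` — the selection differential: within one generation, the mean
  trait of the survivors at the final adult year minus the mean at entry;
* the phenotypic variance of the trait at the last year of the final
  generation; and the elevational shift of the whole population.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "N_BANDS",
    "BAND_EDGES",
    "band_label",
    "assign_bands",
    "compute_cb_fcrit",
    "compute_cb_tbb",
    "compute_cw",
    "phenotypic_variance",
    "elevational_shift",
    "summary_table",
]

BAND_EDGES = np.array([700.0, 900.0, 1100.0, 1300.0, 1500.0, 1700.0])
N_BANDS = 5


def band_label(band: int) -> str:
    return f"Alt{band}"


def assign_bands(elevation: np.ndarray | float) -> np.ndarray:
    """Band index 1..5 by half-open 200-m intervals; the top edge (1700 m)
    closes the last band."""
    e = np.atleast_1d(np.asarray(elevation, float))
    if np.any(e < BAND_EDGES[0]) or np.any(e > BAND_EDGES[-1]):
        raise ValueError("elevation outside the 700-1700 m gradient")
    band = np.minimum(((e - BAND_EDGES[0]) // 200.0).astype(int) + 1, N_BANDS)
    return band


def _first_last(df: pd.DataFrame, g_first: int | None, g_last: int | None) -> tuple[int, int]:
    gens = np.sort(df["generation"].unique())
    return (
        int(gens[0]) if g_first is None else g_first,
        int(gens[-1]) if g_last is None else g_last,
    )


def compute_cb_fcrit(
    band_stats: pd.DataFrame,
    band: int,
    g_first: int | None = None,
    g_last: int | None = None,
) -> tuple[float, int]:
    """Between-generation response to selection for the forcing requirement.

    Mean over repetitions of (band mean at the first adult year of the last
    generation minus the same at the first generation).  Repetitions where
    the band is empty in either generation are excluded; the repetition
    count actually used is returned with the value.
    """
    g0, g5 = _first_last(band_stats, g_first, g_last)
    sel = band_stats[(band_stats["band"] == band) & (band_stats["n_start"] > 0)]
    a = sel[sel["generation"] == g0].set_index("rep")["mean_fcrit_start"]
    b = sel[sel["generation"] == g5].set_index("rep")["mean_fcrit_start"]
    common = a.index.intersection(b.index)
    deltas = (b.loc[common] - a.loc[common]).dropna()
    if len(deltas) == 0:
        return np.nan, 0
    return float(deltas.mean()), int(len(deltas))


def compute_cb_tbb(
    tbb_stats: pd.DataFrame,
    band: int,
    g_first: int | None = None,
    g_last: int | None = None,
) -> tuple[float, int]:
    """Between-generation change of mean budburst date, averaged over the
    matched climatic years of the repeating sequence and over repetitions."""
    g0, g5 = _first_last(tbb_stats, g_first, g_last)
    sel = tbb_stats[tbb_stats["band"] == band]
    a = sel[sel["generation"] == g0].set_index(["rep", "clim_year"])["mean_tbb"]
    b = sel[sel["generation"] == g5].set_index(["rep", "clim_year"])["mean_tbb"]
    common = a.index.intersection(b.index)
    if len(common) == 0:
        return np.nan, 0
    deltas = b.loc[common] - a.loc[common]
    per_rep = deltas.groupby(level="rep").mean()
    return float(per_rep.mean()), int(len(per_rep))


def compute_cw(
    band_stats: pd.DataFrame, band: int, generation: int = 0
) -> tuple[float, int]:
    """Selection differential within one generation: survivors' mean trait at
    the final adult year minus the cohort mean at entry, averaged over
    repetitions (missing where no survivors)."""
    sel = band_stats[
        (band_stats["band"] == band)
        & (band_stats["generation"] == generation)
        & (band_stats["n_start"] > 0)
        & (band_stats["n_end"] > 0)
    ]
    if len(sel) == 0:
        return np.nan, 0
    deltas = (sel["mean_fcrit_end"] - sel["mean_fcrit_start"]).dropna()
    if len(deltas) == 0:
        return np.nan, 0
    return float(deltas.mean()), int(len(deltas))


def phenotypic_variance(
    band_stats: pd.DataFrame, band: int, generation: int | None = None
) -> float:
    """Mean (over repetitions) sample variance of the trait among survivors at
    the last year of the given (default: final) generation."""
    if generation is None:
        generation = int(band_stats["generation"].max())
    sel = band_stats[
        (band_stats["band"] == band) & (band_stats["generation"] == generation)
    ]["vp_end"].dropna()
    return float(sel.mean()) if len(sel) else np.nan


def variance_of(values: np.ndarray) -> float:
    """Sample variance (ddof=1); NaN for fewer than two values."""
    v = np.asarray(values, float)
    return float(np.var(v, ddof=1)) if v.size >= 2 else np.nan


def elevational_shift(
    pop_stats: pd.DataFrame, g_first: int | None = None, g_last: int | None = None
) -> tuple[float, int]:
    """Mean-elevation change of the whole population between the first and
    last generation, averaged over repetitions."""
    g0, g5 = _first_last(pop_stats, g_first, g_last)
    a = pop_stats[pop_stats["generation"] == g0].set_index("rep")["mean_elev_start"]
    b = pop_stats[pop_stats["generation"] == g5].set_index("rep")["mean_elev_start"]
    common = a.index.intersection(b.index)
    if len(common) == 0:
        return np.nan, 0
    deltas = b.loc[common] - a.loc[common]
    return float(deltas.mean()), int(len(deltas))


def summary_table(band_stats: pd.DataFrame, tbb_stats: pd.DataFrame | None = None) -> pd.DataFrame:
    """Wide per-band summary: Cb, Cw at G0, and final phenotypic variance."""
    rows = []
    for band in range(1, N_BANDS + 1):
        cb, n_cb = compute_cb_fcrit(band_stats, band)
        cw, n_cw = compute_cw(band_stats, band, generation=int(band_stats["generation"].min()) if len(band_stats) else 0)
        vp = phenotypic_variance(band_stats, band)
        row = {"band": band_label(band), "Cb_Fcrit": cb, "n_rep_Cb": n_cb, "Cw_G0": cw, "V_P_final": vp}
        if tbb_stats is not None and len(tbb_stats):
            cb_t, _ = compute_cb_tbb(tbb_stats, band)
            row["Cb_TBB"] = cb_t
        rows.append(row)
    return pd.DataFrame(rows)
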