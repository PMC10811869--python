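"""Attribution of fixed-depth stock error to bulk-density change.

When bulk density changes between samplings, a fixed-depth sample at t1
contains a different mass of soil than at t0; the carbon carried by that
gained or lost soil mass is exactly what the fixed-depth method mis-counts.
Per plot, over the top 30 cm, this module computes

* ``bd_stock_delta`` — the SOC stock in the soil mass gained or lost through
  the bulk-density change, valued at the t1 concentration; and
* ``fd_esm_gap`` — the difference between the t1 fixed-depth and t1 ESM
  stocks (FD - ESM by default, so that both quantities share a sign: both
  negative under loosening, both positive under compaction).

The Pearson correlation between the two measures how much of the FD error is
explained by bulk-density change.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import ProfileSample, ProfileSet
from .stocks import ReferenceMassTable, reference_masses, esm_stock_spline, fd_stock

__all__ = ["bd_stock_delta", "association_r", "association_table"]

_TOL = 1e-9


class UndefinedCorrelationError(ValueError):
    """One of the two variables has zero variance; r is undefined."""


def bd_stock_delta(
    p0: ProfileSample, p1: ProfileSample, depth_limit: float = 30.0
) -> float:
    """SOC stock (Mg C ha^-1) in soil gained/lost via BD change above a depth.

    Sum over layers within the depth limit of
    (rho_t1 - rho_t0) x d x 100 x c_t1 / 1000. Both profiles must share the
    increments covering [0, depth_limit].
    """
    inc0 = [l.increment for l in p0.layers if l.increment.bottom <= depth_limit + _TOL]
    inc1 = [l.increment for l in p1.layers if l.increment.bottom <= depth_limit + _TOL]
    if inc0 != inc1 or not inc0 or abs(inc0[-1].bottom - depth_limit) > _TOL:
        raise ValueError(
            f"profiles for plot {p0.plot} do not share increments covering "
            f"0-{depth_limit:g} cm"
        )
    total = 0.0
    for l0, l1 in zip(p0.layers[: len(inc0)], p1.layers[: len(inc1)]):
        d_rho = l1.bulk_density - l0.bulk_density
        total += d_rho * l0.increment.thickness * 100.0 * l1.c_conc / 1000.0
    return total


def association_r(records: pd.DataFrame) -> float:
    """Pearson r between bd_stock_delta and fd_esm_gap across plots."""
    if len(records) < 3:
        raise ValueError("need at least 3 plots to compute a correlation")
    x = records["bd_stock_delta_MgC_ha"].to_numpy(float)
    y = records["fd_esm_gap_MgC_ha"].to_numpy(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            "zero variance in bd_stock_delta or fd_esm_gap; r is undefined"
        )
    return float(stats.pearsonr(x, y).statistic)


def association_table(
    pset: ProfileSet,
    refs: ReferenceMassTable | None = None,
    depth_limit: float = 30.0,
    orientation: str = "fd_minus_esm",
    treatments: list[str] | None = None,
) -> pd.DataFrame:
    """Per-plot association records over the top ``depth_limit`` cm.

    The gap is t1 FD stock minus t1 spline-ESM stock summed over the ESM
    layers within the depth limit (``orientation="esm_minus_fd"`` flips the
    sign). ``treatments`` restricts the pooled plots (default: all).
    """
    if orientation not in ("fd_minus_esm", "esm_minus_fd"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if refs is None:
        refs = reference_masses(pset)
    rows = []
    for p0, p1 in pset.pairs():
        if treatments is not None and p0.treatment not in treatments:
            continue
        delta = bd_stock_delta(p0, p1, depth_limit=depth_limit)
        fd_sum = sum(
            fd_stock(l) for l in p1.layers if l.increment.bottom <= depth_limit + _TOL
        )
        # extrapolation and spline overshoot only affect layers deeper than
        # depth_limit, which are discarded here; allow and silence them
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            esm = esm_stock_spline(p1, refs, allow_extrapolation=True)
        in_top = esm["layer_bottom_cm"] <= depth_limit + _TOL
        esm_sum = esm.loc[in_top, "stock_MgC_ha"].sum()
        gap = fd_sum - esm_sum
        if orientation == "esm_minus_fd":
            gap = -gap
        rows.append(
            {
                "treatment": p0.treatment,
                "plot": p0.plot,
                "bd_stock_delta_MgC_ha": delta,
                "fd_esm_gap_MgC_ha": gap,
            }
        )
    return pd.DataFrame(rows)
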