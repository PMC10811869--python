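"""Change statistics between two sampling times, and the ESM-vs-FD contrast.

For each treatment x depth layer the pipeline reports the mean change in a
variable (bulk density, C concentration, or SOC stock), a Welch two-sample
confidence interval and t-test on that change, Hedges' g (the standardized
mean difference with small-sample bias correction), and the percent change
relative to the baseline mean. The ESM-vs-FD contrast treats the per-plot
stock-change estimates of the two accounting methods as two samples; under
the assumption that ESM is the correct method, their mean difference
(ESM - FD) is the fixed-depth error.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ChangeStat",
    "MethodContrast",
    "DegenerateVarianceError",
    "change_stat",
    "hedges_g",
    "method_contrast",
    "required_sample_size",
]


class DegenerateVarianceError(ValueError):
    """Both groups have zero variance but unequal means: t is undefined."""


@dataclass(frozen=True)
class ChangeStat:
    """Mean change between two groups with Welch CI, t-test, and effect size."""

    n0: int
    n1: int
    mean_t0: float
    mean_t1: float
    mean_change: float
    ci_low: float
    ci_high: float
    t_stat: float
    df: float
    p_value: float
    hedges_g: float
    percent_change: float
    conf: float = 0.95

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class MethodContrast:
    """ESM-vs-FD contrast of per-plot stock-change estimates (diff = ESM - FD)."""

    mean_esm_change: float
    mean_fd_change: float
    diff: float
    ci_low: float
    ci_high: float
    t_stat: float
    df: float
    p_value: float
    hedges_g: float
    paired: bool

    def as_dict(self) -> dict:
        return asdict(self)


def _welch(x0: np.ndarray, x1: np.ndarray, conf: float):
    """Welch statistics on mean(x1) - mean(x0): (d, se, t, df, p, lo, hi)."""
    n0, n1 = len(x0), len(x1)
    v0, v1 = x0.var(ddof=1), x1.var(ddof=1)
    d = x1.mean() - x0.mean()
    if v0 == 0 and v1 == 0:
        if d == 0:
            return 0.0, 0.0, 0.0, float(n0 + n1 - 2), 1.0, 0.0, 0.0
        raise DegenerateVarianceError(
            "zero variance in both groups with unequal means"
        )
    se = np.sqrt(v0 / n0 + v1 / n1)
    df = (v0 / n0 + v1 / n1) ** 2 / (
        (v0 / n0) ** 2 / (n0 - 1) + (v1 / n1) ** 2 / (n1 - 1)
    )
    t = d / se
    p = 2 * stats.t.sf(abs(t), df)
    tcrit = stats.t.ppf(1 - (1 - conf) / 2, df)
    return d, se, t, df, p, d - tcrit * se, d + tcrit * se


def hedges_g(x0, x1) -> float:
    """Hedges' g: bias-corrected standardized mean difference (x1 vs x0).

    g = J x (mean1 - mean0) / s_pooled, with s_pooled the Bessel-corrected
    pooled SD and J = 1 - 3 / (4(n0 + n1 - 2) - 1).
    """
    x0, x1 = np.asarray(x0, float), np.asarray(x1, float)
    n0, n1 = len(x0), len(x1)
    if n0 < 2 or n1 < 2:
        raise ValueError("each group needs at least 2 values")
    d = x1.mean() - x0.mean()
    if d == 0:
        return 0.0
    sp2 = ((n0 - 1) * x0.var(ddof=1) + (n1 - 1) * x1.var(ddof=1)) / (n0 + n1 - 2)
    if sp2 == 0:
        raise DegenerateVarianceError("pooled SD is zero with unequal means")
    j = 1 - 3 / (4 * (n0 + n1 - 2) - 1)
    return float(j * d / np.sqrt(sp2))


def change_stat(x0, x1, conf: float = 0.95) -> ChangeStat:
    """t1-vs-t0 change statistic: Welch t-test, CI, Hedges' g, percent change.

    ``x0`` and ``x1`` are replicate values (one per plot) at the two times.
    """
    x0, x1 = np.asarray(x0, float), np.asarray(x1, float)
    if len(x0) < 2 or len(x1) < 2:
        raise ValueError("each time needs at least 2 replicate values")
    d, _, t, df, p, lo, hi = _welch(x0, x1, conf)
    g = 0.0 if d == 0 else hedges_g(x0, x1)
    m0 = x0.mean()
    pct = float(100.0 * d / m0) if m0 != 0 else float("nan")
    return ChangeStat(
        n0=len(x0),
        n1=len(x1),
        mean_t0=float(m0),
        mean_t1=float(x1.mean()),
        mean_change=float(d),
        ci_low=float(lo),
        ci_high=float(hi),
        t_stat=float(t),
        df=float(df),
        p_value=float(p),
        hedges_g=g,
        percent_change=pct,
        conf=conf,
    )


def method_contrast(
    esm_changes, fd_changes, paired: bool = False, conf: float = 0.95
) -> MethodContrast:
    """Contrast per-plot ESM and FD stock-change estimates (diff = ESM - FD).

    Unpaired (Welch) by default; ``paired=True`` runs a paired t-test on the
    per-plot differences (the vectors must then align plot-by-plot).
    """
    esm = np.asarray(esm_changes, float)
    fd = np.asarray(fd_changes, float)
    if paired:
        if len(esm) != len(fd):
            raise ValueError("paired contrast requires equal-length vectors")
        diffs = esm - fd
        n = len(diffs)
        if n < 2:
            raise ValueError("paired contrast needs at least 2 plots")
        d = diffs.mean()
        sd = diffs.std(ddof=1)
        if sd == 0:
            if d != 0:
                raise DegenerateVarianceError("constant nonzero paired differences")
            t, p, lo, hi = 0.0, 1.0, 0.0, 0.0
            df = float(n - 1)
        else:
            se = sd / np.sqrt(n)
            df = float(n - 1)
            t = d / se
            p = 2 * stats.t.sf(abs(t), df)
            tcrit = stats.t.ppf(1 - (1 - conf) / 2, df)
            lo, hi = d - tcrit * se, d + tcrit * se
        g = 0.0 if d == 0 else hedges_g(fd, esm)
    else:
        d, _, t, df, p, lo, hi = _welch(fd, esm, conf)
        g = 0.0 if d == 0 else hedges_g(fd, esm)
    return MethodContrast(
        mean_esm_change=float(esm.mean()),
        mean_fd_change=float(fd.mean()),
        diff=float(d),
        ci_low=float(lo),
        ci_high=float(hi),
        t_stat=float(t),
        df=float(df),
        p_value=float(p),
        hedges_g=float(g),
        paired=paired,
    )


def required_sample_size(
    cv: float,
    rel_change: float,
    alpha: float = 0.05,
    power: float = 0.8,
    n_max: int = 100000,
) -> int:
    """Smallest per-group n detecting a relative mean change by two-sample t.

    A shift of ``rel_change`` x baseline against replicate SD ``cv`` x
    baseline gives standardized effect size delta = rel_change / cv; the
    two-sided two-sample t power condition is solved by scanning n upward on
    the noncentral t distribution.
    """
    if cv <= 0:
        raise ValueError("cv must be > 0")
    if not 0 < rel_change:
        raise ValueError("rel_change must be > 0 (a zero change is undetectable)")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    delta = rel_change / cv
    for n in range(2, n_max + 1):
        df = 2 * n - 2
        nc = delta * np.sqrt(n / 2)
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        achieved = stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc)
        if achieved >= power:
            return n
    raise ValueError(f"required n exceeds {n_max}")


# ---------------------------------------------------------------------------
# table-level drivers (used by the pipeline)


def change_table(values: pd.DataFrame, value_col: str, conf: float = 0.95) -> pd.DataFrame:
    """Per (treatment, layer) change statistics from a long plot-level table.

    ``values`` needs columns treatment, plot, time, layer_top_cm,
    layer_bottom_cm and ``value_col``, with time coded ``t0``/``t1``.
    """
    rows = []
    for (trt, top, bot), grp in values.groupby(
        ["treatment", "layer_top_cm", "layer_bottom_cm"], sort=True
    ):
        x0 = grp.loc[grp["time"] == "t0", value_col].to_numpy()
        x1 = grp.loc[grp["time"] == "t1", value_col].to_numpy()
        st = change_stat(x0, x1, conf=conf)
        rows.append({"treatment": trt, "layer_top_cm": top, "layer_bottom_cm": bot,
                     "variable": value_col, **st.as_dict()})
    return pd.DataFrame(rows)
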