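"""SOC stock engines: fixed-depth (FD) and equivalent-soil-mass (ESM) accounting.

The fixed-depth stock of a layer is concentration x bulk density x thickness,
so it tracks whatever soil mass happens to occupy the geometric interval at
sampling time, and is therefore biased by bulk-density change. ESM accounting
instead fixes a *reference soil mass* per layer — the initial (t0) sampled
mass averaged across a treatment's replicates — and asks how much carbon that
mass of soil contains at each time.

Two ESM variants are provided:

``ESM_classical``
    Top-down mass correction: a layer holding surplus mass relative to its
    cumulative reference mass sheds the surplus at its own concentration; a
    deficit borrows mass from the next deeper layer at that layer's
    concentration. Equivalently, linear interpolation of cumulative stock
    against cumulative mass.

``ESM_spline``
    Cumulative-coordinates method: a natural cubic spline through the points
    (cumulative soil mass, cumulative SOC stock), anchored at the origin, is
    evaluated at the cumulative reference masses; layer stocks are successive
    differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .profiles import DepthIncrement, LayerMeasurement, ProfileSample, ProfileSet

__all__ = [
    "ExtrapolationError",
    "ReferenceMassTable",
    "soil_mass",
    "fd_stock",
    "reference_masses",
    "esm_stock_spline",
    "esm_stock_classical",
    "stocks_pipeline",
]

#: columns of the stock table
STOCK_COLUMNS = [
    "experiment",
    "treatment",
    "block",
    "plot",
    "time",
    "layer_top_cm",
    "layer_bottom_cm",
    "method",
    "soil_mass_Mg_ha",
    "stock_MgC_ha",
    "cum_mass_Mg_ha",
    "cum_stock_MgC_ha",
    "extrapolated_flag",
]

METHODS = ("FD", "ESM_classical", "ESM_spline")


class ExtrapolationError(ValueError):
    """Reference mass exceeds the sampled soil mass of a profile."""


def soil_mass(layer: LayerMeasurement) -> float:
    """Dry soil mass of a layer in Mg ha^-1.

    With bulk density in g cm^-3 and thickness in cm, the conversion factor
    to Mg ha^-1 is 100 (1 g cm^-3 x 1 cm = 100 Mg ha^-1).
    """
    return layer.bulk_density * layer.increment.thickness * 100.0


def fd_stock(layer: LayerMeasurement) -> float:
    """Fixed-depth SOC stock of a layer in Mg C ha^-1.

    S = c x rho x d x 0.1 with c in g C kg^-1, rho in g cm^-3, d in cm;
    equivalently soil mass (Mg ha^-1) x c / 1000.
    """
    return soil_mass(layer) * layer.c_conc / 1000.0


@dataclass(frozen=True)
class ReferenceMassTable:
    """Per-treatment reference soil masses defining the ESM coordinate system.

    ``masses[treatment]`` holds layer reference masses (Mg ha^-1) in depth
    order; ``increments[treatment]`` the t0 fixed-depth intervals whose names
    label the ESM layers ("ESM depth").
    """

    masses: dict[str, np.ndarray]
    increments: dict[str, tuple[DepthIncrement, ...]]

    def __post_init__(self) -> None:
        for trt, m in self.masses.items():
            if not np.all(m > 0):
                raise ValueError(f"non-positive reference mass for treatment {trt!r}")

    def cumulative(self, treatment: str) -> np.ndarray:
        return np.cumsum(self.masses[treatment])


def reference_masses(pset: ProfileSet) -> ReferenceMassTable:
    """Build the reference-mass table from the t0 profiles of a ProfileSet.

    The reference mass of (treatment, layer) is the arithmetic mean of the
    layer soil masses over that treatment's t0 replicates; all replicates of
    a treatment must share the t0 increment grid.
    """
    masses: dict[str, np.ndarray] = {}
    increments: dict[str, tuple[DepthIncrement, ...]] = {}
    for trt in pset.treatments:
        reps = pset.for_treatment(trt, time=pset.t0)
        if not reps:
            raise ValueError(f"treatment {trt!r} has no t0 profiles")
        grids = {p.increments for p in reps}
        if len(grids) != 1:
            raise ValueError(
                f"treatment {trt!r}: t0 replicates do not share one increment grid"
            )
        per_rep = np.array([[soil_mass(l) for l in p.layers] for p in reps])
        masses[trt] = per_rep.mean(axis=0)
        increments[trt] = reps[0].increments
    return ReferenceMassTable(masses=masses, increments=increments)


def _cumulative_coordinates(profile: ProfileSample) -> tuple[np.ndarray, np.ndarray]:
    """Knots (cumulative mass, cumulative FD stock), anchored at the origin."""
    m = np.array([soil_mass(l) for l in profile.layers])
    s = np.array([fd_stock(l) for l in profile.layers])
    return np.concatenate([[0.0], np.cumsum(m)]), np.concatenate([[0.0], np.cumsum(s)])


def _check_coverage(
    profile: ProfileSample, cum_ref: np.ndarray, allow_extrapolation: bool
) -> bool:
    cum_m = sum(soil_mass(l) for l in profile.layers)
    shortfall = cum_ref[-1] - cum_m
    if shortfall > 1e-9 * cum_ref[-1]:
        if not allow_extrapolation:
            raise ExtrapolationError(
                f"profile {profile.plot}/{profile.time}: deepest cumulative "
                f"reference mass {cum_ref[-1]:.1f} Mg ha^-1 exceeds sampled mass "
                f"{cum_m:.1f} Mg ha^-1 by {shortfall:.1f} Mg ha^-1"
            )
        return True
    return False


def esm_stock_spline(
    profile: ProfileSample,
    refs: ReferenceMassTable,
    allow_extrapolation: bool = False,
) -> pd.DataFrame:
    """Cumulative-coordinates ESM stocks for one profile.

    Fits a natural cubic spline through (0, 0) and the per-layer points of
    cumulative soil mass vs cumulative fixed-depth stock, then evaluates it
    at the treatment's cumulative reference masses. Layer ESM stocks are
    successive differences of the interpolated cumulative stocks; evaluation
    at a knot reproduces the knot exactly, so a profile whose sampled masses
    equal the references returns its FD stocks.

    By default a reference mass deeper than the sampled mass raises
    :class:`ExtrapolationError`; ``allow_extrapolation=True`` instead
    extrapolates the last spline segment and flags the output rows.
    """
    if len(profile.layers) < 2:
        raise ValueError("spline ESM requires at least 2 layers")
    cum_ref = refs.cumulative(profile.treatment)
    extrapolated = _check_coverage(profile, cum_ref, allow_extrapolation)
    cm, cs = _cumulative_coordinates(profile)
    spline = CubicSpline(cm, cs, bc_type="natural", extrapolate=False)
    # queries at or within numerical noise of the last knot are clamped to it
    cum_stock = np.asarray(spline(np.minimum(cum_ref, cm[-1])))
    if extrapolated:
        # linear continuation of the last spline segment beyond the sampled mass
        beyond = cum_ref > cm[-1]
        slope = spline(cm[-1], 1)
        cum_stock[beyond] = cs[-1] + slope * (cum_ref[beyond] - cm[-1])
    layer_stock = np.diff(np.concatenate([[0.0], cum_stock]))
    if np.any(layer_stock < 0):
        warnings.warn(
            f"profile {profile.plot}/{profile.time}: spline interpolation produced "
            "negative layer stock(s) (overshoot); reported as-is",
            RuntimeWarning,
            stacklevel=2,
        )
    return _rows(profile, refs, layer_stock, "ESM_spline", extrapolated)


def esm_stock_classical(
    profile: ProfileSample,
    refs: ReferenceMassTable,
    allow_extrapolation: bool = False,
) -> pd.DataFrame:
    """Classical ESM stocks for one profile (top-down mass correction).

    Processing layers from the surface down, a layer whose cumulative sampled
    mass exceeds the cumulative reference mass sheds the surplus at its own
    concentration; a deficit borrows mass from the next deeper layer at that
    deeper layer's concentration (cascading further down if needed). This is
    exactly linear interpolation of cumulative stock in cumulative-mass
    coordinates, evaluated at the reference masses.

    A deficit at the deepest layer, with no layer below to borrow from, is an
    error unless ``allow_extrapolation=True``, in which case the missing mass
    is valued at the deepest layer's concentration and the rows are flagged.
    """
    cum_ref = refs.cumulative(profile.treatment)
    extrapolated = _check_coverage(profile, cum_ref, allow_extrapolation)
    cm, cs = _cumulative_coordinates(profile)
    cum_stock = np.interp(cum_ref, cm, cs)
    if extrapolated:
        beyond = cum_ref > cm[-1]
        c_last = profile.layers[-1].c_conc
        cum_stock[beyond] = cs[-1] + (cum_ref[beyond] - cm[-1]) * c_last / 1000.0
    layer_stock = np.diff(np.concatenate([[0.0], cum_stock]))
    return _rows(profile, refs, layer_stock, "ESM_classical", extrapolated)


def _rows(
    profile: ProfileSample,
    refs: ReferenceMassTable,
    layer_stock: np.ndarray,
    method: str,
    extrapolated: bool,
) -> pd.DataFrame:
    ref_m = refs.masses[profile.treatment]
    incs = refs.increments[profile.treatment]
    return pd.DataFrame(
        {
            "experiment": profile.experiment,
            "treatment": profile.treatment,
            "block": profile.block,
            "plot": profile.plot,
            "time": profile.time,
            "layer_top_cm": [i.top for i in incs],
            "layer_bottom_cm": [i.bottom for i in incs],
            "method": method,
            "soil_mass_Mg_ha": ref_m,
            "stock_MgC_ha": layer_stock,
            "cum_mass_Mg_ha": np.cumsum(ref_m),
            "cum_stock_MgC_ha": np.cumsum(layer_stock),
            "extrapolated_flag": extrapolated,
        }
    )


def _fd_rows(profile: ProfileSample) -> pd.DataFrame:
    m = np.array([soil_mass(l) for l in profile.layers])
    s = np.array([fd_stock(l) for l in profile.layers])
    return pd.DataFrame(
        {
            "experiment": profile.experiment,
            "treatment": profile.treatment,
            "block": profile.block,
            "plot": profile.plot,
            "time": profile.time,
            "layer_top_cm": [i.top for i in profile.increments],
            "layer_bottom_cm": [i.bottom for i in profile.increments],
            "method": "FD",
            "soil_mass_Mg_ha": m,
            "stock_MgC_ha": s,
            "cum_mass_Mg_ha": np.cumsum(m),
            "cum_stock_MgC_ha": np.cumsum(s),
            "extrapolated_flag": False,
        }
    )


def stocks_pipeline(
    pset: ProfileSet,
    refs: ReferenceMassTable | None = None,
    allow_extrapolation: bool = False,
) -> pd.DataFrame:
    """Compute FD, classical-ESM and spline-ESM stocks for every profile.

    Reference masses default to the t0-derived table (shared across both
    times and all replicates of a treatment); a user-supplied table — e.g.
    published reference masses — may be passed instead. ESM layers are
    labeled with the t0 fixed-depth interval they represent ("ESM depth").
    """
    if refs is None:
        refs = reference_masses(pset)
    frames = []
    for p in sorted(pset, key=lambda q: (q.treatment, q.plot, q.time)):
        frames.append(_fd_rows(p))
        frames.append(esm_stock_classical(p, refs, allow_extrapolation=allow_extrapolation))
        frames.append(esm_stock_spline(p, refs, allow_extrapolation=allow_extrapolation))
    return pd.concat(frames, ignore_index=True)[STOCK_COLUMNS]
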