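import numpy as np
import pytest

from esmsoc.profiles import (
    DepthIncrement,
    LayerMeasurement,
    ProfileSample,
    ProfileSet,
)


def make_profile(
    boundaries,
    bd,
    c,
    treatment="T",
    plot="T-01",
    time="t0",
    experiment="exp",
    block="B1",
):
    layers = tuple(
        LayerMeasurement(DepthIncrement(a, b), float(r), float(cc))
        for a, b, r, cc in zip(boundaries, boundaries[1:], bd, c)
    )
    return ProfileSample(experiment, treatment, block, plot, time, layers)


@pytest.fixture
def century_grid():
    return (0.0, 15.0, 30.0, 60.0, 100.0, 200.0)


@pytest.fixture
def smooth_profile(century_grid):
    """Monotone-decay concentration, compacting bulk density with depth."""
    return make_profile(
        century_grid,
        bd=(1.30, 1.40, 1.50, 1.58, 1.65),
        c=(12.0, 9.0, 6.0, 3.5, 1.8),
    )


def two_time_set(boundaries, bd0, c0, bd1, c1, n=2, treatment="T"):
    """n identical replicates at each of two times (deterministic set)."""
    profiles = []
    for i in range(n):
        plot = f"{treatment}-{i + 1:02d}"
        profiles.append(
            make_profile(boundaries, bd0, c0, treatment=treatment, plot=plot, time="t0")
        )
        profiles.append(
            make_profile(boundaries, bd1, c1, treatment=treatment, plot=plot, time="t1")
        )
    return ProfileSet(profiles, t0="t0", t1="t1")


def smooth_field_scenario(rng, boundaries, dz=0.1):
    """Random smooth soil column discretized in dz-cm sublayers.

    Bulk density rises and concentration decays exponentially with depth;
    layer measurements are the (mass-weighted) means of the fine field, so
    cumulative mass/stock at the layer boundaries are exact. Returns
    (layer_bd, layer_c, fine_cum_mass, fine_cum_stock) — the fine arrays are
    the brute-force integration oracle.
    """
    boundaries = np.asarray(boundaries, float)
    bd0 = rng.uniform(1.0, 1.3)
    bdmax = rng.uniform(1.5, 1.8)
    s_bd = rng.uniform(20, 60)
    c0 = rng.uniform(8, 30)
    s_c = rng.uniform(40, 150)
    floor = rng.uniform(0.5, 2.5)
    z = np.arange(boundaries[0], boundaries[-1], dz) + dz / 2
    bdz = bdmax - (bdmax - bd0) * np.exp(-z / s_bd)
    cz = floor + c0 * np.exp(-z / s_c)
    sub_mass = bdz * dz * 100.0
    sub_stock = sub_mass * cz / 1000.0
    cm = np.concatenate([[0.0], np.cumsum(sub_mass)])
    cs = np.concatenate([[0.0], np.cumsum(sub_stock)])
    idx = np.clip(
        np.searchsorted(boundaries, z, side="right") - 1, 0, len(boundaries) - 2
    )
    layer_bd = np.array([bdz[idx == j].mean() for j in range(len(boundaries) - 1)])
    layer_c = np.array(
        [
            (sub_mass[idx == j] * cz[idx == j]).sum() / sub_mass[idx == j].sum()
            for j in range(len(boundaries) - 1)
        ]
    )
    return layer_bd, layer_c, cm, cs


def fine_cumulative_stock(boundaries, bd, c, query_masses, dz=0.1):
    """Brute-force oracle: integrate mass and stock in dz-cm sublayers.

    Returns cumulative SOC stock (Mg C ha^-1) at each query cumulative soil
    mass (Mg ha^-1), by linear interpolation on the fine discretization.
    """
    boundaries = np.asarray(boundaries, float)
    zs = np.arange(boundaries[0], boundaries[-1] + dz / 2, dz)
    idx = np.clip(np.searchsorted(boundaries, zs[1:], side="right") - 1, 0, len(bd) - 1)
    sub_mass = np.asarray(bd)[idx] * dz * 100.0
    sub_stock = sub_mass * np.asarray(c)[idx] / 1000.0
    cm = np.concatenate([[0.0], np.cumsum(sub_mass)])
    cs = np.concatenate([[0.0], np.cumsum(sub_stock)])
    return np.interp(query_masses, cm, cs)
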