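"""Seeded generator of two-time-point soil profile sets.

Emulates the replicate structure of long-term cropping-system trials: a
treatment with n replicate plots, each sampled at two times on a fixed depth
grid, with layer-level Gaussian replicate noise on bulk density and carbon
concentration. Presets encode the contrasting regimes of two such trials —
a California maize/wheat experiment where organic-matter inputs loosened
surface soil (bulk density down 10-19% at 0-15 cm, concentration up to 41%
higher) and a Wisconsin no-till trial where surface soil compacted (bulk
density up 4-19%) while concentration declined — plus a mass-preserving
compaction null in which the same soil column is merely repacked, so the
true equivalent-soil-mass stock change is zero by construction.

Replicate noise SDs grow with depth relative to the mean concentration,
reproducing the large spread of deep-layer stocks seen in field data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .profiles import DepthIncrement, LayerMeasurement, ProfileSample, ProfileSet

__all__ = ["ScenarioConfig", "generate", "preset", "PRESETS"]

_MAX_RESAMPLE = 1000


@dataclass(frozen=True)
class ScenarioConfig:
    """Mean profiles, per-layer changes, and noise levels for one treatment."""

    treatment: str
    n_reps: int
    boundaries: tuple[float, ...]  # layer boundaries from the surface, cm
    bd_t0: tuple[float, ...]  # g cm^-3, per layer
    c_t0: tuple[float, ...]  # g C kg^-1, per layer
    bd_rel_change: tuple[float, ...]  # fractional t0 -> t1 change
    c_rel_change: tuple[float, ...]
    bd_noise_sd: tuple[float, ...]  # replicate SD, g cm^-3
    c_noise_sd: tuple[float, ...]  # replicate SD, g C kg^-1
    mass_preserving: bool = False  # derive t1 concentration by conserving the
    # concentration-vs-cumulative-mass field (compaction/loosening null)
    bd_change_noise_sd: tuple[float, ...] | None = None  # per-plot SD of the
    # relative BD change itself (spatial variation in management response)
    experiment: str = "synthetic"
    seed: int | None = None

    def __post_init__(self) -> None:
        L = len(self.boundaries) - 1
        if L < 1:
            raise ValueError("need at least one layer")
        if self.boundaries[0] != 0 or np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundaries must increase from 0")
        for name in ("bd_t0", "c_t0", "bd_rel_change", "c_rel_change",
                     "bd_noise_sd", "c_noise_sd"):
            if len(getattr(self, name)) != L:
                raise ValueError(f"{name} must have one value per layer ({L})")
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if np.any(np.asarray(self.bd_t0) <= 0):
            raise ValueError("mean bulk density must be > 0")
        if np.any(np.asarray(self.c_t0) < 0):
            raise ValueError("mean concentration must be >= 0")
        if np.any(np.asarray(self.bd_noise_sd) < 0) or np.any(
            np.asarray(self.c_noise_sd) < 0
        ):
            raise ValueError("noise SDs must be >= 0")
        if np.any(np.asarray(self.bd_t0) * (1 + np.asarray(self.bd_rel_change)) <= 0):
            raise ValueError("t1 mean bulk density must be > 0")
        if self.bd_change_noise_sd is not None and len(self.bd_change_noise_sd) != (
            len(self.boundaries) - 1
        ):
            raise ValueError("bd_change_noise_sd must have one value per layer")

    @property
    def increments(self) -> tuple[DepthIncrement, ...]:
        return tuple(
            DepthIncrement(a, b)
            for a, b in zip(self.boundaries, self.boundaries[1:])
        )


def _truncated_normal(rng, mean, sd, lower, strict, what):
    """Gaussian draw resampled until above (or at) the physical bound."""
    for _ in range(_MAX_RESAMPLE):
        v = rng.normal(mean, sd)
        if (v > lower) if strict else (v >= lower):
            return v
    raise RuntimeError(f"could not draw a physical value for {what}")


def _mass_preserving_conc(
    boundaries: np.ndarray, bd0: np.ndarray, c0: np.ndarray, bd1: np.ndarray
) -> np.ndarray:
    """t1 layer concentrations conserving the concentration-mass field.

    The t0 profile defines cumulative stock as a piecewise-linear function of
    cumulative soil mass (slope c/1000 per layer), extended below the sampled
    column at the deepest concentration. Repacking the column to t1 bulk
    densities shifts the layers' mass boundaries; each t1 concentration is
    the mean slope over its new mass interval.
    """
    d = np.diff(boundaries)
    m0 = bd0 * d * 100.0
    m1 = bd1 * d * 100.0
    cm0 = np.concatenate([[0.0], np.cumsum(m0)])
    cs0 = np.concatenate([[0.0], np.cumsum(m0 * c0 / 1000.0)])

    def cum_stock(m):
        if m <= cm0[-1]:
            return np.interp(m, cm0, cs0)
        return cs0[-1] + (m - cm0[-1]) * c0[-1] / 1000.0

    cm1 = np.concatenate([[0.0], np.cumsum(m1)])
    s_at = np.array([cum_stock(m) for m in cm1])
    return np.diff(s_at) / m1 * 1000.0


def generate(config: ScenarioConfig, seed: int | None = None) -> ProfileSet:
    """Generate a two-time-point ProfileSet for one treatment.

    Per replicate and layer, t0 values are the configured means plus Gaussian
    noise (resampled if unphysical) and t1 values are t0 x (1 + relative
    change) plus fresh noise; with ``mass_preserving`` the t1 concentrations
    are instead derived from the replicate's own t0 column so the true ESM
    stock change is zero. Deterministic given the seed.
    """
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    incs = config.increments
    bd0_m = np.asarray(config.bd_t0, float)
    c0_m = np.asarray(config.c_t0, float)
    bd_rel = np.asarray(config.bd_rel_change, float)
    c_rel = np.asarray(config.c_rel_change, float)
    profiles = []
    for i in range(config.n_reps):
        block = f"B{i % 3 + 1}"
        plot = f"{config.treatment}-{i + 1:02d}"
        bd0 = np.array(
            [
                _truncated_normal(rng, m, s, 0.0, True, "bulk density")
                for m, s in zip(bd0_m, config.bd_noise_sd)
            ]
        )
        c0 = np.array(
            [
                _truncated_normal(rng, m, s, 0.0, False, "concentration")
                for m, s in zip(c0_m, config.c_noise_sd)
            ]
        )
        rel_p = bd_rel
        if config.bd_change_noise_sd is not None:
            rel_p = bd_rel + rng.normal(0.0, np.asarray(config.bd_change_noise_sd))
        if config.mass_preserving:
            bd1 = bd0 * (1 + rel_p)
            c1 = _mass_preserving_conc(np.asarray(config.boundaries, float), bd0, c0, bd1)
        else:
            bd1 = np.array(
                [
                    _truncated_normal(rng, m, s, 0.0, True, "bulk density")
                    for m, s in zip(bd0 * (1 + rel_p), config.bd_noise_sd)
                ]
            )
            c1 = np.array(
                [
                    _truncated_normal(rng, m, s, 0.0, False, "concentration")
                    for m, s in zip(c0 * (1 + c_rel), config.c_noise_sd)
                ]
            )
        for time, bd, c in (("t0", bd0, c0), ("t1", bd1, c1)):
            layers = tuple(
                LayerMeasurement(inc, bd[j], c[j]) for j, inc in enumerate(incs)
            )
            profiles.append(
                ProfileSample(config.experiment, config.treatment, block, plot, time, layers)
            )
    return ProfileSet(profiles, t0="t0", t1="t1")


def generate_many(configs, seed: int | None = None) -> ProfileSet:
    """Generate several treatments into one ProfileSet (independent streams)."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(list(configs)))
    profiles = []
    for cfg, child in zip(configs, children):
        sub = generate(cfg, seed=int(child.generate_state(1)[0] % (2**31)))
        profiles.extend(sub.profiles)
    return ProfileSet(profiles, t0="t0", t1="t1")


_CENTURY_GRID = (0.0, 15.0, 30.0, 60.0, 100.0, 200.0)
_WICST_GRID = (0.0, 15.0, 30.0, 60.0, 90.0)

PRESETS: dict[str, ScenarioConfig] = {
    # organic maize-tomato-like: compost/cover-crop inputs loosen surface soil
    # (BD -16% at 0-15 cm) while concentration rises sharply (+41%)
    "century_maize_like": ScenarioConfig(
        treatment="OMT_like",
        n_reps=6,
        boundaries=_CENTURY_GRID,
        bd_t0=(1.38, 1.45, 1.52, 1.58, 1.62),
        c_t0=(9.8, 8.0, 5.5, 3.5, 2.0),
        bd_rel_change=(-0.16, -0.12, -0.04, -0.01, 0.0),
        c_rel_change=(0.41, 0.22, 0.02, 0.006, 0.0),
        bd_noise_sd=(0.03, 0.03, 0.05, 0.07, 0.08),
        c_noise_sd=(0.6, 0.6, 0.7, 0.8, 0.9),
        bd_change_noise_sd=(0.07, 0.05, 0.03, 0.01, 0.005),
        experiment="century_like",
    ),
    # irrigated wheat-fallow-like: moderate surface loosening, small
    # concentration gains at the surface, slight compaction at 30-60 cm
    "century_wheat_like": ScenarioConfig(
        treatment="IWN_like",
        n_reps=6,
        boundaries=_CENTURY_GRID,
        bd_t0=(1.42, 1.48, 1.53, 1.58, 1.62),
        c_t0=(8.5, 7.0, 5.0, 3.2, 1.8),
        bd_rel_change=(-0.13, -0.08, 0.04, 0.0, 0.0),
        c_rel_change=(0.06, 0.01, -0.02, 0.0, 0.0),
        bd_noise_sd=(0.03, 0.03, 0.05, 0.07, 0.08),
        c_noise_sd=(0.55, 0.55, 0.65, 0.75, 0.85),
        bd_change_noise_sd=(0.07, 0.05, 0.03, 0.01, 0.005),
        experiment="century_like",
    ),
    # no-till maize-soybean-like on a carbon-rich Mollisol: surface compaction
    # (BD +19% at 0-15 cm) with declining concentration
    "wicst_like": ScenarioConfig(
        treatment="MS_like",
        n_reps=12,
        boundaries=_WICST_GRID,
        bd_t0=(1.10, 1.28, 1.40, 1.45),
        c_t0=(25.0, 18.0, 8.0, 4.0),
        bd_rel_change=(0.19, 0.055, 0.0, 0.0),
        c_rel_change=(-0.19, -0.08, -0.05, -0.03),
        bd_noise_sd=(0.06, 0.06, 0.05, 0.05),
        c_noise_sd=(2.0, 2.0, 1.8, 1.5),
        bd_change_noise_sd=(0.05, 0.03, 0.0, 0.0),
        experiment="wicst_like",
    ),
    # deterministic repacking of the same soil column: surface compaction with
    # concentrations rearranged mass-conservatively, so true ESM change is 0
    "compaction_null": ScenarioConfig(
        treatment="COMPACT_null",
        n_reps=6,
        boundaries=_CENTURY_GRID,
        bd_t0=(1.30, 1.40, 1.50, 1.55, 1.60),
        c_t0=(12.0, 9.0, 6.0, 3.5, 2.0),
        bd_rel_change=(0.15, 0.05, 0.0, 0.0, 0.0),
        c_rel_change=(0.0, 0.0, 0.0, 0.0, 0.0),
        bd_noise_sd=(0.0, 0.0, 0.0, 0.0, 0.0),
        c_noise_sd=(0.0, 0.0, 0.0, 0.0, 0.0),
        mass_preserving=True,
        experiment="null_like",
    ),
}


def preset(name: str) -> ScenarioConfig:
    """Return a fully populated scenario configuration by name."""
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
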