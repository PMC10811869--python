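"""Layered soil-profile data model, validated I/O, and depth-increment harmonization.

A profile is an ordered stack of contiguous depth increments, each carrying a
bulk density (g cm^-3) and an organic-carbon concentration (g C kg^-1).
Increments are half-open intervals [top, bottom) in cm, positive downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DepthIncrement",
    "LayerMeasurement",
    "ProfileSample",
    "ProfileSet",
    "SchemaError",
    "ValidationError",
    "read_profiles",
    "remap_increments",
    "write_table",
]

#: required columns of the long input CSV, in canonical order
PROFILE_COLUMNS = [
    "experiment",
    "treatment",
    "block",
    "plot",
    "time",
    "depth_top_cm",
    "depth_bottom_cm",
    "bd_g_cm3",
    "c_g_kg",
]

_BOUNDARY_TOL = 1e-9


class SchemaError(ValueError):
    """Input table does not match the required column schema."""


class ValidationError(ValueError):
    """Profile data violate a structural or physical invariant."""


@dataclass(frozen=True, order=True)
class DepthIncrement:
    """Half-open depth interval [top, bottom) in cm, positive downward."""

    top: float
    bottom: float

    def __post_init__(self) -> None:
        if not (0 <= self.top < self.bottom):
            raise ValidationError(
                f"invalid depth increment [{self.top}, {self.bottom}): "
                "require 0 <= top < bottom"
            )

    @property
    def thickness(self) -> float:
        """Layer thickness d in cm."""
        return self.bottom - self.top

    def overlap(self, other: "DepthIncrement") -> float:
        """Length (cm) of the intersection with another increment."""
        return max(0.0, min(self.bottom, other.bottom) - max(self.top, other.top))

    @property
    def label(self) -> str:
        return f"{self.top:g}-{self.bottom:g}"


@dataclass(frozen=True)
class LayerMeasurement:
    """One depth increment with its bulk density and C concentration."""

    increment: DepthIncrement
    bulk_density: float  # g cm^-3
    c_conc: float  # g C kg^-1

    def __post_init__(self) -> None:
        if not self.bulk_density > 0:
            raise ValidationError(
                f"bulk density must be > 0, got {self.bulk_density} "
                f"at {self.increment.label} cm"
            )
        if self.c_conc < 0:
            raise ValidationError(
                f"C concentration must be >= 0, got {self.c_conc} "
                f"at {self.increment.label} cm"
            )


@dataclass(frozen=True)
class ProfileSample:
    """All layers of one plot at one sampling time.

    Layers must be sorted by depth, contiguous (each top equals the previous
    bottom) and start at the surface.
    """

    experiment: str
    treatment: str
    block: str
    plot: str
    time: str
    layers: tuple[LayerMeasurement, ...]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValidationError(f"profile {self.plot}/{self.time} has no layers")
        layers = tuple(sorted(self.layers, key=lambda l: l.increment.top))
        object.__setattr__(self, "layers", layers)
        if abs(layers[0].increment.top) > _BOUNDARY_TOL:
            raise ValidationError(
                f"profile {self.plot}/{self.time}: first increment starts at "
                f"{layers[0].increment.top} cm, expected 0"
            )
        for upper, lower in zip(layers, layers[1:]):
            if abs(upper.increment.bottom - lower.increment.top) > _BOUNDARY_TOL:
                raise ValidationError(
                    f"profile {self.plot}/{self.time}: increments not contiguous "
                    f"between {upper.increment.bottom} and {lower.increment.top} cm"
                )

    # -- convenience accessors -------------------------------------------------
    @property
    def increments(self) -> tuple[DepthIncrement, ...]:
        return tuple(l.increment for l in self.layers)

    @property
    def bulk_density(self) -> np.ndarray:
        return np.array([l.bulk_density for l in self.layers])

    @property
    def c_conc(self) -> np.ndarray:
        return np.array([l.c_conc for l in self.layers])

    @property
    def thickness(self) -> np.ndarray:
        return np.array([l.increment.thickness for l in self.layers])

    @property
    def max_depth(self) -> float:
        return self.layers[-1].increment.bottom

    def key(self) -> tuple[str, str, str]:
        return (self.treatment, self.plot, self.time)


@dataclass
class ProfileSet:
    """A collection of profiles with the two time labels of the comparison."""

    profiles: list[ProfileSample]
    t0: str = "t0"
    t1: str = "t1"

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        for p in self.profiles:
            for l in p.layers:
                k = (p.treatment, p.plot, p.time, l.increment)
                if k in seen:
                    raise ValidationError(
                        f"duplicate measurement for plot {p.plot}, time {p.time}, "
                        f"increment {l.increment.label} cm"
                    )
                seen.add(k)

    def __iter__(self):
        return iter(self.profiles)

    def __len__(self) -> int:
        return len(self.profiles)

    @property
    def treatments(self) -> list[str]:
        return sorted({p.treatment for p in self.profiles})

    def at_time(self, time: str) -> list[ProfileSample]:
        return [p for p in self.profiles if p.time == time]

    def for_treatment(self, treatment: str, time: str | None = None) -> list[ProfileSample]:
        out = [p for p in self.profiles if p.treatment == treatment]
        if time is not None:
            out = [p for p in out if p.time == time]
        return sorted(out, key=lambda p: (p.plot, p.time))

    def pairs(self) -> list[tuple[ProfileSample, ProfileSample]]:
        """(t0, t1) profile pairs for plots present at both times."""
        by_key = {(p.treatment, p.plot, p.time): p for p in self.profiles}
        out = []
        for (trt, plot, time), p in sorted(by_key.items()):
            if time == self.t0 and (trt, plot, self.t1) in by_key:
                out.append((p, by_key[(trt, plot, self.t1)]))
        return out


# ---------------------------------------------------------------------------
# I/O


def read_profiles(
    path: str | Path,
    time_map: Mapping[str, str] | None = None,
) -> ProfileSet:
    """Read a long-format CSV of layered soil measurements into a ProfileSet.

    Parameters
    ----------
    path
        CSV with columns ``experiment, treatment, block, plot, time,
        depth_top_cm, depth_bottom_cm, bd_g_cm3, c_g_kg``.
    time_map
        Optional mapping from the file's time labels to the canonical
        ``{"t0", "t1"}`` roles, e.g. ``{"1993": "t0", "2012": "t1"}``. When
        omitted, the sorted unique time labels are assigned t0 and t1 in order.
    """
    df = pd.read_csv(path, dtype={c: str for c in PROFILE_COLUMNS[:5]})
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    for col in ("depth_top_cm", "depth_bottom_cm", "bd_g_cm3", "c_g_kg"):
        if df[col].isna().any():
            raise SchemaError(f"column {col} contains missing values")
        df[col] = pd.to_numeric(df[col])

    profiles = []
    for (exp, trt, block, plot, time), grp in df.groupby(
        ["experiment", "treatment", "block", "plot", "time"], sort=True
    ):
        grp = grp.sort_values("depth_top_cm")
        layers = tuple(
            LayerMeasurement(
                DepthIncrement(r.depth_top_cm, r.depth_bottom_cm),
                r.bd_g_cm3,
                r.c_g_kg,
            )
            for r in grp.itertuples()
        )
        profiles.append(ProfileSample(exp, trt, block, plot, time, layers))

    times = sorted({p.time for p in profiles})
    if time_map is not None:
        inv = {v: k for k, v in time_map.items()}
        if "t0" not in inv or "t1" not in inv:
            raise SchemaError("time_map must assign both 't0' and 't1'")
        t0, t1 = inv["t0"], inv["t1"]
    elif len(times) >= 2:
        t0, t1 = times[0], times[1]
    else:
        t0 = t1 = times[0]
    return ProfileSet(profiles, t0=t0, t1=t1)


def write_table(rows: pd.DataFrame, path: str | Path) -> Path:
    """Write a result table to CSV (UTF-8, '.' decimal, full float precision)."""
    if rows is None or len(rows) == 0:
        raise ValueError("refusing to write an empty table")
    path = Path(path)
    rows.to_csv(path, index=False, float_format="%.17g")
    return path


# ---------------------------------------------------------------------------
# Depth-increment harmonization


def remap_increments(
    profile: ProfileSample,
    targets: Sequence[DepthIncrement],
    fields: Iterable[str] = ("bulk_density", "c_conc"),
    supplied: Mapping[str, Sequence[float]] | None = None,
) -> ProfileSample:
    """Re-express a profile on a new contiguous depth grid.

    Each remapped value is the thickness-weighted (overlap-weighted) average of
    the source values over the target increment — the generalization of
    adjusting a coarse bulk-density grid onto a finer sampling grid by
    weighted averages of the adjacent source increments. Only intensive
    quantities (bulk density, concentration) may be remapped; stocks must be
    recomputed from the remapped fields.

    Fields not listed in ``fields`` must be given on the target grid through
    ``supplied``.
    """
    fields = set(fields)
    known = {"bulk_density", "c_conc"}
    if not fields <= known:
        raise ValueError(f"unknown field(s): {sorted(fields - known)}")
    targets = tuple(sorted(targets, key=lambda t: t.top))
    if abs(targets[0].top) > _BOUNDARY_TOL:
        raise ValidationError("target grid must start at 0 cm")
    for a, b in zip(targets, targets[1:]):
        if abs(a.bottom - b.top) > _BOUNDARY_TOL:
            raise ValidationError(
                f"target increments not contiguous between {a.bottom} and {b.top} cm"
            )
    if targets[-1].bottom > profile.max_depth + _BOUNDARY_TOL:
        raise ValidationError(
            f"target grid extends to {targets[-1].bottom} cm but profile "
            f"{profile.plot}/{profile.time} is only sampled to {profile.max_depth} cm"
        )
    supplied = dict(supplied or {})
    for f in known - fields:
        if f not in supplied:
            raise ValueError(
                f"field {f!r} is not remapped; supply its target-grid values"
            )
        if len(supplied[f]) != len(targets):
            raise ValueError(f"supplied {f!r} has wrong length")

    src = profile.increments
    values = {"bulk_density": profile.bulk_density, "c_conc": profile.c_conc}
    out: dict[str, list[float]] = {f: [] for f in known}
    for j, tgt in enumerate(targets):
        w = np.array([s.overlap(tgt) for s in src])
        wsum = w.sum()
        for f in known:
            if f in fields:
                out[f].append(float(w @ values[f] / wsum))
            else:
                out[f].append(float(supplied[f][j]))
    layers = tuple(
        LayerMeasurement(tgt, out["bulk_density"][j], out["c_conc"][j])
        for j, tgt in enumerate(targets)
    )
    return replace(profile, layers=layers)


def profiles_to_frame(pset: ProfileSet) -> pd.DataFrame:
    """Long-format DataFrame view of a ProfileSet (inverse of read_profiles)."""
    rows = []
    for p in pset:
        for l in p.layers:
            rows.append(
                (
                    p.experiment,
                    p.treatment,
                    p.block,
                    p.plot,
                    p.time,
                    l.increment.top,
                    l.increment.bottom,
                    l.bulk_density,
                    l.c_conc,
                )
            )
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)
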