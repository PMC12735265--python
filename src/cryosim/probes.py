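"""Cryoprobe layouts, the probe temperature load curve, and grid rasterization.

Coordinate convention: right-handed SI meters, probe axes along -z (the
insertion direction), specimen surface / entry plane at z = 0, tissue below.
A probe entering at ``(x, y, 0)`` occupies the cylinder of its radius down to
``z = -insertion_depth``; the distal ``active_length`` of that cylinder is the
actively cooled segment that carries the load-curve temperature, while the
remainder is the insulated shaft.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "Probe",
    "ProbeLayout",
    "LoadCurve",
    "make_layout",
    "evaluate_load_curve",
    "rasterize_layout",
]

_PATTERN_COUNTS = {"single": 1, "five": 5, "seven": 7, "nine": 9}


@dataclass(frozen=True)
class Probe:
    """A straight cylindrical cryoprobe."""

    entry_point: tuple[float, float, float]
    axis: tuple[float, float, float] = (0.0, 0.0, -1.0)
    insertion_depth: float = 0.02
    active_length: float = 0.02
    radius: float = 0.00085

    def __post_init__(self) -> None:
        ax = np.asarray(self.axis, dtype=float)
        if not np.isclose(np.linalg.norm(ax), 1.0, atol=1e-9):
            raise ValueError("probe axis must be a unit vector")
        if not 0 < self.active_length <= self.insertion_depth:
            raise ValueError("active_length must satisfy 0 < active_length <= insertion_depth")
        if not 0 < self.radius < self.insertion_depth:
            raise ValueError("radius must be positive and smaller than insertion_depth")

    @property
    def tip(self) -> np.ndarray:
        """Distal end of the probe."""
        return np.asarray(self.entry_point) + self.insertion_depth * np.asarray(self.axis)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ProbeLayout:
    """A set of parallel probes sharing one load curve."""

    pattern: str
    spacing: float
    probes: tuple[Probe, ...]

    def __post_init__(self) -> None:
        if self.pattern in _PATTERN_COUNTS and len(self.probes) != _PATTERN_COUNTS[self.pattern]:
            raise ValueError(
                f"pattern '{self.pattern}' requires {_PATTERN_COUNTS[self.pattern]} probes, "
                f"got {len(self.probes)}"
            )
        pts = np.array([p.entry_point for p in self.probes])
        for i in range(len(self.probes)):
            for j in range(i + 1, len(self.probes)):
                d = np.linalg.norm(pts[i] - pts[j])
                rr = self.probes[i].radius + self.probes[j].radius
                if d < rr:
                    raise ValueError(f"probes {i} and {j} overlap (center distance {d:.4g} m)")

    def __len__(self) -> int:
        return len(self.probes)

    def entry_points(self) -> np.ndarray:
        return np.array([p.entry_point for p in self.probes])

    def to_dict(self) -> dict:
        return {
            "pattern": self.pattern,
            "spacing": self.spacing,
            "probes": [p.to_dict() for p in self.probes],
        }


@dataclass(frozen=True)
class LoadCurve:
    """Piecewise-linear probe surface temperature protocol.

    Ramp from ``start_temperature`` to ``plateau_temperature`` over
    ``ramp_duration``, hold until ``freeze_duration``, then ramp linearly to
    ``thaw_target_temperature`` over ``thaw_duration`` and hold.  A stand-in
    for the measured single-probe boundary trace of an argon/helium console:
    only its plateau level and ramp rate are tunable, not its fine structure.
    """

    start_temperature: float = 25.0
    plateau_temperature: float = -150.0
    ramp_duration: float = 60.0
    freeze_duration: float = 900.0
    thaw_target_temperature: float = 20.0
    thaw_duration: float = 240.0

    def __post_init__(self) -> None:
        if not self.plateau_temperature < self.start_temperature:
            raise ValueError("plateau_temperature must be below start_temperature")
        if self.ramp_duration < 0 or self.thaw_duration < 0:
            raise ValueError("durations must be non-negative")
        if self.freeze_duration < self.ramp_duration:
            raise ValueError("freeze_duration must cover the ramp")

    def __call__(self, t):
        return evaluate_load_curve(self, t)

    def to_dict(self) -> dict:
        return asdict(self)


def evaluate_load_curve(curve: LoadCurve, t):
    """Probe surface temperature at time ``t`` (s); vectorized, clamped at segment ends."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("load curve time must be non-negative")
    # knots of the piecewise-linear protocol
    tp = [0.0, curve.ramp_duration, curve.freeze_duration,
          curve.freeze_duration + curve.thaw_duration]
    Tp = [curve.start_temperature, curve.plateau_temperature,
          curve.plateau_temperature, curve.thaw_target_temperature]
    # np.interp requires strictly increasing x; collapse zero-length segments
    knots_t, knots_T = [tp[0]], [Tp[0]]
    for ti, Ti in zip(tp[1:], Tp[1:]):
        if ti > knots_t[-1]:
            knots_t.append(ti)
            knots_T.append(Ti)
        else:
            knots_T[-1] = Ti
    out = np.interp(t, knots_t, knots_T)
    if np.ndim(t) == 0:
        return float(out)
    return out


def make_layout(
    pattern: str,
    spacing: float = 0.01,
    depth: float = 0.02,
    active_length: float | None = None,
    radius: float = 0.00085,
    center: tuple[float, float] = (0.0, 0.0),
) -> ProbeLayout:
    """Build one of the standard probe patterns.

    single
        one probe at the lateral origin;
    five
        a central probe plus four probes on an annulus of radius ``spacing``
        (at the +-x / +-y positions);
    seven
        a central probe plus a hexagon of circumradius ``spacing``
        ("plum-blossom" arrangement);
    nine
        a 3x3 square lattice with nearest-neighbor distance ``spacing``.

    All probes are parallel, inserted along -z to ``depth``.  The whole
    inserted length cools by default (``active_length=None``).
    """
    if pattern not in _PATTERN_COUNTS:
        raise ValueError(
            f"unknown pattern '{pattern}'; choose from {sorted(_PATTERN_COUNTS)} "
            "or assemble a custom ProbeLayout directly"
        )
    if active_length is None:
        active_length = depth
    cx, cy = center
    if pattern == "single":
        offsets = [(0.0, 0.0)]
    elif pattern == "five":
        offsets = [(0.0, 0.0), (spacing, 0.0), (-spacing, 0.0),
                   (0.0, spacing), (0.0, -spacing)]
    elif pattern == "seven":
        offsets = [(0.0, 0.0)]
        for k in range(6):
            a = np.pi / 3.0 * k
            offsets.append((spacing * np.cos(a), spacing * np.sin(a)))
    else:  # nine
        offsets = [(i * spacing, j * spacing) for j in (-1, 0, 1) for i in (-1, 0, 1)]
    if pattern != "single" and spacing <= 2 * radius:
        raise ValueError(
            f"spacing {spacing} m too small for probe radius {radius} m "
            "(probes would overlap)"
        )
    probes = tuple(
        Probe(
            entry_point=(cx + ox, cy + oy, 0.0),
            insertion_depth=depth,
            active_length=active_length,
            radius=radius,
        )
        for ox, oy in offsets
    )
    return ProbeLayout(pattern=pattern, spacing=spacing, probes=probes)


def rasterize_layout(layout: ProbeLayout, grid, thin_probe: str = "snap"):
    """Mark grid cells covered by the probes.

    Returns ``(active_mask, shaft_mask)`` boolean arrays on ``grid``:
    ``active_mask`` are cells whose centers fall inside a probe cylinder's
    distal active segment (these receive the Dirichlet load-curve
    temperature); ``shaft_mask`` are the remaining probe cells (treated as
    thermally insulated).  The masks are disjoint.

    A probe thinner than the cell size can miss every cell center; with
    ``thin_probe="snap"`` (default) such a probe claims the single nearest
    cell column so coarse-grid runs remain possible, while
    ``thin_probe="error"`` rejects the configuration instead.
    """
    if thin_probe not in ("snap", "error"):
        raise ValueError("thin_probe must be 'snap' or 'error'")
    centers = grid.cell_centers()  # (nx, ny, nz, 3)
    X, Y, Z = centers[..., 0], centers[..., 1], centers[..., 2]
    active = np.zeros(grid.shape, dtype=bool)
    shaft = np.zeros(grid.shape, dtype=bool)
    lo = np.asarray(grid.origin)
    hi = lo + np.asarray(grid.shape) * grid.spacing
    for idx, probe in enumerate(layout.probes):
        ex, ey, ez = probe.entry_point
        tipz = ez - probe.insertion_depth
        if not (lo[0] <= ex <= hi[0] and lo[1] <= ey <= hi[1]
                and lo[2] <= tipz and ez <= hi[2]):
            raise ValueError(f"probe {idx} lies outside the simulation grid")
        r2 = (X - ex) ** 2 + (Y - ey) ** 2
        inside_r = r2 <= probe.radius ** 2
        in_depth = (Z >= tipz) & (Z <= ez)
        act_lo = tipz
        act_hi = tipz + probe.active_length
        in_active = (Z >= act_lo) & (Z <= act_hi)
        cells = inside_r & in_depth
        if not cells.any():
            if thin_probe == "error":
                raise ValueError(
                    f"probe {idx} (radius {probe.radius} m) captured no cells on a "
                    f"{grid.spacing} m grid"
                )
            # claim the nearest lateral column (deterministic: argmin on flat index)
            flat = np.argmin(np.where(in_depth, r2, np.inf))
            i0, j0, _ = np.unravel_index(flat, grid.shape)
            cells = np.zeros(grid.shape, dtype=bool)
            cells[i0, j0, :] = in_depth[i0, j0, :]
        active |= cells & in_active
        shaft |= cells & ~in_active
    shaft &= ~active
    if not active.any():
        raise ValueError("layout rasterization produced no active probe cells")
    return active, shaft
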