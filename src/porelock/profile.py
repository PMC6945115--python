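"""HOLE-style pore radius profiles and hydrophobicity profiles along the
channel axis.

At each axial grid point s the pore radius is the radius of the largest
probe sphere whose centre lies in the slice plane through s: the centre
position is optimised laterally (multi-start local search from a
deterministic lattice of starting points around the axis) and the
radius at a candidate centre c is min over atoms of (|c - x_atom| -
vdW_atom), capped at a search cap and clamped at zero on steric
overlap. A narrow hydrophobic stretch of such a profile (radius below
roughly 4-5 A with hydrophobic lining) is the classic signature of a
hydrophobic gate: sterically passable but prone to dewetting.

The hydrophobicity profile assigns each pore-facing residue its
Wimley-White interface-scale value rescaled to [-1, 1] (-1 very
hydrophilic, +1 very hydrophobic) and averages along s with Gaussian
weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .channel import ChannelAxis
from .data import (
    BONDI_VDW_RADII,
    rescaled_hydrophobicity,
    vdw_radius,
)
from .errors import ConfigurationError

DEFAULT_S_GRID = np.arange(-40.0, 40.0 + 1e-9, 0.5)  # Angstrom
DEFAULT_CAP = 10.0  # Angstrom
DEFAULT_SEARCH_RADIUS = 8.0  # lateral search box half-width, Angstrom


@dataclass
class PoreProfile:
    """Radius and/or hydrophobicity versus axial coordinate for one frame."""

    s: np.ndarray
    radius: np.ndarray | None = None
    hydrophobicity: np.ndarray | None = None
    centers: np.ndarray | None = None  # probe centre per slice, (n, 3)
    frame: int = 0

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        if np.any(np.diff(self.s) <= 0):
            raise ValueError("s grid must be strictly increasing")


@dataclass
class ProfileStatistics:
    s: np.ndarray
    mean_radius: np.ndarray
    sd_radius: np.ndarray
    n_frames: int


def _slice_basis(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ direction) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - (ref @ direction) * direction
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(direction, e1)
    return e1, e2


def _lattice(search_radius: float, spacing: float = 1.0) -> np.ndarray:
    """Deterministic 2D lattice of probe-centre starting points."""
    ticks = np.arange(-search_radius, search_radius + 1e-9, spacing)
    xx, yy = np.meshgrid(ticks, ticks)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    keep = np.linalg.norm(pts, axis=1) <= search_radius + 1e-9
    pts = pts[keep]
    # sort by distance to the axis so ties resolve toward the axis
    order = np.lexsort((pts[:, 1], pts[:, 0], np.linalg.norm(pts, axis=1)))
    return pts[order]


def _clearance(center3: np.ndarray, positions: np.ndarray, radii: np.ndarray) -> float:
    d = np.linalg.norm(positions - center3, axis=1) - radii
    return float(d.min())


def pore_radius_profile(
    positions: np.ndarray,
    elements,
    axis: ChannelAxis,
    s_grid: np.ndarray | None = None,
    vdw_table: dict[str, float] | None = None,
    radii: np.ndarray | None = None,
    cap: float = DEFAULT_CAP,
    search_radius: float = DEFAULT_SEARCH_RADIUS,
    frame: int = 0,
) -> PoreProfile:
    """Pore radius versus axial coordinate for one frame.

    Parameters
    ----------
    positions : (N, 3) array, Angstrom
    elements : sequence of element symbols (ignored when ``radii`` given)
    axis : ChannelAxis
    s_grid : axial grid (A); default -40..40 in 0.5 A steps
    vdw_table : element -> vdW radius; default Bondi radii
    radii : per-atom vdW radii overriding the table lookup
    cap : maximum reported radius (open bulk)
    search_radius : lateral half-width of the probe-centre search box
    """
    positions = np.asarray(positions, dtype=float)
    if positions.size == 0:
        raise ConfigurationError("empty atom set")
    if radii is None:
        table = BONDI_VDW_RADII if vdw_table is None else vdw_table
        radii = np.array([vdw_radius(el, table) for el in elements], dtype=float)
    else:
        radii = np.asarray(radii, dtype=float)
    s_grid = DEFAULT_S_GRID if s_grid is None else np.asarray(s_grid, dtype=float)
    e1, e2 = _slice_basis(axis.direction)
    s_atoms = axis.s(positions)
    lattice = _lattice(search_radius)
    out = np.empty_like(s_grid)
    centers = np.empty((len(s_grid), 3))
    window = cap + radii.max() + search_radius
    for i, s in enumerate(s_grid):
        near = np.abs(s_atoms - s) <= window
        pos = positions[near]
        rad = radii[near]
        plane_origin = axis.origin + s * axis.direction
        if pos.size == 0:
            out[i] = cap
            centers[i] = plane_origin
            continue

        def clearance_uv(uv: np.ndarray) -> float:
            c = plane_origin + uv[0] * e1 + uv[1] * e2
            return _clearance(c, pos, rad)

        def objective(uv: np.ndarray) -> float:
            return -clearance_uv(uv)

        def reachable(uv: np.ndarray) -> bool:
            # the probe centre must be reachable from the axis without
            # steric overlap, so that clearance maxima outside the atom
            # ring (bulk solvent beyond a collapsed pore) are rejected
            length = np.linalg.norm(uv)
            if length < 1e-9:
                return True
            n_steps = max(2, int(np.ceil(length / 0.1)))
            for frac in np.linspace(0.0, 1.0, n_steps):
                if clearance_uv(uv * frac) < -1e-9:
                    return False
            return True

        # coarse pass over the deterministic lattice, then local refinement
        # from the best starts; only centres in the pore basin (reachable
        # from the axis) are accepted, ties resolving toward the axis
        coarse = np.array([objective(uv) for uv in lattice])
        best_idx = list(np.argsort(coarse, kind="stable")[:3])
        if 0 not in best_idx:
            best_idx.append(0)  # always refine from the axis point
        best_val, best_uv = None, lattice[0]
        for j in best_idx:
            res = minimize(
                objective,
                lattice[j],
                method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400},
            )
            uv = res.x
            if np.linalg.norm(uv) > search_radius:  # keep inside the search box
                uv = uv / np.linalg.norm(uv) * search_radius
            val = objective(uv)
            if not reachable(uv):
                continue
            better = best_val is None or val < best_val - 1e-9
            tie_closer = (
                best_val is not None
                and abs(val - best_val) <= 1e-9
                and np.linalg.norm(uv) < np.linalg.norm(best_uv) - 1e-9
            )
            if better or tie_closer:
                best_val, best_uv = val, uv
        if best_val is None:
            # the axis point itself is sterically blocked and no optimum
            # is reachable: the slice is occluded, clearance clamps to 0
            best_val, best_uv = objective(lattice[0]), lattice[0]
        r = -best_val
        out[i] = float(np.clip(r, 0.0, cap))
        centers[i] = plane_origin + best_uv[0] * e1 + best_uv[1] * e2
    return PoreProfile(s=s_grid, radius=out, centers=centers, frame=frame)


def hydrophobicity_profile(
    residue_positions,
    residue_names,
    axis: ChannelAxis,
    s_grid: np.ndarray | None = None,
    radius_profile: PoreProfile | None = None,
    scale_table: dict[str, float] | None = None,
    smoothing_sigma: float = 2.0,
    facing_cutoff: float = 3.5,
) -> PoreProfile:
    """Hydrophobicity of the pore lining versus axial coordinate.

    ``residue_positions`` is a sequence of (n_i, 3) heavy-atom coordinate
    arrays, one per residue, with ``residue_names`` the matching residue
    names. A residue is pore-facing at s when any of its heavy atoms
    lies within ``facing_cutoff`` (A) of the pore surface at s (the
    sphere of the slice's pore radius around its probe centre; when no
    ``radius_profile`` is given, within facing_cutoff of the slice plane
    laterally close to the axis is used). The profile value at s is the
    Gaussian(``smoothing_sigma``)-weighted average of the facing
    residues' rescaled scale values, weighted by axial proximity.
    Values are bounded in [-1, 1]; grid points with no facing residue
    are NaN.
    """
    s_grid = DEFAULT_S_GRID if s_grid is None else np.asarray(s_grid, dtype=float)
    values = np.array(
        [rescaled_hydrophobicity(name, scale_table) for name in residue_names]
    )
    res_s = np.array(
        [axis.s(np.asarray(p, dtype=float)).mean() for p in residue_positions]
    )
    n_res = len(values)
    use_surface = radius_profile is not None and radius_profile.radius is not None
    facing = np.zeros((len(s_grid), n_res), dtype=bool)
    for i, s in enumerate(s_grid):
        for j, pos in enumerate(residue_positions):
            pos = np.asarray(pos, dtype=float)
            if use_surface:
                # distance to the pore surface at s: sphere of the slice
                # pore radius around the optimised probe centre
                center = radius_profile.centers[i]
                r_pore = radius_profile.radius[i]
                dist = np.abs(np.linalg.norm(pos - center, axis=1) - r_pore)
            else:
                # no surface available: axial proximity to the slice plane
                dist = np.abs(axis.s(pos) - s)
            if dist.min() <= facing_cutoff:
                facing[i, j] = True
    out = np.full(len(s_grid), np.nan)
    for i, s in enumerate(s_grid):
        idx = np.nonzero(facing[i])[0]
        if idx.size == 0:
            continue
        w = np.exp(-0.5 * ((res_s[idx] - s) / smoothing_sigma) ** 2)
        if w.sum() <= 0:
            w = np.ones_like(w)
        out[i] = float(np.average(values[idx], weights=w))
    return PoreProfile(s=s_grid, hydrophobicity=out)


def profile_statistics(
    profiles: list[PoreProfile], n_points: int | None = None
) -> ProfileStatistics:
    """Pointwise mean and sample SD of per-frame radius profiles.

    ``n_points`` subsamples the frame list to that many equally spaced
    frames (stride subsampling) before aggregating.
    """
    if len(profiles) < 2:
        raise ConfigurationError("need at least two frames for statistics")
    s0 = profiles[0].s
    for p in profiles[1:]:
        if len(p.s) != len(s0) or not np.allclose(p.s, s0):
            raise ConfigurationError("profiles must share a common s grid")
    if n_points is not None and n_points < len(profiles):
        # equally distributed frames: stride subsampling from frame 0
        idx = (np.arange(n_points) * len(profiles)) // n_points
        profiles = [profiles[i] for i in idx]
    stack = np.array([p.radius for p in profiles])
    return ProfileStatistics(
        s=s0,
        mean_radius=stack.mean(axis=0),
        sd_radius=stack.std(axis=0, ddof=1),
        n_frames=len(profiles),
    )


def classify_gate_geometry(
    stats: ProfileStatistics,
    hydrophobicity: PoreProfile | None = None,
    s_gate_upper: float = 0.0,
    s_gate_lower: float | None = None,
    window: float = 4.0,
    radius_threshold: float = 4.0,
) -> dict:
    """Annotate gate geometry: minimum mean radius around the 9'
    hydrophobic gate (s near 0) and around the -2' intracellular gate,
    with a hydrophobic-gating risk flag when the 9' constriction is
    narrower than ``radius_threshold`` (default 4 A, the lower edge of
    the dehydration-prone range) *and* locally hydrophobic (> 0)."""
    s = stats.s

    def window_min(center: float) -> float:
        mask = np.abs(s - center) <= window
        if not mask.any():
            raise ConfigurationError(
                f"gate window around s={center} falls outside the profile grid"
            )
        return float(stats.mean_radius[mask].min())

    r9 = window_min(s_gate_upper)
    record = {
        "min_radius_9prime": r9,
        "radius_threshold": radius_threshold,
    }
    if s_gate_lower is not None:
        record["min_radius_minus2prime"] = window_min(s_gate_lower)
    local_h = 0.0
    if hydrophobicity is not None and hydrophobicity.hydrophobicity is not None:
        mask = np.abs(hydrophobicity.s - s_gate_upper) <= window
        vals = hydrophobicity.hydrophobicity[mask]
        vals = vals[~np.isnan(vals)]
        local_h = float(vals.mean()) if vals.size else 0.0
    record["local_hydrophobicity_9prime"] = local_h
    record["hydrophobic_gating_risk"] = bool(r9 < radius_threshold and local_h > 0)
    return record
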