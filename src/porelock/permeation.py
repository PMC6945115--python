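"""Ion/water tracking in the pore cylinder: axial traces, permeation
counting, selectivity, wetting, and 3D number densities.

A particle is "in the pore" when it lies within a cylinder around the
channel axis (default radius 5 A) between the intracellular (-2') and
extracellular (20') ring levels. Permeation events are counted with a
three-compartment state machine per particle — below, inside, above —
on the unwrapped axial coordinate: a traversal below -> inside -> above
(direction +1) or above -> inside -> below (direction -1) counts one
event, provided the particle stayed inside the lateral cylinder during
the inside frames (up to a configurable number of tolerated excursion
frames, default 0). Re-entries that return to the starting compartment
count nothing. Both directions are pooled in totals (no membrane
potential). Under periodic boundaries the compartments tile along the
axis, so a particle that permeates, wraps, and permeates again is
counted once per traversal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .channel import ChannelAxis, ChannelModel
from .errors import ConfigurationError


@dataclass
class PoreCylinder:
    """The pore-bound region: lateral radius and axial bounds (in s, A)."""

    z_lo: float
    z_hi: float
    r_cyl: float = 5.0

    def __post_init__(self) -> None:
        if not self.z_lo < self.z_hi:
            raise ValueError("z_lo must be below z_hi")
        if self.r_cyl <= 0:
            raise ValueError("cylinder radius must be positive")

    @classmethod
    def from_model(cls, model: ChannelModel, r_cyl: float = 5.0) -> "PoreCylinder":
        """Bounds at the -2' and 20' Calpha ring centroids of the model
        (fixed, not per-frame, so the state machine stays well defined)."""
        z_lo = float(model.s_of(model.ring_centroid(-2)))
        z_hi = float(model.s_of(model.ring_centroid(20)))
        return cls(z_lo=z_lo, z_hi=z_hi, r_cyl=r_cyl)


@dataclass
class AxialTrace:
    """Per-frame axial coordinate and cylinder membership of one particle."""

    particle_id: int
    species: str
    s: np.ndarray  # unwrapped axial coordinate per frame, A
    lateral: np.ndarray  # distance from the axis per frame, A
    in_cylinder: np.ndarray = field(default=None)  # lateral <= r_cyl

    def __len__(self) -> int:
        return len(self.s)


@dataclass(frozen=True)
class PermeationEvent:
    entry_frame: int
    exit_frame: int
    direction: int  # +1 below->above, -1 above->below

    def __post_init__(self) -> None:
        if not self.entry_frame < self.exit_frame:
            raise ValueError("event frames must be strictly increasing")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +-1")


@dataclass
class PermeationRecord:
    particle_id: int
    species: str
    states: list[str]  # below / inside / above per frame
    events: list[PermeationEvent]


def unwrap_axial(s: np.ndarray, period: float | None) -> np.ndarray:
    """Per-particle unwrapping along the axis by minimum-image
    displacement between consecutive frames. Requires frames sampled
    finely enough that every true |ds| < period/2."""
    s = np.asarray(s, dtype=float)
    if period is None or len(s) < 2:
        return s.copy()
    ds = np.diff(s)
    ds -= period * np.round(ds / period)
    return np.concatenate([[s[0]], s[0] + np.cumsum(ds)])


def _regions(s: np.ndarray, z_lo: float, z_hi: float, period: float | None):
    """Classify unwrapped s into pore slabs and bulk intervals.

    Returns (inside flags, bulk index) where the bulk index counts the
    number of pore slabs below the point; it is meaningful only where
    ``inside`` is False.
    """
    s = np.asarray(s, dtype=float)
    if period is None:
        inside = (s >= z_lo) & (s <= z_hi)
        bulk = np.where(s < z_lo, 0, 1)
    else:
        k = np.floor((s - z_lo) / period).astype(int)
        s0 = s - k * period  # mapped into [z_lo, z_lo + period)
        inside = s0 <= z_hi
        bulk = k + 1
    return inside, bulk


def scan_events(
    s_unwrapped: np.ndarray,
    in_cylinder: np.ndarray,
    cylinder: PoreCylinder,
    period: float | None = None,
    tolerance_frames: int = 0,
) -> tuple[list[PermeationEvent], list[str]]:
    """Run the compartment state machine over one particle's unwrapped
    axial path. Returns (events, per-frame state labels)."""
    inside, bulk = _regions(s_unwrapped, cylinder.z_lo, cylinder.z_hi, period)
    in_cylinder = np.asarray(in_cylinder, dtype=bool)
    events: list[PermeationEvent] = []
    states: list[str] = []
    last_bulk: int | None = None
    inside_frames: list[int] = []
    excursions = 0
    for t in range(len(s_unwrapped)):
        if inside[t]:
            states.append("inside")
            inside_frames.append(t)
            if not in_cylinder[t]:
                excursions += 1
            continue
        b = int(bulk[t])
        states.append("below" if b <= 0 else "above")
        if last_bulk is None:
            last_bulk = b
        elif b != last_bulk:
            if excursions <= tolerance_frames:
                direction = 1 if b > last_bulk else -1
                entry = inside_frames[0] if inside_frames else t - 1
                for _ in range(abs(b - last_bulk)):
                    events.append(PermeationEvent(entry, t, direction))
            last_bulk = b
        # returning to the same bulk resets the attempt
        inside_frames = []
        excursions = 0
    return events, states


# ---------------------------------------------------------------------------
# trajectory wrappers


def axial_traces(
    universe,
    selections: dict[str, str],
    axis: ChannelAxis,
    cylinder: PoreCylinder,
    period: float | str | None = "auto",
    start: int = 0,
    stop: int | None = None,
    step: int = 1,
) -> list[AxialTrace]:
    """Extract per-particle axial traces from an MDAnalysis trajectory.

    ``selections`` maps species name -> selection string (water should
    select oxygen atoms; ions their single atom). ``period='auto'``
    takes the box edge along z as the axial period when the axis is
    near the lab z direction (the usual membrane set-up), else no
    unwrapping. Particles are flagged in-cylinder per frame when their
    lateral distance to the axis is at most the cylinder radius.
    """
    groups = {}
    for species, sel in selections.items():
        ag = universe.select_atoms(sel)
        if len(ag) == 0:
            raise ConfigurationError(f"empty selection for species {species!r}: {sel}")
        groups[species] = ag
    frames = universe.trajectory[start:stop:step]
    n_frames = len(frames)
    data = {
        sp: (np.empty((n_frames, len(ag))), np.empty((n_frames, len(ag))))
        for sp, ag in groups.items()
    }
    box_z = None
    for i, ts in enumerate(frames):
        if box_z is None and ts.dimensions is not None and ts.dimensions[2] > 0:
            box_z = float(ts.dimensions[2])
        for sp, ag in groups.items():
            s_arr, l_arr = data[sp]
            s_arr[i] = axis.s(ag.positions)
            l_arr[i] = axis.lateral(ag.positions)
    if period == "auto":
        period = box_z if (box_z and abs(axis.direction[2]) > 0.97) else None
    traces = []
    for sp, ag in groups.items():
        s_arr, l_arr = data[sp]
        for j, atom in enumerate(ag):
            s_un = unwrap_axial(s_arr[:, j], period)
            traces.append(
                AxialTrace(
                    particle_id=int(atom.index),
                    species=sp,
                    s=s_un,
                    lateral=l_arr[:, j],
                    in_cylinder=l_arr[:, j] <= cylinder.r_cyl,
                )
            )
    return traces


def count_permeations(
    traces: list[AxialTrace],
    cylinder: PoreCylinder,
    period: float | None = None,
    tolerance_frames: int = 0,
) -> tuple[dict[str, int], list[PermeationRecord]]:
    """Count permeation events per species over a set of traces."""
    counts: dict[str, int] = {}
    records: list[PermeationRecord] = []
    for trace in traces:
        if len(trace) < 2:
            raise ConfigurationError("traces must cover at least two frames")
        events, states = scan_events(
            trace.s, trace.in_cylinder, cylinder, period, tolerance_frames
        )
        counts.setdefault(trace.species, 0)
        counts[trace.species] += len(events)
        records.append(
            PermeationRecord(
                particle_id=trace.particle_id,
                species=trace.species,
                states=states,
                events=events,
            )
        )
    return counts, records


def selectivity_ratio(cl_events: int, na_events: int) -> dict:
    """Chloride-over-sodium selectivity from event counts."""
    if cl_events < 0 or na_events < 0:
        raise ValueError("counts must be non-negative")
    out = {"cl_events": cl_events, "na_events": na_events}
    if cl_events == 0 and na_events == 0:
        out.update(ratio=float("nan"), flag="undefined")
    elif na_events == 0:
        out.update(ratio=float("inf"), flag="no_sodium_events")
    else:
        out.update(ratio=cl_events / na_events, flag="ok")
    return out


# ---------------------------------------------------------------------------
# wetting


@dataclass
class WettingReport:
    bin_edges: np.ndarray  # z bin edges, A
    occupancy: np.ndarray  # (n_frames, n_bins) water counts
    dewetted: np.ndarray  # boolean, zero-occupancy bins
    fraction_frames_fully_wetted: float
    stretches: list[dict]  # maximal contiguous dewetted (frame, bin) patches


def wetting_analysis(
    water_traces: list[AxialTrace],
    cylinder: PoreCylinder,
    bin_width: float = 1.0,
) -> WettingReport:
    """Per-frame water occupancy of axial bins inside the cylinder.

    A bin is dewetted at a frame iff no water oxygen occupies it inside
    the cylinder. Maximal contiguous dewetted patches in the (frame,
    z-bin) plane are reported with their bounding boxes.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    edges = np.arange(cylinder.z_lo, cylinder.z_hi + bin_width * 0.999, bin_width)
    if edges[-1] < cylinder.z_hi:
        edges = np.append(edges, cylinder.z_hi)
    n_bins = len(edges) - 1
    if water_traces:
        n_frames = len(water_traces[0])
    else:
        n_frames = 1
    occupancy = np.zeros((n_frames, n_bins), dtype=int)
    for trace in water_traces:
        valid = trace.in_cylinder & (trace.s >= edges[0]) & (trace.s < edges[-1])
        idx = np.searchsorted(edges, trace.s[valid], side="right") - 1
        frames = np.nonzero(valid)[0]
        np.add.at(occupancy, (frames, idx), 1)
    dewetted = occupancy == 0
    fully_wetted = ~dewetted.any(axis=1)
    labels, n_patches = ndimage.label(dewetted)
    stretches = []
    for sl in ndimage.find_objects(labels):
        if sl is None:
            continue
        stretches.append(
            {
                "frame_start": int(sl[0].start),
                "frame_stop": int(sl[0].stop - 1),
                "z_bin_start": int(sl[1].start),
                "z_bin_stop": int(sl[1].stop - 1),
            }
        )
    return WettingReport(
        bin_edges=edges,
        occupancy=occupancy,
        dewetted=dewetted,
        fraction_frames_fully_wetted=float(fully_wetted.mean()),
        stretches=stretches,
    )


# ---------------------------------------------------------------------------
# 3D number densities


@dataclass
class DensityGrid:
    origin: np.ndarray  # lower corner, A
    voxel: np.ndarray  # edge lengths, A
    mean_counts: np.ndarray  # time-averaged counts per voxel
    density: np.ndarray  # particles / nm^3

    def voxels_at_least(self, threshold: float) -> np.ndarray:
        """Boolean mask of voxels meeting an isosurface threshold
        (particles/nm^3), e.g. 0.5 for occupancy isosurfaces."""
        return self.density >= threshold

    @property
    def integral(self) -> float:
        """Total density x volume = mean in-box particle count."""
        voxel_nm3 = float(np.prod(self.voxel)) / 1000.0
        return float(self.density.sum() * voxel_nm3)


def density_grid(
    positions_per_frame: list[np.ndarray],
    bounds: tuple[tuple[float, float], ...],
    voxel: float | tuple[float, float, float] = 1.0,
) -> DensityGrid:
    """Time-averaged 3D number density in particles/nm^3.

    ``positions_per_frame`` is one (N_t, 3) array (A) per frame;
    ``bounds`` three (lo, hi) pairs; ``voxel`` the voxel edge length(s)
    in A.
    """
    if len(positions_per_frame) == 0:
        raise ConfigurationError("need at least one frame")
    voxel = np.broadcast_to(np.atleast_1d(np.asarray(voxel, dtype=float)), (3,)).copy()
    if np.any(voxel <= 0):
        raise ValueError("voxel edges must be positive")
    bounds = [(float(lo), float(hi)) for lo, hi in bounds]
    edges = [
        np.arange(lo, hi + v * 0.999, v) for (lo, hi), v in zip(bounds, voxel)
    ]
    shape = tuple(len(e) - 1 for e in edges)
    counts = np.zeros(shape)
    for pos in positions_per_frame:
        pos = np.atleast_2d(np.asarray(pos, dtype=float))
        if pos.shape[-1] != 3:
            pos = pos.reshape(-1, 3)
        h, _ = np.histogramdd(pos, bins=edges)
        counts += h
    mean_counts = counts / len(positions_per_frame)
    voxel_nm3 = float(np.prod(voxel)) / 1000.0
    return DensityGrid(
        origin=np.array([e[0] for e in edges]),
        voxel=voxel,
        mean_counts=mean_counts,
        density=mean_counts / voxel_nm3,
    )


def density_grid_from_universe(
    universe, selection: str, bounds, voxel=1.0, start=0, stop=None, step=1
) -> DensityGrid:
    ag = universe.select_atoms(selection)
    frames = [
        ag.positions.copy() for _ in universe.trajectory[start:stop:step]
    ]
    return density_grid(frames, bounds, voxel)


def write_opendx(grid: DensityGrid, path) -> None:
    """Export a density grid in OpenDX scalar-field format (A units)."""
    nx, ny, nz = grid.density.shape
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        "origin {:.4f} {:.4f} {:.4f}".format(*grid.origin),
        f"delta {grid.voxel[0]:.4f} 0 0",
        f"delta 0 {grid.voxel[1]:.4f} 0",
        f"delta 0 0 {grid.voxel[2]:.4f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {nx * ny * nz} data follows",
    ]
    flat = grid.density.ravel(order="C")
    for i in range(0, len(flat), 3):
        lines.append(" ".join(f"{v:.6f}" for v in flat[i : i + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "density" class field')
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
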