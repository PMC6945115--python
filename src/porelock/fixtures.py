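"""Synthetic test systems: an idealized 5-fold-symmetric pore and
scripted particle trajectories with known permeation ground truth.

The toy pentamer is a bundle of five straight "M2-like" chains around
the lab z axis: one Calpha per residue at a prescribed ring radius per
primed position (linearly interpolated in between) plus an outward
side-chain centroid pseudo-atom (CB), with the 9' ring at the box
centre. The toy trajectory scripts particle paths directly — each
prescribed permeation is a monotone axial lap through the pore
cylinder (successive laps continue through the periodic image, so
wrapped and unwrapped emissions describe the same physical path) and
distractor particles bounce into the pore mouth and retreat without
traversing. No forces or solvent structure are modelled; only the
geometric/statistical structure the analyses consume.

All generation is seeded (default 42) and deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

import MDAnalysis as mda
from MDAnalysis.coordinates.memory import MemoryReader

from .channel import ChannelAxis, ChannelModel, PRIMED_POSITIONS
from .permeation import PoreCylinder

#: Pore-lining M2-like sequence for primed positions -2' .. 20'
#: (one letter per position; matches the GlyR alpha1 M2 register with
#: P at -2', T at 6' and L at 9').
DEFAULT_M2_SEQUENCE = "PARVGLGITTVLTMTTQSSGSRA"

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

#: Open-state-like ring radii (A) per primed position.
DEFAULT_RING_RADII = {-2: 4.0, 2: 4.5, 6: 4.5, 9: 5.0, 13: 5.5, 16: 6.5, 20: 8.0}


@dataclass
class ToyPoreSpec:
    """Geometry of the idealized symmetric pore."""

    ring_radii: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_RING_RADII)
    )
    rise_per_residue: float = 1.5  # A of z per residue
    n_subunits: int = 5
    sequence: str = DEFAULT_M2_SEQUENCE  # one letter per primed position -2..20
    m2_start: int = 250  # residue number of the -2' position
    box: tuple[float, float, float] = (60.0, 60.0, 80.0)
    jitter: float = 0.0  # Gaussian coordinate noise (A), seeded
    seed: int = 42

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.ring_radii.values()):
            raise ValueError("ring radii must be positive")
        if self.n_subunits != 5:
            raise ValueError("only pentamers are supported")


@dataclass
class TrajectorySpec:
    """Scripted particle trajectory with prescribed permeation counts."""

    n_frames: int = 300
    dt_ps: float = 100.0  # frame spacing label
    roster: dict[str, int] = field(
        default_factory=lambda: {"water": 60, "Cl": 10, "Na": 3}
    )
    traversals: dict[str, int] = field(
        default_factory=lambda: {"water": 0, "Cl": 52, "Na": 1}
    )
    lateral_jitter: float = 1.0  # A
    margin: float = 5.0  # bulk margin beyond the pore bounds, A
    wrapped: bool = False  # emit PBC-wrapped z coordinates
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("need at least two frames")
        for sp, t in self.traversals.items():
            if t < 0:
                raise ValueError("traversal counts must be non-negative")
            if t and self.n_frames <= 2 * t:
                raise ValueError(
                    f"{sp}: {t} traversals need more than {2 * t} frames"
                )


# ---------------------------------------------------------------------------
# toy pentamer


def _pore_geometry(spec: ToyPoreSpec):
    """Residue-level primed indices, radii and z positions (box frame)."""
    primed = np.arange(-2, 21)  # one residue per primed unit
    known = sorted(spec.ring_radii)
    radii = np.interp(primed, known, [spec.ring_radii[p] for p in known])
    cz = spec.box[2] / 2.0
    z = cz + (primed - 9) * spec.rise_per_residue
    return primed, radii, z


def toy_axis(spec: ToyPoreSpec) -> ChannelAxis:
    """The lab-z channel axis of the toy pore, s = 0 at the 9' ring."""
    cx, cy, cz = spec.box[0] / 2.0, spec.box[1] / 2.0, spec.box[2] / 2.0
    return ChannelAxis(origin=np.array([cx, cy, cz]), direction=np.array([0.0, 0.0, 1.0]))


def toy_cylinder(spec: ToyPoreSpec, r_cyl: float = 5.0) -> PoreCylinder:
    """Pore cylinder with bounds at the toy -2' and 20' rings (s units)."""
    rise = spec.rise_per_residue
    return PoreCylinder(z_lo=(-2 - 9) * rise, z_hi=(20 - 9) * rise, r_cyl=r_cyl)


def build_toy_pentamer(spec: ToyPoreSpec | None = None) -> ChannelModel:
    """Build the idealized pentamer as a fully assembled ChannelModel."""
    spec = ToyPoreSpec() if spec is None else spec
    if len(spec.sequence) != 23:
        raise ValueError("sequence must cover primed positions -2..20 (23 residues)")
    primed, radii, z = _pore_geometry(spec)
    rng = np.random.default_rng(spec.seed)
    cx, cy = spec.box[0] / 2.0, spec.box[1] / 2.0

    names, resnames, resids, chains, positions = [], [], [], [], []
    atom_resindex = []
    res_names, res_ids, res_chains = [], [], []
    res_index = -1
    for j in range(5):
        theta = 2.0 * np.pi * j / 5.0
        ux, uy = np.cos(theta), np.sin(theta)
        chain = "ABCDE"[j]
        for i, p in enumerate(primed):
            res_index += 1
            resname = _ONE_TO_THREE[spec.sequence[i]]
            resid = spec.m2_start + int(p) + 2
            res_names.append(resname)
            res_ids.append(resid)
            res_chains.append(chain)
            ca = np.array([cx + radii[i] * ux, cy + radii[i] * uy, z[i]])
            atoms = [("CA", ca)]
            if resname != "GLY":
                cb = np.array(
                    [cx + (radii[i] + 1.4) * ux, cy + (radii[i] + 1.4) * uy, z[i]]
                )
                atoms.append(("CB", cb))
            for name, pos in atoms:
                names.append(name)
                resnames.append(resname)
                resids.append(resid)
                chains.append(chain)
                atom_resindex.append(res_index)
                positions.append(pos)
    positions = np.array(positions)
    if spec.jitter > 0:
        positions = positions + rng.normal(0.0, spec.jitter, positions.shape)

    n_atoms = len(positions)
    n_res = res_index + 1
    segindex = {c: k for k, c in enumerate("ABCDE")}
    universe = mda.Universe.empty(
        n_atoms,
        n_residues=n_res,
        n_segments=5,
        atom_resindex=np.array(atom_resindex),
        residue_segindex=np.array([segindex[c] for c in res_chains]),
        trajectory=True,
    )
    universe.add_TopologyAttr("names", names)
    universe.add_TopologyAttr("elements", ["C"] * n_atoms)
    universe.add_TopologyAttr("resnames", res_names)
    universe.add_TopologyAttr("resids", res_ids)
    universe.add_TopologyAttr("segids", list("ABCDE"))
    universe.add_TopologyAttr("chainIDs", chains)
    universe.add_TopologyAttr("occupancies", np.ones(n_atoms))
    universe.add_TopologyAttr("tempfactors", np.zeros(n_atoms))
    universe.atoms.positions = positions
    universe.dimensions = [spec.box[0], spec.box[1], spec.box[2], 90.0, 90.0, 90.0]

    model = ChannelModel.from_universe(universe)
    model.assign_primed_positions(spec.m2_start, primed_positions=PRIMED_POSITIONS)
    model.compute_axis("ring_centroids")
    return model


def write_structure(model: ChannelModel, path) -> None:
    """Write the model structure as PDB or GRO (by extension)."""
    model.universe.atoms.write(str(path))


# ---------------------------------------------------------------------------
# scripted trajectories


def _split_traversals(total: int, n_particles: int) -> list[int]:
    base, extra = divmod(total, n_particles)
    return [base + (1 if i < extra else 0) for i in range(n_particles)]


_SPECIES_ATOMS = {
    "water": ("OW", "SOL", "O"),
    "Cl": ("CL", "CL", "Cl"),
    "Na": ("NA", "NA", "Na"),
}


def build_trajectory(
    tspec: TrajectorySpec | None = None, pspec: ToyPoreSpec | None = None
):
    """Script particle paths through the toy pore.

    Returns ``(universe, ground_truth)`` where the universe holds the
    particle-only trajectory (frames in memory; write out with
    :func:`write_trajectory`) and ``ground_truth`` records the
    prescribed permeation events per species and particle.

    Path design: a particle with T prescribed traversals climbs
    linearly by T box lengths along z starting from just below the -2'
    bound, passing through the pore cylinder once per lap; lateral
    position jitters inside the cylinder. Particles with none bounce
    into the lower pore mouth and retreat (entering below and returning
    below: zero events). Waters ladder the pore to keep it wetted.
    With ``wrapped=True`` z is emitted wrapped into the box.
    """
    tspec = TrajectorySpec() if tspec is None else tspec
    pspec = ToyPoreSpec() if pspec is None else pspec
    rng = np.random.default_rng(tspec.seed)
    axis = toy_axis(pspec)
    cyl = toy_cylinder(pspec)
    box_z = pspec.box[2]
    cz = box_z / 2.0
    z_lo_abs = cz + cyl.z_lo
    z_hi_abs = cz + cyl.z_hi
    n_frames = tspec.n_frames
    t = np.arange(n_frames, dtype=float)

    names, resnames, elements = [], [], []
    per_atom_z = []  # unwrapped absolute z per particle
    per_atom_lat = []  # (x, y) offsets from the axis
    truth: dict[str, dict] = {}
    max_lat = cyl.r_cyl - 0.5

    for species, count in tspec.roster.items():
        if species not in _SPECIES_ATOMS:
            raise ValueError(f"unknown species {species!r}")
        total = int(tspec.traversals.get(species, 0))
        shares = _split_traversals(total, count) if count else []
        truth[species] = {"events": total, "per_particle": shares}
        aname, rname, elem = _SPECIES_ATOMS[species]
        for i, share in enumerate(shares):
            names.append(aname)
            resnames.append(rname)
            elements.append(elem)
            if species == "water" and share == 0:
                # ladder the pore: static axial stations keep every z bin
                # occupied in every frame (lateral jitter only)
                frac = (i + 0.5) / max(count, 1)
                z0 = z_lo_abs - 2.0 + frac * (z_hi_abs - z_lo_abs + 4.0)
                zpath = np.full(n_frames, z0)
            elif share > 0:
                # monotone climb of `share` box lengths; starts in the
                # lower bulk margin, ends in a bulk margin `share` laps up
                z0 = z_lo_abs - tspec.margin
                total_climb = share * box_z
                zpath = z0 + total_climb * t / (n_frames - 1)
            else:
                # distractor: bounce into the pore mouth and retreat
                depth = 0.4 * (z_hi_abs - z_lo_abs)
                phase = rng.uniform(0.0, np.pi)
                zpath = (
                    z_lo_abs
                    - tspec.margin
                    + depth * np.abs(np.sin(2.0 * np.pi * t / n_frames * 2 + phase))
                )
            per_atom_z.append(zpath)
            lat = rng.normal(0.0, tspec.lateral_jitter, (n_frames, 2))
            norm = np.linalg.norm(lat, axis=1, keepdims=True)
            scale = np.where(norm > max_lat, max_lat / np.maximum(norm, 1e-12), 1.0)
            per_atom_lat.append(lat * scale)

    n_atoms = len(names)
    coords = np.empty((n_frames, n_atoms, 3))
    for j in range(n_atoms):
        z = per_atom_z[j]
        if tspec.wrapped:
            z = np.mod(z, box_z)
        coords[:, j, 0] = axis.origin[0] + per_atom_lat[j][:, 0]
        coords[:, j, 1] = axis.origin[1] + per_atom_lat[j][:, 1]
        coords[:, j, 2] = z

    universe = mda.Universe.empty(
        n_atoms,
        n_residues=n_atoms,
        atom_resindex=np.arange(n_atoms),
        trajectory=True,
    )
    universe.add_TopologyAttr("names", names)
    universe.add_TopologyAttr("elements", elements)
    universe.add_TopologyAttr("resnames", resnames)
    universe.add_TopologyAttr("resids", np.arange(1, n_atoms + 1))
    dims = np.tile(
        [pspec.box[0], pspec.box[1], pspec.box[2], 90.0, 90.0, 90.0], (n_frames, 1)
    )
    universe.load_new(coords, format=MemoryReader, dimensions=dims)
    ground_truth = {
        "seed": tspec.seed,
        "n_frames": n_frames,
        "dt_ps": tspec.dt_ps,
        "wrapped": tspec.wrapped,
        "species": truth,
    }
    return universe, ground_truth


def write_trajectory(universe, outdir, basename: str = "fixture", formats=("gro", "xtc")):
    """Write the scripted trajectory: GRO topology + XTC frames and/or a
    multi-frame PDB fall-back. Returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    if "gro" in formats:
        path = outdir / f"{basename}.gro"
        universe.trajectory[0]
        universe.atoms.write(str(path))
        written.append(path)
    if "xtc" in formats:
        path = outdir / f"{basename}.xtc"
        with mda.Writer(str(path), universe.atoms.n_atoms) as writer:
            for _ in universe.trajectory:
                writer.write(universe.atoms)
        written.append(path)
    if "pdb" in formats:
        path = outdir / f"{basename}_traj.pdb"
        with mda.Writer(str(path), multiframe=True) as writer:
            for _ in universe.trajectory:
                writer.write(universe.atoms)
        written.append(path)
    return written


def write_ground_truth(ground_truth: dict, path) -> None:
    Path(path).write_text(json.dumps(ground_truth, indent=2) + "\n")


def selections_for_fixture() -> dict[str, str]:
    """MDAnalysis selections matching the fixture particle naming."""
    return {"water": "name OW", "Cl": "name CL", "Na": "name NA"}
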