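"""Channel model: structure loading, primed pore positions, channel axis.

Pentameric ligand-gated ion channels (pLGICs) line their ion-conducting
pore with one M2 helix per subunit. Positions along M2 are labelled with
the conserved "primed" numbering, -2' at the intracellular end through
20' at the extracellular end; the pore-lining rings sit at -2', 2', 6',
9', 13', 16' and 20'. This module reads a channel structure (PDB or
GRO), resolves those primed positions to residues per subunit, and
defines the channel axis together with an axial coordinate s whose zero
is the 9' Calpha ring (the hydrophobic gate).

All coordinates are handled in Angstrom (MDAnalysis converts GRO nm
values on read).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

import MDAnalysis as mda

from .errors import AxisError, FormatError, MappingError, StructureError

#: Pore-lining primed positions, intracellular to extracellular.
PRIMED_POSITIONS: tuple[int, ...] = (-2, 2, 6, 9, 13, 16, 20)

#: Primed index p maps to residue number m2_start + p + PRIMED_OFFSET,
#: anchored so that with the human alpha1 GlyR numbering (m2_start=250)
#: position 9' resolves to L261.
PRIMED_OFFSET: int = 2


def primed_to_resid(m2_start: int, primed: int) -> int:
    """Residue number of primed position ``primed`` on an M2 helix whose
    -2' residue is ``m2_start``."""
    return m2_start + primed + PRIMED_OFFSET


@dataclass
class ChannelAxis:
    """A directed line: origin point plus unit vector.

    ``s(x)`` is the signed axial coordinate of point(s) x (projection on
    the direction, relative to the origin); ``lateral(x)`` the distance
    of x from the line.
    """

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise AxisError("axis direction must be non-zero")
        self.direction = d / n

    def s(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = (pts - self.origin) @ self.direction
        return out[0] if np.ndim(points) == 1 else out

    def lateral(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        rel = pts - self.origin
        along = np.outer(rel @ self.direction, self.direction)
        out = np.linalg.norm(rel - along, axis=1)
        return out[0] if np.ndim(points) == 1 else out


@dataclass
class ChannelModel:
    """A channel structure with subunit grouping, primed-position map and axis.

    Attributes
    ----------
    universe : MDAnalysis.Universe
        The underlying structure (coordinates in Angstrom).
    subunits : dict
        Subunit id -> MDAnalysis ResidueGroup.
    subunit_order : list of str
        The five subunit ids in rotational order about the axis
        (positive rotation when viewed along +axis); empty until
        :meth:`compute_axis` runs.
    primed_map : dict
        primed index -> {subunit id -> residue number}.
    axis : ChannelAxis or None
        Channel axis oriented extracellular-positive with s = 0 at the
        9' Calpha ring centroid.
    """

    universe: mda.Universe
    subunits: dict[str, mda.core.groups.ResidueGroup]
    subunit_order: list[str] = field(default_factory=list)
    primed_map: dict[int, dict[str, int]] = field(default_factory=dict)
    axis: ChannelAxis | None = None

    # -- construction -------------------------------------------------

    @classmethod
    def from_file(cls, path, chain_ids: list[str] | None = None) -> "ChannelModel":
        """Load a PDB or GRO structure and group chains into subunits.

        GRO files carry no chain identifiers; if fewer than two distinct
        chain/segment ids are present and the residue count divides by
        five, residues are split into five equal contiguous blocks
        labelled A-E. ``chain_ids`` restricts/grouping to the listed ids.
        """
        try:
            universe = mda.Universe(str(path))
        except Exception as exc:  # MDAnalysis raises a zoo of types
            raise FormatError(f"could not parse structure {path}: {exc}") from exc
        if len(universe.atoms) == 0:
            raise FormatError(f"structure {path} contains no atoms")
        subunits = _group_subunits(universe, chain_ids)
        return cls(universe=universe, subunits=subunits)

    @classmethod
    def from_universe(
        cls, universe: mda.Universe, chain_ids: list[str] | None = None
    ) -> "ChannelModel":
        """Wrap an existing MDAnalysis Universe (e.g. a generated fixture)."""
        return cls(universe=universe, subunits=_group_subunits(universe, chain_ids))

    # -- primed positions ---------------------------------------------

    def assign_primed_positions(
        self,
        m2_start,
        primed_positions: tuple[int, ...] = PRIMED_POSITIONS,
    ) -> "ChannelModel":
        """Fill ``primed_map`` from the -2' residue number per subunit.

        ``m2_start`` is an int (homopentamer) or a dict subunit id ->
        int. Requires exactly five subunits and a resolvable Calpha for
        every primed position on every subunit.
        """
        if len(self.subunits) != 5:
            raise StructureError(
                f"pentamer required: found {len(self.subunits)} subunits"
            )
        if isinstance(m2_start, int):
            starts = {su: m2_start for su in self.subunits}
        else:
            starts = dict(m2_start)
            missing = set(self.subunits) - set(starts)
            if missing:
                raise MappingError(f"no m2_start for subunits {sorted(missing)}")
        primed_map: dict[int, dict[str, int]] = {}
        for p in primed_positions:
            primed_map[p] = {}
            for su, residues in self.subunits.items():
                resid = primed_to_resid(starts[su], p)
                sel = residues.atoms.select_atoms(f"resid {resid} and name CA")
                if len(sel) != 1:
                    raise MappingError(
                        f"primed position {p}' (residue {resid}) does not resolve "
                        f"to exactly one Calpha on subunit {su} (found {len(sel)})"
                    )
                primed_map[p][su] = resid
        self.primed_map = primed_map
        return self

    def primed_ca(self, primed: int, subunit: str | None = None):
        """AtomGroup of Calpha atom(s) at a primed position.

        With ``subunit`` given, the single Calpha of that subunit;
        otherwise all five, ordered by ``subunit_order`` when available.
        """
        if primed not in self.primed_map:
            raise MappingError(f"primed position {primed}' not assigned")
        order = self.subunit_order or sorted(self.subunits)
        subs = [subunit] if subunit is not None else order
        atoms = []
        for su in subs:
            resid = self.primed_map[primed][su]
            atoms.append(
                self.subunits[su].atoms.select_atoms(f"resid {resid} and name CA")
            )
        group = atoms[0]
        for a in atoms[1:]:
            group = group + a
        return group

    def ring_centroid(self, primed: int) -> np.ndarray:
        return self.primed_ca(primed).positions.mean(axis=0)

    # -- axis ----------------------------------------------------------

    def compute_axis(self, method: str = "ring_centroids") -> "ChannelModel":
        """Define the channel axis and axial coordinate system.

        ``ring_centroids`` (default): best-fit line through the per-ring
        centroids of the pore-lining Calpha atoms. ``principal``: the
        principal axis of largest extent of all pore-lining Calphas.
        The axis is oriented extracellular-positive (20' ring at s > 0)
        and its origin placed so the 9' ring centroid has s = 0. Also
        establishes the subunit rotational order.
        """
        if not self.primed_map:
            raise MappingError("assign_primed_positions before compute_axis")
        primed = sorted(self.primed_map)
        centroids = np.array([self.ring_centroid(p) for p in primed])
        if method == "ring_centroids":
            cloud = centroids
        elif method == "principal":
            cloud = np.concatenate(
                [self.primed_ca(p).positions for p in primed], axis=0
            )
        else:
            raise ValueError(f"unknown axis method {method!r}")
        mean = cloud.mean(axis=0)
        centered = cloud - mean
        # direction of largest spatial extent == smallest moment of inertia
        _, svals, vecs = np.linalg.svd(centered, full_matrices=False)
        if svals[0] < 1e-9:
            raise AxisError("degenerate geometry: pore-lining atoms coincide")
        direction = vecs[0]
        axis = ChannelAxis(origin=mean, direction=direction)
        # orient extracellular-positive: the highest primed ring (20' when
        # present) must sit at larger s than the lowest
        s_lo = axis.s(self.ring_centroid(primed[0]))
        s_hi = axis.s(self.ring_centroid(primed[-1]))
        if len(primed) < 2 or abs(s_hi - s_lo) < 1e-9:
            raise AxisError("cannot orient axis: primed rings coincide axially")
        if s_hi < s_lo:
            axis = ChannelAxis(origin=axis.origin, direction=-axis.direction)
        # shift origin so the 9' centroid (hydrophobic gate) projects to s = 0
        zero_p = 9 if 9 in self.primed_map else primed[0]
        c0 = self.ring_centroid(zero_p)
        origin = axis.origin + axis.s(c0) * axis.direction
        self.axis = ChannelAxis(origin=origin, direction=axis.direction)
        self.subunit_order = self._rotational_order()
        return self

    def _rotational_order(self) -> list[str]:
        """Subunit ids ordered by positive rotation about the axis,
        starting from the lexicographically smallest id."""
        assert self.axis is not None
        d = self.axis.direction
        # build an orthonormal in-plane basis
        ref = np.array([1.0, 0.0, 0.0])
        if abs(ref @ d) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = ref - (ref @ d) * d
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(d, e1)
        ref_p = 9 if 9 in self.primed_map else sorted(self.primed_map)[0]
        angles = {}
        for su in self.subunits:
            resid = self.primed_map[ref_p][su]
            ca = self.subunits[su].atoms.select_atoms(f"resid {resid} and name CA")
            rel = ca.positions[0] - self.axis.origin
            angles[su] = np.arctan2(rel @ e2, rel @ e1)
        ordered = sorted(angles, key=lambda su: angles[su])
        start = ordered.index(min(ordered))
        return ordered[start:] + ordered[:start]

    # -- coordinates ---------------------------------------------------

    def s_of(self, points: np.ndarray) -> np.ndarray:
        if self.axis is None:
            raise AxisError("axis not computed")
        return self.axis.s(points)


def _group_subunits(universe: mda.Universe, chain_ids=None):
    """Group residues into subunits by chain/segment id, with an equal
    contiguous split into 5 blocks as the fall-back for id-less files."""
    atoms = universe.atoms
    protein = atoms.select_atoms("protein") if hasattr(atoms, "resnames") else atoms
    if len(protein) == 0:
        protein = atoms
    ids = None
    if hasattr(protein, "chainIDs") and len(set(protein.chainIDs)) >= 2:
        ids = "chainIDs"
    elif hasattr(protein, "segids") and len(set(protein.segids)) >= 2:
        ids = "segids"
    subunits: dict[str, mda.core.groups.ResidueGroup] = {}
    if ids is not None:
        labels = getattr(protein, ids)
        wanted = chain_ids if chain_ids is not None else sorted(set(labels))
        for label in wanted:
            group = protein[labels == label].residues
            if len(group):
                subunits[str(label)] = group
    else:
        residues = protein.residues
        n = len(residues)
        if n % 5 == 0 and n >= 5:
            block = n // 5
            for i, label in enumerate("ABCDE"):
                subunits[label] = residues[i * block : (i + 1) * block]
        else:
            subunits["A"] = residues
    return subunits


def load_config(path) -> dict:
    """Read a channel config file (YAML key-value): ``subunits`` (chain
    id list, optional), ``m2_start`` (int or per-subunit map), and
    ``axis_method`` (optional, default ring_centroids)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if "m2_start" not in cfg:
        raise KeyError("channel config must define m2_start")
    cfg.setdefault("axis_method", "ring_centroids")
    cfg.setdefault("subunits", None)
    return cfg


def load_channel(structure_path, config: dict) -> ChannelModel:
    """Convenience: load a structure and fully assemble the ChannelModel
    (primed map + axis) from a parsed config dict."""
    model = ChannelModel.from_file(structure_path, chain_ids=config.get("subunits"))
    model.assign_primed_positions(config["m2_start"])
    model.compute_axis(config.get("axis_method", "ring_centroids"))
    return model
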