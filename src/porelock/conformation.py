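"""Conformational signatures of the refined open state: Calpha RMSF,
9' hydrophobic-pocket burial, -2' proline-ring pairing/asymmetry, and
representative-frame selection.

The stable open pore is locked by each 9' side chain burying into a
hydrophobic pocket at the subunit interface, while the intracellular
-2' proline ring adopts dynamic, asymmetric pairings; both are
quantified here as simple contact metrics. RMSF after rigid-body
alignment separates flexible regions (the intracellular pore mouth,
typically > 1 A) from helical cores (around 0.7 A).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .channel import ChannelAxis
from .errors import ConfigurationError


# ---------------------------------------------------------------------------
# rigid-body alignment (Kabsch)


def kabsch_align(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares superpose ``mobile`` (N,3) onto ``reference`` (N,3);
    returns the transformed mobile coordinates."""
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    h = mob_c.T @ ref_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    rot = u @ np.diag([1.0, 1.0, d]) @ vt
    return mob_c @ rot + reference.mean(axis=0)


def align_frames(coords: np.ndarray, reference: np.ndarray | None = None) -> np.ndarray:
    """Align every frame of a (T, N, 3) stack onto a reference
    (default: frame 0), then once more onto the aligned time average."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 3:
        raise ConfigurationError("expected a (frames, atoms, 3) coordinate stack")
    ref = coords[0] if reference is None else np.asarray(reference, dtype=float)
    aligned = np.array([kabsch_align(frame, ref) for frame in coords])
    mean = aligned.mean(axis=0)
    return np.array([kabsch_align(frame, mean) for frame in aligned])


# ---------------------------------------------------------------------------
# RMSF


def rmsf(coords: np.ndarray, reference: np.ndarray | None = None) -> np.ndarray:
    """Per-atom root-mean-square fluctuation after alignment.

    RMSF_i = sqrt(mean_t |x_i(t) - <x_i>|^2) with frames superposed by
    least squares onto the reference (default frame 0) and then onto
    the running average. Input is a (T, N, 3) stack of the selected
    (typically Calpha) coordinates.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 3 or coords.shape[0] < 2:
        raise ConfigurationError("RMSF needs at least two frames of (N,3) coordinates")
    if coords.shape[1] == 0:
        raise ConfigurationError("empty atom selection")
    aligned = align_frames(coords, reference)
    mean = aligned.mean(axis=0)
    return np.sqrt(((aligned - mean) ** 2).sum(axis=2).mean(axis=0))


def rmsf_from_universe(universe, selection: str = "name CA",
                       start=0, stop=None, step=1) -> tuple[np.ndarray, np.ndarray]:
    """RMSF over an MDAnalysis trajectory; returns (resids, rmsf)."""
    ag = universe.select_atoms(selection)
    if len(ag) == 0:
        raise ConfigurationError(f"empty selection: {selection}")
    coords = np.array(
        [ag.positions.copy() for _ in universe.trajectory[start:stop:step]]
    )
    return ag.resids.copy(), rmsf(coords)


# ---------------------------------------------------------------------------
# 9' pocket burial


@dataclass
class PocketDefinition:
    """The hydrophobic pocket receiving one 9' side chain: probe heavy
    atoms (9' side chain of the principal subunit) and the pocket heavy
    atoms on the (+)M2, (-)M2 and (-)M1 segments."""

    probe_positions: np.ndarray  # (P, 3) probe side-chain heavy atoms
    pocket_positions: np.ndarray  # (Q, 3) pocket heavy atoms

    def __post_init__(self) -> None:
        self.probe_positions = np.atleast_2d(np.asarray(self.probe_positions, float))
        self.pocket_positions = np.atleast_2d(np.asarray(self.pocket_positions, float))
        if self.probe_positions.size == 0 or self.pocket_positions.size == 0:
            raise ConfigurationError("pocket definition needs probe and pocket atoms")


#: Residues lining the 9' pocket at each subunit interface, by segment:
#: principal-subunit M2, complementary-subunit M2, complementary-subunit M1.
POCKET_RESIDUES = {
    "plus_M2": (257, 260, 264),   # I257, V260, T264
    "minus_M2": (255, 258, 259, 262),  # L255, T258, T259, T262
    "minus_M1": (233, 234, 237),  # L233, I234, L237
}


def pocket_burial(
    pocket: PocketDefinition,
    contact_cutoff: float = 4.5,
    buried_threshold: int = 10,
) -> dict:
    """Burial score of a 9' side chain in its interface pocket.

    Score = number of pocket heavy atoms within ``contact_cutoff`` (A)
    of any probe side-chain heavy atom. Classified ``buried`` at or
    above ``buried_threshold`` contacts, ``vacated`` at zero.
    """
    if contact_cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    diff = pocket.pocket_positions[:, None, :] - pocket.probe_positions[None, :, :]
    dists = np.linalg.norm(diff, axis=2)
    score = 0 if contact_cutoff == 0 else int((dists.min(axis=1) <= contact_cutoff).sum())
    if score >= buried_threshold:
        label = "buried"
    elif score == 0:
        label = "vacated"
    else:
        label = "partial"
    return {"score": score, "classification": label, "cutoff": contact_cutoff}


# ---------------------------------------------------------------------------
# -2' proline pairing


@dataclass
class ProlinePairing:
    """Partition of the five -2' residues into contact pairs/singletons."""

    pairs: list[tuple[int, int]]
    singletons: list[int]
    asymmetric: bool
    axis_distance_cv: float

    def partition(self) -> list[tuple[int, ...]]:
        return [tuple(p) for p in self.pairs] + [(s,) for s in self.singletons]


def proline_pairing(
    centroids: np.ndarray,
    axis: ChannelAxis,
    pair_cutoff: float = 6.0,
    asymmetry_cv_threshold: float = 0.05,
) -> ProlinePairing:
    """Pairing of the five -2' side chains by side-chain centroid contact.

    An edge joins two centroids closer than ``pair_cutoff`` (A); edges
    are matched greedily by increasing distance into pairs, the rest
    remain singletons. The ring is asymmetric when the coefficient of
    variation of the five centroid-axis distances exceeds the threshold
    or any pair forms (a symmetric ring is five singletons at even
    spacing).
    """
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    if centroids.shape != (5, 3):
        raise ConfigurationError("exactly five -2' residues required")
    d = np.linalg.norm(centroids[:, None] - centroids[None, :], axis=2)
    candidates = sorted(
        ((d[i, j], i, j) for i in range(5) for j in range(i + 1, 5) if d[i, j] < pair_cutoff)
    )
    used: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, i, j in candidates:
        if i not in used and j not in used:
            pairs.append((i, j))
            used.update((i, j))
    singletons = [i for i in range(5) if i not in used]
    axial_r = axis.lateral(centroids)
    cv = float(axial_r.std() / axial_r.mean()) if axial_r.mean() > 0 else 0.0
    asymmetric = bool(cv > asymmetry_cv_threshold or len(pairs) > 0)
    return ProlinePairing(
        pairs=pairs, singletons=singletons, asymmetric=asymmetric, axis_distance_cv=cv
    )


# ---------------------------------------------------------------------------
# representative frame


def representative_frame(coords: np.ndarray) -> tuple[int, np.ndarray]:
    """Frame with minimal Calpha RMSD to the time-average structure.

    Frames are aligned onto the average; ties resolve to the earliest
    frame. Returns (frame index, per-frame RMSD array).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 3 or coords.shape[0] < 1:
        raise ConfigurationError("empty trajectory")
    aligned = align_frames(coords)
    mean = aligned.mean(axis=0)
    rmsd = np.sqrt(((aligned - mean) ** 2).sum(axis=2).mean(axis=1))
    # strictly-less comparison on the running minimum -> earliest tie wins
    best = int(np.argmin(rmsd))
    return best, rmsd


def representative_frame_from_universe(
    universe, selection: str = "name CA", start=0, stop=None, step=1
) -> tuple[int, np.ndarray]:
    ag = universe.select_atoms(selection)
    if len(ag) == 0:
        raise ConfigurationError(f"empty selection: {selection}")
    coords = np.array(
        [ag.positions.copy() for _ in universe.trajectory[start:stop:step]]
    )
    return representative_frame(coords)
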