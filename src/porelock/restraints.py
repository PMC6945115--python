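"""Flat-bottom pore restraints, ligand tethers, and the staged
equilibration schedule.

The open-state refinement protocol keeps a pLGIC pore from undergoing
hydrophobic collapse by restraining the cross-pore Calpha-Calpha
distances between non-adjacent subunits at each pore-lining primed
position: the potential is zero while a cross distance is at least its
value in the open-state reference structure and harmonic (half-open
flat bottom) below it,

    V(d) = 1/2 k (d0 - d)^2   for d < d0,   0 otherwise,

so the restoring force magnitude is k (d0 - d), i.e. proportional to
the distance deficit. For a pentamer there are five non-adjacent
("diagonal") subunit pairs per ring, hence 5 restraints per primed
position and 35 for the seven standard positions.

Ligand tethers are upper-side flat bottoms on the distance between the
ligand Calpha and binding-site anchor Calphas: zero until a threshold
distance, harmonic beyond it, preventing dissociation while allowing
exploration of the pocket.

Internally distances are Angstrom and force constants kJ mol^-1 nm^-2
(harmonic restraints are dimensionally kJ mol^-1 nm^-2 even where the
looser label "kJ mol^-1 nm^-1" is conventional in tables); emitted
GROMACS files use nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .channel import ChannelModel
from .errors import ConfigurationError

DEFAULT_FORCE_CONSTANT = 5000.0  # kJ mol^-1 nm^-2

_A_PER_NM = 10.0


@dataclass(frozen=True)
class FlatBottomRestraint:
    """One half-open flat-bottom distance restraint between two atoms.

    ``side='lower'`` acts when d < d0 (pore cross restraints);
    ``side='upper'`` acts when d > d0 (ligand tethers use this form via
    :class:`LigandTether`). Atom identifiers are 1-based serials in the
    topology the restraint file refers to.
    """

    atom_i: int
    atom_j: int
    d0: float  # Angstrom
    k: float  # kJ mol^-1 nm^-2
    side: str = "lower"
    label_i: str = ""
    label_j: str = ""

    def __post_init__(self) -> None:
        if self.d0 <= 0:
            raise ValueError("d0 must be positive")
        if self.k < 0:
            raise ValueError("k must be non-negative")
        if self.atom_i == self.atom_j:
            raise ValueError("restraint endpoints must differ")
        if self.side not in ("lower", "upper"):
            raise ValueError("side must be 'lower' or 'upper'")


@dataclass
class RestraintSet:
    restraints: list[FlatBottomRestraint]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.restraints)


@dataclass(frozen=True)
class LigandTether:
    """Upper-side flat-bottom tether: acts when d > threshold."""

    ligand_atom: int
    anchor_atom: int
    threshold: float  # Angstrom
    k: float = DEFAULT_FORCE_CONSTANT
    label: str = ""


@dataclass(frozen=True)
class EquilibrationStage:
    duration_ps: float
    ensemble: str  # NVT | NPT
    restrained_selection: str
    force_constant: float  # printed as kJ mol^-1 nm^-1 in the protocol table

    def __post_init__(self) -> None:
        if self.duration_ps <= 0:
            raise ValueError("duration must be positive")
        if self.ensemble not in ("NVT", "NPT"):
            raise ValueError("ensemble must be NVT or NPT")
        if self.force_constant < 0:
            raise ValueError("force constant must be non-negative")


# ---------------------------------------------------------------------------
# potential evaluation


def evaluate_flat_bottom(
    restraint: FlatBottomRestraint | LigandTether, d: float
) -> tuple[float, float]:
    """Energy (kJ/mol) and force magnitude (kJ mol^-1 nm^-1) at distance d (A).

    Zero in the flat region; V = 1/2 k delta^2 and |F| = k*delta outside,
    with delta the distance excursion in nm. C1-continuous at the boundary.
    """
    if d < 0:
        raise ValueError("distance must be non-negative")
    if isinstance(restraint, LigandTether):
        d0, k, side = restraint.threshold, restraint.k, "upper"
    else:
        d0, k, side = restraint.d0, restraint.k, restraint.side
    if side == "lower":
        delta_nm = (d0 - d) / _A_PER_NM
    else:
        delta_nm = (d - d0) / _A_PER_NM
    if delta_nm <= 0:
        return 0.0, 0.0
    return 0.5 * k * delta_nm**2, k * delta_nm


# ---------------------------------------------------------------------------
# construction


def _ca_atom(model: ChannelModel, subunit: str, resid: int):
    sel = model.subunits[subunit].atoms.select_atoms(f"resid {resid} and name CA")
    if len(sel) != 1:
        raise ConfigurationError(
            f"residue {resid} of subunit {subunit} has no unique Calpha"
        )
    return sel[0]


def nonadjacent_pairs(order: list[str]) -> list[tuple[str, str]]:
    """The five pentagon diagonals (i, i+2) under rotational order,
    tie-broken deterministically by sorting each pair's subunit ids."""
    if len(order) != 5:
        raise ConfigurationError(f"pentamer required: got {len(order)} subunits")
    pairs = []
    for i in range(5):
        a, b = order[i], order[(i + 2) % 5]
        pairs.append(tuple(sorted((a, b))))
    return sorted(set(pairs))


def build_pore_restraints(
    model: ChannelModel,
    reference: ChannelModel | None = None,
    k: float = DEFAULT_FORCE_CONSTANT,
) -> RestraintSet:
    """Cross-pore flat-bottom restraints for every primed position.

    One lower-side restraint per non-adjacent subunit pair per primed
    position (5 per position; 35 for the standard seven). d0 is the
    Calpha-Calpha distance in ``reference`` (default: ``model`` itself,
    i.e. the open-state structure being protected). Atom serials refer
    to ``model``'s topology.
    """
    reference = model if reference is None else reference
    for m in (model, reference):
        if not m.primed_map:
            raise ConfigurationError("primed positions not assigned")
        if len(m.subunits) != 5:
            raise ConfigurationError(
                f"pentamer required: got {len(m.subunits)} subunits"
            )
    if set(model.primed_map) != set(reference.primed_map):
        raise ConfigurationError("model and reference primed positions differ")
    order = model.subunit_order or sorted(model.subunits)
    ref_order = reference.subunit_order or sorted(reference.subunits)
    su_map = dict(zip(order, ref_order))
    restraints = []
    for p in sorted(model.primed_map):
        for a, b in nonadjacent_pairs(order):
            atom_a = _ca_atom(model, a, model.primed_map[p][a])
            atom_b = _ca_atom(model, b, model.primed_map[p][b])
            ref_a = _ca_atom(reference, su_map[a], reference.primed_map[p][su_map[a]])
            ref_b = _ca_atom(reference, su_map[b], reference.primed_map[p][su_map[b]])
            d0 = float(math.dist(ref_a.position, ref_b.position))
            restraints.append(
                FlatBottomRestraint(
                    atom_i=int(atom_a.index) + 1,
                    atom_j=int(atom_b.index) + 1,
                    d0=d0,
                    k=k,
                    side="lower",
                    label_i=f"{a}/{model.primed_map[p][a]}/CA/{p}'",
                    label_j=f"{b}/{model.primed_map[p][b]}/CA/{p}'",
                )
            )
    return RestraintSet(
        restraints=restraints,
        provenance={
            "primed_positions": sorted(model.primed_map),
            "n_subunits": 5,
            "k": k,
        },
    )


#: Default GlyR binding-site tether spec: anchor residue Calphas on the
#: principal (+) and complementary (-) subunits with their threshold
#: distances (Angstrom) to the glycine ligand Calpha.
GLYR_TETHER_SITE = (
    {"label": "(+)F207", "resid": 207, "threshold": 10.60},
    {"label": "(-)F63", "resid": 63, "threshold": 10.53},
    {"label": "(-)S129", "resid": 129, "threshold": 9.15},
)


def build_ligand_tethers(
    model,
    ligand_atom: int,
    site_spec=GLYR_TETHER_SITE,
    k: float = DEFAULT_FORCE_CONSTANT,
    resolve=None,
) -> list[LigandTether]:
    """Upper-side flat-bottom tethers from a ligand Calpha to binding-site
    anchor Calphas.

    ``site_spec`` entries carry ``resid``, ``threshold`` (A) and
    optionally ``subunit`` and ``label``. Anchors are resolved to Calpha
    serials in ``model`` (a ChannelModel or a bare MDAnalysis Universe);
    ``resolve`` may override resolution with a callable entry -> serial.
    """
    tethers = []
    for entry in site_spec:
        if resolve is not None:
            serial = resolve(entry)
        else:
            universe = model.universe if isinstance(model, ChannelModel) else model
            sel = universe.select_atoms(f"resid {entry['resid']} and name CA")
            if "subunit" in entry and isinstance(model, ChannelModel):
                sel = model.subunits[entry["subunit"]].atoms.select_atoms(
                    f"resid {entry['resid']} and name CA"
                )
            if len(sel) == 0:
                raise ConfigurationError(
                    f"anchor residue {entry.get('label', entry['resid'])} not found"
                )
            serial = int(sel[0].index) + 1
        tethers.append(
            LigandTether(
                ligand_atom=ligand_atom,
                anchor_atom=serial,
                threshold=float(entry["threshold"]),
                k=k,
                label=str(entry.get("label", entry["resid"])),
            )
        )
    return tethers


# ---------------------------------------------------------------------------
# equilibration schedule (the staged position-restraint release protocol)

_HEAVY = "protein heavy atoms, ligand heavy atoms, crystal water oxygen"
_BACKBONE = "protein backbone, ligand Calpha atom, crystal water oxygen"


def build_equilibration_schedule() -> list[EquilibrationStage]:
    """The seven-stage initial equilibration protocol: a short NVT run
    followed by NPT stages in which position restraints are first kept
    on all heavy atoms, then relaxed to the backbone with a stepwise
    halving of the force constant (1024 -> 64 kJ mol^-1 nm^-2)."""
    rows = [
        (100.0, "NVT", _HEAVY, 1000.0),
        (1000.0, "NPT", _HEAVY, 1000.0),
        (10000.0, "NPT", _BACKBONE, 1024.0),
        (1000.0, "NPT", _BACKBONE, 512.0),
        (1000.0, "NPT", _BACKBONE, 256.0),
        (1000.0, "NPT", _BACKBONE, 128.0),
        (1000.0, "NPT", _BACKBONE, 64.0),
    ]
    return [EquilibrationStage(*row) for row in rows]


# ---------------------------------------------------------------------------
# file I/O (GROMACS dialect)

_FLAT_UP = 99.0  # nm; effectively infinite upper edge for lower-side restraints


def write_restraints_itp(rset: RestraintSet, path) -> None:
    """Emit the cross-pore restraints as GROMACS ``[ bonds ]`` type-10
    restraint lines (low/up1/up2 in nm encoding the flat-bottom sides)."""
    if len(rset) == 0:
        raise ConfigurationError("refusing to write an empty restraint set")
    lines = [
        "; porelock flat-bottom cross-pore restraints",
        "; ai    aj  funct      low       up1       up2        k",
        "[ bonds ]",
    ]
    for r in rset.restraints:
        if r.side == "lower":
            low, up1, up2 = r.d0 / _A_PER_NM, _FLAT_UP, _FLAT_UP + 0.9
        else:
            low, up1, up2 = 0.0, r.d0 / _A_PER_NM, r.d0 / _A_PER_NM + _FLAT_UP
        lines.append(
            f"{r.atom_i:>6d} {r.atom_j:>6d}     10 "
            f"{low:9.4f} {up1:9.4f} {up2:9.4f} {r.k:9.1f}"
            f" ; {r.label_i} -- {r.label_j}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_restraints_itp(path) -> RestraintSet:
    """Read back an ITP written by :func:`write_restraints_itp`."""
    restraints = []
    for raw in Path(path).read_text().splitlines():
        line, _, comment = raw.partition(";")
        line = line.strip()
        if not line or line.startswith("["):
            continue
        fields = line.split()
        ai, aj, funct = int(fields[0]), int(fields[1]), int(fields[2])
        if funct != 10:
            continue
        low, up1, _up2, k = (float(x) for x in fields[3:7])
        labels = [t.strip() for t in comment.split("--")] if comment else ["", ""]
        if low > 0 and up1 >= _FLAT_UP:
            side, d0 = "lower", low * _A_PER_NM
        else:
            side, d0 = "upper", up1 * _A_PER_NM
        restraints.append(
            FlatBottomRestraint(
                atom_i=ai,
                atom_j=aj,
                d0=d0,
                k=k,
                side=side,
                label_i=labels[0],
                label_j=labels[-1],
            )
        )
    return RestraintSet(restraints=restraints, provenance={"source": str(path)})


def restraints_to_frame(rset: RestraintSet) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "atom_i": r.atom_i,
                "atom_j": r.atom_j,
                "d0_A": r.d0,
                "k_kJ_mol_nm2": r.k,
                "side": r.side,
                "label_i": r.label_i,
                "label_j": r.label_j,
            }
            for r in rset.restraints
        ]
    )


def write_restraints_tsv(rset: RestraintSet, path) -> None:
    if len(rset) == 0:
        raise ConfigurationError("refusing to write an empty restraint set")
    restraints_to_frame(rset).to_csv(path, sep="\t", index=False)


def read_restraints_tsv(path) -> RestraintSet:
    df = pd.read_csv(path, sep="\t")
    restraints = [
        FlatBottomRestraint(
            atom_i=int(row.atom_i),
            atom_j=int(row.atom_j),
            d0=float(row.d0_A),
            k=float(row.k_kJ_mol_nm2),
            side=str(row.side),
            label_i=str(row.label_i),
            label_j=str(row.label_j),
        )
        for row in df.itertuples()
    ]
    return RestraintSet(restraints=restraints, provenance={"source": str(path)})


def write_schedule(stages: list[EquilibrationStage], outdir) -> None:
    """Emit the equilibration schedule: one mdp fragment plus one
    position-restraint include fragment per stage (schedule-relevant
    keys only), and a ``schedule.tsv`` master table that round-trips
    through :func:`read_schedule`."""
    if not stages:
        raise ConfigurationError("empty schedule")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, st in enumerate(stages, start=1):
        dt_ps = 0.001 if st.ensemble == "NVT" else 0.002  # 1 fs NVT, 2 fs NPT
        nsteps = int(round(st.duration_ps / dt_ps))
        mdp = [
            f"; equilibration stage {i}: {st.duration_ps:g} ps {st.ensemble}",
            f"define                = -DPOSRES_STAGE{i}",
            f"dt                    = {dt_ps:g}",
            f"nsteps                = {nsteps}",
            f"pcoupl                = {'no' if st.ensemble == 'NVT' else 'berendsen'}",
        ]
        (outdir / f"eq_stage_{i:02d}.mdp").write_text("\n".join(mdp) + "\n")
        itp = [
            f"; position restraints for stage {i}",
            f"; restrained selection: {st.restrained_selection}",
            f"#ifdef POSRES_STAGE{i}",
            f"#define POSRES_FC {st.force_constant:g}",
            "#endif",
        ]
        (outdir / f"posre_stage_{i:02d}.itp").write_text("\n".join(itp) + "\n")
        rows.append(
            {
                "stage": i,
                "duration_ps": st.duration_ps,
                "ensemble": st.ensemble,
                "restrained_selection": st.restrained_selection,
                "force_constant": st.force_constant,
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "schedule.tsv", sep="\t", index=False)


def read_schedule(outdir) -> list[EquilibrationStage]:
    df = pd.read_csv(Path(outdir) / "schedule.tsv", sep="\t")
    return [
        EquilibrationStage(
            duration_ps=float(row.duration_ps),
            ensemble=str(row.ensemble),
            restrained_selection=str(row.restrained_selection),
            force_constant=float(row.force_constant),
        )
        for row in df.itertuples()
    ]
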