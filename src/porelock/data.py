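"""Reference tables: van der Waals radii and the Wimley-White hydrophobicity scale.

All radii in Angstrom. The hydrophobicity table stores the *negated*
Wimley-White interface-scale transfer free energy (kcal/mol), so larger
values mean more hydrophobic; :func:`rescaled_hydrophobicity` maps it
linearly onto [-1, 1] with the most hydrophilic residue (Glu) at -1 and
the most hydrophobic (Trp) at +1.
"""

from __future__ import annotations

# Bondi (1964) van der Waals radii, Angstrom.
BONDI_VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "NA": 2.27,
    "K": 2.75,
    "MG": 1.73,
    "ZN": 1.39,
    "BR": 1.85,
    "I": 1.98,
}

DEFAULT_VDW_RADIUS = 1.70  # fall-back for unknown elements (carbon-like)

# Wimley & White (1996) interface scale, free energy of transfer
# water -> POPC interface, kcal/mol, for Ace-WL-X-LL peptides.
# Charged-state values used for D, E (deprotonated) and H (neutral).
_WW_INTERFACE_DELTA_G: dict[str, float] = {
    "ALA": 0.17,
    "ARG": 0.81,
    "ASN": 0.42,
    "ASP": 1.23,
    "CYS": -0.24,
    "GLN": 0.58,
    "GLU": 2.02,
    "GLY": 0.01,
    "HIS": 0.17,
    "ILE": -0.31,
    "LEU": -0.56,
    "LYS": 0.99,
    "MET": -0.23,
    "PHE": -1.13,
    "PRO": 0.45,
    "SER": 0.13,
    "THR": 0.14,
    "TRP": -1.85,
    "TYR": -0.94,
    "VAL": 0.07,
}

# Hydrophobicity = -DeltaG so that hydrophobic residues score high.
WIMLEY_WHITE_HYDROPHOBICITY: dict[str, float] = {
    res: -dg for res, dg in _WW_INTERFACE_DELTA_G.items()
}

# Dehydrated / hydrated chloride radii (Angstrom) — external literature
# constants (Pauling ionic radius; first hydration-shell radius), used only
# as plot/annotation reference lines, configurable everywhere they appear.
CHLORIDE_RADIUS_DEHYDRATED = 1.81
CHLORIDE_RADIUS_HYDRATED = 3.3


def vdw_radius(element: str, table: dict[str, float] | None = None) -> float:
    """Look up a van der Waals radius by element symbol (case-insensitive)."""
    table = BONDI_VDW_RADII if table is None else table
    return table.get(element.upper(), DEFAULT_VDW_RADIUS)


def rescaled_hydrophobicity(
    resname: str, scale_table: dict[str, float] | None = None
) -> float:
    """Per-residue hydrophobicity linearly rescaled to [-1, 1].

    The rescaling maps the minimum of the 20-residue scale to -1 (very
    hydrophilic) and the maximum to +1 (very hydrophobic).

    Raises
    ------
    KeyError
        If ``resname`` is not in the scale table.
    """
    table = WIMLEY_WHITE_HYDROPHOBICITY if scale_table is None else scale_table
    key = resname.upper()
    if key not in table:
        raise KeyError(f"residue {resname!r} not in hydrophobicity scale table")
    lo = min(table.values())
    hi = max(table.values())
    return -1.0 + 2.0 * (table[key] - lo) / (hi - lo)
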