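# Methods

This note documents the models, conventions, numerics and deliberate
design choices behind `porelock`, and what its synthetic fixtures do
and do not establish about real data.

## Channel model and coordinate system

A channel is a pentamer whose pore-lining M2 helices are indexed by the
conserved primed numbering: position *p* maps to residue number
`m2_start + p + 2`, where `m2_start` is the residue number of the −2′
position. For the human α1 GlyR numbering (`m2_start = 250`) this puts
the 9′ leucine gate at L261. The seven pore-lining rings are −2′, 2′,
6′, 9′, 13′, 16′ and 20′.

The channel axis is, by default, the best-fit line (SVD) through the
seven per-ring Cα centroids (`ring_centroids`); the alternative
`principal` method takes the largest-extent principal axis of all 35
pore-lining Cα atoms. Both are stand-ins for whatever internal axis
definition a pore-profiling tool might use; `ring_centroids` is the
default because per-ring centroids are robust to extracellular-domain
asymmetry. The axis is oriented extracellular-positive (the 20′ ring at
s > 0) and its origin is placed so the 9′ ring centroid projects to
s = 0. The axial coordinate of any atom is then invariant under rigid
motion of the whole system (to machine precision in double; coordinates
stored by the trajectory backend are single-precision, which bounds the
practical invariance near 1e-5 Å).

Subunit rotational order is fixed by sorting the five 9′ Cα azimuths
about the axis (positive rotation viewed along +axis), starting from
the lexicographically smallest subunit id, so "non-adjacent" is well
defined regardless of chain labelling. Internal length unit is Å
throughout; GRO nm values are converted on read/write. Frames are
0-based. GRO files carry no chain identifiers: when fewer than two
distinct chain/segment ids are present, the loader splits the protein's
residues into five equal contiguous blocks (overridable by listing
chain ids in the channel config).

## Flat-bottom restraints and the equilibration schedule

Cross-pore restraints are lower-side flat bottoms on the Cα–Cα
distances of the five pentagon-diagonal subunit pairs at each primed
position: V(d) = ½k(d₀ − d)² for d < d₀ and 0 otherwise, with d₀ the
distance in the open-state reference structure and k = 5000
kJ mol⁻¹ nm⁻² by default. The ½k half-harmonic convention matches
GROMACS type-10 restraint bonds, which is also the emission format
(`low` = d₀ in nm, `up1`/`up2` pushed effectively to infinity so the
potential is flat above d₀). Note the dimensional point: a harmonic
distance restraint constant is kJ mol⁻¹ nm⁻², even though protocol
tables conventionally print kJ mol⁻¹ nm⁻¹; the stored unit is nm⁻² and
the printed label is treated as a label only. Ligand tethers are the
upper-side mirror image (act when d exceeds a threshold), with GlyR
defaults of 10.60 / 10.53 / 9.15 Å to the (+)F207, (−)F63 and (−)S129
anchor Cα atoms.

The staged equilibration schedule is the fixed seven-row protocol —
100 ps NVT then six NPT stages totalling 15 ns, position restraints
first on all heavy atoms (k = 1000), then on the backbone with a
stepwise halving 1024 → 64. It is emitted as one mdp fragment plus one
position-restraint include fragment per stage (schedule-relevant keys
only: duration, ensemble, restrained selection, force constant; the
NVT stage uses a 1 fs timestep, NPT stages 2 fs) and a master
`schedule.tsv` that round-trips through the module's reader. The
package validates these files structurally; it never runs MD.

## Pore radius profile

At each grid point s (default −40…40 Å in 0.5 Å steps) the radius is
max over probe centres c in the slice plane of min over atoms of
(|c − x_atom| − r_vdW), capped (default 10 Å, reported for open bulk)
and clamped at 0 on steric overlap. The centre search is deterministic:
a coarse pass over a 1 Å lattice within 8 Å of the axis, Nelder–Mead
refinement from the best starts (the axis start always included), ties
resolved toward the axis. A candidate centre is accepted only if the
straight segment from the axis point to it is sterically passable
(clearance ≥ 0 sampled at 0.1 Å); this rejects clearance maxima in the
bulk *outside* a collapsed pore, which would otherwise dominate the
unconstrained maximum. Van der Waals radii default to the Bondi set.
Because the clearance function shifts pointwise when all vdW radii
shrink by δ, the profile grows by exactly δ (until the cap) — a
property the tests check against a brute-force lattice oracle.
Agreement with any particular external profiling tool is qualitative,
not bit-level: probe and smoothing parameters of published profiles
are generally unstated.

The dehydrated/hydrated chloride reference radii used for annotation
default to 1.81 Å and 3.3 Å; they are external literature constants
(Pauling ionic radius; first-shell hydrated radius) and configurable.

## Hydrophobicity profile

Each residue carries the negated Wimley–White interface-scale transfer
free energy, linearly rescaled over the 20 standard residues so the
most hydrophilic (Glu) maps to −1 and the most hydrophobic (Trp) to +1.
A residue is pore-facing at s when any heavy atom lies within a cutoff
(default 3.5 Å) of the pore surface at s (the sphere of the slice's
pore radius around its probe centre; without a radius profile, axial
proximity to the slice plane is used instead). The profile value at s
is the Gaussian-weighted (σ = 2 Å, axial proximity) average of the
facing residues' values — a weighted mean, hence always within
[−1, 1]; grid points with no facing residue are NaN.

Gate annotation reports the minimum mean radius in ±4 Å windows around
the 9′ level (s = 0) and the −2′ level and flags hydrophobic-gating
risk when the 9′ minimum falls below 4 Å (the low edge of the
dehydration-prone 4–5 Å range) with locally hydrophobic lining (> 0).

## Permeation counting

The pore-bound region is a cylinder: lateral radius 5 Å around the
axis, axial bounds at the −2′ and 20′ Cα ring centroids of frame 0
(fixed, not per-frame, so the compartment machine stays well defined).
Water is tracked by its oxygen, ions by their single atom. Axial
coordinates are unwrapped per particle by minimum-image displacement
between consecutive frames (valid when frames are sampled finely enough
that every true |Δs| < period/2; the axial period is the box edge along
z when the axis is near lab z, the usual membrane set-up).

Compartments tile periodically along the unwrapped axis: pore slab k
occupies [z_lo + kL, z_hi + kL], and the bulk index counts slabs below
the particle. An event is a bulk→bulk transition of ±1 with every
observed inside frame within the lateral cylinder (a configurable
number of excursion frames is tolerated, default 0 — strict); returning
to the starting bulk resets the attempt and counts nothing. A direct
bulk k → k±1 jump with no observed inside frame still counts one event:
continuity of the unwrapped path implies a traversal, and this keeps
counts invariant under frame-stride refinement. Both directions pool
into species totals (appropriate for simulations without a membrane
potential); the per-event direction is retained in the event table.
With this construction, up-events minus down-events equals the net
bulk-index displacement of each particle — an invariant the tests
verify against an independent brute-force compartment re-scan.

Selectivity is the ratio of chloride to sodium event counts, reported
as ∞ (with both counts retained) when sodium observed no events and as
undefined when neither species did. Wetting divides the pore slab into
axial bins (default 1 Å): a bin is dewetted at a frame iff no water
oxygen occupies it inside the cylinder; maximal contiguous dewetted
patches in the (frame, bin) plane are reported via connected-component
labelling. Number densities are time-averaged voxel counts divided by
voxel volume (particles/nm³), exported as OpenDX; total density times
volume equals the mean in-box particle count by construction.

## Conformational metrics

RMSF: frames are least-squares superposed (Kabsch) onto a reference and
then onto their time average; RMSF_i = √⟨|x_i − ⟨x_i⟩|²⟩. Isotropic
Gaussian jitter of σ per coordinate converges to σ√3 (alignment removes
six rigid degrees of freedom, a ≈1–2 % depression at the selection
sizes used in the tests). The averaging window is the whole trajectory
by default.

Pocket burial: the 9′ side chain of the principal subunit against the
ten pocket residues of the interface (I257/V260/T264 on (+)M2,
L255/T258/T259/T262 on (−)M2, L233/I234/L237 on (−)M1, GlyR α1
numbering). The score is the number of pocket heavy atoms within a
cutoff (default 4.5 Å) of any probe heavy atom; ≥ 10 contacts is
classified buried, 0 vacated. These thresholds are operational
definitions — published descriptions of burial are qualitative — so the
raw scores are always reported alongside the classification.

Proline pairing: the five −2′ side-chain centroids form a contact graph
(edge < 6 Å), greedily matched by increasing distance into pairs; the
ring is asymmetric when any pair forms or the coefficient of variation
of the centroid–axis distances exceeds a threshold (default 0.05).

Representative frame: the frame of minimal Cα RMSD to the aligned
time-average structure, earliest frame on ties.

## Synthetic fixtures

The toy pentamer is five straight vertical chains of Cα plus an
outward side-chain centroid pseudo-atom, one residue per primed unit
from −2′ to 20′ (rise 1.5 Å/residue), ring radii per primed position
interpolated between configurable anchors, 9′ ring at the box centre,
axis on lab z. The default M2-like register places Pro at −2′, Thr at
6′ and Leu at 9′. Generation is seeded (default 42) and byte-for-byte
deterministic.

The scripted trajectory prescribes permeation ground truth directly: a
particle with T traversals climbs linearly by T box lengths along z
(one pass through the pore per periodic lap, so wrapped and unwrapped
emissions describe the same physical path and must count identically);
distractors bounce into the lower pore mouth and retreat; waters hold
fixed axial stations laddering the pore (keeping every wetting bin
occupied) with lateral jitter inside the cylinder. Defaults mirror the
study conditions the annotations target: 300 frames at a 100 ps frame
label (30 ns of nominal sampling of a 300 ns production run at stride),
52 prescribed chloride and 1 sodium traversal, 150 mM-like ion counts
scaled to a handful of tracked particles.

What the fixtures do *not* emulate: forces, solvent structure,
diffusive ion motion, gradual pore breathing, or correlated
protein–ion dynamics. Passing the fixture suite establishes that the
geometry and counting machinery are correct on paths with known truth,
not that any particular real trajectory is open or selective; on real
data the pore-bound definition (cylinder radius, axial bounds,
excursion tolerance) makes counts sensitive at the few-event level, so
benchmark comparisons should be read to within a small tolerance.

## Problem sizes and numerics

The test suite and the acceptance script run on fixture-scale problems:
100-frame trajectories of ~45 particles for the seed-sweep permeation
checks (100 seeds, both wrapped and unwrapped emission), a 300-frame
reference fixture for the headline counts, 24-atom analytic rings for
the radius oracle, 2000 × 80-atom stacks for RMSF convergence. These
sizes were chosen so every statistical check sits far inside its
tolerance while the whole suite completes in seconds. Tolerances:
radius oracle 0.1 Å (optimizer lattice + refinement accuracy), RMSF
convergence 5 % at 2000 frames (sampling noise plus the alignment
depression), flat-bottom energies 1e-9 (pure arithmetic), permeation
counts exact.
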