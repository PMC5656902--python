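# Methods

This note documents the models, numerical choices and limitations behind
`cpaselect`, in the order a user meets them: structure handling, the two
steric descriptors, pathway classification, ee prediction, the decision
tree, and the synthetic fixtures the tests rest on.

## Structures and anchor atoms

All geometry is expressed relative to the anchor atoms of the
monophosphoric-acid binaphthyl scaffold: the single phosphorus, the two
terminal ("acid") oxygens, the two aryl-ether oxygens, the two C3/C3′
carbons and the first atom of each 3,3′ substituent. Anchors are perceived
from connectivity alone: the ether-bearing carbon's ring neighbour that
does *not* carry the biaryl linkage is C3, and its exocyclic heavy
neighbour (if any) is the substituent root. The rule is element-agnostic,
so silyl and alkyl substituents are handled identically to aryl ones.

SDF/MOL files are read and written through RDKit. XYZ input carries no
bonds, so connectivity is inferred by the standard covalent-radius
criterion (bonded iff d < 1.25·(r_cov,i + r_cov,j)); this heuristic is only
used where the format is silent. Hydrogens must be explicit. Structures
lacking the acidic hydrogen are accepted as the phosphate anion with a
logged warning and an `acid_form` flag carried into descriptor provenance —
descriptor values are insensitive to that proton at the fidelity targeted
here. Coordinates are always Å, energies kcal/mol (1 hartree =
627.5094740631 kcal/mol), temperatures Kelvin.

## AREA(θ): the remote environment angle

AREA(θ) is implemented as a clear-cone search: with apex **a** (default:
the phosphorus) and unit axis **û** pointing from the apex towards the
midpoint of the two acid oxygens (the direction the substrate approaches
from), θ is the largest half-aperture such that no *remote* atom — any atom
farther than `remote_cutoff` (default 4.0 Å) from the apex, backbone and
substituent alike — intrudes into the open cone when inflated to its Bondi
radius. The search walks a θ grid at `angular_resolution` (default 0.5°)
and tests cone–sphere intersection through the exact point-to-solid-cone
distance, which keeps it independent of the closed-form tangent construction
used as the test oracle (for a single sphere at distance d and polar angle
α, θ = α − arcsin(r/d)).

Choices worth recording:

* **Axis direction.** The cone opens over the binding face. Pointing it the
  other way (into the binaphthyl backbone) leaves every catalyst with
  θ ≈ 2–3° — the backbone itself fills that hemisphere — and destroys all
  discrimination, so the binding-face axis is the package default
  (`axis_mode` remains configurable).
* **Cutoff.** 4.0 Å excludes the phosphate core and the C2/C3 ring carbons
  while keeping the substituent arms that flank the binding cleft. With
  these defaults the computed apertures for the benchmark set
  {H, Ph, 9-anthryl, TRIP, SiPh₃} are {109, 64, 52, 48, 19}°, against
  catalog values {107, 70, 61, 51, 29}° — rank-perfect and close in
  magnitude, which is more than the protocol promises (see *Fidelity*
  below).
* Every `StericProfile` embeds `params_used`, so any figure produced with
  non-default parameters is self-describing.
* Degenerate inputs: a zero axis raises; a molecule with no remote atoms
  returns the configured maximum aperture (default 179°) with a warning;
  adding an obstruction can only shrink θ (tested as a monotonicity
  property); the result is invariant under rigid motion of the whole
  structure and under atom reordering.

## The rotation barrier: proximal bulk

The proximal descriptor is a rigid-rotor scan of the C3–Cipso torsion: the
substituent subtree is rotated about the bond axis over [0°, 360°) at
`step` (default 10°), the other substituent and the backbone held fixed;
the barrier is max E − min E, reported for the more hindered of the two
substituents. A hydrogen substituent has no rotor and is defined to have
barrier 0.00.

The default energy function is an in-package pairwise 12-6 Lennard-Jones
steric potential (Bondi contact distances, UFF well depths, pairs closer
than three bonds excluded) with each pair contribution capped at
25 kcal/mol. The cap matters: a rigid rotation drives ortho substituents
through genuine atomic overlap, where an uncapped r⁻¹² term produces
meaningless 10⁵–10⁶ kcal/mol spikes; capping keeps the scan finite while
preserving order. An optional 2-fold intrinsic torsion term
(V₂/2)(1 − cos 2φ) is available but defaults to 0 so that a clash-free
rotor scans flat. Any deterministic conformational energy (e.g. a force
field from the ecosystem) can be supplied as `energy_fn`; relaxed scans are
out of scope.

Computed barriers therefore live on their own scale — larger than the
catalog's QM-derived values (a capped rigid clash is worth tens of
kcal/mol). Orderings are faithful: 2,6-disubstituted aryls (TRIP ≈ 500)
≫ peri-hindered 1-naphthyl (≈ 190) ≫ para-substituted phenyls (≈ 14), and
9-anthryl > 1-naphthyl > Ph, as the screening trends require.

## Steric classes and fidelity

Class bins follow the screening-table conventions and are applied with
strict inequalities so that printed boundary catalysts fall in the middle
bins: AREA large iff θ > 70°, small iff θ ≤ 36°; proximal small iff
barrier < 3, large iff barrier > 26 kcal/mol. (One source table heads its
small-AREA column "<29" instead of "<36"; the package adopts ≤36 globally —
the only catalyst concerned, SiPh₃ at θ = 29, is small under both.) For
silyl/alkyl 3,3′ groups one arm points up-and-towards the acid and acts as
proximal bulk even though the C3–Si rotation barrier is small; the catalog
records a `proximal_class_override = "large"` for the SiPh₃ entries and the
classifier honours such overrides.

Fidelity claim, stated precisely: the descriptor protocols are calibrated
to reproduce *orderings and class assignments* of the catalog catalysts,
not their printed magnitudes, which derive from a different (QM-based)
protocol. The test suite asserts rank agreement (Spearman ≥ 0.8 on the
benchmark set) and pairwise orderings, never magnitudes. Electronic
effects are outside the model entirely — the 1-naphthyl catalyst, whose
anomalous selectivity is thought to be electronic in origin, is the known
defect of any purely steric description.

## Pathway classification

Declarative inference: large N-substituents direct the imine away from the
3,3′ front (Type I), small ones towards it (Type II); the imine reacts
through *Z* whenever that configuration is accessible (always for cyclic
imines, which are locked *Z*) and through *E* otherwise. A declared
pathway overrides the inference. Transcribing the packaged acyclic screens
into `ReactionSpec`s reproduces every unambiguous printed mechanism label
(mixed "I *E*/*Z*" and "I/II *E*" rows are stored as ambiguous and excluded
from that check).

Geometric classification of an explicit TS uses two conventions, both
deliberate simplifications:

* **E/Z** from the anchor dihedral (C-substituent, imine C, imine N,
  N-substituent): |φ| ≥ 90° is *E*, with the tie at exactly 90° assigned
  *E* so the function is total and deterministic. This is anchor-atom
  geometry, not CIP priority — a documented limitation.
* **Type I/II** from the *front plane* through phosphorus and the two C3
  carbons, its normal oriented towards the acid-oxygen midpoint (the
  binding face). Type I iff the N-substituent vector from the imine
  nitrogen has negative projection on that normal. The assignment is a
  computable surrogate for a visual definition and may disagree with a
  human reading for strongly tilted TSs.

A consequence of anchoring the normal to the acid oxygens: reflecting the
*entire* structure through the front plane re-orients the normal too and
leaves the label unchanged (as it should — a global mirror image preserves
relative orientation). The orientation-flipping symmetry that the model
does obey, and that the tests exercise, reflects only the substrate through
the front plane with the catalyst frame fixed: Type I ↔ Type II, E/Z
preserved.

## Ee prediction

Curtin–Hammett weighting with R = 1.987204×10⁻³ kcal mol⁻¹ K⁻¹, as in the
README. Sign conventions are explicit per ensemble (`positive_config`);
the worked example encodes the transfer-hydrogenation screen, where the
Type II pathway yields the negatively-signed enantiomer. Temperature is
always an explicit argument with a library default of 298.15 K; the worked
example runs at 333.15 K, the 60 °C reaction conditions, which is what
makes the 0.7 kcal/mol gap correspond to −48% rather than −53%. Exact
energy ties between pathways are broken towards Type I then *E* (a fixed
total order) with a warning. `ddg_from_ee` refuses |ee| ≥ 100%, where the
two-state gap diverges; full precision is kept in the library and rounding
to integer percent happens only at the CLI layer.

## The decision tree

The eight outcomes and four requirements are tabulated in
`recommender.py`'s module docstring. Two resolutions were genuinely open:

* **Leaf 6** (Type II *E*, small displaced nucleophile). One prose
  formulation of the qualitative model asks for *small* AREA(θ) here, but
  that contradicts the computational result it summarises — small-AREA
  catalysts cannot discriminate Type II from Type I (they bias Type I
  outright) — and the screening data (the medium-AREA catalysts win the
  Friedel–Crafts and enamide screens; the θ = 29 silyl catalyst is poor in
  both). The implementation follows the computation and data: medium AREA.
* **Type II *E* with a symmetrical nucleophile** is not one of the eight
  catalogued outcomes. For totality the tree routes it to the leaf-6
  requirement, treating an in-line donor like a small displaced one.

Acyclic Type II *Z* has no literature precedent and raises a dedicated
error rather than guessing. Displaced-nucleophile bulk is a binary split
(small/large) keyed to the substituent on the binding carbon; whether it is
really a continuum is an open question the data cannot yet settle. The
shortlist ranks class-matching catalog catalysts by their best |ee|
evidence across the screens (most screen rows carry no mechanism label, so
no per-mechanism filtering is attempted), ties alphabetical, and leaf 7
carries an explicit TRIP-avoidance warning.

Concordance: at strict tolerance the recommended class attains the row
maximum for 20 of 23 judged summary rows; the three near-misses (two
reductive aminations where medium beats small AREA by 7–8 ee points, and
one indole addition where medium beats small by 20) are listed verbatim by
`cpa validate`. The default reporting tolerance of 10 ee points counts the
first two as concordant, matching the qualitative reading that both
classes are highly selective there.

## Fixtures: what the synthetic data does and does not show

* **Cone and torsion toys** have closed-form or brute-force reference
  values; they validate the numeric machinery exactly.
* **Catalyst models** are ETKDG-embedded, UFF-relaxed single conformers
  (seed 20170914, cached; identical name + seed is bit-identical). They are
  real 3D structures of the real catalysts, but single gas-phase
  conformers: descriptor values on them probe the protocol, not
  conformational ensembles. Passing the ordering tests shows the
  descriptors rank genuine structures correctly; it does not certify
  magnitudes against any QM protocol.
* **TS fixtures** are minimal ten-atom arrangements whose only contract is
  their geometric label; they contain no chemistry. They validate the
  classifier's conventions and symmetries, not its agreement with real
  TS geometries.
* **Ensemble fixtures** encode prescribed gaps exactly, so ee tests probe
  the statistical mechanics, not electronic-structure accuracy.

## Problem sizes

Everything is desk-scale by design: the largest routine computation is a
two-substituent rigid scan on a ~110-atom catalyst (36 grid points,
vectorised pair energies, well under a second), and the full test suite —
including embedding six catalysts and a 1000-point property sweep of the ee
identities — runs in seconds on one CPU.
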