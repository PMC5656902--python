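# cpaselect

Steric descriptors and rational catalyst selection for BINOL-derived chiral
phosphoric acids (CPAs).

CPAs catalyse nucleophilic additions to imines through a bifunctional
transition state: the P–OH hydrogen-bonds to the imine nitrogen while the
P=O accepts the nucleophile's proton. Four diastereomeric pathways compete —
the imine N-substituent points away from (Type I) or towards (Type II) the
front of the 3,3′ groups, combined with an *E* or *Z* C=N configuration —
and which one wins is governed almost entirely by two steric features of the
3,3′ substituents:

* **proximal bulk**, adjacent to the phosphoric acid, quantified here as the
  rigid-rotor rotation barrier (kcal/mol) about the C3–Cipso biaryl bond;
* **remote bulk**, distant from the acid, quantified as **AREA(θ)**: the
  half-aperture (degrees) of the widest cone, anchored at phosphorus and
  opening over the substrate-binding face, that clears every
  van-der-Waals-inflated atom beyond a distance cutoff. Large θ = open
  remote environment.

On top of the descriptors the package provides:

* **Pathway classification** — declarative reaction descriptions are mapped
  to their operative Type I/II × *E*/*Z* pathway, and explicit TS geometries
  are labelled from anchor-atom dihedrals and the 3,3′ front-plane
  projection.
* **Curtin–Hammett ee prediction** — for an ensemble of competing TSs with
  relative free energies ΔG‡ᵢ at temperature T, Boltzmann weights
  wᵢ ∝ exp(−ΔG‡ᵢ/RT) give ee = 100·(Σw₊ − Σw₋); two states reduce to
  ee = 100·tanh(ΔΔG‡/2RT), invertible as ΔΔG‡ = RT·ln((1+ee)/(1−ee)).
* **An eight-outcome decision tree** that maps any imine/nucleophile
  combination to one of four catalyst steric requirements
  ((proximal, AREA) ∈ {(large, medium), (large, small), (large, any),
  (small, medium)}) and shortlists catalysts from packaged,
  checksum-verified literature screens.

The package never runs quantum chemistry: TS energies and geometries are
inputs (CSV/XYZ/SDF), and all fixtures are generated programmatically.

## Worked example

Predict the ee for the transfer hydrogenation of a cyclic imine with the
phenyl-substituted catalyst, where the Type II TS lies 0.7 kcal/mol below
the competing Type I TS at the 60 °C reaction temperature:

```sh
$ cat ens.csv
label,pathway,config,energy
TS1,II_Z,S,0.0
TS2,I_Z,R,0.7
$ cpa predict-ee ens.csv --temperature 333.15
{
  "ee_percent": -48.43648074480911,
  "ee_percent_rounded": -48,
  "dominant_pathway": "II_Z",
  "delta_delta_g_kcal_per_mol": -0.7,
  "weights": { "TS1": 0.7421824037240455, "TS2": 0.2578175962759544 }
}
```

The Type II TS carries 74% of the Boltzmann population, so the S-product
(negative by this screen's convention) dominates with −48% ee — matching
both the sign and magnitude expected for this catalyst.

Recommend a catalyst for the reductive amination of an acyclic ketimine
(Type I, *Z* accessible) with a symmetrical hydride donor:

```sh
$ cpa recommend --reaction rxn.yaml
{
  "pathway": "I_Z",
  "leaf": 3,
  "required_proximal": "large",
  "required_area": "small",
  "shortlist": [ { "catalyst": "SiPh3", "area_theta": 29.0, ... } ]
}
```

The tree asks for large proximal sterics (to suppress Type II) and small
AREA(θ) (to suppress Type I *E*); the triphenylsilyl catalyst — small cone
aperture, but silyl arms acting as proximal bulk — is the catalog's match.

Other subcommands: `cpa descriptors catalyst.sdf` (compute θ, the barrier
and their classes for a 3D structure), `cpa classify-ts ts.xyz --map
map.yaml`, `cpa catalog --table 4`, `cpa validate --tolerance 0`
(concordance of the decision tree against the packaged screens) and
`cpa fixtures` (synthetic test inputs).

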