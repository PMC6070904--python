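# Methods

`iupair` analyzes the geometry, hydrogen bonding, energetics and
flexibility of inosine–uracil (I–U) wobble pairs in double-stranded
RNA. Inosine arises from A-to-I editing of adenosine: the 6-amino
group of adenine is replaced by a carbonyl oxygen, so the base
(hypoxanthine) pairs with uracil through N1–H1(I)···O2(U) and
O6(I)···H3–N3(U) instead of the Watson–Crick A–U bonds, shifting the
pair sideways into a wobble. The package implements the full analysis
chain — rigid-base reference frames, helicoidal parameters, H-bond
substate classification, vacuum interaction energies, Boltzmann-
inverted free-energy profiles and quasi-harmonic entropy — and a
synthetic rigid-base ensemble generator that supplies statistically
structured input for every stage, so the whole pipeline is testable
without molecular-dynamics output.

## Rigid-base model

Each base (A, G, C, U, I) is a rigid, planar template expressed in its
standard reference frame (Tsukuba convention: x into the major groove,
y along the long pair axis, z along the helix). Two bases placed on
the same frame, the second rotated 180° about x, form an ideal
Watson–Crick pair. Template heavy-atom geometry is the idealized
planar set used by the standard helicoidal-parameter tools; hydrogens
are placed in-plane at 1.01 Å (N–H) / 1.08 Å (C–H) along the external
bisector of the parent atom's bonds.

Atoms carry partial charges and 12-6 Lennard-Jones parameters in the
style of the AMBER nucleic-acid force fields (Coulomb constant
332.0637 kcal·Å/mol/e², arithmetic-mean Rmin, geometric-mean well
depths). The charge table is transcribed, not fitted, and the
hypoxanthine entry is assembled from the guanine Watson–Crick edge
(N1/H1/C6/O6) plus an adenine-like C2–H group, since no published
charge set for inosine is reproduced verbatim here. Absolute energies
therefore carry a transcription uncertainty of order 1 kcal/mol, and
all energy checks use tolerances, never exact values. Base fragments
are not individually neutral (the remainder of the nucleotide charge
lives on the absent sugar–phosphate); each template declares its net
charge as the sum of its atoms.

Base frames are fitted to observed coordinates by Kabsch superposition
of the ring atoms only (reflections corrected to proper rotations),
matching the convention behind the pair-parameter definitions. The
fit–rebuild roundtrip is exact to machine precision and equivariant
under rigid motions.

## Helicoidal parameters

One mid-frame scheme (the CEHS/3DNA construction) is used for both
pair parameters (shear, stretch, stagger, buckle, propeller, opening)
and step parameters (shift, slide, rise, tilt, roll, twist): the
relative rotation between two frames is split symmetrically about the
hinge axis, twist is measured about the shared z of the symmetrized
frames, and translations are read in the mid-frame. The decomposition
and its inverse (used by the generator) round-trip to 1e-13. Pair
parameters are computed from the flipped strand-2 frame to the
strand-1 frame, which makes a strand-1 purine wobble carry *negative*
shear, and minor-groove opening carry negative opening — the sign
convention of the printed values. Local step bend is
`sqrt(roll² + tilt²)`; the global bend of a duplex is the angle
between the mean mid-pair z-axes of its two terminal halves, terminal
pairs excluded (end fraying would otherwise dominate).

## Wobble-pair construction

`build_wobble_pair` emulates the restrained in-vacuo minimization that
resolves the steric clash created by placing inosine on the adenine
position of an ideal A–U pair (O6(I) against O4(U)). Both bases move
as rigid bodies (6 DOF each) minimizing the vacuum nonbonded energy
plus: (i) harmonic restraints of 20 kcal/mol/Å² pulling the
N1(I)–O2(U) and O6(I)–N3(U) distances to 2.90 Å (a typical N···O
hydrogen-bond length; the restraint targets are not printed anywhere
and are declared here); (ii) the nonbonded field of two fixed
canonical A–U neighbour pairs stacked one ideal A-form step above and
below; and (iii) stiff tethers (200 kcal/mol/Å²) pinning each
glycosidic nitrogen, standing in for the covalent attachment to the
fixed backbone — soft tethers would let the free pair over-relax into
a buckled gas-phase minimum that the duplex does not allow. L-BFGS-B
with a 2000-iteration budget; non-convergence raises with the final
projected gradient norm. The relaxed pair classifies as the two-bond
A-geometry with shear ≈ −2.6 Å and pair energy ≈ −12.9 kcal/mol
(the same protocol applied to A–U gives ≈ −12.0; the ideal unrelaxed
A–U pair gives −11.7).

## H-bond detection and substates

A hydrogen bond is donor–H···acceptor with donor–acceptor distance
≤ 3.4 Å and donor–H–acceptor angle ≥ 135°. The generous distance
cutoff deliberately keeps minor fluctuations of a formed bond inside
the definition. C–H donors are excluded except inosine C2–H2, which
is required for the D and F substates and admitted only for the
monitored pair. The monitored I–U pair is classified each frame by
its bond pattern in priority order A (both wobble bonds), B (O6–N3
only), C (N1–O2 only), D (C2–O2), E (N1–O4, alone or bifurcated with
C2–O4), F (C2–O4 alone), else "other". Priority resolves boundary
overlaps in favour of the more-bonded, more-populated state. Whether
a bond is "absent" through distance or angle is deliberately not
distinguished — either failure breaks it.

## Synthetic ensembles

The generator emulates the statistical structure the analysis assumes
of an MD trajectory, not the physics. Canonical steps fluctuate as
Gaussians around an idealized straight A-form (shift 0, slide −1.5 Å,
rise 3.3 Å, tilt 0, roll 0, twist 32.7°; an option substitutes the
29.5° twist seen in simulations). Zero roll makes the noise-free
duplex exactly straight, which anchors the bend tests; the
characteristic A-form displacement of the pairs off the helix axis is
carried by the slide term. Steps flanking an I–U pair redistribute
twist by ∓8° (5′ step under-twists, 3′ step over-twists), conserving
the global twist exactly — the compensation pattern of the real
trajectories. Canonical-pair fluctuation SDs (0.25/0.12/0.3 Å,
6/6/4°) are MD-like breathing amplitudes; step SDs similarly.

The six substate geometries are frozen six-parameter vectors solved
(once, by penalized minimization over pair parameters under the rigid
templates) so that the rebuilt pair satisfies exactly its label's
H-bond pattern: A(shear −2.59), B(opening −35.0), C(opening +24.7),
D(shear +0.40, strongly non-planar), E(shear +3.59), F(shear +5.33).
Where the printed record states a substate's coordinate (B at −35°,
D near zero shear, E near +4 Å) that coordinate was pinned during the
solve; remaining components follow from bond satisfaction and clash
avoidance. Each template classifies back to its own label by
construction, and ≥98.5% of frames do so under the monitored-pair
noise (0.08 Å / 2.5°) — deliberately tight so that the H-bond
pattern, not the noise, defines the state. The monitored (5′ tandem)
pair switches between substates by a stationary Markov chain
`P = (1−r)I + r·1πᵀ` whose stationary distribution π defaults to the
observed population row for the pair's 5′-neighbour context
(U: 90/6/3/1/0/0 … C: 56/21/4/7/6/6 …); the switching rate r
(default 0.05/frame) sets the correlation time. Population-recovery
experiments at binomial tolerances use r = 1 (independent draws),
because the binomial bound presumes independence; the default r keeps
realistic persistence for profile and entropy work.

The backbone is represented by one phosphorus atom per residue placed
rigidly in the base frame — sufficient for the phosphorus-only
entropy analysis and nothing else. What the generator does *not*
emulate: backbone internal degrees of freedom, sequence-dependent
stacking preferences, coupling between a substate and its neighbours'
geometry (neighbour pairs are drawn independently, so strongly
non-planar substates occasionally interpenetrate a neighbour — such
frames are recognizable by their repulsive stacking energies and are
excluded from conditioned summaries), solvent, and any barrier
heights. Passing tests therefore demonstrate that the *analysis*
recovers what the generator put in, not that real RNA behaves this
way.

## Energetics

Interaction energies are bases-only vacuum sums of Coulomb
(dielectric 1, no cutoff) and 12-6 LJ terms over cross pairs of atom
groups: E_H-bond between the two bases of a pair, E_stack between the
four bases of two stacked pairs grouped pair-against-pair, and the
total step energy their sum (an identity, tested as such). The duplex
formation energy is the cross-strand nonbonded energy — for rigid
strands all intra-strand terms cancel in
E(duplex) − E(strand1) − E(strand2). No solvation or surface term is
included anywhere, so formation-energy magnitudes are roughly 2.5×
the solvated published scale and only orderings are meaningful.
Configurations with interatomic overlap (< 0.3 Å) are flagged, not
clipped.

## Free-energy profiles

Profiles over shear ([−5, +5] Å) and opening ([−80°, +80°]), 100 bins
each, come from direct Boltzmann inversion of unbiased ensemble
sampling: ΔG = −kT ln(p/p_max) at 300 K, empty bins marked unsampled
(NaN), never zero. The adaptive-bias machinery that produced the
published profiles is not implemented; consequently well *positions*
are quantitative here but barrier heights between rarely exchanged
wells are not. Minima are detected on a 3-bin moving average with a
prominence filter (0.3 kcal/mol) and a 5-sample occupancy floor,
which suppresses single-bin statistical dimples without displacing
real wells by more than one bin.

## Quasi-harmonic entropy

The mass-weighted covariance of the superposed phosphorus coordinates
yields eigenvalues λ (amu Å²); each mode of frequency
ω = sqrt(kBT/λ) contributes the quantum harmonic-oscillator entropy,
summed in cal/mol/K. Modes with λ < 1e-8 amu Å² are excluded as
rigid-body/numerical nulls. Entropy is computed over nested windows
(by default ending at 40–100% of the trajectory after a 20% offset)
and regressed against the *reciprocal* window length; the intercept
is S∞. The reciprocal abscissa is this package's choice — it gives a
finite intercept independent of trajectory length, and recovers
constructed S(t) = S∞ − c/t series exactly — but the published
regression variable is not stated, so S∞ values are comparable
internally, not externally.

## Numerical choices and degenerate inputs

Frame fitting requires ≥3 non-collinear matched ring atoms; the
decomposition handles the zero-rotation limit by an arbitrary in-plane
hinge. Angle averages are arithmetic (values stay far from ±180°).
Population tables refuse empty inputs and mixed pair ids; entropy
refuses single frames and non-increasing windows; inversion refuses
fully out-of-range samples. All randomness flows from a single
`numpy` Generator seeded per run; identical seeds give byte-identical
artifacts.

## Problem sizes

Default analysis sizes keep every stage interactive on one core:
10⁴ frames for population recovery, 5×10³ for profiles, 2×10³ for
entropy, 8×10² for helicoidal averages. They can be raised freely;
accuracy scales as 1/√n throughout.

## Known limitations

* Charges are a documented approximation; absolute energies carry
  ~1 kcal/mol systematic uncertainty (orderings are robust).
* The D-geometry is intrinsically strained under rigid planar
  templates (its pair energy is repulsive); in real RNA the strain
  relaxes through base and backbone flexibility the model excludes.
* The E-geometry satisfies its H-bond pattern at shear ≈ +3.6 Å under
  rigid geometry, slightly short of the ≈ +4 Å seen with flexible
  bases.
* Total-bend averages over noisy ensembles are positive by
  construction (the angle is unsigned); only noise-free geometry
  gives zero, and only comparisons between systems are meaningful.
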