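# Methods

This note documents the models behind each analysis, the tunable
parameters, the synthetic-data design, and the numerical choices where
the design was genuinely open.

## Coordinate system and units

All internal lengths are nm; Ångström values (PDB coordinates, the
salt-bridge cutoff table) are converted at the I/O boundary (1 Å =
0.1 nm). Energies are kcal/mol externally and kJ/mol internally in the
WHAM solver (1 kcal = 4.184 kJ); k_B = 0.0083145 kJ mol⁻¹ K⁻¹, so at the
default 310 K, kT = 2.5775 kJ/mol = 0.6160 kcal/mol. Analyses assume an
orthorhombic box with the membrane normal along z, molecules whole, and
the bilayer not split across the z boundary; the minimum-image convention
is applied in x,y only.

## Membrane geometry and the insertion coordinate ζ

Per frame, the bilayer is located by (i) the z centre of geometry of all
lipid atoms, (ii) sorting phosphate oxygens into leaflets by z relative
to that centre, (iii) taking each leaflet plane as the mean z of its
oxygens, and (iv) buffering the inter-plane slab by 0.2 nm on each side
to absorb surface roughness. A leaflet with no phosphate oxygens is a
hard error rather than a silent misassignment.

ζ is the z-distance between the anchor residue's Cα and the membrane
middle, signed positive toward the intracellular side. Two reductions of
"membrane middle" are exposed: the mass-weighted centre (the default, and
the definition used for ζ) and the plain centre of geometry (used by the
slab construction). Orientation comes from configuration
(`intracellular: +z|-z`, default `+z`); no auto-detection is attempted,
because a half-inserted hairpin makes any heuristic ambiguous.

## Water-defect and headgroup counting

A water belongs to the defect when its **oxygen** satisfies both the slab
criterion and the cylinder criterion (in-plane distance to the hairpin
centre ≤ radius 1.0 nm, |Δz| ≤ half-height 3.0 nm); each water residue
counts once. All geometric boundaries are inclusive (≤) so boundary
fixtures are deterministic; the salt-bridge comparison additionally
tolerates ~1e-9 relative coordinate-representation roundoff. The
cylinder follows the hairpins' centre of geometry frame by frame, since
the protein drifts laterally over microseconds.

"Pulled into the core" for a phosphate means: inside the cylinder and
displaced more than `depth_margin` (default 0.5 nm) past its own
leaflet's plane. The margin is a declared operationalisation — no
numerical criterion exists in the literature for this observable — and is
exposed in configuration. Leaflet membership is frozen at the first frame
of a trajectory (nearest plane) to avoid flip-flop artefacts when a
headgroup crosses the midplane.

Headgroup contacts are phosphorus atoms within 1.0 nm (configurable) of
any hairpin atom, annotated with the lipid residue name so counts can be
aggregated by class (PE / PG / cardiolipin).

## Salt bridges: the central-atom criterion

Measuring every N⁺–O⁻ pair each frame is wasteful; instead each charged
side chain is reduced to one central atom (Lys NZ, Arg CZ, Glu CD,
Asp CG — a configurable name table, since force fields differ) and the
cutoffs are adapted per pair type: 4.58 Å (K–E), 5.28 Å (R–E),
5.10 Å (R–D), 4.40 Å (K–D).

The K–E value is consistent with the conventional 4.0 Å N–O criterion
under an idealised carboxylate (C–O 1.25 Å, O–C–O 124°) when the 4.0 Å is
read as the *axial* N–O separation along the approach axis: each oxygen
projects onto the carboxylate bisector at 1.25·cos 62° = 0.587 Å ahead of
the carbon, giving a carbon–nitrogen cutoff of 4.0 + 0.587 = 4.59 Å
(`central_cutoff_from_no_criterion`). The literal 3-D N–O distance
reading would instead give 4.43 Å — close to the K–D table value — so the
table values are taken as given rather than re-derived. Histidine is
excluded (treated neutral). Occupancy is the percentage of frames a
pair's central-atom distance is within its cutoff; occurrences can be
binned along ζ (default bin 0.1 nm) when a frame-aligned ζ series is
supplied.

## WHAM

The solver operates on binned data (default bin width 0.05 nm; the
histogram range defaults to the sampled range padded by one bin). Window
free energies f_i are iterated through the standard self-consistency
equations in log space (logsumexp throughout). Direct substitution
converges linearly with a rate that approaches one for many strongly
overlapping windows, so the default iteration applies Anderson mixing of
depth one to the substitution map — same fixed point, orders of magnitude
fewer iterations; `accelerate=False` restores plain substitution. The
gauge is f_1 = 0; convergence is declared when the maximum relative
residual of the substitution map falls below 1e-10 (configurable), and
non-convergence within `max_iter` raises with the final residual. Bins
with zero aggregate counts are NaN ("undefined"), and adjacent windows
that share no occupied bin trigger a warning, because the PMF offset
across such a gap is unconstrained.

The emitted profile is shifted so G = 0 in the bin containing ζ = 2.5 nm
— far enough into the aqueous phase that profiles of different proteins
are comparable — and the shift is idempotent.

A `bias_quadrature` option replaces the bias Boltzmann factor at the bin
centre by its midpoint-rule bin average. It is **off** by default: for
stiff biases the centre-point errors of the numerator histogram and the
denominator weights largely cancel, and measured deviation from the
generating potential grows when only the denominator is refined. This is
the one place where the textbook scheme beat the "more accurate"
quadrature in validation, and the option is retained for sensitivity
studies only.

Known systematic: with k = 1000 kJ nm⁻² mol⁻¹ the bias varies by more
than 1 kT across a 0.05 nm bin, and the residual binning systematic of
the centre-point scheme is of order 0.1 kcal/mol. The double-well
recovery test therefore carries a 0.1 kcal/mol RMS tolerance at k = 1000,
while the closed-form harmonic *limit* test uses a softer bias
(k = 250 kJ nm⁻² mol⁻¹, binning floor ~0.01 kcal/mol) with dense windows
(41 over [−1.5, 2.5] nm) and 8×10⁴ exact samples per window so that the
0.05 kcal/mol tolerance tests the estimator rather than the
discretisation. Recovery error is assessed as RMS over bins covered by at
least two windows: single-window tail bins carry O(1) counts and say
nothing about the estimator.

## Uncertainty: 4 random parts

Each window's retained samples are partitioned into four equal parts —
an independently seeded random partition by default, contiguous blocks as
an alternative — WHAM plus the reference shift is re-run per part, and
the per-bin sample standard deviation (ddof 1) across the four profiles
is reported; bins defined in fewer than two parts are NaN. Two practical
notes, reflected in the validation design:

* A four-way split yields a 3-degree-of-freedom variance estimate, so any
  *ratio* of such estimates is volatile; scaling checks pool the squared
  deviations over replicate datasets before forming the ratio.
* Bins at the frontier of coverage hold O(1) counts at any sample size
  and contribute an n-independent O(kT) deviation; scaling checks
  therefore restrict to the restrained range.

## Feature extraction

The adsorbed minimum is the global minimum of G over ζ ∈ [1.0, 2.5] nm,
the inserted minimum over ζ ∈ [−2.0, 0.0] nm (both user-overridable, and
disjoint by construction); the barrier is the global maximum on the
closed interval between the two minima. When the profile is monotone
there, the barrier degenerates to an endpoint and is flagged
(`interior_barrier = False`). Derived energies: barrier height
G(barrier) − G(adsorbed min); well depth G(barrier) − G(inserted min);
insertion preference = their difference, positive when the inserted state
is favoured.

## Synthetic data

The membrane generator builds pseudo-lipids as three-atom tokens (P
headgroup, phosphate-O marker 0.02 nm coreward, tail bead 0.8 nm
coreward) on two leaflet planes (±2.0 nm about the centre, 0.03 nm
plane jitter, 60 lipids per leaflet in an 8×8×10 nm box), a pseudo-
hairpin ladder of single-Cα residues hugging the box axis in the lower
half of the membrane, bulk waters, and planted objects. Every planted
object is placed at least 0.05 nm inside its defining boundary and every
excluded object at least 0.05 nm outside, against the *realised* planes
and hairpin centre, so the expected counts are exact by construction, not
statistically. The anchor Cα is pinned against the realised mass-weighted
lipid z-centre so the frame's ζ is exact to machine precision.
Infeasible requests — e.g. a core phosphate that cannot simultaneously
sit inside the cylinder and stay clear of the 1 nm near-hairpin cutoff at
the requested ζ — raise instead of silently bending a criterion.

Umbrella windows are drawn *exactly* from the biased Boltzmann density of
a declared potential (harmonic, tilted quartic double well, or tabulated)
by inverse-CDF sampling on a 0.005 nm grid, with an explicit error when
more than 99.9% of a window's biased mass falls outside the potential's
domain. Exact sampling removes autocorrelation, so recovery tests are
sharp: residual error is estimator error. What this does **not** emulate:
correlated MD dynamics (no autocorrelation, no equilibration transient),
force-field lipid geometry, protein structure, or solvent physics — a
passing recovery test validates the estimator and the geometric
predicates, not the convergence of any particular MD protocol.

Salt-bridge fixtures place an idealised planar carboxylate (C–O 1.25 Å,
O–C–O 124°, bisector toward the base) and the basic group's central atom
at an exact separation, enabling boundary tests at each cutoff.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` use: 40 windows ×
2×10⁴ samples (k = 1000) for double-well recovery; 41 windows × 8×10⁴
samples (k = 250) for the closed-form limit; 100 planted frames
(~120 lipids, ~310 waters each) for count recovery; 8 boundary fixtures
for the cutoffs; and 4 replicate datasets × (2×10³ vs 8×10³ samples) for
the uncertainty scaling. These sizes put Monte-Carlo noise comfortably
below each check's tolerance while keeping a full run to a few seconds.

## Known limitations

* Binned WHAM, not MBAR: the binning systematic noted above is inherent
  to the estimator; MBAR is deliberately out of scope as the primary
  estimator.
* No periodic-image handling along z during analysis; a `--rewrap`
  preprocessing step (circular-mean recentering of the bilayer at Lz/2)
  handles frames whose bilayer straddles the z boundary, but molecules
  are otherwise assumed whole.
* The phosphate "in the defect" margin (0.5 nm) and the near-hairpin
  cutoff (1.0 nm) are conventions, not derived quantities.
* Binary trajectory formats are not parsed; frames arrive as PDB/GRO
  structures or through the in-memory API.
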