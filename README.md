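# gdminsert

Analysis toolkit for the membrane insertion of gasdermin β-hairpins:
geometric water-defect and lipid-headgroup statistics, salt-bridge
occupancies with a reduced central-atom criterion, the membrane-insertion
reaction coordinate ζ, and a from-scratch WHAM solver that turns
umbrella-sampling windows into a potential of mean force (PMF) with
feature extraction and split-sample uncertainties.

## Who it is for

Researchers analysing molecular-dynamics simulations of pore-forming
proteins — gasdermin D (GSDMD), gasdermin A3 (GSDMA3), and similar
β-hairpin inserters — who need the per-frame membrane observables that
characterise insertion: how many waters the hairpins drag into the
bilayer core, which phosphate headgroups follow them, which salt bridges
shield the charged hairpin residues, and the free-energy profile along
the insertion coordinate. Every analysis is validated against synthetic
fixtures with planted, exactly-known ground truth, so the package also
serves as a reference implementation of the methods.

## The quantities it computes

**Reaction coordinate.** ζ is the signed distance along the membrane
normal between the Cα of an anchor residue at the hairpin tip (C191 for
GSDMD, K97 for GSDMA3) and the membrane middle; positive ζ is
intracellular (membrane-adsorbed ≈ +2 nm, inserted < 0).

**Water defects.** The membrane slab is located per frame from the
z-centre of all lipid atoms and the leaflet phosphate-oxygen planes,
buffered by 0.2 nm. A water counts as "in the defect" when its oxygen is
inside the buffered slab *and* inside a cylinder (radius 1.0 nm, height
6.0 nm) that follows the hairpins' centre of geometry. Phosphates count
as pulled into the core when they sit inside the cylinder and more than
0.5 nm past their own leaflet's plane.

**Salt bridges.** Each charged side chain is reduced to one central atom
(Lys NZ, Arg CZ, Glu CD, Asp CG) and the conventional 4 Å N⁺–O⁻
criterion maps onto central-atom cutoffs: Lys–Glu 4.58 Å, Arg–Glu 5.28 Å,
Arg–Asp 5.10 Å, Lys–Asp 4.40 Å (inclusive).

**PMF.** Umbrella windows with harmonic biases w_i(ζ) = ½k(ζ−ζ_i)²
(k = 1000 kJ nm⁻² mol⁻¹ by convention, T = 310 K) are combined with the
WHAM self-consistency equations

    p_b = Σ_i n_ib / Σ_i N_i exp[(f_i − w_i(ζ_b))/kT]
    f_i = −kT ln Σ_b p_b exp(−w_i(ζ_b)/kT)

iterated to a fixed point (Anderson-accelerated, tol 1e−10), giving
G_b = −kT ln p_b in kcal/mol, shifted to zero at ζ = 2.5 nm. Feature
extraction reports the adsorbed minimum, insertion barrier and inserted
minimum, with barrier height, well depth, and the insertion preference
(≡ well depth − barrier height). Uncertainties follow the 4-random-part
convention: samples are split into four parts, WHAM is re-run per part,
and the per-bin standard deviation across parts is reported.

## Worked example

Sample umbrella windows exactly from a declared double-well landscape,
solve WHAM, and extract the insertion features:

```
$ cat dw.yaml
form: double_well
params: {A: 4.0, c: 0.5, w: 1.5, b: -1.0}
domain: [-2.5, 3.0]

$ gdm simulate-umbrella --potential dw.yaml --centers -2.0:2.6:0.1 \
      --k 1000 --n 20000 --seed 7 --outdir windows
wrote 47 windows and manifest to windows
$ gdm wham --manifest windows/manifest.csv --bin-nm 0.05 --shift-at 2.5 --out pmf.tsv
wrote PMF (96 defined bins) to pmf.tsv
$ gdm pmf-features --pmf pmf.tsv --adsorbed 1.0:2.5 --inserted -2.0:0.0
{
 "zeta_adsorbed_min_nm": 2.0642,
 "zeta_barrier_nm": 0.3642,
 "zeta_inserted_min_nm": -0.8858,
 "barrier_height_kcal_mol": 5.59168,
 "well_depth_kcal_mol": 2.653045,
 "insertion_preference_kcal_mol": -2.938635,
 "interior_barrier": true
}
```

The generating double well has its shallow minimum on the inserted side,
so the recovered profile shows a 5.6 kcal/mol barrier from the adsorbed
minimum near ζ = 2.06 nm and a *negative* insertion preference
(−2.9 kcal/mol: adsorbed state favoured, the GSDMA3-like situation). The
recovered curve tracks the declared potential to ~0.05 kcal/mol RMS.

The geometric analyses run the same way on structure files; synthetic
frames carry a JSON truth sidecar:

```
$ gdm simulate-frame --seed 11 --defect-waters 12 --core-phosphates 3 \
      --zeta -0.8 --out frame.gro
$ gdm defect-waters --structure frame.gro --config cfg.yaml --out series.csv
$ cat series.csv
time_ps,zeta_nm,n_waters,n_core_phosphates
0.000000,,12,3
```

Both planted counts are recovered exactly.

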