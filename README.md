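# hingeflow

Interfacial-structure and water-transport analysis for water/octanol
molecular-dynamics trajectories.

Water/octanol is the reference system for lipophilicity (log P), yet how a
water molecule actually crosses the interface is not simple diffusion.  At
the instantaneous surface octanol forms a bilayer-like structure: a
monolayer with hydroxyls toward the water (**Layer-1**) and a second,
patchy layer with hydroxyls toward the organic phase (**Layer-2**, made of
hydrogen-bonded "bilayer islands").  Water moves between these layers
three ways: bare **diffusion**, a ride on a single stochastically
**flipping** octanol, or — dominantly — inside an intact
(oct)<sub>n</sub>(H₂O)<sub>m</sub> cluster that swings between the layers
like a door hinge (the **hinge mechanism**).  This package provides the
full analysis chain for anyone studying transport at soft liquid/liquid
interfaces:

* typed molecular configurations (GRO / extended-XYZ) with periodic
  minimum-image geometry;
* hydrogen-bond network graphs (O⋯O < 3.5 Å, H–O⋯O ≤ 30°) and O–O
  proximity clusters;
* intrinsic surfaces: ITIM (probe radius 1.5 Å, grid 0.2 Å, with a DBSCAN
  correction for waters that penetrated the organic phase) and the
  Willard–Chandler isosurface (coarse-graining 2.5 Å, 90% bulk density)
  with its area;
* five-region layer assignment, orientation/density profiles, 2D-RDFs,
  excess coordination numbers N<sub>excess</sub>(r) = ρ∫₀^r(g−1)2πr′dr′,
  packing densities, bilayer-island detection;
* transport-event detection and mechanism classification
  (diffusion / flip / hinge), transfer statistics with 3-block errors, and
  Arrhenius barriers E_a = R·T·ln(A/k);
* a Langevin model of hinge transport: BAOAB dynamics on a constrained
  double-well potential (minima at −0.868/+0.854 nm, barriers
  6.00/5.60 kcal/mol) counting forward/backward well crossings;
* a synthetic-data module that generates biphasic slabs, scripted
  transport events with ground truth, and pressure-tensor series, so the
  whole pipeline is testable without MD output.

## Worked example

Generate a slab with planted interfacial structure, assign layers, and
measure the surface:

```python
import hingeflow as hf

frame, truth = hf.gen_slab(hf.SlabSpec(seed=7))
graph = hf.detect_hbonds(frame)
assignment = hf.assign_layers(frame, graph)

print({r: len(assignment.members(r)) for r in
       ("bulk_water", "water_surface", "layer1", "layer2", "bulk_octanol")})
islands = hf.find_bilayer_islands(assignment, frame)
print(sorted((i.octanol_count, i.water_count) for i in islands))
```

prints

```
{'bulk_water': 1184, 'water_surface': 169, 'layer1': 49, 'layer2': 19, 'bulk_octanol': 12}
[(4, 2), (4, 2), (5, 2)]
```

— 169 waters form the instantaneous surface, 49 octanols are Layer-1
(hydrogen-bonded to a surface water at 45° tilt), and the three planted
Layer-2 islands are recovered with their exact octanol/water compositions.

The same works end-to-end from the command line:

```bash
hingeflow all --seed 7 --out demo/
```

whose `demo/summary.json` contains (abridged)

```json
{
  "mechanism_fractions": {"hinge": 0.8, "flip": 0.067, "diffusion": 0.133},
  "stoichiometry_L1_L2": 1.69,
  "gamma_mN_per_m": 25.54,
  "wc_area_A2": 1601.8
}
```

The scripted demo plants a hinge-heavy event mix, and the classifier
recovers the planted water shares (80% hinge, ~7% flip, ~13% diffusion);
the Willard–Chandler area of the flat slab equals the 40×40 Å cell cross
section to 0.1%; the interfacial tension of the synthetic pressure series
(planted 100 bar anisotropy, L_z = 100 Å, two interfaces) comes out at
25.5 mN/m against the exact 25.0.

The Langevin hinge model runs as its own subcommand:

```bash
hingeflow langevin --replicates 100 --samples 100000 --seed 1 --out ld.json
```

which on this smoke scale reports a forward/backward crossing ratio of
1.394 ± 0.085 (138/99 crossings, friction 0.5 ps⁻¹).  See
`docs/methods.md` for why the constrained quartic well shape places this
ratio near 1.3–1.4.

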