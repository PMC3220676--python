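# dendristab

Solution-structure and stability analysis for guanidinium-modified PAMAM
dendrimer salts around model proteins.

Guanidinium (Gdm) groups donate multiple hydrogen bonds, so a generation-0
PAMAM dendrimer whose four surface amines are converted to guanidinium binds
protein surfaces cooperatively — unless hydrogen-bond-accepting counterions
(sulfate, dihydrogen phosphate) pair with the Gdm groups first. That ion-ion
pairing bridges dendrimers into clusters, switches binding from multi-arm to
single-arm, and turns a denaturant into a potent aggregation suppressor.
`dendristab` provides the analysis layer for studying exactly this
competition, on particle configurations (from any source that can be
expressed as multi-frame XYZ / multi-model PDB plus a topology sidecar) and
on tabular kinetics data:

- **Preferential interaction coefficients** Γ₂₃ = n₃ˡᵒᶜ − (n₃ᵇᵘˡᵏ/n₁ᵇᵘˡᵏ)·n₁ˡᵒᶜ
  from a local/bulk partition at a protein-surface cutoff, with burn-in,
  block-averaged standard errors, per-ion components, salt-level weighted
  averages, and the exclusion-only reference Γ_excl = −c₃·N_A·V_shell for an
  inert solute of the same size.
- **Hydrogen-bond networks**: geometric detection (donor-acceptor distance
  ≤ 3.5 Å, D-H⋯A deviation ≤ 30°, distance-only for reduced models),
  classification into D-D / D-A / P-D / P-A pair categories and bridged
  D-A-D / P-A-D triplets, and cluster extraction as connected components.
- **SASA loss decomposition** (Shrake-Rupley-style deterministic spiral
  sampling): per-dendrimer ΔSAA split exactly into dendrimer-overlap and
  counterion-overlap parts, ΔSAA_total = ΔSAA_dend + ΔSAA_ion.
- **Distributions**: center-of-mass / site RDFs with ideal-gas
  normalization, and arm-ranked protein-surface distance profiles (arms
  re-ranked 1–4 by distance every frame).
- **Aggregation kinetics**: second-order monomer loss 1/M = 1/M₀ + k·t,
  t50/t95, relative rates k/k₀ and shelf-life extension factors
  t95/t95,₀ = k₀/k, plus linear dTm/d[c] thermal-shift slopes.
- **Synthetic systems**: seeded generators for well-mixed (chloride-like)
  vs. anion-bridged (sulfate-like) solutions around a model protein, and
  noisy second-order decay curves — so every analysis is testable without
  molecular dynamics.

## Worked example

```python
import dendristab as ds

kw = dict(box=(60, 60, 60), n_dendrimer=8, n_anion=16, n_water=50, seed=1)
mix_cfg, mix_topo = ds.gen_mixture(ds.SolutionSpec(**kw))
bri_cfg, bri_topo = ds.gen_bridged_solution(
    ds.SolutionSpec(bridge_propensity=0.9, **kw))

for name, cfg, topo in [("well-mixed", mix_cfg, mix_topo),
                        ("bridged", bri_cfg, bri_topo)]:
    bonds = ds.detect_hbonds(cfg, topo)
    mc = ds.classify_and_count(bonds, topo)
    part = ds.cluster_components(bonds, topo, {"dendrimer", "anion"})
    print(name, mc.as_dict()["D-A"], mc.as_dict()["D-A-D"], part.largest)
```

prints

```
well-mixed 0 0 1
bridged 18 4 9
```

— at identical composition, the bridged (sulfate-like) solution shows 18
dendrimer-anion hydrogen bonds, 4 anion-bridged D-A-D motifs and a
9-molecule hydrogen-bonded cluster, while the well-mixed (chloride-like)
solution stays fully dispersed. The same contrast drives the surface-area
and arm-ranking outputs (`examples/04`, `examples/05`):

```
well-mixed: SAA_iso   406.2 Å²  ΔSAA    3.9  (dendrimer    0.0 + ion    3.9)
bridged   : SAA_iso   405.7 Å²  ΔSAA   68.1  (dendrimer   15.9 + ion   52.1)

well-mixed: rank means  7.87  8.87  9.81 10.92  Å   gap 3.04 Å
bridged   : rank means  9.34 13.56 14.80 16.16  Å   gap 6.82 Å
```

Bridging buries dendrimer surface against other dendrimers and widens the
rank-1→rank-4 arm gap near the protein: one arm stays engaged with the
surface while the others are pulled into the bulk.

The `examples/` directory holds one short narrative script per capability;
each builds a small input, runs the analysis and prints what the numbers
mean. A thin CLI mirrors the library
(`dendristab synth|gamma|hbond|cluster|sasa|rdf|kinetics ...`).

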