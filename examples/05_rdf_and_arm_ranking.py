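"""Radial distribution functions and arm-ranked protein-surface distances.

The dendrimer-anion RDF shows the contact peak from hydrogen-bonded ion
pairing.  The arm-ranked analysis sorts each dendrimer's four arm sites by
distance to the protein surface every frame: a small rank-1→rank-4 gap
means several arms engage the surface simultaneously (cooperative binding);
a wide gap means one arm binds while the rest face the bulk.
"""
import numpy as np

import dendristab as ds

kw = dict(box=(70, 70, 70), n_dendrimer=8, n_anion=16, n_water=0,
          protein=20.0)

mix_frames, mix_topo, bri_frames, bri_topo = [], None, [], None
for s in range(25):
    cfg, mix_topo = ds.gen_mixture(ds.SolutionSpec(seed=s, **kw))
    mix_frames.append(cfg)
    cfg, bri_topo = ds.gen_bridged_solution(
        ds.SolutionSpec(bridge_propensity=0.9, seed=s, **kw)
    )
    bri_frames.append(cfg)

rdf = ds.radial_distribution(bri_frames, bri_topo, "dendrimer:arm",
                             "anion:com", bin_width=0.25, r_max=12.0)
peak = rdf.r[np.argmax(rdf.g)]
print(f"dendrimer-arm / anion RDF peak at {peak:.2f} Å "
      f"(g = {rdf.g.max():.1f}) — the hydrogen-bonded contact shell")

for name, frames, topo in [("well-mixed", mix_frames, mix_topo),
                           ("bridged", bri_frames, bri_topo)]:
    prof = ds.rank_arms(frames, topo)
    means = prof.mean_by_rank()
    print(f"{name:10s}: rank means "
          + " ".join(f"{m:5.2f}" for m in means)
          + f"  Å   gap {prof.gap():.2f} Å")
# The bridged system's wider gap reflects single-arm, anion-mediated
# attachment; the well-mixed system's narrow gap reflects cooperative
# multi-arm binding.
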