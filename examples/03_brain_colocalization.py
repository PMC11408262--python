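"""Colocalize gene sets in brain regions by permutation testing.

Builds an atlas with planted over-expression of a transcriptomic gene set
and a genomic-environmental (GE) set in partially overlapping regions, then
forms GET subsets from the shared significant regions.
"""

import personet as pn
from personet.colocalize import significant_regions

cfg = pn.SynthConfig(
    n_subjects=30,
    profile_sizes={"creative": 8, "organized": 15, "unregulated": 7},
    n_genes=400, n_responsive=100, n_biclusters=2,
    bicluster_genes=25, bicluster_subjects=10,
    n_regions=10,
    region_enrichment={"T1": ["R02", "R03"], "SAER": ["R03", "R04"]},
    region_effect=3.5, rng_seed=5)
genes = [f"G{i:06d}" for i in range(1, 401)]
sets = {"T1": genes[:25], "SAER": [f"PG{i:05d}" for i in range(1, 16)]}
atlas = pn.gen_atlas(cfg, sets)
print(f"atlas: {atlas.shape[0]} genes x {atlas.shape[1]} regions")

links = {}
for set_id, members in sets.items():
    links[set_id] = pn.region_significance(members, atlas, n_perm=1000,
                                           seed=5, set_id=set_id)
    sig = sorted(significant_regions(links[set_id]))
    print(f"  {set_id}: significantly over-expressed in {sig}")

gets = pn.find_get_subsets({"T1": links["T1"]}, {"SAER": links["SAER"]},
                           {"T1": sets["T1"]}, {"SAER": sets["SAER"]})
for subset in gets:
    print(f"GET subset {subset.id}: shared regions {subset.shared_regions}, "
          f"{len(subset.genes)} genes pooled")
print("a GET subset pairs a transcriptomic bicluster with a GE set through "
      "the brain regions where both are over-expressed; the gene sets "
      "themselves need not overlap.")
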