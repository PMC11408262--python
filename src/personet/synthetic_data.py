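"""Synthetic multi-omic inputs with the statistical structure the pipeline assumes.

No public dataset accompanies the analysis this package implements (the
cohort data are access-restricted), so every pipeline input is emulated:

* a subjects x genes log2 expression matrix with three personality-profile
  groups carrying an ordered mean-expression effect
  (creative > organized > unregulated) on a responsive gene subset, plus
  planted subject x gene biclusters (disjoint gene blocks, overlapping
  subject sets);
* a genes x brain-regions atlas with configurable per-set region enrichment;
* named genomic-environmental (GE) gene sets;
* typed interaction tables (ppi / tf_gene / mirna_gene) containing a planted
  control hub of 3 miRNAs + 3 protein-coding genes whose targets populate
  all seven non-empty regulator signatures, miRNA clusters on each hub
  protein, PPI partners, two seed sets wired to all six hub genes, and a
  personality-lncRNA extension layer;
* annotation tables (biotypes, reviewed and high-throughput LLPS lists,
  personality and switch gene lists).

Default sizes and counts follow the replication conditions of the study the
pipeline reproduces (459 subjects split 125/241/93, 34,602 genes, k = 7
biclusters, module sizes 122/80/67/8/2413/577/708, ...).  All generators are
pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._util import ConfigError
from .netbuild import InteractionTable

PROFILES = ("creative", "organized", "unregulated")

#: canonical regulator-signature module sizes used by the replication profile
PAPER_SIGNATURE_COUNTS = {
    "M1": 122, "M2": 80, "M3": 67, "M4": 8,
    "M5": 2413, "M6": 577, "M7": 708,
}


@dataclass
class SynthConfig:
    """All knobs of the synthetic cohort, atlas, and interaction universe.

    Defaults describe the replication-scale study conditions; tests and the
    small pipeline profile override sizes downwards explicitly.
    """

    n_subjects: int = 459
    profile_sizes: dict = field(default_factory=lambda: {
        "creative": 125, "organized": 241, "unregulated": 93})
    n_genes: int = 34602
    n_responsive: int = 1500
    n_biclusters: int = 7
    bicluster_genes: int = 150
    bicluster_subjects: int = 150
    bicluster_effect: float = 1.0      # log2-units shift inside a planted block
    profile_effect: dict = field(default_factory=lambda: {
        "creative": 0.6, "organized": 0.3, "unregulated": 0.0})
    noise_sd: float = 0.5              # log2-units residual noise
    baseline_mean: float = 7.0         # typical log2 intensity level
    baseline_sd: float = 1.0
    # --- atlas ---
    n_regions: int = 30
    region_enrichment: dict = field(default_factory=dict)  # set id -> [regions]
    region_effect: float = 2.0
    # --- gene sets ---
    n_personality_genes: int = 972
    # --- interactions ---
    hub_mirnas: tuple = ("mir-A", "mir-B", "mir-C")
    hub_proteins: tuple = ("prot-A", "prot-B", "prot-C")
    signature_counts: dict = field(
        default_factory=lambda: dict(PAPER_SIGNATURE_COUNTS))
    n_pseudogenes: int = 38            # planted inside the M5 signature block
    n_other_ncrna: int = 35            # planted inside the M5 signature block
    protein_mirna_clusters: tuple = (65, 64, 69)
    n_ppi_partners: int = 17
    seed_set_sizes: tuple = (11, 13)
    n_personality_in_network: int = 129
    n_switch_genes: int = 6
    # --- lncRNA extension ---
    n_personality_lncrnas: int = 20
    n_lnc_interactions: int = 102
    n_ext_mirnas: int = 173
    n_ext_other_ncrna: int = 13
    # --- annotations ---
    llps_fraction: float = 0.157
    llps_reviewed_fraction: float = 72 / 61035
    rng_seed: int = 0

    def validate(self) -> None:
        if sum(self.profile_sizes.values()) != self.n_subjects:
            raise ConfigError(
                f"profile_sizes sums to {sum(self.profile_sizes.values())}, "
                f"not n_subjects={self.n_subjects}")
        if self.n_biclusters < 1:
            raise ConfigError("n_biclusters must be >= 1")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if not 0 <= self.llps_fraction <= 1:
            raise ConfigError("llps_fraction must lie in [0, 1]")
        if self.n_responsive > self.n_genes:
            raise ConfigError("n_responsive exceeds n_genes")
        if self.n_biclusters * self.bicluster_genes > self.n_responsive:
            raise ConfigError(
                "bicluster gene blocks exceed the responsive gene pool "
                f"({self.n_biclusters} x {self.bicluster_genes} > {self.n_responsive})")
        if self.bicluster_subjects > self.n_subjects:
            raise ConfigError("bicluster_subjects exceeds n_subjects")
        m5 = self.signature_counts.get("M5", 0)
        if self.n_pseudogenes + self.n_other_ncrna > m5:
            raise ConfigError(
                "n_pseudogenes + n_other_ncrna exceed the M5 signature count")
        hub = set(self.hub_mirnas) | set(self.hub_proteins)
        if len(hub) != len(self.hub_mirnas) + len(self.hub_proteins):
            raise ConfigError("hub identifiers must be distinct")
        if self.n_lnc_interactions < self.n_personality_lncrnas:
            raise ConfigError(
                "n_lnc_interactions must be >= n_personality_lncrnas "
                "(every lncRNA carries at least one interaction)")
        if self.n_lnc_interactions > self.n_ext_mirnas + self.n_ext_other_ncrna:
            raise ConfigError(
                "n_lnc_interactions exceeds the number of extension genes")

    def to_dict(self) -> dict:
        return asdict(self)


def gene_names(cfg: SynthConfig) -> list[str]:
    return [f"G{i:06d}" for i in range(1, cfg.n_genes + 1)]


def subject_names(cfg: SynthConfig) -> list[str]:
    return [f"S{i:04d}" for i in range(1, cfg.n_subjects + 1)]


def region_names(cfg: SynthConfig) -> list[str]:
    return [f"R{i:02d}" for i in range(1, cfg.n_regions + 1)]


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def gen_expression(cfg: SynthConfig):
    """Labeled expression matrix with planted profile effect and biclusters.

    Returns ``(matrix, labels, truth)``: a subjects x genes DataFrame of
    log2 intensities, a subject -> profile map, and the planted truth
    (responsive genes, per-bicluster gene blocks and subject sets).

    The responsive genes (the first ``n_responsive``) receive the ordered
    per-profile mean shift; the first ``n_biclusters * bicluster_genes`` of
    them are additionally organized in disjoint gene blocks that are shifted
    by ``bicluster_effect`` for a random (possibly overlapping) subject
    subset per block.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    genes = gene_names(cfg)
    subjects = subject_names(cfg)
    labels: dict[str, str] = {}
    i = 0
    for profile, size in cfg.profile_sizes.items():
        for _ in range(size):
            labels[subjects[i]] = profile
            i += 1
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    values = baseline + rng.normal(0.0, cfg.noise_sd,
                                   size=(cfg.n_subjects, cfg.n_genes))
    responsive = genes[:cfg.n_responsive]
    shift = np.array([cfg.profile_effect.get(labels[s], 0.0) for s in subjects])
    values[:, :cfg.n_responsive] += shift[:, None]
    truth = {"responsive_genes": responsive, "biclusters": {}}
    for b in range(cfg.n_biclusters):
        g0 = b * cfg.bicluster_genes
        block = list(range(g0, g0 + cfg.bicluster_genes))
        members = np.sort(rng.choice(cfg.n_subjects, size=cfg.bicluster_subjects,
                                     replace=False))
        values[np.ix_(members, block)] += cfg.bicluster_effect
        truth["biclusters"][f"T{b + 1}"] = {
            "genes": [genes[j] for j in block],
            "subjects": [subjects[s] for s in members],
        }
    matrix = pd.DataFrame(values, index=subjects, columns=genes)
    return matrix, labels, truth


# ---------------------------------------------------------------------------
# gene sets and atlas
# ---------------------------------------------------------------------------

def gen_gene_sets(cfg: SynthConfig) -> dict[str, list[str]]:
    """Genomic-environmental (GE) personality gene sets.

    The personality gene pool (PG...) is disjoint from the expression gene
    namespace, mirroring the absence of direct overlap between variably
    transcribed genes and the known personality-associated genes.  The pool
    is split across the three core networks and their interaction sets.
    """
    cfg.validate()
    pool = [f"PG{i:05d}" for i in range(1, cfg.n_personality_genes + 1)]
    names = ["SA", "SC", "ER", "SASC", "SAER", "SASCER"]
    bounds = np.linspace(0, len(pool), len(names) + 1).astype(int)
    return {name: pool[bounds[i]:bounds[i + 1]] for i, name in enumerate(names)}


def gen_atlas(cfg: SynthConfig, gene_sets: dict[str, list[str]],
              genes: list[str] | None = None) -> pd.DataFrame:
    """Genes x regions non-negative expression summary with planted enrichment.

    The atlas universe is ``genes`` (defaulting to the expression gene
    namespace) plus every gene named in ``gene_sets``, in input order.  For
    each (set, regions) pair in ``cfg.region_enrichment`` the set's genes
    get an elevated mean in those regions.
    """
    cfg.validate()
    if genes is None:
        genes = gene_names(cfg)
    universe = list(dict.fromkeys(
        list(genes) + [g for gs in gene_sets.values() for g in gs]))
    regions = region_names(cfg)
    rng = np.random.default_rng(cfg.rng_seed + 1)
    values = rng.gamma(shape=4.0, scale=1.0, size=(len(universe), len(regions)))
    atlas = pd.DataFrame(values, index=universe, columns=regions)
    index = {g: i for i, g in enumerate(universe)}
    for set_id, enriched_regions in cfg.region_enrichment.items():
        if set_id not in gene_sets:
            raise ConfigError(
                f"region_enrichment references unknown gene set {set_id!r}")
        unknown = [g for g in gene_sets[set_id] if g not in index]
        if unknown:
            raise ConfigError(
                f"region_enrichment set {set_id!r} has genes absent from the "
                f"atlas: {unknown[:5]}")
        bad_regions = [r for r in enriched_regions if r not in regions]
        if bad_regions:
            raise ConfigError(
                f"region_enrichment set {set_id!r} names unknown regions: "
                f"{bad_regions}")
        rows = [index[g] for g in gene_sets[set_id]]
        cols = [regions.index(r) for r in enriched_regions]
        atlas.iloc[rows, cols] += cfg.region_effect
    return atlas


# ---------------------------------------------------------------------------
# interactions
# ---------------------------------------------------------------------------

#: signature module -> which of the three (ordered) hub miRNAs regulate it
SIGNATURE_PATTERN = {
    "M1": (0, 1), "M2": (1, 2), "M3": (0, 2), "M4": (0, 1, 2),
    "M5": (1,), "M6": (2,), "M7": (0,),
}


def gen_interactions(cfg: SynthConfig, seed_sets: dict[str, list[str]] | None = None,
                     personality_genes: list[str] | None = None):
    """Typed interaction edges with a planted control hub, plus planted truth.

    Returns ``(interactions, lnc_edges, truth)``:

    * ``interactions`` — an :class:`~personet.netbuild.InteractionTable`
      whose three layers contain the hub-internal wiring, the signature
      target genes of the hub miRNAs, the miRNA clusters of the hub
      proteins, PPI partners, and two seed sets each wired to all six hub
      genes;
    * ``lnc_edges`` — the personality-lncRNA extension layer as a separate
      edge table;
    * ``truth`` — planted module memberships, the hub, seed sets,
      personality/switch overlaps and the expected composition totals.

    If ``personality_genes`` is given, ``cfg.n_personality_in_network`` of
    the target genes take identifiers from that list (planting the overlap
    between the network and the known personality genes);
    ``cfg.n_switch_genes`` of those are designated switch genes, all but one
    inside the M5 module.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed + 2)
    edges: list[tuple[str, str, str]] = []
    node_types: dict[str, str] = {}
    mirnas = list(cfg.hub_mirnas)
    proteins = list(cfg.hub_proteins)
    hub = mirnas + proteins
    for m in mirnas:
        node_types[m] = "mirna"
    for p in proteins:
        node_types[p] = "protein_coding"
    # hub-internal wiring: PPI chain among proteins, each miRNA targets one protein
    edges.append((proteins[0], proteins[1], "ppi"))
    edges.append((proteins[1], proteins[2], "ppi"))
    for m, p in zip(mirnas, proteins):
        edges.append((m, p, "mirna_gene"))

    # signature target genes
    modules: dict[str, list[str]] = {}
    for mid in sorted(cfg.signature_counts):
        count = cfg.signature_counts[mid]
        regulators = [mirnas[i] for i in SIGNATURE_PATTERN[mid]]
        members = []
        for j in range(count):
            gene = f"TG-{mid}-{j + 1:05d}"
            if mid == "M5" and j < cfg.n_pseudogenes:
                node_types[gene] = "pseudogene"
            elif mid == "M5" and j < cfg.n_pseudogenes + cfg.n_other_ncrna:
                node_types[gene] = "other_ncrna"
            else:
                node_types[gene] = "protein_coding"
            for m in regulators:
                edges.append((m, gene, "mirna_gene"))
            members.append(gene)
        modules[mid] = members

    # plant the personality-gene overlap by renaming target genes
    personality_in_network: list[str] = []
    switch_genes: list[str] = []
    if personality_genes is not None:
        allocation = _personality_allocation(cfg, modules)
        renames: dict[str, str] = {}
        supply = iter(personality_genes)
        for mid, take in allocation.items():
            if take <= 0:
                continue
            chosen = [g for g in modules[mid][-take:]
                      if node_types[g] == "protein_coding"]
            for g in chosen:
                new = next(supply)
                renames[g] = new
                personality_in_network.append(new)
        edges = [(renames.get(s, s), renames.get(t, t), l) for s, t, l in edges]
        for old, new in renames.items():
            node_types[new] = node_types.pop(old)
        modules = {mid: [renames.get(g, g) for g in members]
                   for mid, members in modules.items()}
        # switch genes: all but one in M5, the remaining one in M1
        m5_personality = [g for g in modules["M5"] if g in set(personality_in_network)]
        m1_personality = [g for g in modules["M1"] if g in set(personality_in_network)]
        n_in_m5 = min(cfg.n_switch_genes - 1, len(m5_personality))
        switch_genes = m5_personality[:n_in_m5] + m1_personality[:1]

    # miRNA clusters attached to each hub protein
    for i, (p, size) in enumerate(zip(proteins, cfg.protein_mirna_clusters)):
        cluster = []
        for j in range(size):
            m = f"PM{i + 1}-{j + 1:04d}"
            node_types[m] = "mirna"
            edges.append((m, p, "mirna_gene"))
            cluster.append(m)
        modules[f"M{8 + i}"] = cluster

    # protein-coding PPI partners of the hub proteins
    ppi_partners = []
    for j in range(cfg.n_ppi_partners):
        g = f"PPI-{j + 1:03d}"
        node_types[g] = "protein_coding"
        edges.append((g, proteins[j % len(proteins)], "ppi"))
        ppi_partners.append(g)

    # two seed sets, each wired to all six hub genes
    if seed_sets is None:
        seed_sets = {
            "A": [f"SEEDA-{j + 1:02d}" for j in range(cfg.seed_set_sizes[0])],
            "B": [f"SEEDB-{j + 1:02d}" for j in range(cfg.seed_set_sizes[1])],
        }
    for name, seeds in seed_sets.items():
        seeds = list(seeds)
        if len(seeds) < len(hub):
            raise ConfigError(
                f"seed set {name!r} has fewer genes ({len(seeds)}) than hub "
                f"members ({len(hub)}); cannot wire it to every hub gene")
        # seed-to-hub wiring rides the tf_gene layer: the hub expansion step
        # queries only the miRNA-gene and PPI layers, so GET seed genes are
        # regulators of the hub, not direct interactors swept into it
        for j, s in enumerate(seeds):
            node_types.setdefault(s, "protein_coding")
            edges.append((s, hub[j % len(hub)], "tf_gene"))

    # personality-lncRNA extension layer (kept as a separate table)
    lnc_rows: list[tuple[str, str, str]] = []
    lncs = [f"LNC-{j + 1:02d}" for j in range(cfg.n_personality_lncrnas)]
    ext_genes = ([f"EXTM-{j + 1:04d}" for j in range(cfg.n_ext_mirnas)]
                 + [f"EXTO-{j + 1:03d}" for j in range(cfg.n_ext_other_ncrna)])
    lnc_types: dict[str, str] = {l: "lncrna" for l in lncs}
    for j, g in enumerate(ext_genes):
        lnc_types[g] = "mirna" if j < cfg.n_ext_mirnas else "other_ncrna"
    # each lncRNA carries a share of the interactions, targets cycle over a
    # covered prefix of the extension genes
    n_cov = min(cfg.n_lnc_interactions, len(ext_genes))
    covered = ext_genes[:n_cov]
    for e in range(cfg.n_lnc_interactions):
        lnc = lncs[e % len(lncs)]
        lnc_rows.append((lnc, covered[e % n_cov], "mirna_gene"))
    # chain uncovered extension genes onto covered ones so that the whole
    # extension layer is reachable from the personality lncRNAs
    for i, g in enumerate(ext_genes[n_cov:]):
        lnc_rows.append((g, covered[i % n_cov], "mirna_gene"))

    interactions = InteractionTable.from_edges(
        pd.DataFrame(edges, columns=["source", "target", "layer"]),
        node_types=node_types)
    lnc_edges = pd.DataFrame(lnc_rows, columns=["source", "target", "layer"])

    n_signature = sum(cfg.signature_counts.values())
    composition = {
        "protein_coding": (n_signature - cfg.n_pseudogenes - cfg.n_other_ncrna
                           + cfg.n_ppi_partners),
        "mirna": sum(cfg.protein_mirna_clusters),
        "pseudogene": cfg.n_pseudogenes,
        "other_ncrna": cfg.n_other_ncrna,
    }
    truth = {
        "hub": hub,
        "hub_mirnas": mirnas,
        "hub_proteins": proteins,
        "modules": modules,
        "ppi_partners": ppi_partners,
        "seed_sets": {k: list(v) for k, v in seed_sets.items()},
        "composition": composition,
        "n_direct_interactors": sum(composition.values()),
        "extension": {
            "lncrnas": lncs,
            "new_genes": ext_genes,
            "node_types": lnc_types,
            "n_interactions": cfg.n_lnc_interactions,
            "n_extended": sum(composition.values()) + len(ext_genes),
        },
        "personality_in_network": personality_in_network,
        "switch_genes": switch_genes,
    }
    return interactions, lnc_edges, truth


def _personality_allocation(cfg: SynthConfig,
                            modules: dict[str, list[str]]) -> dict[str, int]:
    """Spread the planted personality-gene overlap across modules.

    M5 gets the lion's share (it is by far the largest module and must host
    the switch genes); M1 always receives some (one switch gene sits there).
    """
    total = cfg.n_personality_in_network
    weights = {"M5": 0.47, "M7": 0.23, "M6": 0.15, "M1": 0.08, "M2": 0.04,
               "M3": 0.03}
    alloc: dict[str, int] = {}
    assigned = 0
    for mid, w in weights.items():
        take = min(int(round(total * w)), len(modules.get(mid, [])))
        alloc[mid] = take
        assigned += take
    # top up / trim on M5 to hit the exact total
    alloc["M5"] = max(0, alloc.get("M5", 0) + (total - assigned))
    return alloc


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def gen_annotations(cfg: SynthConfig, genes,
                    node_types: dict[str, str] | None = None,
                    exact_llps: list[tuple[list[str], int]] | None = None,
                    enriched_genes=None,
                    enriched_rate: float = 0.39) -> pd.DataFrame:
    """Biotype and LLPS annotations for a gene universe.

    Biotypes come from ``node_types`` where known; the remainder are drawn
    from a realistic genome-wide mixture (about a third protein-coding, the
    rest regulatory RNAs and pseudogenes).  High-throughput LLPS membership
    is Bernoulli(``llps_fraction``) in the background, elevated to
    ``enriched_rate`` inside ``enriched_genes``; ``exact_llps`` plants an
    exact LLPS count inside given gene lists (overriding the draw there).
    Reviewed LLPS membership uses ``llps_reviewed_fraction``.
    """
    cfg.validate()
    genes = list(genes)
    node_types = dict(node_types or {})
    rng = np.random.default_rng(cfg.rng_seed + 3)
    mixture = (["protein_coding"] * 33 + ["lncrna"] * 28 + ["other_ncrna"] * 24
               + ["pseudogene"] * 12 + ["mirna"] * 3)
    draw = rng.choice(mixture, size=len(genes))
    biotype = [node_types.get(g, draw[i]) for i, g in enumerate(genes)]
    llps_ht = rng.random(len(genes)) < cfg.llps_fraction
    llps_rev = rng.random(len(genes)) < cfg.llps_reviewed_fraction
    index = {g: i for i, g in enumerate(genes)}
    if enriched_genes is not None:
        for g in enriched_genes:
            if g in index:
                llps_ht[index[g]] = rng.random() < enriched_rate
    if exact_llps:
        for gene_list, count in exact_llps:
            rows = [index[g] for g in gene_list if g in index]
            if count > len(rows):
                raise ConfigError(
                    f"exact_llps count {count} exceeds list size {len(rows)}")
            llps_ht[rows] = False
            chosen = rng.choice(rows, size=count, replace=False)
            llps_ht[chosen] = True
    return pd.DataFrame({
        "gene": genes,
        "biotype": biotype,
        "llps_reviewed": llps_rev,
        "llps_ht": llps_ht,
    })


# ---------------------------------------------------------------------------
# replication-profile minimum networks (deterministic, no RNG)
# ---------------------------------------------------------------------------

def gen_replication_networks(cfg: SynthConfig):
    """Two minimum networks shaped like the published extrinsic/intrinsic pair.

    Synthetic stand-ins for the two curated GET minimum networks: network A
    has 45 nodes (11 seeds), network B has 43 nodes (13 seeds), and they
    share exactly the six hub genes (3 miRNAs + 3 protein-coding).  Each
    network is a seed-connector chain, so every connector is essential and
    the networks are fixed points of minimum-network pruning.

    Returns ``(edges_a, seeds_a, edges_b, seeds_b, node_types)``.
    """
    hub = list(cfg.hub_mirnas) + list(cfg.hub_proteins)
    node_types = {m: "mirna" for m in cfg.hub_mirnas}
    node_types.update({p: "protein_coding" for p in cfg.hub_proteins})

    def build_chain(prefix, n_seeds, gap_sizes, connector_biotypes):
        seeds = [f"{prefix}-seed-{i + 1:02d}" for i in range(n_seeds)]
        for s in seeds:
            node_types[s] = "protein_coding"
        connectors = iter(connector_biotypes)
        chain = []
        for i, s in enumerate(seeds):
            chain.append(s)
            if i < len(gap_sizes):
                for _ in range(gap_sizes[i]):
                    name, biotype = next(connectors)
                    node_types.setdefault(name, biotype)
                    chain.append(name)
        rows = [(chain[i], chain[i + 1], "ppi") for i in range(len(chain) - 1)]
        return pd.DataFrame(rows, columns=["source", "target", "layer"]), seeds

    hub_block = [(h, node_types[h]) for h in hub]
    conn_a = (hub_block
              + [(f"A-tf-{i + 1:02d}", "tf") for i in range(20)]
              + [(f"A-mir-{i + 1:02d}", "mirna") for i in range(7)]
              + [(f"A-pc-{i + 1:02d}", "protein_coding") for i in range(1)])
    gaps_a = [6, 4, 4, 3, 3, 3, 3, 3, 3, 2]          # 34 connectors, 45 nodes
    edges_a, seeds_a = build_chain("A", 11, gaps_a, conn_a)

    conn_b = (hub_block
              + [(f"B-tf-{i + 1:02d}", "tf") for i in range(18)]
              + [(f"B-mir-{i + 1:02d}", "mirna") for i in range(6)])
    gaps_b = [6, 3, 3, 3, 2, 2, 2, 2, 2, 2, 2, 1]    # 30 connectors, 43 nodes
    edges_b, seeds_b = build_chain("B", 13, gaps_b, conn_b)
    return edges_a, seeds_a, edges_b, seeds_b, node_types
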