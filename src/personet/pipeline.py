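"""Seven-stage pipeline orchestration and fixture profiles.

Stages: preprocess -> bicluster -> colocalize -> netbuild -> tcmin ->
enrich, driven by a single :class:`PipelineConfig` and one root seed from
which every stage derives its own named substream.  Each stage writes its
artifact under the output directory and contributes to a JSON + Markdown
report that embeds full provenance (config, seed, package version).

Two fixture profiles are provided:

* ``small`` — a minutes-scale cohort (60 subjects, 400 genes) with planted
  biclusters, region enrichments and a planted control hub, suitable for an
  end-to-end run;
* ``paper_scale`` — the replication-scale interaction universe (module
  sizes 122/80/67/8/2413/577/708, 198 hub-protein miRNAs, 38 pseudogenes,
  35 other ncRNAs, the 459-subject cohort labels).  The transcriptomic
  matrix itself is generated in memory by the API when needed rather than
  written to disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from ._util import ConfigError, substream_seed
from . import bicluster as bc
from . import colocalize as cl
from . import enrich as en
from . import io
from . import netbuild as nb
from . import preprocess as pp
from . import synthetic_data as sd
from . import tcmin as tc


@dataclass
class PipelineConfig:
    """Paths to all inputs plus the tunable analysis parameters."""

    expression: str
    labels: str
    atlas: str
    ge_sets: str
    edges: str
    annotations: str
    rng_seed: int
    lnc_edges: str | None = None
    personality_genes: str | None = None
    switch_genes: str | None = None
    personality_lncrnas: str | None = None
    n_top_genes: int = 1500
    k: int = 7
    membership_threshold: float | None = None
    n_perm: int = 300
    alpha: float = 0.05
    correction: str = "bonferroni"
    layers: tuple = nb.LAYERS
    n_boot: int = 50
    genome_size: int = 61035  # background universe for LLPS enrichment

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "rng_seed" not in raw:
            raise ConfigError("pipeline config must set rng_seed")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("expression", "labels", "atlas", "ge_sets", "edges",
                     "annotations"):
            path = getattr(self, name)
            if not Path(path).exists():
                raise ConfigError(f"input path for {name!r} does not exist: {path}")
        if self.n_top_genes <= 0:
            raise ConfigError("n_top_genes must be positive")
        if self.k < 2:
            raise ConfigError("k must be >= 2")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["layers"] = list(d["layers"])
        return d


def _read_lines(path) -> list[str]:
    return [l.strip() for l in Path(path).read_text().splitlines() if l.strip()]


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute all stages, writing artifacts and returning the report dict."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.rng_seed
    report: dict = {
        "provenance": {
            "package_version": __version__,
            "rng_seed": seed,
            "config": config.to_dict(),
            "config_hash": hashlib.sha256(
                json.dumps(config.to_dict(), sort_keys=True).encode()
            ).hexdigest()[:16],
        }
    }

    # ---- stage 1: preprocess -------------------------------------------
    matrix = io.read_expression(config.expression)
    labels = io.read_labels(config.labels)
    normalized = pp.quantile_normalize(matrix)
    n_top = min(config.n_top_genes, normalized.shape[1])
    top_genes = pp.select_variable_genes(normalized, n_top)
    selected = normalized.loc[:, top_genes]
    boot = pp.bootstrap_profile_anova(
        selected, labels, n_boot=config.n_boot,
        seed=substream_seed(seed, "bootstrap"))
    selected.to_csv(out / "selected_expression.tsv", sep="\t")
    report["preprocess"] = {
        "n_subjects": int(matrix.shape[0]),
        "n_genes": int(matrix.shape[1]),
        "n_selected": len(top_genes),
        "profile_sizes": pd.Series(labels).value_counts().to_dict(),
        "bootstrap_anova": boot.to_dict(),
    }

    # ---- stage 2: bicluster --------------------------------------------
    fp = bc.fnmf(bc.center_expression(selected), k=config.k,
                 seed=substream_seed(seed, "fnmf"))
    biclusters = bc.extract_biclusters(fp, config.membership_threshold)
    overlap = bc.bicluster_overlap(biclusters)
    io.write_gmt(out / "biclusters.gmt",
                 {b.id: sorted(b.genes) for b in biclusters})
    report["bicluster"] = {
        "k": config.k,
        "sizes": {b.id: {"subjects": len(b.subjects), "genes": len(b.genes)}
                  for b in biclusters},
        "n_shared_genes": overlap["n_shared"],
        "final_objective": fp.objective_trace[-1],
    }

    # ---- stage 3: colocalize -------------------------------------------
    atlas = io.read_atlas(config.atlas)
    ge_sets = io.read_gmt(config.ge_sets)
    t_sets = {b.id: sorted(b.genes) for b in biclusters if b.genes}
    coloc_seed = substream_seed(seed, "colocalize")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t_links = {tid: cl.region_significance(
            genes, atlas, n_perm=config.n_perm, seed=coloc_seed,
            alpha=config.alpha, correction=config.correction, set_id=tid)
            for tid, genes in t_sets.items()}
        ge_links = {gid: cl.region_significance(
            genes, atlas, n_perm=config.n_perm, seed=coloc_seed,
            alpha=config.alpha, correction=config.correction, set_id=gid)
            for gid, genes in ge_sets.items()}
    gets = cl.find_get_subsets(t_links, ge_links, t_sets, ge_sets)
    io.write_json(out / "get_subsets.json", [g.to_dict() for g in gets])
    report["colocalize"] = {
        "n_get_subsets": len(gets),
        "subsets": {g.id: {"shared_regions": g.shared_regions,
                           "n_genes": len(g.genes)} for g in gets},
    }

    # ---- stage 4: netbuild ---------------------------------------------
    interactions = nb.InteractionTable.from_edges(io.read_edges(config.edges))
    annotations = io.read_annotations(config.annotations)
    interactions.node_types.update(
        dict(zip(annotations["gene"], annotations["biotype"])))
    minimums = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for g in gets:
            net = nb.build_network(g.genes, interactions, layers=config.layers)
            minimums[g.id] = nb.minimum_network(net)
    report["netbuild"] = {
        gid: {"n_nodes": net.n_nodes,
              "n_seeds": len(net.seeds & net.nodes),
              "n_connectors": len(net.connectors)}
        for gid, net in minimums.items()
    }
    hub_nodes: list[str] = []
    if len(minimums) >= 2:
        ids = sorted(minimums)
        merged = nb.merge_networks([minimums[i] for i in ids])
        hub = nb.shared_hub(minimums[ids[0]], minimums[ids[1]])
        # the control hub consists of the shared *connectors*: nodes that
        # network analysis introduced into both minimum networks (shared
        # seed genes merely reflect overlapping input gene sets)
        shared_connectors = (minimums[ids[0]].connectors
                             & minimums[ids[1]].connectors)
        hub_nodes = sorted(shared_connectors)
        merged.node_table().to_csv(out / "merged_network_nodes.tsv",
                                   sep="\t", index=False)
        report["netbuild"]["merged"] = {
            "n_nodes": merged.n_nodes,
            "shared_by_biotype": hub,
            "shared_connectors": hub_nodes,
            "hub_size": len(hub_nodes),
        }

    # ---- stage 5: tcmin -------------------------------------------------
    hub_mirnas = [n for n in hub_nodes
                  if interactions.node_types.get(n) == "mirna"]
    hub_proteins = [n for n in hub_nodes
                    if interactions.node_types.get(n) in ("protein_coding", "tf")]
    if len(hub_mirnas) == 3 and len(hub_proteins) == 3:
        hub6 = hub_mirnas + hub_proteins
        network = tc.expand_hub(hub6, interactions)
        modules, unassigned = tc.regulator_signature_modules(network)
        metrics = tc.node_metrics(network.graph)
        communities, q = tc.community_detection(
            network.graph, seed=substream_seed(seed, "community"))
        metrics.to_csv(out / "tcmin_metrics.tsv", sep="\t", index=False)
        report["tcmin"] = {
            "hub": hub6,
            "n_genes": network.n_genes,
            "composition": network.biotype_composition(),
            "modules": {m.module_id: len(m.members) for m in modules},
            "n_unassigned": len(unassigned),
            "modularity_Q": q,
            "n_communities": len(set(communities.values())),
        }
        if config.lnc_edges and config.personality_lncrnas:
            lnc_edges = io.read_edges(config.lnc_edges)
            lncs = _read_lines(config.personality_lncrnas)
            lnc_types = dict(zip(annotations["gene"], annotations["biotype"]))
            extended, ext_summary = tc.extend_with_lncrna(
                network, lnc_edges, lncs, node_types=lnc_types)
            report["tcmin"]["extension"] = dict(
                ext_summary, composition=extended.biotype_composition())
            network_for_enrich = extended
        else:
            network_for_enrich = network

        # ---- stage 6: enrich -------------------------------------------
        llps = set(annotations.loc[annotations["llps_ht"], "gene"])
        member = set(network_for_enrich.non_hub_nodes)
        result = en.enrichment_from_counts(
            member_count=len(member & llps), member_total=len(member),
            background_count=len(llps),
            background_total=max(config.genome_size, len(annotations)))
        module_map = {m.module_id: m.members for m in modules}
        fractions = en.module_llps_fractions(module_map, llps)
        report["enrich"] = {
            "llps": result.to_dict(),
            "module_llps": fractions,
        }
        if config.personality_genes:
            ref = _read_lines(config.personality_genes)
            ov = en.gene_list_overlap(member, ref, modules)
            report["enrich"]["personality_overlap"] = {
                "count": ov["count"],
                "by_module": {k: len(v) for k, v in ov["by_module"].items()},
            }
        if config.switch_genes:
            sw = _read_lines(config.switch_genes)
            ov = en.gene_list_overlap(member, sw, modules)
            report["enrich"]["switch_overlap"] = {
                "count": ov["count"],
                "by_module": {k: len(v) for k, v in ov["by_module"].items()},
            }
    else:
        report["tcmin"] = {
            "skipped": f"hub is not 3 miRNAs + 3 proteins "
                       f"({len(hub_mirnas)} + {len(hub_proteins)})"}

    io.write_json(out / "report.json", report)
    _write_markdown_report(out / "report.md", report)
    return report


def _write_markdown_report(path: Path, report: dict) -> None:
    lines = ["# Pipeline report", ""]
    prov = report["provenance"]
    lines += [f"- package version: {prov['package_version']}",
              f"- seed: {prov['rng_seed']}",
              f"- config hash: {prov['config_hash']}", ""]
    for stage in ("preprocess", "bicluster", "colocalize", "netbuild",
                  "tcmin", "enrich"):
        if stage not in report:
            continue
        lines.append(f"## {stage}")
        lines.append("```json")
        lines.append(json.dumps(report[stage], indent=2, sort_keys=True, default=str))
        lines.append("```")
        lines.append("")
    path.write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# fixture profiles
# ---------------------------------------------------------------------------

def small_profile_config(seed: int = 0) -> sd.SynthConfig:
    """A minutes-scale synthetic cohort for end-to-end runs."""
    return sd.SynthConfig(
        n_subjects=60,
        profile_sizes={"creative": 16, "organized": 31, "unregulated": 13},
        n_genes=400, n_responsive=160, n_biclusters=7,
        bicluster_genes=20, bicluster_subjects=20,
        bicluster_effect=1.2, noise_sd=0.5,
        n_regions=12,
        region_enrichment={
            "T1": ["R02", "R03"], "SAER": ["R03", "R04"],
            "T2": ["R06", "R07"], "SASC": ["R07", "R08"],
        },
        # strong planted enrichment: 10-gene sets against a gamma(4,1) atlas
        # need a mean shift well above the null-mean spread to stay
        # family-wise significant across 12 regions
        region_effect=3.5,
        n_personality_genes=60,
        signature_counts={"M1": 12, "M2": 8, "M3": 7, "M4": 8,
                          "M5": 60, "M6": 20, "M7": 25},
        n_pseudogenes=4, n_other_ncrna=3,
        protein_mirna_clusters=(5, 4, 6), n_ppi_partners=5,
        n_personality_in_network=12, n_switch_genes=6,
        n_personality_lncrnas=5, n_lnc_interactions=12,
        n_ext_mirnas=10, n_ext_other_ncrna=3,
        rng_seed=seed)


def paper_scale_config(seed: int = 0) -> sd.SynthConfig:
    """The replication-scale study conditions (the SynthConfig defaults)."""
    return sd.SynthConfig(rng_seed=seed)


def make_fixtures(profile: str, out_dir: str | Path, seed: int = 0) -> dict:
    """Write a synthetic input bundle plus a ready-to-run pipeline config.

    ``small`` writes every input needed by :func:`run_pipeline`;
    ``paper_scale`` writes the interaction-universe fixtures and the cohort
    labels (its expression matrix is meant to be generated in memory by the
    API).  Returns a dict of written paths plus the planted truth.
    """
    if profile not in ("small", "paper_scale"):
        raise ConfigError(f"unknown fixture profile {profile!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = (small_profile_config(seed) if profile == "small"
           else paper_scale_config(seed))
    paths: dict[str, str] = {}
    ge_sets = sd.gen_gene_sets(cfg)
    io.write_gmt(out / "ge_sets.gmt", ge_sets)
    paths["ge_sets"] = str(out / "ge_sets.gmt")

    truth: dict = {}
    if profile == "small":
        matrix, labels, expr_truth = sd.gen_expression(cfg)
        truth["expression"] = expr_truth
        io.write_expression(out / "expression.tsv", matrix)
        io.write_labels(out / "labels.tsv", labels)
        paths["expression"] = str(out / "expression.tsv")
        paths["labels"] = str(out / "labels.tsv")
        atlas_sets = dict(ge_sets)
        atlas_sets.update({tid: t["genes"]
                           for tid, t in expr_truth["biclusters"].items()})
        atlas = sd.gen_atlas(cfg, atlas_sets, genes=list(matrix.columns))
        io.write_atlas(out / "atlas.tsv", atlas)
        paths["atlas"] = str(out / "atlas.tsv")
        # wire the planted GET payloads (bicluster genes + GE partner set)
        # to the hub so the network stages can rediscover it
        seed_sets = {
            "T1-SAER": expr_truth["biclusters"]["T1"]["genes"] + ge_sets["SAER"],
            "T2-SASC": expr_truth["biclusters"]["T2"]["genes"] + ge_sets["SASC"],
        }
    else:
        _, labels, _ = _labels_only(cfg)
        io.write_labels(out / "labels.tsv", labels)
        paths["labels"] = str(out / "labels.tsv")
        seed_sets = None

    personality_pool = [g for gs in ge_sets.values() for g in gs]
    interactions, lnc_edges, net_truth = sd.gen_interactions(
        cfg, seed_sets=seed_sets, personality_genes=personality_pool)
    truth["interactions"] = {
        k: v for k, v in net_truth.items() if k != "extension"}
    truth["extension"] = {k: v for k, v in net_truth["extension"].items()
                          if k != "node_types"}
    io.write_edges(out / "edges.tsv", interactions.edges)
    io.write_edges(out / "lnc_edges.tsv", lnc_edges)
    paths["edges"] = str(out / "edges.tsv")
    paths["lnc_edges"] = str(out / "lnc_edges.tsv")

    universe = sorted(interactions.universe
                      | set(net_truth["extension"]["new_genes"]))
    node_types = dict(net_truth["extension"]["node_types"])
    node_types.update(interactions.node_types)
    annotations = sd.gen_annotations(
        cfg, universe, node_types=node_types,
        exact_llps=[(net_truth["modules"]["M4"], 5)])
    io.write_annotations(out / "annotations.tsv", annotations)
    paths["annotations"] = str(out / "annotations.tsv")

    (out / "personality_genes.txt").write_text(
        "\n".join(personality_pool) + "\n")
    paths["personality_genes"] = str(out / "personality_genes.txt")
    (out / "switch_genes.txt").write_text(
        "\n".join(net_truth["switch_genes"]) + "\n")
    paths["switch_genes"] = str(out / "switch_genes.txt")
    (out / "personality_lncrnas.txt").write_text(
        "\n".join(net_truth["extension"]["lncrnas"]) + "\n")
    paths["personality_lncrnas"] = str(out / "personality_lncrnas.txt")

    io.write_json(out / "truth.json", truth)
    paths["truth"] = str(out / "truth.json")

    if profile == "small":
        run_cfg = {
            "expression": paths["expression"],
            "labels": paths["labels"],
            "atlas": paths["atlas"],
            "ge_sets": paths["ge_sets"],
            "edges": paths["edges"],
            "lnc_edges": paths["lnc_edges"],
            "annotations": paths["annotations"],
            "personality_genes": paths["personality_genes"],
            "switch_genes": paths["switch_genes"],
            "personality_lncrnas": paths["personality_lncrnas"],
            "n_top_genes": cfg.n_responsive,
            "k": cfg.n_biclusters,
            "n_perm": 500,
            "n_boot": 30,
            "genome_size": 2000,
            "rng_seed": seed,
        }
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(run_cfg, fh)
        paths["config"] = str(out / "config.yaml")
    return {"paths": paths, "truth": truth, "synth_config": cfg.to_dict()}


def _labels_only(cfg: sd.SynthConfig):
    """Subject labels without materializing the expression matrix."""
    cfg.validate()
    subjects = sd.subject_names(cfg)
    labels = {}
    i = 0
    for profile, size in cfg.profile_sizes.items():
        for _ in range(size):
            labels[subjects[i]] = profile
            i += 1
    return subjects, labels, None
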