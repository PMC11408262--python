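"""Brain-region colocalization of gene sets against an expression atlas.

For a gene set, the score in a brain region is the arithmetic mean of the
set's atlas expression in that region.  Significance of over-expression is
assessed by permutation: random gene sets of identical size are drawn from
the atlas (without replacement within a draw) and the empirical p-value is

    p = (1 + #{null mean >= observed mean}) / (1 + n_perm),

one-sided for over-expression, corrected across regions (Bonferroni by
default, Benjamini-Hochberg available).  A transcriptomic bicluster and a
genomic-environmental gene set that are both significantly over-expressed
in at least one common region form a GET subset: the pairing of their genes
via the shared regions.  The gene sets themselves need not overlap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from ._util import ValidationError


@dataclass
class RegionLink:
    gene_set_id: str
    region: str
    mean_expression: float
    empirical_p: float
    adjusted_p: float
    significant: bool


@dataclass
class GETSubset:
    """A (bicluster, GE-set) pair joined through shared significant regions."""

    id: str
    t_id: str
    ge_id: str
    t_genes: list[str]
    ge_genes: list[str]
    shared_regions: list[str]

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.t_genes) | set(self.ge_genes))

    def to_dict(self) -> dict:
        return {"id": self.id, "t_id": self.t_id, "ge_id": self.ge_id,
                "t_genes": sorted(self.t_genes), "ge_genes": sorted(self.ge_genes),
                "shared_regions": sorted(self.shared_regions)}


def region_scores(gene_set, atlas: pd.DataFrame,
                  set_id: str = "set") -> pd.Series:
    """Per-region mean atlas expression of the genes in the set.

    Genes absent from the atlas are reported with a warning; if none of the
    set's genes are present this is an error.
    """
    genes = list(dict.fromkeys(gene_set))
    present = [g for g in genes if g in atlas.index]
    missing = [g for g in genes if g not in atlas.index]
    if not present:
        raise ValidationError(f"region_scores: no genes of set {set_id!r} in atlas")
    if missing:
        warnings.warn(
            f"region_scores: {len(missing)} gene(s) of set {set_id!r} "
            f"missing from atlas: {missing[:5]}...")
    return atlas.loc[present].mean(axis=0)


def region_significance(gene_set, atlas: pd.DataFrame, n_perm: int = 1000,
                        seed: int = 0, alpha: float = 0.05,
                        correction: str = "bonferroni",
                        set_id: str = "set") -> list[RegionLink]:
    """One-sided permutation test for over-expression per region.

    The null distribution of each region's mean is built by drawing
    ``n_perm`` random gene sets of the same (present-in-atlas) size from the
    whole atlas without replacement.
    """
    if n_perm < 100:
        raise ValidationError("region_significance: n_perm must be >= 100")
    if correction not in ("bonferroni", "bh"):
        raise ValidationError("correction must be 'bonferroni' or 'bh'")
    genes = [g for g in dict.fromkeys(gene_set) if g in atlas.index]
    if len(genes) > len(atlas.index):
        raise ValidationError("gene set larger than atlas")
    observed = region_scores(genes, atlas, set_id=set_id)
    values = np.asarray(atlas, dtype=float)
    n_genes = values.shape[0]
    m = len(genes)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(values.shape[1], dtype=int)
    obs = observed.to_numpy()
    for _ in range(n_perm):
        idx = rng.choice(n_genes, size=m, replace=False)
        null_mean = values[idx].mean(axis=0)
        exceed += null_mean >= obs
    emp_p = (1.0 + exceed) / (1.0 + n_perm)
    if correction == "bonferroni":
        adj = np.minimum(1.0, emp_p * len(emp_p))
    else:
        adj = multipletests(emp_p, method="fdr_bh")[1]
    adj = np.maximum(adj, emp_p)
    return [
        RegionLink(gene_set_id=set_id, region=str(region),
                   mean_expression=float(obs[i]), empirical_p=float(emp_p[i]),
                   adjusted_p=float(adj[i]), significant=bool(adj[i] <= alpha))
        for i, region in enumerate(atlas.columns)
    ]


def significant_regions(links: list[RegionLink]) -> set[str]:
    return {l.region for l in links if l.significant}


def find_get_subsets(t_links: dict[str, list[RegionLink]],
                     ge_links: dict[str, list[RegionLink]],
                     t_sets: dict[str, list[str]],
                     ge_sets: dict[str, list[str]]) -> list[GETSubset]:
    """Intersect significant regions of every (bicluster, GE-set) pair.

    Emits a GET subset for each pair with a non-empty region intersection;
    the gene payload is the union of the pair's genes with provenance
    (t_genes vs ge_genes) retained.
    """
    out = []
    for t_id, tl in t_links.items():
        t_regions = significant_regions(tl)
        for ge_id, gl in ge_links.items():
            shared = t_regions & significant_regions(gl)
            if shared:
                out.append(GETSubset(
                    id=f"{t_id}-{ge_id}", t_id=t_id, ge_id=ge_id,
                    t_genes=list(t_sets[t_id]), ge_genes=list(ge_sets[ge_id]),
                    shared_regions=sorted(shared)))
    return out
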