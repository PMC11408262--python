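"""Annotation overlays and contingency-table enrichment statistics.

The central test is a 2x2 Pearson chi-square (without continuity
correction) for enrichment of an annotation — canonically membership in the
liquid-liquid phase separation (LLPS) RNA lists — in a network gene set
against a background universe, accompanied by a two-sided Fisher exact
test.  Percentages are reported both raw and rounded the way headline
figures are usually printed (integer for large fractions, one decimal
otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import ValidationError


@dataclass
class EnrichmentResult:
    member_count: int
    member_total: int
    background_count: int
    background_total: int
    chi2: float
    p: float
    fisher_p: float

    @property
    def member_fraction(self) -> float:
        return self.member_count / self.member_total

    @property
    def background_fraction(self) -> float:
        return self.background_count / self.background_total

    @property
    def member_percent(self) -> float:
        return 100.0 * self.member_fraction

    @property
    def background_percent(self) -> float:
        return 100.0 * self.background_fraction

    def to_dict(self) -> dict:
        return {
            "member_count": self.member_count,
            "member_total": self.member_total,
            "background_count": self.background_count,
            "background_total": self.background_total,
            "member_percent": self.member_percent,
            "member_percent_rounded": round(self.member_percent),
            "background_percent": self.background_percent,
            "background_percent_rounded": round(self.background_percent, 1),
            "chi2": self.chi2,
            "p": self.p,
            "fisher_p": self.fisher_p,
        }


def enrichment_from_counts(member_count: int, member_total: int,
                           background_count: int,
                           background_total: int) -> EnrichmentResult:
    """Chi-square and Fisher tests on a 2x2 annotated-vs-not table.

    The table contrasts the member set (e.g. a network's genes) against the
    background universe as printed in comparative summaries:
    [[in_member, not_in_member], [in_background, not_in_background]].
    """
    if background_total <= 0:
        raise ValidationError("enrichment: empty background")
    if member_count > member_total or background_count > background_total:
        raise ValidationError("enrichment: count exceeds total")
    table = np.array([
        [member_count, member_total - member_count],
        [background_count, background_total - background_count],
    ])
    if table.min() < 0:
        raise ValidationError("enrichment: negative cell count")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        chi2, p = 0.0, 1.0
    else:
        if member_count / member_total == background_count / background_total:
            chi2, p = 0.0, 1.0
        else:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    _, fisher_p = stats.fisher_exact(table, alternative="two-sided")
    return EnrichmentResult(
        member_count=int(member_count), member_total=int(member_total),
        background_count=int(background_count),
        background_total=int(background_total),
        chi2=float(chi2), p=float(p), fisher_p=float(fisher_p))


def set_enrichment(member_genes, annotation_set,
                   background_genes) -> EnrichmentResult:
    """Enrichment of an annotation in a gene set against a background.

    Preconditions: members and annotation are subsets of the background.
    """
    member = set(member_genes)
    annotation = set(annotation_set)
    background = set(background_genes)
    if not background:
        raise ValidationError("set_enrichment: empty background")
    if not member <= background:
        raise ValidationError("set_enrichment: member genes not within background")
    if not annotation <= background:
        raise ValidationError("set_enrichment: annotation not within background")
    return enrichment_from_counts(
        member_count=len(member & annotation), member_total=len(member),
        background_count=len(annotation), background_total=len(background))


def biotype_composition(nodes, annotations: pd.DataFrame,
                        collapse_tf: bool = True) -> dict[str, int]:
    """Counts per biotype for a node set; unannotated nodes count as 'other_ncrna'.

    ``annotations`` carries columns ``gene`` and ``biotype``.  Counts sum to
    the size of the node set.
    """
    lookup = dict(zip(annotations["gene"], annotations["biotype"]))
    counts: dict[str, int] = {}
    for n in set(nodes):
        bt = lookup.get(n, "other_ncrna")
        if collapse_tf and bt == "tf":
            bt = "protein_coding"
        counts[bt] = counts.get(bt, 0) + 1
    counts["total"] = len(set(nodes))
    return counts


def gene_list_overlap(network_nodes, reference_list,
                      modules=None) -> dict:
    """Intersection of network nodes with a reference gene list.

    With ``modules`` (list of ModuleAssignment or mapping id -> members) the
    per-module location of each overlapping gene is reported.
    """
    nodes = set(network_nodes)
    reference = set(reference_list)
    overlap = sorted(nodes & reference)
    by_module: dict[str, list[str]] = {}
    if modules is not None:
        items = (modules.items() if isinstance(modules, dict)
                 else ((m.module_id, m.members) for m in modules))
        for mid, members in items:
            hits = sorted(set(members) & set(overlap))
            if hits:
                by_module[mid] = hits
    return {"overlap": overlap, "count": len(overlap), "by_module": by_module}


def module_llps_fractions(modules, llps_set) -> dict[str, dict]:
    """Percentage of LLPS-annotated members per module (one-decimal report).

    Empty modules are reported as absent rather than as a fraction.
    """
    llps = set(llps_set)
    out: dict[str, dict] = {}
    items = (modules.items() if isinstance(modules, dict)
             else ((m.module_id, m.members) for m in modules))
    for mid, members in items:
        members = list(members)
        if not members:
            continue
        frac = 100.0 * len(set(members) & llps) / len(members)
        out[mid] = {"n": len(members),
                    "n_llps": len(set(members) & llps),
                    "percent": frac,
                    "percent_rounded": round(frac, 1)}
    return out
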