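"""Fuzzy non-negative matrix factorization biclustering.

The selected-gene expression matrix X (subjects x genes) is factorized as
X ~ W H with W (subjects x k) and H (k x genes) non-negative, by
multiplicative updates minimizing the Frobenius reconstruction error

    ||X - WH||_F^2 .

Fuzzy memberships are obtained post hoc by normalizing the subject loadings
(rows of W) and the gene loadings (columns of H) across the k factors so
each sums to one, giving a fuzzy partition.  A bicluster T_t collects the
subjects and genes whose normalized membership in factor t reaches a
threshold (default 1/k, i.e. exceeding a uniform membership); subjects and
genes may belong to several biclusters.

An optional consensus mode runs the factorization from several seeded
initializations and averages the normalized memberships before
thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import ValidationError

_EPS = 1e-12


@dataclass
class FactorPair:
    """Non-negative factors W, H with the per-iteration objective trace."""

    W: np.ndarray  # subjects x k
    H: np.ndarray  # k x genes
    k: int
    objective_trace: list[float]
    shift: float = 0.0  # amount added to make the input non-negative
    subjects: list[str] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)


@dataclass
class Bicluster:
    """A fuzzy co-cluster of subjects and genes (one factor)."""

    id: str
    subjects: list[str]
    genes: list[str]
    subject_memberships: dict[str, float]
    gene_memberships: dict[str, float]


def center_expression(matrix: pd.DataFrame) -> pd.DataFrame:
    """Remove each gene's mean expression across subjects.

    Absolute log2 intensity is dominated by a per-gene baseline that soaks
    up factorization capacity; centering leaves the subject-by-gene
    co-variation that biclusters are made of.  The centered matrix contains
    negative values, which :func:`fnmf` handles by its recorded min-shift.
    """
    return matrix - matrix.mean(axis=0)


def fnmf(matrix: pd.DataFrame, k: int, seed: int = 0,
         max_iter: int = 500, tol: float = 1e-6) -> FactorPair:
    """Seeded multiplicative-update NMF of an expression matrix.

    A matrix containing negative entries is shifted by its global minimum
    (recorded on the result).  Iterations stop when the relative change of
    the objective falls below ``tol`` or after ``max_iter`` updates.  The
    objective trace is non-increasing.
    """
    X = np.asarray(matrix, dtype=float)
    if k < 1:
        raise ValidationError("fnmf: k must be >= 1")
    if k > min(X.shape):
        raise ValidationError(f"fnmf: k={k} exceeds min matrix dimension {min(X.shape)}")
    shift = 0.0
    lo = X.min()
    if lo < 0:
        shift = -lo
        X = X + shift
    if not X.any():
        raise ValidationError("fnmf: all-zero matrix cannot be factorized")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(X.mean() / k)
    W = rng.uniform(0.0, 1.0, size=(X.shape[0], k)) * scale + _EPS
    H = rng.uniform(0.0, 1.0, size=(k, X.shape[1])) * scale + _EPS
    trace = [float(np.linalg.norm(X - W @ H) ** 2)]
    for _ in range(max_iter):
        H *= (W.T @ X) / (W.T @ W @ H + _EPS)
        W *= (X @ H.T) / (W @ (H @ H.T) + _EPS)
        obj = float(np.linalg.norm(X - W @ H) ** 2)
        trace.append(obj)
        prev = trace[-2]
        if prev > 0 and (prev - obj) / prev < tol:
            break
    return FactorPair(W=W, H=H, k=k, objective_trace=trace, shift=shift,
                      subjects=[str(s) for s in matrix.index],
                      genes=[str(g) for g in matrix.columns])


def _normalize_rows(M: np.ndarray) -> np.ndarray:
    s = M.sum(axis=1, keepdims=True)
    out = np.where(s > 0, M / np.where(s == 0, 1.0, s), 1.0 / M.shape[1])
    return out


def memberships(fp: FactorPair) -> tuple[np.ndarray, np.ndarray]:
    """Fuzzy memberships: rows of W and columns of H normalized over k.

    Returns (subject_memberships [n x k], gene_memberships [m x k]); each
    row sums to one.  All-zero loadings fall back to uniform membership.
    """
    return _normalize_rows(fp.W), _normalize_rows(fp.H.T)


def extract_biclusters(fp: FactorPair,
                       membership_threshold: float | None = None) -> list[Bicluster]:
    """Threshold fuzzy memberships into biclusters T1..Tk.

    The default threshold 1/k keeps members whose affinity for a factor
    exceeds a uniform spread over the factors.
    """
    if membership_threshold is None:
        membership_threshold = 1.0 / fp.k
    if not 0 < membership_threshold <= 1:
        raise ValidationError("membership_threshold must lie in (0, 1]")
    subj_m, gene_m = memberships(fp)
    out = []
    for t in range(fp.k):
        s_idx = np.flatnonzero(subj_m[:, t] >= membership_threshold)
        g_idx = np.flatnonzero(gene_m[:, t] >= membership_threshold)
        out.append(Bicluster(
            id=f"T{t + 1}",
            subjects=[fp.subjects[i] for i in s_idx],
            genes=[fp.genes[j] for j in g_idx],
            subject_memberships={fp.subjects[i]: float(subj_m[i, t]) for i in s_idx},
            gene_memberships={fp.genes[j]: float(gene_m[j, t]) for j in g_idx},
        ))
    return out


def consensus_biclusters(matrix: pd.DataFrame, k: int, seed: int = 0,
                         n_runs: int = 5, membership_threshold: float | None = None,
                         max_iter: int = 500, tol: float = 1e-6) -> list[Bicluster]:
    """Average normalized memberships over several seeded runs, then threshold.

    Factors from different runs are aligned to the first run by greedy
    matching of gene-membership correlation before averaging.
    """
    if n_runs < 1:
        raise ValidationError("consensus_biclusters: n_runs must be >= 1")
    base = fnmf(matrix, k, seed=seed, max_iter=max_iter, tol=tol)
    subj_acc, gene_acc = memberships(base)
    subj_acc, gene_acc = subj_acc.copy(), gene_acc.copy()
    for r in range(1, n_runs):
        fp = fnmf(matrix, k, seed=seed + r, max_iter=max_iter, tol=tol)
        sm, gm = memberships(fp)
        # align factors to the base run on gene memberships
        corr = np.corrcoef(gene_acc.T / max(r, 1), gm.T)[:k, k:]
        mapping = [-1] * k
        used = set()
        for _ in range(k):
            i, j = np.unravel_index(np.nanargmax(np.where(
                np.isnan(corr), -np.inf, corr)), corr.shape)
            mapping[i] = j
            corr[i, :] = np.nan
            corr[:, j] = np.nan
            used.add(j)
        subj_acc += sm[:, mapping]
        gene_acc += gm[:, mapping]
    subj_acc /= n_runs
    gene_acc /= n_runs
    thr = membership_threshold if membership_threshold is not None else 1.0 / k
    out = []
    for t in range(k):
        s_idx = np.flatnonzero(subj_acc[:, t] >= thr)
        g_idx = np.flatnonzero(gene_acc[:, t] >= thr)
        out.append(Bicluster(
            id=f"T{t + 1}",
            subjects=[base.subjects[i] for i in s_idx],
            genes=[base.genes[j] for j in g_idx],
            subject_memberships={base.subjects[i]: float(subj_acc[i, t]) for i in s_idx},
            gene_memberships={base.genes[j]: float(gene_acc[j, t]) for j in g_idx},
        ))
    return out


def bicluster_overlap(biclusters: list[Bicluster]) -> dict:
    """Pairwise and global shared-gene sets across biclusters."""
    if len(biclusters) < 2:
        raise ValidationError("bicluster_overlap: need at least two biclusters")
    pairwise = {}
    for i, a in enumerate(biclusters):
        for b in biclusters[i + 1:]:
            shared = sorted(set(a.genes) & set(b.genes))
            pairwise[(a.id, b.id)] = shared
    counts: dict[str, int] = {}
    for bc in biclusters:
        for g in set(bc.genes):
            counts[g] = counts.get(g, 0) + 1
    shared_genes = sorted(g for g, c in counts.items() if c >= 2)
    return {"pairwise": pairwise,
            "shared_genes": shared_genes,
            "n_shared": len(shared_genes)}


def gene_assignments(fp_or_biclusters, genes: list[str] | None = None) -> dict[str, int]:
    """Hard gene assignment: the factor with maximal gene membership.

    Accepts either a FactorPair or a list of biclusters (membership argmax).
    Used for comparing recovered biclusters against planted truth.
    """
    if isinstance(fp_or_biclusters, FactorPair):
        _, gm = memberships(fp_or_biclusters)
        names = fp_or_biclusters.genes
        return {names[j]: int(np.argmax(gm[j])) for j in range(len(names))}
    best: dict[str, tuple[float, int]] = {}
    for t, bc in enumerate(fp_or_biclusters):
        for g, m in bc.gene_memberships.items():
            if g not in best or m > best[g][0]:
                best[g] = (m, t)
    return {g: t for g, (_, t) in best.items()}
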