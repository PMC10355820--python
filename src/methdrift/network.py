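"""Consensus comethylation network construction.

The pipeline: biweight midcorrelation between CpG methylation profiles,
soft-threshold adjacency, topological overlap (TOM), two-dataset consensus by
elementwise minimum of quantile-scaled TOMs, average-linkage clustering of
1 - consensus TOM with a static height/min-size tree cut, then module
eigengenes and eigengene-based connectivity (kME).

Structure retained by the consensus (present in BOTH datasets) is the device
that segregates physiological replication signal from culture artifacts: a
module that comethylates only in vitro collapses in the consensus TOM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import BetaMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityMatrix", "ModulePartition", "EigengeneSet",
    "bicor_matrix", "adjacency", "tom", "consensus_tom",
    "cluster_modules", "module_eigengenes", "kme", "top_kme",
]

#: WGCNA-style color aliases for size-ranked module labels (reporting only)
MODULE_COLORS = [
    "grey", "turquoise", "blue", "brown", "yellow", "green", "red", "black",
    "pink", "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
]


@dataclass
class SimilarityMatrix:
    """Symmetric CpG x CpG similarity with a kind tag.

    kind is one of "correlation" (values in [-1, 1], unit diagonal),
    "adjacency" ([0, 1]), "tom" ([0, 1], unit diagonal).
    """

    cpg_ids: list[str]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.cpg_ids):
            raise ValueError("similarity matrix shape mismatch")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("similarity matrix is not symmetric")


@dataclass
class ModulePartition:
    """CpG -> module label map; label 0 means unassigned ("grey")."""

    cpg_ids: list[str]
    labels: np.ndarray  # int labels aligned with cpg_ids
    min_cluster_size: int

    @property
    def module_ids(self) -> list[int]:
        return sorted(int(l) for l in np.unique(self.labels) if l != 0)

    def module_sizes(self) -> dict[int, int]:
        uniq, counts = np.unique(self.labels, return_counts=True)
        return {int(u): int(c) for u, c in zip(uniq, counts) if u != 0}

    def members(self, label: int) -> list[str]:
        return [c for c, l in zip(self.cpg_ids, self.labels) if l == label]

    def color_of(self, label: int) -> str:
        return MODULE_COLORS[label] if label < len(MODULE_COLORS) else f"module{label}"

    def as_dict(self) -> dict[str, int]:
        return {c: int(l) for c, l in zip(self.cpg_ids, self.labels)}


@dataclass
class EigengeneSet:
    """Samples x modules eigengene scores (unit variance, sign-anchored)."""

    sample_ids: list[str]
    module_ids: list[int]
    values: np.ndarray                     # (n_samples, n_modules)
    explained_variance: dict[int, float]

    def eigengene(self, module: int) -> np.ndarray:
        return self.values[:, self.module_ids.index(module)]


def _bicor_rows(X: np.ndarray) -> np.ndarray:
    """Per-row weighted deviations for biweight midcorrelation.

    Rows with zero median absolute deviation fall back to plain mean-centered
    deviations (Pearson behavior), the standard robust-correlation fallback.
    """
    med = np.median(X, axis=1, keepdims=True)
    mad = np.median(np.abs(X - med), axis=1, keepdims=True)
    degenerate = (mad[:, 0] == 0)
    if degenerate.any():
        logger.warning(
            "%d CpGs have zero MAD; Pearson fallback applied", int(degenerate.sum())
        )
    safe_mad = np.where(mad == 0, 1.0, mad)
    u = (X - med) / (9.0 * safe_mad)
    w = (1 - u ** 2) ** 2 * (np.abs(u) < 1)
    D = (X - med) * w
    if degenerate.any():
        D[degenerate] = X[degenerate] - X[degenerate].mean(axis=1, keepdims=True)
    return D


def bicor_matrix(m: BetaMatrix) -> SimilarityMatrix:
    """Biweight midcorrelation between all CpG pairs.

    For each CpG the observations are median-centered and downweighted by the
    Tukey biweight w = (1 - u^2)^2 for |u| < 1 (else 0), with
    u = (x - median) / (9 * MAD); the correlation is the normalized inner
    product of the weighted deviations.  Robust to outlying samples, which
    matters when adjacencies feed a power transform.
    """
    if m.n_samples < 4:
        raise ValueError("bicor requires at least 4 samples")
    D = _bicor_rows(m.values)
    G = D @ D.T
    diag = np.diag(G).copy()
    diag[diag == 0] = 1.0
    # divide by sqrt of the *product* so that exactly affine CpG pairs give
    # exactly +-1 (sqrt(fl(a*a)) == a in IEEE double arithmetic)
    C = G / np.sqrt(np.outer(diag, diag))
    np.clip(C, -1.0, 1.0, out=C)
    np.fill_diagonal(C, 1.0)
    C = (C + C.T) / 2
    return SimilarityMatrix(list(m.cpg_ids), C, "correlation")


def adjacency(corr: SimilarityMatrix, power: float = 6.0,
              mode: str = "unsigned") -> SimilarityMatrix:
    """Soft-threshold a correlation matrix into a network adjacency.

    unsigned: a = |r|^power; signed: a = ((1 + r) / 2)^power.  The diagonal is
    stored as 1 and excluded inside the TOM sums downstream.
    """
    if corr.kind != "correlation":
        raise ValueError("adjacency expects a correlation matrix")
    if power <= 0:
        raise ValueError("soft-threshold power must be positive")
    if mode == "unsigned":
        a = np.abs(corr.values) ** power
    elif mode == "signed":
        a = ((1 + corr.values) / 2) ** power
    else:
        raise ValueError(f"unknown adjacency mode {mode!r}")
    np.fill_diagonal(a, 1.0)
    return SimilarityMatrix(list(corr.cpg_ids), a, "adjacency")


def tom(a: SimilarityMatrix) -> SimilarityMatrix:
    """Topological overlap: shared-neighbor-augmented similarity.

    omega_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) for i != j, with
    l_ij = sum_{u != i,j} a_iu a_uj and connectivity k_i = sum_{u != i} a_iu;
    the diagonal is 1.
    """
    if a.kind != "adjacency":
        raise ValueError("tom expects an adjacency matrix")
    A = a.values.copy()
    if A.min() < 0 or A.max() > 1:
        raise ValueError("adjacency values must lie in [0, 1]")
    np.fill_diagonal(A, 0.0)
    L = A @ A                       # diag(A)=0 makes u=i and u=j terms vanish
    k = A.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        W = (L + A) / (kmin + 1.0 - A)
    W[~np.isfinite(W)] = 0.0
    np.fill_diagonal(W, 1.0)
    W = (W + W.T) / 2
    return SimilarityMatrix(list(a.cpg_ids), W, "tom")


def consensus_tom(tom_a: SimilarityMatrix, tom_b: SimilarityMatrix,
                  scale_quantile: float = 0.95,
                  scale: bool = True) -> SimilarityMatrix:
    """Elementwise-minimum consensus of two TOMs after quantile calibration.

    The second TOM is raised to the power log q_a / log q_b so that its
    ``scale_quantile`` off-diagonal quantile matches the first TOM's,
    compensating for dataset-specific overall connectivity before taking the
    minimum; the consensus dissimilarity is 1 - consensus.
    """
    if tom_a.cpg_ids != tom_b.cpg_ids:
        raise ValueError("consensus requires identical CpG universes")
    if not (0 < scale_quantile <= 1):
        raise ValueError("scale_quantile must be in (0, 1]")
    B = tom_b.values
    if scale:
        off = ~np.eye(len(tom_a.cpg_ids), dtype=bool)
        qa = float(np.quantile(tom_a.values[off], scale_quantile))
        qb = float(np.quantile(B[off], scale_quantile))
        if 0 < qa < 1 and 0 < qb < 1:
            B = B ** (np.log(qa) / np.log(qb))
        else:
            logger.warning("degenerate TOM quantiles (%g, %g); scaling skipped", qa, qb)
    cons = np.minimum(tom_a.values, B)
    np.fill_diagonal(cons, 1.0)
    return SimilarityMatrix(list(tom_a.cpg_ids), cons, "tom")


def cluster_modules(consensus: SimilarityMatrix, deep_split: int = 1,
                    cut_height: float = 0.95, min_cluster_size: int = 50):
    """Average-linkage clustering of 1 - TOM with a static tree cut.

    The dendrogram is cut at ``cut_height``; clusters smaller than
    ``min_cluster_size`` are left unassigned (label 0).  Labels are assigned
    by decreasing module size (1 = largest).  ``deep_split`` is recorded for
    provenance; this implementation applies only the height and minimum-size
    semantics of the cut (see the methods documentation).

    Returns (ModulePartition, linkage matrix).
    """
    if consensus.kind != "tom":
        raise ValueError("cluster_modules expects a TOM")
    if not (0 < cut_height <= 1):
        raise ValueError("cut_height must be in (0, 1]")
    D = 1.0 - consensus.values
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, None)
    Z = linkage(squareform(D, checks=False), method="average")
    raw = fcluster(Z, t=cut_height, criterion="distance")
    labels = np.zeros(len(raw), dtype=int)
    sizes = [(np.sum(raw == c), c) for c in np.unique(raw)]
    kept = [(n, c) for n, c in sizes if n >= min_cluster_size]
    # rank by size; ties broken by smallest member index for determinism
    kept.sort(key=lambda nc: (-nc[0], int(np.argmax(raw == nc[1]))))
    for new_label, (_, c) in enumerate(kept, start=1):
        labels[raw == c] = new_label
    part = ModulePartition(list(consensus.cpg_ids), labels, min_cluster_size)
    return part, Z


def module_eigengenes(m: BetaMatrix, part: ModulePartition) -> EigengeneSet:
    """First principal component of each module's standardized CpG profiles.

    Each member CpG is z-scored across samples (zero-variance CpGs dropped
    with a warning); the eigengene is PC1 of the resulting samples x CpGs
    block, rescaled to unit sample variance, with sign fixed so the mean kME
    of module members is non-negative.  The explained-variance fraction of
    PC1 within the module is reported.
    """
    cpg_pos = {c: i for i, c in enumerate(m.cpg_ids)}
    module_ids = part.module_ids
    cols, ev = [], {}
    n = m.n_samples
    for mod in module_ids:
        members = part.members(mod)
        if not members:
            raise ValueError(f"module {mod} is empty")
        idx = [cpg_pos[c] for c in members if c in cpg_pos]
        if len(idx) < 2:
            raise ValueError(f"module {mod} has fewer than 2 CpGs in the matrix")
        X = m.values[idx].T  # samples x members
        sd = X.std(axis=0)
        if (sd == 0).any():
            logger.warning("module %d: %d zero-variance CpGs dropped",
                           mod, int((sd == 0).sum()))
            X = X[:, sd > 0]
            sd = sd[sd > 0]
            if X.shape[1] == 0:
                raise ValueError(f"module {mod} has no varying CpGs")
        Z = (X - X.mean(axis=0)) / sd
        U, s, _ = np.linalg.svd(Z, full_matrices=False)
        pc1 = U[:, 0] * s[0]
        pc1 = pc1 / pc1.std(ddof=0) if pc1.std(ddof=0) > 0 else pc1
        # sign anchor: mean correlation with members >= 0
        corr_sign = np.sign(np.mean(Z.T @ pc1))
        if corr_sign < 0:
            pc1 = -pc1
        cols.append(pc1)
        ev[mod] = float(s[0] ** 2 / np.sum(s ** 2))
    values = np.column_stack(cols) if cols else np.empty((n, 0))
    return EigengeneSet(list(m.sample_ids), module_ids, values, ev)


def kme(m: BetaMatrix, eig: EigengeneSet) -> np.ndarray:
    """Eigengene-based connectivity: Pearson r of each CpG with each eigengene.

    Zero-variance CpGs get kME 0 with a warning.  Returns a
    (n_cpgs, n_modules) matrix aligned with ``m.cpg_ids`` and
    ``eig.module_ids``.
    """
    if list(m.sample_ids) != list(eig.sample_ids):
        raise ValueError("sample sets of matrix and eigengenes differ")
    X = m.values
    sd = X.std(axis=1)
    zero = sd == 0
    if zero.any():
        logger.warning("%d zero-variance CpGs get kME 0", int(zero.sum()))
    Xc = X - X.mean(axis=1, keepdims=True)
    Xn = np.zeros_like(Xc)
    Xn[~zero] = Xc[~zero] / np.linalg.norm(Xc[~zero], axis=1, keepdims=True)
    E = eig.values - eig.values.mean(axis=0)
    En = E / np.linalg.norm(E, axis=0, keepdims=True)
    K = Xn @ En
    np.clip(K, -1.0, 1.0, out=K)
    return K


def top_kme(m: BetaMatrix, eig: EigengeneSet, part: ModulePartition,
            module: int, n: int) -> list[str]:
    """Top-n module members by descending kME, lexicographic tie-break."""
    K = kme(m, eig)
    col = eig.module_ids.index(module)
    members = set(part.members(module))
    ranked = sorted(
        (c for c in m.cpg_ids if c in members),
        key=lambda c: (-K[m.cpg_ids.index(c), col], c),
    )
    return ranked[:n]
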