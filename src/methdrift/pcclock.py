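"""Principal-component clocks: PCA on beta values, elastic-net selection of
component scores against a continuous target (cPD or age), and driver-CpG
extraction from loadings.

A PC clock regresses the target on principal-component scores of the training
matrix rather than on individual CpGs; the elastic net picks the informative
components, and the clock transfers to new data by projecting onto the frozen
loadings.  All min(n_samples, n_CpGs) components are retained at fit time,
including the degenerate trailing one — the penalized fit simply leaves it at
zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._enet import ElasticNetFit, fit_cv_enet
from .io import BetaMatrix

__all__ = ["PCModel", "PCClock", "fit_pca", "fit_pc_clock", "predict_score",
           "select_driver_cpgs"]


@dataclass
class PCModel:
    """Centered (not scaled) principal-component decomposition of a BetaMatrix.

    ``loadings`` has orthonormal columns, one per component; component order
    follows non-increasing explained variance.
    """

    cpg_ids: list[str]
    center: np.ndarray            # per-CpG mean, (n_cpgs,)
    loadings: np.ndarray          # (n_cpgs, n_components)
    component_variances: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def scores(self, m: BetaMatrix) -> np.ndarray:
        """Project samples of ``m`` onto the components, (n_samples, n_comp).

        ``m`` must contain every model CpG; extra CpGs are ignored and row
        order is irrelevant.
        """
        sub = _extract(m, self.cpg_ids)
        return (sub - self.center[:, None]).T @ self.loadings

    def to_state(self) -> dict:
        return {
            "cpg_ids": list(self.cpg_ids),
            "center": self.center,
            "loadings": self.loadings,
            "component_variances": self.component_variances,
        }

    @classmethod
    def from_state(cls, state: dict) -> "PCModel":
        return cls(
            cpg_ids=[str(c) for c in state["cpg_ids"]],
            center=state["center"],
            loadings=state["loadings"],
            component_variances=state["component_variances"],
        )


@dataclass
class PCClock:
    """A PCModel plus an elastic-net fit over its component scores."""

    pcs: PCModel
    enet: ElasticNetFit
    target_name: str = "cpd"

    def to_state(self) -> dict:
        return {
            "pcs": self.pcs.to_state(),
            "target_name": self.target_name,
            "enet": {
                "alpha": self.enet.alpha,
                "lam": self.enet.lam,
                "coefficients": self.enet.coefficients,
                "intercept": self.enet.intercept,
                "cv_folds": self.enet.cv_folds,
                "cv_seed": self.enet.cv_seed,
                "cv_curve": self.enet.cv_curve,
            },
        }

    @classmethod
    def from_state(cls, state: dict) -> "PCClock":
        e = state["enet"]
        return cls(
            pcs=PCModel.from_state(state["pcs"]),
            enet=ElasticNetFit(
                alpha=float(e["alpha"]),
                lam=float(e["lam"]),
                coefficients=e["coefficients"],
                intercept=float(e["intercept"]),
                cv_folds=int(e["cv_folds"]),
                cv_seed=int(e["cv_seed"]),
                cv_curve=e["cv_curve"],
            ),
            target_name=str(state["target_name"]),
        )


def _extract(m: BetaMatrix, cpg_ids: list[str]) -> np.ndarray:
    pos = {c: i for i, c in enumerate(m.cpg_ids)}
    missing = [c for c in cpg_ids if c not in pos]
    if missing:
        head = ", ".join(missing[:10])
        more = f" (+{len(missing) - 10} more)" if len(missing) > 10 else ""
        raise KeyError(f"matrix lacks clock CpGs: {head}{more}")
    return m.values[[pos[c] for c in cpg_ids]]


def fit_pca(m: BetaMatrix) -> PCModel:
    """PCA of a beta matrix: center per CpG, retain all min(n, p) components.

    Uses SVD of the centered samples x CpGs matrix; loadings are the right
    singular vectors.  The trailing component is degenerate (centering removes
    one degree of freedom when n <= p) but is retained so every sample
    projects onto exactly min(n, p) scores.
    """
    if m.n_samples < 3:
        raise ValueError("PCA requires at least 3 samples")
    if not np.all(np.isfinite(m.values)):
        raise ValueError("beta matrix contains missing/non-finite values")
    X = m.values.T  # samples x CpGs
    center = X.mean(axis=0)
    Xc = X - center
    n_comp = min(m.n_samples, m.n_cpgs)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    variances = (s ** 2) / (m.n_samples - 1)
    return PCModel(
        cpg_ids=list(m.cpg_ids),
        center=center,
        loadings=Vt.T[:, :n_comp],
        component_variances=variances[:n_comp],
    )


def fit_pc_clock(
    pcs: PCModel,
    scores: np.ndarray,
    target: np.ndarray,
    alpha: float = 0.5,
    folds: int = 10,
    seed: int = 0,
    target_name: str = "cpd",
) -> PCClock:
    """Elastic-net regression of a continuous target on component scores.

    The penalty is chosen at the minimum mean squared error over a
    deterministic K-fold split (``seed``); the lambda grid descends
    log-uniformly from the all-zero penalty.
    """
    target = np.asarray(target, float)
    enet = fit_cv_enet(np.asarray(scores, float), target, alpha=alpha,
                       folds=folds, seed=seed)
    return PCClock(pcs=pcs, enet=enet, target_name=target_name)


def train_pc_clock(
    m: BetaMatrix,
    target: np.ndarray,
    alpha: float = 0.5,
    folds: int = 10,
    seed: int = 0,
    target_name: str = "cpd",
) -> PCClock:
    """Convenience: fit_pca then fit_pc_clock on the training matrix."""
    pcs = fit_pca(m)
    return fit_pc_clock(pcs, pcs.scores(m), target, alpha=alpha, folds=folds,
                        seed=seed, target_name=target_name)


def predict_score(clock: PCClock, m: BetaMatrix) -> np.ndarray:
    """Drift score per sample: intercept + sum_k coef_k * projected score_k.

    Invariant to CpG row order; errors listing identifiers if any clock CpG
    is absent.
    """
    return clock.enet.predict(clock.pcs.scores(m))


def select_driver_cpgs(
    clock: PCClock,
    top_k: int,
    aggregation: str = "sum",
) -> list[str]:
    """Rank CpGs by their contribution to the clock's active components.

    Per component with a non-zero coefficient, absolute loadings are
    z-normalized across CpGs; a CpG's importance is the weighted sum (or,
    with ``aggregation="max"``, maximum) of these normalized values.  The
    component weight is |coef_k| * sd(score_k): coefficients are stored on
    the raw component-score scale, so the score SD puts every component's
    contribution on the standardized scale the penalized fit actually saw —
    otherwise near-degenerate trailing components, whose raw-scale
    coefficients are inflated by their tiny variance, would dominate.
    Returns the ``top_k`` CpGs by descending importance, ties broken
    lexicographically by CpG id.  Sign flips of loading columns do not change
    the result.
    """
    if top_k > len(clock.pcs.cpg_ids):
        raise ValueError("top_k exceeds the number of CpGs")
    if aggregation not in ("sum", "max"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    coefs = clock.enet.coefficients
    active = np.nonzero(coefs)[0]
    if active.size == 0:
        raise ValueError("clock has no active components (all coefficients zero)")
    score_sd = np.sqrt(np.maximum(clock.pcs.component_variances, 0.0))
    parts = []
    for k in active:
        a = np.abs(clock.pcs.loadings[:, k])
        sd = a.std()
        z = (a - a.mean()) / sd if sd > 0 else np.zeros_like(a)
        parts.append(np.abs(coefs[k]) * score_sd[k] * z)
    parts = np.asarray(parts)
    importance = parts.sum(axis=0) if aggregation == "sum" else parts.max(axis=0)
    order = sorted(
        range(len(importance)),
        key=lambda i: (-importance[i], clock.pcs.cpg_ids[i]),
    )
    return [clock.pcs.cpg_ids[i] for i in order[:top_k]]
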