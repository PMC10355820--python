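"""Module clocks, physiological-module selection, and the pooled-PC composite
drift score.

Per-module clocks are PC clocks restricted to one module's CpGs.  Modules are
retained as "physiological" only if their clock score tracks the drift
covariate both in vitro (cPD) and in vivo (age) on held-out data.  The
composite then pools the component scores of each selected module's own PCA
(rather than re-decomposing the union of CpGs) and fits one elastic net over
the concatenation, so every module contributes components on an equal footing
regardless of its CpG count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from ._enet import ElasticNetFit, fit_cv_enet
from .io import BetaMatrix, SampleSheet
from .network import ModulePartition
from .pcclock import PCClock, PCModel, fit_pca, fit_pc_clock, predict_score

logger = logging.getLogger(__name__)

__all__ = ["ModuleClockSet", "CompositeModel", "fit_module_clocks",
           "select_modules", "fit_composite", "score_composite"]


@dataclass
class ModuleClockSet:
    """One PC clock per module, plus recorded validation correlations."""

    clocks: dict[int, PCClock]
    validation_r: dict[int, dict[str, float]]

    @property
    def module_ids(self) -> list[int]:
        return sorted(self.clocks)


@dataclass
class CompositeModel:
    """Pooled-PC composite: per-module PCAs + one elastic net on pooled scores.

    ``provenance`` maps each pooled-score column to its (module, component)
    origin.
    """

    module_ids: list[int]
    pc_models: dict[int, PCModel]
    enet: ElasticNetFit
    provenance: list[tuple[int, int]]
    target_name: str = "cpd"

    @property
    def n_pooled(self) -> int:
        return len(self.provenance)

    def pooled_scores(self, m: BetaMatrix) -> np.ndarray:
        blocks = [self.pc_models[mod].scores(m) for mod in self.module_ids]
        return np.hstack(blocks)

    def to_state(self) -> dict:
        return {
            "module_ids": self.module_ids,
            "target_name": self.target_name,
            "pc_models": {str(k): v.to_state() for k, v in self.pc_models.items()},
            "provenance": [[int(a), int(b)] for a, b in self.provenance],
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
    def from_state(cls, state: dict) -> "CompositeModel":
        e = state["enet"]
        return cls(
            module_ids=[int(m) for m in state["module_ids"]],
            pc_models={int(k): PCModel.from_state(v)
                       for k, v in state["pc_models"].items()},
            enet=ElasticNetFit(
                alpha=float(e["alpha"]), lam=float(e["lam"]),
                coefficients=e["coefficients"], intercept=float(e["intercept"]),
                cv_folds=int(e["cv_folds"]), cv_seed=int(e["cv_seed"]),
                cv_curve=e["cv_curve"],
            ),
            provenance=[(int(a), int(b)) for a, b in state["provenance"]],
            target_name=str(state["target_name"]),
        )


def _target_vector(sheet: SampleSheet, m: BetaMatrix, target: str) -> np.ndarray:
    aligned = sheet.aligned_to(m)
    if target not in aligned:
        raise KeyError(f"sample sheet lacks the target column {target!r}")
    y = aligned[target].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError(f"target {target!r} missing for some samples")
    return y


def fit_module_clocks(
    train: BetaMatrix,
    sheet: SampleSheet,
    part: ModulePartition,
    target: str = "cpd",
    alpha: float = 0.5,
    folds: int = 10,
    seed: int = 0,
) -> ModuleClockSet:
    """Train one PC clock per labeled module on that module's CpGs only."""
    y = _target_vector(sheet, train, target)
    clocks: dict[int, PCClock] = {}
    for mod in part.module_ids:
        members = [c for c in part.members(mod) if c in set(train.cpg_ids)]
        if len(members) < 2:
            logger.warning("module %d has <2 CpGs in the training matrix; skipped", mod)
            continue
        sub = train.subset_cpgs(members)
        pcs = fit_pca(sub)
        clocks[mod] = fit_pc_clock(pcs, pcs.scores(sub), y, alpha=alpha,
                                   folds=folds, seed=seed, target_name=target)
    return ModuleClockSet(clocks=clocks, validation_r={})


def _safe_pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(stats.pearsonr(x, y)[0])


def select_modules(
    clocks: ModuleClockSet,
    invitro_eval: tuple[BetaMatrix, SampleSheet],
    invivo_eval: tuple[BetaMatrix, SampleSheet],
    r_min: float = 0.5,
) -> list[int]:
    """Keep modules whose clock tracks drift both in vitro and in vivo.

    A module passes iff Pearson r(score, cPD) >= r_min on the in-vitro
    evaluation set AND Pearson r(score, age) >= r_min on the in-vivo set.
    The per-module correlation table is recorded on ``clocks.validation_r``
    and included in the error message when nothing passes.
    """
    beta_vitro, sheet_vitro = invitro_eval
    beta_vivo, sheet_vivo = invivo_eval
    cpd = _target_vector(sheet_vitro, beta_vitro, "cpd")
    age = _target_vector(sheet_vivo, beta_vivo, "age")
    selected = []
    for mod in clocks.module_ids:
        clock = clocks.clocks[mod]
        r_vitro = _safe_pearson(predict_score(clock, beta_vitro), cpd)
        r_vivo = _safe_pearson(predict_score(clock, beta_vivo), age)
        clocks.validation_r[mod] = {"invitro_cpd": r_vitro, "invivo_age": r_vivo}
        if r_vitro >= r_min and r_vivo >= r_min:
            selected.append(mod)
    if not selected:
        raise ValueError(
            f"no module passes r_min={r_min}; correlations: {clocks.validation_r}"
        )
    return selected


def fit_composite(
    train: BetaMatrix,
    sheet: SampleSheet,
    part: ModulePartition,
    selected: list[int],
    target: str = "cpd",
    alpha: float = 0.5,
    folds: int = 10,
    seed: int = 0,
) -> CompositeModel:
    """Fit the pooled-PC composite over the selected modules.

    Each selected module gets an independent PCA on its own CpGs (all
    min(n_samples, module size) components); the component scores are
    concatenated across modules and one elastic net is fitted on the pooled
    scores, so a small module contributes as many candidate components as a
    large one when n_samples is the binding dimension.
    """
    if not selected:
        raise ValueError("at least one module must be selected")
    y = _target_vector(sheet, train, target)
    member_sets = {mod: part.members(mod) for mod in selected}
    seen: set[str] = set()
    for mod, members in member_sets.items():
        overlap = seen & set(members)
        if overlap:
            raise ValueError(f"modules share CpGs (e.g. {sorted(overlap)[:5]})")
        seen |= set(members)

    pc_models: dict[int, PCModel] = {}
    blocks, provenance = [], []
    for mod in selected:
        sub = train.subset_cpgs(member_sets[mod])
        pcs = fit_pca(sub)
        pc_models[mod] = pcs
        blocks.append(pcs.scores(sub))
        provenance.extend((mod, k) for k in range(pcs.n_components))
    pooled = np.hstack(blocks)
    enet = fit_cv_enet(pooled, y, alpha=alpha, folds=folds, seed=seed)
    return CompositeModel(
        module_ids=list(selected),
        pc_models=pc_models,
        enet=enet,
        provenance=provenance,
        target_name=target,
    )


def score_composite(model: CompositeModel, m: BetaMatrix) -> np.ndarray:
    """Composite drift score per sample of ``m``.

    Deterministic; invariant to CpG and sample order; requires every selected
    module's CpGs (errors list the module and missing identifiers).
    """
    present = set(m.cpg_ids)
    for mod in model.module_ids:
        missing = [c for c in model.pc_models[mod].cpg_ids if c not in present]
        if missing:
            raise KeyError(
                f"module {mod}: matrix lacks CpGs {missing[:10]}"
                + (f" (+{len(missing) - 10} more)" if len(missing) > 10 else "")
            )
    return model.enet.predict(model.pooled_scores(m))
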