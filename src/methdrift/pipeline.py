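"""End-to-end convenience: from a two-dataset study to a composite model.

Chains the consensus network construction (bicor -> adjacency -> TOM ->
consensus minimum -> tree cut), per-module clock training on the passaging
series, physiological-module selection against held-out in-vitro and in-vivo
data, and the pooled-PC composite fit.  Each step is the public function of
its module; this file only wires them together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .composite import (CompositeModel, ModuleClockSet, fit_composite,
                        fit_module_clocks, select_modules)
from .io import BetaMatrix, SampleSheet, align_to_reference
from .network import (ModulePartition, adjacency, bicor_matrix,
                      cluster_modules, consensus_tom, module_eigengenes, tom)
from .pcclock import select_driver_cpgs, train_pc_clock

__all__ = ["ConsensusResult", "consensus_pipeline", "train_composite_pipeline"]


@dataclass
class ConsensusResult:
    partition: ModulePartition
    linkage: np.ndarray
    eigengenes: object


def consensus_pipeline(
    beta_a: BetaMatrix,
    beta_b: BetaMatrix,
    power: float = 6.0,
    mode: str = "unsigned",
    deep_split: int = 1,
    cut_height: float = 0.95,
    min_cluster_size: int = 50,
) -> ConsensusResult:
    """Consensus modules from two beta matrices over the same CpG universe."""
    if beta_a.cpg_ids != beta_b.cpg_ids:
        raise ValueError("datasets must share an identical CpG universe")
    toms = [
        tom(adjacency(bicor_matrix(b), power=power, mode=mode))
        for b in (beta_a, beta_b)
    ]
    cons = consensus_tom(toms[0], toms[1])
    part, Z = cluster_modules(cons, deep_split=deep_split,
                              cut_height=cut_height,
                              min_cluster_size=min_cluster_size)
    eig = module_eigengenes(beta_a, part) if part.module_ids else None
    return ConsensusResult(partition=part, linkage=Z, eigengenes=eig)


def train_composite_pipeline(
    train: tuple[BetaMatrix, SampleSheet],
    tissue: tuple[BetaMatrix, SampleSheet],
    invitro_eval: tuple[BetaMatrix, SampleSheet],
    invivo_eval: tuple[BetaMatrix, SampleSheet],
    n_drivers: int | None = None,
    r_min: float = 0.5,
    power: float = 6.0,
    alpha: float = 0.5,
    folds: int = 10,
    seed: int = 0,
) -> tuple[ConsensusResult, ModuleClockSet, list[int], CompositeModel]:
    """Full training path: global clock -> driver CpGs -> consensus modules
    -> module clocks -> physiological selection -> pooled composite.

    ``n_drivers`` restricts the consensus universe to the top driver CpGs of
    a global PC clock trained on the passaging series (pass None to run the
    consensus on all CpGs).  Driver restriction keeps the consensus
    calibration quantile inside real comethylation structure in both
    datasets.  Returns all intermediate artifacts.
    """
    train_beta, train_sheet = train
    if n_drivers is not None:
        sheet = train_sheet.aligned_to(train_beta)
        global_clock = train_pc_clock(
            train_beta, sheet["cpd"].to_numpy(dtype=float),
            alpha=alpha, folds=folds, seed=seed)
        drivers = select_driver_cpgs(global_clock, n_drivers)
        train = (align_to_reference(train_beta, drivers), train_sheet)
        tissue = (align_to_reference(tissue[0], drivers), tissue[1])
    consensus = consensus_pipeline(train[0], tissue[0], power=power)
    clocks = fit_module_clocks(train[0], train[1], consensus.partition,
                               target="cpd", alpha=alpha, folds=folds, seed=seed)
    selected = select_modules(clocks, invitro_eval, invivo_eval, r_min=r_min)
    model = fit_composite(train[0], train[1], consensus.partition, selected,
                          target="cpd", alpha=alpha, folds=folds, seed=seed)
    return consensus, clocks, selected, model
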