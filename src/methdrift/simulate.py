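"""Synthetic methylation datasets with planted replication-drift structure.

The generator emulates the two-dataset consensus design the analysis assumes:

* a **passaging series** (in vitro) in which *physiological* modules of CpGs
  drift with cumulative population doublings (cPD) and *artifact* modules
  comethylate under a culture factor that is itself correlated with cPD —
  the precise confound a single-dataset analysis cannot break;
* an **aging-tissue dataset** (in vivo) sharing the CpG universe and the
  physiological loadings (driven by age), in which artifact CpGs are pure
  noise;
* **downstream cohorts** (tumor/normal, survival, multi-tissue) whose group
  structure is driven by a planted latent drift value pushed through the same
  physiological loadings.

All signals live on the M-value (base-2 logit) scale, where latent-factor
models are additive Gaussian; betas are obtained by the logistic transform
beta = 2^M / (2^M + 1).  Each physiological module carries its own latent
factor (shared drift signal plus per-module noise), so distinct modules stay
statistically separable while all correlate with the drift covariate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BetaMatrix, SampleSheet

__all__ = ["SimulationConfig", "GroundTruth", "simulate_passaging",
           "simulate_tissue", "simulate_cohort", "simulate_study"]


def _logit2(b: float) -> float:
    return float(np.log2(b / (1 - b)))


def _expit2(m: np.ndarray) -> np.ndarray:
    p = np.power(2.0, m)
    return p / (p + 1.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for the synthetic datasets.

    Counts and covariate supports mirror the emulated study design: 31
    training and 14 validation passaging samples spanning cPD ~43-75, an
    85-sample tissue series aged 23-83 years.  Effect sizes are on the
    M-value (logit) scale: ``slope`` is drift per population doubling,
    ``age_slope`` drift per year; ``module_sd_*`` set the per-module latent
    noise that keeps the physiological modules distinct; the artifact factor
    correlates with cPD at ``artifact_cpd_corr`` in vitro only.
    """

    n_physio_modules: int = 2
    n_artifact_modules: int = 2
    module_size: int = 60
    n_background: int = 200
    loading_scale: float = 1.0
    noise_sd: float = 0.2
    slope: float = 0.04
    age_slope: float = 0.02
    module_sd_invitro: float = 0.05
    module_sd_tissue: float = 0.35
    artifact_cpd_corr: float = 0.8
    n_train: int = 31
    n_val: int = 14
    n_tissue: int = 85
    cpd_range: tuple[float, float] = (43.0, 75.0)
    age_range: tuple[float, float] = (23.0, 83.0)
    # downstream cohorts
    n_cohort: int = 120
    tumor_shift: float = 8.0          # latent-drift offset of the tumor group
    cohort_age_slope: float = 0.5     # latent drift per year of age in cohorts
    survival_coef: float = 0.64       # log hazard per SD of latent drift
                                      # (magnitude of a ~1.9 hazard ratio)
    baseline_hazard: float = 0.05
    censor_hazard: float = 0.03
    n_tissues: int = 8
    division_slope: float = 1.0       # latent drift per division-rate unit
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_physio_modules, self.n_artifact_modules,
                  self.module_size, self.n_background, self.n_train,
                  self.n_val, self.n_tissue, self.n_cohort)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if not -1 <= self.artifact_cpd_corr <= 1:
            raise ValueError("artifact_cpd_corr must be in [-1, 1]")
        if self.cpd_range[0] >= self.cpd_range[1]:
            raise ValueError("cpd_range must be increasing")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")

    @property
    def n_cpgs(self) -> int:
        n_mod = self.n_physio_modules + self.n_artifact_modules
        return n_mod * self.module_size + self.n_background


@dataclass
class GroundTruth:
    """Planted structure behind a simulated dataset.

    ``cpg_module`` maps each CpG to its module label (0 = background);
    ``module_kind`` tags each module "physio" or "artifact"; ``latent`` is
    the per-sample drift value that drove the emitted dataset.  ``mu`` and
    ``lam`` (baseline and signed loading per CpG, M-value scale) are carried
    so further datasets can share the same CpG universe and loadings.
    """

    cpg_ids: list[str]
    cpg_module: dict[str, int]
    module_kind: dict[int, str]
    mu: np.ndarray
    lam: np.ndarray
    latent: np.ndarray | None = None
    sample_ids: list[str] | None = None

    @property
    def physio_modules(self) -> list[int]:
        return sorted(m for m, k in self.module_kind.items() if k == "physio")

    @property
    def artifact_modules(self) -> list[int]:
        return sorted(m for m, k in self.module_kind.items() if k == "artifact")

    def module_labels(self, cpg_ids: list[str] | None = None) -> np.ndarray:
        ids = cpg_ids if cpg_ids is not None else self.cpg_ids
        return np.array([self.cpg_module[c] for c in ids], dtype=int)


def _build_truth(config: SimulationConfig, rng: np.random.Generator) -> GroundTruth:
    n = config.n_cpgs
    cpg_ids = [f"cg{i:06d}" for i in range(n)]
    labels = np.zeros(n, dtype=int)
    kinds: dict[int, str] = {}
    pos = 0
    label = 1
    for _ in range(config.n_physio_modules):
        labels[pos:pos + config.module_size] = label
        kinds[label] = "physio"
        pos += config.module_size
        label += 1
    for _ in range(config.n_artifact_modules):
        labels[pos:pos + config.module_size] = label
        kinds[label] = "artifact"
        pos += config.module_size
        label += 1
    mu = rng.uniform(_logit2(0.1), _logit2(0.9), size=n)
    signs = rng.choice([-1.0, 1.0], size=n)
    lam = np.where(labels > 0, signs * config.loading_scale, 0.0)
    return GroundTruth(
        cpg_ids=cpg_ids,
        cpg_module={c: int(l) for c, l in zip(cpg_ids, labels)},
        module_kind=kinds,
        mu=mu,
        lam=lam,
    )


def _emit(config: SimulationConfig, truth: GroundTruth,
          factors: dict[int, np.ndarray], n_samples: int,
          rng: np.random.Generator, sample_prefix: str) -> BetaMatrix:
    labels = truth.module_labels()
    M = np.tile(truth.mu[:, None], (1, n_samples))
    for mod, f in factors.items():
        rows = labels == mod
        M[rows] += truth.lam[rows, None] * f[None, :]
    M += rng.normal(0.0, config.noise_sd, size=M.shape)
    sample_ids = [f"{sample_prefix}{i:03d}" for i in range(n_samples)]
    return BetaMatrix(list(truth.cpg_ids), sample_ids, _expit2(M))


def simulate_passaging(
    config: SimulationConfig,
    truth: GroundTruth | None = None,
    n_samples: int | None = None,
    seed: int | None = None,
    sample_prefix: str = "HT",
):
    """Simulate an in-vitro passaging series.

    Each sample draws a cPD uniformly on ``config.cpd_range``.  Physiological
    module m is driven by the factor ``slope * cPD + eta_m`` with per-module
    noise ``module_sd_invitro``; artifact module factors are standard-normal
    draws correlated with cPD at ``artifact_cpd_corr`` and rescaled to the
    drift-signal amplitude, so in this dataset alone they are nearly
    indistinguishable from replication signal.  Pass ``truth`` to reuse the
    CpG universe and loadings of a previous call (e.g. for a held-out
    validation series).

    Returns (BetaMatrix, SampleSheet, GroundTruth).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if truth is None:
        truth = _build_truth(config, rng)
    n = config.n_train if n_samples is None else n_samples
    lo, hi = config.cpd_range
    cpd = rng.uniform(lo, hi, size=n)
    sd_c = (hi - lo) / np.sqrt(12.0)
    z_c = (cpd - (lo + hi) / 2) / sd_c
    amp = config.slope * sd_c
    rho = config.artifact_cpd_corr

    factors: dict[int, np.ndarray] = {}
    drive = config.slope * (cpd - (lo + hi) / 2)  # centered: drift perturbs
    for mod in truth.physio_modules:              # around the CpG baseline
        factors[mod] = drive + rng.normal(0.0, config.module_sd_invitro, size=n)
    for mod in truth.artifact_modules:
        xi = rng.normal(0.0, 1.0, size=n)
        factors[mod] = amp * (rho * z_c + np.sqrt(1 - rho ** 2) * xi)

    beta = _emit(config, truth, factors, n, rng, sample_prefix)
    sheet = SampleSheet(pd.DataFrame({
        "sample_id": beta.sample_ids,
        "cpd": cpd,
        "passage": np.floor(13 + 14 * (cpd - lo) / (hi - lo)).astype(int),
        "tissue": "astrocyte",
    }))
    out_truth = replace_latent(truth, cpd, beta.sample_ids)
    return beta, sheet, out_truth


def simulate_tissue(
    config: SimulationConfig,
    shared_truth: GroundTruth,
    n_samples: int | None = None,
    seed: int | None = None,
    sample_prefix: str = "TS",
):
    """Simulate the aging-tissue consensus partner.

    Same CpG universe and loadings as the passaging series; physiological
    modules are driven by ``age_slope * age + eta_m`` with per-module noise
    ``module_sd_tissue``; artifact CpGs carry no latent factor here (baseline
    plus measurement noise only).  It is this asymmetry that lets the
    consensus step separate physiological replication signal from culture
    artifacts.
    """
    if shared_truth is None:
        raise ValueError("simulate_tissue requires the passaging ground truth")
    rng = np.random.default_rng(
        (config.seed + 1) if seed is None else seed)
    n = config.n_tissue if n_samples is None else n_samples
    lo, hi = config.age_range
    age = rng.uniform(lo, hi, size=n)
    drive = config.age_slope * (age - (lo + hi) / 2)
    factors = {
        mod: drive + rng.normal(0.0, config.module_sd_tissue, size=n)
        for mod in shared_truth.physio_modules
    }
    beta = _emit(config, shared_truth, factors, n, rng, sample_prefix)
    sheet = SampleSheet(pd.DataFrame({
        "sample_id": beta.sample_ids,
        "age": age,
        "tissue": "liver",
    }))
    return beta, sheet, replace_latent(shared_truth, age, beta.sample_ids)


def replace_latent(truth: GroundTruth, latent: np.ndarray,
                   sample_ids: list[str]) -> GroundTruth:
    return GroundTruth(
        cpg_ids=truth.cpg_ids,
        cpg_module=truth.cpg_module,
        module_kind=truth.module_kind,
        mu=truth.mu,
        lam=truth.lam,
        latent=np.asarray(latent, float),
        sample_ids=list(sample_ids),
    )


def _cohort_betas(config: SimulationConfig, truth: GroundTruth,
                  latent: np.ndarray, rng: np.random.Generator,
                  prefix: str) -> BetaMatrix:
    """Physio modules track the latent drift; artifact CpGs are noise."""
    n = len(latent)
    drive = config.slope * (latent - latent.mean())
    factors = {
        mod: drive + rng.normal(0.0, config.module_sd_tissue, size=n)
        for mod in truth.physio_modules
    }
    return _emit(config, truth, factors, n, rng, prefix)


def simulate_cohort(
    kind: str,
    truth: GroundTruth,
    config: SimulationConfig,
    seed: int | None = None,
    shift: float | None = None,
    hazard_coef: float | None = None,
    division_slope: float | None = None,
):
    """Simulate a downstream evaluation cohort keyed to the planted drift.

    kind
        ``tumor_normal`` — two equal groups whose latent drift differs by
        ``shift`` (default ``config.tumor_shift``) on top of an age trend, so
        residualization by age matters;
        ``survival`` — event hazard proportional to exp(b * z(latent)) with
        b = ``hazard_coef`` (default ``config.survival_coef``), exponential
        event and censoring times;
        ``multi_tissue`` — per-tissue latent drift proportional to a division
        -rate covariate with slope ``division_slope``.

    Returns (BetaMatrix, SampleSheet, GroundTruth with the cohort latent).
    """
    rng = np.random.default_rng((config.seed + 2) if seed is None else seed)
    n = config.n_cohort
    if kind == "tumor_normal":
        shift = config.tumor_shift if shift is None else shift
        group = np.array(["normal", "tumor"])[np.arange(n) % 2]
        age = rng.uniform(30.0, 80.0, size=n)
        sex = rng.choice(["F", "M"], size=n)
        latent = (config.cohort_age_slope * age
                  + shift * (group == "tumor")
                  + rng.normal(0.0, 2.0, size=n))
        beta = _cohort_betas(config, truth, latent, rng, "TN")
        sheet = SampleSheet(pd.DataFrame({
            "sample_id": beta.sample_ids, "group": group, "age": age,
            "sex": sex, "tissue": "breast",
        }))
    elif kind == "survival":
        b = config.survival_coef if hazard_coef is None else hazard_coef
        age = rng.uniform(40.0, 80.0, size=n)
        latent = rng.normal(0.0, 5.0, size=n)
        z = (latent - latent.mean()) / latent.std()
        rate = config.baseline_hazard * np.exp(b * z)
        t_event = rng.exponential(1.0 / rate)
        t_cens = rng.exponential(1.0 / config.censor_hazard, size=n)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
        beta = _cohort_betas(config, truth, latent, rng, "SV")
        sheet = SampleSheet(pd.DataFrame({
            "sample_id": beta.sample_ids, "age": age,
            "time": time, "event": event,
        }))
    elif kind == "multi_tissue":
        slope = config.division_slope if division_slope is None else division_slope
        per = max(1, n // config.n_tissues)
        rates = np.linspace(1.0, 10.0, config.n_tissues)
        tissue = np.repeat([f"tissue{i}" for i in range(config.n_tissues)], per)[:n]
        division = np.repeat(rates, per)[:n]
        if len(tissue) < n:  # pad the remainder with the last tissue
            pad = n - len(tissue)
            tissue = np.concatenate([tissue, [tissue[-1]] * pad])
            division = np.concatenate([division, [division[-1]] * pad])
        latent = slope * division + rng.normal(0.0, 1.0, size=n)
        beta = _cohort_betas(config, truth, latent, rng, "MT")
        sheet = SampleSheet(pd.DataFrame({
            "sample_id": beta.sample_ids, "tissue": tissue,
            "division_rate": division,
        }))
    else:
        raise ValueError(f"unknown cohort kind {kind!r}")
    return beta, sheet, replace_latent(truth, latent, beta.sample_ids)


def simulate_study(config: SimulationConfig, seed: int | None = None) -> dict:
    """Generate the full two-dataset study with held-out evaluation sets.

    Returns a dict with keys ``passaging_train``, ``passaging_val``,
    ``tissue``, ``tissue_val`` — each a (BetaMatrix, SampleSheet, GroundTruth)
    triple sharing one CpG universe — plus ``truth`` (the shared structure).
    Sub-seeds are derived deterministically from the one study seed.
    """
    base = config.seed if seed is None else seed
    ss = np.random.SeedSequence(base)
    s_train, s_val, s_tissue, s_tval = [
        int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(4)
    ]
    train = simulate_passaging(config, seed=s_train)
    truth = train[2]
    val = simulate_passaging(config, truth=truth, n_samples=config.n_val,
                             seed=s_val, sample_prefix="HV")
    tissue = simulate_tissue(config, truth, seed=s_tissue)
    tissue_val = simulate_tissue(config, truth, seed=s_tval, sample_prefix="TV")
    return {
        "passaging_train": train,
        "passaging_val": val,
        "tissue": tissue,
        "tissue_val": tissue_val,
        "truth": truth,
    }
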