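"""Model selection and validation: evidence matrix, groups, LOO, specificity,
late-phase predictability.

The 81 wirings are laid out on a 9x9 grid — rows enumerate (Z->W, Z->Na),
columns enumerate (W->Cl, W->Z) with W->Cl major — so the 27 wirings carrying
W->Cl inhibition ("group b") occupy the right-hand three columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dataset import Dataset
from .inference import (
    EvidenceConfig,
    EvidenceResult,
    McmcConfig,
    OptConfig,
    estimate_log_evidence,
    fit_peripherals,
    maximize_log_likelihood,
    posterior_mean_estimate,
    sample_posterior,
)
from .model import CoreParams, ModelTopology, PathwaySign, simulate_grid
from .priors import PriorSet

__all__ = [
    "EvidenceMatrix",
    "LooResult",
    "PredictionResult",
    "evidence_matrix",
    "split_model_groups",
    "matrix_cell",
    "loo_cross_validate",
    "shuffle_condition_labels",
    "specificity_fitness",
    "group_contrast",
    "predictability_test",
    "normalized_rmse",
]


def matrix_cell(topology: ModelTopology) -> tuple[int, int]:
    """(row, col) of a wiring on the 9x9 display grid."""
    row = 3 * int(topology.s_ZtoNa) + int(topology.s_ZtoW)
    col = 3 * int(topology.s_WtoCl) + int(topology.s_WtoZ)
    return row, col


@dataclass
class EvidenceMatrix:
    """9x9 grid of log evidences plus the cell <-> topology bookkeeping."""

    results: dict[int, EvidenceResult] = field(default_factory=dict)
    errors: dict[int, str] = field(default_factory=dict)

    def add(self, topology: ModelTopology, result: EvidenceResult) -> None:
        self.results[topology.index] = result

    def grid(self) -> np.ndarray:
        from .model import topology_from_index

        out = np.full((9, 9), np.nan)
        for idx, res in self.results.items():
            r, c = matrix_cell(topology_from_index(idx))
            out[r, c] = res.log_evidence
        return out

    def log_evidence(self, index: int) -> float:
        return self.results[index].log_evidence

    def to_frame(self):
        import pandas as pd

        from .model import topology_from_index

        rows = []
        for idx in sorted(self.results):
            topo = topology_from_index(idx)
            res = self.results[idx]
            r, c = matrix_cell(topo)
            rows.append(
                {
                    "model_index": idx,
                    "signs": topo.sign_string(),
                    "row": r,
                    "col": c,
                    "group": "b" if topo.in_group_b else "a",
                    "log_evidence": res.log_evidence,
                    "mc_se": res.mc_standard_error,
                }
            )
        return pd.DataFrame(rows)


def evidence_matrix(
    dataset: Dataset,
    priors: PriorSet,
    ev_config: EvidenceConfig | None = None,
    model_subset: list[int] | None = None,
    base_theta: CoreParams | None = None,
) -> EvidenceMatrix:
    """Log evidence per topology; per-cell failures are recorded, not fatal."""
    from .model import enumerate_topologies, topology_from_index

    ev_config = ev_config or EvidenceConfig()
    topologies = (
        [topology_from_index(i) for i in model_subset]
        if model_subset is not None
        else enumerate_topologies()
    )
    matrix = EvidenceMatrix()
    for topo in topologies:
        cfg = EvidenceConfig(**{**ev_config.__dict__, "seed": ev_config.seed + topo.index})
        try:
            matrix.add(topo, estimate_log_evidence(dataset, topo, priors, cfg,
                                                   base_theta=base_theta))
        except Exception as exc:  # record and continue with remaining cells
            matrix.errors[topo.index] = f"{type(exc).__name__}: {exc}"
    return matrix


def split_model_groups(matrix: EvidenceMatrix | None = None) -> tuple[list[int], list[int]]:
    """(group_a, group_b) indices; b = wirings with W->Cl inhibition."""
    from .model import enumerate_topologies

    group_a, group_b = [], []
    for topo in enumerate_topologies():
        (group_b if topo.in_group_b else group_a).append(topo.index)
    return group_a, group_b


@dataclass
class LooResult:
    topology_index: int
    theta_per_fold: list[CoreParams]
    phi_per_fold: list
    heldout_avg_loglik: list[float]

    @property
    def n_folds(self) -> int:
        return len(self.theta_per_fold)


def loo_cross_validate(
    dataset: Dataset,
    topology: ModelTopology,
    priors: PriorSet,
    fit_mode: str = "fast_optimize",
    opt_config: OptConfig | None = None,
    mcmc_config: McmcConfig | None = None,
    base_theta: CoreParams | None = None,
) -> LooResult:
    """Leave-one-out: core trained on all-but-i, phi_i and fitness on series i.

    Held-out fitness is the log likelihood of the left-out series divided by
    its point count.  Folds are independent given the seed.
    """
    if len(dataset) < 2:
        raise ValueError("LOO needs at least 2 series")
    if fit_mode not in ("fast_optimize", "mcmc"):
        raise ValueError(f"unknown fit_mode {fit_mode!r}")
    thetas, phis, fitness = [], [], []
    for i in range(len(dataset)):
        train, test = dataset.leave_one_out(i)
        if fit_mode == "fast_optimize":
            cfg = opt_config or OptConfig()
            fit = maximize_log_likelihood(train, topology, priors, cfg,
                                          base_theta=base_theta)
            theta_i = fit.theta_est
        else:
            cfg = mcmc_config or McmcConfig()
            chain = sample_posterior(train, topology, priors, cfg, base_theta=base_theta)
            theta_i, _ = posterior_mean_estimate(chain)
        phi_i, ll = fit_peripherals(
            test.series[0], test.conditions[0], topology, theta_i, priors
        )
        thetas.append(theta_i)
        phis.append(phi_i)
        fitness.append(ll / test.series[0].T_i)
    return LooResult(topology.index, thetas, phis, fitness)


def shuffle_condition_labels(dataset: Dataset, seed: int) -> Dataset:
    """Permute condition assignments across series; values untouched."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(dataset))
    return Dataset(
        series=[s.replace() for s in dataset.series],
        conditions=[dataset.conditions[j] for j in perm],
        description=dataset.description + f" [labels shuffled, seed {seed}]",
    )


def specificity_fitness(
    test_dataset: Dataset,
    theta_fixed: dict[int, CoreParams] | CoreParams,
    topologies: list[ModelTopology],
    priors: PriorSet,
) -> dict[int, float]:
    """Average log likelihood per point with the core frozen, phi_i refit.

    theta_fixed may be a single CoreParams applied to every topology or a map
    from topology index to its own frozen core.
    """
    out = {}
    for topo in topologies:
        theta = theta_fixed[topo.index] if isinstance(theta_fixed, dict) else theta_fixed
        total_ll = 0.0
        total_T = 0
        for series, cond in test_dataset:
            _, ll = fit_peripherals(series, cond, topo, theta, priors)
            total_ll += ll
            total_T += series.T_i
        out[topo.index] = total_ll / total_T
    return out


def group_contrast(fitness: dict[int, float]) -> float:
    """mean(group-b fitness) - mean(group-a fitness) over the scored models."""
    from .model import topology_from_index

    a_vals = [v for i, v in fitness.items() if not topology_from_index(i).in_group_b]
    b_vals = [v for i, v in fitness.items() if topology_from_index(i).in_group_b]
    if not a_vals or not b_vals:
        raise ValueError("need fitness values in both model groups")
    return float(np.mean(b_vals) - np.mean(a_vals))


@dataclass
class PredictionResult:
    topology_index: int
    split_s: int
    horizon_s: int
    late_loglik_per_point: list[float]
    normalized_rmses: list[float]
    predicted: list[np.ndarray]
    skipped: list[int] = field(default_factory=list)


def normalized_rmse(observed: np.ndarray, predicted: np.ndarray) -> float:
    """RMSE divided by the s.d. of the observed segment; 1 = mean predictor."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or len(observed) < 2:
        raise ValueError("observed and predicted must have equal length >= 2")
    sd = np.std(observed)
    if sd == 0:
        raise ZeroDivisionError("observed late phase has zero s.d.; normalization undefined")
    return float(np.sqrt(np.mean((observed - predicted) ** 2)) / sd)


def predictability_test(
    dataset: Dataset,
    topology: ModelTopology,
    priors: PriorSet,
    split_s: int = 250,
    horizon_s: int = 800,
    opt_config: OptConfig | None = None,
    theta_per_fold: list[CoreParams] | None = None,
    base_theta: CoreParams | None = None,
) -> PredictionResult:
    """Forecast the late phase from peripherals trained on the initial phase.

    Per fold: core from the other series (full length), phi_i from series i
    restricted to t <= split_s, then forward simulation to horizon_s scored on
    (split_s, horizon] by average log likelihood and normalized RMSE.
    Precomputed per-fold cores can be passed to share them across topologies.
    """
    lls, rmses, preds, skipped = [], [], [], []
    for i in range(len(dataset)):
        series, cond = dataset.series[i], dataset.conditions[i]
        if series.T_i <= split_s + 1:
            skipped.append(i)
            continue
        if theta_per_fold is not None:
            theta_i = theta_per_fold[i]
        else:
            train, _ = dataset.leave_one_out(i)
            fit = maximize_log_likelihood(train, topology, priors,
                                          opt_config or OptConfig(),
                                          base_theta=base_theta)
            theta_i = fit.theta_est
        early = series.replace(values=series.values[: split_s + 1])
        phi_i, _ = fit_peripherals(early, cond, topology, theta_i, priors)
        T_end = min(series.T_i - 1, horizon_s)
        cl, na = simulate_grid(
            topology, theta_i,
            np.array([phi_i.tau_S]),
            np.array([cond.effective_smax]),
            np.array([float(cond.pkg_active)]),
            T_end,
            A_Z=np.array([phi_i.A_Z]), A_W=np.array([phi_i.A_W]),
        )
        v_hat = (
            phi_i.V_K
            - cond.eta_Cl * phi_i.A_Cl * cl[0]
            + cond.eta_Na * phi_i.A_Na * na[0]
        )
        late = slice(split_s + 1, T_end + 1)
        obs = series.values[late]
        pred = v_hat[late]
        s = series.sigma_i
        ll = float(-len(obs) * (0.5 * math.log(2 * math.pi) + math.log(s))
                   - 0.5 * np.sum(((obs - pred) / s) ** 2))
        lls.append(ll / len(obs))
        rmses.append(normalized_rmse(obs, pred))
        preds.append(v_hat)
    return PredictionResult(topology.index, split_s, horizon_s, lls, rmses, preds, skipped)
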