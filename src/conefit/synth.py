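"""Synthetic datasets emulating the study design of the original recordings.

The real recordings are not public, so analyses run against generated
datasets with the same structure: a 10 uM stimulant arm of 16 series
(control n=7, chloride-blocked n=5, sodium-blocked n=4), a 5 uM arm (2/5/4),
a PKG-inhibited arm, and a "different core" arm driven by an unrelated wiring
(netrin-like), each with spike, step and white observation noise injected at
the raw sampling rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import Dataset, condition_from_label
from .model import (
    ConditionParams,
    CoreParams,
    ModelTopology,
    PathwaySign,
    PeripheralParams,
    _hill,
    _sat,
    simulate_mpts,
)
from .preprocess import RawTrace, StepArtifact, preprocess_trace
from .priors import TruncatedNormalPrior

__all__ = [
    "DEFAULT_DESIGN_10UM",
    "DEFAULT_DESIGN_5UM",
    "RAW_RATE_HZ",
    "NoiseSpec",
    "PopulationSpec",
    "SyntheticDatasetSpec",
    "GeneratedDataset",
    "generate_dataset",
    "generate_alternative_dataset",
    "inject_artifacts",
    "default_generating_topology",
    "default_generating_core",
    "population_matched_priors",
]

RAW_RATE_HZ = 10.0

DEFAULT_DESIGN_10UM = (("control", 7), ("DNDS", 5), ("STX", 4))
DEFAULT_DESIGN_5UM = (("control", 2), ("DNDS", 5), ("STX", 4))


def default_generating_topology() -> ModelTopology:
    """M_7: the chloride channel is inhibited by the PKG arm, nothing else."""
    return ModelTopology(s_WtoCl=PathwaySign.INHIBITION)


def default_generating_core() -> CoreParams:
    return CoreParams(
        K_X=1.15, n_X=4.0, K_Y=16.61, n_Y=2.0,
        g_WtoCl=1.5, A_Cl0=10.0, A_Na0=10.0,
    )


@dataclass(frozen=True)
class NoiseSpec:
    white_sd: float = 2.0          # mV, Gaussian per raw sample
    spike_rate: float = 0.02       # events per second (Poisson)
    spike_amplitude: float = 40.0  # mV, single-sample
    step_probability: float = 0.3  # per series
    step_amplitude: float = 12.0   # mV
    step_duration: float = 60.0    # s before the offset reverts

    def is_zero(self) -> bool:
        return self.white_sd == 0 and self.spike_rate == 0 and self.step_probability == 0


@dataclass(frozen=True)
class PopulationSpec:
    """Cell-to-cell variability: truncated-normal draws around hyper-means."""

    V_K: TruncatedNormalPrior = TruncatedNormalPrior(-75.0, 3.0, -np.inf)
    tau_S: TruncatedNormalPrior = TruncatedNormalPrior(30.0, 8.0, 5.0)
    A_Cl: TruncatedNormalPrior = TruncatedNormalPrior(10.0, 2.0, 1.0)
    A_Na: TruncatedNormalPrior = TruncatedNormalPrior(10.0, 2.0, 1.0)

    def draw(self, rng: np.random.Generator, A_Z: float, A_W: float) -> PeripheralParams:
        return PeripheralParams(
            V_K=float(self.V_K.rvs(1, rng)[0]),
            tau_S=float(self.tau_S.rvs(1, rng)[0]),
            A_Cl=float(self.A_Cl.rvs(1, rng)[0]),
            A_Na=float(self.A_Na.rvs(1, rng)[0]),
            A_Z=A_Z,
            A_W=A_W,
        )


def population_matched_priors(population: "PopulationSpec | None" = None):
    """Default priors with peripheral entries equal to the generating
    population law — the hierarchical model's self-consistency condition for
    recovery studies (a cell's amplitude prior *is* its population
    distribution)."""
    from .priors import default_priors

    population = population or PopulationSpec()
    priors = default_priors()
    priors["V_K"] = population.V_K
    priors["tau_S"] = population.tau_S
    priors["A_Cl"] = population.A_Cl
    priors["A_Na"] = population.A_Na
    priors.validate()
    return priors


@dataclass
class SyntheticDatasetSpec:
    design: tuple = DEFAULT_DESIGN_10UM
    stimulant_uM: float = 10.0
    topology: ModelTopology = field(default_factory=default_generating_topology)
    theta: CoreParams = field(default_factory=default_generating_core)
    population: PopulationSpec = field(default_factory=PopulationSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    series_length_s: int = 600
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for _, n in self.design):
            raise ValueError("design counts must be >= 0")
        if not 300 <= self.series_length_s <= 900:
            raise ValueError("series_length_s must be within [300, 900]")


@dataclass
class GeneratedDataset:
    """Preprocessed dataset plus everything needed to recompute the truth."""

    dataset: Dataset
    raw_traces: list[RawTrace]
    clean_values: list[np.ndarray]       # noiseless V on the 1 s grid
    phi_true: list[PeripheralParams]
    theta_true: CoreParams
    topology: ModelTopology
    artifact_log: list[list[StepArtifact]]
    spec: SyntheticDatasetSpec


def inject_artifacts(
    clean: RawTrace,
    noise: NoiseSpec,
    seed: int | np.random.Generator,
) -> tuple[RawTrace, list[StepArtifact]]:
    """Add spike, step and white noise at the raw rate; log injected steps.

    Step windows are reported in 1 s grid indices so they can double as
    annotations for the preprocessing stage.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v = clean.values.copy()
    t = clean.times
    duration = t[-1] - t[0]
    steps: list[StepArtifact] = []

    if noise.spike_rate > 0:
        n_spikes = rng.poisson(noise.spike_rate * duration)
        if n_spikes:
            # single-sample spikes land strictly between grid seconds: the
            # 1 s decimation removes them by construction, which is the
            # premise the preprocessing stage relies on
            off_grid = np.flatnonzero(np.abs(t - np.round(t)) > 1e-9)
            idx = rng.choice(off_grid, size=min(n_spikes, len(off_grid)), replace=False)
            sign = rng.choice([-1.0, 1.0], len(idx))
            v[idx] += sign * noise.spike_amplitude

    if noise.step_probability > 0 and rng.random() < noise.step_probability:
        onset_s = float(rng.uniform(0.1 * duration, 0.7 * duration))
        height = float(rng.choice([-1.0, 1.0]) * noise.step_amplitude)
        end_s = min(onset_s + noise.step_duration, duration)
        mask = (t >= onset_s) & (t < end_s)
        v[mask] += height
        # each level transition gets its own short annotation window; the
        # offset region between the two is then repaired automatically by the
        # tail-shift of the first correction
        last = int(np.floor(t[-1]))
        o1 = int(np.floor(onset_s))
        steps.append(StepArtifact(o1, min(o1 + 1, last), offset=height))
        if end_s < duration:
            o2 = int(np.floor(end_s))
            if o2 > o1 + 1:
                steps.append(StepArtifact(o2, min(o2 + 1, last), offset=-height))

    if noise.white_sd > 0:
        v += rng.normal(0.0, noise.white_sd, len(v))

    return RawTrace(times=t, values=v, series_id=clean.series_id,
                    condition_label=clean.condition_label), steps


def _clean_raw_from_grid(v_grid: np.ndarray, T: int, sid: str, label: str) -> RawTrace:
    raw_t = np.arange(0.0, T + 1e-9, 1.0 / RAW_RATE_HZ)
    grid_t = np.arange(len(v_grid), dtype=float)
    return RawTrace(times=raw_t, values=np.interp(raw_t, grid_t, v_grid),
                    series_id=sid, condition_label=label)


def _build(spec: SyntheticDatasetSpec, simulate, condition_of, theta_truth,
           prefix: str, description: str) -> GeneratedDataset:
    """Common generation loop: draw phi, simulate clean, inject noise, preprocess."""
    rng = np.random.default_rng(spec.seed)
    series, conds, raws, cleans, phis, art_log = [], [], [], [], [], []
    k = 0
    for label, count in spec.design:
        for _ in range(count):
            sid = f"{prefix}{label}_{k:02d}"
            cond = condition_of(label)
            phi = spec.population.draw(rng, theta_truth.A_Z0, theta_truth.A_W0)
            v_grid = simulate(phi, cond)
            raw_clean = _clean_raw_from_grid(v_grid, spec.series_length_s, sid, label)
            raw, steps = inject_artifacts(raw_clean, spec.noise, rng)
            processed = preprocess_trace(raw, annotations=steps or None,
                                         auto_detect_steps=not steps)
            if spec.noise.is_zero():
                # keep sigma positive so the Gaussian likelihood stays defined
                processed = processed.replace(sigma_i=max(processed.sigma_i, 1e-6))
            series.append(processed)
            conds.append(cond)
            raws.append(raw)
            cleans.append(v_grid[: processed.T_i].copy())
            phis.append(phi)
            art_log.append(steps)
            k += 1
    ds = Dataset(series=series, conditions=conds, description=description)
    return GeneratedDataset(ds, raws, cleans, phis, theta_truth, spec.topology,
                            art_log, spec)


def generate_dataset(spec: SyntheticDatasetSpec) -> GeneratedDataset:
    """Simulate the study design; deterministic for a given spec.seed."""

    def simulate(phi, cond):
        return simulate_mpts(spec.topology, spec.theta, phi, cond,
                             spec.series_length_s).V_hat

    return _build(
        spec, simulate,
        lambda label: condition_from_label(label, S_max=spec.stimulant_uM),
        spec.theta, "",
        f"synthetic {spec.stimulant_uM} uM, seed {spec.seed}",
    )


def _simulate_alt_core(theta: CoreParams, phi: PeripheralParams,
                       cond: ConditionParams, T: int) -> np.ndarray:
    """Different core system: both channels driven by the X arm; no W pathway.

    Two first-order factors relax toward A_Z*X and A_W*X (forward Euler at
    1 s, well inside stability for these rates); chloride follows the first,
    sodium the second.  Shares only the stimulus/readout plumbing with the
    candidate wirings.
    """
    times = np.arange(0.0, T + 0.5, 1.0)
    S = cond.effective_smax * (1.0 - np.exp(-times / phi.tau_S))
    X = _hill(S, theta.K_X, theta.n_X)
    Z = np.zeros_like(times)
    Q = np.zeros_like(times)
    for j in range(1, len(times)):
        Z[j] = Z[j - 1] + theta.k_Z * (phi.A_Z * X[j - 1] - Z[j - 1])
        Q[j] = Q[j - 1] + theta.k_W * (phi.A_W * X[j - 1] - Q[j - 1])
    return (
        phi.V_K
        - cond.eta_Cl * phi.A_Cl * _sat(Z)
        + cond.eta_Na * phi.A_Na * _sat(Q)
    )


def generate_alternative_dataset(spec: SyntheticDatasetSpec, mode: str) -> GeneratedDataset:
    """Datasets from outside the trained core system.

    mode='pkg_inhibited': same wiring but PKG off in every condition (KT5823).
    mode='different_core': netrin-like system where both channels hang off the
    X arm, so the candidate wirings' group structure carries no information.
    """
    if mode == "pkg_inhibited":

        def condition_of(label):
            return condition_from_label(label, S_max=spec.stimulant_uM).replace(pkg_active=0)

        def simulate(phi, cond):
            return simulate_mpts(spec.topology, spec.theta, phi, cond,
                                 spec.series_length_s).V_hat

        return _build(spec, simulate, condition_of, spec.theta, "kt_",
                      f"synthetic PKG-inhibited, seed {spec.seed}")

    if mode == "different_core":
        alt_theta = spec.theta.replace(K_X=2.0, n_X=2.0, k_Z=0.15, k_W=0.01)

        def simulate(phi, cond):
            return _simulate_alt_core(alt_theta, phi, cond, spec.series_length_s)

        return _build(
            spec, simulate,
            lambda label: condition_from_label(label, S_max=spec.stimulant_uM),
            alt_theta, "alt_",
            f"synthetic different-core (netrin-like), seed {spec.seed}",
        )

    raise ValueError(f"unknown mode {mode!r}")
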