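"""The six validation experiments for the DNS and DNES indices.

Experiments 1-4 sweep one controlled variable per replicate (phase offset
delta_phi, amplitude ratio lam, structural noise power alpha, strength
scale beta) with the other three held at neutral values, simulate a fresh
network pair, and summarize the resulting (variable, index) scatter with
a Pearson correlation, its p-value and the residual sum of squares of the
ordinary-least-squares line.  Experiments 5-6 perturb a copy of network 1
directly (additive Gaussian noise of standard deviation sigma; random
permutation of a fraction gamma of the timepoints).

Default replicate counts are 200 for experiments 1-4 and 1000 for 5-6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .indices import dnes, dns
from .simulate import (
    SimulationSpec,
    add_edge_noise,
    make_network_pair,
    shuffle_timepoints,
)

__all__ = [
    "ExperimentResult",
    "DegenerateFitError",
    "FEATURE_SWEEPS",
    "run_feature_experiment",
    "run_general_experiment",
    "run_experiment",
    "correlation_and_rss",
    "binned_means",
]

#: swept variable and its range per feature experiment
FEATURE_SWEEPS: dict[int, tuple[str, tuple[float, float]]] = {
    1: ("delta_phi", (0.0, math.pi)),
    2: ("lam", (0.05, 1.0)),
    3: ("alpha", (0.0, 0.5)),
    4: ("beta", (0.1, 1.0)),
}

GENERAL_SWEEPS: dict[int, tuple[str, tuple[float, float]]] = {
    5: ("sigma", (0.01, 10.0)),
    6: ("gamma", (0.0, 1.0)),
}


class DegenerateFitError(ValueError):
    """Raised when a correlation/regression summary is undefined."""


def correlation_and_rss(x, y) -> tuple[float, float, float]:
    """Pearson r with two-sided p, and the RSS of the OLS fit of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise DegenerateFitError("need at least 3 samples")
    if np.std(x) < 1e-12 or np.std(y) < 1e-12:
        raise DegenerateFitError("constant variable or index value")
    r, p = stats.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return float(r), float(p), float(resid @ resid)


@dataclass
class ExperimentResult:
    """Per-replicate samples plus correlation and RSS summaries."""

    experiment_id: int
    variable_name: str
    noise_power: float
    seed: int | None
    variable: np.ndarray
    dns_values: np.ndarray
    dnes_values: np.ndarray
    r_dns: float = float("nan")
    p_dns: float = float("nan")
    rss_dns: float = float("nan")
    r_dnes: float = float("nan")
    p_dnes: float = float("nan")
    rss_dnes: float = float("nan")

    def summarize(self) -> "ExperimentResult":
        # a degenerate sweep (e.g. a single fixed sigma) leaves NaN summaries
        try:
            self.r_dns, self.p_dns, self.rss_dns = correlation_and_rss(
                self.variable, self.dns_values
            )
            self.r_dnes, self.p_dnes, self.rss_dnes = correlation_and_rss(
                self.variable, self.dnes_values
            )
        except DegenerateFitError:
            pass
        return self

    @property
    def n_reps(self) -> int:
        return self.variable.size

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                self.variable_name: self.variable,
                "dns": self.dns_values,
                "dnes": self.dnes_values,
            }
        )

    def summary_dict(self) -> dict:
        return {
            "experiment_id": self.experiment_id,
            "variable_name": self.variable_name,
            "noise_power": self.noise_power,
            "seed": self.seed,
            "n_reps": self.n_reps,
            "r_dns": self.r_dns,
            "p_dns": self.p_dns,
            "rss_dns": self.rss_dns,
            "r_dnes": self.r_dnes,
            "p_dnes": self.p_dnes,
            "rss_dnes": self.rss_dnes,
        }


def _base_spec(noise_power: float, seed: int, **overrides) -> SimulationSpec:
    return SimulationSpec(noise_power=noise_power, seed=seed, **overrides)


def run_feature_experiment(
    experiment_id: int,
    noise_power: float = 0.001,
    n_reps: int = 200,
    seed: int | None = None,
    n_nodes: int = 10,
    n_timepoints: int = 10,
) -> ExperimentResult:
    """Run one of the four feature-sensitivity sweeps (experiments 1-4).

    Each replicate draws the swept variable uniformly from its range,
    simulates a fresh pair with the other variables neutral, and records
    DNS and DNES.
    """
    if experiment_id not in FEATURE_SWEEPS:
        raise ValueError(f"feature experiment id must be 1-4, got {experiment_id}")
    if n_reps < 3:
        raise DegenerateFitError("need at least 3 replicates for the correlation summary")
    var_name, (lo, hi) = FEATURE_SWEEPS[experiment_id]
    ss = np.random.SeedSequence(seed)
    sweep_rng = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = ss.generate_state(n_reps)

    values = sweep_rng.uniform(lo, hi, size=n_reps)
    dns_vals = np.empty(n_reps)
    dnes_vals = np.empty(n_reps)
    for k in range(n_reps):
        spec = _base_spec(
            noise_power,
            int(child_seeds[k]),
            n_nodes=n_nodes,
            n_timepoints=n_timepoints,
            **{var_name: float(values[k])},
        )
        pair = make_network_pair(spec)
        dns_vals[k] = dns(pair.net1, pair.net2).value
        dnes_vals[k] = dnes(pair.net1, pair.net2).value
    return ExperimentResult(
        experiment_id=experiment_id,
        variable_name=var_name,
        noise_power=noise_power,
        seed=seed,
        variable=values,
        dns_values=dns_vals,
        dnes_values=dnes_vals,
    ).summarize()


def run_general_experiment(
    experiment_id: int,
    n_reps: int = 1000,
    seed: int | None = None,
    sweep_range: tuple[float, float] | None = None,
    n_nodes: int = 10,
    n_timepoints: int = 10,
) -> ExperimentResult:
    """Run experiment 5 (noise randomization) or 6 (timing shuffle).

    Per replicate, network 2 is a perturbed copy of network 1: experiment 5
    superimposes N(0, sigma^2) edge noise with sigma drawn log-uniformly
    from ``sweep_range`` (default 0.01..10); experiment 6 permutes a
    uniformly drawn fraction gamma of the timepoints.  No observation
    noise is added, so the perturbation is the only difference.
    """
    if experiment_id not in GENERAL_SWEEPS:
        raise ValueError(f"general experiment id must be 5 or 6, got {experiment_id}")
    if n_reps < 3:
        raise DegenerateFitError("need at least 3 replicates for the correlation summary")
    var_name, default_range = GENERAL_SWEEPS[experiment_id]
    lo, hi = sweep_range if sweep_range is not None else default_range
    ss = np.random.SeedSequence(seed)
    sweep_rng = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = ss.generate_state(n_reps)

    if experiment_id == 5:
        if lo <= 0:
            raise ValueError("sigma sweep must be positive for the log grid")
        values = np.exp(sweep_rng.uniform(math.log(lo), math.log(hi), size=n_reps))
    else:
        values = sweep_rng.uniform(lo, hi, size=n_reps)

    dns_vals = np.empty(n_reps)
    dnes_vals = np.empty(n_reps)
    for k in range(n_reps):
        rng = np.random.default_rng(int(child_seeds[k]))
        spec = SimulationSpec(
            n_nodes=n_nodes, n_timepoints=n_timepoints, seed=int(child_seeds[k])
        )
        net1 = make_network_pair(spec).net1
        if experiment_id == 5:
            net2 = add_edge_noise(net1, float(values[k]), rng)
        else:
            net2 = shuffle_timepoints(net1, float(values[k]), rng)
        dns_vals[k] = dns(net1, net2).value
        dnes_vals[k] = dnes(net1, net2).value
    return ExperimentResult(
        experiment_id=experiment_id,
        variable_name=var_name,
        noise_power=0.0,
        seed=seed,
        variable=values,
        dns_values=dns_vals,
        dnes_values=dnes_vals,
    ).summarize()


def run_experiment(experiment_id: int, **kwargs) -> ExperimentResult:
    """Dispatch any of experiments 1-6 by id."""
    if experiment_id in FEATURE_SWEEPS:
        return run_feature_experiment(experiment_id, **kwargs)
    return run_general_experiment(experiment_id, **kwargs)


def binned_means(x, y, n_bins: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Mean of y per equal-width bin of x (empty bins dropped)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    centers, means = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.any():
            centers.append(0.5 * (edges[b] + edges[b + 1]))
            means.append(y[mask].mean())
    return np.array(centers), np.array(means)
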