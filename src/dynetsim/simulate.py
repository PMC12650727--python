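"""Controlled-variable simulator for pairs of dynamic weighted networks.

Each edge of a simulated network follows

    F_i(t) = F_i(0) + a_i * sin(t + phi_i) + eps_{i,t},   t = 0 .. T-1

with an initial strength ``F_i(0)``, a sine evolution of per-edge amplitude
``a_i`` and phase ``phi_i``, and i.i.d. zero-mean Gaussian observation noise
``eps`` of power (variance) ``noise_power``.  A network *pair* shares the
initial structure and evolution parameters, with four controlled deviations
applied to the second network:

* ``delta_phi`` — phase offset added to every edge (evolutionary trend);
* ``lam``       — amplitude ratio, ``a_2i = a_1i / lam`` (relative amplitude);
* ``alpha``     — power of zero-mean Gaussian noise perturbing the second
  network's initial structure (structural topology);
* ``beta``      — multiplicative scale on the second network's initial
  strengths (connectivity strength span).

With all four at their neutral values (0, 1, 0, 1) and no observation
noise, the two networks are bit-identical.

Initial weights are uniform on ``init_weight_range`` (default [0.5, 1.5],
mean squared weight ~= 1.08, keeping the edge power around 1 as required
by the 10/20/30 dB SNR mapping for noise powers 0.1/0.01/0.001).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .core import DynamicNetwork, edge_index_pairs

__all__ = [
    "SimulationSpec",
    "NetworkPair",
    "generate_initial_structure",
    "evolve",
    "make_network_pair",
    "shuffle_timepoints",
    "add_edge_noise",
    "snr_db",
]


@dataclass
class SimulationSpec:
    """All parameters of one simulated network pair."""

    n_nodes: int = 10
    n_timepoints: int = 10
    delta_phi: float = 0.0
    lam: float = 1.0
    alpha: float = 0.0
    beta: float = 1.0
    noise_power: float = 0.0
    base_amplitude_range: tuple[float, float] = (0.2, 0.5)
    base_phase_range: tuple[float, float] = (0.0, 2.0 * math.pi)
    init_weight_range: tuple[float, float] = (0.5, 1.5)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        if self.n_timepoints < 1:
            raise ValueError("need at least 1 timepoint")
        if not 0.0 < self.lam <= 1.0 + 1e-12:
            raise ValueError(f"lam must lie in (0, 1], got {self.lam}")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.noise_power < 0:
            raise ValueError("noise_power must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def n_edges(self) -> int:
        return self.n_nodes * (self.n_nodes - 1) // 2


@dataclass
class NetworkPair:
    net1: DynamicNetwork
    net2: DynamicNetwork
    spec: SimulationSpec


def snr_db(noise_power: float, signal_power: float = 1.0) -> float:
    """SNR = 10 log10(P_S / P_N) in decibels."""
    if noise_power <= 0:
        return math.inf
    return 10.0 * math.log10(signal_power / noise_power)


def _edges_to_matrix(edge_values: np.ndarray, n: int) -> np.ndarray:
    iu, ju = edge_index_pairs(n)
    mat = np.zeros((n, n))
    mat[iu, ju] = edge_values
    mat[ju, iu] = edge_values
    return mat


def generate_initial_structure(spec: SimulationSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Random symmetric zero-diagonal initial weight matrix.

    Every edge weight is drawn independently and uniformly from
    ``spec.init_weight_range``, so the mean squared weight is close to 1.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    lo, hi = spec.init_weight_range
    edge_values = rng.uniform(lo, hi, size=spec.n_edges)
    return _edges_to_matrix(edge_values, spec.n_nodes)


def evolve(
    initial: np.ndarray,
    amplitudes: np.ndarray,
    phases: np.ndarray,
    T: int,
    noise_power: float = 0.0,
    rng: np.random.Generator | None = None,
) -> DynamicNetwork:
    """Run the sine evolution forward from ``initial`` for ``T`` timepoints.

    ``amplitudes`` and ``phases`` are per-edge arrays of length m in the
    canonical upper-triangle order; time takes integer values 0..T-1.
    """
    if noise_power < 0:
        raise ValueError("noise_power must be >= 0")
    initial = np.asarray(initial, dtype=float)
    n = initial.shape[0]
    iu, ju = edge_index_pairs(n)
    f0 = initial[iu, ju]
    m = f0.size
    amplitudes = np.broadcast_to(np.asarray(amplitudes, dtype=float), (m,))
    phases = np.broadcast_to(np.asarray(phases, dtype=float), (m,))
    t = np.arange(T, dtype=float)[:, None]
    series = f0[None, :] + amplitudes[None, :] * np.sin(t + phases[None, :])
    if noise_power > 0:
        if rng is None:
            rng = np.random.default_rng()
        series = series + rng.normal(0.0, math.sqrt(noise_power), size=series.shape)
    weights = np.zeros((T, n, n))
    weights[:, iu, ju] = series
    weights[:, ju, iu] = series
    return DynamicNetwork(weights)


def make_network_pair(spec: SimulationSpec) -> NetworkPair:
    """Simulate two dynamic networks sharing structure and evolution.

    Network 1 uses the initial structure S and parameters (a_1i, phi_1i);
    network 2 uses initial ``beta * (S + eta)`` with ``eta`` symmetrized
    zero-mean Gaussian noise of power ``alpha``, amplitudes
    ``a_2i = a_1i / lam`` and phases ``phi_2i = phi_1i + delta_phi``.
    Observation noise is drawn independently for the two networks.
    """
    rng = np.random.default_rng(spec.seed)
    s = generate_initial_structure(spec, rng)
    a1 = rng.uniform(*spec.base_amplitude_range, size=spec.n_edges)
    phi1 = rng.uniform(*spec.base_phase_range, size=spec.n_edges)

    init2 = s.copy()
    if spec.alpha > 0:
        eta = rng.normal(0.0, math.sqrt(spec.alpha), size=s.shape)
        eta = 0.5 * (eta + eta.T)
        np.fill_diagonal(eta, 0.0)
        init2 = init2 + eta
    init2 = spec.beta * init2

    net1 = evolve(s, a1, phi1, spec.n_timepoints, spec.noise_power, rng)
    net2 = evolve(
        init2, a1 / spec.lam, phi1 + spec.delta_phi, spec.n_timepoints, spec.noise_power, rng
    )
    return NetworkPair(net1=net1, net2=net2, spec=spec)


def shuffle_timepoints(
    net: DynamicNetwork, gamma: float, rng: np.random.Generator | int | None = None
) -> DynamicNetwork:
    """Randomly permute a fraction ``gamma`` of the timepoints.

    ``floor(gamma * T)`` timepoints are chosen uniformly without
    replacement and permuted among themselves; the rest keep their slots.
    The multiset of snapshots is conserved.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must lie in [0, 1], got {gamma}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    T = net.n_timepoints
    k = int(math.floor(gamma * T))
    order = np.arange(T)
    if k >= 2:
        chosen = np.sort(rng.choice(T, size=k, replace=False))
        order[chosen] = chosen[rng.permutation(k)]
    return net.with_weights(net.weights[order])


def add_edge_noise(
    net: DynamicNetwork, sigma: float, rng: np.random.Generator | int | None = None
) -> DynamicNetwork:
    """Superimpose i.i.d. N(0, sigma^2) noise on every edge at every timepoint."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    iu, ju = edge_index_pairs(net.n_nodes)
    weights = net.weights.copy()
    noise = rng.normal(0.0, sigma, size=(net.n_timepoints, iu.size))
    weights[:, iu, ju] += noise
    weights[:, ju, iu] += noise
    return net.with_weights(weights)
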