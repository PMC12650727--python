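"""Similarity indices for dynamic and static weighted networks.

Two indices operate on whole dynamic networks:

* **DNS** — Pearson correlation of the two long vectors, multiplied by the
  min/max ratio of their standard deviations, affinely mapped to [0, 1].
  Sensitive to both structural configuration and temporal evolution.
* **DNES** — the same correlation-times-SD-ratio similarity computed per
  corresponding edge time series, averaged over edges, mapped to [0, 1].
  By construction insensitive to purely structural differences.

Four traditional snapshot comparators (Dice, Jaccard, normalized-Laplacian
spectral similarity and normalized Pearson) are included for reference;
their dynamic extension is the arithmetic mean over timepoints.

All standard deviations are population flavoured (divide by the count);
the min/max ratio is invariant to that choice but reported components use
population values.

Zero-variance conventions (continuity of the min/max ratio as one SD
vanishes): if both vectors are constant and equal the similarity term is 1;
if both are constant but unequal, or exactly one is constant, the term is 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    AlignmentError,
    DynamicNetwork,
    ValidationError,
    align_networks,
    edge_index_pairs,
    flatten_long_vector,
)

__all__ = [
    "IndexValue",
    "ZeroVarianceError",
    "pearson_corr",
    "dns",
    "dnes",
    "sd_decomposition",
    "dice",
    "jaccard",
    "spectral_similarity",
    "normalized_laplacian",
    "corr_norm",
    "traditional_dynamic_similarity",
    "INDEX_NAMES",
]

INDEX_NAMES = ("dns", "dnes", "dice", "jaccard", "spectral", "corr")

_EPS = 1e-12


class ZeroVarianceError(ValueError):
    """Raised when a correlation is requested on a constant vector."""


@dataclass
class IndexValue:
    """A named similarity value in [0, 1] plus intermediate components."""

    name: str
    value: float
    components: dict = field(default_factory=dict)

    def __float__(self) -> float:
        return float(self.value)


def pearson_corr(v1, v2) -> float:
    """Pearson product-moment correlation of two equal-length sequences.

    Raises
    ------
    ZeroVarianceError
        If either input is constant (callers decide the convention).
    """
    x = np.asarray(v1, dtype=float)
    y = np.asarray(v2, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"need two equal-length 1-D sequences, got {x.shape} and {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom < _EPS:
        raise ZeroVarianceError("constant input vector")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def _sim_term(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Corr(x, y) * min(sd)/max(sd) with the zero-variance conventions.

    Returns ``(term, corr, sd_x, sd_y)``; ``corr`` is NaN when undefined.
    """
    sd_x = float(np.std(x))
    sd_y = float(np.std(y))
    if sd_x < _EPS and sd_y < _EPS:
        equal = abs(float(x[0]) - float(y[0])) < _EPS
        return (1.0 if equal else 0.0), float("nan"), sd_x, sd_y
    if sd_x < _EPS or sd_y < _EPS:
        return 0.0, float("nan"), sd_x, sd_y
    corr = pearson_corr(x, y)
    ratio = min(sd_x, sd_y) / max(sd_x, sd_y)
    return corr * ratio, corr, sd_x, sd_y


def _edge_block(net: DynamicNetwork, edges=None) -> np.ndarray:
    """(T, m) matrix of edge weights; optionally restricted to ``edges``."""
    if edges is None:
        iu, ju = edge_index_pairs(net.n_nodes)
    else:
        iu = np.array([e[0] for e in edges], dtype=int)
        ju = np.array([e[1] for e in edges], dtype=int)
        if np.any(iu >= ju):
            raise ValidationError("edge subset must use (i, j) pairs with i < j")
    return net.weights[:, iu, ju]


def dns(a: DynamicNetwork, b: DynamicNetwork, edges=None, strict_labels: bool = False) -> IndexValue:
    """Dynamic Network Similarity of two aligned dynamic networks.

    ``DNS = (Corr(V_A, V_B) * min(sd_A, sd_B)/max(sd_A, sd_B) + 1) / 2``
    computed on the long vectors ``V_A``, ``V_B``.

    Parameters
    ----------
    edges : sequence of (i, j), optional
        Restrict the edge universe to this subset (e.g. a selected
        sub-network); default is all node pairs.
    """
    align_networks(a, b, strict_labels=strict_labels)
    va = _edge_block(a, edges).reshape(-1)
    vb = _edge_block(b, edges).reshape(-1)
    term, corr, sd_a, sd_b = _sim_term(va, vb)
    value = 0.5 * (term + 1.0)
    ratio = min(sd_a, sd_b) / max(sd_a, sd_b) if max(sd_a, sd_b) > _EPS else 1.0
    return IndexValue(
        name="dns",
        value=float(value),
        components={"corr_term": corr, "sd_a": sd_a, "sd_b": sd_b, "sd_ratio": ratio},
    )


def dnes(a: DynamicNetwork, b: DynamicNetwork, edges=None, strict_labels: bool = False) -> IndexValue:
    """Dynamic Network Evolution Similarity of two aligned dynamic networks.

    Per corresponding edge ``i``, ``S_i = Corr(E_A^i, E_B^i) *
    min(SD)/max(SD)``; ``DNES = (mean_i S_i + 1) / 2``.
    """
    align_networks(a, b, strict_labels=strict_labels)
    if a.n_timepoints < 2:
        raise ValidationError("DNES needs at least 2 timepoints")
    ea = _edge_block(a, edges)  # (T, m)
    eb = _edge_block(b, edges)
    s = np.empty(ea.shape[1])
    for k in range(ea.shape[1]):
        s[k], _, _, _ = _sim_term(ea[:, k], eb[:, k])
    value = 0.5 * (float(s.mean()) + 1.0)
    return IndexValue(name="dnes", value=float(value), components={"per_edge_S_i": s})


def sd_decomposition(net: DynamicNetwork) -> tuple[float, float, float]:
    """Split the long-vector population variance into its two parts.

    Returns ``(within_term, between_term, total_variance)`` where the
    within term averages, over timepoints, the spread of edge strengths
    inside each snapshot (connectivity-strength span), and the between
    term is the variance of the per-timepoint mean strengths (evolving
    relative amplitude).  Their sum equals the population variance of the
    long vector.
    """
    block = _edge_block(net)  # (T, m)
    tp_means = block.mean(axis=1)
    within = float(((block - tp_means[:, None]) ** 2).mean())
    between = float(((tp_means - tp_means.mean()) ** 2).mean())
    total = float(np.var(block.reshape(-1)))
    return within, between, total


# ---------------------------------------------------------------------------
# Traditional snapshot indices
# ---------------------------------------------------------------------------


def _check_binary(mat: np.ndarray, label: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if not np.all(np.isin(mat, (0.0, 1.0))):
        raise ValidationError(f"{label} must be binary (0/1) for this index")
    return mat


def _edge_sets(a_bin: np.ndarray, b_bin: np.ndarray) -> tuple[float, float, float]:
    iu, ju = np.triu_indices(a_bin.shape[0], k=1)
    ea = a_bin[iu, ju].astype(bool)
    eb = b_bin[iu, ju].astype(bool)
    inter = float(np.sum(ea & eb))
    return inter, float(ea.sum()), float(eb.sum())


def dice(a_bin: np.ndarray, b_bin: np.ndarray) -> float:
    """Dice coefficient 2|E_A & E_B| / (|E_A| + |E_B|); both empty -> 1."""
    a_bin = _check_binary(a_bin, "a")
    b_bin = _check_binary(b_bin, "b")
    inter, na, nb = _edge_sets(a_bin, b_bin)
    if na + nb == 0:
        return 1.0
    return 2.0 * inter / (na + nb)


def jaccard(a_bin: np.ndarray, b_bin: np.ndarray) -> float:
    """Jaccard coefficient |E_A & E_B| / |E_A | E_B|; both empty -> 1."""
    a_bin = _check_binary(a_bin, "a")
    b_bin = _check_binary(b_bin, "b")
    inter, na, nb = _edge_sets(a_bin, b_bin)
    union = na + nb - inter
    if union == 0:
        return 1.0
    return inter / union


def normalized_laplacian(mat: np.ndarray) -> np.ndarray:
    """``L = D^(-1/2) (D - M) D^(-1/2)`` with isolated-node entries set to 0.

    Degrees are node strengths (row sums); for binary matrices these are
    edge counts.  Isolated nodes contribute eigenvalue 0.
    """
    mat = np.asarray(mat, dtype=float)
    deg = mat.sum(axis=1)
    inv_sqrt = np.zeros_like(deg)
    nz = deg > _EPS
    inv_sqrt[nz] = 1.0 / np.sqrt(deg[nz])
    lap = np.diag(deg) - mat
    return inv_sqrt[:, None] * lap * inv_sqrt[None, :]


def spectral_similarity(a_snap: np.ndarray, b_snap: np.ndarray) -> float:
    """1 minus the normalized spectral distance of the two snapshots.

    Eigenvalues of each normalized Laplacian are sorted ascending and
    paired by rank; the distance is the 2-norm of their difference divided
    by the larger spectrum 2-norm.  Identical spectra give 1; two empty
    graphs are treated as identical (similarity 1).
    """
    if a_snap.shape != b_snap.shape:
        raise AlignmentError(f"shape mismatch: {a_snap.shape} vs {b_snap.shape}")
    ev_a = np.sort(np.linalg.eigvalsh(normalized_laplacian(a_snap)))
    ev_b = np.sort(np.linalg.eigvalsh(normalized_laplacian(b_snap)))
    denom = max(float(ev_a @ ev_a), float(ev_b @ ev_b))
    if denom < _EPS:
        return 1.0
    sd_norm = float(np.sqrt(((ev_a - ev_b) ** 2).sum() / denom))
    return float(np.clip(1.0 - sd_norm, 0.0, 1.0))


def corr_norm(a_snap: np.ndarray, b_snap: np.ndarray) -> float:
    """Normalized Pearson correlation (1 + Corr)/2 of vectorized snapshots."""
    if a_snap.shape != b_snap.shape:
        raise AlignmentError(f"shape mismatch: {a_snap.shape} vs {b_snap.shape}")
    iu, ju = np.triu_indices(a_snap.shape[0], k=1)
    corr = pearson_corr(a_snap[iu, ju], b_snap[iu, ju])
    return 0.5 * (1.0 + corr)


_SNAPSHOT_INDEX = {
    "dice": dice,
    "jaccard": jaccard,
    "spectral": spectral_similarity,
    "corr": corr_norm,
}


def traditional_dynamic_similarity(a: DynamicNetwork, b: DynamicNetwork, index_name: str) -> float:
    """Mean over timepoints of a snapshot index ('dice', 'jaccard',
    'spectral' or 'corr'); dice/jaccard require binary snapshots."""
    try:
        fn = _SNAPSHOT_INDEX[index_name]
    except KeyError:
        raise ValueError(
            f"unknown snapshot index {index_name!r}; choose from {sorted(_SNAPSHOT_INDEX)}"
        ) from None
    align_networks(a, b)
    vals = [fn(a.snapshot(t), b.snapshot(t)) for t in range(a.n_timepoints)]
    return float(np.mean(vals))


def compute_index(name: str, a: DynamicNetwork, b: DynamicNetwork, edges=None) -> IndexValue:
    """Dispatch any of the six indices by name on a pair of dynamic networks."""
    if name == "dns":
        return dns(a, b, edges=edges)
    if name == "dnes":
        return dnes(a, b, edges=edges)
    return IndexValue(name=name, value=traditional_dynamic_similarity(a, b, name))
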