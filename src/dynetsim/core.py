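"""Data model and I/O for dynamic weighted networks.

A dynamic network is an ordered sequence of ``T`` symmetric, zero-diagonal
``n x n`` adjacency matrices over a fixed node set.  Two derived views feed
the similarity indices:

* the *long vector*: the upper-triangular entries of every timepoint,
  concatenated end-to-end along the time axis (time-major, row-major
  within each triangle);
* the *edge time series*: for each unordered node pair ``(i, j)`` with
  ``i < j``, the length-``T`` trajectory of that edge's weight.

Only the upper triangle is ever stored in the flattened views.  For
symmetric zero-diagonal matrices this is equivalent to vectorising the
full matrix (duplicated entries rescale numerators and denominators of
every index identically) and halves memory.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DynamicNetwork",
    "LongVector",
    "EdgeSeries",
    "ValidationError",
    "ParseError",
    "AlignmentError",
    "SYMMETRY_TOL",
    "edge_index_pairs",
    "flatten_long_vector",
    "edge_time_series",
    "read_dynamic_network",
    "write_dynamic_network",
    "read_roi_table",
    "write_roi_table",
]

#: absolute tolerance for symmetry / zero-diagonal validation
SYMMETRY_TOL = 1e-9


class ValidationError(ValueError):
    """Raised when an array does not satisfy the dynamic-network invariants."""


class ParseError(ValueError):
    """Raised on malformed network files; message carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class AlignmentError(ValueError):
    """Raised when two networks cannot be compared (shape or label mismatch)."""


def _validate_weights(weights: np.ndarray, tol: float = SYMMETRY_TOL) -> None:
    if weights.ndim != 3:
        raise ValidationError(f"weights must be a T x n x n array, got shape {weights.shape}")
    T, n, n2 = weights.shape
    if n != n2:
        raise ValidationError(f"adjacency slices must be square, got {n} x {n2}")
    if n < 2:
        raise ValidationError(f"need at least 2 nodes, got {n}")
    if T < 1:
        raise ValidationError("need at least 1 timepoint")
    if not np.all(np.isfinite(weights)):
        raise ValidationError("weights contain non-finite values")
    asym = np.abs(weights - weights.transpose(0, 2, 1)).max()
    if asym > tol:
        raise ValidationError(f"adjacency slice asymmetric (max |A - A^T| = {asym:.3g} > {tol:g})")
    diag = np.abs(np.diagonal(weights, axis1=1, axis2=2)).max()
    if diag > tol:
        raise ValidationError(f"nonzero diagonal (max |A_ii| = {diag:.3g} > {tol:g})")


@dataclass
class DynamicNetwork:
    """An ordered sequence of symmetric weighted adjacency matrices.

    Parameters
    ----------
    weights : ndarray of shape (T, n, n)
        One symmetric zero-diagonal matrix per timepoint.
    node_labels : sequence of str, optional
        Defaults to ``["n0", ..., "n{n-1}"]``.
    time_labels : sequence, optional
        Defaults to ``[0, ..., T-1]``.
    """

    weights: np.ndarray
    node_labels: list[str] = field(default=None)  # type: ignore[assignment]
    time_labels: list = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        _validate_weights(self.weights)
        T, n, _ = self.weights.shape
        if self.node_labels is None:
            self.node_labels = [f"n{i}" for i in range(n)]
        else:
            self.node_labels = [str(x) for x in self.node_labels]
        if len(self.node_labels) != n:
            raise ValidationError(
                f"{len(self.node_labels)} node labels for {n} nodes"
            )
        if self.time_labels is None:
            self.time_labels = list(range(T))
        elif len(self.time_labels) != T:
            raise ValidationError(
                f"{len(self.time_labels)} time labels for {T} timepoints"
            )

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        n = self.n_nodes
        return n * (n - 1) // 2

    def snapshot(self, t: int) -> np.ndarray:
        """The ``n x n`` adjacency matrix at timepoint index ``t``."""
        return self.weights[t]

    def with_weights(self, weights: np.ndarray) -> "DynamicNetwork":
        """A copy of this network carrying new weights, same labels.

        Time labels are kept only when the timepoint count is unchanged.
        """
        weights = np.asarray(weights, dtype=float)
        tl = list(self.time_labels) if weights.shape[0] == len(self.time_labels) else None
        return DynamicNetwork(weights, list(self.node_labels), tl)


@dataclass
class LongVector:
    """Concatenated upper-triangle entries, time-major then row-major."""

    values: np.ndarray
    m: int  # edges per timepoint
    T: int  # timepoints

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.T * self.m,):
            raise ValidationError(
                f"long vector length {self.values.size} != T*m = {self.T * self.m}"
            )

    def timepoint(self, t: int) -> np.ndarray:
        """The slice of the long vector belonging to timepoint ``t``."""
        return self.values[t * self.m:(t + 1) * self.m]


@dataclass
class EdgeSeries:
    """The weight trajectory of one node pair across all timepoints."""

    node_pair: tuple[int, int]
    series: np.ndarray

    def __post_init__(self) -> None:
        i, j = self.node_pair
        if not i < j:
            raise ValidationError(f"node pair must satisfy i < j, got ({i}, {j})")
        self.series = np.asarray(self.series, dtype=float)


def edge_index_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the upper triangle (k=1), row-major order.

    This is the canonical edge order used by every flattened view.
    """
    return np.triu_indices(n, k=1)


def flatten_long_vector(net: DynamicNetwork) -> LongVector:
    """Reshape every timepoint matrix into an edge vector and concatenate.

    The result has length ``T * n(n-1)/2``; timepoints are laid out in
    temporal order and, within a timepoint, edges follow the row-major
    upper triangle.
    """
    iu, ju = edge_index_pairs(net.n_nodes)
    values = net.weights[:, iu, ju].reshape(-1)
    return LongVector(values=values, m=net.n_edges, T=net.n_timepoints)


def edge_time_series(net: DynamicNetwork) -> list[EdgeSeries]:
    """Extract the length-``T`` weight series of every node pair.

    Edge order matches :func:`flatten_long_vector`.
    """
    iu, ju = edge_index_pairs(net.n_nodes)
    block = net.weights[:, iu, ju]  # (T, m)
    return [
        EdgeSeries(node_pair=(int(i), int(j)), series=block[:, k])
        for k, (i, j) in enumerate(zip(iu, ju))
    ]


def align_networks(a: DynamicNetwork, b: DynamicNetwork, strict_labels: bool = False) -> None:
    """Check that two networks are comparable; raise :class:`AlignmentError` if not."""
    if a.weights.shape != b.weights.shape:
        raise AlignmentError(
            f"shape mismatch: {a.weights.shape} vs {b.weights.shape}"
        )
    if strict_labels and a.node_labels != b.node_labels:
        raise AlignmentError("node label lists differ (strict mode)")


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------
# stacked-text (.dnt): optional leading '#' comment lines (a line of the form
# "# nodes: a b c" carries node labels), then a header "n T", then T
# whitespace-delimited n x n blocks separated by blank lines.
#
# manifest: a JSON file {"node_labels": [...], "time_labels": [...],
# "files": [...]} whose files (relative to the manifest) each hold one
# delimited (comma or whitespace) n x n matrix.


def _parse_matrix_row(tokens: list[str], lineno: int, n: int) -> list[float]:
    if len(tokens) != n:
        raise ParseError(f"expected {n} values per row, got {len(tokens)}", lineno)
    out = []
    for tok in tokens:
        try:
            out.append(float(tok))
        except ValueError:
            raise ParseError(f"non-numeric token {tok!r}", lineno) from None
    return out


def _read_stacked(path: str) -> DynamicNetwork:
    node_labels = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    # leading comments
    while pos < len(lines) and lines[pos].lstrip().startswith("#"):
        body = lines[pos].lstrip()[1:].strip()
        if body.lower().startswith("nodes:"):
            node_labels = body.split(":", 1)[1].split()
        pos += 1
    if pos >= len(lines):
        raise ParseError("missing header line 'n T'", pos + 1)
    header = lines[pos].split()
    try:
        n, T = int(header[0]), int(header[1])
        if len(header) != 2:
            raise ValueError
    except (ValueError, IndexError):
        raise ParseError(f"header must be 'n T', got {lines[pos]!r}", pos + 1) from None
    pos += 1
    blocks: list[list[list[float]]] = []
    current: list[list[float]] = []
    for lineno0 in range(pos, len(lines)):
        line = lines[lineno0].strip()
        if line.startswith("#"):
            continue
        if not line:
            if current:
                blocks.append(current)
                current = []
            continue
        if len(current) >= n:
            raise ParseError(f"block has more than {n} rows", lineno0 + 1)
        current.append(_parse_matrix_row(line.split(), lineno0 + 1, n))
    if current:
        blocks.append(current)
    if len(blocks) != T:
        raise ParseError(
            f"header declares {T} timepoints but found {len(blocks)} blocks",
            len(lines),
        )
    for b, block in enumerate(blocks):
        if len(block) != n:
            raise ParseError(f"block {b} has {len(block)} rows, expected {n}", len(lines))
    weights = np.array(blocks, dtype=float)
    try:
        return DynamicNetwork(weights, node_labels=node_labels)
    except ValidationError as exc:
        raise ParseError(str(exc)) from exc


def _write_stacked(net: DynamicNetwork, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("# nodes: " + " ".join(net.node_labels) + "\n")
        fh.write(f"{net.n_nodes} {net.n_timepoints}\n")
        for t in range(net.n_timepoints):
            for row in net.weights[t]:
                fh.write(" ".join(repr(float(x)) for x in row) + "\n")
            fh.write("\n")


def _read_manifest(path: str) -> DynamicNetwork:
    with open(path) as fh:
        try:
            manifest = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"manifest is not valid JSON: {exc}") from exc
    base = os.path.dirname(os.path.abspath(path))
    slices = []
    for fname in manifest["files"]:
        fpath = os.path.join(base, fname)
        text = open(fpath).read()
        delim = "," if "," in text.splitlines()[0] else None
        try:
            mat = np.loadtxt(fpath, delimiter=delim)
        except ValueError as exc:
            raise ParseError(f"{fname}: {exc}") from exc
        slices.append(np.atleast_2d(mat))
    weights = np.stack(slices)
    try:
        return DynamicNetwork(
            weights,
            node_labels=manifest.get("node_labels"),
            time_labels=manifest.get("time_labels"),
        )
    except ValidationError as exc:
        raise ParseError(str(exc)) from exc


def _write_manifest(net: DynamicNetwork, path: str) -> None:
    base = os.path.dirname(os.path.abspath(path))
    os.makedirs(base, exist_ok=True)
    stem = os.path.splitext(os.path.basename(path))[0]
    files = []
    for t in range(net.n_timepoints):
        fname = f"{stem}_t{t}.txt"
        np.savetxt(os.path.join(base, fname), net.weights[t], fmt="%.17g")
        files.append(fname)
    manifest = {
        "node_labels": net.node_labels,
        "time_labels": list(net.time_labels),
        "files": files,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
        fh.write("\n")


_FORMATS = {"stacked", "manifest"}


def read_dynamic_network(path: str, format: str = "stacked") -> DynamicNetwork:
    """Read a dynamic network from ``path`` in the given ``format``."""
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; choose from {sorted(_FORMATS)}")
    return _read_stacked(path) if format == "stacked" else _read_manifest(path)


def write_dynamic_network(net: DynamicNetwork, path: str, format: str = "stacked") -> None:
    """Write ``net`` to ``path``; ``write o read`` is the identity to 1e-12."""
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; choose from {sorted(_FORMATS)}")
    if format == "stacked":
        _write_stacked(net, path)
    else:
        _write_manifest(net, path)


def read_roi_table(path: str) -> tuple[list[str], np.ndarray]:
    """Read a delimited ROI time-series table (header row = ROI names).

    Returns ``(roi_names, data)`` with ``data`` of shape (T_scan, n_roi).
    """
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python")
    return [str(c) for c in df.columns], df.to_numpy(dtype=float)


def write_roi_table(path: str, roi_names: Sequence[str], data: np.ndarray) -> None:
    import pandas as pd

    pd.DataFrame(np.asarray(data, dtype=float), columns=list(roi_names)).to_csv(
        path, sep="\t", index=False
    )
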