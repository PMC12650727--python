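"""Group-level workflow: ROI time series -> connectivity -> dynamic
sub-network -> pairwise similarity -> nonparametric group statistics.

The pipeline mirrors a two-arm longitudinal design: every subject has a
pre- and a post-treatment ROI time-series table; subjects belong to one of
three groups (two active-treatment subgroups and one sham group).  Steps:

1. per session, pairwise Pearson correlation between ROI signals, mapped
   to Fisher-Z values (``z = atanh(r)``) before any averaging or testing;
2. edge selection by a paired t-test (pre vs post, active subjects only,
   lenient uncorrected p < 0.05) defining the treatment-responsive
   sub-network;
3. per subject, a T=2 dynamic network (pre, post) over the selected
   edges' weighted Fisher-Z values;
4. pairwise DNS/DNES between subjects of the "same therapy" pairing
   (group1 x group2) and the "different therapy" pairing (group1 x
   group3);
5. one-sample Wilcoxon signed-rank of each pairing's values against 0.5,
   Mann-Whitney U between pairings, and Cohen's d for each test.

A synthetic cohort generator stands in for unavailable clinical data: all
subjects share a base covariance; treated groups receive a common
post-session decrease in covariance on a designated edge subset.

Statistical caveat: pairwise similarity values within a pairing share
subjects and are treated as independent observations, as the tests in
step 5 imply.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import DynamicNetwork, ValidationError, edge_index_pairs
from .indices import compute_index

__all__ = [
    "SubjectSession",
    "ConnectivityMatrix",
    "EdgeTest",
    "GroupComparison",
    "GROUPS",
    "build_connectivity",
    "binarize_bonferroni",
    "select_motor_network",
    "dynamic_motor_network",
    "pairwise_similarity",
    "compare_groups",
    "generate_synthetic_cohort",
    "run_group_pipeline",
    "write_cohort",
    "read_cohort",
]

GROUPS = ("tDCS1", "tDCS2", "sham")
SESSIONS = ("pre", "post")

_R_CLIP = 1.0 - 1e-12


@dataclass
class SubjectSession:
    """One subject-session ROI time-series table (rows = scan volumes)."""

    subject_id: str
    group: str
    session: str
    roi_series: np.ndarray
    roi_names: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.session not in SESSIONS:
            raise ValueError(f"session must be 'pre' or 'post', got {self.session!r}")
        self.roi_series = np.asarray(self.roi_series, dtype=float)
        if self.roi_series.ndim != 2:
            raise ValueError("roi_series must be 2-D (T_scan x n_roi)")
        if self.roi_names is None:
            self.roi_names = [f"roi{i:02d}" for i in range(self.roi_series.shape[1])]


@dataclass
class ConnectivityMatrix:
    """Fisher-Z connectivity with per-edge correlation p-values."""

    z_values: np.ndarray
    p_values: np.ndarray
    r_values: np.ndarray
    roi_names: list[str]

    @property
    def n_roi(self) -> int:
        return self.z_values.shape[0]


@dataclass
class EdgeTest:
    edge: tuple[int, int]
    t: float
    p: float


@dataclass
class GroupComparison:
    """Wilcoxon-vs-0.5, Mann-Whitney and Cohen's d summaries."""

    st_values: np.ndarray
    dt_values: np.ndarray
    z_st: float
    p_st: float
    d_st: float
    z_dt: float
    p_dt: float
    d_dt: float
    z_between: float
    p_between: float
    d_between: float

    def to_dict(self) -> dict:
        return {
            "n_st": int(self.st_values.size),
            "n_dt": int(self.dt_values.size),
            "st_median": float(np.median(self.st_values)),
            "dt_median": float(np.median(self.dt_values)),
            "z_st": self.z_st, "p_st": self.p_st, "d_st": self.d_st,
            "z_dt": self.z_dt, "p_dt": self.p_dt, "d_dt": self.d_dt,
            "z_between": self.z_between,
            "p_between": self.p_between,
            "d_between": self.d_between,
        }


def build_connectivity(session: SubjectSession) -> ConnectivityMatrix:
    """Pairwise Pearson correlation between ROI signals, Fisher-Z mapped.

    Raises a :class:`ValidationError` naming the first constant ROI.
    """
    data = session.roi_series
    if data.shape[0] < 3:
        raise ValidationError("need at least 3 scan volumes")
    sds = data.std(axis=0)
    if np.any(sds < 1e-12):
        bad = session.roi_names[int(np.argmin(sds))]
        raise ValidationError(f"constant ROI series: {bad}")
    n = data.shape[1]
    r = np.corrcoef(data, rowvar=False)
    np.fill_diagonal(r, 0.0)
    r = np.clip(r, -_R_CLIP, _R_CLIP)
    # two-sided p of the correlation via the exact t transform
    dof = data.shape[0] - 2
    with np.errstate(divide="ignore"):
        tstat = r * np.sqrt(dof / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    np.fill_diagonal(p, 1.0)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(z_values=z, p_values=p, r_values=r, roi_names=list(session.roi_names))


def binarize_bonferroni(conn: ConnectivityMatrix, alpha_level: float = 0.05) -> np.ndarray:
    """Keep edge (i, j) iff p < alpha_level / m, m = n(n-1)/2 tests (strict)."""
    n = conn.n_roi
    m = n * (n - 1) // 2
    keep = (conn.p_values < alpha_level / m).astype(float)
    keep = np.minimum(keep, keep.T)
    np.fill_diagonal(keep, 0.0)
    return keep


def select_motor_network(
    pre_list: list[ConnectivityMatrix],
    post_list: list[ConnectivityMatrix],
    p_threshold: float = 0.05,
) -> list[EdgeTest]:
    """Edges whose Fisher-Z values changed pre vs post (paired t, p < thr).

    The threshold is deliberately lenient and uncorrected so the selected
    sub-network is not excessively small.
    """
    if len(pre_list) != len(post_list) or not pre_list:
        raise ValueError("need equal-length, non-empty paired lists")
    n = pre_list[0].n_roi
    iu, ju = edge_index_pairs(n)
    pre = np.stack([c.z_values[iu, ju] for c in pre_list])   # (S, m)
    post = np.stack([c.z_values[iu, ju] for c in post_list])
    t, p = stats.ttest_rel(post, pre, axis=0)
    hits = []
    for k in np.nonzero(p < p_threshold)[0]:
        hits.append(EdgeTest(edge=(int(iu[k]), int(ju[k])), t=float(t[k]), p=float(p[k])))
    return hits


def dynamic_motor_network(
    pre: ConnectivityMatrix,
    post: ConnectivityMatrix,
    edges: list[tuple[int, int]],
) -> DynamicNetwork:
    """T=2 dynamic network (pre, post) carrying the selected edges'
    weighted Fisher-Z values, embedded in the full ROI node set."""
    n = pre.n_roi
    weights = np.zeros((2, n, n))
    for (i, j) in edges:
        for t, conn in enumerate((pre, post)):
            weights[t, i, j] = weights[t, j, i] = conn.z_values[i, j]
    return DynamicNetwork(weights, node_labels=pre.roi_names, time_labels=["pre", "post"])


def pairwise_similarity(
    nets_a: list[DynamicNetwork],
    nets_b: list[DynamicNetwork],
    index_name: str = "dns",
    edges: list[tuple[int, int]] | None = None,
) -> np.ndarray:
    """|A| x |B| matrix of the chosen index between the two subject lists.

    For DNS/DNES the edge universe is restricted to ``edges`` when given,
    so that edges outside the selected sub-network (identically zero in
    every subject) do not enter the comparison.
    """
    out = np.empty((len(nets_a), len(nets_b)))
    for ia, na in enumerate(nets_a):
        for ib, nb in enumerate(nets_b):
            if index_name in ("dns", "dnes"):
                out[ia, ib] = compute_index(index_name, na, nb, edges=edges).value
            else:
                out[ia, ib] = compute_index(index_name, na, nb).value
    return out


# ---------------------------------------------------------------------------
# Nonparametric statistics
# ---------------------------------------------------------------------------


def _wilcoxon_vs(values: np.ndarray, null_value: float = 0.5) -> tuple[float, float]:
    """One-sample Wilcoxon signed-rank vs ``null_value``: (z, two-sided p).

    p uses the exact distribution for small samples without ties; z is the
    normal approximation used for reporting.
    """
    diffs = np.asarray(values, dtype=float) - null_value
    if np.all(diffs == 0):
        return 0.0, 1.0
    res = stats.wilcoxon(diffs, zero_method="wilcox")
    approx = stats.wilcoxon(diffs, zero_method="wilcox", method="approx")
    return float(approx.zstatistic), float(res.pvalue)


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney U between two samples: (z, two-sided p)."""
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    n1, n2 = len(x), len(y)
    mu = n1 * n2 / 2.0
    sigma = math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    z = (res.statistic - mu) / sigma if sigma > 0 else 0.0
    return float(z), float(res.pvalue)


def _cohens_d_one_sample(values: np.ndarray, null_value: float = 0.5) -> float:
    sd = float(np.std(values, ddof=1))
    diff = float(np.mean(values)) - null_value
    if sd < 1e-12:
        if abs(diff) < 1e-12:
            return 0.0
        raise ValidationError("Cohen's d undefined: zero-variance sample with nonzero shift")
    return diff / sd


def _cohens_d_two_sample(x: np.ndarray, y: np.ndarray) -> float:
    nx, ny = len(x), len(y)
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    pooled = math.sqrt(((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2))
    diff = float(np.mean(x) - np.mean(y))
    if pooled < 1e-12:
        if abs(diff) < 1e-12:
            return 0.0
        raise ValidationError("Cohen's d undefined: zero pooled variance with nonzero shift")
    return diff / pooled


def compare_groups(st_values, dt_values, null_value: float = 0.5) -> GroupComparison:
    """Wilcoxon-vs-0.5 per pairing, Mann-Whitney between pairings, Cohen's d."""
    st = np.asarray(st_values, dtype=float).reshape(-1)
    dt = np.asarray(dt_values, dtype=float).reshape(-1)
    z_st, p_st = _wilcoxon_vs(st, null_value)
    z_dt, p_dt = _wilcoxon_vs(dt, null_value)
    z_b, p_b = _mannwhitney(st, dt)
    return GroupComparison(
        st_values=st,
        dt_values=dt,
        z_st=z_st, p_st=p_st, d_st=_cohens_d_one_sample(st, null_value),
        z_dt=z_dt, p_dt=p_dt, d_dt=_cohens_d_one_sample(dt, null_value),
        z_between=z_b, p_between=p_b, d_between=_cohens_d_two_sample(st, dt),
    )


# ---------------------------------------------------------------------------
# Synthetic cohort
# ---------------------------------------------------------------------------


def _nearest_correlation(mat: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Clip eigenvalues and rescale to unit diagonal."""
    vals, vecs = np.linalg.eigh(mat)
    vals = np.clip(vals, floor, None)
    out = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def _base_correlation(n_roi: int, rng: np.random.Generator) -> np.ndarray:
    """Random factor-structured correlation matrix with moderate off-diagonals."""
    loadings = rng.normal(0.0, 1.0, size=(n_roi, 3))
    raw = loadings @ loadings.T
    d = np.sqrt(np.diag(raw))
    corr = raw / np.outer(d, d)
    base = 0.6 * corr + 0.4 * np.eye(n_roi)
    np.fill_diagonal(base, 1.0)
    return _nearest_correlation(base)


def generate_synthetic_cohort(
    n1: int = 6,
    n2: int = 5,
    n3: int = 7,
    n_roi: int = 20,
    t_scan: int = 230,
    effect_edges: list[tuple[int, int]] | None = None,
    effect_size: float = 0.25,
    n_effect_edges: int = 9,
    seed: int | None = None,
) -> tuple[list[SubjectSession], list[tuple[int, int]]]:
    """Simulate pre/post ROI time series for a 3-group cohort.

    All sessions sample a zero-mean multivariate normal with a common base
    correlation matrix.  Post-treatment sessions of the two treated groups
    share a decrease of ``effect_size`` in correlation on ``effect_edges``
    (default: the ``n_effect_edges`` strongest base-correlation edges);
    the sham group's post sessions use the unchanged base matrix.

    Returns ``(sessions, effect_edges)``.
    """
    rng = np.random.default_rng(seed)
    base = _base_correlation(n_roi, rng)
    iu, ju = edge_index_pairs(n_roi)
    if effect_edges is None:
        order = np.argsort(-np.abs(base[iu, ju]))[:n_effect_edges]
        effect_edges = [(int(iu[k]), int(ju[k])) for k in order]
    post_treated = base.copy()
    for (i, j) in effect_edges:
        shifted = post_treated[i, j] - math.copysign(effect_size, post_treated[i, j])
        post_treated[i, j] = post_treated[j, i] = shifted
    post_treated = _nearest_correlation(post_treated)

    chol_base = np.linalg.cholesky(base)
    chol_post = np.linalg.cholesky(post_treated)
    sessions: list[SubjectSession] = []
    counter = 0
    for group, size in zip(GROUPS, (n1, n2, n3)):
        for _ in range(size):
            sid = f"sub{counter:02d}"
            counter += 1
            for sess in SESSIONS:
                chol = chol_post if (sess == "post" and group != "sham") else chol_base
                data = rng.standard_normal((t_scan, n_roi)) @ chol.T
                sessions.append(
                    SubjectSession(subject_id=sid, group=group, session=sess, roi_series=data)
                )
    return sessions, effect_edges


# ---------------------------------------------------------------------------
# End-to-end pipeline and cohort I/O
# ---------------------------------------------------------------------------


def run_group_pipeline(
    sessions: list[SubjectSession],
    index_names: tuple[str, ...] = ("dns", "dnes"),
    p_threshold: float = 0.05,
    bonferroni_alpha: float = 0.05,
) -> dict:
    """ROI tables -> edge selection -> pairwise similarity -> statistics.

    Returns a dict with the selected edges, pair counts, and one
    :class:`GroupComparison` (as a dict) per requested index.  Traditional
    indices (dice/jaccard/spectral/corr) operate on Bonferroni-binarized
    snapshots; DNS/DNES operate on the weighted Fisher-Z sub-network.
    """
    by_subject: dict[str, dict] = {}
    for s in sessions:
        entry = by_subject.setdefault(s.subject_id, {"group": s.group})
        entry[s.session] = build_connectivity(s)
    for sid, entry in by_subject.items():
        if "pre" not in entry or "post" not in entry:
            raise ValueError(f"subject {sid} is missing a session")

    groups: dict[str, list[str]] = {g: [] for g in GROUPS}
    for sid, entry in by_subject.items():
        groups[entry["group"]].append(sid)
    for g in groups:
        groups[g].sort()

    treated = groups["tDCS1"] + groups["tDCS2"]
    if not treated or not groups["sham"]:
        raise ValueError("cohort must contain treated and sham subjects")
    hits = select_motor_network(
        [by_subject[s]["pre"] for s in treated],
        [by_subject[s]["post"] for s in treated],
        p_threshold=p_threshold,
    )
    edges = [h.edge for h in hits]
    if not edges:
        raise ValidationError("no edge changed significantly; cannot form a sub-network")

    weighted_nets = {
        sid: dynamic_motor_network(e["pre"], e["post"], edges)
        for sid, e in by_subject.items()
    }
    binary_nets = {}
    if any(name not in ("dns", "dnes") for name in index_names):
        for sid, e in by_subject.items():
            stack = np.stack(
                [binarize_bonferroni(e["pre"], bonferroni_alpha),
                 binarize_bonferroni(e["post"], bonferroni_alpha)]
            )
            binary_nets[sid] = DynamicNetwork(stack, node_labels=e["pre"].roi_names,
                                              time_labels=["pre", "post"])

    result: dict = {
        "edges": [list(e) for e in edges],
        "edge_tests": [{"edge": list(h.edge), "t": h.t, "p": h.p} for h in hits],
        "groups": {g: list(groups[g]) for g in GROUPS},
        "n_st_pairs": len(groups["tDCS1"]) * len(groups["tDCS2"]),
        "n_dt_pairs": len(groups["tDCS1"]) * len(groups["sham"]),
        "indices": {},
    }
    for name in index_names:
        nets = weighted_nets if name in ("dns", "dnes") else binary_nets
        mask = edges if name in ("dns", "dnes") else None
        st = pairwise_similarity([nets[s] for s in groups["tDCS1"]],
                                 [nets[s] for s in groups["tDCS2"]], name, edges=mask)
        dt = pairwise_similarity([nets[s] for s in groups["tDCS1"]],
                                 [nets[s] for s in groups["sham"]], name, edges=mask)
        comp = compare_groups(st.reshape(-1), dt.reshape(-1))
        result["indices"][name] = comp.to_dict()
        result["indices"][name]["st_values"] = st.reshape(-1).tolist()
        result["indices"][name]["dt_values"] = dt.reshape(-1).tolist()
    return result


def write_cohort(sessions: list[SubjectSession], out_dir: str) -> None:
    """Write one TSV per subject-session plus a subject->group manifest."""
    from .core import write_roi_table

    os.makedirs(out_dir, exist_ok=True)
    manifest_rows = {}
    for s in sessions:
        write_roi_table(
            os.path.join(out_dir, f"{s.subject_id}_{s.session}.tsv"), s.roi_names, s.roi_series
        )
        manifest_rows[s.subject_id] = s.group
    with open(os.path.join(out_dir, "manifest.tsv"), "w") as fh:
        fh.write("subject_id\tgroup\n")
        for sid in sorted(manifest_rows):
            fh.write(f"{sid}\t{manifest_rows[sid]}\n")


def read_cohort(cohort_dir: str) -> list[SubjectSession]:
    """Read a cohort directory written by :func:`write_cohort`."""
    from .core import read_roi_table

    manifest = pd.read_csv(os.path.join(cohort_dir, "manifest.tsv"), sep="\t")
    sessions = []
    for _, row in manifest.iterrows():
        for sess in SESSIONS:
            path = os.path.join(cohort_dir, f"{row.subject_id}_{sess}.tsv")
            names, data = read_roi_table(path)
            sessions.append(
                SubjectSession(
                    subject_id=str(row.subject_id),
                    group=str(row.group),
                    session=sess,
                    roi_series=data,
                    roi_names=names,
                )
            )
    return sessions
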