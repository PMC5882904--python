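"""In-vivo analysis path: ROI timeseries -> directed connectome.

The pipeline mirrors the validated synthetic workflow on measured data:

1. read per-session ROI-by-time BOLD matrices (delimited text);
2. advisory stationarity pre-check — each ROI's series is split into
   3-minute windows and each window's empirical distribution is compared to
   the rest of the series with a two-sample Kolmogorov–Smirnov test;
3. per subject, one segment-aware MVGC fit pooling all sessions gives the
   GC matrix ``G_k``;
4. subject matrices are aggregated into the elementwise median ``G``;
5. the strongest 1% of directed links are retained, and the *normalized
   causality flow* ``F = (G - G^T) / (G + G^T)`` summarizes the prevailing
   direction of each pair net of overall strength.

Label metadata for the 116-region AAL atlas (hemisphere, lobe) ships with
the package for hemisphere-level summaries.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .mvgc import MVGC, GcMatrix, ParameterError, var_parameter_count

__all__ = [
    "RoiTimeseriesSession",
    "FlowMatrix",
    "DirectedEdgeList",
    "read_roi_timeseries",
    "ks_stationarity_fraction",
    "subject_gc",
    "group_median",
    "threshold_top_fraction",
    "flow_matrix",
    "aal116_labels",
    "hemisphere_flow_summary",
    "run_connectome",
    "FormatError",
]

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed ROI-timeseries input."""


@dataclass
class RoiTimeseriesSession:
    """One scanning session: ``data[t, r]`` is ROI ``r`` at volume ``t``."""

    data: np.ndarray  # (n_volumes, n_rois)
    tr: float
    roi_labels: list[str]
    subject_id: str = ""
    session_id: str = ""
    constant_rois: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise FormatError("session data must be 2-D (volumes x ROIs)")
        if len(self.roi_labels) != self.data.shape[1]:
            raise FormatError("ROI label count must match column count")
        if self.tr <= 0:
            raise FormatError("tr must be positive")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("session data contains non-finite values")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


def read_roi_timeseries(
    path: str | Path,
    tr: float | None = None,
    subject_id: str = "",
    session_id: str = "",
) -> RoiTimeseriesSession:
    """Read delimited text (header of ROI labels, one row per volume).

    ``tr`` comes from a ``<file>.json`` sidecar (key ``"tr"``) unless given
    explicitly.  Zero-variance ROIs are flagged (``constant_rois``) with a
    warning but not dropped.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file")
    delim = "\t" if "\t" in lines[0] else ","
    labels = [tok.strip() for tok in lines[0].split(delim)]
    n_cols = len(labels)
    rows = []
    for lineno, ln in enumerate(lines[1:], start=2):
        toks = ln.split(delim)
        if len(toks) != n_cols:
            raise FormatError(
                f"{path}:{lineno}: expected {n_cols} columns, got {len(toks)}")
        try:
            rows.append([float(t) for t in toks])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    if not rows:
        raise FormatError(f"{path}: no data rows")
    if tr is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise FormatError(f"{path}: tr not given and sidecar {sidecar.name} missing")
        tr = float(json.loads(sidecar.read_text())["tr"])
    data = np.asarray(rows)
    constant = [labels[i] for i in range(n_cols) if np.ptp(data[:, i]) == 0.0]
    if constant:
        logger.warning("%s: constant (zero-variance) ROIs: %s", path, constant)
    return RoiTimeseriesSession(data=data, tr=tr, roi_labels=labels,
                                subject_id=subject_id, session_id=session_id,
                                constant_rois=constant)


# ---------------------------------------------------------------------------
# stationarity pre-check
# ---------------------------------------------------------------------------


def ks_stationarity_fraction(
    session: RoiTimeseriesSession,
    window_seconds: float = 180.0,
    alpha: float = 0.05,
    compare: str = "complement",
) -> tuple[float, np.ndarray]:
    """Fraction of (ROI, window) cells whose distribution differs (p < alpha).

    The series of each ROI is cut into consecutive non-overlapping windows of
    ``floor(window_seconds / tr)`` volumes and each window is compared with a
    two-sample KS test against either the rest of that ROI's series
    (``compare="complement"``, default — keeps the test's false-flag rate at
    its nominal alpha on stationary data) or the whole series including the
    window (``compare="full"`` — the pooled variant, which is conservative
    because the window overlaps its reference sample).

    Returns ``(fraction, flags)`` with ``flags[r, w]`` boolean.
    """
    if compare not in ("complement", "full"):
        raise ParameterError("compare must be 'complement' or 'full'")
    wlen = int(np.floor(window_seconds / session.tr))
    if wlen >= session.n_volumes:
        raise ParameterError(
            f"window of {wlen} volumes >= series length {session.n_volumes}")
    if wlen < 2:
        raise ParameterError("window too short for a KS test")
    n_win = session.n_volumes // wlen
    if n_win < 2:
        raise ParameterError("need at least 2 windows")
    flags = np.zeros((session.n_rois, n_win), dtype=bool)
    for r in range(session.n_rois):
        series = session.data[:, r]
        for w in range(n_win):
            win = series[w * wlen:(w + 1) * wlen]
            if compare == "full":
                ref = series
            else:
                ref = np.concatenate([series[: w * wlen], series[(w + 1) * wlen:]])
            _, p = ks_2samp(win, ref)
            flags[r, w] = p < alpha
    return float(flags.mean()), flags


# ---------------------------------------------------------------------------
# GC aggregation
# ---------------------------------------------------------------------------


def subject_gc(
    sessions: Sequence[RoiTimeseriesSession],
    order: int = 3,
    method: str = "burg",
    mode: str = "pool",
) -> GcMatrix:
    """Per-subject GC matrix ``G_k`` from one or more sessions.

    ``mode="pool"`` (default) runs a single segment-aware fit over all
    sessions (lagged predictors never span a session boundary), so all
    sessions' datapoints count toward one model.  ``mode="average"``
    estimates one GC matrix per session and averages them elementwise.
    """
    if not sessions:
        raise ParameterError("need at least one session")
    labels = sessions[0].roi_labels
    tr = sessions[0].tr
    for s in sessions[1:]:
        if s.roi_labels != labels:
            raise ValueError("sessions disagree on ROI labels")
        if not np.isclose(s.tr, tr):
            raise ValueError("sessions disagree on TR")
    if mode == "pool":
        x = np.vstack([s.data for s in sessions])
        bounds = list(np.cumsum([s.n_volumes for s in sessions])[:-1])
        res = MVGC(x, order=order, method=method,
                   segment_bounds=bounds or None, labels=labels).fit()
        return res.gc
    if mode == "average":
        mats = [
            MVGC(s.data, order=order, method=method, labels=labels).fit().gc
            for s in sessions
        ]
        stack = np.stack([m.values for m in mats])
        return GcMatrix(values=stack.mean(axis=0), labels=list(labels))
    raise ParameterError("mode must be 'pool' or 'average'")


def group_median(matrices: Sequence[GcMatrix]) -> GcMatrix:
    """Elementwise median of per-subject GC matrices."""
    if not matrices:
        raise ValueError("need at least one matrix")
    labels = matrices[0].labels
    for m in matrices[1:]:
        if m.labels != labels or m.values.shape != matrices[0].values.shape:
            raise ValueError("matrices disagree on labels or shape")
    med = np.median(np.stack([m.values for m in matrices]), axis=0)
    return GcMatrix(values=med, labels=list(labels))


# ---------------------------------------------------------------------------
# flow and thresholding
# ---------------------------------------------------------------------------


@dataclass
class FlowMatrix:
    """Normalized causality flow ``F = (G - G^T) / (G + G^T)``.

    Antisymmetric, entries in [-1, 1]; ``F[i, j] > 0`` means the pair's net
    causality runs ``j -> i`` (same orientation as :class:`GcMatrix`).
    """

    values: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if not self.labels:
            self.labels = [str(i) for i in range(n)]
        if np.abs(self.values + self.values.T).max() > 1e-12:
            raise ValueError("flow matrix must be antisymmetric")

    def flow(self, source, target) -> float:
        i = self.labels.index(target) if isinstance(target, str) else int(target)
        j = self.labels.index(source) if isinstance(source, str) else int(source)
        return float(self.values[i, j])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)


def flow_matrix(g: GcMatrix) -> FlowMatrix:
    """Antisymmetric part of ``G`` rescaled by its symmetric part.

    Cells with ``G_ij + G_ji = 0`` (no causality either way) are set to 0,
    which preserves antisymmetry and boundedness.
    """
    v = g.values
    if np.any(v < 0):
        raise ValueError("GC matrix entries must be nonnegative")
    num = v - v.T
    den = v + v.T
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    np.fill_diagonal(f, 0.0)
    return FlowMatrix(values=f, labels=list(g.labels))


@dataclass
class DirectedEdgeList:
    """Thresholded directed edges, strongest first."""

    edges: pd.DataFrame  # columns: source, target, strength, flow

    def __post_init__(self) -> None:
        if (self.edges["strength"] < 0).any():
            raise ValueError("edge strengths must be nonnegative")
        if (self.edges["source"] == self.edges["target"]).any():
            raise ValueError("self-pairs not allowed")

    def __len__(self) -> int:
        return len(self.edges)

    def to_tsv(self, path: str | Path, label_table: pd.DataFrame | None = None) -> None:
        df = self.edges.copy()
        if label_table is not None:
            hemi = label_table.set_index("name")["hemisphere"]
            df["same_hemisphere"] = (
                df.source.map(hemi).eq(df.target.map(hemi))
            )
        df.to_csv(path, sep="\t", index=False)


def threshold_top_fraction(
    g: GcMatrix,
    fraction: float = 0.01,
    flow: FlowMatrix | None = None,
) -> DirectedEdgeList:
    """Strongest ``fraction`` of off-diagonal links, with flow attached.

    ``k = max(1, floor(fraction * n (n - 1)))``; ties in strength resolve by
    ascending (source, target) index; rows are sorted by descending strength.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if flow is None:
        flow = flow_matrix(g)
    n = g.n
    pairs = [(j, i) for j in range(n) for i in range(n) if i != j]  # (src, tgt)
    strengths = np.array([g.values[i, j] for j, i in pairs])
    k = max(1, int(np.floor(fraction * n * (n - 1))))
    order = np.argsort(-strengths, kind="stable")[:k]
    rows = [
        {
            "source": g.labels[pairs[idx][0]],
            "target": g.labels[pairs[idx][1]],
            "strength": strengths[idx],
            "flow": flow.values[pairs[idx][1], pairs[idx][0]],
        }
        for idx in order
    ]
    return DirectedEdgeList(edges=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# atlas metadata and summaries
# ---------------------------------------------------------------------------


def aal116_labels() -> pd.DataFrame:
    """Packaged AAL-116 label table: name, hemisphere (L/R/M), lobe."""
    with resources.files("gcbold.data").joinpath("aal116.csv").open() as fh:
        return pd.read_csv(fh)


def hemisphere_flow_summary(
    edges: DirectedEdgeList, label_table: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Intra- vs inter-hemisphere counts and summed strength/|flow|."""
    if label_table is None:
        label_table = aal116_labels()
    hemi = label_table.set_index("name")["hemisphere"]
    df = edges.edges.copy()
    df["kind"] = np.where(
        df.source.map(hemi).eq(df.target.map(hemi)), "intra", "inter")
    return (
        df.groupby("kind")
        .agg(n_edges=("strength", "size"),
             total_strength=("strength", "sum"),
             total_abs_flow=("flow", lambda s: float(np.abs(s).sum())))
        .reset_index()
    )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def run_connectome(
    subject_sessions: dict[str, list[RoiTimeseriesSession]],
    order: int = 3,
    method: str = "burg",
    top_fraction: float = 0.01,
    out_dir: str | Path | None = None,
    stationarity_alpha: float = 0.05,
) -> dict:
    """Full analysis: sessions -> G_k -> median G -> top links + flow.

    Returns a report dict (and, with ``out_dir``, writes the labeled GC
    matrix, flow matrix, edge list and a JSON run report).  The stationarity
    check is advisory: the flagged fraction is reported, nothing is dropped.
    """
    if not subject_sessions:
        raise ValueError("no subjects given")
    frac_flagged = []
    per_subject = {}
    for subj, sessions in sorted(subject_sessions.items()):
        for sess in sessions:
            try:
                frac, _ = ks_stationarity_fraction(sess, alpha=stationarity_alpha)
                frac_flagged.append(frac)
            except ParameterError:
                logger.warning("session too short for stationarity windows; skipped check")
        per_subject[subj] = subject_gc(sessions, order=order, method=method)
    g = group_median(list(per_subject.values()))
    flow = flow_matrix(g)
    edges = threshold_top_fraction(g, fraction=top_fraction, flow=flow)
    n = g.n
    n_obs = sum(s.data.size for ss in subject_sessions.values() for s in ss)
    report = {
        "n_subjects": len(per_subject),
        "n_rois": n,
        "order": order,
        "method": method,
        "top_fraction": top_fraction,
        "n_edges_retained": len(edges),
        "stationarity_fraction_flagged": (
            float(np.mean(frac_flagged)) if frac_flagged else None),
        "model_parameters": var_parameter_count(n, order),
        "datapoints_per_parameter_per_subject": (
            n_obs / len(per_subject) / var_parameter_count(n, order)),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        g.to_csv(out / "gc_median.csv")
        flow.to_csv(out / "flow.csv")
        table = aal116_labels() if set(g.labels) <= set(aal116_labels()["name"]) else None
        edges.to_tsv(out / "edges_top.tsv", label_table=table)
        (out / "report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report
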