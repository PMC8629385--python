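"""Developmental stage alignment between two conditions' time courses.

The method: for each time point, call development-associated genes (DAGs)
— genes both abundant (RPKM > 1) and relatively high within their own time
course (Z > 1.5) at that point.  For every time-point pair (i, j) across
conditions, score the overlap of DAG sets with an upper-tail hypergeometric
test; the mapping score is -log10 of the Bonferroni-corrected P-value.  A
monotone staircase path from the first to the last time-point pair that
maximizes the summed mapping score (the "maximum trace", found by dynamic
programming) gives the stage-to-stage correspondence; its deviations from
the diagonal measure which condition leads or lags development.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import ValidationError
from .expression import ExpressionMatrix, GeneStats

SCORE_CAP = 300.0  # corrected P clamped below at 1e-300


@dataclass
class DagSet:
    """Development-associated genes of one condition at one time point."""

    condition: str
    timepoint: str
    genes: frozenset
    universe_n: int

    def __post_init__(self) -> None:
        if len(self.genes) > self.universe_n:
            raise ValidationError("DAG set larger than its universe")


def shared_universe(ma: ExpressionMatrix, mb: ExpressionMatrix) -> pd.Index:
    """Genes present in both conditions' matrices (the test universe N)."""
    return ma.gene_ids.intersection(mb.gene_ids)


def call_dags(m: ExpressionMatrix, stats: GeneStats, rpkm_min: float = 1.0,
              z_min: float = 1.5, universe: pd.Index | None = None) -> list[DagSet]:
    """One DagSet per time point: abundance > rpkm_min AND Z > z_min there."""
    if m.values.empty:
        raise ValidationError("empty expression matrix")
    if universe is None:
        universe = m.gene_ids
    in_universe = m.gene_ids.isin(universe)
    hit = (m.values.to_numpy() > rpkm_min) & (stats.z.to_numpy() > z_min)
    hit &= in_universe[:, None]
    out = []
    for j, tp in enumerate(m.timepoints):
        genes = frozenset(m.gene_ids[hit[:, j]])
        out.append(DagSet(condition=m.condition, timepoint=tp, genes=genes,
                          universe_n=len(universe)))
    return out


@dataclass
class MappingScoreMatrix:
    """T_A x T_B grid of mapping scores with per-cell test bookkeeping.

    score = -log10(min(1, m * raw_p)) clamped to [0, 300], where raw_p is
    the upper-tail hypergeometric P(X >= k) for the shared-DAG count k and
    m = T_A * T_B is the Bonferroni factor.
    """

    score: pd.DataFrame
    shared: pd.DataFrame
    raw_p: pd.DataFrame
    size_a: pd.Series
    size_b: pd.Series
    universe_n: int
    bonferroni_m: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.score.shape


def mapping_score_matrix(dags_a: list[DagSet], dags_b: list[DagSet],
                         universe_n: int | None = None,
                         bonferroni_m: int | None = None) -> MappingScoreMatrix:
    """Hypergeometric mapping-score matrix between two DAG-set lists."""
    if not dags_a or not dags_b:
        raise ValidationError("empty DAG list")
    if universe_n is None:
        universe_n = dags_a[0].universe_n
    for d in (*dags_a, *dags_b):
        if len(d.genes) > universe_n:
            raise ValidationError(
                f"DAG set at {d.timepoint} exceeds universe {universe_n}")
    ta, tb = len(dags_a), len(dags_b)
    m = ta * tb if bonferroni_m is None else bonferroni_m
    rows_a = [d.timepoint for d in dags_a]
    cols_b = [d.timepoint for d in dags_b]
    k = np.zeros((ta, tb), dtype=int)
    raw = np.ones((ta, tb))
    for i, da in enumerate(dags_a):
        na = len(da.genes)
        for j, db in enumerate(dags_b):
            kk = len(da.genes & db.genes)
            k[i, j] = kk
            # P(X >= k) drawing |A| from universe with |B| successes
            raw[i, j] = hypergeom.sf(kk - 1, universe_n, len(db.genes), na)
    corrected = np.clip(m * raw, 1e-300, 1.0)
    score = np.minimum(-np.log10(corrected), SCORE_CAP)
    as_df = lambda x, dt=float: pd.DataFrame(  # noqa: E731
        np.asarray(x, dtype=dt), index=rows_a, columns=cols_b)
    return MappingScoreMatrix(
        score=as_df(score), shared=as_df(k, int), raw_p=as_df(raw),
        size_a=pd.Series([len(d.genes) for d in dags_a], index=rows_a),
        size_b=pd.Series([len(d.genes) for d in dags_b], index=cols_b),
        universe_n=universe_n, bonferroni_m=m)


@dataclass
class TraceResult:
    """Maximum trace through a mapping-score matrix.

    path cells are 0-based (i, j) from (0, 0) to (T_A-1, T_B-1); successive
    cells differ by (+1, 0), (0, +1) or (+1, +1).  total is the sum of the
    score over all path cells, endpoints included.
    """

    path: list[tuple[int, int]]
    total: float
    row_labels: list[str]
    col_labels: list[str]

    def path_labels(self) -> list[tuple[str, str]]:
        return [(self.row_labels[i], self.col_labels[j]) for i, j in self.path]

    def to_frame(self, score: pd.DataFrame | None = None) -> pd.DataFrame:
        rows = []
        for i, j in self.path:
            s = float(score.iat[i, j]) if score is not None else np.nan
            rows.append((self.row_labels[i], self.col_labels[j], i, j, s))
        return pd.DataFrame(rows, columns=["A_timepoint", "B_timepoint",
                                           "A_index", "B_index", "score"])


def maximum_trace(msm: MappingScoreMatrix | np.ndarray) -> TraceResult:
    """DP maximum-sum staircase path from the first to the last cell.

    Recurrence: S(i,j) = M(i,j) + max(S(i-1,j-1), S(i-1,j), S(i,j-1));
    traceback from the last cell prefers diagonal, then vertical (advance
    the row condition), then horizontal — a deterministic tie rule biased
    toward synchrony.
    """
    if isinstance(msm, MappingScoreMatrix):
        m = msm.score.to_numpy(dtype=float)
        row_labels = list(msm.score.index)
        col_labels = list(msm.score.columns)
    else:
        m = np.asarray(msm, dtype=float)
        row_labels = [str(i + 1) for i in range(m.shape[0])]
        col_labels = [str(j + 1) for j in range(m.shape[1])]
    if m.size == 0:
        raise ValidationError("empty mapping-score matrix")
    ta, tb = m.shape
    s = np.full((ta, tb), -np.inf)
    s[0, 0] = m[0, 0]
    for i in range(ta):
        for j in range(tb):
            if i == 0 and j == 0:
                continue
            best = -np.inf
            if i > 0 and j > 0:
                best = s[i - 1, j - 1]
            if i > 0:
                best = max(best, s[i - 1, j])
            if j > 0:
                best = max(best, s[i, j - 1])
            s[i, j] = m[i, j] + best
    path = [(ta - 1, tb - 1)]
    i, j = ta - 1, tb - 1
    while (i, j) != (0, 0):
        cand = []
        if i > 0 and j > 0:
            cand.append((s[i - 1, j - 1], 0, (i - 1, j - 1)))
        if i > 0:
            cand.append((s[i - 1, j], 1, (i - 1, j)))
        if j > 0:
            cand.append((s[i, j - 1], 2, (i, j - 1)))
        # max value; ties broken by move preference order (diag, vert, horiz)
        best_val = max(c[0] for c in cand)
        nxt = min((c for c in cand if c[0] == best_val), key=lambda c: c[1])[2]
        path.append(nxt)
        i, j = nxt
    path.reverse()
    return TraceResult(path=path, total=float(s[ta - 1, tb - 1]),
                       row_labels=row_labels, col_labels=col_labels)


def summarize_mapping(trace: TraceResult) -> pd.DataFrame:
    """Per row-condition time point: mapped column span, lag and class.

    lag = (median column index on the trace in that row) - (row index).
    Positive lag means the row condition maps to LATER column time points
    (the row condition is developmentally ahead; the column condition
    lags).  classification: synchronous (lag 0), A-ahead (lag > 0),
    B-ahead (lag < 0), for row condition A and column condition B.
    """
    by_row: dict[int, list[int]] = {}
    for i, j in trace.path:
        by_row.setdefault(i, []).append(j)
    rows = []
    for i in sorted(by_row):
        js = sorted(by_row[i])
        lag = float(np.median(js)) - i
        if lag == 0:
            cls = "synchronous"
        elif lag > 0:
            cls = "A-ahead"
        else:
            cls = "B-ahead"
        rows.append((trace.row_labels[i], i, trace.col_labels[js[0]],
                     trace.col_labels[js[-1]], float(np.median(js)), lag, cls))
    return pd.DataFrame(rows, columns=["A_timepoint", "A_index", "B_span_start",
                                       "B_span_end", "B_median_index", "lag",
                                       "classification"])


def modal_interior_lag(summary: pd.DataFrame, edge: int = 2) -> float:
    """Most frequent (rounded) lag over interior time points.

    The first and last `edge` time points are excluded: the trace is pinned
    to the matrix corners there, and a right-shift lag is boundary-clamped,
    so edge rows cannot express the true offset.
    """
    interior = summary.iloc[edge:len(summary) - edge if edge else None]
    lags = interior["lag"].round().astype(int)
    if lags.empty:
        raise ValidationError("no interior time points")
    counts = lags.value_counts()
    top = counts[counts == counts.max()]
    return float(min(top.index, key=abs))
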