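"""Expression-matrix data model, summary statistics, phase scheme and MDS.

The central container is :class:`ExpressionMatrix`: a gene x time-point
abundance grid (RPKM for genes/lincRNAs, TPM for miRNAs) for one condition
(breed), with per-gene biotype and an ordered time-point metadata table
carrying numeric day and developmental phase.  The default time grid is the
27-point pig skeletal-muscle course (15 prenatal E33..E105, 12 postnatal
D0..D180) split into Embryonic / Fetal / Neonatal / Adult phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ColumnMismatchError,
    DuplicateGeneError,
    NegativeAbundanceError,
    ValidationError,
)

PHASES = ("Embryonic", "Fetal", "Neonatal", "Adult")

#: the 27-time-point developmental course; postnatal days are offset by a
#: 114-day gestation so day_numeric is monotone across birth
DEFAULT_TIMEPOINTS: list[tuple[str, float, str]] = (
    [(f"E{d}", float(d), "Embryonic") for d in (33, 40, 45, 50, 55, 60, 65)]
    + [(f"E{d}", float(d), "Fetal") for d in (70, 75, 80, 85, 90, 95, 100, 105)]
    + [(f"D{d}", 114.0 + d, "Neonatal") for d in (0, 9, 20, 30, 40, 60)]
    + [(f"D{d}", 114.0 + d, "Adult") for d in (80, 100, 120, 140, 160, 180)]
)


def default_metadata() -> pd.DataFrame:
    """Time-point metadata table: label index, day_numeric, phase."""
    meta = pd.DataFrame(DEFAULT_TIMEPOINTS, columns=["timepoint", "day_numeric", "phase"])
    return meta.set_index("timepoint")


@dataclass
class PhaseScheme:
    """Assignment of every time point to exactly one contiguous phase."""

    mapping: pd.Series  # index = time-point label, value = phase name

    def __post_init__(self) -> None:
        bad = set(self.mapping.unique()) - set(PHASES)
        if bad:
            raise ValidationError(f"unknown phases: {sorted(bad)}")
        # contiguity: each phase occupies one run of consecutive time points
        runs = (self.mapping != self.mapping.shift()).cumsum()
        if runs.groupby(self.mapping.values).nunique().max() > 1:
            raise ValidationError("phases must be contiguous in time order")

    @classmethod
    def default(cls) -> "PhaseScheme":
        return cls(default_metadata()["phase"])

    def timepoints_of(self, phase: str) -> list[str]:
        return list(self.mapping.index[self.mapping == phase])


@dataclass
class ExpressionMatrix:
    """One condition's gene x time-point abundance grid with metadata.

    values    : DataFrame, rows = gene ids, columns = time-point labels
                (ordered as in `meta`), nonnegative abundances.
    biotype   : per-gene class, one of {"pcg", "lincRNA", "miRNA"}.
    is_tf     : per-gene transcription-factor flag.
    condition : condition/breed label, used as the column prefix on disk.
    meta      : time-point metadata (index = label, day_numeric, phase).
    """

    values: pd.DataFrame
    biotype: pd.Series
    condition: str
    meta: pd.DataFrame
    is_tf: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise DuplicateGeneError(f"duplicate gene ids: {dups[:5]}")
        if list(self.values.columns) != list(self.meta.index):
            raise ColumnMismatchError(
                "expression columns do not match metadata time points: "
                f"{list(self.values.columns)} vs {list(self.meta.index)}"
            )
        if (self.values.to_numpy() < 0).any():
            raise NegativeAbundanceError("negative abundance values present")
        if self.is_tf is None:
            self.is_tf = pd.Series(False, index=self.values.index)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def timepoints(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def sample_labels(self) -> list[str]:
        return [f"{self.condition}_{tp}" for tp in self.timepoints]

    def to_tsv(self, expr_path, meta_path=None) -> None:
        out = self.values.copy()
        out.columns = self.sample_labels()
        out.insert(0, "biotype", self.biotype)
        out.insert(1, "is_tf", self.is_tf.astype(int))
        out.index.name = "gene_id"
        out.to_csv(expr_path, sep="\t")
        if meta_path is not None:
            self.meta.to_csv(meta_path, sep="\t")


def load_expression(expr_path, meta_path, condition: str | None = None) -> ExpressionMatrix:
    """Read an expression TSV plus its time-point metadata TSV.

    The expression table has `gene_id`, `biotype`, optional `is_tf`, then
    abundance columns labelled `<COND>_<TIMEPOINT>`.  Columns are reordered
    to metadata order; mismatches raise named errors.
    """
    tab = pd.read_csv(expr_path, sep="\t", index_col="gene_id")
    meta = pd.read_csv(meta_path, sep="\t", index_col="timepoint")
    biotype = tab.pop("biotype")
    is_tf = tab.pop("is_tf").astype(bool) if "is_tf" in tab.columns else None
    conds = {c.split("_", 1)[0] for c in tab.columns}
    if condition is None:
        if len(conds) != 1:
            raise ColumnMismatchError(f"ambiguous condition prefixes: {sorted(conds)}")
        condition = conds.pop()
    cols = {}
    for c in tab.columns:
        prefix, _, tp = c.partition("_")
        if prefix != condition:
            raise ColumnMismatchError(f"column {c!r} does not belong to condition {condition!r}")
        if tp not in meta.index:
            raise ColumnMismatchError(f"column {c!r}: time point {tp!r} absent from metadata")
        cols[tp] = c
    missing = [tp for tp in meta.index if tp not in cols]
    if missing:
        raise ColumnMismatchError(f"metadata time points missing from table: {missing}")
    values = tab[[cols[tp] for tp in meta.index]].copy()
    values.columns = list(meta.index)
    return ExpressionMatrix(values=values, biotype=biotype, condition=condition,
                            meta=meta, is_tf=is_tf)


@dataclass
class GeneStats:
    """Per-gene summary statistics over the time course of one condition.

    Z scores are computed within gene across time points on the raw
    abundance scale with sample (n-1) standard deviation; a log2(x+1)
    variant is available via ``gene_stats(log_scale=True)``.
    """

    mean: pd.Series
    sd: pd.Series
    cv: pd.Series
    z: pd.DataFrame
    expressed: pd.Series
    zero_mean: pd.Series = field(repr=False, default=None)


def gene_stats(m: ExpressionMatrix, expressed_threshold: float = 0.1,
               log_scale: bool = False) -> GeneStats:
    """Mean, sd, CV=sd/mean, per-cell Z and expressed flag per gene.

    expressed: any time point exceeds `expressed_threshold` (RPKM/TPM > 0.1).
    Degenerate genes are flagged, never dropped: constant genes get Z=0 and
    CV=0; zero-mean genes get CV=0 with `zero_mean` set.
    """
    if m.values.empty:
        raise ValidationError("empty expression matrix")
    x = np.log2(m.values + 1.0) if log_scale else m.values
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    zero_mean = mean == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = sd / mean
    cv = cv.where(~zero_mean, 0.0).fillna(0.0)
    safe_sd = sd.replace(0.0, np.nan)
    z = x.sub(mean, axis=0).div(safe_sd, axis=0).fillna(0.0)
    expressed = (m.values > expressed_threshold).any(axis=1)
    return GeneStats(mean=mean, sd=sd, cv=cv, z=z, expressed=expressed, zero_mean=zero_mean)


def classical_mds(matrices: list[ExpressionMatrix], dims: int = 2,
                  expressed_only: bool = True,
                  expressed_threshold: float = 0.1):
    """Torgerson classical MDS of samples on log2(x+1) Euclidean distances.

    All matrices must share gene ids; their columns are pooled so both
    conditions embed in one space (the joint-sample analogue).  By default
    only genes expressed (> threshold) in at least one pooled sample enter
    the distance, mirroring an ordination on expressed genes.

    Returns (coords DataFrame indexed by sample label, eigenvalues,
    distortion) where distortion is the max absolute error between input
    and embedded distances.
    """
    genes = matrices[0].gene_ids
    for m in matrices[1:]:
        if not genes.equals(m.gene_ids):
            raise ValidationError("matrices must share identical gene ids")
    blocks, labels = [], []
    for m in matrices:
        blocks.append(m.values.to_numpy(dtype=float))
        labels.extend(m.sample_labels())
    x = np.hstack(blocks)
    if expressed_only:
        x = x[(x > expressed_threshold).any(axis=1)]
    logx = np.log2(x + 1.0)
    # pairwise Euclidean distances between samples (columns)
    sq = (logx**2).sum(axis=0)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (logx.T @ logx)
    np.clip(d2, 0.0, None, out=d2)
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    rank = int((evals > max(evals.max(), 0.0) * 1e-9 + 1e-12).sum())
    if dims > rank:
        raise ValidationError(f"dims={dims} exceeds embedding rank {rank}")
    coords = evecs[:, :dims] * np.sqrt(np.maximum(evals[:dims], 0.0))
    emb_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    distortion = float(np.abs(np.sqrt(emb_d2) - np.sqrt(d2)).max())
    cdf = pd.DataFrame(coords, index=labels,
                       columns=[f"dim{i+1}" for i in range(dims)])
    return cdf, evals, distortion
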