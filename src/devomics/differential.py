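"""Differential-expression layers and phase-specific gene calling.

Three layers mirror the study design on pooled-RNA time courses (one
library per time point, so time points within a phase serve as replicates):

* :func:`two_group_de` — Welch t-test on log2(x+1) with a variance floor,
  BH-adjusted FDR, thresholds |log2FC| >= 1 and FDR <= 0.05.
* :func:`phase_specific_genes` — one-vs-rest test per developmental phase,
  keeping genes significantly HIGHER in the phase (FDR <= 0.05, FC >= 2).
* :func:`trajectory_interaction_test` — per-gene linear model
  log2(x+1) ~ condition + time + condition:time; the F-test of the
  interaction term flags genes whose trajectories differ between
  conditions (trajectory-divergent genes).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .expression import ExpressionMatrix, PhaseScheme


def _bh(p: np.ndarray) -> np.ndarray:
    return multipletests(p, method="fdr_bh")[1]


def two_group_de(values: pd.DataFrame, group_a: list[str], group_b: list[str],
                 lfc_cut: float = 1.0, fdr_cut: float = 0.05,
                 expression_floor: float = 0.1,
                 comparison: str = "A_vs_B") -> pd.DataFrame:
    """Welch t-test per gene on log2(x+1) between two column groups.

    FC is the difference of group means on the log2(x+1) scale (A minus B).
    Genes below `expression_floor` in every column of both groups are
    excluded before testing (their count is in ``result.attrs``).
    Zero-variance groups receive a variance floor equal to the 5th
    percentile of positive per-gene variances, so exact fold changes with
    no within-group spread still yield finite, significant statistics.
    """
    for name, g in (("A", group_a), ("B", group_b)):
        if len(g) < 2:
            raise ValidationError(f"group {name} needs >= 2 columns, got {len(g)}")
    xa_raw, xb_raw = values[group_a], values[group_b]
    tested = ((xa_raw > expression_floor).any(axis=1)
              | (xb_raw > expression_floor).any(axis=1))
    n_skipped = int((~tested).sum())
    xa = np.log2(xa_raw[tested].to_numpy() + 1.0)
    xb = np.log2(xb_raw[tested].to_numpy() + 1.0)
    na, nb = xa.shape[1], xb.shape[1]
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    va, vb = xa.var(axis=1, ddof=1), xb.var(axis=1, ddof=1)
    pos = np.concatenate([va[va > 0], vb[vb > 0]])
    floor = np.percentile(pos, 5) if pos.size else 1e-6
    va = np.maximum(va, floor)
    vb = np.maximum(vb, floor)
    se2 = va / na + vb / nb
    tstat = (ma - mb) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    pval = 2.0 * sps.t.sf(np.abs(tstat), df)
    pval = np.where(np.isnan(pval), 1.0, pval)
    fdr = _bh(pval)
    lfc = ma - mb
    res = pd.DataFrame({
        "gene_id": values.index[tested],
        "comparison": comparison,
        "log2FC": lfc,
        "pvalue": pval,
        "fdr": fdr,
        "direction": np.where(lfc > 0, "up", np.where(lfc < 0, "down", "none")),
        "significant": (np.abs(lfc) >= lfc_cut) & (fdr <= fdr_cut),
    }).set_index("gene_id")
    res.attrs["n_excluded_low_expression"] = n_skipped
    res.attrs["variance_floor"] = float(floor)
    return res


def pooled_values(ma: ExpressionMatrix, mb: ExpressionMatrix) -> pd.DataFrame:
    """Concatenate both conditions' columns over shared genes."""
    genes = ma.gene_ids.intersection(mb.gene_ids)
    a = ma.values.loc[genes].copy()
    a.columns = ma.sample_labels()
    b = mb.values.loc[genes].copy()
    b.columns = mb.sample_labels()
    return pd.concat([a, b], axis=1)


def phase_specific_genes(ma: ExpressionMatrix, mb: ExpressionMatrix,
                         scheme: PhaseScheme | None = None,
                         lfc_cut: float = 1.0, fdr_cut: float = 0.05,
                         pooled: bool = True) -> dict[str, pd.DataFrame]:
    """Per-phase one-vs-rest DE; keep genes HIGHER in the phase.

    FC >= 2 on the linear scale is applied as log2FC >= 1 in the phase
    direction.  A gene passing for several phases is kept only for the
    phase with the larger FC, so the per-phase lists are disjoint.
    With ``pooled=False`` a dict per condition is returned instead.
    """
    if scheme is None:
        scheme = PhaseScheme(ma.meta["phase"])
    if not pooled:
        return {
            ma.condition: _phase_specific_one(ma.values, ma, scheme, lfc_cut, fdr_cut),
            mb.condition: _phase_specific_one(mb.values, mb, scheme, lfc_cut, fdr_cut),
        }
    values = pooled_values(ma, mb)
    cols_by_phase = {
        ph: [f"{c}_{tp}" for c in (ma.condition, mb.condition)
             for tp in scheme.timepoints_of(ph)]
        for ph in scheme.mapping.unique()
    }
    return _phase_specific_from_groups(values, cols_by_phase, lfc_cut, fdr_cut)


def _phase_specific_one(values, m, scheme, lfc_cut, fdr_cut):
    cols_by_phase = {ph: scheme.timepoints_of(ph) for ph in scheme.mapping.unique()}
    return _phase_specific_from_groups(values, cols_by_phase, lfc_cut, fdr_cut)


def _phase_specific_from_groups(values, cols_by_phase, lfc_cut, fdr_cut):
    per_phase = {}
    for ph, cols in cols_by_phase.items():
        if len(cols) < 2:
            raise ValidationError(f"phase {ph!r} has fewer than 2 time points")
        rest = [c for c in values.columns if c not in cols]
        de = two_group_de(values, cols, rest, lfc_cut=lfc_cut, fdr_cut=fdr_cut,
                          comparison=f"{ph}_vs_rest")
        per_phase[ph] = de[de["significant"] & (de["log2FC"] >= lfc_cut)]
    # enforce phase uniqueness: keep the phase with the larger FC
    best: dict[str, tuple[float, str]] = {}
    for ph, de in per_phase.items():
        for g, fc in de["log2FC"].items():
            if g not in best or fc > best[g][0]:
                best[g] = (fc, ph)
    return {ph: de[[best[g][1] == ph for g in de.index]]
            for ph, de in per_phase.items()}


def trajectory_interaction_test(ma: ExpressionMatrix, mb: ExpressionMatrix,
                                fdr_cut: float = 0.05) -> pd.DataFrame:
    """F-test of the condition x time interaction per gene.

    Fits log2(x+1) ~ intercept + condition + time_index + condition:time
    against the nested no-interaction model; time is the ordinal index
    1..T (prenatal/postnatal day scales are incommensurate).  Significant
    genes have different expression trajectories between conditions.
    """
    shared_t = [tp for tp in ma.timepoints if tp in set(mb.timepoints)]
    if len(shared_t) < 4:
        raise ValidationError("need at least 4 shared time points")
    genes = ma.gene_ids.intersection(mb.gene_ids)
    ya = np.log2(ma.values.loc[genes, shared_t].to_numpy() + 1.0)
    yb = np.log2(mb.values.loc[genes, shared_t].to_numpy() + 1.0)
    y = np.hstack([ya, yb])  # genes x (2T)
    t_idx = np.arange(1, len(shared_t) + 1, dtype=float)
    cond = np.concatenate([np.zeros(len(shared_t)), np.ones(len(shared_t))])
    tt = np.concatenate([t_idx, t_idx])
    x_full = np.column_stack([np.ones_like(tt), cond, tt, cond * tt])
    x_red = x_full[:, :3]

    def rss(x):
        # one shared design => one projector for all genes
        q, _ = np.linalg.qr(x)
        resid = y - (y @ q) @ q.T
        return (resid**2).sum(axis=1)

    rss_full, rss_red = rss(x_full), rss(x_red)
    df_resid = y.shape[1] - x_full.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        fstat = (rss_red - rss_full) / (rss_full / df_resid)
    fstat = np.where(rss_full <= 0, 0.0, fstat)
    pval = sps.f.sf(fstat, 1, df_resid)
    pval = np.where(np.isnan(pval), 1.0, pval)
    fdr = _bh(pval)
    return pd.DataFrame({
        "gene_id": genes,
        "comparison": "trajectory_interaction",
        "fstat": fstat,
        "pvalue": pval,
        "fdr": fdr,
        "significant": fdr <= fdr_cut,
    }).set_index("gene_id")
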