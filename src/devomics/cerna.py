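"""Competing-endogenous-RNA (ceRNA) triplet network construction.

A lincRNA and an mRNA that share miRNA binding sites can titrate the same
miRNA, coupling their expression.  Triplets (lincRNA, miRNA, mRNA) are
built from miRNA-target pairs by requiring, over the concatenated time
courses of both conditions: R(miRNA, lincRNA) < -0.5, R(miRNA, mRNA)
< -0.5, and R(lincRNA, mRNA) > +0.5, each with P < 0.05 (Pearson, two
sided, t-distribution on n-2 df).  Triplets are then partitioned by the
shared developmental trend of their lincRNA and mRNA into network I
(down-regulated across development, miRNA up) and network II (the
reverse).

Target pairs may come from external predictor output (tool intersection)
or from the built-in canonical seed matcher, which looks for 7mer-m8
(perfect match to the reverse complement of miRNA positions 2-8),
7mer-A1 (positions 2-7 plus an A opposite position 1) and 8mer sites.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import MissingExpressionError, ValidationError
from .expression import ExpressionMatrix

_VALID = set("ACGTU")


def _norm_seq(seq: str) -> str:
    s = str(seq).upper().replace("U", "T")
    bad = set(s) - (_VALID | {"T"})
    if bad or not s:
        raise ValidationError(f"invalid sequence alphabet: {sorted(bad)}")
    return s


_RC = str.maketrans("ACGT", "TGCA")


def _rc(s: str) -> str:
    return s.translate(_RC)[::-1]


def _read_fasta(src) -> dict[str, str]:
    if isinstance(src, dict):
        return dict(src)
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(src), "fasta")}


def seed_sites(mirna: str, target: str) -> list[tuple[int, int, str]]:
    """Canonical seed-site matches as (start, end, kind) in the target."""
    m = _norm_seq(mirna)
    t = _norm_seq(target)
    if len(m) < 8:
        raise ValidationError("miRNA shorter than 8 nt")
    site_m8 = _rc(m[1:8])          # pairs miRNA positions 2-8
    site_a1 = _rc(m[1:7]) + "A"    # positions 2-7 plus target A opposite pos 1
    site_8mer = site_m8 + "A"
    hits = []
    for pat, kind in ((site_8mer, "8mer"), (site_m8, "7mer-m8"), (site_a1, "7mer-A1")):
        for hit in re.finditer(f"(?={re.escape(pat)})", t):
            hits.append((hit.start(), hit.start() + len(pat), kind))
    hits.sort()
    # merge overlapping matches into distinct non-overlapping sites,
    # preferring the longer (8mer) call at a position
    merged: list[tuple[int, int, str]] = []
    for start, end, kind in hits:
        if merged and start < merged[-1][1]:
            prev = merged[-1]
            if end - start > prev[1] - prev[0]:
                merged[-1] = (prev[0], end, "8mer")
            continue
        merged.append((start, end, kind))
    return merged


def seed_match_targets(mirna_seqs, target_seqs,
                       target_class: dict[str, str] | str = "mRNA") -> pd.DataFrame:
    """Pair table from canonical seed matching (case-insensitive, U==T).

    `target_class` is either one class for all targets or a per-id dict
    with values in {"lincRNA", "mRNA"}.
    """
    mirnas = _read_fasta(mirna_seqs)
    targets = _read_fasta(target_seqs)
    rows = []
    for mid, mseq in mirnas.items():
        for tid, tseq in targets.items():
            sites = seed_sites(mseq, tseq)
            if sites:
                cls = target_class if isinstance(target_class, str) \
                    else target_class[tid]
                rows.append((mid, tid, cls, "builtin-seed-match", len(sites)))
    return pd.DataFrame(rows, columns=["mirna", "target", "target_class",
                                       "source", "sites"])


def concat_expression(mats: list[ExpressionMatrix]) -> pd.DataFrame:
    """Row-wise union of matrices with condition-prefixed columns."""
    blocks = []
    for m in mats:
        b = m.values.copy()
        b.columns = m.sample_labels()
        blocks.append(b)
    out = pd.concat(blocks, axis=0)
    out = out.groupby(level=0).first() if out.index.duplicated().any() else out
    return out


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson R with a two-sided P from the t-distribution on n-2 df."""
    n = len(x)
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0 or n < 3:
        return 0.0, 1.0
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return r, float(2.0 * sps.t.sf(abs(t), n - 2))


@dataclass
class CernaTriplet:
    """One lincRNA-miRNA-mRNA competing triplet with its three edges."""

    lincrna: str
    mirna: str
    mrna: str
    r_mir_lnc: float
    p_mir_lnc: float
    r_mir_mrna: float
    p_mir_mrna: float
    r_lnc_mrna: float
    p_lnc_mrna: float
    network: str = "unassigned"


def correlation_filter(pairs: pd.DataFrame, expr: pd.DataFrame,
                       r_cut: float = 0.5, p_cut: float = 0.05):
    """Keep miRNA-target pairs with R < -r_cut and P < p_cut.

    `expr` holds one row per id (genes and miRNAs) over the concatenated
    samples.  Returns (edges, kept_pairs); edges record R/P for every
    input pair.
    """
    ids = pd.unique(pd.concat([pairs["mirna"], pairs["target"]]))
    missing = [i for i in ids if i not in expr.index]
    if missing:
        raise MissingExpressionError(f"no expression row for: {missing[:10]}")
    rows, keep = [], []
    for idx, row in pairs.iterrows():
        x = expr.loc[row["mirna"]].to_numpy(dtype=float)
        y = expr.loc[row["target"]].to_numpy(dtype=float)
        r, p = pearson_with_p(x, y)
        rel = ("miRNA-lincRNA" if row["target_class"] == "lincRNA"
               else "miRNA-mRNA")
        rows.append((row["mirna"], row["target"], rel, r, p))
        keep.append(r < -r_cut and p < p_cut)
    edges = pd.DataFrame(rows, columns=["source", "target", "edge_type", "R", "P"])
    kept = pairs.loc[np.asarray(keep, dtype=bool)].reset_index(drop=True)
    return edges, kept


def build_triplets(lnc_pairs: pd.DataFrame, mrna_pairs: pd.DataFrame,
                   expr: pd.DataFrame, r_cut: float = 0.5,
                   p_cut: float = 0.05) -> pd.DataFrame:
    """Join surviving pairs through shared miRNAs into candidate triplets.

    For each miRNA the cross product of its lincRNA and mRNA partners is
    retained iff the lincRNA-mRNA correlation passes the positive arm
    (R > r_cut, P < p_cut).  Duplicated input pairs yield no duplicate
    triplets.
    """
    lnc = lnc_pairs.drop_duplicates(subset=["mirna", "target"])
    mr = mrna_pairs.drop_duplicates(subset=["mirna", "target"])
    rows = []
    by_mirna_lnc = lnc.groupby("mirna")["target"].apply(list)
    by_mirna_mr = mr.groupby("mirna")["target"].apply(list)
    for mid in by_mirna_lnc.index.intersection(by_mirna_mr.index):
        xm = expr.loc[mid].to_numpy(dtype=float)
        for ln in by_mirna_lnc[mid]:
            xl = expr.loc[ln].to_numpy(dtype=float)
            r_ml, p_ml = pearson_with_p(xm, xl)
            for mg in by_mirna_mr[mid]:
                xg = expr.loc[mg].to_numpy(dtype=float)
                r_lm, p_lm = pearson_with_p(xl, xg)
                if not (r_lm > r_cut and p_lm < p_cut):
                    continue
                r_mg, p_mg = pearson_with_p(xm, xg)
                rows.append((ln, mid, mg, r_ml, p_ml, r_mg, p_mg, r_lm, p_lm))
    cols = ["lincrna", "mirna", "mrna", "R_mir_lnc", "P_mir_lnc",
            "R_mir_mrna", "P_mir_mrna", "R_lnc_mrna", "P_lnc_mrna"]
    out = pd.DataFrame(rows, columns=cols)
    return out.drop_duplicates(subset=["lincrna", "mirna", "mrna"]).reset_index(drop=True)


def partition_networks(triplets: pd.DataFrame, expr: pd.DataFrame,
                       time_index: np.ndarray | None = None,
                       rho_min: float = 0.3) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign triplets to the two opposing developmental-trend networks.

    Spearman rho of the lincRNA and of the mRNA against the time index
    (the ordinal time position, repeated per condition): both <= -rho_min
    puts the triplet in network I (down-regulated RNAs, miRNA up across
    development); both >= +rho_min in network II; anything else stays
    unassigned.  Returns (labelled triplets, per-network tallies).
    """
    out = triplets.copy()
    if out.empty:
        out["network"] = pd.Series(dtype=object)
        return out, pd.DataFrame(columns=["network", "n_triplets", "n_lincRNA",
                                          "n_miRNA", "n_mRNA"])
    n_cols = expr.shape[1]
    if time_index is None:
        # default: columns are two equal condition blocks in time order
        t = n_cols // 2 if n_cols % 2 == 0 else n_cols
        time_index = np.tile(np.arange(1, t + 1), n_cols // t)
    labels = []
    rho_cache: dict[str, float] = {}

    def rho(gid: str) -> float:
        if gid not in rho_cache:
            vals = expr.loc[gid].to_numpy(dtype=float)
            if np.ptp(vals) == 0:  # constant profile: no trend
                rho_cache[gid] = np.nan
            else:
                rho_cache[gid] = sps.spearmanr(vals, time_index).statistic
        return rho_cache[gid]

    for _, row in out.iterrows():
        rl, rm = rho(row["lincrna"]), rho(row["mrna"])
        if np.isnan(rl) or np.isnan(rm):
            labels.append("unassigned")
        elif rl <= -rho_min and rm <= -rho_min:
            labels.append("I")
        elif rl >= rho_min and rm >= rho_min:
            labels.append("II")
        else:
            labels.append("unassigned")
    out["network"] = labels
    tallies = []
    for net, grp in out.groupby("network"):
        tallies.append((net, len(grp), grp["lincrna"].nunique(),
                        grp["mirna"].nunique(), grp["mrna"].nunique()))
    tally = pd.DataFrame(tallies, columns=["network", "n_triplets", "n_lincRNA",
                                           "n_miRNA", "n_mRNA"])
    return out, tally


def guilt_by_association(lincrna_ids: list[str], expr: pd.DataFrame,
                         mrna_ids: list[str], r_cut: float = 0.5,
                         p_cut: float = 0.001) -> pd.DataFrame:
    """mRNAs strongly co-expressed with each lincRNA (R > 0.5, P < 0.001)."""
    rows = []
    for ln in lincrna_ids:
        x = expr.loc[ln].to_numpy(dtype=float)
        for mg in mrna_ids:
            r, p = pearson_with_p(x, expr.loc[mg].to_numpy(dtype=float))
            if r > r_cut and p < p_cut:
                rows.append((ln, mg, r, p))
    return pd.DataFrame(rows, columns=["lincrna", "mrna", "R", "P"])
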