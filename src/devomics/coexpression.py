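"""CV-filtered k-means co-expression modules with figure-of-merit k choice.

Genes whose expression varies over the course (CV > 0.5) are Z-scaled per
gene over the concatenated time points of both conditions and clustered
with k-means.  The number of modules is suggested by the figure of merit
(FOM): the leave-one-condition-out root-mean-square error of predicting
the held-out column from cluster means, with the n/(n-k) adjustment; the
elbow (maximum second difference) of the FOM curve picks k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .errors import ValidationError
from .expression import ExpressionMatrix, GeneStats


def select_high_cv(stats: GeneStats, cv_min: float = 0.5) -> pd.Index:
    """Genes with CV strictly greater than `cv_min`, in input order."""
    return stats.cv.index[stats.cv > cv_min]


def zscore_profiles(mats: list[ExpressionMatrix],
                    genes: pd.Index | None = None) -> pd.DataFrame:
    """Per-gene Z over the concatenated columns of all matrices."""
    if genes is None:
        genes = mats[0].gene_ids
        for m in mats[1:]:
            genes = genes.intersection(m.gene_ids)
    blocks = []
    for m in mats:
        b = m.values.loc[genes].copy()
        b.columns = m.sample_labels()
        blocks.append(b)
    x = pd.concat(blocks, axis=1)
    mu = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1).replace(0.0, np.nan)
    return x.sub(mu, axis=0).div(sd, axis=0).fillna(0.0)


def figure_of_merit(z: pd.DataFrame, k_range=range(1, 9),
                    seed: int = 0) -> tuple[pd.DataFrame, int]:
    """FOM per k (leave-one-column-out) and the suggested elbow k.

    For each held-out column: cluster genes on the remaining columns, then
    FOM(col, k) = sqrt(mean over genes of (x_g,col - cluster mean)^2),
    adjusted by sqrt(n/(n-k)); FOM(k) sums over held-out columns.  The
    suggested k maximizes the second difference of the curve (interior ks
    only); for well-separated trajectory families the curve drops steeply
    to the true k then flattens.
    """
    n, t = z.shape
    if t < 3:
        raise ValidationError("FOM needs at least 3 columns")
    ks = list(k_range)
    if max(ks) >= n:
        raise ValidationError("k must be smaller than the number of genes")
    x = z.to_numpy()
    fom = []
    for k in ks:
        total = 0.0
        for held in range(t):
            rest = np.delete(x, held, axis=1)
            if k == 1:
                labels = np.zeros(n, dtype=int)
            else:
                labels = KMeans(n_clusters=k, n_init=10,
                                random_state=seed).fit_predict(rest)
            col = x[:, held]
            sse = 0.0
            for c in range(k):
                mask = labels == c
                if mask.any():
                    sse += ((col[mask] - col[mask].mean()) ** 2).sum()
            total += np.sqrt(sse / n) * np.sqrt(n / max(n - k, 1))
        fom.append(total)
    curve = pd.DataFrame({"k": ks, "fom": fom})
    if len(ks) >= 3:
        second = np.diff(fom, 2)  # f(k-1) - 2 f(k) + f(k+1)
        suggested = ks[1 + int(np.argmax(second))]
    else:
        suggested = ks[int(np.argmin(fom))]
    return curve, int(suggested)


@dataclass
class ModuleAssignment:
    """k-means module membership and per-module summaries."""

    labels: pd.Series             # gene -> module id (1..k)
    medians: pd.DataFrame         # module x column median Z trajectory
    counts: pd.DataFrame          # per-module gene/TF/lincRNA tallies
    k: int
    inertia: float
    fom_curve: pd.DataFrame | None = None
    seed: int = 0


def kmeans_modules(z: pd.DataFrame, k: int, seed: int = 0,
                   biotype: pd.Series | None = None,
                   is_tf: pd.Series | None = None,
                   fom_curve: pd.DataFrame | None = None) -> ModuleAssignment:
    """k-means (k-means++ init, 10 restarts, fixed seed) on Z profiles."""
    if z.empty:
        raise ValidationError("empty Z matrix")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(z.to_numpy())
    labels = pd.Series(km.labels_ + 1, index=z.index, name="module")
    medians = z.groupby(labels).median()
    medians.index.name = "module"
    tallies = {"n_genes": labels.value_counts().sort_index()}
    if biotype is not None:
        bt = biotype.reindex(z.index)
        tallies["n_lincRNA"] = (bt == "lincRNA").groupby(labels).sum()
        tallies["n_pcg"] = (bt == "pcg").groupby(labels).sum()
    if is_tf is not None:
        tallies["n_tf"] = is_tf.reindex(z.index).fillna(False).groupby(labels).sum()
    counts = pd.DataFrame(tallies).fillna(0).astype(int)
    counts.index.name = "module"
    return ModuleAssignment(labels=labels, medians=medians, counts=counts,
                            k=k, inertia=float(km.inertia_),
                            fom_curve=fom_curve, seed=seed)
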