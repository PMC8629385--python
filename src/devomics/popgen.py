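"""Two-population genomics: filtering, windowed FST/pi, sweep scan, LD,
PCA and a neighbor-joining tree.

Statistics follow the conventions of the standard command-line tools:

* nucleotide diversity theta_pi per site is the unbiased pairwise
  heterozygosity 2*c_ref*c_alt / (n*(n-1)) over called alleles, summed per
  50 kb window (10 kb step) and divided by the full window span (per-bp);
* FST is the Weir-Cockerham (1984) estimator, windows weighted as
  sum(a) / sum(a+b+c) over per-site variance components, negative values
  retained;
* the sweep scan calls windows jointly extreme in FST (upper tail) and in
  log2(pi_A/pi_B) (either tail, signing which population lost diversity),
  with thresholds taken as empirical quantiles of the analyzed windows;
  overlapping or adjacent candidate windows of the same population merge
  into candidate selective regions, and genes overlapping those regions
  are the selected genes;
* LD is composite (genotype) r^2 between alt-dosage vectors, binned by
  physical distance; PCA uses Patterson scaling; the NJ tree is built on
  1 - IBS allele-sharing distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .errors import AnnotationParseError, MissingSampleError, ValidationError

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Biallelic SNP records with alt-allele dosages per individual."""

    chrom: np.ndarray          # str per SNP
    pos: np.ndarray            # 1-based, strictly increasing within chrom
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray         # snps x individuals, 0/1/2, MISSING=-1
    samples: list[str]
    populations: pd.Series     # sample -> population label
    filter_log: dict = field(default_factory=dict)

    @property
    def n_snps(self) -> int:
        return len(self.pos)

    def pop_columns(self, pop: str) -> np.ndarray:
        cols = [i for i, s in enumerate(self.samples)
                if self.populations.get(s) == pop]
        if not cols:
            raise ValidationError(f"population {pop!r} has no samples")
        return np.asarray(cols)

    def subset_chrom(self, chrom: str) -> "GenotypeMatrix":
        m = self.chrom == chrom
        return GenotypeMatrix(self.chrom[m], self.pos[m], self.ref[m],
                              self.alt[m], self.dosage[m], self.samples,
                              self.populations)


def load_and_filter(vcf_path, pops: dict[str, list[str]],
                    call_rate_min: float = 0.9,
                    maf_min: float = 0.05) -> GenotypeMatrix:
    """Read a VCF and keep biallelic SNPs passing call-rate and MAF filters.

    `pops` maps population label -> sample names.  Multiallelic records and
    indels are dropped; call rate and minor allele frequency are computed
    over all requested samples.  Exclusion counts land in `filter_log`.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    wanted = [s for samps in pops.values() for s in samps]
    missing = sorted(set(wanted) - set(vcf.samples))
    if missing:
        raise MissingSampleError(f"samples absent from VCF: {missing}")
    vcf = VCF(str(vcf_path), gts012=True, samples=wanted)
    order = list(vcf.samples)  # cyvcf2 preserves VCF column order
    populations = pd.Series({s: p for p, samps in pops.items() for s in samps})

    log = {"multiallelic_or_indel": 0, "low_call_rate": 0, "low_maf": 0, "kept": 0}
    chroms, positions, refs, alts, rows = [], [], [], [], []
    n = len(order)
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            log["multiallelic_or_indel"] += 1
            continue
        # gts012: 0/1/2 = dosage, 3 = missing
        d = np.asarray(var.gt_types, dtype=np.int8)
        d[d == 3] = MISSING
        called = d != MISSING
        if called.sum() / n < call_rate_min:
            log["low_call_rate"] += 1
            continue
        ac = d[called].sum()
        an = 2 * called.sum()
        maf = min(ac / an, 1 - ac / an) if an else 0.0
        if maf < maf_min:
            log["low_maf"] += 1
            continue
        log["kept"] += 1
        chroms.append(var.CHROM)
        positions.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        rows.append(d)
    dosage = (np.vstack(rows) if rows
              else np.empty((0, n), dtype=np.int8))
    return GenotypeMatrix(np.asarray(chroms), np.asarray(positions, dtype=np.int64),
                          np.asarray(refs), np.asarray(alts), dosage,
                          order, populations, filter_log=log)


def _site_pi(dos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site pairwise heterozygosity and called-allele counts."""
    called = dos != MISSING
    n_alleles = 2 * called.sum(axis=1)
    ac = np.where(dos == MISSING, 0, dos).sum(axis=1)
    c_ref = n_alleles - ac
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = 2.0 * c_ref * ac / (n_alleles * (n_alleles - 1.0))
    pi = np.where(n_alleles < 2, 0.0, pi)
    return pi, n_alleles


def _windows(max_pos: int, window: int, step: int) -> np.ndarray:
    starts = np.arange(1, max(max_pos, 1) + 1, step)
    starts = starts[starts <= max_pos]
    return starts


def _window_sums(pos: np.ndarray, values: np.ndarray, starts: np.ndarray,
                 window: int):
    """Sum `values` (and count SNPs) for each [start, start+window-1]."""
    order = np.argsort(pos, kind="stable")
    pos_s, val_s = pos[order], values[order]
    csum = np.concatenate([[0.0], np.cumsum(val_s)])
    lo = np.searchsorted(pos_s, starts, side="left")
    hi = np.searchsorted(pos_s, starts + window - 1, side="right")
    return csum[hi] - csum[lo], hi - lo


def windowed_pi(g: GenotypeMatrix, pop: str, window: int = 50_000,
                step: int = 10_000, chrom_length: int | None = None) -> pd.DataFrame:
    """Per-window theta_pi (per bp over the full window span) for one pop."""
    cols = g.pop_columns(pop)
    frames = []
    for chrom in pd.unique(g.chrom):
        sub = g.subset_chrom(chrom)
        pi, _ = _site_pi(sub.dosage[:, cols])
        max_pos = chrom_length or int(sub.pos.max())
        starts = _windows(max_pos, window, step)
        sums, counts = _window_sums(sub.pos, pi, starts, window)
        ends = starts + window - 1
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": ends,
            "n_snps": counts, "pi_sum": sums, "pi": sums / window,
            "partial": ends > max_pos,
        }))
    return pd.concat(frames, ignore_index=True)


def wc_site_components(dos_a: np.ndarray, dos_b: np.ndarray):
    """Weir-Cockerham (1984) per-site variance components a, b, c.

    Two populations, missing-aware.  Sites where either population has
    fewer than 2 called diploids get NaN components (skipped downstream).
    """
    comps = []
    stats = []
    for dos in (dos_a, dos_b):
        called = dos != MISSING
        ni = called.sum(axis=1).astype(float)
        ac = np.where(dos == MISSING, 0, dos).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            pi_freq = ac / (2.0 * ni)
            hi = (dos == 1).sum(axis=1) / ni
        stats.append((ni, pi_freq, hi))
    (n1, p1, h1), (n2, p2, h2) = stats
    r = 2.0
    valid = (n1 >= 2) & (n2 >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        n_bar = (n1 + n2) / r
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1.0)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        a = (n_bar / n_c) * (
            s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4.0)
            / (n_bar - 1.0))
        b = (n_bar / (n_bar - 1.0)) * (
            p_bar * (1 - p_bar) - (r - 1) / r * s2
            - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar)
        c = h_bar / 2.0
    nan = ~valid
    for arr in (a, b, c):
        arr[nan] = np.nan
    comps = (a, b, c)
    return comps


def genome_wide_fst(g: GenotypeMatrix, pop_a: str, pop_b: str) -> float:
    """Weighted Weir-Cockerham FST over all retained sites."""
    a, b, c = wc_site_components(g.dosage[:, g.pop_columns(pop_a)],
                                 g.dosage[:, g.pop_columns(pop_b)])
    num = np.nansum(a)
    den = np.nansum(a + b + c)
    if den == 0:
        raise ValidationError("FST undefined: zero total variance")
    return float(num / den)


def windowed_fst(g: GenotypeMatrix, pop_a: str, pop_b: str,
                 window: int = 50_000, step: int = 10_000,
                 min_snps: int = 10,
                 chrom_length: int | None = None) -> pd.DataFrame:
    """Per-window weighted WC FST; windows with < min_snps flagged excluded."""
    ca, cb = g.pop_columns(pop_a), g.pop_columns(pop_b)
    frames = []
    for chrom in pd.unique(g.chrom):
        sub = g.subset_chrom(chrom)
        a, b, c = wc_site_components(sub.dosage[:, ca], sub.dosage[:, cb])
        ok = ~np.isnan(a)
        abc = np.where(ok, a + b + c, 0.0)
        a0 = np.where(ok, a, 0.0)
        max_pos = chrom_length or int(sub.pos.max())
        starts = _windows(max_pos, window, step)
        sum_a, counts = _window_sums(sub.pos[ok], a0[ok], starts, window)
        sum_abc, _ = _window_sums(sub.pos[ok], abc[ok], starts, window)
        with np.errstate(divide="ignore", invalid="ignore"):
            fst = sum_a / sum_abc
        excluded = (counts < min_snps) | (sum_abc == 0)
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts, "end": starts + window - 1,
            "n_snps": counts, "fst": np.where(sum_abc == 0, np.nan, fst),
            "excluded": excluded,
        }))
    return pd.concat(frames, ignore_index=True)


def sweep_scan(pi_a: pd.DataFrame, pi_b: pd.DataFrame, fst: pd.DataFrame,
               fst_quantile: float = 0.95, ratio_tail: float = 0.05,
               pop_a: str = "A", pop_b: str = "B"):
    """Joint FST / log2(pi_A/pi_B) outlier scan over shared window frames.

    Thresholds are empirical quantiles of the included windows (windows
    excluded for SNP count, and windows with zero diversity in either
    population, never enter the quantiles).  A candidate window strictly
    exceeds the FST threshold (fst > q(fst_quantile)) and lies strictly in
    a ratio tail: ratio < q(ratio_tail) means pop A lost diversity (sweep
    in A); ratio > q(1 - ratio_tail) means sweep in B.  Strict comparisons
    make a degenerate all-identical genome yield no candidates.  Candidate
    windows of one population merge into regions when they overlap or
    touch.  Returns (window table, region table).
    """
    key = ["chrom", "start", "end"]
    w = fst.merge(pi_a[key + ["pi", "n_snps"]], on=key, suffixes=("", "_a"))
    w = w.rename(columns={"pi": "pi_a"})
    w = w.merge(pi_b[key + ["pi"]].rename(columns={"pi": "pi_b"}), on=key)
    zero_pi = (w["pi_a"] == 0) | (w["pi_b"] == 0)
    w["excluded_reason"] = np.where(w["excluded"], "few_snps",
                                    np.where(zero_pi, "zero_pi", ""))
    w["included"] = ~(w["excluded"] | zero_pi)
    with np.errstate(divide="ignore", invalid="ignore"):
        w["log2_ratio"] = np.log2(w["pi_a"] / w["pi_b"])
    inc = w[w["included"]]
    if inc.empty:
        raise ValidationError("no windows left after exclusions")
    fst_thr = inc["fst"].quantile(fst_quantile)
    lo_thr = inc["log2_ratio"].quantile(ratio_tail)
    hi_thr = inc["log2_ratio"].quantile(1.0 - ratio_tail)
    call = np.full(len(w), "none", dtype=object)
    m = w["included"] & (w["fst"] > fst_thr)
    call[m & (w["log2_ratio"] < lo_thr)] = f"sweep-in-{pop_a}"
    call[m & (w["log2_ratio"] > hi_thr)] = f"sweep-in-{pop_b}"
    w["sweep_call"] = call
    w.attrs["thresholds"] = {"fst": float(fst_thr), "ratio_low": float(lo_thr),
                             "ratio_high": float(hi_thr)}
    regions = merge_candidate_windows(w)
    return w, regions


def merge_candidate_windows(w: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent candidate windows of the same population."""
    rows = []
    cand = w[w["sweep_call"] != "none"]
    for (chrom, call), grp in cand.groupby(["chrom", "sweep_call"]):
        grp = grp.sort_values("start")
        cur_s, cur_e, nwin = None, None, 0
        for _, r in grp.iterrows():
            if cur_s is None:
                cur_s, cur_e, nwin = r["start"], r["end"], 1
            elif r["start"] <= cur_e + 1:
                cur_e = max(cur_e, r["end"])
                nwin += 1
            else:
                rows.append((chrom, cur_s, cur_e, call.removeprefix("sweep-in-"), nwin))
                cur_s, cur_e, nwin = r["start"], r["end"], 1
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e, call.removeprefix("sweep-in-"), nwin))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "population",
                                      "n_windows"])
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def _parse_genes(path_or_df, feature_type: str = "gene") -> pd.DataFrame:
    """Gene spans as 1-based inclusive (chrom, start, end, gene_id)."""
    if isinstance(path_or_df, pd.DataFrame):
        return path_or_df
    path = str(path_or_df)
    rows = []
    is_bed = path.endswith(".bed")
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            try:
                if is_bed:
                    chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                    name = parts[3] if len(parts) > 3 else f"feature{lineno}"
                    rows.append((chrom, start + 1, end, name))  # 0-based half-open
                else:  # GFF3, 1-based inclusive
                    if len(parts) < 9:
                        raise ValueError("fewer than 9 GFF3 columns")
                    if parts[2] != feature_type:
                        continue
                    attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
                    name = attrs.get("ID") or attrs.get("Name") or f"feature{lineno}"
                    rows.append((parts[0], int(parts[3]), int(parts[4]), name))
            except (ValueError, IndexError) as exc:
                raise AnnotationParseError(f"{path}:{lineno}: {exc}") from exc
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


def annotate_regions(regions: pd.DataFrame, genes) -> pd.DataFrame:
    """Genes overlapping (>= 1 bp) each candidate region; selected genes.

    `genes` is a BED path (0-based half-open), a GFF3 path (1-based
    inclusive) or a pre-parsed 1-based DataFrame.  The returned table has
    one row per (region, gene); ``attrs["selected_genes"]`` holds the
    deduplicated gene list.
    """
    gtab = _parse_genes(genes)
    rows = []
    for _, reg in regions.iterrows():
        hit = gtab[(gtab["chrom"] == reg["chrom"])
                   & (gtab["start"] <= reg["end"])
                   & (gtab["end"] >= reg["start"])]
        for _, g in hit.iterrows():
            rows.append((reg["chrom"], reg["start"], reg["end"],
                         reg["population"], g["gene_id"]))
    out = pd.DataFrame(rows, columns=["chrom", "region_start", "region_end",
                                      "population", "gene_id"])
    out.attrs["selected_genes"] = sorted(out["gene_id"].unique())
    return out


def ld_decay(g: GenotypeMatrix, pop: str, max_dist: int = 300_000,
             bin_bp: int = 100) -> pd.DataFrame:
    """Mean composite r^2 between SNP pairs, binned by physical distance.

    r^2 is the squared Pearson correlation of alt-dosage vectors over
    pairwise-complete individuals; pairs involving a monomorphic SNP are
    skipped and counted.  Bins cover (0, max_dist] in `bin_bp` steps.
    """
    cols = g.pop_columns(pop)
    if len(cols) < 4:
        raise ValidationError("LD needs at least 4 individuals")
    n_bins = int(np.ceil(max_dist / bin_bp))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    skipped = 0
    for chrom in pd.unique(g.chrom):
        sub = g.subset_chrom(chrom)
        x = sub.dosage[:, cols].astype(float)
        x[x == MISSING] = np.nan
        pos = sub.pos
        n = len(pos)
        for i in range(n - 1):
            j_hi = np.searchsorted(pos, pos[i] + max_dist, side="right")
            if j_hi <= i + 1:
                continue
            xi = x[i]
            block = x[i + 1:j_hi]
            both = ~np.isnan(xi)[None, :] & ~np.isnan(block)
            nn = both.sum(axis=1)
            xi_m = np.where(both, xi[None, :], 0.0)
            bl_m = np.where(both, block, 0.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                mi = xi_m.sum(axis=1) / nn
                mj = bl_m.sum(axis=1) / nn
                cov = (xi_m * bl_m).sum(axis=1) / nn - mi * mj
                vi = (xi_m**2).sum(axis=1) / nn - mi**2
                vj = (bl_m**2).sum(axis=1) / nn - mj**2
                r2 = cov**2 / (vi * vj)
            dist = pos[i + 1:j_hi] - pos[i]
            ok = (vi > 0) & (vj > 0) & (nn >= 2) & (dist > 0)
            skipped += int((~ok).sum())
            bins = (dist[ok] - 1) // bin_bp
            np.add.at(sums, bins, r2[ok])
            np.add.at(counts, bins, 1)
    starts = np.arange(n_bins) * bin_bp + 1
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    out = pd.DataFrame({"bin_start": starts, "bin_end": starts + bin_bp - 1,
                        "mean_r2": mean_r2, "n_pairs": counts})
    out.attrs["skipped_pairs"] = skipped
    return out


def genotype_pca(g: GenotypeMatrix, n_components: int = 2):
    """Patterson-scaled genotype PCA.

    Dosages are centered per SNP at 2p and scaled by sqrt(2p(1-p));
    missing entries contribute 0 after centering; monomorphic and
    all-missing SNPs are dropped.  Returns (coords DataFrame, eigenvalues).
    """
    if len(g.samples) < 3:
        raise ValidationError("PCA needs at least 3 individuals")
    x = g.dosage.astype(float)
    x[x == MISSING] = np.nan
    p = np.nanmean(x, axis=1) / 2.0
    keep = ~np.isnan(p) & (p > 0) & (p < 1)
    x = x[keep]
    p = p[keep]
    z = (x - 2 * p[:, None]) / np.sqrt(2 * p * (1 - p))[:, None]
    z = np.nan_to_num(z, nan=0.0)
    cov = z.T @ z / z.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    coords = evecs[:, :n_components] * np.sqrt(np.maximum(evals[:n_components], 0))
    cdf = pd.DataFrame(coords, index=g.samples,
                       columns=[f"PC{i+1}" for i in range(n_components)])
    cdf["population"] = [g.populations.get(s) for s in g.samples]
    return cdf, evals


def ibs_distance(g: GenotypeMatrix) -> pd.DataFrame:
    """1 - IBS: mean |dosage difference|/2 over jointly-called SNPs."""
    x = g.dosage.astype(float)
    x[x == MISSING] = np.nan
    n = len(g.samples)
    d = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(x - x[:, i][:, None]) / 2.0
        cnt = (~np.isnan(diff)).sum(axis=0)
        if (cnt == 0).any():
            bad = [g.samples[j] for j in np.flatnonzero(cnt == 0) if j != i]
            if bad:
                raise ValidationError(
                    f"no jointly-called SNPs between {g.samples[i]} and {bad}")
        d[i] = np.nansum(diff, axis=0) / np.maximum(cnt, 1)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=g.samples, columns=g.samples)


def neighbor_joining(dist: pd.DataFrame) -> str:
    """Saitou-Nei neighbor joining; returns a newick string.

    Negative limb lengths are clamped to 0 with the excess moved to the
    sister limb.  The final three nodes are joined by the three-point
    closed form.
    """
    labels = list(dist.index)
    if len(labels) < 3:
        raise ValidationError("NJ needs at least 3 taxa")
    d = dist.to_numpy(dtype=float).copy()
    nodes = [str(x) for x in labels]
    active = list(range(len(nodes)))
    newick = {i: nodes[i] for i in active}
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        q = (m - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(q, np.inf)
        fi, fj = divmod(int(np.argmin(q)), m)
        if fi > fj:
            fi, fj = fj, fi
        i, j = active[fi], active[fj]
        dij = d[i, j]
        li = 0.5 * dij + (totals[fi] - totals[fj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj, li = lj + li, 0.0
        if lj < 0:
            li, lj = li + lj, 0.0
        # distances from the new node u to every other active node
        du = 0.5 * (d[i, :] + d[j, :] - dij)
        u = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        d[u, :u] = du
        d[:u, u] = du
        d[u, u] = 0.0
        newick[u] = f"({newick[i]}:{li:.10g},{newick[j]}:{lj:.10g})"
        active = [a for a in active if a not in (i, j)] + [u]
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    li, lj, lk = (max(x, 0.0) for x in (li, lj, lk))
    return (f"({newick[i]}:{li:.10g},{newick[j]}:{lj:.10g},"
            f"{newick[k]}:{lk:.10g});")


def _tree_splits(newick: str, taxa: set[str]) -> set[frozenset]:
    from io import StringIO

    from skbio import TreeNode
    tree = TreeNode.read(StringIO(newick), convert_underscores=False)
    splits = set()
    for node in tree.non_tips():
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(taxa) - 1:
            splits.add(min(side, frozenset(taxa - side), key=sorted))
    return splits


def nj_tree(g: GenotypeMatrix, bootstrap: int = 0, seed: int = 0) -> str:
    """NJ tree on 1-IBS distances, optionally with bootstrap support.

    Bootstrap resamples SNPs with replacement `bootstrap` times; support
    (percent of replicates containing each internal split of the main
    tree) is annotated as internal node labels in the returned newick.
    """
    main = neighbor_joining(ibs_distance(g))
    if bootstrap <= 0:
        return main
    from io import StringIO

    from skbio import TreeNode
    taxa = set(g.samples)
    rng = substream(seed, "nj-bootstrap")
    counts: dict[frozenset, int] = {}
    for _ in range(bootstrap):
        idx = rng.integers(0, g.n_snps, size=g.n_snps)
        boot = GenotypeMatrix(g.chrom[idx], g.pos[idx], g.ref[idx], g.alt[idx],
                              g.dosage[idx], g.samples, g.populations)
        for split in _tree_splits(neighbor_joining(ibs_distance(boot)), taxa):
            counts[split] = counts.get(split, 0) + 1
    tree = TreeNode.read(StringIO(main), convert_underscores=False)
    for node in tree.non_tips():
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(taxa) - 1:
            key = min(side, frozenset(taxa - side), key=sorted)
            node.name = str(round(100.0 * counts.get(key, 0) / bootstrap))
    out = StringIO()
    tree.write(out)
    return out.getvalue().strip()
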