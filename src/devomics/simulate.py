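"""Synthetic data generators with known ground truth.

Three generators emulate the statistical structure the analysis stages
assume, at desk scale:

* :func:`simulate_expression` — two-condition expression time courses over
  the 27-point developmental grid, built from four trajectory archetypes
  (monotone-up, monotone-down, single-phase Gaussian bump, flat) with
  multiplicative log-normal noise and an injectable inter-condition
  developmental lag (condition B's mean trajectory is condition A's
  shifted right by `lag_steps`, boundary-clamped).
* :func:`simulate_cerna_layer` — miRNA time courses anticorrelated with
  their true lincRNA/mRNA targets, plus decoy miRNAs with randomized
  trajectories.
* :func:`simulate_genotypes` — a two-population biallelic SNP panel under
  the Balding-Nichols model (per-SNP population frequencies Beta-distributed
  around an ancestral frequency with drift parameter F = the target FST),
  with optional selective sweeps injected as near-fixation frequency pushes
  in one population.

All randomness flows from the config seed through named substreams, so
every generator is bit-reproducible and each stage can be rerun alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .errors import ValidationError
from .expression import DEFAULT_TIMEPOINTS, ExpressionMatrix

ARCHETYPES = ("up", "down", "bump", "flat")
BUMP_WIDTH = 1.5  # gaussian bump sd in time-point index units


@dataclass
class ExprSimConfig:
    """Conditions for the expression simulation.

    Defaults are the desk-scale study conditions: 2,000 genes over the
    27-point grid, 60% of genes lagged by two time points in condition B,
    log-scale noise sd 0.2.
    """

    n_genes: int = 2000
    n_mirnas: int = 90
    timepoints: list[tuple[str, float, str]] = field(
        default_factory=lambda: list(DEFAULT_TIMEPOINTS))
    lag_steps: int = 2
    frac_lagged: float = 0.6
    noise_sd: float = 0.2
    frac_lincrna: float = 0.12
    frac_tf: float = 0.08
    module_archetypes: tuple[str, ...] = ARCHETYPES
    conditions: tuple[str, str] = ("A", "B")
    seed: int = 1

    def __post_init__(self) -> None:
        t = len(self.timepoints)
        if self.n_genes <= 0:
            raise ValidationError("n_genes must be positive")
        if not (0 <= self.lag_steps < t):
            raise ValidationError(f"lag_steps must be in [0, {t})")
        if not (0.0 <= self.frac_lagged <= 1.0):
            raise ValidationError("frac_lagged must be in [0, 1]")
        unknown = set(self.module_archetypes) - set(ARCHETYPES)
        if unknown:
            raise ValidationError(f"unknown archetypes: {sorted(unknown)}")

    @property
    def meta(self) -> pd.DataFrame:
        m = pd.DataFrame(self.timepoints, columns=["timepoint", "day_numeric", "phase"])
        return m.set_index("timepoint")

    @property
    def phase_boundaries(self) -> dict[str, tuple[str, str]]:
        """First and last time-point label of each phase."""
        spans = {}
        for phase, grp in self.meta.groupby("phase", sort=False):
            spans[str(phase)] = (grp.index[0], grp.index[-1])
        return spans


@dataclass
class GenoSimConfig:
    """Conditions for the two-population genotype simulation."""

    n_snps: int = 20000
    n_individuals_per_pop: int = 20
    chrom_length: int = 20_000_000
    fst_target: float = 0.2
    sweep_intervals: list[tuple[int, int, str]] = field(default_factory=list)
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    chrom: str = "1"
    pop_labels: tuple[str, str] = ("A", "B")
    seed: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.fst_target < 1.0):
            raise ValidationError("fst_target must be in (0, 1)")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ValidationError("ancestral_freq_range must be within (0, 1)")
        ivs = sorted(self.sweep_intervals)
        for start, end, pop in ivs:
            if not (1 <= start <= end <= self.chrom_length):
                raise ValidationError(
                    f"sweep interval ({start}, {end}) outside chromosome "
                    f"[1, {self.chrom_length}]")
            if pop not in self.pop_labels:
                raise ValidationError(f"unknown swept population {pop!r}")
        for (s1, e1, _), (s2, _, _) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise ValidationError("sweep intervals must not overlap")


@dataclass
class SimTruth:
    """Ground truth emitted by the generators, for recovery tests."""

    archetype: pd.Series | None = None        # per gene
    bump_center: pd.Series | None = None      # time index of bump peak, -1 otherwise
    lagged: pd.Series | None = None           # per gene, condition-B lag flag
    lag_steps: int = 0
    mirna_targets: dict[str, list[str]] = field(default_factory=dict)
    mirna_direction: dict[str, str] = field(default_factory=dict)
    decoy_mirnas: list[str] = field(default_factory=list)
    sweep_intervals: list[tuple[int, int, str]] = field(default_factory=list)
    snp_pos: np.ndarray | None = None
    ancestral_freq: np.ndarray | None = None

    @property
    def lagged_gene_ids(self) -> list[str]:
        if self.lagged is None:
            return []
        return list(self.lagged.index[self.lagged])

    def expression_sidecar(self) -> pd.DataFrame:
        return pd.DataFrame({
            "archetype": self.archetype,
            "bump_center": self.bump_center,
            "lagged": self.lagged.astype(int),
        })

    def target_sidecar(self) -> pd.DataFrame:
        rows = [(m, t, self.mirna_direction[m]) for m, ts in self.mirna_targets.items()
                for t in ts]
        return pd.DataFrame(rows, columns=["mirna", "target", "direction"])


def _unit_latents(t: int) -> dict[str, np.ndarray]:
    ramp = np.arange(t) / (t - 1)
    return {"up": ramp, "down": 1.0 - ramp, "flat": np.full(t, 0.5)}


def _bump_latent(t: int, center: int) -> np.ndarray:
    idx = np.arange(t)
    return np.exp(-((idx - center) ** 2) / (2.0 * BUMP_WIDTH**2))


def _gene_base(archetype: str, center: int, high: float, t: int) -> np.ndarray:
    if archetype == "bump":
        latent = _bump_latent(t, center)
    else:
        latent = _unit_latents(t)[archetype]
    low = 0.02 * high
    return low + (high - low) * latent


def _shift_right(base: np.ndarray, lag: int) -> np.ndarray:
    if lag == 0:
        return base.copy()
    out = np.empty_like(base)
    out[lag:] = base[:-lag]
    out[:lag] = base[0]
    return out


def simulate_expression(cfg: ExprSimConfig):
    """Simulate two conditions' gene expression; return (A, B, truth).

    Condition B's mean trajectory for lagged genes equals condition A's
    shifted right by ``cfg.lag_steps`` with the left boundary clamped, so
    condition B reaches each expression state later (B developmentally
    lags A).  Abundances are ``base * exp(N(0, noise_sd^2))``.
    """
    meta = cfg.meta
    t = len(meta)
    rng = substream(cfg.seed, "expression")
    n = cfg.n_genes
    gene_ids = pd.Index([f"G{i:05d}" for i in range(n)], name="gene_id")

    arch = pd.Series(rng.choice(cfg.module_archetypes, size=n), index=gene_ids)
    center = pd.Series(-1, index=gene_ids, dtype=int)
    is_bump = arch == "bump"
    center[is_bump] = rng.integers(0, t, size=int(is_bump.sum()))
    lagged = pd.Series(rng.random(n) < cfg.frac_lagged, index=gene_ids)
    if cfg.lag_steps == 0:
        lagged[:] = False
    high = 10.0 ** rng.uniform(0.7, 2.0, size=n)

    base_a = np.empty((n, t))
    for i, g in enumerate(gene_ids):
        base_a[i] = _gene_base(arch[g], center[g], high[i], t)
    base_b = base_a.copy()
    lag_rows = lagged.to_numpy()
    for i in np.flatnonzero(lag_rows):
        base_b[i] = _shift_right(base_a[i], cfg.lag_steps)

    noise = substream(cfg.seed, "expression-noise")
    val_a = base_a * np.exp(noise.normal(0.0, cfg.noise_sd, size=(n, t)))
    val_b = base_b * np.exp(noise.normal(0.0, cfg.noise_sd, size=(n, t)))

    biotype = pd.Series("pcg", index=gene_ids)
    n_lnc = int(round(cfg.frac_lincrna * n))
    lnc_idx = substream(cfg.seed, "biotype").choice(n, size=n_lnc, replace=False)
    biotype.iloc[lnc_idx] = "lincRNA"
    is_tf = pd.Series(False, index=gene_ids)
    pcg_pos = np.flatnonzero((biotype == "pcg").to_numpy())
    n_tf = int(round(cfg.frac_tf * len(pcg_pos)))
    tf_idx = substream(cfg.seed, "tf").choice(pcg_pos, size=n_tf, replace=False)
    is_tf.iloc[tf_idx] = True

    def _mat(vals, cond):
        df = pd.DataFrame(vals, index=gene_ids, columns=list(meta.index))
        return ExpressionMatrix(values=df, biotype=biotype.copy(), condition=cond,
                                meta=meta.copy(), is_tf=is_tf.copy())

    truth = SimTruth(archetype=arch, bump_center=center, lagged=lagged,
                     lag_steps=cfg.lag_steps)
    return _mat(val_a, cfg.conditions[0]), _mat(val_b, cfg.conditions[1]), truth


def simulate_cerna_layer(cfg: ExprSimConfig, expr_a: ExpressionMatrix,
                         expr_b: ExpressionMatrix, truth: SimTruth):
    """Simulate the miRNA layer on top of simulated gene matrices.

    Two thirds of the miRNAs are "true" regulators: each picks a monotone
    direction, takes unlagged lincRNA and mRNA targets of that archetype
    (their noise-free trajectories are positive affine transforms of one
    latent ramp), and receives a negative affine transform of the same
    latent, so at noise 0 every true miRNA-target Pearson R is exactly -1
    and co-targets correlate +1.  The remainder are decoys with iid
    log-normal trajectories, paired with random genes.

    Returns (miRNA matrix A, miRNA matrix B, pair table, updated truth).
    """
    t = expr_a.n_timepoints
    cols = expr_a.timepoints
    if cfg.n_mirnas == 0:
        warnings.warn("n_mirnas=0: returning empty miRNA layer")
        empty = pd.DataFrame(np.empty((0, t)), columns=cols)
        empty.index.name = "gene_id"
        mk = lambda cond: ExpressionMatrix(  # noqa: E731
            values=empty.copy(), biotype=pd.Series(dtype=object),
            condition=cond, meta=expr_a.meta.copy())
        pairs = pd.DataFrame(columns=["mirna", "target", "target_class", "source", "sites"])
        return mk(expr_a.condition), mk(expr_b.condition), pairs, truth

    rng = substream(cfg.seed, "cerna")
    n_true = int(round(cfg.n_mirnas * 2 / 3))
    n_decoy = cfg.n_mirnas - n_true
    mirna_ids = [f"MIR{i:04d}" for i in range(cfg.n_mirnas)]
    latents = _unit_latents(t)

    unlagged = ~truth.lagged
    pools = {
        (d, cls): list(truth.archetype.index[
            (truth.archetype == d) & unlagged & (expr_a.biotype == bt)])
        for d in ("up", "down")
        for cls, bt in (("lincRNA", "lincRNA"), ("mRNA", "pcg"))
    }

    rows_a = np.empty((cfg.n_mirnas, t))
    rows_b = np.empty((cfg.n_mirnas, t))
    pair_rows = []
    for i in range(n_true):
        mid = mirna_ids[i]
        direction = ("up", "down")[i % 2]  # direction of the *targets*
        n_lnc = int(rng.integers(1, 3))
        n_mrna = int(rng.integers(2, 4))
        lnc_pool, mrna_pool = pools[(direction, "lincRNA")], pools[(direction, "mRNA")]
        lncs = list(rng.choice(lnc_pool, size=min(n_lnc, len(lnc_pool)), replace=False))
        mrnas = list(rng.choice(mrna_pool, size=min(n_mrna, len(mrna_pool)), replace=False))
        targets = lncs + mrnas
        scale = rng.uniform(20.0, 200.0)
        base = scale * (1.05 - latents[direction])  # anti-affine to targets
        rows_a[i] = base
        rows_b[i] = base
        truth.mirna_targets[mid] = targets
        truth.mirna_direction[mid] = direction
        for g in lncs:
            pair_rows.append((mid, g, "lincRNA", "sim-true", 1))
        for g in mrnas:
            pair_rows.append((mid, g, "mRNA", "sim-true", 1))

    all_genes = list(expr_a.gene_ids)
    for i in range(n_true, cfg.n_mirnas):
        mid = mirna_ids[i]
        rows_a[i] = np.exp(rng.normal(np.log(10.0), 1.0, size=t))
        rows_b[i] = np.exp(rng.normal(np.log(10.0), 1.0, size=t))
        truth.decoy_mirnas.append(mid)
        for g in rng.choice(all_genes, size=int(rng.integers(2, 5)), replace=False):
            cls = "lincRNA" if expr_a.biotype[g] == "lincRNA" else "mRNA"
            pair_rows.append((mid, g, cls, "sim-decoy", 1))

    noise = substream(cfg.seed, "cerna-noise")
    val_a = rows_a * np.exp(noise.normal(0.0, cfg.noise_sd, size=rows_a.shape))
    val_b = rows_b * np.exp(noise.normal(0.0, cfg.noise_sd, size=rows_b.shape))

    idx = pd.Index(mirna_ids, name="gene_id")

    def _mat(vals, cond):
        df = pd.DataFrame(vals, index=idx, columns=cols)
        return ExpressionMatrix(values=df, biotype=pd.Series("miRNA", index=idx),
                                condition=cond, meta=expr_a.meta.copy())

    pairs = pd.DataFrame(pair_rows,
                         columns=["mirna", "target", "target_class", "source", "sites"])
    pairs = pairs.drop_duplicates(subset=["mirna", "target"]).reset_index(drop=True)
    return _mat(val_a, expr_a.condition), _mat(val_b, expr_b.condition), pairs, truth


def simulate_archetype_profiles(archetypes: list[tuple[str, int]],
                                n_per: int = 50, noise_sd: float = 0.1,
                                t: int = 27, seed: int = 1):
    """Coherent trajectory families for clustering recovery tests.

    Each (name, center) entry — center only meaningful for "bump" — yields
    `n_per` profiles equal to the archetype's unit latent plus Gaussian
    noise of sd `noise_sd`.  Returns (profiles DataFrame, true labels).
    """
    rng = substream(seed, "archetype-profiles")
    rows, labels, ids = [], [], []
    for a_idx, (name, center) in enumerate(archetypes):
        latent = _bump_latent(t, center) if name == "bump" else _unit_latents(t)[name]
        for i in range(n_per):
            rows.append(latent + rng.normal(0.0, noise_sd, size=t))
            labels.append(a_idx)
            ids.append(f"P{a_idx}_{i:03d}")
    profiles = pd.DataFrame(rows, index=pd.Index(ids, name="gene_id"),
                            columns=[f"t{i+1}" for i in range(t)])
    return profiles, pd.Series(labels, index=profiles.index, name="archetype")


_BASES = np.array(list("ACGT"))


def simulate_genotypes(cfg: GenoSimConfig, out_vcf):
    """Simulate a two-population SNP panel and write a VCF v4.2.

    Balding-Nichols: per SNP an ancestral frequency p is drawn uniformly
    from ``ancestral_freq_range`` and each population's frequency from
    Beta(p(1-F)/F, (1-p)(1-F)/F) with F = ``fst_target``; diploid genotypes
    are Binomial(2, freq).  Inside a sweep interval the swept population's
    frequency is pushed to within 0.98-1.0 of fixation (toward its major
    allele), depressing its diversity and inflating FST there.

    Returns (path, truth).
    """
    rng = substream(cfg.seed, "genotypes")
    n, L = cfg.n_snps, cfg.chrom_length
    pos = np.unique(rng.integers(1, L + 1, size=int(n * 1.2) + 16))
    while len(pos) < n:
        pos = np.unique(np.concatenate([pos, rng.integers(1, L + 1, size=n)]))
    keep = np.sort(rng.choice(len(pos), size=n, replace=False))
    pos = pos[keep]

    lo, hi = cfg.ancestral_freq_range
    p = rng.uniform(lo, hi, size=n)
    f = cfg.fst_target
    a, b = p * (1 - f) / f, (1 - p) * (1 - f) / f
    freqs = {pop: rng.beta(a, b) for pop in cfg.pop_labels}

    # separate substream: injecting a sweep must not perturb the genotype
    # draws of SNPs outside the swept interval
    rng_push = substream(cfg.seed, "sweep-push")
    for start, end, pop in cfg.sweep_intervals:
        inside = (pos >= start) & (pos <= end)
        push = rng_push.uniform(0.98, 1.0, size=int(inside.sum()))
        major_is_alt = freqs[pop][inside] >= 0.5
        freqs[pop][inside] = np.where(major_is_alt, push, 1.0 - push)

    m = cfg.n_individuals_per_pop
    geno = {pop: rng.binomial(2, freqs[pop][:, None], size=(n, m))
            for pop in cfg.pop_labels}

    ref_i = rng.integers(0, 4, size=n)
    alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4
    ref, alt = _BASES[ref_i], _BASES[alt_i]

    samples = [f"{pop}_{i+1}" for pop in cfg.pop_labels for i in range(m)]
    gt_str = np.array(["0/0", "0/1", "1/1"])
    with open(out_vcf, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={cfg.chrom},length={L}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        g = np.hstack([geno[pop] for pop in cfg.pop_labels])
        for i in range(n):
            fields = [cfg.chrom, str(pos[i]), f"snp{i}", ref[i], alt[i],
                      ".", "PASS", ".", "GT"]
            fh.write("\t".join(fields) + "\t" + "\t".join(gt_str[g[i]]) + "\n")

    truth = SimTruth(sweep_intervals=list(cfg.sweep_intervals), snp_pos=pos,
                     ancestral_freq=p)
    return out_vcf, truth
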