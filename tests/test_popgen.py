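from fractions import Fraction
from io import StringIO
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj as skbio_nj

from devomics import GenoSimConfig, simulate_genotypes
from devomics import popgen
from devomics.errors import AnnotationParseError, MissingSampleError, ValidationError
from devomics.popgen import (
    GenotypeMatrix,
    annotate_regions,
    genome_wide_fst,
    genotype_pca,
    ibs_distance,
    ld_decay,
    load_and_filter,
    merge_candidate_windows,
    neighbor_joining,
    nj_tree,
    sweep_scan,
    wc_site_components,
    windowed_fst,
    windowed_pi,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=1,length=100000>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
)


def write_vcf(tmp_path, rows, samples):
    text = VCF_HEADER + "\t".join(samples) + "\n"
    for r in rows:
        text += "\t".join(r) + "\n"
    p = tmp_path / "toy.vcf"
    p.write_text(text)
    return p


def make_geno(dosage, pops, pos=None, chrom=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    n_snps, n_ind = dosage.shape
    samples = [f"s{i}" for i in range(n_ind)]
    if pos is None:
        pos = np.arange(1, n_snps + 1) * 10
    return GenotypeMatrix(
        chrom=np.asarray(chrom if chrom is not None else ["1"] * n_snps),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(["A"] * n_snps), alt=np.asarray(["G"] * n_snps),
        dosage=dosage, samples=samples,
        populations=pd.Series([pops[i] for i in range(n_ind)],
                              index=samples))


class TestLoadAndFilter:
    def test_filters_and_logging(self, tmp_path):
        samples = [f"A_{i}" for i in range(1, 6)] + [f"B_{i}" for i in range(1, 6)]
        gts = lambda *g: list(g)  # noqa: E731
        rows = [
            # kept: full call rate, MAF 0.3
            ["1", "100", ".", "A", "G", ".", "PASS", ".", "GT"] + ["0/1"] * 6 + ["0/0"] * 4,
            # triallelic: dropped
            ["1", "200", ".", "A", "G,T", ".", "PASS", ".", "GT"] + ["0/1"] * 10,
            # indel: dropped
            ["1", "300", ".", "AT", "A", ".", "PASS", ".", "GT"] + ["0/1"] * 10,
            # low call rate (2/10 called): dropped
            ["1", "400", ".", "C", "T", ".", "PASS", ".", "GT"] + ["./."] * 8 + ["0/1"] * 2,
            # monomorphic (MAF 0 < 0.05): dropped
            ["1", "500", ".", "G", "C", ".", "PASS", ".", "GT"] + ["0/0"] * 10,
        ]
        path = write_vcf(tmp_path, rows, samples)
        pops = {"A": samples[:5], "B": samples[5:]}
        g = load_and_filter(path, pops)
        assert g.n_snps == 1 and g.pos[0] == 100
        log = g.filter_log
        assert log["multiallelic_or_indel"] == 2
        assert log["low_call_rate"] == 1
        assert log["low_maf"] == 1

    def test_missing_sample_is_named_error(self, tmp_path):
        path = write_vcf(tmp_path, [], ["A_1", "A_2"])
        with pytest.raises(MissingSampleError):
            load_and_filter(path, {"A": ["A_1", "ghost"]})


class TestWindowedPi:
    def test_hand_worked_site(self):
        # one site, 2 het diploids => 2 ref / 2 alt among 4 alleles:
        # pi = 2*2*2/(4*3) = 2/3; alone in a 100-bp window => 1/150 per bp
        g = make_geno([[1, 1]], {0: "A", 1: "A"}, pos=[50])
        pi = windowed_pi(g, "A", window=100, step=100, chrom_length=100)
        assert pi.pi_sum.iloc[0] == pytest.approx(2 / 3)
        assert pi.pi.iloc[0] == pytest.approx(2 / 3 / 100)

    def test_monomorphic_window_is_zero(self):
        g = make_geno([[2, 2], [0, 0]], {0: "A", 1: "A"})
        pi = windowed_pi(g, "A", window=100, step=100, chrom_length=100)
        assert (pi.pi == 0).all()

    def test_doubling_window_halves_per_bp_value(self):
        g = make_geno([[1, 1], [0, 1]], {0: "A", 1: "A"}, pos=[10, 20])
        p1 = windowed_pi(g, "A", window=100, step=100, chrom_length=100)
        p2 = windowed_pi(g, "A", window=200, step=200, chrom_length=100)
        assert p2.pi.iloc[0] == pytest.approx(p1.pi.iloc[0] / 2)

    def test_matches_allele_pair_oracle(self):
        rng = np.random.default_rng(6)
        dosage = rng.integers(0, 3, size=(50, 6))
        g = make_geno(dosage, {i: "A" for i in range(6)},
                      pos=rng.choice(np.arange(1, 5000), 50, replace=False))
        got = windowed_pi(g, "A", window=5000, step=5000, chrom_length=5000)
        total = Fraction(0)
        for row in dosage:
            # expand to the allele pool and count differing pairs exactly
            alleles = []
            for d in row:
                alleles += [1] * int(d) + [0] * (2 - int(d))
            diff = sum(a != b for a, b in combinations(alleles, 2))
            total += Fraction(diff, len(list(combinations(alleles, 2))) or 1)
        assert got.pi_sum.iloc[0] == pytest.approx(float(total), rel=1e-12)


class TestWeirCockerham:
    def test_fixed_opposite_alleles_give_unit_fst(self):
        dosage = np.array([[2] * 10 + [0] * 10] * 5)
        g = make_geno(dosage, {i: ("A" if i < 10 else "B") for i in range(20)})
        a, b, c = wc_site_components(g.dosage[:, :10], g.dosage[:, 10:])
        assert np.allclose(a, 0.5) and np.allclose(b, 0) and np.allclose(c, 0)
        assert genome_wide_fst(g, "A", "B") == pytest.approx(1.0)

    def test_all_heterozygote_components(self):
        # both pops all het: s2=0, h_bar=1 => a=0, b=-1/4, c=1/2 exactly
        dosage = np.ones((3, 12), dtype=int)
        g = make_geno(dosage, {i: ("A" if i < 6 else "B") for i in range(12)})
        a, b, c = wc_site_components(g.dosage[:, :6], g.dosage[:, 6:])
        assert np.allclose(a, 0.0)
        assert np.allclose(b, -0.25)
        assert np.allclose(c, 0.5)

    def test_panmictic_split_is_near_zero(self):
        rng = np.random.default_rng(1)
        freqs = rng.uniform(0.1, 0.9, size=3000)
        dosage = rng.binomial(2, freqs[:, None], size=(3000, 40))
        g = make_geno(dosage, {i: ("A" if i < 20 else "B") for i in range(40)},
                      pos=np.sort(rng.choice(10**6, 3000, replace=False)))
        assert abs(genome_wide_fst(g, "A", "B")) < 0.02

    def test_window_exclusion_below_min_snps(self):
        dosage = np.array([[1, 1, 0, 2]] * 5)
        g = make_geno(dosage, {0: "A", 1: "A", 2: "B", 3: "B"},
                      pos=[10, 20, 30, 40, 50])
        fst = windowed_fst(g, "A", "B", window=100, step=100, min_snps=10,
                           chrom_length=100)
        assert fst.excluded.iloc[0]


class TestSweepScan:
    def _tracks(self, n=100):
        rng = np.random.default_rng(0)
        start = np.arange(n) * 10_000 + 1
        base = dict(chrom="1", start=start, end=start + 49_999)
        fst = pd.DataFrame({**base, "n_snps": 50,
                            "fst": rng.uniform(0.1, 0.3, n), "excluded": False})
        pi_a = pd.DataFrame({**base, "n_snps": 50,
                             "pi": rng.uniform(2e-4, 4e-4, n)})
        pi_b = pd.DataFrame({**base, "n_snps": 50,
                             "pi": rng.uniform(2e-4, 4e-4, n)})
        return pi_a, pi_b, fst

    def test_joint_outlier_called_for_depleted_population(self):
        pi_a, pi_b, fst = self._tracks()
        fst.loc[40:42, "fst"] = 0.9
        pi_b.loc[40:42, "pi"] = 1e-6  # pop B lost diversity
        w, regions = sweep_scan(pi_a, pi_b, fst)
        assert (w.loc[40:42, "sweep_call"] == "sweep-in-B").all()
        assert (regions.population == "B").any()

    def test_identical_statistics_yield_no_candidates(self):
        pi_a, pi_b, fst = self._tracks()
        for df, col, val in ((fst, "fst", 0.2), (pi_a, "pi", 3e-4),
                             (pi_b, "pi", 2e-4)):
            df[col] = val
        w, regions = sweep_scan(pi_a, pi_b, fst)
        # every window ties at the quantile: strict comparisons call nothing
        assert (w.sweep_call == "none").all()
        assert regions.empty

    def test_zero_pi_windows_excluded_from_quantiles(self):
        pi_a, pi_b, fst = self._tracks()
        pi_a.loc[5, "pi"] = 0.0
        w, _ = sweep_scan(pi_a, pi_b, fst)
        assert w.loc[5, "excluded_reason"] == "zero_pi"
        assert w.loc[5, "sweep_call"] == "none"

    def test_overlapping_candidates_merge(self):
        w = pd.DataFrame({
            "chrom": ["1", "1"], "start": [1, 10_001],
            "end": [50_000, 60_000],
            "sweep_call": ["sweep-in-B", "sweep-in-B"]})
        regions = merge_candidate_windows(w)
        assert len(regions) == 1
        assert (regions.start.iloc[0], regions.end.iloc[0]) == (1, 60_000)
        # idempotent under re-merge
        again = merge_candidate_windows(w)
        pd.testing.assert_frame_equal(regions, again)


class TestAnnotateRegions:
    def _regions(self):
        return pd.DataFrame({"chrom": ["1", "1"], "start": [150, 1000],
                             "end": [300, 1200], "population": ["B", "B"],
                             "n_windows": [1, 1]})

    def test_bed_coordinate_conversion(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("1\t100\t200\tgeneX\n1\t400\t500\tgeneY\n")
        out = annotate_regions(self._regions(), bed)
        # BED [100,200) is 1-based 101-200: overlaps region 150-300
        assert out.gene_id.tolist() == ["geneX"]

    def test_gff3_gene_spanning_two_regions_deduplicated(self, tmp_path):
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "1\tsrc\tgene\t200\t1100\t.\t+\t.\tID=geneZ\n"
            "1\tsrc\texon\t200\t260\t.\t+\t.\tID=geneZ.e1\n")
        out = annotate_regions(self._regions(), gff)
        assert len(out) == 2  # one row per region
        assert out.attrs["selected_genes"] == ["geneZ"]

    def test_malformed_line_reports_line_number(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("1\t100\t200\tok\n1\tnotanumber\t300\tbad\n")
        with pytest.raises(AnnotationParseError, match=":2"):
            annotate_regions(self._regions(), bed)


class TestLdDecay:
    def test_perfect_ld_of_duplicated_snp(self):
        rng = np.random.default_rng(2)
        col = rng.integers(0, 3, size=10)
        g = make_geno(np.vstack([col, col]), {i: "A" for i in range(10)},
                      pos=[100, 250])
        bins = ld_decay(g, "A", max_dist=1000, bin_bp=100)
        hit = bins[(bins.bin_start == 101)]
        assert hit.n_pairs.iloc[0] == 1
        assert hit.mean_r2.iloc[0] == pytest.approx(1.0)

    def test_pairs_beyond_max_distance_excluded(self):
        rng = np.random.default_rng(3)
        g = make_geno(rng.integers(0, 3, size=(2, 10)),
                      {i: "A" for i in range(10)}, pos=[1, 300_002])
        bins = ld_decay(g, "A")
        assert bins.n_pairs.sum() == 0

    def test_independent_snps_background_level(self):
        # for unlinked sites, E[r^2] ~ 1/(n-1) with n individuals
        rng = np.random.default_rng(1)
        n_ind, n_snp = 50, 300
        freqs = rng.uniform(0.2, 0.8, size=n_snp)
        dosage = rng.binomial(2, freqs[:, None], size=(n_snp, n_ind))
        g = make_geno(dosage, {i: "A" for i in range(n_ind)},
                      pos=np.sort(rng.choice(np.arange(1, 30_000), n_snp,
                                             replace=False)))
        bins = ld_decay(g, "A", max_dist=30_000, bin_bp=30_000)
        mean_r2 = (bins.mean_r2 * bins.n_pairs).sum() / bins.n_pairs.sum()
        assert mean_r2 == pytest.approx(1 / (n_ind - 1), abs=0.01)

    def test_too_few_individuals_rejected(self):
        g = make_geno([[1, 1, 0]], {0: "A", 1: "A", 2: "A"})
        with pytest.raises(ValidationError):
            ld_decay(g, "A")


class TestPCA:
    def test_identical_individuals_coincide(self):
        # columns: individuals; the first two carry identical genotypes
        dosage = np.array([[0, 0, 2, 1],
                           [2, 2, 0, 1],
                           [1, 1, 1, 0],
                           [0, 0, 2, 2]])
        g = make_geno(dosage, {0: "A", 1: "A", 2: "B", 3: "B"})
        coords, _ = genotype_pca(g)
        pcs = coords[["PC1", "PC2"]].to_numpy(dtype=float)
        assert np.allclose(pcs[0], pcs[1], atol=1e-9)

    def test_two_populations_separate_on_pc1(self, geno_panel):
        _, g = geno_panel
        coords, evals = genotype_pca(g)
        a = coords[coords.population == "A"]["PC1"]
        b = coords[coords.population == "B"]["PC1"]
        assert a.max() < b.min() or b.max() < a.min()
        assert evals[0] > evals[1]


class TestNeighborJoining:
    def test_additive_four_taxon_tree_recovered_exactly(self):
        # ((A:1,B:2):1,(C:3,D:4)): additive matrix from path lengths
        d = pd.DataFrame(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float)
        nwk = neighbor_joining(d)
        tree = TreeNode.read(StringIO(nwk))
        # the split {A,B} | {C,D} must be present with interior edge 1
        for node in tree.non_tips():
            tips = {t.name for t in node.tips()}
            if tips in ({"A", "B"}, {"C", "D"}):
                break
        else:
            pytest.fail("expected split not found")
        dist = tree.tip_tip_distances()
        for i, j in combinations("ABCD", 2):
            assert dist[i, j] == pytest.approx(d.loc[i, j])

    def test_three_taxa_closed_form(self):
        d = pd.DataFrame([[0, 4, 6], [4, 0, 8], [6, 8, 0]],
                         index=list("XYZ"), columns=list("XYZ"), dtype=float)
        nwk = neighbor_joining(d)
        tree = TreeNode.read(StringIO(nwk))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"X": pytest.approx(1.0), "Y": pytest.approx(3.0),
                           "Z": pytest.approx(5.0)}

    def test_random_additive_matrices_recover_topology(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            nwk_true, d = random_additive_tree(8, rng)
            got = neighbor_joining(d)
            assert rf_distance(nwk_true, got) == 0

    def test_agrees_with_skbio_on_random_distances(self):
        rng = np.random.default_rng(13)
        x = rng.uniform(size=(6, 10))
        d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        labels = [f"t{i}" for i in range(6)]
        ours = neighbor_joining(pd.DataFrame(d, index=labels, columns=labels))
        ref = skbio_nj(DistanceMatrix(d, ids=labels))
        out = StringIO()
        ref.write(out)
        assert rf_distance(ours, out.getvalue()) == 0

    def test_two_population_panel_forms_clades_with_support(self, geno_panel):
        _, g = geno_panel
        nwk = nj_tree(g, bootstrap=30, seed=1)
        tree = TreeNode.read(StringIO(nwk), convert_underscores=False)
        pop_a = {s for s in g.samples if s.startswith("A_")}
        for node in tree.non_tips():
            tips = {t.name for t in node.tips()}
            if tips == pop_a or tips == set(g.samples) - pop_a:
                assert int(node.name) >= 95
                break
        else:
            pytest.fail("population split not recovered")


def random_additive_tree(n_taxa, rng):
    """Random binary tree with positive branch lengths; returns (newick, D)."""
    nodes = [f"t{i}" for i in range(n_taxa)]
    newicks = {x: x for x in nodes}
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False), reverse=True)
        a, b = nodes.pop(i), nodes.pop(j)
        la, lb = rng.uniform(0.5, 2.0, size=2)
        key = f"({newicks.pop(a)}:{la},{newicks.pop(b)}:{lb})"
        nodes.append(key)
        newicks[key] = key
    la, lb, lc = rng.uniform(0.5, 2.0, size=3)
    nwk = (f"({newicks[nodes[0]]}:{la},{newicks[nodes[1]]}:{lb},"
           f"{newicks[nodes[2]]}:{lc});")
    tree = TreeNode.read(StringIO(nwk))
    tips = [t.name for t in tree.tips()]
    dist = tree.tip_tip_distances()
    d = pd.DataFrame(dist.data, index=dist.ids, columns=dist.ids)
    return nwk, d.loc[sorted(tips), sorted(tips)]


def rf_distance(nwk1, nwk2):
    t1 = TreeNode.read(StringIO(nwk1))
    t2 = TreeNode.read(StringIO(nwk2))
    return t1.compare_rfd(t2)


def test_ibs_distance_zero_on_self(geno_panel):
    _, g = geno_panel
    d = ibs_distance(g)
    assert np.allclose(np.diag(d), 0.0)
    assert (d.to_numpy() >= 0).all()
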