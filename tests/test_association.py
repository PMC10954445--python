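import math

import numpy as np
import pandas as pd
import pytest

from nrskit.association import (
    batch_effect_filter,
    bh_fdr,
    bonferroni_threshold,
    cis_eqtl_scan,
    genotype_pca,
    gwas,
    hudson_fst,
    ld_catalogue_scan,
    ld_r2,
    pbs,
    pbs_scan,
)
from nrskit.genotyping import GenotypeMatrix


def matrix_from(dosage: np.ndarray, samples=None, loci=None):
    n_loci, n_samples = dosage.shape
    samples = samples or [f"s{i}" for i in range(n_samples)]
    loci = loci or [f"L{i}" for i in range(n_loci)]
    frame = pd.DataFrame(dosage, index=loci, columns=samples)
    return GenotypeMatrix(dosage=frame.astype("int8"))


def hwe_dosage(rng, af, n):
    return rng.binomial(1, af, size=(n, 2)).sum(axis=1)


def simulate_panel(rng, afs_by_pop, n_per_pop):
    """Genotype matrix + panel frame for stratified populations."""
    pops = list(afs_by_pop)
    columns, rows = {}, []
    for pop in pops:
        for i in range(n_per_pop):
            name = f"{pop}_{i}"
            columns[name] = [
                int(hwe_dosage(rng, af, 1)[0]) for af in afs_by_pop[pop]]
            rows.append({"sample": name, "population": pop,
                         "platform": "ONT", "sex": "M",
                         "trio_id": "", "trio_role": "none"})
    dosage = pd.DataFrame(columns,
                          index=[f"L{i}"
                                 for i in range(len(next(iter(
                                     afs_by_pop.values()))))])
    return (GenotypeMatrix(dosage=dosage.astype("int8")),
            pd.DataFrame(rows))


class TestBhFdr:
    def test_single_small_p(self):
        flags, q = bh_fdr([0.01], 0.05)
        assert flags[0]
        assert q[0] == pytest.approx(0.01)

    def test_step_up_by_hand(self):
        # (0.001, 0.02, 0.9): q = (0.003, 0.03, 0.9)
        flags, q = bh_fdr([0.001, 0.02, 0.9], 0.05)
        assert list(flags) == [True, True, False]
        assert q == pytest.approx([0.003, 0.03, 0.9])

    def test_all_ones(self):
        flags, q = bh_fdr([1.0, 1.0, 1.0], 0.05)
        assert not flags.any()

    def test_q_monotone_in_p(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=100)
        _, q = bh_fdr(p, 0.05)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q >= p - 1e-12).all()


class TestBonferroni:
    def test_paper_threshold(self):
        threshold, display = bonferroni_threshold(0.05, 5643)
        assert display == "8.9e-06"
        assert threshold == pytest.approx(0.05 / 5643)

    def test_identity_cases(self):
        assert bonferroni_threshold(0.05, 1)[0] == 0.05
        assert bonferroni_threshold(0.05, 5)[0] == pytest.approx(0.01)

    def test_bad_m(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestHudsonFst:
    def test_equal_frequencies_near_zero(self):
        fst = hudson_fst([500], [1000], [500], [1000])
        assert abs(fst[0]) < 0.01

    def test_fixed_difference_one(self):
        fst = hudson_fst([100], [100], [0], [100])
        assert fst[0] == pytest.approx(1.0)

    def test_formula_by_hand(self):
        # p1=0.8, p2=0.2, n1=n2=50 alleles
        p1, p2, n1, n2 = 0.8, 0.2, 50, 50
        num = ((p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1)
               - p2 * (1 - p2) / (n2 - 1))
        den = p1 * (1 - p2) + p2 * (1 - p1)
        fst = hudson_fst([40], [50], [10], [50])
        assert fst[0] == pytest.approx(num / den)

    def test_degenerate_denominator_nan(self):
        fst = hudson_fst([0], [100], [0], [100])
        assert math.isnan(fst[0])


class TestPbs:
    def test_zero(self):
        assert pbs(0.0, 0.0, 0.0) == 0.0

    def test_ln2_closed_form(self):
        assert pbs(0.5, 0.5, 0.0) == pytest.approx(math.log(2))

    def test_symmetric_point_one(self):
        expected = -math.log(0.9) / 2
        assert pbs(0.1, 0.1, 0.1) == pytest.approx(expected, abs=1e-5)
        assert pbs(0.1, 0.1, 0.1) == pytest.approx(0.05268, abs=1e-4)

    def test_clamping_high_fst(self):
        assert np.isfinite(pbs(1.0, 1.0, 0.0))

    def test_monotonicity_grid(self):
        grid = np.linspace(0.0, 0.9, 10)
        base = pbs(0.3, 0.3, 0.3)
        assert all(pbs(f, 0.3, 0.3) >= base - 1e-12 for f in grid
                   if f >= 0.3)
        assert all(pbs(0.3, 0.3, f) <= base + 1e-12 for f in grid
                   if f >= 0.3)


class TestGenotypePca:
    def test_separates_populations(self):
        rng = np.random.default_rng(1)
        n_loci = 150
        afs = {"A": rng.uniform(0.1, 0.4, n_loci),
               "B": rng.uniform(0.6, 0.9, n_loci)}
        matrix, panel = simulate_panel(rng, afs, 30)
        scores, explained = genotype_pca(matrix, n_components=2)
        pc1 = scores["PC1"]
        a = pc1[[s for s in scores.index if s.startswith("A_")]]
        b = pc1[[s for s in scores.index if s.startswith("B_")]]
        # silhouette-style separation on PC1
        gap = abs(a.mean() - b.mean())
        spread = max(a.std(), b.std())
        assert gap > 4 * spread

    def test_constant_matrix_rejected(self):
        dosage = np.ones((20, 30), dtype=int)
        with pytest.raises(ValueError):
            genotype_pca(matrix_from(dosage))

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(2)
        dosage = rng.binomial(2, 0.4, size=(60, 40))
        matrix = matrix_from(dosage)
        scores, _ = genotype_pca(matrix, n_components=3)
        perm = rng.permutation(40)
        shuffled = GenotypeMatrix(
            dosage=matrix.dosage.iloc[:, perm])
        scores2, _ = genotype_pca(shuffled, n_components=3)
        pd.testing.assert_frame_equal(
            scores2.loc[scores.index], scores, atol=1e-8, rtol=1e-6)


class TestPbsScan:
    def _three_pop(self, rng, n_loci=400, n=50, planted=None):
        afs = {}
        base = rng.uniform(0.2, 0.8, n_loci)
        for pop in ("A", "B", "C"):
            noise = np.clip(base + rng.normal(0, 0.05, n_loci), 0.01, 0.99)
            afs[pop] = noise
        if planted is not None:
            afs["A"][planted] = 0.9
            afs["B"][planted] = 0.05
            afs["C"][planted] = 0.05
        return simulate_panel(rng, afs, n)

    def test_planted_locus_detected(self):
        rng = np.random.default_rng(3)
        matrix, panel = self._three_pop(rng, planted=7)
        result, signals = pbs_scan(matrix, panel, "A", "B", "C",
                                   downsample_to=40, seed=0)
        assert bool(result.loc[result["locus"] == "L7",
                               "candidate"].iloc[0])

    def test_full_population_replicates_identical(self):
        rng = np.random.default_rng(4)
        matrix, panel = self._three_pop(rng, n_loci=100, n=30)
        result, _ = pbs_scan(matrix, panel, "A", "B", "C",
                             downsample_to=30, seed=0)
        # downsample_to == population size: every replicate identical,
        # so hits are 0 or the full replicate count
        assert set(result["replicate_hits"].unique()) <= {0, 10}

    def test_neutral_candidate_rate_bounded(self):
        rng = np.random.default_rng(5)
        total_candidates = total_loci = 0
        for rep in range(5):
            matrix, panel = self._three_pop(rng, n_loci=300, n=40)
            result, _ = pbs_scan(matrix, panel, "A", "B", "C",
                                 downsample_to=30, seed=rep)
            total_candidates += int(result["candidate"].sum())
            total_loci += len(result)
        assert total_candidates <= 0.002 * total_loci + 3

    def test_merge_window_groups_signals(self):
        rng = np.random.default_rng(6)
        matrix, panel = self._three_pop(rng, n_loci=50, n=50, planted=10)
        # plant a second hit 500 kb away on the same chromosome
        for pop, af in (("A", 0.9), ("B", 0.05), ("C", 0.05)):
            cols = [s for s in matrix.samples if s.startswith(pop)]
            matrix.dosage.loc["L11", cols] = rng.binomial(
                1, af, size=(len(cols), 2)).sum(axis=1).astype("int8")
        positions = {f"L{i}": ("chr1", i * 10_000) for i in range(50)}
        positions["L11"] = ("chr1", positions["L10"][1] + 500_000)
        result, signals = pbs_scan(matrix, panel, "A", "B", "C",
                                   downsample_to=40, seed=0,
                                   positions=positions)
        cands = set(result.loc[result["candidate"], "locus"])
        if {"L10", "L11"} <= cands:
            merged = signals[signals["locus"].isin(["L10", "L11"])]
            assert merged["signal"].nunique() == 1


class TestBatchEffectFilter:
    def _panel(self, n, platforms):
        return pd.DataFrame({
            "sample": [f"s{i}" for i in range(n)],
            "population": ["P"] * n,
            "platform": [platforms[i % len(platforms)] for i in range(n)],
            "sex": ["M"] * n, "trio_id": [""] * n,
            "trio_role": ["none"] * n})

    def test_platform_independent_rarely_flagged(self):
        rng = np.random.default_rng(7)
        dosage = rng.binomial(2, 0.4, size=(100, 60))
        q = batch_effect_filter(matrix_from(dosage),
                                self._panel(60, ["ONT", "HiFi"]))
        assert (q < 0.05).mean() <= 0.05

    def test_platform_determined_flagged(self):
        rng = np.random.default_rng(8)
        dosage = rng.binomial(2, 0.4, size=(50, 60))
        # locus 0 genotype fully determined by platform
        dosage[0] = [2 if i % 2 == 0 else 0 for i in range(60)]
        q = batch_effect_filter(matrix_from(dosage),
                                self._panel(60, ["ONT", "HiFi"]))
        assert q.iloc[0] < 0.05

    def test_single_platform_untestable(self):
        rng = np.random.default_rng(9)
        dosage = rng.binomial(2, 0.4, size=(20, 30))
        q = batch_effect_filter(matrix_from(dosage),
                                self._panel(30, ["ONT"]))
        assert (q == 1.0).all()


class TestCisEqtl:
    def _inputs(self, rng, n_samples=200, n_loci=30, n_transcripts=10,
                beta=0.0, planted=(0, 0)):
        dosage = rng.binomial(2, 0.3, size=(n_loci, n_samples))
        matrix = matrix_from(dosage)
        positions = {f"L{i}": ("chr1", 10_000 * i) for i in range(n_loci)}
        tss = {f"T{j}": ("chr1", 10_000 * j * 3)
               for j in range(n_transcripts)}
        expr = rng.normal(10, 1, size=(n_transcripts, n_samples))
        if beta:
            locus, transcript = planted
            expr[transcript] += beta * dosage[locus]
        expression = pd.DataFrame(expr,
                                  index=[f"T{j}"
                                         for j in range(n_transcripts)],
                                  columns=matrix.samples)
        return expression, matrix, tss, positions

    def test_window_excludes_distant_locus(self):
        rng = np.random.default_rng(10)
        expression, matrix, tss, positions = self._inputs(rng)
        positions["L0"] = ("chr1", 5_000_000)
        result = cis_eqtl_scan(expression, matrix, tss, positions,
                               n_genotype_pcs=0)
        assert "L0" not in set(result["locus"])

    def test_planted_pair_recovered(self):
        rng = np.random.default_rng(11)
        expression, matrix, tss, positions = self._inputs(
            rng, beta=1.5, planted=(3, 1))
        result = cis_eqtl_scan(expression, matrix, tss, positions,
                               n_genotype_pcs=2)
        hit = result[(result["locus"] == "L3") & (result["target"] == "T1")]
        assert len(hit) == 1
        assert bool(hit["significant"].iloc[0])

    def test_null_fdr_calibrated(self):
        """Realized FDR under the null stays near nominal (everything
        significant is a false discovery)."""
        rng = np.random.default_rng(12)
        false = tested = 0
        for rep in range(20):
            expression, matrix, tss, positions = self._inputs(
                rng, n_samples=120, n_loci=20, n_transcripts=8)
            result = cis_eqtl_scan(expression, matrix, tss, positions,
                                   n_genotype_pcs=0)
            false += int(result["significant"].sum())
            tested += len(result)
        # families with any rejection are rare under the null
        assert false / max(tested, 1) < 0.02

    def test_multiallelic_dropped(self):
        rng = np.random.default_rng(13)
        expression, matrix, tss, positions = self._inputs(rng)
        result = cis_eqtl_scan(expression, matrix, tss, positions,
                               multiallelic={"L1"}, n_genotype_pcs=0)
        assert "L1" not in set(result["locus"])


class TestGwas:
    def _inputs(self, rng, n_samples=300, n_loci=50, beta=0.0, trait_of=0):
        dosage = rng.binomial(2, 0.3, size=(n_loci, n_samples))
        matrix = matrix_from(dosage)
        phen = pd.DataFrame({
            "age": rng.integers(20, 70, n_samples).astype(float),
            "sex": rng.integers(0, 2, n_samples).astype(float),
            "BMI": rng.normal(23, 3, n_samples),
        }, index=matrix.samples)
        phen["trait"] = (0.02 * phen["age"] + 0.1 * phen["sex"]
                         + rng.normal(0, 1, n_samples))
        if beta:
            phen["trait"] += beta * dosage[trait_of]
        return matrix, phen

    def test_null_lambda_gc_near_one(self):
        rng = np.random.default_rng(14)
        matrix, phen = self._inputs(rng, n_samples=400, n_loci=800)
        result, meta = gwas(matrix, phen, ["trait"], n_pcs=0)
        assert 0.9 < meta["lambda_gc"] < 1.1

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(15)
        matrix, phen = self._inputs(rng, beta=0.8, trait_of=5)
        result, meta = gwas(matrix, phen, ["trait"], n_pcs=0)
        hit = result[result["locus"] == "L5"]
        assert bool(hit["significant"].iloc[0])
        assert hit["p"].iloc[0] <= meta["bonferroni_threshold"]

    def test_bmi_excluded_from_own_covariates(self):
        rng = np.random.default_rng(16)
        matrix, phen = self._inputs(rng, n_samples=100, n_loci=10)
        # would be a perfect collinearity if BMI stayed in the design
        result, meta = gwas(matrix, phen, ["BMI"], n_pcs=0)
        assert np.isfinite(result["p"]).all()

    def test_logistic_model(self):
        rng = np.random.default_rng(17)
        matrix, phen = self._inputs(rng, n_samples=200, n_loci=5)
        phen["cc"] = rng.integers(0, 2, 200)
        result, meta = gwas(matrix, phen, ["cc"], model="logistic",
                            n_pcs=0)
        assert meta["model"] == "logistic"
        assert ((result["p"] > 0) & (result["p"] <= 1)).all()

    def test_unknown_model_rejected(self):
        rng = np.random.default_rng(18)
        matrix, phen = self._inputs(rng, n_samples=50, n_loci=5)
        with pytest.raises(ValueError):
            gwas(matrix, phen, ["trait"], model="ridge")


class TestLdR2:
    def test_identical_vectors(self):
        a = [0, 1, 2, 1, 0, 2, 1]
        assert ld_r2(a, a) == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(19)
        a = rng.binomial(2, 0.4, 100)
        b = rng.binomial(2, 0.4, 100)
        assert ld_r2(a, b) == ld_r2(b, a)

    def test_independent_vectors_small(self):
        rng = np.random.default_rng(20)
        hits = 0
        for _ in range(40):
            a = rng.binomial(2, 0.4, 500)
            b = rng.binomial(2, 0.4, 500)
            if ld_r2(a, b) < 0.05:
                hits += 1
        assert hits >= 36   # ~95% of replicates

    def test_constant_vector_nan(self):
        assert math.isnan(ld_r2([1, 1, 1], [0, 1, 2]))

    def test_missing_as_ref_coding(self):
        a = [2, -1, 2, 0]
        b = [2, 0, 2, 0]
        assert ld_r2(a, b, "as_ref") == pytest.approx(1.0)

    def test_pairwise_deletion(self):
        a = [2, -1, 1, 0]
        b = [2, 2, 1, 0]
        assert ld_r2(a, b, "pairwise") == pytest.approx(1.0)

    def test_unknown_policy(self):
        with pytest.raises(ValueError):
            ld_r2([0, 1], [0, 1], "drop")


class TestLdCatalogueScan:
    def _inputs(self, rng, offset=50_000, r2_identical=True, p=1e-12):
        n = 100
        nrs = pd.DataFrame(
            [rng.binomial(2, 0.4, n)], index=["L0"],
            columns=[f"s{i}" for i in range(n)]).astype(float)
        snp_row = (nrs.loc["L0"].to_numpy().copy() if r2_identical
                   else rng.binomial(2, 0.4, n))
        snps = pd.DataFrame([snp_row], index=["SNP1"],
                            columns=nrs.columns).astype(float)
        table = pd.DataFrame([{"snp": "SNP1", "chrom": "chr1",
                               "position": 100_000 + offset, "p": p}])
        positions = {"L0": ("chr1", 100_000)}
        return nrs, positions, snps, table

    def test_tag_within_window_reported(self):
        rng = np.random.default_rng(21)
        pairs = ld_catalogue_scan(*self._inputs(rng))
        assert len(pairs) == 1
        assert pairs["r2"].iloc[0] == pytest.approx(1.0)

    def test_tag_beyond_window_excluded(self):
        rng = np.random.default_rng(22)
        pairs = ld_catalogue_scan(*self._inputs(rng, offset=150_000))
        assert len(pairs) == 0

    def test_weak_ld_excluded(self):
        rng = np.random.default_rng(23)
        pairs = ld_catalogue_scan(*self._inputs(rng, r2_identical=False))
        assert len(pairs) == 0

    def test_nonsignificant_snp_excluded(self):
        rng = np.random.default_rng(24)
        pairs = ld_catalogue_scan(*self._inputs(rng, p=1e-4))
        assert len(pairs) == 0
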