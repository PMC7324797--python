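import math

import numpy as np
import pandas as pd
import pytest

from bsmeth.diffmeth import (
    DiffConfig,
    call_dmr,
    dml_test,
    estimate_dispersion,
    filter_covered_loci,
    map_regions_to_genes,
    wald_test_dml,
)
from bsmeth.genome_io import FeatureAnnotation, GeneModel
from bsmeth.methylome import CX_COLUMNS, MethylomeSample


def sample_from(rows, sid="s", group="G", rep="1"):
    return MethylomeSample(sid, group, rep, pd.DataFrame(rows, columns=CX_COLUMNS))


def make_group(coverages, contig="c1", pos=20, meth_frac=0.5, group="G"):
    """One single-site replicate per coverage value."""
    out = []
    for i, cov in enumerate(coverages):
        meth = int(round(cov * meth_frac))
        out.append(
            sample_from(
                [(contig, pos, "+", meth, cov - meth, "CpG", "CGA")],
                sid=f"{group}{i}", group=group, rep=str(i),
            )
        )
    return out


GENIC_ANN = FeatureAnnotation(
    [GeneModel("g1", "c1", "+", 10, 100, [(10, 100)])], {"c1": 200}
)


class TestFilter:
    def test_every_replicate_rule(self):
        a = make_group([10, 10, 10])
        b = make_group([10, 10, 9])
        kept = filter_covered_loci(a, b, GENIC_ANN, DiffConfig())
        assert len(kept) == 0
        b_ok = make_group([10, 10, 10])
        assert len(filter_covered_loci(a, b_ok, GENIC_ANN, DiffConfig())) == 1

    def test_intergenic_excluded_when_genic_required(self):
        a = make_group([30, 30, 30], pos=150)
        b = make_group([30, 30, 30], pos=150)
        assert len(filter_covered_loci(a, b, GENIC_ANN, DiffConfig())) == 0
        cfg = DiffConfig(require_genic=False)
        assert len(filter_covered_loci(a, b, None, cfg)) == 1

    def test_non_target_context_excluded(self):
        rows = [("c1", 20, "+", 5, 25, "CHH", "CAT")]
        a = [sample_from(rows, sid=f"a{i}") for i in range(3)]
        b = [sample_from(rows, sid=f"b{i}") for i in range(3)]
        assert len(filter_covered_loci(a, b, GENIC_ANN, DiffConfig())) == 0

    def test_matches_brute_force_recount(self, small_dataset):
        genome, ann, samples, _ = small_dataset
        a = [samples[("G1", r)] for r in (1, 2, 3)]
        b = [samples[("G2", r)] for r in (1, 2, 3)]
        cfg = DiffConfig()
        kept = filter_covered_loci(a, b, ann, cfg)
        got = set(zip(kept["contig"], kept["pos"], kept["strand"]))
        # brute force: loop over sites of the first replicate
        expect = set()
        by_key = [
            s.sites.set_index(["contig", "pos", "strand"]) for s in a + b
        ]
        for key, row in by_key[0].iterrows():
            if row["context"] != "CpG":
                continue
            contig, pos, strand = key
            if ann.classify(contig, pos) == "intergenic":
                continue
            if all(
                key in df.index
                and df.loc[key, "meth"] + df.loc[key, "unmeth"] >= cfg.min_coverage
                for df in by_key
            ):
                expect.add(key)
        assert got == expect


class TestWaldTest:
    def test_identical_counts_give_zero_statistic(self):
        m = np.array([[5, 5, 5]], float)
        c = np.array([[20, 20, 20]], float)
        out = wald_test_dml(m, c, m, c, 0.0, 0.0)
        assert out["stat"].iloc[0] == 0.0
        assert out["p"].iloc[0] == 1.0

    def test_worked_example(self):
        # A = (50,100) x3, B = (10,100) x3, phi = 0: pooled proportions 0.5
        # vs 0.1 over 300 calls each, unbiased variance p q / (N - 1)
        ma = np.full((1, 3), 50.0); ca = np.full((1, 3), 100.0)
        mb = np.full((1, 3), 10.0); cb = np.full((1, 3), 100.0)
        out = wald_test_dml(ma, ca, mb, cb, 0.0, 0.0)
        se = math.sqrt(0.5 * 0.5 / 299 + 0.1 * 0.9 / 299)
        assert out["se"].iloc[0] == pytest.approx(se, rel=1e-12)
        assert out["stat"].iloc[0] == pytest.approx(0.4 / se, rel=1e-12)
        assert out["stat"].iloc[0] == pytest.approx(11.86, abs=0.005)

    def test_boundary_proportions_define_zero_statistic(self):
        z = np.zeros((1, 3))
        c = np.full((1, 3), 20.0)
        out = wald_test_dml(z, c, z, c, 0.0, 0.0)
        assert out["stat"].iloc[0] == 0.0 and out["p"].iloc[0] == 1.0
        full = c.copy()
        out = wald_test_dml(full, c, full, c, 0.0, 0.0)
        assert out["stat"].iloc[0] == 0.0

    def test_zero_coverage_group_skipped_with_reason(self):
        ma = np.array([[5.0]]); ca = np.array([[10.0]])
        mb = np.array([[0.0]]); cb = np.array([[0.0]])
        out = wald_test_dml(ma, ca, mb, cb, 0.0, 0.0)
        assert bool(out["skipped"].iloc[0])
        assert math.isnan(out["p"].iloc[0])

    def test_dispersion_widens_se(self):
        ma = np.full((1, 3), 30.0); ca = np.full((1, 3), 100.0)
        mb = np.full((1, 3), 10.0); cb = np.full((1, 3), 100.0)
        se0 = wald_test_dml(ma, ca, mb, cb, 0.0, 0.0)["se"].iloc[0]
        se1 = wald_test_dml(ma, ca, mb, cb, 0.05, 0.05)["se"].iloc[0]
        assert se1 > se0


def simulate_counts(rng, n_loci, reps, p, phi, cov_mean):
    cov = rng.poisson(cov_mean, size=(n_loci, reps)).clip(min=1)
    if phi > 0:
        a = p * (1 - phi) / phi
        b = (1 - p) * (1 - phi) / phi
        pr = rng.beta(a, b, size=(n_loci, reps))
    else:
        pr = np.full((n_loci, reps), p)
    meth = rng.binomial(cov, pr)
    return meth.astype(float), cov.astype(float)


class TestDispersion:
    def test_binomial_data_recovers_zero(self, rng):
        meth, cov = simulate_counts(rng, 20_000, 3, 0.3, 0.0, 30)
        assert estimate_dispersion(meth, cov) < 0.004

    def test_phi_recovery(self, rng):
        meth, cov = simulate_counts(rng, 40_000, 3, 0.3, 0.05, 30)
        est = estimate_dispersion(meth, cov)
        assert est == pytest.approx(0.05, abs=0.01)

    def test_single_replicate_returns_zero(self, rng):
        meth, cov = simulate_counts(rng, 100, 1, 0.3, 0.0, 30)
        assert estimate_dispersion(meth, cov) == 0.0


class TestCalibrationAndPower:
    def test_null_type_one_error(self, rng):
        """At a moderate rate the empirical size matches alpha at 0.01 and 0.05."""
        n = 20_000
        ma, ca = simulate_counts(rng, n, 3, 0.3, 0.02, 30)
        mb, cb = simulate_counts(rng, n, 3, 0.3, 0.02, 30)
        phi_a = estimate_dispersion(ma, ca)
        phi_b = estimate_dispersion(mb, cb)
        out = wald_test_dml(ma, ca, mb, cb, phi_a, phi_b)
        for alpha in (0.01, 0.05):
            emp = float((out["p"] < alpha).mean())
            se = math.sqrt(alpha * (1 - alpha) / n)
            assert abs(emp - alpha) < 3 * se, (alpha, emp)

    def test_power_monotone_in_effect_and_coverage(self, rng):
        n = 4000
        powers_effect = []
        for delta in (0.05, 0.15, 0.30):
            ma, ca = simulate_counts(rng, n, 3, 0.3, 0.02, 30)
            mb, cb = simulate_counts(rng, n, 3, 0.3 + delta, 0.02, 30)
            out = wald_test_dml(ma, ca, mb, cb, 0.02, 0.02)
            powers_effect.append(float(out["significant"].mean()))
        assert powers_effect == sorted(powers_effect)
        powers_cov = []
        for cov in (5, 15, 45):
            ma, ca = simulate_counts(rng, n, 3, 0.3, 0.02, cov)
            mb, cb = simulate_counts(rng, n, 3, 0.45, 0.02, cov)
            out = wald_test_dml(ma, ca, mb, cb, 0.02, 0.02)
            powers_cov.append(float(out["significant"].mean()))
        assert powers_cov == sorted(powers_cov)


def dml_frame(positions, stats, sig, diffs=None, contig="c1"):
    stats = np.asarray(stats, float)
    if diffs is None:
        diffs = np.sign(stats) * 0.3
    return pd.DataFrame(
        {
            "contig": contig,
            "pos": positions,
            "strand": "+",
            "mu1": 0.5,
            "mu2": 0.2,
            "diff": diffs,
            "se": 0.1,
            "stat": stats,
            "p": np.where(sig, 0.001, 0.5),
            "p_adj": np.where(sig, 0.01, 0.7),
            "significant": sig,
            "skipped": False,
        }
    )


class TestCallDmr:
    def test_no_significant_loci_no_regions(self):
        dml = dml_frame([10, 20, 30], [1.0, -0.5, 0.3], [False] * 3)
        assert call_dmr(dml) == []

    def test_five_consecutive_significant_loci(self):
        dml = dml_frame([10, 25, 40, 55, 70], [3, 3, 4, 3, 3], [True] * 5)
        regions = call_dmr(dml)
        assert len(regions) == 1
        r = regions[0]
        assert r.area_stat == pytest.approx(16.0)
        assert r.frac_significant == 1.0
        assert (r.start, r.end) == (11, 71)  # 1-based inclusive
        assert r.n_sites == 5

    def test_two_clusters_split_by_gap(self):
        pos = [10, 25, 40, 55, 70, 500, 515, 530, 545, 560]
        dml = dml_frame(pos, [3] * 10, [True] * 10)
        regions = call_dmr(dml, DiffConfig(merge_distance=100))
        assert len(regions) == 2

    def test_opposite_sign_clusters_not_merged(self):
        pos = [10, 20, 30, 60, 70, 80]
        stats = [3, 3, 3, -3, -3, -3]
        dml = dml_frame(pos, stats, [True] * 6)
        regions = call_dmr(dml, DiffConfig(min_length=10))
        assert len(regions) == 2
        assert {np.sign(r.mean_diff) for r in regions} == {1.0, -1.0}

    def test_thresholds_enforced(self):
        dml = dml_frame([10, 20], [3, 3], [True] * 2)
        assert call_dmr(dml, DiffConfig(min_sites=3)) == []  # too few sites
        dml = dml_frame([10, 20, 30], [3, 3, 3], [True] * 3)
        assert call_dmr(dml, DiffConfig(min_length=50)) == []  # span 21 < 50
        # low significant fraction: 2 of 5 tested inside the span
        dml = dml_frame([10, 20, 30, 40, 110], [3, 0.1, 0.1, 0.2, 3],
                        [True, False, False, False, True])
        assert call_dmr(dml, DiffConfig(pct_sig=0.5)) == []

    def test_ranked_by_absolute_area_stat(self):
        d1 = dml_frame([10, 20, 30], [2, 2, 2], [True] * 3)
        d2 = dml_frame([500, 510, 520], [-4, -4, -4], [True] * 3)
        dml = pd.concat([d1, d2], ignore_index=True)
        regions = call_dmr(dml, DiffConfig(min_length=10))
        assert [r.area_stat for r in regions] == [-12.0, 6.0]

    def test_deterministic(self):
        dml = dml_frame([10, 20, 30, 200, 210, 220], [3, 3, 3, 3, 3, 3], [True] * 6)
        r1 = call_dmr(dml, DiffConfig(min_length=10))
        r2 = call_dmr(dml, DiffConfig(min_length=10))
        assert [(r.contig, r.start, r.end) for r in r1] == [
            (r.contig, r.start, r.end) for r in r2
        ]


class TestMapRegionsToGenes:
    ANN = FeatureAnnotation(
        [
            GeneModel("g1", "c1", "+", 10, 100, [(10, 100)]),
            GeneModel("g2", "c1", "-", 80, 200, [(80, 200)]),
        ],
        {"c1": 400},
    )

    def region(self, start, end, area=5.0):
        from bsmeth.diffmeth import DmRegion

        return DmRegion("c1", start, end, 3, 1.0, area, 0.3)

    def test_region_inside_one_gene(self):
        df = map_regions_to_genes([self.region(20, 60)], self.ANN)
        assert list(df["gene_id"]) == ["g1"]
        assert df["n_regions"].iloc[0] == 1

    def test_region_spanning_overlapping_genes(self):
        df = map_regions_to_genes([self.region(85, 95)], self.ANN)
        assert set(df["gene_id"]) == {"g1", "g2"}

    def test_intergenic_region_maps_nowhere(self):
        df = map_regions_to_genes([self.region(250, 300)], self.ANN)
        assert len(df) == 0


class TestEndToEnd:
    def test_group_swap_negates_differences(self, small_dataset):
        _, ann, samples, _ = small_dataset
        a = [samples[("G1", r)] for r in (1, 2, 3)]
        b = [samples[("G2", r)] for r in (1, 2, 3)]
        d1 = dml_test(a, b, ann)
        d2 = dml_test(b, a, ann)
        np.testing.assert_allclose(d1["diff"], -d2["diff"], atol=1e-12)
        np.testing.assert_allclose(
            np.abs(d1["stat"]), np.abs(d2["stat"]), atol=1e-12
        )
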