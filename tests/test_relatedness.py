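"""KING kinship, degree classification, ML inbreeding, covariance PCA."""

import numpy as np
import pytest

from loadscape import genolik, relatedness, simdata


def test_classify_degree_bins():
    assert relatedness.classify_degree(0.5) == "identical/self"
    assert relatedness.classify_degree(0.25) == "1st"
    assert relatedness.classify_degree(0.125) == "2nd"
    assert relatedness.classify_degree(0.0625) == "3rd"
    assert relatedness.classify_degree(0.01) == "unrelated"
    assert relatedness.classify_degree(-0.2) == "unrelated"
    with pytest.raises(ValueError):
        relatedness.classify_degree(float("nan"))


def test_pair_ibs_stats_hand_example():
    ga = np.array([0, 0, 1, 1, 1, 2, 2, 1, -1, 0])
    gb = np.array([0, 2, 1, 1, 0, 2, 0, 2, 1, -1])
    res = relatedness.pair_ibs_stats(ga, gb, min_sites=1)
    assert res.n_sites_compared == 8
    # joint counts: N(1,1)=2, opposing homs N(0,2)+N(2,0)=2,
    # het rows/cols: het_a=4, het_b=2
    assert res.joint_counts[1, 1] == 2
    assert res.joint_counts[0, 2] + res.joint_counts[2, 0] == 2
    assert res.king == pytest.approx((2 - 2 * 2) / (4 + 2))
    assert res.r0 == pytest.approx(2 / 2)
    # R1 = N(1,1) / (single-het discordant + opposing homs + N(1,1))
    # single-het discordant pairs here: (1,0) and (1,2)
    assert res.r1 == pytest.approx(2 / (2 + 2 + 2))
    assert not res.filtered


def test_pair_ibs_stats_no_overlap_raises():
    with pytest.raises(ValueError):
        relatedness.pair_ibs_stats(np.array([-1, 0]), np.array([1, -1]))


def test_parent_offspring_kinship():
    ga, gb = simdata.simulate_pedigree_pair("parent-offspring", n_sites=50_000, seed=10)
    res = relatedness.pair_ibs_stats(ga, gb)
    assert 0.20 <= res.king <= 0.30
    assert res.r0 < 0.005
    assert res.degree == "1st"


def test_full_sib_kinship_has_opposing_homozygotes():
    ga, gb = simdata.simulate_pedigree_pair("full-sib", n_sites=50_000, seed=11)
    res = relatedness.pair_ibs_stats(ga, gb)
    assert 0.15 <= res.king <= 0.35
    assert res.r0 > 0.01  # unlike parent-offspring, sibs show opposing homs
    assert res.degree == "1st"


def test_unrelated_kinship_near_zero():
    ga, gb = simdata.simulate_pedigree_pair("unrelated", n_sites=50_000, seed=12)
    res = relatedness.pair_ibs_stats(ga, gb)
    assert abs(res.king) < 0.02
    assert res.degree == "unrelated"


def test_identical_kinship_is_half():
    ga, gb = simdata.simulate_pedigree_pair("self", n_sites=50_000, seed=13)
    res = relatedness.pair_ibs_stats(ga, gb)
    assert res.king == pytest.approx(0.5)
    assert res.r0 == 0.0
    assert res.degree == "identical/self"


def test_kinship_table_tolerates_empty_overlap():
    g = np.array([[0, -1, 1], [1, -1, 0], [2, -1, 1]])  # middle sample uncalled
    tab = relatedness.kinship_table(g, ["a", "b", "c"], min_sites=1)
    assert len(tab) == 3
    bad = tab[(tab["id_a"] == "a") & (tab["id_b"] == "b")].iloc[0]
    assert bad["filtered"] and bad["degree"] == "undefined"
    ok = tab[(tab["id_a"] == "a") & (tab["id_b"] == "c")].iloc[0]
    assert np.isfinite(ok["king"])


def _inbred_gl(F, n_sites, seed, depth=10, e=0.01):
    rng = np.random.default_rng(seed)
    f = rng.uniform(0.1, 0.5, size=n_sites)
    p = np.stack([(1 - f) ** 2 + f * (1 - f) * F,
                  2 * f * (1 - f) * (1 - F),
                  f**2 + f * (1 - f) * F], axis=-1)
    g = (rng.random(n_sites)[:, None] > p.cumsum(axis=1)).sum(axis=1)
    d = rng.poisson(depth, size=n_sites)
    p_min = np.array([e / 3, 0.5, 1 - e])[g]
    minor = rng.binomial(d, p_min)
    ll = genolik.gl_from_pileup(d - minor, minor, e)
    return ll, f


def test_individual_f_recovery_and_monotonicity():
    hats = []
    for F in (0.0, 0.5, 1.0):
        ll, f = _inbred_gl(F, 2_000, seed=int(100 * F) + 1)
        res = relatedness.individual_F(ll, f)
        assert res.converged
        assert abs(res.F - F) < 0.1
        hats.append(res.F)
    assert hats[0] < hats[1] < hats[2]


def test_individual_f_negative_for_het_excess():
    ll, f = _inbred_gl(-0.8, 2_000, seed=6)
    res = relatedness.individual_F(ll, f)
    assert res.F < -0.5


def test_individual_f_needs_sites():
    ll, f = _inbred_gl(0.0, 50, seed=2)
    with pytest.raises(ValueError):
        relatedness.individual_F(ll, f, min_sites=100)


def test_inbreeding_table_matches_individual(small_gl, small_variants):
    idx = small_variants["gl_index"].to_numpy()
    tab = relatedness.inbreeding_table(
        small_gl.ll[idx], small_variants["maf"].to_numpy(),
        small_gl.sample_ids, min_sites=20,
    )
    assert list(tab["individual"]) == small_gl.sample_ids
    one = relatedness.individual_F(
        small_gl.ll[idx][:, 0, :], small_variants["maf"].to_numpy(), min_sites=20
    )
    assert tab["F"].iloc[0] == pytest.approx(one.F)
    assert tab["F"].between(-1, 1).all()


def test_selfing_population_more_inbred(small_truth, small_gl, small_variants):
    idx = small_variants["gl_index"].to_numpy()
    tab = relatedness.inbreeding_table(
        small_gl.ll[idx], small_variants["maf"].to_numpy(),
        small_gl.sample_ids, min_sites=20,
    )
    F = tab["F"].to_numpy()
    mean_self = F[small_truth.pop_labels == "pop1"].mean()
    mean_out = F[small_truth.pop_labels == "pop0"].mean()
    assert mean_self > mean_out + 0.1  # selfing rate 0.5 vs outbred


def test_covariance_pca_separates_populations(rng):
    # two populations with divergent allele frequencies split on PC1
    n_sites, n_per = 500, 12
    fa = rng.uniform(0.1, 0.9, n_sites)
    fb = np.clip(fa + rng.normal(0, 0.25, n_sites), 0.02, 0.98)
    g = np.concatenate(
        [rng.binomial(2, fa[:, None], (n_sites, n_per)),
         rng.binomial(2, fb[:, None], (n_sites, n_per))], axis=1,
    )
    vals, vecs, scores = relatedness.covariance_pca(g.astype(float))
    assert (np.diff(vals) <= 1e-9).all()
    pc1_a, pc1_b = scores[:n_per, 0], scores[n_per:, 0]
    assert min(pc1_a.min(), pc1_b.min()) == pytest.approx(scores[:, 0].min())
    assert abs(pc1_a.mean() - pc1_b.mean()) > 3 * (pc1_a.std() + pc1_b.std())


def test_covariance_pca_handles_missing_and_errors(rng):
    g = rng.binomial(2, 0.3, (200, 10)).astype(float)
    g[rng.random(g.shape) < 0.1] = -1
    vals, _, scores = relatedness.covariance_pca(g)
    assert np.isfinite(scores).all()
    with pytest.raises(ValueError):
        relatedness.covariance_pca(np.zeros((5, 4)))  # no polymorphic sites
    with pytest.raises(ValueError):
        relatedness.covariance_pca(np.zeros((1, 4)))
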