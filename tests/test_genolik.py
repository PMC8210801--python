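"""Genotype likelihoods, EM allele frequencies, and SNP/genotype calling."""

import numpy as np
import pytest

from loadscape import genolik


def test_gl_triplet_frozen_values():
    # 4 ref reads, 0 alt, e = 0.01, hand-computed:
    # ll0 = 4 ln 0.99, ll1 = 4 ln(0.5 - 0.01/3), ll2 = 4 ln(0.01/3)
    ll0, ll1, ll2 = genolik.gl_from_pileup(4, 0, 0.01)
    assert ll0 == pytest.approx(-0.0402, abs=1e-4)
    assert ll1 == pytest.approx(-2.7993, abs=1e-4)
    assert ll2 == pytest.approx(-22.8151, abs=1e-4)


def test_gl_no_reads_is_flat():
    assert genolik.gl_from_pileup(0, 0, 0.01) == (0.0, 0.0, 0.0)


def test_gl_symmetry_and_validation():
    a = genolik.gl_from_pileup(3, 1, 0.02)
    b = genolik.gl_from_pileup(1, 3, 0.02)
    assert a == pytest.approx(b[::-1])
    with pytest.raises(ValueError):
        genolik.gl_from_pileup(2, 1, 0.9)
    with pytest.raises(ValueError):
        genolik.gl_from_pileup(-1, 1, 0.01)


def _gl_for_genotypes(genos, depth, e, seed):
    """Read counts drawn from the GL model itself, then likelihoods."""
    rng = np.random.default_rng(seed)
    p_alt = {0: e / 3, 1: 0.5 - e / 3 + e / 3, 2: 1 - e}  # P(read = alt)
    n = len(genos)
    d = rng.poisson(depth, size=n)
    alt = rng.binomial(d, [p_alt[g] for g in genos])
    ref = d - alt
    return genolik.gl_from_pileup(ref, alt, e), d


def test_em_af_matches_grid_search_oracle():
    rng = np.random.default_rng(4)
    true_f = 0.3
    genos = rng.binomial(2, true_f, size=40)
    ll, d = _gl_for_genotypes(genos, 12, 0.01, seed=7)
    f_em = genolik.estimate_af_em(ll, has_data=d > 0)
    grid = np.linspace(0.0, 0.5, 2001)
    L = np.exp(ll - ll.max(axis=-1, keepdims=True))

    def loglik(f):
        pr = np.array([(1 - f) ** 2, 2 * f * (1 - f), f**2])
        return np.log(np.maximum(L @ pr, 1e-300))[d > 0].sum()

    f_grid = grid[np.argmax([loglik(f) for f in grid])]
    assert f_em == pytest.approx(f_grid, abs=5e-4)
    # close to the realised sample frequency (the estimand at one site)
    assert abs(f_em - genos.mean() / 2.0) < 0.1


def test_em_af_no_data_is_nan():
    ll = np.zeros((3, 5, 3))
    f = genolik.estimate_af_em(ll, has_data=np.zeros((3, 5), dtype=bool))
    assert np.isnan(f).all()


def test_monomorphic_site_is_not_called():
    # all individuals hom-major at high depth: LRT must not reject f = 0
    ll = np.asarray(genolik.gl_from_pileup(np.full(30, 20), np.zeros(30, dtype=int), 0.01))
    f = genolik.estimate_af_em(ll, has_data=np.ones(30, dtype=bool))
    p = genolik.polymorphism_lrt(ll[None], np.array([f]),
                                 np.ones((1, 30), dtype=bool))[0]
    assert f < 0.01
    assert p > 1e-6


def test_polymorphic_site_has_tiny_lrt_p():
    genos = np.array([0] * 10 + [1] * 10 + [2] * 10)
    ll, d = _gl_for_genotypes(genos, 20, 0.01, seed=9)
    f = genolik.estimate_af_em(ll, has_data=d > 0)
    p = genolik.polymorphism_lrt(ll[None], np.array([f]), (d > 0)[None])[0]
    assert p < 1e-20


def test_hwe_test_flags_universal_heterozygosity():
    # every individual het -> strong het excess, small one-sided p
    ll, d = _gl_for_genotypes(np.ones(40, dtype=int), 20, 0.01, seed=3)
    p = genolik.hwe_test(ll, 0.5, d > 0)
    assert p < 0.01
    # HWE-conforming genotypes at the same frequency are retained
    rng = np.random.default_rng(12)
    ll2, d2 = _gl_for_genotypes(rng.binomial(2, 0.5, size=40), 20, 0.01, seed=5)
    assert genolik.hwe_test(ll2, 0.5, d2 > 0) >= 0.01


def test_call_snps_filters(small_gl, small_variants):
    assert len(small_variants) > 30
    assert (small_variants["maf"] >= 0.05).all()
    assert (small_variants["lrt_p"] < 1e-6).all()
    assert (small_variants["hwe_p"] >= 0.01).all()
    assert (small_variants["n_ind"] >= 12).all()


def test_call_snps_recovers_truth(small_truth, small_variants):
    # called positions are real variants, and common truth sites are found
    true_pos = set(small_truth.positions.tolist())
    assert set(small_variants["pos"].tolist()) <= true_pos
    f_true = small_truth.true_genotypes.sum(axis=0) / (2.0 * small_truth.n_individuals)
    common = (np.minimum(f_true, 1 - f_true) >= 0.15) & (f_true != 1.0)
    found = np.isin(small_truth.positions[common],
                    small_variants["pos"].to_numpy())
    assert found.mean() > 0.9


def test_call_snps_profile_equivalence(small_gl):
    a = genolik.call_snps(small_gl, min_ind=15, max_depth=100)
    b = genolik.call_snps(small_gl, profile="genomic")
    assert a.equals(b)
    with pytest.raises(ValueError):
        genolik.call_snps(small_gl)  # neither profile nor explicit filters


def test_call_genotypes_concordance(small_truth, small_variants, small_genotypes):
    # compare called genotypes against truth in minor-allele orientation
    idx = {int(p): i for i, p in enumerate(small_truth.positions)}
    rows = [idx[int(p)] for p in small_variants["pos"]]
    g_true = small_truth.true_genotypes.T[rows]
    flip = (small_variants["minor"] != small_variants["alt"]).to_numpy()
    g_true = np.where(flip[:, None], 2 - g_true, g_true)
    called = small_genotypes >= 0
    assert called.mean() > 0.5
    conc = (small_genotypes[called] == g_true[called]).mean()
    assert conc > 0.95


def test_call_genotypes_min_depth(small_gl, small_variants):
    g = genolik.call_genotypes(small_gl, small_variants, min_depth=5)
    idx = small_variants["gl_index"].to_numpy()
    assert (g[small_gl.depth[idx] < 5] == -1).all()
    assert (g[small_gl.depth[idx] >= 5] >= 0).all()


def test_alt_oriented_round_trip(small_variants, small_genotypes):
    alt = genolik.alt_oriented(small_genotypes, small_variants)
    back = genolik.alt_oriented(alt, small_variants)
    assert np.array_equal(back, small_genotypes)
    miss = small_genotypes == -1
    assert (alt[miss] == -1).all()


def test_variant_vcf_round_trip(tmp_path, small_gl, small_variants, small_genotypes):
    path = tmp_path / "calls.vcf"
    genolik.write_variant_vcf(path, small_gl, small_variants, small_genotypes)
    text = path.read_text().splitlines()
    body = [ln for ln in text if not ln.startswith("#")]
    assert len(body) == len(small_variants)
    assert int(body[0].split("\t")[1]) == int(small_variants["pos"].iloc[0]) + 1
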