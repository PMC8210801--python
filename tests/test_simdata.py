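"""Simulator invariants, analytic oracles, and bundle round-trips."""

import filecmp

import numpy as np
import pytest
from scipy import stats

from loadscape import diversity, simdata


def test_mu_zero_means_no_variation():
    cfg = simdata.SimulationConfig(
        n_pops=1, pop_sizes=(30,), split_gens=(), selfing_rates=(0.0,),
        seq_length=30_000, n_genes=4, mu_sim=0.0, seed=5, n_sample=(10,),
        burn_in=20,
    )
    truth = simdata.simulate_populations(cfg)
    assert truth.n_sites == 0


def test_genotypes_are_haplotype_sums(small_truth):
    g = small_truth.haplotypes[0::2] + small_truth.haplotypes[1::2]
    assert np.array_equal(g, small_truth.true_genotypes)


def test_site_class_modifier_outside_cds(small_truth):
    non_cds = small_truth.site_context != "CDS"
    assert (small_truth.site_class[non_cds] == "MODIFIER").all()
    # CDS sites never carry the MODIFIER label under the class-realising draw
    cds = small_truth.site_context == "CDS"
    assert (small_truth.site_class[cds] != "MODIFIER").all()


def test_positions_sorted_and_unique(small_truth):
    pos = small_truth.positions
    assert (np.diff(pos) > 0).all()


def test_expected_segregating_sites_neutral_equilibrium():
    # neutral single population, 2N = 20 chromosomes, per-locus theta = 10:
    # E[S] = theta * sum_{i=1}^{19} 1/i = 35.48 under the coalescent;
    # the monomorphic-start forward simulator must reach the same
    # equilibrium after its 10 N burn-in.
    n, L, theta = 10, 2_000, 10.0
    mu = theta / (4 * n * L)
    reps = 150
    S = np.empty(reps)
    for r in range(reps):
        cfg = simdata.SimulationConfig(
            n_pops=1, pop_sizes=(n,), split_gens=(), selfing_rates=(0.0,),
            seq_length=L, n_genes=1, gene_length=300, mu_sim=mu,
            seed=9000 + r, n_sample=(n,), init="monomorphic",
        )
        S[r] = simdata.simulate_populations(cfg).n_sites
    expected = theta * diversity.harmonic(2 * n - 1)
    se = S.std(ddof=1) / np.sqrt(reps)
    assert abs(S.mean() - expected) < 3.5 * se + 1.0


def test_complete_selfing_inbreeding_recursion():
    # F_{t+1} = (1 + F_t)/2 under selfing rate 1 gives F_20 > 0.9
    cfg = simdata.SimulationConfig(
        n_pops=1, pop_sizes=(40,), split_gens=(), selfing_rates=(1.0,),
        seq_length=30_000, n_genes=4, seed=21, n_sample=(20,), burn_in=20,
    )
    truth = simdata.simulate_populations(cfg)
    assert truth.true_F.mean() > 0.9


def test_selection_suppresses_high_class_frequencies():
    cfg = simdata.SimulationConfig(
        n_pops=1, pop_sizes=(300,), split_gens=(), selfing_rates=(0.0,),
        seed=31, n_sample=(60,), track_pedigree=False,
    )
    truth = simdata.simulate_populations(cfg)
    freq = truth.true_genotypes.sum(axis=0) / (2.0 * truth.n_individuals)
    sel = np.isin(truth.site_class, ["HIGH", "MODERATE"])
    neu = truth.site_class == "MODIFIER"
    assert sel.sum() >= 5
    res = stats.mannwhitneyu(freq[sel], freq[neu], alternative="less")
    assert res.pvalue < 0.05


def test_pileup_depth_and_error_statistics(small_truth, small_config, small_pileup):
    depth = small_pileup.depth
    assert abs(depth.mean() - small_config.mean_depth) < 0.1
    hom_ref = small_truth.true_genotypes.T == 0
    alt = small_pileup.alt_count[hom_ref].sum()
    tot = depth[hom_ref].sum()
    # alt reads at hom-ref sites arise only from the error process
    assert abs(alt / tot - small_config.error_rate) < 0.005


def test_pileup_zero_depth():
    cfg = simdata.SimulationConfig(
        n_pops=1, pop_sizes=(20,), split_gens=(), selfing_rates=(0.0,),
        seq_length=20_000, n_genes=2, gene_length=300, mean_depth=0.0,
        seed=3, n_sample=(6,), burn_in=30,
    )
    truth = simdata.simulate_populations(cfg)
    pu = simdata.simulate_pileups(truth, cfg)
    assert pu.depth.sum() == 0


def test_config_validation_errors():
    ok = dict(n_pops=1, pop_sizes=(20,), split_gens=(), selfing_rates=(0.0,),
              seq_length=20_000, n_genes=2, gene_length=300, n_sample=(5,))
    with pytest.raises(ValueError):
        simdata.SimulationConfig(**{**ok, "selfing_rates": (1.5,)})
    with pytest.raises(ValueError):
        simdata.SimulationConfig(**{**ok, "class_probs": (0.5, 0.1, 0.1)})
    with pytest.raises(ValueError):
        simdata.SimulationConfig(
            **{**ok, "sel_coeffs": {"HIGH": 1.5, "MODERATE": 0.03,
                                    "LOW": 0.003, "MODIFIER": 0.0}}
        )
    with pytest.raises(ValueError):
        simdata.SimulationConfig(
            **{**ok, "dominance_h": {"HIGH": -0.1, "MODERATE": 0.2,
                                     "LOW": 0.3, "MODIFIER": 0.5}}
        )
    with pytest.raises(ValueError):
        simdata.SimulationConfig(**{**ok, "n_sample": (50,)})


def test_truth_bundle_round_trip(tmp_path, small_truth, small_config, small_pileup):
    paths = simdata.write_truth_bundle(small_truth, small_config,
                                       tmp_path / "b", small_pileup)
    data = simdata.read_truth_vcf(paths["vcf"])
    assert data["samples"] == small_truth.sample_ids
    assert np.array_equal(data["positions"], small_truth.positions)
    assert np.array_equal(data["genotypes"], small_truth.true_genotypes.T)
    pu = simdata.read_pileup_tsv(paths["pileup"])
    assert np.array_equal(pu.ref_count, small_pileup.ref_count)
    assert np.array_equal(pu.alt_count, small_pileup.alt_count)


def test_truth_bundle_vcf_one_based_sorted(tmp_path, small_truth, small_config):
    paths = simdata.write_truth_bundle(small_truth, small_config, tmp_path / "b")
    pos = []
    with open(paths["vcf"]) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            pos.append(int(line.split("\t")[1]))
    assert pos == sorted(pos)
    assert np.array_equal(np.asarray(pos) - 1, small_truth.positions)
    assert min(pos) >= 1


def test_gff3_round_trip(tmp_path, small_truth, small_config):
    paths = simdata.write_truth_bundle(small_truth, small_config, tmp_path / "b")
    from loadscape import loadcalc

    back = loadcalc.gene_models_from_gff3(paths["gff3"])
    orig = {g.gene_id: g for g in small_truth.gene_models}
    assert len(back) == len(orig)
    for g in back:
        o = orig[g.gene_id]
        assert g.cds == o.cds and g.utr5 == o.utr5 and g.utr3 == o.utr3
        assert g.strand == o.strand


def test_identical_seed_identical_bundle(tmp_path):
    cfg = simdata.SimulationConfig(
        n_pops=1, pop_sizes=(30,), split_gens=(), selfing_rates=(0.2,),
        seq_length=30_000, n_genes=4, gene_length=300, seed=77, n_sample=(8,),
        burn_in=40,
    )
    for d in ("a", "b"):
        truth = simdata.simulate_populations(cfg)
        pu = simdata.simulate_pileups(truth, cfg)
        simdata.write_truth_bundle(truth, cfg, tmp_path / d, pu)
    for name in ("reference.fasta", "genes.gff3", "truth.vcf", "pileup.tsv",
                 "truth.json"):
        assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name,
                           shallow=False), name


def test_pedigree_pair_relationships():
    ga, gb = simdata.simulate_pedigree_pair("self", n_sites=5_000, seed=1)
    assert np.array_equal(ga, gb)
    ga, gb = simdata.simulate_pedigree_pair("parent-offspring", n_sites=5_000, seed=2)
    # a parent and offspring share one allele at every site: no opposing homs
    assert not ((ga == 0) & (gb == 2)).any()
    assert not ((ga == 2) & (gb == 0)).any()
    with pytest.raises(ValueError):
        simdata.simulate_pedigree_pair("twin", n_sites=100, seed=3)


def test_neutral_coalescent_haplotypes_deterministic():
    a = [h for _, h in simdata.neutral_coalescent_haplotypes(8, 50_000, 1e-3, seed=5)]
    b = [h for _, h in simdata.neutral_coalescent_haplotypes(8, 50_000, 1e-3, seed=5)]
    assert np.array_equal(a[0], b[0])
    assert a[0].shape[0] == 8
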