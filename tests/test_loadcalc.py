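"""Variant-impact classification against a re-translation oracle, and
potential/realized load statistics."""

import numpy as np
import pandas as pd
import pytest

from loadscape import loadcalc


# ---------------------------------------------------------------------------
# toy gene set and an independent re-translate-and-diff oracle
# ---------------------------------------------------------------------------


def _toy_genes_and_reference():
    rng = np.random.default_rng(2024)
    ref = rng.choice(list("ACGT"), size=600)
    # plus-strand gene: UTR5, CDS exon, intron, CDS exon, UTR3
    ga = loadcalc.GeneModel(
        gene_id="gA", chrom="1", strand="+",
        cds=((60, 75), (95, 110)), utr5=((50, 60),), utr3=((110, 120),),
    )
    # give gA a well-formed ORF: ATG ... internal codons ... TAA
    orf = "ATG" + "GCTTTCAAAGGGCATCCGTGGTAT" + "TAA"
    assert len(orf) == 30
    ref[60:75] = list(orf[:15])
    ref[95:110] = list(orf[15:])
    # minus-strand gene with arbitrary codons
    gb = loadcalc.GeneModel(
        gene_id="gB", chrom="1", strand="-",
        cds=((200, 215), (235, 250)), utr5=((250, 260),), utr3=((190, 200),),
    )
    return [ga, gb], "".join(ref)


def _oracle_class(pos, ref_b, alt_b, genes, reference):
    """Full re-translation diff, independent of the codon-local logic."""
    for g in genes:
        off = g.cds_offset(pos)
        if off is None:
            continue
        cds_ref = g.spliced_cds(reference).upper()
        r, a = ref_b, alt_b
        if g.strand == "-":
            r, a = loadcalc.revcomp(r), loadcalc.revcomp(a)
        assert cds_ref[off] == r
        cds_alt = cds_ref[:off] + a + cds_ref[off + 1 :]
        if off < 3 and cds_alt[:3] != "ATG":
            return "HIGH"  # start codon destroyed
        aa_ref = "".join(loadcalc.CODON_TABLE[cds_ref[i:i + 3]]
                         for i in range(0, len(cds_ref), 3))
        aa_alt = "".join(loadcalc.CODON_TABLE[cds_alt[i:i + 3]]
                         for i in range(0, len(cds_alt), 3))
        if aa_ref == aa_alt:
            return "LOW"  # synonymous / stop retained
        diffs = [i for i, (x, y) in enumerate(zip(aa_ref, aa_alt)) if x != y]
        assert len(diffs) == 1
        x, y = aa_ref[diffs[0]], aa_alt[diffs[0]]
        if x == "*" or y == "*":
            return "HIGH"  # stop lost or gained
        return "MODERATE"
    # non-coding: splice dinucleotides are HIGH, everything else MODIFIER
    for g in genes:
        for i_s, i_e in g.introns:
            if i_s <= pos < i_s + 2 or i_e - 2 <= pos < i_e:
                return "HIGH"
    return "MODIFIER"


def test_every_possible_snp_matches_retranslation_oracle():
    genes, reference = _toy_genes_and_reference()
    for pos in range(len(reference)):
        ref_b = reference[pos]
        for alt_b in "ACGT":
            if alt_b == ref_b:
                continue
            cls, effect = loadcalc.classify_variant(
                pos, ref_b, alt_b, genes, reference, flank=50
            )
            assert cls == _oracle_class(pos, ref_b, alt_b, genes, reference), (
                pos, ref_b, alt_b, effect
            )


def test_effect_labels_on_known_changes():
    genes, reference = _toy_genes_and_reference()
    # destroy the start codon of gA (ATG -> TTG at position 60)
    assert loadcalc.classify_variant(60, "A", "T", genes, reference)[1] == "start_lost"
    # first intronic base after the first CDS exon: splice donor on + strand
    assert loadcalc.classify_variant(75, reference[75],
                                     "ACGT".replace(reference[75], "")[0],
                                     genes, reference)[1] == "splice_donor"
    assert loadcalc.classify_variant(93, reference[93],
                                     "ACGT".replace(reference[93], "")[0],
                                     genes, reference)[1] == "splice_acceptor"
    # far from any gene with a small flank: intergenic
    assert loadcalc.classify_variant(580, reference[580],
                                     "ACGT".replace(reference[580], "")[0],
                                     genes, reference, flank=10)[1] == "intergenic"
    with pytest.raises(ValueError):
        loadcalc.classify_variant(10, "AC", "A", genes, reference)


def test_annotate_variants_frame(small_truth):
    df = pd.DataFrame(
        {
            "pos": small_truth.positions,
            "ref": [small_truth.reference[p] for p in small_truth.positions],
            "alt": small_truth.derived_allele,
        }
    )
    ann = loadcalc.annotate_variants(df, list(small_truth.gene_models),
                                     small_truth.reference)
    assert {"impact_class", "effect"} <= set(ann.columns)
    # the simulator assigned each site's class with the same classifier
    assert (ann["impact_class"].to_numpy() == small_truth.site_class).all()


def test_load_realized_toy():
    # one individual: 1 hom-alt, 2 het, 1 hom-ref at HIGH sites -> 0.25
    g = np.array([[2], [1], [1], [0]])
    cls = np.array(["HIGH"] * 4)
    lr = loadcalc.load_realized(g, cls, mode="hom")
    assert lr["HIGH"].iloc[0] == pytest.approx(0.25)
    lr2 = loadcalc.load_realized(g, cls, mode="alleles")
    assert lr2["HIGH"].iloc[0] == pytest.approx(4 / 8)
    assert np.isnan(lr["LOW"].iloc[0])  # no genotyped LOW site
    with pytest.raises(ValueError):
        loadcalc.load_realized(g, cls, mode="bogus")


def test_load_realized_missing_excluded():
    g = np.array([[2], [-1], [0], [2]])
    lr = loadcalc.load_realized(g, np.array(["HIGH"] * 4))
    assert lr["HIGH"].iloc[0] == pytest.approx(2 * 2 / (2 * 3))


def test_load_potential_toy():
    # 2 individuals, 4 segregating genic sites: 1 HIGH, 2 MODERATE, 1 LOW
    g = np.array([[1, 0], [2, 1], [0, 0], [1, 2]])
    cls = np.array(["HIGH", "MODERATE", "MODERATE", "LOW"])
    per_ind, pop = loadcalc.load_potential(g, cls)
    assert pop["HIGH"] == pytest.approx(1 / 4)
    assert pop["MODERATE"] == pytest.approx(2 / 4)
    assert pop.sum() == pytest.approx(1.0)
    assert per_ind["HIGH"].tolist() == pytest.approx([1 / 4, 0.0])
    assert per_ind["MODERATE"].tolist() == pytest.approx([1 / 4, 1 / 4])
    with pytest.raises(ValueError):
        loadcalc.load_potential(g[:0], cls[:0])


def test_welch_t_frozen_example():
    t, df, p = loadcalc.welch_t([1, 2, 3], [2, 4, 6])
    assert t == pytest.approx(-1.549, abs=1e-3)
    assert df == pytest.approx(2.941, abs=1e-3)
    assert 0 < p < 1
    with pytest.raises(ValueError):
        loadcalc.welch_t([1], [2, 3])


def test_welch_t_matches_scipy(rng):
    from scipy import stats

    a = rng.normal(0, 1, 15)
    b = rng.normal(0.5, 2, 9)
    t, df, p = loadcalc.welch_t(a, b)
    ref = stats.ttest_ind(a, b, equal_var=False)
    assert t == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue)


def test_load_table_structure(small_truth):
    genic = small_truth.site_context != "intergenic"
    tab = loadcalc.load_table(
        small_truth.true_genotypes.T[genic],
        small_truth.site_class[genic],
        small_truth.pop_labels,
        sample_ids=small_truth.sample_ids,
        fdr=True,
    )
    n_ind = small_truth.n_individuals
    assert len(tab.per_individual) == n_ind * len(loadcalc.IMPACT_CLASSES)
    # classes partition each population's genic segregating sites
    assert tab.population_load_p.sum(axis=1).tolist() == pytest.approx(
        [1.0] * len(tab.population_load_p)
    )
    assert len(tab.welch) == 2 * len(loadcalc.IMPACT_CLASSES)  # one pop pair
    assert (tab.welch["p_bh"].dropna() >= tab.welch["p"].dropna() - 1e-12).all()
    assert (tab.per_individual["load_p"] >= 0).all()
    assert tab.per_individual["load_r"].dropna().between(0, 1).all()
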