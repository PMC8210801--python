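"""Variant-impact classification and potential/realized genetic-load statistics.

A biallelic SNP inside an annotated gene is classified by its predicted
effect on protein translation, under the convention that the reference
allele is functional and the alternate allele is the putatively deleterious
one:

* ``HIGH`` — premature stop (stop_gained), loss of the stop codon
  (stop_lost), loss of the start codon (start_lost), or disruption of a
  splice donor/acceptor dinucleotide (first/last two intronic bases);
* ``MODERATE`` — missense substitutions;
* ``LOW`` — synonymous substitutions and stop_retained changes;
* ``MODIFIER`` — intronic, UTR, upstream/downstream flank (default 5 kb)
  and intergenic variants.

Two load statistics summarise the burden of classified variants:

* potential load ``Load_P[i, j, k]`` — the number of class-``i`` genic sites
  at which individual ``j`` carries at least one alternate allele, divided
  by the total number of genic segregating sites in population ``k``. A
  population-level variant uses the class-``i`` segregating count as the
  numerator. Load_P is zygosity-independent: it measures what the gene pool
  (or an individual's diploid genome) carries.
* realized load ``Load_R[i, j, k]`` — the proportion of class-``i`` alleles
  exposed as homozygotes in individual ``j``:
  ``2 x (hom-alt class-i sites) / (2 x class-i sites genotyped in j)``
  (mode ``"hom"``, the default). Mode ``"alleles"`` instead counts every
  alternate allele, including heterozygous ones.

Population contrasts of mean load are tested with Welch's two-sample t-test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

IMPACT_CLASSES = ("HIGH", "MODERATE", "LOW", "MODIFIER")

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

# standard nuclear codon table
_BASES = "TCAG"
_AMINO = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
CODON_TABLE = {
    a + b + c: _AMINO[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}

HIGH_EFFECTS = frozenset(
    {"stop_gained", "stop_lost", "start_lost", "splice_donor", "splice_acceptor"}
)
LOW_EFFECTS = frozenset({"synonymous", "stop_retained"})


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneModel:
    """A protein-coding gene model on a single reference sequence.

    Intervals are 0-based half-open internally; GFF3 I/O converts to/from
    the 1-based inclusive convention of the format.
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    cds: tuple[tuple[int, int], ...]  # sorted by genomic coordinate
    utr5: tuple[tuple[int, int], ...] = ()
    utr3: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        self.cds = tuple(sorted(tuple(iv) for iv in self.cds))
        self.utr5 = tuple(sorted(tuple(iv) for iv in self.utr5))
        self.utr3 = tuple(sorted(tuple(iv) for iv in self.utr3))
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        ivs = sorted(self.cds + self.utr5 + self.utr3)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if e1 > s2:
                raise ValueError(f"overlapping intervals in gene {self.gene_id}")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def exons(self) -> tuple[tuple[int, int], ...]:
        return tuple(sorted(self.cds + self.utr5 + self.utr3))

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        ex = self.exons
        return tuple((e1, s2) for (_, e1), (s2, _) in zip(ex, ex[1:]) if s2 > e1)

    @property
    def span(self) -> tuple[int, int]:
        ex = self.exons
        return ex[0][0], ex[-1][1]

    def spliced_cds(self, reference: str) -> str:
        """Coding sequence in translation (5'->3') orientation."""
        seq = "".join(reference[s:e] for s, e in self.cds)
        return revcomp(seq) if self.strand == "-" else seq

    def cds_offset(self, pos: int) -> int | None:
        """Map a genomic position to an offset in the spliced CDS, or None."""
        off = 0
        for s, e in self.cds:
            if s <= pos < e:
                fwd = off + (pos - s)
                if self.strand == "-":
                    return self.cds_length - 1 - fwd
                return fwd
            off += e - s
        return None


def _effect_to_class(effect: str) -> str:
    if effect in HIGH_EFFECTS:
        return "HIGH"
    if effect == "missense":
        return "MODERATE"
    if effect in LOW_EFFECTS:
        return "LOW"
    return "MODIFIER"


def _cds_effect(gene: GeneModel, reference: str, pos: int, ref: str, alt: str) -> str:
    cds_seq = gene.spliced_cds(reference)
    n = len(cds_seq)
    if n % 3:
        raise ValueError(f"CDS length of {gene.gene_id} not divisible by 3")
    off = gene.cds_offset(pos)
    assert off is not None
    ref_b, alt_b = ref.upper(), alt.upper()
    if gene.strand == "-":
        ref_b, alt_b = revcomp(ref_b), revcomp(alt_b)
    if cds_seq[off].upper() != ref_b:
        warnings.warn(
            f"reference mismatch at {gene.gene_id} CDS offset {off}", stacklevel=2
        )
    ci = off // 3
    codon = cds_seq[3 * ci : 3 * ci + 3].upper()
    alt_codon = codon[: off % 3] + alt_b + codon[off % 3 + 1 :]
    aa_ref = CODON_TABLE[codon]
    aa_alt = CODON_TABLE[alt_codon]
    if ci == 0 and alt_codon != "ATG":
        return "start_lost"
    if aa_ref == "*" and aa_alt == "*":
        return "stop_retained"
    if aa_ref == "*" and aa_alt != "*":
        return "stop_lost"
    if aa_alt == "*":
        return "stop_gained"
    if aa_ref == aa_alt:
        return "synonymous"
    return "missense"


def classify_variant(
    pos: int,
    ref: str,
    alt: str,
    genes: list[GeneModel] | "GeneIndex",
    reference: str,
    flank: int = 5000,
) -> tuple[str, str]:
    """Classify a biallelic SNP; returns ``(impact_class, effect_label)``.

    ``pos`` is 0-based on the same reference sequence as ``genes``.
    """
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("only biallelic SNPs are supported")
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(list(genes))
    gene = index.gene_at(pos, flank)
    if gene is None:
        return "MODIFIER", "intergenic"
    start, end = gene.span
    if start <= pos < end:
        if gene.cds_offset(pos) is not None:
            eff = _cds_effect(gene, reference, pos, ref, alt)
            return _effect_to_class(eff), eff
        for i_s, i_e in gene.introns:
            if i_s <= pos < i_e:
                if pos < i_s + 2:
                    eff = "splice_donor" if gene.strand == "+" else "splice_acceptor"
                    return "HIGH", eff
                if pos >= i_e - 2:
                    eff = "splice_acceptor" if gene.strand == "+" else "splice_donor"
                    return "HIGH", eff
                return "MODIFIER", "intron"
        for s, e in gene.utr5:
            if s <= pos < e:
                return "MODIFIER", "utr5"
        for s, e in gene.utr3:
            if s <= pos < e:
                return "MODIFIER", "utr3"
        return "MODIFIER", "intron"
    upstream = pos < start
    if gene.strand == "-":
        upstream = not upstream
    return "MODIFIER", "upstream" if upstream else "downstream"


class GeneIndex:
    """Sorted-interval lookup of non-overlapping gene spans (plus flanks)."""

    def __init__(self, genes: list[GeneModel]):
        self.genes = sorted(genes, key=lambda g: g.span[0])
        self._starts = np.array([g.span[0] for g in self.genes])
        self._ends = np.array([g.span[1] for g in self.genes])

    def gene_at(self, pos: int, flank: int = 0) -> GeneModel | None:
        if not self.genes:
            return None
        # nearest gene whose flanked span contains pos; prefer the closest span
        i = int(np.searchsorted(self._starts, pos, side="right"))
        best, best_dist = None, None
        for j in (i - 1, i):
            if 0 <= j < len(self.genes):
                s, e = self._starts[j], self._ends[j]
                if s - flank <= pos < e + flank:
                    dist = 0 if s <= pos < e else min(abs(pos - s), abs(pos - e + 1))
                    if best is None or dist < best_dist:
                        best, best_dist = self.genes[j], dist
        return best


def annotate_variants(
    variants: pd.DataFrame,
    genes: list[GeneModel],
    reference: str,
    flank: int = 5000,
    ref_col: str = "ref",
    alt_col: str = "alt",
) -> pd.DataFrame:
    """Add ``impact_class`` and ``effect`` columns to a variant table."""
    index = GeneIndex(list(genes))
    classes, effects = [], []
    for pos, ref, alt in zip(variants["pos"], variants[ref_col], variants[alt_col]):
        cls, eff = classify_variant(int(pos), ref, alt, index, reference, flank)
        classes.append(cls)
        effects.append(eff)
    out = variants.copy()
    out["impact_class"] = classes
    out["effect"] = effects
    return out


# ---------------------------------------------------------------------------
# load statistics
# ---------------------------------------------------------------------------


def load_potential(
    alt_genotypes: np.ndarray,
    impact_class: np.ndarray,
    genic_mask: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Potential load per individual and per population.

    Parameters
    ----------
    alt_genotypes
        (sites x individuals) alternate-allele counts in {0, 1, 2}, -1 for
        missing, for the sites segregating in this population.
    impact_class
        per-site class label among ``IMPACT_CLASSES``.
    genic_mask
        per-site boolean; sites outside it are excluded entirely. Default:
        all sites are genic.

    Returns
    -------
    per_individual
        DataFrame indexed by individual, one column per class, values
        ``n_class_i_carried / n_genic_segregating``.
    population
        Series per class: ``n_class_i_segregating / n_genic_segregating``.
    """
    gt = np.asarray(alt_genotypes)
    cls = np.asarray(impact_class)
    if genic_mask is not None:
        gt = gt[np.asarray(genic_mask)]
        cls = cls[np.asarray(genic_mask)]
    denom = gt.shape[0]
    if denom == 0:
        raise ValueError("no genic segregating sites in this population")
    carries = gt > 0
    per_ind = {}
    pop = {}
    for c in IMPACT_CLASSES:
        m = cls == c
        per_ind[c] = carries[m].sum(axis=0) / denom
        pop[c] = m.sum() / denom
    return pd.DataFrame(per_ind), pd.Series(pop)


def load_realized(
    alt_genotypes: np.ndarray,
    impact_class: np.ndarray,
    mode: str = "hom",
) -> pd.DataFrame:
    """Realized load per individual and impact class.

    Mode ``"hom"``: ``2 x hom-alt sites / (2 x genotyped class-i sites)``;
    mode ``"alleles"``: ``alt allele count / (2 x genotyped class-i sites)``.
    Individuals with no genotyped class-i site get NaN.
    """
    if mode not in ("hom", "alleles"):
        raise ValueError("mode must be 'hom' or 'alleles'")
    gt = np.asarray(alt_genotypes)
    cls = np.asarray(impact_class)
    out = {}
    for c in IMPACT_CLASSES:
        m = cls == c
        sub = gt[m]
        called = sub >= 0
        n_called = called.sum(axis=0).astype(float)
        if mode == "hom":
            num = 2.0 * (sub == 2).sum(axis=0)
        else:
            num = np.where(called, sub, 0).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[c] = np.where(n_called > 0, num / (2.0 * n_called), np.nan)
    return pd.DataFrame(out)


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's two-sample t-test: returns ``(t, df, p_two_sided)``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two values per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    diff = a.mean() - b.mean()
    if se2 == 0:
        if diff == 0:
            return 0.0, float(na + nb - 2), 1.0
        return float(np.sign(diff) * np.inf), float(na + nb - 2), 0.0
    t = diff / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


@dataclass
class LoadTable:
    """Per-individual load values plus population summaries and Welch tests."""

    per_individual: pd.DataFrame  # columns: individual, population, class, load_p, load_r
    population_load_p: pd.DataFrame  # rows: population, columns: class
    welch: pd.DataFrame  # population pair x class x statistic
    mode: str = "hom"


def load_table(
    alt_genotypes: np.ndarray,
    impact_class: np.ndarray,
    pop_labels: np.ndarray,
    sample_ids: list[str] | None = None,
    mode: str = "hom",
    fdr: bool = False,
) -> LoadTable:
    """Full load analysis over several populations.

    Sites are the union of classified genic SNPs; within each population only
    the sites segregating in that population enter its Load_P denominator and
    its Load_R site set.
    """
    gt = np.asarray(alt_genotypes)
    cls = np.asarray(impact_class)
    pops = np.asarray(pop_labels)
    n_ind = gt.shape[1]
    ids = sample_ids or [f"ind{i}" for i in range(n_ind)]
    rows = []
    pop_lp = {}
    per_pop_values: dict[str, dict[str, pd.DataFrame]] = {}
    for k in pd.unique(pops):
        cols = np.where(pops == k)[0]
        sub = gt[:, cols]
        ac = np.where(sub > 0, sub, 0).sum(axis=1)
        n_called = (sub >= 0).sum(axis=1)
        seg = (ac > 0) & (ac < 2 * n_called)
        lp_ind, lp_pop = load_potential(sub[seg], cls[seg])
        lr_ind = load_realized(sub[seg], cls[seg], mode=mode)
        pop_lp[k] = lp_pop
        per_pop_values[k] = {"load_p": lp_ind, "load_r": lr_ind}
        for j, col in enumerate(cols):
            for c in IMPACT_CLASSES:
                rows.append(
                    {
                        "individual": ids[col],
                        "population": k,
                        "impact_class": c,
                        "load_p": lp_ind[c].iloc[j],
                        "load_r": lr_ind[c].iloc[j],
                    }
                )
    per_ind = pd.DataFrame(rows)
    wrows = []
    for ka, kb in itertools.combinations(per_pop_values, 2):
        for stat in ("load_p", "load_r"):
            for c in IMPACT_CLASSES:
                va = per_pop_values[ka][stat][c].to_numpy()
                vb = per_pop_values[kb][stat][c].to_numpy()
                try:
                    t, df, p = welch_t(va, vb)
                except ValueError:
                    t = df = p = np.nan
                wrows.append(
                    {
                        "pop_a": ka,
                        "pop_b": kb,
                        "statistic": stat,
                        "impact_class": c,
                        "t": t,
                        "df": df,
                        "p": p,
                    }
                )
    welch = pd.DataFrame(wrows)
    if fdr and len(welch):
        welch["p_bh"] = _bh_fdr(welch["p"].to_numpy())
    return LoadTable(
        per_individual=per_ind,
        population_load_p=pd.DataFrame(pop_lp).T,
        welch=welch,
        mode=mode,
    )


def _bh_fdr(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    ok = ~np.isnan(p)
    q = np.full_like(p, np.nan)
    if ok.sum():
        ps = p[ok]
        order = np.argsort(ps)
        m = len(ps)
        adj = ps[order] * m / (np.arange(m) + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(adj, 1.0)
        q[ok] = out
    return q


# ---------------------------------------------------------------------------
# GFF3 I/O
# ---------------------------------------------------------------------------


def gene_models_to_gff3(genes: list[GeneModel], path, seq_lengths: dict[str, int]) -> None:
    """Write gene models as GFF3 (gene/mRNA/CDS/UTR features, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, length in seq_lengths.items():
            fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for g in genes:
            s, e = g.span
            fh.write(
                f"{g.chrom}\tloadscape\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            fh.write(
                f"{g.chrom}\tloadscape\tmRNA\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            # phase: number of bases to skip to reach the next codon start
            cds_in_order = g.cds if g.strand == "+" else g.cds[::-1]
            done = 0
            phases = []
            for cs, ce in cds_in_order:
                phases.append((3 - done % 3) % 3)
                done += ce - cs
            for (cs, ce), ph in zip(cds_in_order, phases):
                fh.write(
                    f"{g.chrom}\tloadscape\tCDS\t{cs + 1}\t{ce}\t.\t{g.strand}\t{ph}\t"
                    f"ID={g.gene_id}.cds;Parent={g.gene_id}.t1\n"
                )
            for kind, ivs in (("five_prime_UTR", g.utr5), ("three_prime_UTR", g.utr3)):
                for us, ue in ivs:
                    fh.write(
                        f"{g.chrom}\tloadscape\t{kind}\t{us + 1}\t{ue}\t.\t{g.strand}\t.\t"
                        f"ID={g.gene_id}.{kind};Parent={g.gene_id}.t1\n"
                    )


def gene_models_from_gff3(path) -> list[GeneModel]:
    """Read gene models from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for g in db.features_of_type("gene"):
        cds, utr5, utr3 = [], [], []
        for f in db.children(g, featuretype="CDS"):
            cds.append((f.start - 1, f.end))
        for f in db.children(g, featuretype="five_prime_UTR"):
            utr5.append((f.start - 1, f.end))
        for f in db.children(g, featuretype="three_prime_UTR"):
            utr3.append((f.start - 1, f.end))
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                strand=g.strand,
                cds=tuple(cds),
                utr5=tuple(utr5),
                utr3=tuple(utr3),
            )
        )
    return genes
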