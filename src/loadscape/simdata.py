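"""Forward Wright-Fisher simulation of diploid populations with selection,
selfing, and a gene-structured genome, plus low-coverage read evidence.

The simulator produces the statistical structure the downstream estimators
assume: two or three diploid populations of unequal size descended from a
common ancestor, partial self-fertilization in the small population, sites
partitioned into genomic contexts (CDS / intron / UTR / flank / intergenic),
and coding mutations drawn from a four-class distribution of fitness effects
(HIGH / MODERATE / LOW / MODIFIER) with class-specific selection and
dominance coefficients. Genotype fitness at a site with coefficients
``(s, h)`` is ``1``, ``1 - h s``, ``1 - s`` for 0/1/2 copies of the derived
allele, multiplicative across sites.

The ancestral population is seeded with neutral standing variation drawn
from an equilibrium coalescent (msprime) and then burnt in forward in time
so that the selected classes reach mutation-selection-drift balance before
any split; a pure forward mode starting from a monomorphic population with a
``10 N`` burn-in is available via ``init="monomorphic"``. Sites segregate
independently (free recombination); a pedigree (coancestry) matrix is
tracked so every sampled individual carries its exact pedigree inbreeding
coefficient.

Read evidence is simulated per individual and site as ``depth ~
Poisson(mean_depth)`` reads, each drawn from one of the two true alleles and
flipped to the other segregating allele with probability ``error_rate``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import loadcalc
from .loadcalc import GeneModel

CONTEXTS = ("intergenic", "CDS", "intron", "UTR", "upstream", "downstream")
_CTX_CODE = {name: i for i, name in enumerate(CONTEXTS)}
_CLASS_CODE = {name: i for i, name in enumerate(loadcalc.IMPACT_CLASSES)}

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [c for c in loadcalc.CODON_TABLE if c not in _STOP_CODONS and c != "ATG"]


@dataclass
class SimulationConfig:
    """Parameters of a simulation scenario.

    Defaults mirror a desk-scale version of the study design: a large
    outbred population, a mid-sized population, and a small population with
    partial selfing, all split from a common ancestor, sequenced at low
    coverage (~2x) with 1% read error.
    """

    n_pops: int = 3
    pop_sizes: tuple[int, ...] = (1000, 300, 50)  # diploid census sizes
    split_gens: tuple[int, ...] = (150, 100)  # pop k splits from pop 0
    selfing_rates: tuple[float, ...] = (0.0, 0.0, 0.3)
    seq_length: int = 500_000
    n_genes: int = 100
    gene_length: int = 1500  # total CDS length, divisible by 3
    mu_sim: float = 2e-7  # per site per generation
    class_probs: tuple[float, float, float] = (0.25, 0.5, 0.25)  # high/moderate/low
    sel_coeffs: dict = field(
        default_factory=lambda: {"HIGH": 0.5, "MODERATE": 0.03, "LOW": 0.003, "MODIFIER": 0.0}
    )
    dominance_h: dict = field(
        default_factory=lambda: {"HIGH": 0.0, "MODERATE": 0.2, "LOW": 0.3, "MODIFIER": 0.5}
    )
    mean_depth: float = 2.14
    error_rate: float = 0.01
    seed: int = 1
    n_sample: tuple[int, ...] = (15, 10, 7)
    # genome architecture
    intron_length: int = 500
    utr_length: int = 200
    flank: int = 5000
    # simulation control
    init: str = "coalescent"  # or "monomorphic"
    burn_in: int | None = None  # None -> policy default (see resolved_burn_in)
    track_pedigree: bool = True

    def __post_init__(self) -> None:
        if self.n_pops < 1:
            raise ValueError("n_pops must be >= 1")
        for name in ("pop_sizes", "selfing_rates", "n_sample"):
            if len(getattr(self, name)) != self.n_pops:
                raise ValueError(f"{name} must have length n_pops")
        if self.n_pops > 1 and len(self.split_gens) != self.n_pops - 1:
            raise ValueError("split_gens must have length n_pops - 1")
        if any(n <= 0 for n in self.pop_sizes):
            raise ValueError("pop_sizes must be positive")
        if any(not 0.0 <= a <= 1.0 for a in self.selfing_rates):
            raise ValueError("selfing_rates must lie in [0, 1]")
        if self.seq_length <= 0 or self.gene_length <= 0:
            raise ValueError("lengths must be positive")
        if self.gene_length % 3:
            raise ValueError("gene_length must be divisible by 3")
        if abs(sum(self.class_probs) - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")
        if self.mu_sim < 0 or self.mean_depth < 0 or not 0 <= self.error_rate < 0.5:
            raise ValueError("invalid rate parameter")
        for c in loadcalc.IMPACT_CLASSES:
            s = self.sel_coeffs[c]
            h = self.dominance_h[c]
            if s > 1:
                raise ValueError(f"selection coefficient for {c} exceeds 1")
            if not 0.0 <= h <= 1.0:
                raise ValueError(f"dominance for {c} outside [0, 1]")
        if self.init not in ("coalescent", "monomorphic"):
            raise ValueError("init must be 'coalescent' or 'monomorphic'")
        if any(n > N for n, N in zip(self.n_sample, self.pop_sizes)):
            raise ValueError("n_sample cannot exceed pop_sizes")

    @property
    def resolved_burn_in(self) -> int:
        """Burn-in generations before the first split.

        Monomorphic start: ``10 N`` (mutation-drift equilibrium from
        scratch). Coalescent start: neutral variation is already at
        equilibrium, so the burn-in only has to equilibrate the selected
        classes, whose sojourn times are of order ``1/(h s)`` generations;
        ``max(150, N/4)`` covers the default DFE comfortably.
        """
        if self.burn_in is not None:
            return self.burn_in
        n_anc = self.pop_sizes[0]
        if self.init == "monomorphic":
            return 10 * n_anc
        return max(150, n_anc // 4)


@dataclass
class SimTruth:
    """Ground truth for every quantity the pipeline estimates."""

    chrom: str
    positions: np.ndarray  # (S,) 0-based
    ancestral_allele: np.ndarray  # (S,) single chars; ancestral == reference
    derived_allele: np.ndarray  # (S,)
    site_class: np.ndarray  # (S,) labels from IMPACT_CLASSES
    site_context: np.ndarray  # (S,) labels from CONTEXTS
    haplotypes: np.ndarray  # (2n, S) uint8 derived-allele indicators
    true_genotypes: np.ndarray  # (n, S) derived-allele counts
    pop_labels: np.ndarray  # (n,)
    sample_ids: list[str]
    true_F: np.ndarray  # (n,) pedigree inbreeding coefficients
    pedigree: np.ndarray  # (n, 2) parent indices within the parental generation
    reference: str
    gene_models: list[GeneModel]

    @property
    def n_individuals(self) -> int:
        return self.true_genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return len(self.positions)


@dataclass
class PileupMatrix:
    """Per-site, per-individual counts of reads supporting the two alleles."""

    chrom: str
    positions: np.ndarray  # (S,)
    ref_allele: np.ndarray  # (S,)
    alt_allele: np.ndarray  # (S,)
    ref_count: np.ndarray  # (S, n) int32
    alt_count: np.ndarray  # (S, n) int32
    sample_ids: list[str]
    pop_labels: np.ndarray

    @property
    def depth(self) -> np.ndarray:
        return self.ref_count + self.alt_count


# ---------------------------------------------------------------------------
# genome architecture
# ---------------------------------------------------------------------------


def build_genome(config: SimulationConfig, rng: np.random.Generator):
    """Random reference sequence, gene models, and per-base context array.

    Genes are placed non-overlapping on the '+' strand at regular intervals:
    5'UTR, CDS exon, intron, CDS exon, 3'UTR. Each CDS starts with ATG, ends
    with TAA, and contains no internal stop codon, so every possible SNP has
    a well-defined translational effect.
    """
    L = config.seq_length
    ref = rng.choice(list("ACGT"), size=L)
    n_codons = config.gene_length // 3
    c1 = 3 * (n_codons // 2)  # exon split need not respect frame, but this keeps
    c2 = config.gene_length - c1  # the toy architecture simple
    span = 2 * config.utr_length + c1 + config.intron_length + c2
    slot = L // config.n_genes
    if slot < span + 2:
        raise ValueError("seq_length too small for the requested gene architecture")
    context = np.zeros(L, dtype=np.int8)  # intergenic
    genes = []
    for gi in range(config.n_genes):
        start = gi * slot + (slot - span) // 2
        u5 = (start, start + config.utr_length)
        e1 = (u5[1], u5[1] + c1)
        intr = (e1[1], e1[1] + config.intron_length)
        e2 = (intr[1], intr[1] + c2)
        u3 = (e2[1], e2[1] + config.utr_length)
        codons = ["ATG"] + list(rng.choice(_SENSE_CODONS, size=n_codons - 2)) + ["TAA"]
        cds_seq = "".join(codons)
        ref[e1[0] : e1[1]] = list(cds_seq[:c1])
        ref[e2[0] : e2[1]] = list(cds_seq[c1:])
        genes.append(
            GeneModel(
                gene_id=f"gene{gi:04d}",
                chrom="1",
                strand="+",
                cds=((e1[0], e1[1]), (e2[0], e2[1])),
                utr5=(u5,),
                utr3=(u3,),
            )
        )
        context[u5[0] : u5[1]] = _CTX_CODE["UTR"]
        context[u3[0] : u3[1]] = _CTX_CODE["UTR"]
        context[e1[0] : e1[1]] = _CTX_CODE["CDS"]
        context[e2[0] : e2[1]] = _CTX_CODE["CDS"]
        context[intr[0] : intr[1]] = _CTX_CODE["intron"]
        up_s = max(0, u5[0] - config.flank)
        context[up_s : u5[0]] = np.where(
            context[up_s : u5[0]] == 0, _CTX_CODE["upstream"], context[up_s : u5[0]]
        )
        dn_e = min(L, u3[1] + config.flank)
        context[u3[1] : dn_e] = np.where(
            context[u3[1] : dn_e] == 0, _CTX_CODE["downstream"], context[u3[1] : dn_e]
        )
    return "".join(ref), genes, context


def _assign_site(
    pos: int,
    reference: str,
    context_code: int,
    gene_index: loadcalc.GeneIndex,
    class_probs,
    rng: np.random.Generator,
) -> tuple[str, str]:
    """Derived allele and impact class for a new mutation at ``pos``.

    Non-CDS sites are MODIFIER with a uniformly random derived base. For CDS
    sites a target class is drawn from ``class_probs`` and an alternate base
    realising that class (stop_gained etc. for HIGH, missense for MODERATE,
    synonymous for LOW) is chosen; if the codon offers no base with the
    drawn effect, the class is redrawn among the effects available, so the
    truth label always agrees with sequence-based classification.
    """
    ref_b = reference[pos]
    if context_code != _CTX_CODE["CDS"]:
        others = "ACGT".replace(ref_b, "")
        return others[int(rng.integers(3))], "MODIFIER"
    cache = getattr(gene_index, "_alt_cache", None)
    if cache is None:
        cache = gene_index._alt_cache = {}
    by_class = cache.get(pos)
    if by_class is None:
        by_class = {"HIGH": [], "MODERATE": [], "LOW": []}
        for alt in "ACGT":
            if alt == ref_b:
                continue
            cls, _ = loadcalc.classify_variant(pos, ref_b, alt, gene_index, reference)
            if cls in by_class:
                by_class[cls].append(alt)
        cache[pos] = by_class
    order = ("HIGH", "MODERATE", "LOW")
    probs = np.asarray(class_probs, dtype=float)
    avail = np.array([len(by_class[c]) > 0 for c in order])
    if not avail.any():  # cannot happen for a sense codon, but stay safe
        others = "ACGT".replace(ref_b, "")
        return others[int(rng.integers(3))], "MODIFIER"
    w = np.where(avail, probs, 0.0)
    if w.sum() == 0:
        w = avail.astype(float)
    w = w / w.sum()
    cls = order[int(np.searchsorted(np.cumsum(w), rng.random(), side="right"))]
    alts = by_class[cls]
    return alts[int(rng.integers(len(alts)))], cls


# ---------------------------------------------------------------------------
# Wright-Fisher machinery
# ---------------------------------------------------------------------------


def _log_fitness(hap: np.ndarray, lw_het: np.ndarray, lw_hom: np.ndarray) -> np.ndarray:
    g = hap[0::2] + hap[1::2]
    return (g == 1).astype(np.float32) @ lw_het + (g == 2).astype(np.float32) @ lw_hom


def _gametes(hap: np.ndarray, parents: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    h1 = hap[2 * parents]
    h2 = hap[2 * parents + 1]
    n, S = h1.shape
    packed = rng.integers(0, 256, size=(n, (S + 7) // 8), dtype=np.uint8)
    pick = np.unpackbits(packed, axis=1)[:, :S]
    return h1 ^ ((h1 ^ h2) & pick)


def _choose_parents(logw, n_off, selfing, rng):
    w = np.exp(logw - logw.max())
    tot = w.sum()
    p = np.full(len(w), 1.0 / len(w)) if tot <= 0 else w / tot
    p1 = rng.choice(len(p), size=n_off, p=p)
    p2 = rng.choice(len(p), size=n_off, p=p)
    if selfing > 0:
        selfed = rng.random(n_off) < selfing
        p2[selfed] = p1[selfed]
    return p1, p2


def _kinship_next(K, p1, p2):
    f_child = K[p1, p2]
    half = 0.5 * (K[p1, :] + K[p2, :])
    Kc = 0.5 * (half[:, p1] + half[:, p2])
    np.fill_diagonal(Kc, 0.5 * (1.0 + f_child))
    return Kc, f_child


class _Population:
    """Mutable state of one population during forward simulation."""

    def __init__(self, hap, selfing, rng, track, K=None, F=None):
        self.hap = hap  # (2N, S) uint8
        self.selfing = selfing
        self.rng = rng
        self.track = track
        n = hap.shape[0] // 2
        self.K = K if K is not None else (0.5 * np.eye(n, dtype=np.float32) if track else None)
        self.F = F if F is not None else np.zeros(n, dtype=np.float32)
        self.parents = np.zeros((n, 2), dtype=np.int64)

    @property
    def n(self) -> int:
        return self.hap.shape[0] // 2

    def step(self, lw_het, lw_hom, n_next=None):
        n_next = n_next or self.n
        logw = _log_fitness(self.hap, lw_het, lw_hom)
        p1, p2 = _choose_parents(logw, n_next, self.selfing, self.rng)
        gA = _gametes(self.hap, p1, self.rng)
        gB = _gametes(self.hap, p2, self.rng)
        new = np.empty((2 * n_next, self.hap.shape[1]), dtype=np.uint8)
        new[0::2] = gA
        new[1::2] = gB
        self.hap = new
        self.parents = np.column_stack([p1, p2])
        if self.track:
            self.K, self.F = _kinship_next(self.K, p1, p2)
        else:
            # selfing-chain recursion; non-self parents treated as unrelated
            newF = np.where(p1 == p2, 0.5 * (1.0 + self.F[p1]), 0.0)
            self.F = newF.astype(np.float32)
        return p1, p2

    def spawn(self, n_daughter, lw_het, lw_hom, selfing, rng):
        """Found a daughter population by one round of WF reproduction."""
        logw = _log_fitness(self.hap, lw_het, lw_hom)
        p1, p2 = _choose_parents(logw, n_daughter, selfing, rng)
        gA = _gametes(self.hap, p1, rng)
        gB = _gametes(self.hap, p2, rng)
        hap = np.empty((2 * n_daughter, self.hap.shape[1]), dtype=np.uint8)
        hap[0::2] = gA
        hap[1::2] = gB
        daughter = _Population(hap, selfing, rng, self.track)
        if self.track:
            daughter.K, daughter.F = _kinship_next(self.K, p1, p2)
        daughter.parents = np.column_stack([p1, p2])
        return daughter


def _coalescent_init(n_chrom, config, rng) -> tuple[np.ndarray, np.ndarray]:
    """Equilibrium neutral standing variation from msprime.

    Returns (positions, haplotype matrix (n_chrom, S)). The scaled mutation
    rate matches the forward model (theta = 4 N mu per site); recombination
    is set to the mutation rate, consistent with the forward simulator's
    free recombination between sites.
    """
    import msprime

    if config.mu_sim == 0:
        return np.empty(0, dtype=np.int64), np.empty((n_chrom, 0), dtype=np.uint8)
    N = config.pop_sizes[0]
    seed = int(rng.integers(1, 2**31 - 1))
    ts = msprime.sim_ancestry(
        samples=n_chrom,
        ploidy=1,
        population_size=2 * N,  # ploidy-1 pairwise coalescence at rate 1/(2N)
        sequence_length=config.seq_length,
        recombination_rate=config.mu_sim,
        random_seed=seed,
    )
    mts = msprime.sim_mutations(
        ts,
        rate=config.mu_sim,
        random_seed=seed + 1,
        model=msprime.BinaryMutationModel(),
        discrete_genome=True,
    )
    pos, keep_cols = [], []
    seen = set()
    G = mts.genotype_matrix()  # (S, n_chrom)
    for i, var_pos in enumerate(mts.tables.sites.position):
        p = int(var_pos)
        if p in seen:
            continue
        seen.add(p)
        pos.append(p)
        keep_cols.append(i)
    hap = np.ascontiguousarray(G[keep_cols].T.astype(np.uint8))
    hap = np.minimum(hap, 1)
    return np.asarray(pos, dtype=np.int64), hap


def simulate_populations(config: SimulationConfig) -> SimTruth:
    """Run the forward simulation and return sampled individuals with truth."""
    rng = np.random.default_rng([config.seed, 0])
    reference, genes, context = build_genome(config, rng)
    gene_index = loadcalc.GeneIndex(genes)
    L = config.seq_length
    class_names = np.array(loadcalc.IMPACT_CLASSES)

    # --- site registry -----------------------------------------------------
    if config.init == "coalescent":
        positions, hap0 = _coalescent_init(2 * config.pop_sizes[0], config, rng)
    else:
        positions = np.empty(0, dtype=np.int64)
        hap0 = np.zeros((2 * config.pop_sizes[0], 0), dtype=np.uint8)
    site_class = np.empty(len(positions), dtype=np.int8)
    derived = np.empty(len(positions), dtype="U1")
    for i, p in enumerate(positions):
        alt, cls = _assign_site(int(p), reference, context[p], gene_index, config.class_probs, rng)
        derived[i] = alt
        site_class[i] = _CLASS_CODE[cls]
    occupied = set(int(p) for p in positions)

    s_by_class = np.array([config.sel_coeffs[c] for c in loadcalc.IMPACT_CLASSES])
    h_by_class = np.array([config.dominance_h[c] for c in loadcalc.IMPACT_CLASSES])

    def _lw(site_cls):
        s = s_by_class[site_cls]
        h = h_by_class[site_cls]
        lw_het = np.log(np.maximum(1.0 - h * s, 1e-26)).astype(np.float32)
        lw_hom = np.log(np.maximum(1.0 - s, 1e-26)).astype(np.float32)
        return np.maximum(lw_het, -60.0), np.maximum(lw_hom, -60.0)

    pops: list[_Population | None] = [
        _Population(hap0, config.selfing_rates[0], rng, config.track_pedigree)
    ] + [None] * (config.n_pops - 1)

    split_at = {}  # generations before present -> list of pop indices to found
    for k, g in enumerate(config.split_gens, start=1):
        split_at.setdefault(int(g), []).append(k)
    horizon = max(split_at) if split_at else 0

    def _mutate_and_prune():
        nonlocal positions, site_class, derived
        total_chrom = sum(p.hap.shape[0] for p in pops if p is not None)
        n_new = rng.poisson(total_chrom * config.mu_sim * L) if config.mu_sim > 0 else 0
        if n_new:
            new_pos, new_cls, new_alt, new_row = [], [], [], []
            for _ in range(n_new):
                for _try in range(20):
                    p = int(rng.integers(L))
                    if p not in occupied:
                        break
                else:
                    continue
                occupied.add(p)
                alt, cls = _assign_site(
                    p, reference, context[p], gene_index, config.class_probs, rng
                )
                new_pos.append(p)
                new_cls.append(_CLASS_CODE[cls])
                new_alt.append(alt)
                new_row.append(int(rng.integers(total_chrom)))
            if new_pos:
                k = len(new_pos)
                rows = np.asarray(new_row)
                cols = np.arange(k)
                row_off = 0
                for pp in pops:
                    if pp is None:
                        continue
                    block = np.zeros((pp.hap.shape[0], k), dtype=np.uint8)
                    here = (rows >= row_off) & (rows < row_off + pp.hap.shape[0])
                    block[rows[here] - row_off, cols[here]] = 1
                    row_off += pp.hap.shape[0]
                    pp.hap = np.concatenate([pp.hap, block], axis=1)
                positions = np.concatenate([positions, np.asarray(new_pos, dtype=np.int64)])
                site_class = np.concatenate([site_class, np.asarray(new_cls, dtype=np.int8)])
                derived = np.concatenate([derived, np.asarray(new_alt, dtype="U1")])
        # prune sites lost everywhere or fixed everywhere
        tot = np.zeros(len(positions), dtype=np.int64)
        cap = 0
        for pp in pops:
            if pp is None:
                continue
            tot += pp.hap.sum(axis=0, dtype=np.int64)
            cap += pp.hap.shape[0]
        keep = (tot > 0) & (tot < cap)
        if not keep.all():
            lost = positions[~keep]
            for p in lost:
                occupied.discard(int(p))
            positions = positions[keep]
            site_class = site_class[keep]
            derived = derived[keep]
            for pp in pops:
                if pp is not None:
                    pp.hap = np.ascontiguousarray(pp.hap[:, keep])

    # --- burn-in -----------------------------------------------------------
    for _ in range(config.resolved_burn_in):
        lw_het, lw_hom = _lw(site_class)
        pops[0].step(lw_het, lw_hom)
        _mutate_and_prune()

    # --- post-split phase --------------------------------------------------
    for t in range(horizon, 0, -1):
        if t in split_at:
            lw_het, lw_hom = _lw(site_class)
            for k in split_at[t]:
                pops[k] = pops[0].spawn(
                    config.pop_sizes[k], lw_het, lw_hom, config.selfing_rates[k], rng
                )
        lw_het, lw_hom = _lw(site_class)
        for k, pp in enumerate(pops):
            if pp is not None:
                pp.step(lw_het, lw_hom, n_next=config.pop_sizes[k])
        _mutate_and_prune()

    # --- sample ------------------------------------------------------------
    hap_rows, gts, labels, ids, Fs, peds = [], [], [], [], [], []
    for k, pp in enumerate(pops):
        if pp is None:  # unsplit pop in a 1-population scenario
            continue
        take = rng.choice(pp.n, size=config.n_sample[k], replace=False)
        for j, ind in enumerate(take):
            hap_rows.append(pp.hap[2 * ind])
            hap_rows.append(pp.hap[2 * ind + 1])
            gts.append(pp.hap[2 * ind] + pp.hap[2 * ind + 1])
            labels.append(f"pop{k}")
            ids.append(f"pop{k}_ind{j:03d}")
            Fs.append(float(pp.F[ind]))
            peds.append(pp.parents[ind])
    haplotypes = np.array(hap_rows, dtype=np.uint8)
    true_genotypes = np.array(gts, dtype=np.uint8)
    # restrict to sites polymorphic among the sampled individuals
    tot = haplotypes.sum(axis=0)
    seg = (tot > 0) & (tot < haplotypes.shape[0])
    order = np.argsort(positions[seg], kind="stable")

    def _sel(a):
        return np.ascontiguousarray(a[seg][order]) if a.ndim == 1 else None

    keep_idx = np.where(seg)[0][order]
    return SimTruth(
        chrom="1",
        positions=positions[keep_idx],
        ancestral_allele=np.array([reference[p] for p in positions[keep_idx]], dtype="U1"),
        derived_allele=derived[keep_idx],
        site_class=class_names[site_class[keep_idx]],
        site_context=np.array(CONTEXTS)[context[positions[keep_idx]]],
        haplotypes=np.ascontiguousarray(haplotypes[:, keep_idx]),
        true_genotypes=np.ascontiguousarray(true_genotypes[:, keep_idx]),
        pop_labels=np.array(labels),
        sample_ids=ids,
        true_F=np.array(Fs),
        pedigree=np.array(peds, dtype=np.int64),
        reference=reference,
        gene_models=genes,
    )


def simulate_pileups(truth: SimTruth, config: SimulationConfig) -> PileupMatrix:
    """Low-coverage read evidence for the sampled individuals.

    Depth is Poisson(``mean_depth``) per individual and site; each read is
    drawn from one of the individual's two alleles at random and reports the
    other segregating allele with probability ``error_rate``.
    """
    if config.mean_depth < 0:
        raise ValueError("mean_depth must be >= 0")
    rng = np.random.default_rng([config.seed, 7])
    g = truth.true_genotypes.T.astype(np.int64)  # (S, n)
    S, n = g.shape
    depth = rng.poisson(config.mean_depth, size=(S, n))
    from_alt = rng.binomial(depth, g / 2.0)
    from_ref = depth - from_alt
    e = config.error_rate
    alt_count = rng.binomial(from_alt, 1.0 - e) + rng.binomial(from_ref, e)
    return PileupMatrix(
        chrom=truth.chrom,
        positions=truth.positions.copy(),
        ref_allele=truth.ancestral_allele.copy(),
        alt_allele=truth.derived_allele.copy(),
        ref_count=(depth - alt_count).astype(np.int32),
        alt_count=alt_count.astype(np.int32),
        sample_ids=list(truth.sample_ids),
        pop_labels=truth.pop_labels.copy(),
    )


# ---------------------------------------------------------------------------
# neutral coalescent mode (estimator calibration)
# ---------------------------------------------------------------------------


def neutral_coalescent_haplotypes(
    n_chrom: int,
    seq_length: int,
    theta_site: float,
    seed: int,
    num_replicates: int = 1,
    recomb_theta_ratio: float = 1.0,
    size_changes: list[tuple[float, float]] | None = None,
):
    """Neutral haplotypes from the coalescent (msprime).

    Yields ``(positions, hap)`` with ``hap`` of shape (n_chrom, S) and
    ``theta_site = 4 Ne mu`` per site at the present-day size. Recombination
    rate is ``recomb_theta_ratio`` times the mutation rate (1.0 approximates
    a genome of quasi-independent sites). ``size_changes`` is an optional
    list of ``(time_generations, size_ratio)`` steps backward in time: the
    population size becomes ``size_ratio`` times the present-day size at
    that time, so ``[(t, 0.1)]`` models a 10x expansion at ``t`` generations
    ago and ``[(t, 20.0)]`` a 95% bottleneck at ``t``.
    """
    import msprime

    N = 10_000.0
    mu = theta_site / (4.0 * N)
    demography = None
    if size_changes:
        demography = msprime.Demography()
        demography.add_population(name="pop0", initial_size=2 * N)
        for t, ratio in size_changes:
            demography.add_population_parameters_change(
                time=t, initial_size=2 * N * ratio, population="pop0"
            )
    anc = msprime.sim_ancestry(
        samples=n_chrom,
        ploidy=1,
        population_size=None if demography else 2 * N,
        demography=demography,
        sequence_length=seq_length,
        recombination_rate=recomb_theta_ratio * mu,
        random_seed=seed,
        num_replicates=num_replicates,
    )
    for i, ts in enumerate(anc):
        mts = msprime.sim_mutations(
            ts,
            rate=mu,
            random_seed=seed + 1 + i,
            model=msprime.BinaryMutationModel(),
            discrete_genome=False,
        )
        pos = mts.tables.sites.position
        hap = np.minimum(mts.genotype_matrix().T.astype(np.uint8), 1)
        yield pos, hap


# ---------------------------------------------------------------------------
# pedigree micro-simulator (kinship oracles)
# ---------------------------------------------------------------------------


def simulate_pedigree_pair(
    relationship: str,
    n_sites: int,
    seed: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
) -> tuple[np.ndarray, np.ndarray]:
    """Genotypes of a pair with a known pedigree at unlinked sites.

    Relationships: ``self``, ``parent-offspring``, ``full-sib``,
    ``half-sib``, ``cousin``, ``unrelated``. Founders are drawn at
    Hardy-Weinberg with per-site frequencies uniform in ``maf_range``.
    """
    rng = np.random.default_rng(seed)
    f = rng.uniform(*maf_range, size=n_sites)

    def founder_hap():
        return (rng.random(n_sites) < f).astype(np.int8)

    def child(p, q):
        # p and q are (hap1, hap2) tuples
        pick = rng.integers(0, 2, n_sites)
        ga = np.where(pick, p[1], p[0])
        pick = rng.integers(0, 2, n_sites)
        gb = np.where(pick, q[1], q[0])
        return ga, gb

    def ind():
        return founder_hap(), founder_hap()

    def gt(h):
        return (h[0] + h[1]).astype(np.int8)

    if relationship == "self":
        a = ind()
        return gt(a), gt(a)
    if relationship == "parent-offspring":
        p, q = ind(), ind()
        return gt(p), gt(child(p, q))
    if relationship == "full-sib":
        p, q = ind(), ind()
        return gt(child(p, q)), gt(child(p, q))
    if relationship == "half-sib":
        p, q, r = ind(), ind(), ind()
        return gt(child(p, q)), gt(child(p, r))
    if relationship == "cousin":
        gpa, gpb = ind(), ind()
        sib1, sib2 = child(gpa, gpb), child(gpa, gpb)
        return gt(child(sib1, ind())), gt(child(sib2, ind()))
    if relationship == "unrelated":
        return gt(ind()), gt(ind())
    raise ValueError(f"unknown relationship {relationship!r}")


# ---------------------------------------------------------------------------
# truth bundle I/O
# ---------------------------------------------------------------------------


def write_truth_bundle(
    truth: SimTruth,
    config: SimulationConfig,
    outdir,
    pileup: PileupMatrix | None = None,
) -> dict[str, Path]:
    """Write the simulation as standard files (VCF, GFF3, FASTA, TSV, JSON)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": out / "reference.fasta",
        "ancestral": out / "ancestral.fasta",
        "gff3": out / "genes.gff3",
        "vcf": out / "truth.vcf",
        "pileup": out / "pileup.tsv",
        "json": out / "truth.json",
    }
    _write_fasta(paths["reference"], {truth.chrom: truth.reference})
    _write_fasta(paths["ancestral"], {truth.chrom: truth.reference})
    loadcalc.gene_models_to_gff3(
        truth.gene_models, paths["gff3"], {truth.chrom: len(truth.reference)}
    )
    _write_truth_vcf(paths["vcf"], truth, config, pileup)
    with open(paths["pileup"], "w") as fh:
        fh.write("chrom\tpos0\tindividual\tref_count\talt_count\n")
        if pileup is not None:
            S, n = pileup.ref_count.shape
            for i in range(S):
                for j in range(n):
                    fh.write(
                        f"{pileup.chrom}\t{pileup.positions[i]}\t{pileup.sample_ids[j]}\t"
                        f"{pileup.ref_count[i, j]}\t{pileup.alt_count[i, j]}\n"
                    )
    meta = {
        "config": _config_to_dict(config),
        "sample_ids": truth.sample_ids,
        "pop_labels": truth.pop_labels.tolist(),
        "true_F": truth.true_F.tolist(),
        "pedigree": truth.pedigree.tolist(),
    }
    with open(paths["json"], "w") as fh:
        json.dump(meta, fh, indent=1)
    return paths


def _config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    for key, val in d.items():
        if isinstance(val, tuple):
            d[key] = list(val)
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    kwargs = dict(d)
    for key in ("pop_sizes", "split_gens", "selfing_rates", "n_sample", "class_probs"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    return SimulationConfig(**kwargs)


def _write_fasta(path, seqs: dict[str, str]) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def _write_truth_vcf(path, truth: SimTruth, config: SimulationConfig, pileup) -> None:
    from . import genolik

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={truth.chrom},length={len(truth.reference)}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##INFO=<ID=CTX,Number=1,Type=String,Description="Genomic context">\n')
        fh.write('##INFO=<ID=CLS,Number=1,Type=String,Description="Impact class">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if pileup is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
            fh.write(
                '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele read depths">\n'
            )
            fh.write(
                '##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred genotype likelihoods">\n'
            )
        cols = "\t".join(truth.sample_ids)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        fmt = "GT" if pileup is None else "GT:DP:AD:PL"
        for i in range(truth.n_sites):
            info = (
                f"AA={truth.ancestral_allele[i]};CTX={truth.site_context[i]};"
                f"CLS={truth.site_class[i]}"
            )
            fields = []
            for j in range(truth.n_individuals):
                h1 = truth.haplotypes[2 * j, i]
                h2 = truth.haplotypes[2 * j + 1, i]
                entry = f"{h1}/{h2}"
                if pileup is not None:
                    rc = int(pileup.ref_count[i, j])
                    ac = int(pileup.alt_count[i, j])
                    ll = genolik.gl_from_pileup(rc, ac, config.error_rate)
                    pl = np.round(-10 * (np.array(ll) - max(ll)) / np.log(10)).astype(int)
                    entry += f":{rc + ac}:{rc},{ac}:{pl[0]},{pl[1]},{pl[2]}"
                fields.append(entry)
            fh.write(
                f"{truth.chrom}\t{truth.positions[i] + 1}\t.\t{truth.ancestral_allele[i]}\t"
                f"{truth.derived_allele[i]}\t.\tPASS\t{info}\t{fmt}\t" + "\t".join(fields) + "\n"
            )


def read_truth_vcf(path):
    """Read a truth VCF back into arrays (positions, ref, alt, class, context, GT)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    pos, ref, alt, cls, ctx, gts = [], [], [], [], [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue
        pos.append(rec.POS - 1)
        ref.append(rec.REF)
        alt.append(rec.ALT[0])
        cls.append(rec.INFO.get("CLS"))
        ctx.append(rec.INFO.get("CTX"))
        g = rec.genotype.array()[:, :2].sum(axis=1)
        gts.append(g)
    return {
        "samples": samples,
        "positions": np.asarray(pos, dtype=np.int64),
        "ref": np.asarray(ref, dtype="U1"),
        "alt": np.asarray(alt, dtype="U1"),
        "site_class": np.asarray(cls),
        "site_context": np.asarray(ctx),
        "genotypes": np.asarray(gts, dtype=np.int8),
    }


def read_pileup_tsv(path) -> PileupMatrix:
    """Read the bundle's pileup TSV back into a PileupMatrix."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    samples = list(dict.fromkeys(df["individual"]))
    positions = np.array(sorted(df["pos0"].unique()), dtype=np.int64)
    pos_idx = {p: i for i, p in enumerate(positions)}
    samp_idx = {s: j for j, s in enumerate(samples)}
    S, n = len(positions), len(samples)
    rc = np.zeros((S, n), dtype=np.int32)
    ac = np.zeros((S, n), dtype=np.int32)
    for row in df.itertuples(index=False):
        i, j = pos_idx[row.pos0], samp_idx[row.individual]
        rc[i, j] = row.ref_count
        ac[i, j] = row.alt_count
    chrom = str(df["chrom"].iloc[0]) if len(df) else "1"
    return PileupMatrix(
        chrom=chrom,
        positions=positions,
        ref_allele=np.full(S, "N", dtype="U1"),
        alt_allele=np.full(S, "N", dtype="U1"),
        ref_count=rc,
        alt_count=ac,
        sample_ids=samples,
        pop_labels=np.full(n, "pop0"),
    )
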