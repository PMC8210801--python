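"""Genotype likelihoods, allele-frequency estimation, SNP calling, and
posterior genotype calling for low-coverage data.

Per-read model (biallelic collapse of the classic per-base error model):
a read matches the allele that generated it with probability ``1 - e`` and
reports any specific other base with probability ``e/3``. For a diploid
genotype the per-read likelihood is the mean over the genotype's two
alleles, so with ``r`` reads of the major and ``a`` reads of the minor
allele::

    ln L(hom-major) = r ln(1 - e) + a ln(e/3)
    ln L(het)       = (r + a) ln(1/2 - e/3)
    ln L(hom-minor) = r ln(e/3) + a ln(1 - e)

The minor-allele frequency at a site is the maximum-likelihood value under
a Hardy-Weinberg prior, found by EM over individuals. A site is called
polymorphic when the likelihood-ratio test of ``f_hat`` against ``f = 0``
falls below a p-value cutoff (chi-square with 1 df), and retained sites
must additionally pass minor-allele-frequency, individuals-with-data,
summed-depth, and heterozygote-excess (HWE) filters. Genotypes are called
as the maximum-posterior genotype under the HWE prior at the estimated
frequency, with individuals below a per-site depth floor set to missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .simdata import PileupMatrix

#: site filters mirroring the two analysis profiles: all-samples calling
#: ("population": >= 60 individuals with data, summed depth <= 500) and
#: equal-subset calling ("genomic": >= 15 individuals, summed depth <= 100).
PROFILES = {"population": {"min_ind": 60, "max_depth": 500},
            "genomic": {"min_ind": 15, "max_depth": 100}}

EM_TOL = 1e-8
EM_MAX_ITER = 200
EM_INIT = 0.25


@dataclass
class GLMatrix:
    """Per-site, per-individual log-likelihoods of the three genotypes.

    ``ll[s, j]`` holds natural-log likelihoods for (hom-major, het,
    hom-minor) at site ``s`` in individual ``j``. Likelihood triplets are
    defined up to an additive constant; every downstream computation is
    invariant to renormalisation.
    """

    chrom: str
    positions: np.ndarray  # (S,)
    major: np.ndarray  # (S,) allele characters
    minor: np.ndarray
    ref: np.ndarray  # reference/ancestral allele as given by the pileup
    alt: np.ndarray
    ll: np.ndarray  # (S, n, 3)
    depth: np.ndarray  # (S, n)
    sample_ids: list
    pop_labels: np.ndarray

    @property
    def n_sites(self) -> int:
        return self.ll.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.ll.shape[1]

    @property
    def has_data(self) -> np.ndarray:
        return self.depth > 0


def gl_from_pileup(ref_count, alt_count, e: float):
    """Log-likelihoods of (hom-ref, het, hom-alt) from biallelic read counts.

    Accepts scalars or arrays; with no reads the triplet is flat (0, 0, 0).
    """
    if not 0.0 < e < 0.75:
        raise ValueError("error rate must lie in (0, 0.75)")
    r = np.asarray(ref_count)
    a = np.asarray(alt_count)
    if (r < 0).any() or (a < 0).any():
        raise ValueError("read counts must be non-negative")
    l_match = np.log(1.0 - e)
    l_mis = np.log(e / 3.0)
    l_het = np.log(0.5 - e / 3.0)
    ll0 = r * l_match + a * l_mis
    ll1 = (r + a) * l_het
    ll2 = r * l_mis + a * l_match
    if np.isscalar(ref_count) and np.isscalar(alt_count):
        return float(ll0), float(ll1), float(ll2)
    return np.stack([ll0, ll1, ll2], axis=-1)


def glmatrix_from_pileup(pileup: PileupMatrix, e: float) -> GLMatrix:
    """Compute genotype likelihoods, orienting each site to its major allele.

    The major allele is the one with the larger total read count across
    individuals, with a lexicographic tie-break on the allele character.
    """
    ll_refalt = gl_from_pileup(pileup.ref_count, pileup.alt_count, e)  # (S, n, 3)
    tot_ref = pileup.ref_count.sum(axis=1)
    tot_alt = pileup.alt_count.sum(axis=1)
    ref_major = (tot_ref > tot_alt) | (
        (tot_ref == tot_alt) & (pileup.ref_allele <= pileup.alt_allele)
    )
    ll = np.where(ref_major[:, None, None], ll_refalt, ll_refalt[:, :, ::-1])
    major = np.where(ref_major, pileup.ref_allele, pileup.alt_allele)
    minor = np.where(ref_major, pileup.alt_allele, pileup.ref_allele)
    return GLMatrix(
        chrom=pileup.chrom,
        positions=pileup.positions.copy(),
        major=major,
        minor=minor,
        ref=pileup.ref_allele.copy(),
        alt=pileup.alt_allele.copy(),
        ll=np.ascontiguousarray(ll),
        depth=pileup.depth.astype(np.int32),
        sample_ids=list(pileup.sample_ids),
        pop_labels=pileup.pop_labels.copy(),
    )


def _norm_lik(ll: np.ndarray) -> np.ndarray:
    """Likelihoods normalised to max 1 per triplet (safe to exponentiate)."""
    return np.exp(ll - ll.max(axis=-1, keepdims=True))


def estimate_af_em(
    ll: np.ndarray,
    has_data: np.ndarray | None = None,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> np.ndarray | float:
    """ML minor-allele frequency per site by EM under a HWE prior.

    ``ll`` is (S, n, 3) or (n, 3) natural-log likelihoods in (hom-major,
    het, hom-minor) order. Individuals with ``has_data`` False are
    excluded. Sites where no individual has data return NaN.
    """
    single = ll.ndim == 2
    L = _norm_lik(np.asarray(ll, dtype=float))
    if single:
        L = L[None]
    S, n, _ = L.shape
    if has_data is None:
        has_data = np.ones((S, n), dtype=bool)
    elif single and has_data.ndim == 1:
        has_data = has_data[None]
    W = has_data.astype(float)
    n_eff = W.sum(axis=1)
    f = np.full(S, EM_INIT)
    active = n_eff > 0
    for _ in range(max_iter):
        prior = np.stack(
            [(1 - f) ** 2, 2 * f * (1 - f), f**2], axis=-1
        )  # (S, 3)
        post = L * prior[:, None, :]
        tot = post.sum(axis=-1, keepdims=True)
        tot[tot == 0] = 1.0
        post /= tot
        eg = post[..., 1] + 2 * post[..., 2]  # E[g] per individual
        with np.errstate(invalid="ignore", divide="ignore"):
            f_new = (eg * W).sum(axis=1) / (2.0 * n_eff)
        f_new = np.clip(np.where(active, f_new, np.nan), 0.0, 0.5)
        moved = np.nanmax(np.abs(np.where(active, f_new - f, 0.0))) if active.any() else 0.0
        f = np.where(active, f_new, np.nan)
        if moved < tol:
            break
    return float(f[0]) if single else f


def _site_loglik(L: np.ndarray, w: np.ndarray, prior: np.ndarray) -> np.ndarray:
    """Sum over individuals of log of the prior-weighted likelihood."""
    mix = (L * prior[..., None, :]).sum(axis=-1)
    mix = np.maximum(mix, 1e-300)
    return (np.log(mix) * w).sum(axis=-1)


def polymorphism_lrt(ll: np.ndarray, f: np.ndarray, has_data: np.ndarray) -> np.ndarray:
    """P-value of the likelihood-ratio test of ``f`` against ``f = 0``.

    The null distribution is chi-square with 1 df (no boundary halving),
    following common genotype-likelihood calling practice.
    """
    L = _norm_lik(np.asarray(ll, dtype=float))
    w = has_data.astype(float)
    f = np.asarray(f, dtype=float)
    fs = np.nan_to_num(f)
    prior1 = np.stack([(1 - fs) ** 2, 2 * fs * (1 - fs), fs**2], axis=-1)
    prior0 = np.zeros_like(prior1)
    prior0[..., 0] = 1.0
    lrt = 2.0 * (_site_loglik(L, w, prior1) - _site_loglik(L, w, prior0))
    p = stats.chi2.sf(np.maximum(lrt, 0.0), df=1)
    return np.where(np.isnan(f), np.nan, p)


def hwe_test(ll: np.ndarray, f: float, has_data: np.ndarray | None = None) -> float:
    """One-sided heterozygote-excess test at a single site.

    Genotype priors are parameterised by a per-site inbreeding-style
    coefficient ``F``: ``P(0) = (1-f)^2 + f(1-f)F``, ``P(1) = 2f(1-f)(1-F)``,
    ``P(2) = f^2 + f(1-f)F`` (clipped at zero and renormalised). ``F`` is
    fitted by maximum likelihood on [-1, 1]; the p-value is one-sided
    toward heterozygote excess (``F < 0``): 1 when ``F_hat >= 0``, else
    half the chi-square(1) tail of the LRT.
    """
    if not 0.0 < f <= 0.5:
        return 1.0
    L = _norm_lik(np.asarray(ll, dtype=float))  # (n, 3)
    if has_data is not None:
        L = L[np.asarray(has_data, dtype=bool)]
    if len(L) == 0:
        return 1.0

    def negll(F: float) -> float:
        p0 = (1 - f) ** 2 + f * (1 - f) * F
        p1 = 2 * f * (1 - f) * (1 - F)
        p2 = f**2 + f * (1 - f) * F
        pr = np.maximum(np.array([p0, p1, p2]), 0.0)
        pr = pr / pr.sum()
        mix = np.maximum(L @ pr, 1e-300)
        return -np.log(mix).sum()

    res = optimize.minimize_scalar(negll, bounds=(-1.0, 1.0), method="bounded",
                                   options={"xatol": 1e-6})
    f_hat = float(res.x)
    if f_hat >= 0.0:
        return 1.0
    lrt = 2.0 * (negll(0.0) - float(res.fun))
    if lrt <= 0:
        return 1.0
    return float(0.5 * stats.chi2.sf(lrt, df=1))


def call_snps(
    gl: GLMatrix,
    p_cut: float = 1e-6,
    maf_min: float = 0.05,
    min_ind: int | None = None,
    max_depth: int | None = None,
    hwe_cut: float = 0.01,
    profile: str | None = None,
) -> pd.DataFrame:
    """Call polymorphic sites and return the retained-site variant table.

    Columns: ``chrom, pos, major, minor, ref, alt, maf, n_ind, lrt_p,
    hwe_p, gl_index``. ``gl_index`` points back into the GLMatrix rows.
    """
    if profile is not None:
        prof = PROFILES[profile]
        min_ind = prof["min_ind"] if min_ind is None else min_ind
        max_depth = prof["max_depth"] if max_depth is None else max_depth
    if min_ind is None or max_depth is None:
        raise ValueError("min_ind and max_depth are required (or pass a profile)")
    if min_ind > gl.n_individuals:
        raise ValueError("min_ind exceeds the number of individuals")
    has_data = gl.has_data
    n_ind = has_data.sum(axis=1)
    site_depth = gl.depth.sum(axis=1)
    f = estimate_af_em(gl.ll, has_data)
    lrt_p = polymorphism_lrt(gl.ll, f, has_data)
    with np.errstate(invalid="ignore"):
        candidate = (
            (n_ind >= min_ind)
            & (site_depth <= max_depth)
            & (lrt_p < p_cut)
            & (f >= maf_min)
        )
    hwe_p = np.ones(gl.n_sites)
    for s in np.where(candidate)[0]:
        hwe_p[s] = hwe_test(gl.ll[s], float(f[s]), has_data[s])
    keep = candidate & (hwe_p >= hwe_cut)
    idx = np.where(keep)[0]
    return pd.DataFrame(
        {
            "chrom": gl.chrom,
            "pos": gl.positions[idx],
            "major": gl.major[idx],
            "minor": gl.minor[idx],
            "ref": gl.ref[idx],
            "alt": gl.alt[idx],
            "maf": f[idx],
            "n_ind": n_ind[idx],
            "lrt_p": lrt_p[idx],
            "hwe_p": hwe_p[idx],
            "gl_index": idx,
        }
    )


def call_genotypes(
    gl: GLMatrix, variants: pd.DataFrame, min_depth: int = 5
) -> np.ndarray:
    """Maximum-posterior genotypes (minor-allele counts) at called sites.

    Returns (n_variants, n_individuals) int8 with -1 for missing:
    individuals below ``min_depth`` reads at a site, or with flat
    likelihoods, are not called. The prior is HWE at the site's estimated
    minor-allele frequency.
    """
    idx = variants["gl_index"].to_numpy()
    f = variants["maf"].to_numpy()
    L = _norm_lik(gl.ll[idx])  # (V, n, 3)
    prior = np.stack([(1 - f) ** 2, 2 * f * (1 - f), f**2], axis=-1)
    post = L * prior[:, None, :]
    g = post.argmax(axis=-1).astype(np.int8)
    flat = np.ptp(gl.ll[idx], axis=-1) == 0
    low = gl.depth[idx] < min_depth
    g[flat | low] = -1
    return g


def alt_oriented(genotypes: np.ndarray, variants: pd.DataFrame) -> np.ndarray:
    """Convert minor-allele counts to alternate(derived)-allele counts."""
    g = np.asarray(genotypes).copy()
    flip = (variants["minor"] != variants["alt"]).to_numpy()
    sub = g[flip]
    sub[sub >= 0] = 2 - sub[sub >= 0]
    g[flip] = sub
    return g


def write_variant_vcf(path, gl: GLMatrix, variants: pd.DataFrame, genotypes: np.ndarray,
                      reference_length: int | None = None) -> None:
    """Write called sites as a VCF with GT and PL fields (ref/alt oriented)."""
    alt_gt = alt_oriented(genotypes, variants)
    idx = variants["gl_index"].to_numpy()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if reference_length:
            fh.write(f"##contig=<ID={gl.chrom},length={reference_length}>\n")
        fh.write('##INFO=<ID=MAF,Number=1,Type=Float,Description="Minor allele frequency">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred likelihoods">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in gl.sample_ids) + "\n")
        gt_str = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
        for r, (_, row) in enumerate(variants.iterrows()):
            s = idx[r]
            ll = gl.ll[s]
            flip = row["minor"] == row["ref"]
            entries = []
            for j in range(gl.n_individuals):
                tri = ll[j][::-1] if flip else ll[j]
                pl = np.round(-10 * (tri - tri.max()) / np.log(10)).astype(int)
                entries.append(f"{gt_str[int(alt_gt[r, j])]}:{pl[0]},{pl[1]},{pl[2]}")
            fh.write(
                f"{gl.chrom}\t{row['pos'] + 1}\t.\t{row['ref']}\t{row['alt']}\t.\tPASS\t"
                f"MAF={row['maf']:.6f}\tGT:PL\t" + "\t".join(entries) + "\n"
            )
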