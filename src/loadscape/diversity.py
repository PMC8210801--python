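"""Site-frequency-spectrum diversity, heterozygosity, mutation rate, and
effective population size.

Watterson's estimator converts the count of segregating sites ``S`` among
``n`` sampled chromosomes over ``L`` assayed base pairs into a per-site
diversity ``theta_W = S / (a_n L)`` with ``a_n = sum_{i=1}^{n-1} 1/i``.
Under neutrality ``theta_W`` estimates ``4 Ne mu``, so with an externally
calibrated per-site mutation rate the long-term effective population size
is ``Ne = theta_W / (4 mu)``. The mutation rate itself is taken from
interspecific divergence: the proportion of mismatching, unambiguously
aligned sites between two species divided by twice their divergence time
(per site per year).

Note the units: divergence-calibrated ``mu`` is per year while ``theta_W``
reflects per-generation mutation. ``ne_from_theta`` reproduces the
year-based arithmetic literally by default and exposes an optional
generations-per-year factor for a generation-time-aware estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SFSResult:
    """Folded site-frequency spectrum with site-bootstrap replicates."""

    folded: np.ndarray  # counts by minor-allele count, length n_chrom//2 + 1
    n_chrom: int
    L: int  # sites considered (including monomorphic bin 0)
    bootstraps: np.ndarray  # (n_boot, len(folded))

    @property
    def mean(self) -> np.ndarray:
        """Mean bootstrap spectrum (the downstream point estimate)."""
        return self.bootstraps.mean(axis=0)

    @property
    def segregating(self) -> int:
        return int(self.folded[1:].sum())

    def theta_w(self, L: int | None = None) -> float:
        return watterson_theta(self.segregating, self.n_chrom, L or self.L)


def harmonic(n: int, power: int = 1) -> float:
    """``sum_{i=1}^{n} 1/i^power``."""
    i = np.arange(1, n + 1, dtype=float)
    return float((1.0 / i**power).sum())


def minor_allele_counts(genotypes: np.ndarray) -> tuple[np.ndarray, int]:
    """Per-site folded (minor) allele counts from a genotype matrix.

    ``genotypes`` is (sites x individuals) derived- or minor-allele counts
    in {0, 1, 2}; sites with any missing (-1) individual are dropped
    (complete deletion), keeping the sample size constant across sites.
    """
    g = np.asarray(genotypes)
    complete = (g >= 0).all(axis=1)
    g = g[complete]
    n_chrom = 2 * g.shape[1]
    ac = g.sum(axis=1)
    return np.minimum(ac, n_chrom - ac), n_chrom


def _sfs_result(mac: np.ndarray, n_chrom: int, total_sites: int | None,
                n_boot: int, seed: int) -> SFSResult:
    k = n_chrom // 2 + 1
    folded = np.bincount(mac, minlength=k).astype(float)
    L = int(total_sites) if total_sites is not None else len(mac)
    if L < len(mac):
        raise ValueError("total_sites smaller than the number of variant sites")
    folded[0] += L - len(mac)  # monomorphic remainder of the assayed length
    rng = np.random.default_rng(seed)
    if n_boot and L:
        # resampling L sites with replacement == a multinomial draw over the
        # observed spectrum, which avoids materialising invariant columns
        boots = rng.multinomial(L, folded / L, size=n_boot).astype(float)
    else:
        boots = np.zeros((n_boot, k))
    return SFSResult(folded=folded, n_chrom=n_chrom, L=L, bootstraps=boots)


def folded_sfs(
    genotypes: np.ndarray,
    n_boot: int = 100,
    seed: int = 0,
    total_sites: int | None = None,
) -> SFSResult:
    """Folded SFS of a genotype matrix with site-resampling bootstraps.

    The spectrum is a histogram of minor-allele counts; bin 0 holds
    monomorphic sites, including the ``total_sites - n_variant`` assayed
    sites absent from a variants-only matrix when ``total_sites`` is given
    (bootstrap variance of S is understated otherwise). 100 bootstrap
    replicates resample sites with replacement; their mean is the
    downstream point spectrum.
    """
    g = np.asarray(genotypes)
    if g.shape[1] < 2:
        raise ValueError("need at least two individuals")
    mac, n_chrom = minor_allele_counts(g)
    return _sfs_result(mac, n_chrom, total_sites, n_boot, seed)


def folded_sfs_from_haplotypes(
    hap: np.ndarray, n_boot: int = 100, seed: int = 0, total_sites: int | None = None
) -> SFSResult:
    """Folded SFS directly from a (n_chrom x sites) 0/1 haplotype matrix."""
    h = np.asarray(hap)
    n_chrom = h.shape[0]
    if n_chrom < 4:
        raise ValueError("need at least two diploid individuals (4 chromosomes)")
    ac = h.sum(axis=0)
    mac = np.minimum(ac, n_chrom - ac)
    return _sfs_result(mac, n_chrom, total_sites, n_boot, seed)


def expected_neutral_folded_sfs(n_chrom: int) -> np.ndarray:
    """Normalised neutral expectation for folded bins 1..floor(n/2).

    Proportional to ``(1/i + 1/(n-i)) / (1 + delta_{i, n-i})``.
    """
    n = n_chrom
    ks = np.arange(1, n // 2 + 1)
    w = (1.0 / ks + 1.0 / (n - ks)) / (1.0 + (ks == n - ks))
    return w / w.sum()


def watterson_theta(S: int, n_chrom: int, L: float) -> float:
    """Per-site Watterson's theta, ``S / (a_n L)``."""
    if n_chrom < 2:
        raise ValueError("need at least two chromosomes")
    if L <= 0:
        raise ValueError("L must be positive")
    return S / (harmonic(n_chrom - 1) * L)


def theta_w_bootstrap(sfs: SFSResult, L: float | None = None) -> tuple[float, float]:
    """(theta_W from the mean bootstrap spectrum, bootstrap SE of theta_W)."""
    L = L or sfs.L
    reps = sfs.bootstraps[:, 1:].sum(axis=1) / (harmonic(sfs.n_chrom - 1) * L)
    return float(reps.mean()), float(reps.std(ddof=1))


def heterozygosity_per_individual(
    genotypes: np.ndarray, total_sites: float | None = None
) -> np.ndarray:
    """Proportion of heterozygous sites per individual.

    Denominator: that individual's genotyped site count, or ``total_sites``
    when the matrix holds only variant sites out of a larger assayed length
    (invariant sites are never heterozygous, so only the denominator
    changes).
    """
    g = np.asarray(genotypes)
    het = (g == 1).sum(axis=0).astype(float)
    if total_sites is not None:
        return het / float(total_sites)
    n_called = (g >= 0).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_called > 0, het / n_called, np.nan)


def mutation_rate_from_divergence(seq_a: str, seq_b: str, t_div: float) -> float:
    """Per-site per-year mutation rate from a pairwise species alignment.

    Columns where either sequence is N/n or a gap are excluded from both
    numerator and denominator; ``mu = (mismatches / valid_length) / (2 t)``.
    """
    if t_div <= 0:
        raise ValueError("t_div must be positive")
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    a = np.frombuffer(seq_a.upper().encode(), dtype="S1")
    b = np.frombuffer(seq_b.upper().encode(), dtype="S1")
    bad = (a == b"N") | (b == b"N") | (a == b"-") | (b == b"-")
    valid = ~bad
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("no unambiguous aligned sites")
    mism = int((a[valid] != b[valid]).sum())
    return (mism / n_valid) / (2.0 * t_div)


def ne_from_theta(
    theta_w: float,
    mu: float,
    theta_se: float | None = None,
    generations_per_year: float = 1.0,
) -> tuple[float, tuple[float, float] | None]:
    """Effective population size ``Ne = theta_W / (4 mu)``.

    ``mu`` is per site per year; the default ``generations_per_year = 1``
    reproduces the literal year-based arithmetic. A 95% CI is propagated
    from the standard error of ``theta_W`` when given.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    scale = 4.0 * mu / generations_per_year
    ne = theta_w / scale
    ci = None
    if theta_se is not None:
        ci = ((theta_w - 1.96 * theta_se) / scale, (theta_w + 1.96 * theta_se) / scale)
    return ne, ci
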