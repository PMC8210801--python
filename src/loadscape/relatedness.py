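"""Pairwise kinship from identity-by-state patterns, individual inbreeding
coefficients, and covariance PCA.

Kinship uses only the joint-genotype counts of a pair — no allele
frequencies — making it robust to population structure. With
``N(g_i, g_j)`` the number of overlapping sites where the pair carries
``g_i`` and ``g_j`` copies of the minor allele:

* KING-robust kinship ``= (N(1,1) - 2[N(0,2) + N(2,0)]) / (N_het_i + N_het_j)``
* ``R0 = [N(0,2) + N(2,0)] / N(1,1)`` (opposing homozygotes per shared het)
* ``R1 = N(1,1) / (discordant + het categories)``

Relationship degrees are assigned with the standard powers-of-two kinship
bins (cutoffs ``2^-1.5``, ``2^-2.5``, ``2^-3.5``, ``2^-4.5``). Pairs whose
overlapping-site count falls below 100,000 are flagged and excluded from
population summaries, since short overlaps make the ratios unstable.

The individual inbreeding coefficient ``F`` is fitted by maximum likelihood
from genotype likelihoods against population allele frequencies, with
genotype priors ``P(0) = (1-f)^2 + f(1-f)F``, ``P(1) = 2f(1-f)(1-F)``,
``P(2) = f^2 + f(1-f)F`` clipped at zero; ``F`` ranges over [-1, 1], where
negative values indicate heterozygote excess.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

MIN_PAIR_SITES = 100_000

#: kinship cutoffs for degree bins: self/identical, 1st, 2nd, 3rd, unrelated
DEGREE_CUTOFFS = (2**-1.5, 2**-2.5, 2**-3.5, 2**-4.5)
DEGREE_NAMES = ("identical/self", "1st", "2nd", "3rd", "unrelated")


@dataclass
class KinshipResult:
    id_a: str
    id_b: str
    n_sites_compared: int
    joint_counts: np.ndarray  # (3, 3) N(g_a, g_b)
    r0: float
    r1: float
    king: float
    degree: str
    filtered: bool  # overlap below MIN_PAIR_SITES


@dataclass
class InbreedingResult:
    individual: str
    F: float
    n_sites: int
    converged: bool


def classify_degree(kinship: float) -> str:
    """Relationship degree from a kinship coefficient."""
    if not np.isfinite(kinship):
        raise ValueError("kinship must be finite")
    for cut, name in zip(DEGREE_CUTOFFS, DEGREE_NAMES):
        if kinship > cut:
            return name
    return DEGREE_NAMES[-1]


def pair_ibs_stats(
    g_a: np.ndarray,
    g_b: np.ndarray,
    id_a: str = "a",
    id_b: str = "b",
    min_sites: int = MIN_PAIR_SITES,
) -> KinshipResult:
    """Joint-genotype IBS statistics for one pair.

    ``g_a``/``g_b`` are per-site minor-allele counts with -1 for missing;
    only sites genotyped in both individuals are compared.
    """
    a = np.asarray(g_a)
    b = np.asarray(g_b)
    ok = (a >= 0) & (b >= 0)
    if not ok.any():
        raise ValueError("no overlapping genotyped sites")
    a = a[ok]
    b = b[ok]
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (a, b), 1)
    n11 = counts[1, 1]
    opp = counts[0, 2] + counts[2, 0]
    het_a = counts[1, :].sum()
    het_b = counts[:, 1].sum()
    denom = het_a + het_b
    king = (n11 - 2.0 * opp) / denom if denom else np.nan
    r0 = opp / n11 if n11 else np.nan
    r1_den = counts[0, 1] + counts[1, 0] + counts[1, 2] + counts[2, 1] + opp + n11
    r1 = n11 / r1_den if r1_den else np.nan
    degree = classify_degree(king) if np.isfinite(king) else "undefined"
    return KinshipResult(
        id_a=id_a,
        id_b=id_b,
        n_sites_compared=int(ok.sum()),
        joint_counts=counts,
        r0=float(r0),
        r1=float(r1),
        king=float(king),
        degree=degree,
        filtered=int(ok.sum()) < min_sites,
    )


def kinship_table(
    genotypes: np.ndarray,
    sample_ids: list[str],
    min_sites: int = MIN_PAIR_SITES,
) -> pd.DataFrame:
    """All-pairs kinship table from a (sites x individuals) genotype matrix."""
    n = genotypes.shape[1]
    rows = []
    for i, j in itertools.combinations(range(n), 2):
        try:
            res = pair_ibs_stats(
                genotypes[:, i], genotypes[:, j], sample_ids[i], sample_ids[j], min_sites
            )
        except ValueError:  # no overlapping genotyped sites
            res = KinshipResult(
                id_a=sample_ids[i], id_b=sample_ids[j], n_sites_compared=0,
                joint_counts=np.zeros((3, 3), dtype=np.int64), r0=np.nan,
                r1=np.nan, king=np.nan, degree="undefined", filtered=True,
            )
        rows.append(
            {
                "id_a": res.id_a,
                "id_b": res.id_b,
                "n_sites": res.n_sites_compared,
                "r0": res.r0,
                "r1": res.r1,
                "king": res.king,
                "degree": res.degree,
                "filtered": res.filtered,
            }
        )
    return pd.DataFrame(rows)


F_TOL = 1e-9
F_MAX_ITER = 5000


def _f_priors(f: np.ndarray, F: float) -> np.ndarray:
    p0 = (1 - f) ** 2 + f * (1 - f) * F
    p1 = 2 * f * (1 - f) * (1 - F)
    p2 = f**2 + f * (1 - f) * F
    pr = np.maximum(np.stack([p0, p1, p2], axis=-1), 0.0)
    return pr / pr.sum(axis=-1, keepdims=True)


def individual_F(
    ll: np.ndarray,
    freqs: np.ndarray,
    individual: str = "ind",
    min_sites: int = 100,
    tol: float = F_TOL,
    max_iter: int = F_MAX_ITER,
) -> InbreedingResult:
    """ML inbreeding coefficient for one individual.

    ``ll`` is (sites x 3) natural-log genotype likelihoods in minor-allele
    orientation; ``freqs`` the matching minor-allele frequencies. Sites
    with flat likelihoods (no data) or non-polymorphic frequencies are
    ignored. The likelihood is maximised over F in [-1, 1] by bounded
    scalar optimisation to tolerance 1e-9.
    """
    ll = np.asarray(ll, dtype=float)
    f = np.asarray(freqs, dtype=float)
    use = (f > 0) & (f < 1) & (np.ptp(ll, axis=-1) > 0)
    ll = ll[use]
    f = f[use]
    if len(f) < min_sites:
        raise ValueError(f"need at least {min_sites} polymorphic sites with data")
    L = np.exp(ll - ll.max(axis=-1, keepdims=True))

    def negll(F: float) -> float:
        mix = np.maximum((L * _f_priors(f, F)).sum(axis=-1), 1e-300)
        return -np.log(mix).sum()

    res = optimize.minimize_scalar(
        negll, bounds=(-1.0, 1.0), method="bounded",
        options={"xatol": tol, "maxiter": max_iter},
    )
    return InbreedingResult(
        individual=individual,
        F=float(np.clip(res.x, -1.0, 1.0)),
        n_sites=int(len(f)),
        converged=bool(res.success),
    )


def inbreeding_table(
    ll: np.ndarray, freqs: np.ndarray, sample_ids: list[str], min_sites: int = 100
) -> pd.DataFrame:
    """Per-individual F from a (sites x individuals x 3) GL array."""
    rows = []
    for j, sid in enumerate(sample_ids):
        res = individual_F(ll[:, j, :], freqs, sid, min_sites=min_sites)
        rows.append({"individual": sid, "F": res.F, "n_sites": res.n_sites,
                     "converged": res.converged})
    return pd.DataFrame(rows)


def covariance_pca(
    genotypes: np.ndarray, freqs: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of the standardized genotype covariance matrix.

    Genotypes (sites x individuals, minor-allele counts, -1 missing) are
    standardized per site as ``(g - 2f) / sqrt(2f(1-f))``; missing entries
    are mean-imputed (zero after centring). Returns (eigenvalues
    descending, eigenvectors as columns, PC scores per individual).
    """
    g = np.asarray(genotypes, dtype=float)
    if g.shape[0] < 2 or g.shape[1] < 2:
        raise ValueError("need at least two sites and two individuals")
    miss = g < 0
    g[miss] = np.nan
    if freqs is None:
        n_called = (~miss).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs = np.where(n_called > 0, np.nansum(g, axis=1), np.nan) / (
                2.0 * np.maximum(n_called, 1)
            )
    f = np.asarray(freqs, dtype=float)
    poly = (f > 0) & (f < 1) & ~np.isnan(f)
    if not poly.any():
        raise ValueError("no polymorphic sites")
    g = g[poly]
    f = f[poly]
    z = (g - 2 * f[:, None]) / np.sqrt(2 * f * (1 - f))[:, None]
    z[np.isnan(z)] = 0.0
    cov = z.T @ z / z.shape[0]
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    scores = vecs * np.sqrt(np.maximum(vals, 0.0))
    return vals, vecs, scores
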