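"""Alignment-based diversity statistics for small multi-sequence datasets
(e.g. mitogenome panels): haplotype counts, haplotype diversity, per-site
nucleotide diversity, Kimura 2-parameter distances, and a subsampling
permutation comparison between populations of unequal size.

Columns containing a gap or an ambiguous base (N) in any sequence are
masked out of every statistic (complete deletion) by default; pairwise
deletion is available for K2P distances.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

_PURINES = frozenset({b"A", b"G"})
_PYRIMIDINES = frozenset({b"C", b"T"})


@dataclass
class AlignmentSet:
    """Equal-length sequences with ids and population labels."""

    ids: list[str]
    pops: np.ndarray
    seqs: np.ndarray  # (n, L) bytes ('S1')

    def __post_init__(self) -> None:
        self.seqs = np.asarray(self.seqs, dtype="S1")
        self.pops = np.asarray(self.pops)
        if self.seqs.ndim != 2:
            raise ValueError("alignment must be a 2-D character matrix")
        if len(self.ids) != self.seqs.shape[0] or len(self.pops) != self.seqs.shape[0]:
            raise ValueError("ids/pops length must match the number of sequences")

    @classmethod
    def from_strings(cls, seqs: list[str], ids=None, pops=None) -> "AlignmentSet":
        if len({len(s) for s in seqs}) > 1:
            raise ValueError("sequences must have equal length")
        mat = np.array([list(s.upper()) for s in seqs], dtype="S1")
        ids = ids or [f"seq{i}" for i in range(len(seqs))]
        pops = np.asarray(pops if pops is not None else ["pop0"] * len(seqs))
        return cls(ids=list(ids), pops=pops, seqs=mat)

    @classmethod
    def from_fasta(cls, path, pops: dict[str, str] | None = None) -> "AlignmentSet":
        from Bio import SeqIO

        ids, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            seqs.append(str(rec.seq))
        labels = [pops.get(i, "pop0") if pops else "pop0" for i in ids]
        return cls.from_strings(seqs, ids=ids, pops=labels)

    @property
    def mask(self) -> np.ndarray:
        """Columns with no gap and no ambiguous base in any sequence."""
        bad = (self.seqs == b"-") | (self.seqs == b"N") | (self.seqs == b"n")
        return ~bad.any(axis=0)

    def masked(self) -> np.ndarray:
        return self.seqs[:, self.mask]

    def subset(self, idx) -> "AlignmentSet":
        idx = np.asarray(idx)
        return AlignmentSet(
            ids=[self.ids[i] for i in idx], pops=self.pops[idx], seqs=self.seqs[idx]
        )

    def trim_ends(self, n: int = 40) -> "AlignmentSet":
        """Drop ``n`` columns from each end (circular-assembly edge control)."""
        return AlignmentSet(ids=list(self.ids), pops=self.pops.copy(),
                            seqs=self.seqs[:, n : self.seqs.shape[1] - n])


@dataclass
class SeqDivStats:
    n_haplotypes: int
    hd: float
    pi: float
    k2p: np.ndarray  # pairwise matrix
    n_parsimony_informative: int


def haplotype_stats(aln: AlignmentSet) -> tuple[int, float, int]:
    """(unique haplotypes, haplotype diversity, parsimony-informative sites).

    Haplotypes are unique sequences over the masked columns;
    ``Hd = n (1 - sum p_h^2) / (n - 1)``. A parsimony-informative column
    has at least two alleles each carried by at least two sequences.
    """
    m = aln.masked()
    n = m.shape[0]
    if n < 2:
        raise ValueError("need at least two sequences")
    _, counts = np.unique(
        np.ascontiguousarray(m).view(f"S{max(m.shape[1], 1)}").ravel(), return_counts=True
    )
    p = counts / n
    hd = n * (1.0 - (p**2).sum()) / (n - 1.0)
    n_pi = 0
    for col in range(m.shape[1]):
        _, c = np.unique(m[:, col], return_counts=True)
        if (c >= 2).sum() >= 2:
            n_pi += 1
    return int(len(counts)), float(hd), n_pi


def nucleotide_diversity(aln: AlignmentSet) -> float:
    """Mean pairwise differences per masked site over all sequence pairs."""
    m = aln.masked()
    n, L = m.shape
    if n < 2:
        raise ValueError("need at least two sequences")
    if L == 0:
        return 0.0
    total = 0
    for i, j in itertools.combinations(range(n), 2):
        total += int((m[i] != m[j]).sum())
    n_pairs = n * (n - 1) // 2
    return total / (n_pairs * L)


def k2p_distance(seq_a, seq_b, mask: np.ndarray | None = None) -> float:
    """Kimura 2-parameter distance between two aligned sequences.

    ``d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)`` with P and Q the
    transition and transversion proportions over valid (non-gap, non-N)
    columns. Saturated pairs (non-positive log argument) return NaN with a
    warning.
    """
    a = np.asarray(
        list(seq_a.upper()) if isinstance(seq_a, str) else seq_a, dtype="S1"
    )
    b = np.asarray(
        list(seq_b.upper()) if isinstance(seq_b, str) else seq_b, dtype="S1"
    )
    if a.shape != b.shape:
        raise ValueError("sequences must have equal length")
    valid = ~((a == b"-") | (b == b"-") | (a == b"N") | (b == b"N"))
    if mask is not None:
        valid &= mask
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no valid aligned sites")
    av, bv = a[valid], b[valid]
    diff = av != bv
    is_transition = np.array(
        [
            (x in _PURINES and y in _PURINES) or (x in _PYRIMIDINES and y in _PYRIMIDINES)
            for x, y in zip(av[diff], bv[diff])
        ],
        dtype=bool,
    )
    P = is_transition.sum() / n
    Q = (diff.sum() - is_transition.sum()) / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        warnings.warn("K2P saturation: log argument <= 0", stacklevel=2)
        return np.nan
    return float(-0.5 * np.log(w1) - 0.25 * np.log(w2))


def k2p_matrix(aln: AlignmentSet, pairwise_deletion: bool = False) -> np.ndarray:
    """Symmetric K2P matrix; listwise column mask by default."""
    n = aln.seqs.shape[0]
    mask = None if pairwise_deletion else aln.mask
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = k2p_distance(aln.seqs[i], aln.seqs[j], mask)
    return d


def seqdiv_stats(aln: AlignmentSet) -> SeqDivStats:
    n_h, hd, n_pi = haplotype_stats(aln)
    return SeqDivStats(
        n_haplotypes=n_h,
        hd=hd,
        pi=nucleotide_diversity(aln),
        k2p=k2p_matrix(aln),
        n_parsimony_informative=n_pi,
    )


_STATS = {
    "pi": nucleotide_diversity,
    "hd": lambda a: haplotype_stats(a)[1],
    "k2p_mean": lambda a: float(np.nanmean(k2p_matrix(a)[np.triu_indices(len(a.ids), 1)])),
}


def subsample_compare(
    aln: AlignmentSet,
    pop_a: str,
    pop_b: str,
    n_sub: int = 7,
    n_perm: int = 100,
    statistic="pi",
    seed: int = 0,
) -> dict:
    """Equal-size subsampling comparison of a statistic between populations.

    Each permutation draws ``n_sub`` sequences per population without
    replacement and recomputes the statistic. The empirical two-sided
    p-value is twice the smaller of the fractions of permutations with a
    non-negative / non-positive between-population difference (capped at
    1), so identical populations give p near 1. A Welch t-test on the two
    permutation distributions is reported as a labelled secondary output.
    """
    from .loadcalc import welch_t

    stat = _STATS[statistic] if isinstance(statistic, str) else statistic
    rng = np.random.default_rng(seed)
    idx_a = np.where(aln.pops == pop_a)[0]
    idx_b = np.where(aln.pops == pop_b)[0]
    if len(idx_a) < n_sub or len(idx_b) < n_sub:
        raise ValueError("population smaller than the subsample size")
    stats_a = np.empty(n_perm)
    stats_b = np.empty(n_perm)
    for p in range(n_perm):
        sa = aln.subset(rng.choice(idx_a, n_sub, replace=False))
        sb = aln.subset(rng.choice(idx_b, n_sub, replace=False))
        stats_a[p] = stat(sa)
        stats_b[p] = stat(sb)
    diff = stats_a - stats_b
    p_emp = min(1.0, 2.0 * min((diff >= 0).mean(), (diff <= 0).mean()))
    try:
        t, df, p_welch = welch_t(stats_a, stats_b)
    except ValueError:
        t = df = p_welch = np.nan
    return {
        "stat_a": stats_a,
        "stat_b": stats_b,
        "mean_diff": float(diff.mean()),
        "p_empirical": float(p_emp),
        "welch_secondary": {"t": t, "df": df, "p": p_welch},
    }
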