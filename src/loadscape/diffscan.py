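"""Windowed differentiation (Fst), absolute divergence (Dxy), Z-score
outlier scans, and Fu & Li's neutrality statistics.

Fst uses the Hudson estimator with small-sample correction, combined as a
ratio of sums within each window: per site,

    N = (p1 - p2)^2 - p1(1 - p1)/(n1 - 1) - p2(1 - p2)/(n2 - 1)
    D = p1(1 - p2) + p2(1 - p1)

and the window (or global) estimate is ``sum N / sum D``. Negative window
values are retained (clipping would distort the null standard deviation of
the outlier scan). Windows are 100 kb wide with a 50 kb step by default;
the Z-transform is taken over windows with at least a floor of usable
sites, and outliers are windows with ``|Z| > 5``.

Dxy at a site is ``p1(1 - p2) + p2(1 - p1)``; a window's value is the sum
over variant sites divided by the window length in bp, so sites fixed in
one population still contribute.

Fu & Li's D and F contrast the number of derived singletons (which require
ancestral polarization) against total polymorphism and pairwise diversity;
under neutral equilibrium both are near zero, population expansion drives
them negative (excess of new rare variants) and a bottleneck positive
(deficit of rare variants).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import harmonic

WINDOW = 100_000
STEP = 50_000
Z_CUT = 5.0
MIN_WINDOW_SITES = 10


def make_windows(L: int, window: int = WINDOW, step: int = STEP) -> np.ndarray:
    """0-based half-open sliding windows covering [0, L)."""
    starts = np.arange(0, max(L - window, 0) + step, step)
    if len(starts) == 0:
        starts = np.array([0])
    return np.column_stack([starts, np.minimum(starts + window, L)])


def hudson_fst_components(p1, p2, n1, n2):
    """Per-site numerator and denominator of the Hudson estimator."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if (n1 < 2).any() or (n2 < 2).any():
        raise ValueError("need >= 2 chromosomes with data per population")
    num = (
        (p1 - p2) ** 2
        - p1 * (1 - p1) / (n1 - 1)
        - p2 * (1 - p2) / (n2 - 1)
    )
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def fst_window(
    positions: np.ndarray,
    p1: np.ndarray,
    p2: np.ndarray,
    n1,
    n2,
    L: int,
    window: int = WINDOW,
    step: int = STEP,
) -> tuple[pd.DataFrame, float]:
    """Sliding-window and global Hudson Fst as ratios of sums.

    ``n1``/``n2`` are per-site haploid sample sizes (scalars broadcast).
    Windows without usable sites get NaN. Returns (window table, global).
    """
    pos = np.asarray(positions)
    num, den = hudson_fst_components(p1, p2, np.broadcast_to(n1, pos.shape),
                                     np.broadcast_to(n2, pos.shape))
    wins = make_windows(L, window, step)
    rows = []
    for s, e in wins:
        m = (pos >= s) & (pos < e)
        d = den[m].sum()
        rows.append(
            {
                "start": s,
                "end": e,
                "n_sites": int(m.sum()),
                "fst": num[m].sum() / d if d > 0 else np.nan,
            }
        )
    g_den = den.sum()
    global_fst = float(num.sum() / g_den) if g_den > 0 else np.nan
    return pd.DataFrame(rows), global_fst


def global_fst_bootstrap(
    p1, p2, n1, n2, n_boot: int = 100, seed: int = 0
) -> tuple[float, tuple[float, float]]:
    """Global Hudson Fst with a site-bootstrap 95% CI."""
    p1 = np.asarray(p1, dtype=float)
    num, den = hudson_fst_components(p1, p2, np.broadcast_to(n1, p1.shape),
                                     np.broadcast_to(n2, p1.shape))
    point = float(num.sum() / den.sum())
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    S = len(num)
    for b in range(n_boot):
        idx = rng.integers(0, S, size=S)
        reps[b] = num[idx].sum() / max(den[idx].sum(), 1e-300)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return point, (float(lo), float(hi))


def z_fst_outliers(
    fst: np.ndarray,
    n_sites: np.ndarray | None = None,
    min_sites: int = MIN_WINDOW_SITES,
    z_cut: float = Z_CUT,
) -> tuple[np.ndarray, np.ndarray]:
    """Z-transform window Fst and flag outliers beyond ``z_cut`` SDs.

    Windows with fewer than ``min_sites`` usable sites are excluded before
    standardization (they produce spuriously extreme values) and can never
    be outliers. Returns (z array with NaN for excluded, outlier mask).
    """
    fst = np.asarray(fst, dtype=float)
    use = np.isfinite(fst)
    if n_sites is not None:
        use &= np.asarray(n_sites) >= min_sites
    if use.sum() < 2:
        raise ValueError("need at least two usable windows")
    mean = fst[use].mean()
    sd = fst[use].std(ddof=0)
    z = np.full_like(fst, np.nan)
    if sd == 0:
        z[use] = 0.0
    else:
        z[use] = (fst[use] - mean) / sd
    outliers = np.zeros(len(fst), dtype=bool)
    outliers[use] = np.abs(z[use]) > z_cut
    return z, outliers


def dxy_window(
    positions: np.ndarray,
    p1: np.ndarray,
    p2: np.ndarray,
    L: int,
    window: int = WINDOW,
    step: int = STEP,
) -> pd.DataFrame:
    """Per-window nucleotide divergence: sum of per-site dxy over window bp."""
    pos = np.asarray(positions)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    d = p1 * (1 - p2) + p2 * (1 - p1)
    rows = []
    for s, e in make_windows(L, window, step):
        m = (pos >= s) & (pos < e)
        rows.append(
            {"start": s, "end": e, "n_sites": int(m.sum()), "dxy": d[m].sum() / (e - s)}
        )
    return pd.DataFrame(rows)


def dxy_site(p1, p2):
    """Per-site Dxy, ``p1(1-p2) + p2(1-p1)``."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    return p1 * (1 - p2) + p2 * (1 - p1)


# ---------------------------------------------------------------------------
# Fu & Li's D and F
# ---------------------------------------------------------------------------


@dataclass
class _FuLiCoeffs:
    a_n: float
    u_d: float
    v_d: float
    u_f: float
    v_f: float


def _fu_li_coeffs(n: int) -> _FuLiCoeffs:
    if n < 3:
        raise ValueError("need at least three chromosomes")
    a_n = harmonic(n - 1)
    b_n = harmonic(n - 1, power=2)
    a_n1 = a_n + 1.0 / n  # a_{n+1}
    c_n = 1.0 if n == 2 else 2.0 * (n * a_n - 2.0 * (n - 1)) / ((n - 1) * (n - 2))
    v_d = 1.0 + a_n**2 / (b_n + a_n**2) * (c_n - (n + 1.0) / (n - 1.0))
    u_d = a_n - 1.0 - v_d
    v_f = (c_n + 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0)) - 2.0 / (n - 1.0)) / (
        a_n**2 + b_n
    )
    u_f = (
        1.0
        + (n + 1.0) / (3.0 * (n - 1.0))
        - 4.0 * (n + 1.0) / (n - 1.0) ** 2 * (a_n1 - 2.0 * n / (n + 1.0))
    ) / a_n - v_f
    return _FuLiCoeffs(a_n=a_n, u_d=u_d, v_d=v_d, u_f=u_f, v_f=v_f)


def fu_li_stats(derived_counts: np.ndarray, n_chrom: int) -> tuple[float, float]:
    """Fu & Li's D and F from polarized derived-allele counts in one window.

    ``derived_counts`` holds, per segregating site, the number of sampled
    chromosomes carrying the derived allele (in [1, n-1]; unpolarizable
    sites must be excluded beforehand). Returns (D, F); both are NaN when
    the window has no segregating site.
    """
    dc = np.asarray(derived_counts)
    dc = dc[(dc >= 1) & (dc <= n_chrom - 1)]
    eta = len(dc)
    if eta == 0:
        return np.nan, np.nan
    co = _fu_li_coeffs(n_chrom)
    eta_s = int((dc == 1).sum())
    n = n_chrom
    pi = float((2.0 * dc * (n - dc) / (n * (n - 1.0))).sum())
    var_d = co.u_d * eta + co.v_d * eta**2
    var_f = co.u_f * eta + co.v_f * eta**2
    d = (eta - co.a_n * eta_s) / np.sqrt(var_d) if var_d > 0 else np.nan
    f = (pi - eta_s) / np.sqrt(var_f) if var_f > 0 else np.nan
    return float(d), float(f)


def fu_li_windows(
    positions: np.ndarray,
    derived_counts: np.ndarray,
    n_chrom: int,
    L: int,
    window: int = WINDOW,
    step: int = STEP,
) -> pd.DataFrame:
    """Sliding-window Fu & Li's D and F along a chromosome."""
    pos = np.asarray(positions)
    dc = np.asarray(derived_counts)
    rows = []
    for s, e in make_windows(L, window, step):
        m = (pos >= s) & (pos < e)
        d, f = fu_li_stats(dc[m], n_chrom)
        rows.append(
            {"start": s, "end": e, "n_sites": int(m.sum()), "fu_li_d": d, "fu_li_f": f}
        )
    return pd.DataFrame(rows)


def scan_windows(
    positions,
    p1,
    p2,
    n1,
    n2,
    L,
    derived_counts_1=None,
    derived_counts_2=None,
    window: int = WINDOW,
    step: int = STEP,
    z_cut: float = Z_CUT,
    min_sites: int = MIN_WINDOW_SITES,
) -> pd.DataFrame:
    """Combined window table: Fst, Z(Fst), outlier flag, and Dxy."""
    fst_tab, _ = fst_window(positions, p1, p2, n1, n2, L, window, step)
    z, out = z_fst_outliers(fst_tab["fst"].to_numpy(), fst_tab["n_sites"].to_numpy(),
                            min_sites, z_cut)
    tab = fst_tab.copy()
    tab["z_fst"] = z
    tab["outlier"] = out
    tab["dxy"] = dxy_window(positions, p1, p2, L, window, step)["dxy"]
    return tab
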