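"""End-to-end orchestration: simulate, call, estimate, scan, and summarise.

``run_all`` executes the full analysis on a simulated scenario and returns
a structured report (JSON-serialisable) with per-population diversity,
kinship, inbreeding, PCA, differentiation-scan, neutrality, load, and
alignment-statistics sections. Every number in the report is produced by a
named module operation; the pipeline only routes data.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import diffscan, diversity, genolik, loadcalc, relatedness, seqdiv, simdata


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Scenario plus analysis parameters for a full pipeline run."""

    sim: simdata.SimulationConfig = field(default_factory=simdata.SimulationConfig)
    profile: str = "genomic"  # filter profile for SNP calling
    min_ind: int | None = None  # override the profile's individual floor
    max_depth: int | None = None
    min_genotype_depth: int = 5
    window: int = diffscan.WINDOW
    step: int = diffscan.STEP
    z_cut: float = diffscan.Z_CUT
    min_window_sites: int = diffscan.MIN_WINDOW_SITES
    load_mode: str = "hom"
    flank: int = 5000
    # desk-scale overlap floor; the relatedness module default (100,000)
    # reflects genome-scale data and would filter every desk-scale pair
    kinship_min_sites: int = 200
    # depth floor for the genotypes entering kinship only: at ~2x coverage a
    # >=5-read requirement leaves pairs with no overlapping calls
    kinship_min_depth: int = 2
    alignment_segment: int = 5000  # bp of haplotype sequence for seqdiv
    subsample_n: int = 7
    subsample_perms: int = 100

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", {})
        sim = simdata.config_from_dict({**simdata._config_to_dict(simdata.SimulationConfig()),
                                        **sim_raw})
        return cls(sim=sim, **raw)

    def to_yaml(self, path) -> None:
        import yaml

        d = asdict(self)
        d["sim"] = simdata._config_to_dict(self.sim)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def n_pairs(N: int) -> int:
    """Number of unordered individual pairs, ``N (N - 1) / 2``."""
    if N < 2:
        raise ValueError("need at least two individuals")
    return N * (N - 1) // 2


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-tag with the stage name
                raise PipelineError(name, str(exc)) from exc

        return wrapped

    return deco


def run_all(config: PipelineConfig, outdir=None) -> dict:
    """Run every stage on one simulated scenario; returns the report dict."""
    report: dict = {"stages": {}}
    t0 = time.perf_counter()

    def tick(name):
        report["stages"][name] = round(time.perf_counter() - t0, 3)

    truth, pileup = _simulate(config)
    tick("simulate")
    gl, variants, called = _call(config, pileup)
    tick("call")
    report["n_individuals"] = truth.n_individuals
    report["n_pairs"] = n_pairs(truth.n_individuals)
    report["n_called_snps"] = int(len(variants))
    report["diversity"] = _diversity(config, truth, gl)
    tick("diversity")
    report["relatedness"] = _relatedness(config, truth, gl, variants, called)
    tick("relatedness")
    report["scan"] = _scan(config, truth)
    tick("scan")
    report["load"] = _load(config, truth)
    tick("load")
    report["seqdiv"] = _seqdiv(config, truth)
    tick("seqdiv")
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        simdata.write_truth_bundle(truth, config.sim, out / "bundle", pileup)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=_jsonable)
        with open(out / "report.txt", "w") as fh:
            fh.write(_render_report(report))
    return report


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serialisable: {type(x)}")


def _render_report(report: dict) -> str:
    lines = ["loadscape pipeline report", "=" * 30]
    for key, val in report.items():
        lines.append(f"{key}: {json.dumps(val, indent=1, default=_jsonable)[:2000]}")
    return "\n".join(lines) + "\n"


@_stage("simulate")
def _simulate(config):
    truth = simdata.simulate_populations(config.sim)
    pileup = simdata.simulate_pileups(truth, config.sim)
    return truth, pileup


@_stage("call")
def _call(config, pileup):
    gl = genolik.glmatrix_from_pileup(pileup, config.sim.error_rate)
    variants = genolik.call_snps(
        gl,
        profile=config.profile,
        min_ind=config.min_ind,
        max_depth=config.max_depth,
    )
    called = genolik.call_genotypes(gl, variants, min_depth=config.min_genotype_depth)
    return gl, variants, called


@_stage("diversity")
def _diversity(config, truth, gl):
    out = {}
    for pop in np.unique(truth.pop_labels):
        cols = np.where(truth.pop_labels == pop)[0]
        rows = np.sort(np.concatenate([2 * cols, 2 * cols + 1]))
        hap = truth.haplotypes[rows]
        sfs = diversity.folded_sfs_from_haplotypes(
            hap, seed=config.sim.seed, total_sites=config.sim.seq_length
        )
        theta, se = diversity.theta_w_bootstrap(sfs)
        ne, ci = diversity.ne_from_theta(theta, config.sim.mu_sim, se)
        het = diversity.heterozygosity_per_individual(
            truth.true_genotypes[cols].T, total_sites=config.sim.seq_length
        )
        out[pop] = {
            "S": sfs.segregating,
            "theta_w": theta,
            "theta_w_se": se,
            "ne": ne,
            "ne_ci": ci,
            "het_mean": float(het.mean()),
        }
    return out


@_stage("relatedness")
def _relatedness(config, truth, gl, variants, called):
    if len(variants) < 2:
        raise ValueError("too few called variants for relatedness analysis")
    kin_geno = genolik.call_genotypes(gl, variants, min_depth=config.kinship_min_depth)
    kin = relatedness.kinship_table(kin_geno, gl.sample_ids, config.kinship_min_sites)
    degrees = kin.loc[~kin["filtered"], "degree"].value_counts().to_dict()
    idx = variants["gl_index"].to_numpy()
    try:
        ftab = relatedness.inbreeding_table(
            gl.ll[idx], variants["maf"].to_numpy(), gl.sample_ids,
            min_sites=min(100, max(10, len(variants) // 2)),
        )
        mean_f = {
            pop: float(ftab["F"].to_numpy()[truth.pop_labels == pop].mean())
            for pop in np.unique(truth.pop_labels)
        }
    except ValueError:
        mean_f = {}
    vals, _, scores = relatedness.covariance_pca(called.astype(float))
    return {
        "n_pairs_retained": int((~kin["filtered"]).sum()),
        "degree_counts": degrees,
        "mean_F": mean_f,
        "pca_top_eigenvalues": vals[:3].tolist(),
        "pc1_scores_by_pop": {
            pop: float(np.mean(scores[truth.pop_labels == pop, 0]))
            for pop in np.unique(truth.pop_labels)
        },
    }


@_stage("scan")
def _scan(config, truth):
    pops = list(np.unique(truth.pop_labels))
    L = config.sim.seq_length
    out = {"pairs": {}, "fu_li_mean_f": {}}
    freqs = {}
    nchrom = {}
    for pop in pops:
        cols = truth.pop_labels == pop
        g = truth.true_genotypes[cols].T
        freqs[pop] = g.sum(axis=1) / (2.0 * cols.sum())
        nchrom[pop] = 2 * int(cols.sum())
        ft = diffscan.fu_li_windows(
            truth.positions, g.sum(axis=1), nchrom[pop], L, config.window, config.step
        )
        out["fu_li_mean_f"][pop] = float(np.nanmean(ft["fu_li_f"]))
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            tab = diffscan.scan_windows(
                truth.positions, freqs[a], freqs[b], nchrom[a], nchrom[b], L,
                window=config.window, step=config.step, z_cut=config.z_cut,
                min_sites=config.min_window_sites,
            )
            point, ci = diffscan.global_fst_bootstrap(
                freqs[a], freqs[b], nchrom[a], nchrom[b], seed=config.sim.seed
            )
            out["pairs"][f"{a}-{b}"] = {
                "global_fst": point,
                "global_fst_ci": ci,
                "n_outlier_windows": int(tab["outlier"].sum()),
                "mean_dxy": float(np.nanmean(tab["dxy"])),
            }
    return out


@_stage("load")
def _load(config, truth):
    genic = np.isin(truth.site_context, ["CDS", "intron", "UTR", "upstream", "downstream"])
    table = loadcalc.load_table(
        truth.true_genotypes.T[genic],
        truth.site_class[genic],
        truth.pop_labels,
        sample_ids=truth.sample_ids,
        mode=config.load_mode,
    )
    mean_lr = (
        table.per_individual.groupby(["population", "impact_class"])["load_r"]
        .mean()
        .unstack()
        .to_dict(orient="index")
    )
    return {
        "mode": table.mode,
        "population_load_p": table.population_load_p.to_dict(orient="index"),
        "mean_load_r": mean_lr,
        "welch": table.welch.to_dict(orient="records"),
    }


@_stage("seqdiv")
def _seqdiv(config, truth):
    seg = config.alignment_segment
    ref = np.array(list(truth.reference[:seg]), dtype="U1")
    in_seg = truth.positions < seg
    seqs = []
    for row in range(0, truth.haplotypes.shape[0], 2):  # first haplotype per individual
        s = ref.copy()
        carried = truth.haplotypes[row, in_seg].astype(bool)
        s[truth.positions[in_seg][carried]] = truth.derived_allele[in_seg][carried]
        seqs.append("".join(s))
    aln = seqdiv.AlignmentSet.from_strings(
        seqs, ids=truth.sample_ids, pops=truth.pop_labels
    )
    out = {}
    for pop in np.unique(truth.pop_labels):
        sub = aln.subset(np.where(aln.pops == pop)[0])
        n_h, hd, n_pi = seqdiv.haplotype_stats(sub)
        out[pop] = {
            "n_haplotypes": n_h,
            "hd": hd,
            "pi": seqdiv.nucleotide_diversity(sub),
            "parsimony_informative": n_pi,
        }
    pops = list(np.unique(truth.pop_labels))
    if len(pops) >= 2:
        counts = {p: int((aln.pops == p).sum()) for p in pops[:2]}
        n_sub = min(config.subsample_n, *counts.values())
        cmp = seqdiv.subsample_compare(
            aln, pops[0], pops[1], n_sub=n_sub, n_perm=config.subsample_perms,
            statistic="pi", seed=config.sim.seed,
        )
        out["subsample_pi"] = {
            "mean_diff": cmp["mean_diff"],
            "p_empirical": cmp["p_empirical"],
        }
    return out
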