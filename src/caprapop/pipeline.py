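"""End-to-end orchestration of the study pipeline.

Stage order: load-or-simulate -> QC -> diversity/FST -> structure (PCA +
admixture) -> admixed-sample exclusion -> ROH -> LD/Ne -> discriminatory
panel -> assignment.  Every stage writes TSV/JSON outputs into the run
directory and is recorded, with row/SNP counts, wall-clock and output
checksums, in a run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity, ld, panel, qc, roh, structure
from .io import GenotypeDataset, read_plink_binary, read_plink_text, write_plink_binary
from .simulate import SimulationConfig, simulate_genotypes


@dataclasses.dataclass
class RunConfig:
    out_dir: str = "caprapop_run"
    # exactly one of the two input modes
    ped_path: str | None = None
    map_path: str | None = None
    bed_prefix: str | None = None
    simulation: SimulationConfig | None = None
    qc_thresholds: qc.QCThresholds = dataclasses.field(default_factory=qc.QCThresholds)
    roh_params: roh.ROHParams = dataclasses.field(default_factory=roh.ROHParams)
    admixture_k: tuple[int, ...] = (1, 2, 3)
    admix_exclude_threshold: float = 0.5
    exclude_sample_ids: tuple[str, ...] = ()
    ld_max_dist: int = 1_000_000
    ld_min_dist: int = 1_000
    panel_quantile: float = 0.995
    panel_top_n: int = 200
    split_fraction: float = 0.5
    exclusion_n_sim: int = 1000
    exclusion_alpha: float = 0.001
    seed: int = 0

    def __post_init__(self):
        modes = sum(x is not None for x in
                    (self.ped_path, self.bed_prefix, self.simulation))
        if modes != 1:
            raise ValueError("exactly one input mode (ped/bed/simulation) required")


def exclude_admixed(ds: GenotypeDataset, Q: np.ndarray,
                    threshold: float = 0.5,
                    explicit_ids: tuple[str, ...] = ()) -> tuple[GenotypeDataset, list[str]]:
    """Drop samples whose own-breed majority ancestry falls below ``threshold``,
    or whose id is on the explicit exclusion roster.

    Ancestry components are mapped to breeds by the breed with the highest
    mean component value; aborts if a whole breed would be removed.
    """
    breeds = ds.breeds
    uniq = sorted(set(breeds))
    comp_of_breed = {}
    for b in uniq:
        comp_of_breed[b] = int(np.argmax(Q[breeds == b].mean(axis=0)))
    removed = []
    keep = np.ones(ds.n_samples, dtype=bool)
    for i, s in enumerate(ds.samples):
        if s.sample_id in explicit_ids or \
                Q[i, comp_of_breed[s.breed]] < threshold:
            keep[i] = False
            removed.append(s.sample_id)
    for b in uniq:
        if not keep[breeds == b].any():
            raise ValueError(f"exclusion rule removes all of breed {b!r}")
    return ds.subset(sample_idx=keep), removed


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class RunManifest:
    def __init__(self, cfg: RunConfig):
        self.config = dataclasses.asdict(cfg)
        self.stages: list[dict] = []
        self.outputs: dict[str, str] = {}
        self.failed: str | None = None

    def record(self, name: str, t0: float, **info):
        self.stages.append({"stage": name, "seconds": round(time.time() - t0, 3),
                            **info})

    def add_output(self, path: Path):
        self.outputs[str(path)] = _sha256(path)

    def write(self, path: Path):
        obj = {"config": self.config, "stages": self.stages,
               "outputs": self.outputs, "failed": self.failed}
        path.write_text(json.dumps(obj, indent=1, default=str))


def run_all(cfg: RunConfig) -> RunManifest:
    """Execute the full pipeline; returns the manifest (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(cfg)
    try:
        _run_stages(cfg, out, manifest)
    except Exception as exc:  # manifest is written even on partial failure
        manifest.failed = f"{type(exc).__name__}: {exc}"
        manifest.write(out / "manifest.json")
        raise
    manifest.write(out / "manifest.json")
    return manifest


def _write_tsv(df: pd.DataFrame, path: Path, manifest: RunManifest):
    df.to_csv(path, sep="\t", index=False)
    manifest.add_output(path)


def _run_stages(cfg: RunConfig, out: Path, manifest: RunManifest):
    rng = np.random.default_rng(cfg.seed)

    t0 = time.time()
    if cfg.simulation is not None:
        ds, truth = simulate_genotypes(cfg.simulation)
        truth.to_json(out / "truth.json")
        manifest.add_output(out / "truth.json")
    elif cfg.ped_path is not None:
        ds = read_plink_text(cfg.ped_path, cfg.map_path)
        ds = ds.sort_markers()
    else:
        p = cfg.bed_prefix
        ds = read_plink_binary(f"{p}.bed", f"{p}.bim", f"{p}.fam").sort_markers()
    manifest.record("load", t0, n_samples=ds.n_samples, n_snps=ds.n_markers)

    t0 = time.time()
    ds_qc, report = qc.apply_qc(ds, cfg.qc_thresholds)
    (out / "qc_report.json").write_text(json.dumps(report.as_dict(), indent=1,
                                                   default=str))
    manifest.add_output(out / "qc_report.json")
    write_plink_binary(ds_qc, out / "filtered")
    for suffix in (".bed", ".bim", ".fam"):
        manifest.add_output((out / "filtered").with_suffix(suffix))
    manifest.record("qc", t0, n_samples=ds_qc.n_samples, n_snps=ds_qc.n_markers)

    t0 = time.time()
    pca_res = structure.pca(ds_qc)
    eig = pd.DataFrame(pca_res.eigenvectors[:, :10],
                       columns=[f"PC{k+1}" for k in range(min(10, pca_res.eigenvectors.shape[1]))])
    eig.insert(0, "sample_id", ds_qc.sample_ids)
    _write_tsv(eig, out / "pca_eigenvectors.tsv", manifest)
    cv_rows = []
    fits = {}
    for K in cfg.admixture_k:
        fit = structure.admixture_em(ds_qc, K,
                                     seed=int(rng.integers(2**31 - 1)))
        fits[K] = fit
        cv = structure.admixture_cv(ds_qc, K, seed=int(rng.integers(2**31 - 1)))
        cv_rows.append({"K": K, "loglik": fit.loglik, "cv_error": cv})
    cv_tab = pd.DataFrame(cv_rows)
    _write_tsv(cv_tab, out / "admixture_cv.tsv", manifest)
    best_k = int(cv_tab.loc[cv_tab["cv_error"].idxmin(), "K"])
    q_best = fits[best_k].Q
    qtab = pd.DataFrame(q_best, columns=[f"Q{k+1}" for k in range(best_k)])
    qtab.insert(0, "sample_id", ds_qc.sample_ids)
    _write_tsv(qtab, out / f"admixture_Q_K{best_k}.tsv", manifest)
    manifest.record("structure", t0, best_k=best_k,
                    pc12_pct=float(pca_res.pct_variance[:2].sum()))

    t0 = time.time()
    if best_k >= 2:
        ds_core, removed = exclude_admixed(ds_qc, q_best,
                                           cfg.admix_exclude_threshold,
                                           cfg.exclude_sample_ids)
    else:
        ds_core, removed = ds_qc, []
    manifest.record("exclude_admixed", t0, removed=removed,
                    n_samples=ds_core.n_samples)

    t0 = time.time()
    div_tab = diversity.diversity_table(ds_core)
    _write_tsv(div_tab, out / "diversity_by_breed.tsv", manifest)
    fis = diversity.fis_per_individual(ds_core)
    fg = diversity.fgrm(ds_core)
    fst = diversity.fst_weir_cockerham(ds_core)
    per_snp = pd.DataFrame({"chromosome": ds_core.chromosomes,
                            "bp_pos": ds_core.bp_positions,
                            "snp_id": ds_core.snp_ids,
                            "theta": fst.theta})
    _write_tsv(per_snp, out / "fst_per_snp.tsv", manifest)
    manifest.record("diversity", t0, fst_global=fst.theta_global)

    t0 = time.time()
    params = cfg.roh_params
    segments = roh.detect_roh(ds_core, params)
    _write_tsv(roh.segments_table(segments), out / "roh_segments.tsv", manifest)
    froh_recs = roh.froh(segments, ds_core)
    froh_tab = pd.DataFrame([dataclasses.asdict(r) for r in froh_recs])
    froh_tab["fis"] = fis[:len(froh_tab)] if len(fis) == len(froh_tab) else np.nan
    inbr = pd.DataFrame({
        "sample_id": ds_core.sample_ids,
        "breed": ds_core.breeds,
        "fis": fis, "fgrm": fg,
        "froh_total": [r.froh_total for r in froh_recs],
        "froh_lt10mb": [r.froh_lt10mb for r in froh_recs],
        "froh_10_20mb": [r.froh_10_20mb for r in froh_recs],
        "froh_gt20mb": [r.froh_gt20mb for r in froh_recs]})
    _write_tsv(inbr, out / "inbreeding_by_sample.tsv", manifest)
    _write_tsv(roh.roh_class_spectrum(segments), out / "roh_spectrum.tsv", manifest)
    _write_tsv(roh.avg_pct_roh_per_chromosome(segments, ds_core),
               out / "roh_per_chromosome.tsv", manifest)
    manifest.record("roh", t0, n_segments=len(segments))

    t0 = time.time()
    ld_rows = []
    for b in sorted(set(ds_core.breeds)):
        pairs = ld.pairwise_r2(ds_core, breed=b, min_dist=cfg.ld_min_dist,
                               max_dist=cfg.ld_max_dist)
        if len(pairs.pairs):
            ne = ld.ne_trajectory(pairs, int((ds_core.breeds == b).sum()))
            _write_tsv(ne, out / f"ne_trajectory_{b}.tsv", manifest)
            ld_rows.append({"breed": b, "mean_r2": pairs.mean_r2,
                            "mean_dist_bp": pairs.mean_dist_bp,
                            "n_pairs": len(pairs.pairs)})
    _write_tsv(pd.DataFrame(ld_rows), out / "ld_summary.tsv", manifest)
    manifest.record("ld_ne", t0)

    t0 = time.time()
    scores = panel.panel_scores(ds_core).table
    _write_tsv(scores, out / "panel_scores.tsv", manifest)
    fst_set, thr = panel.fst_percentile_panel(scores["theta"].to_numpy(),
                                              list(scores["snp_id"]),
                                              q=cfg.panel_quantile)
    tres_all = panel.tres_panel(ds_core, top_n=cfg.panel_top_n)
    tt = panel.tres_train_test(ds_core, cfg.split_fraction,
                               seed=int(rng.integers(2**31 - 1)),
                               top_n=cfg.panel_top_n)
    venn = panel.consensus_panel(fst_set, tres_all, tt.panel)
    consensus = sorted(venn.pop("consensus"))
    venn["fst_threshold"] = thr
    venn["consensus_snps"] = consensus
    venn["tres_tt_test_accuracy"] = tt.test_accuracy
    (out / "panel_venn.json").write_text(json.dumps(venn, indent=1))
    manifest.add_output(out / "panel_venn.json")
    manifest.record("panel", t0, n_consensus=len(consensus))

    t0 = time.time()
    panel_ids = consensus if consensus else sorted(fst_set)
    keep = np.isin(np.array(ds_core.snp_ids), panel_ids)
    recs = panel.assign_and_detect_migrants(
        ds_core.subset(marker_idx=keep),
        criterion="frequency",
        exclusion_n_sim=cfg.exclusion_n_sim,
        exclusion_alpha=cfg.exclusion_alpha,
        seed=int(rng.integers(2**31 - 1)))
    _write_tsv(recs, out / "assignment.tsv", manifest)
    acc = float((recs["assigned_breed"] == recs["true_breed"]).mean())
    manifest.record("assignment", t0, n_panel_snps=int(keep.sum()),
                    self_assignment_accuracy=acc)
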