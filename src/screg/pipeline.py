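"""Pipeline orchestration: staged, file-backed, reproducible.

Every stage reads its inputs from the output directory, writes deterministic
TSV/JSON/Matrix Market outputs plus a JSON stage log (resolved parameters,
seed, input/output counts, wall time), and derives its randomness from the
single top-level seed so stages are individually re-runnable.
"""

from __future__ import annotations

import json
import time
import dataclasses
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic, qc, metacell, network, enrichment, abundance, mr, io

STAGES = ("qc", "metacell", "network", "activity", "abundance", "mr")


class MissingStageError(FileNotFoundError):
    """An upstream stage's outputs are absent."""


@dataclass
class PipelineConfig:
    outdir: str = "screg_out"
    seed: int = 0
    sim: dict = field(default_factory=dict)          # SimConfig overrides
    qc: dict = field(default_factory=lambda: {
        "min_depth": 1000, "max_depth": 50000, "min_genes": 500,
        "max_mito_pct": 20.0, "mito_prefix": "mt-",
        "n_pcs": 20, "knn_k": 15})
    metacell: dict = field(default_factory=lambda: {
        "k": 5, "cap": 500, "condition": "WT", "residual_theta": 100.0})
    network: dict = field(default_factory=lambda: {
        # desk profile; the full-scale profile is alpha=1e-8, n_boot=200,
        # min_targets=50
        "n_boot": 50, "alpha": 1e-4, "n_perm": 1000, "bins": 6,
        "dpi_tolerance": 0.0, "min_targets": 10})
    comparisons: list = field(default_factory=lambda: [["WT", "KO"], ["KO", "rescue"]])
    mr: dict = field(default_factory=lambda: {
        "revert_fraction": 0.5, "q_thresh": 0.05, "epsilon": 0.05})

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        base = cls()
        for k in ("qc", "metacell", "network", "mr"):
            if k in d:
                merged = dict(getattr(base, k))
                bad = set(d[k]) - set(merged)
                if bad:
                    raise ValueError(f"unknown {k} config keys: {sorted(bad)}")
                merged.update(d[k])
                d[k] = merged
        return cls(**{k: v for k, v in d.items() if k in known})


def _log(outdir: Path, stage: str, params: dict, t0: float, **counts) -> None:
    logdir = outdir / "logs"
    logdir.mkdir(parents=True, exist_ok=True)
    payload = {"stage": stage, "params": params,
               "wall_seconds": round(time.time() - t0, 3), **counts}
    (logdir / f"{stage}.json").write_text(
        json.dumps(payload, indent=1, sort_keys=True, default=str) + "\n")


def _require(path: Path, stage: str):
    if not path.exists():
        raise MissingStageError(
            f"missing {path}; run the `{stage}` stage first")
    return path


def stage_simulate(config: PipelineConfig) -> Path:
    t0 = time.time()
    outdir = Path(config.outdir)
    sim_cfg = synthetic.SimConfig(**{**config.sim, "seed": config.seed})
    gt = synthetic.make_ground_truth(sim_cfg)
    adata = synthetic.simulate_counts(gt, sim_cfg)
    io.write_dataset(adata, gt, outdir / "data")
    _log(outdir, "simulate", dataclasses.asdict(sim_cfg), t0,
         cells=adata.n_obs, genes=adata.n_vars)
    return outdir / "data"


def stage_qc(config: PipelineConfig):
    t0 = time.time()
    outdir = Path(config.outdir)
    adata = io.read_10x_mtx(_require(outdir / "data", "simulate"))
    p = config.qc
    thr = qc.QCThresholds(min_depth=p["min_depth"], max_depth=p["max_depth"],
                          min_genes=p["min_genes"], max_mito_pct=p["max_mito_pct"])
    filtered = qc.qc_filter(adata, thr, mito_prefix=p["mito_prefix"])
    logcpm = qc.normalize_log_cpm(filtered)
    clusters = qc.cluster_cells(logcpm, n_pcs=p["n_pcs"], knn_k=p["knn_k"],
                                seed=config.seed)
    qcdir = outdir / "qc"
    io.write_10x_mtx(filtered, qcdir)
    io.write_tsv(filtered.uns["qc_report"], qcdir / "qc_report.tsv")
    io.write_tsv(pd.DataFrame({"barcode": filtered.obs_names,
                               "cluster": clusters.labels}),
                 qcdir / "clusters.tsv", index=False)
    _log(outdir, "qc", p, t0, cells_in=adata.n_obs, cells_out=filtered.n_obs,
         n_clusters=clusters.n_clusters)
    return filtered, clusters


def _load_qc(outdir: Path):
    adata = io.read_10x_mtx(_require(outdir / "qc", "qc"))
    cl = pd.read_csv(_require(outdir / "qc" / "clusters.tsv", "qc"), sep="\t")
    labels = cl.set_index("barcode").loc[adata.obs_names, "cluster"].to_numpy()
    return adata, labels


def stage_metacell(config: PipelineConfig):
    t0 = time.time()
    outdir = Path(config.outdir)
    adata, _ = _load_qc(outdir)
    p = config.metacell
    if p["condition"] is not None:
        sel = adata.obs["condition"] == p["condition"]
        if not sel.any():
            raise ValueError(f"no cells in condition {p['condition']!r}")
        adata = adata[sel.to_numpy()].copy()
    residuals = qc.pearson_residuals(adata, theta=p["residual_theta"])
    mc = metacell.build_metacells(adata, residuals, k=p["k"])
    mc = metacell.subset_and_cpm(mc, cap=p["cap"], seed=config.seed)
    io.write_metacells(mc, outdir / "metacells")
    _log(outdir, "metacell", p, t0, cells=adata.n_obs, metacells=mc.n_metacells)
    return mc


def stage_network(config: PipelineConfig):
    t0 = time.time()
    outdir = Path(config.outdir)
    mc = io.read_metacells(_require(outdir / "metacells", "metacell"))
    classes = io.read_regulator_classes(
        _require(outdir / "data" / "regulators.tsv", "simulate"))
    p = config.network
    edges = network.bootstrap_consolidate(
        mc, classes, n_boot=p["n_boot"], alpha=p["alpha"], n_perm=p["n_perm"],
        bins=p["bins"], dpi_tolerance=p["dpi_tolerance"], seed=config.seed)
    regulons = network.assemble_regulons(edges, mc, min_targets=p["min_targets"])
    netdir = outdir / "network"
    netdir.mkdir(parents=True, exist_ok=True)
    io.write_tsv(edges, netdir / "network.tsv", index=False)
    io.write_regulons(regulons, netdir / "regulons.json")
    _log(outdir, "network", p, t0, edges=len(edges), regulons=len(regulons))
    return edges, regulons


def stage_activity(config: PipelineConfig):
    t0 = time.time()
    outdir = Path(config.outdir)
    adata, labels = _load_qc(outdir)
    regulons = io.read_regulons(
        _require(outdir / "network" / "regulons.json", "network"))
    logcpm = qc.normalize_log_cpm(adata)
    genes = list(adata.var_names)
    cond = adata.obs["condition"].to_numpy()

    sigs = enrichment.cluster_signatures(logcpm, labels, genes)
    sigs.columns = [f"cluster_{c}" for c in sigs.columns]
    contrasts = {}
    for a, b in (("KO", "WT"), ("rescue", "WT")):
        contrasts[f"{a}_vs_{b}"] = mr.contrast_signature(
            logcpm, cond == a, cond == b, genes)
    ges = pd.concat([sigs, pd.DataFrame(contrasts)], axis=1)
    act = mr.activity_matrix(regulons, ges)

    actdir = outdir / "activity"
    actdir.mkdir(parents=True, exist_ok=True)
    io.write_tsv(sigs, actdir / "signatures.tsv")
    io.write_tsv(act, actdir / "activity.tsv")
    _log(outdir, "activity", {}, t0, regulators=len(act), samples=act.shape[1])
    return sigs, act


def stage_abundance(config: PipelineConfig):
    t0 = time.time()
    outdir = Path(config.outdir)
    adata, labels = _load_qc(outdir)
    sigs = pd.read_csv(_require(outdir / "activity" / "signatures.tsv", "activity"),
                       sep="\t", index_col=0)
    marker_sets = json.loads(
        _require(outdir / "data" / "marker_sets.json", "simulate").read_text())
    sigs.columns = [int(c.replace("cluster_", "")) for c in sigs.columns]
    mapping, detail = abundance.assign_cell_types(sigs, marker_sets)
    types = pd.Series(labels).map(mapping).to_numpy()
    table = abundance.celltype_table(adata.obs["condition"].to_numpy(), types)

    rows = []
    for a, b in config.comparisons:
        res = abundance.abundance_chisq(table, a, b)
        t = res.table.reset_index()
        t.insert(0, "comparison", f"{a}_vs_{b}")
        rows.append(t)
    abdir = outdir / "abundance"
    abdir.mkdir(parents=True, exist_ok=True)
    io.write_tsv(detail, abdir / "celltypes.tsv", index=False)
    io.write_tsv(table, abdir / "celltype_counts.tsv")
    io.write_tsv(pd.concat(rows, ignore_index=True), abdir / "abundance.tsv",
                 index=False)
    io.write_tsv(pd.DataFrame({"barcode": adata.obs_names, "cell_type": types}),
                 abdir / "cell_assignments.tsv", index=False)
    _log(outdir, "abundance", {"comparisons": config.comparisons}, t0,
         types=table.shape[1])
    return mapping, table


def stage_mr(config: PipelineConfig):
    t0 = time.time()
    outdir = Path(config.outdir)
    act = pd.read_csv(_require(outdir / "activity" / "activity.tsv", "activity"),
                      sep="\t", index_col=0)
    p = config.mr
    calls = mr.mr_calls(act, ko_col="KO_vs_WT", rescue_col="rescue_vs_WT",
                        revert_fraction=p["revert_fraction"],
                        q_thresh=p["q_thresh"], epsilon=p["epsilon"])
    mrdir = outdir / "mr"
    mrdir.mkdir(parents=True, exist_ok=True)
    io.write_tsv(calls, mrdir / "mr_calls.tsv")
    long = calls.reset_index().melt(
        id_vars=["regulator", "category"],
        value_vars=["nes_ko", "nes_rescue"],
        var_name="contrast", value_name="nes")
    io.write_tsv(long, mrdir / "mr_long.tsv", index=False)
    _log(outdir, "mr", p, t0, regulators=len(calls),
         **calls["category"].value_counts().to_dict())
    return calls


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "metacell": stage_metacell,
    "network": stage_network,
    "activity": stage_activity,
    "abundance": stage_abundance,
    "mr": stage_mr,
}


def run_pipeline(config: PipelineConfig, stages=("all",)) -> dict:
    """Run the requested stages (``all`` = qc through mr) in order."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(config.to_json() + "\n")
    todo = []
    for s in stages:
        todo.extend(STAGES if s == "all" else [s])
    results = {}
    for s in todo:
        if s not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {s!r}; choose from "
                             f"{('simulate',) + STAGES + ('all',)}")
        results[s] = _STAGE_FUNCS[s](config)
    return results
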