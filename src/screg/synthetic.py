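"""Synthetic three-condition single-cell dataset with planted regulatory ground truth.

Emulates a FACS-purified neonatal retinal endothelial scRNA-seq experiment with a
wild-type (WT) condition, a ligand knockout (KO) that suppresses a WNT-driven
regulator module and depletes the deep-diving tip-cell population, and a rescue
condition (KO plus a WNT surrogate agonist) that restores both.  Counts follow a
negative-binomial model; regulator "activity" acts multiplicatively on the
log-mean of the regulator's own transcript and of its targets, so that the
planted regulons are recoverable by mutual-information network inference and the
planted activity shifts are recoverable by regulon enrichment.

The generative model is a stand-in: the real study used droplet scRNA-seq data,
and no generative model is implied by it.  All distributional choices are
flagged as synthetic in the ground-truth metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp
import anndata as ad

CONDITIONS = ("WT", "KO", "rescue")

CELL_TYPES = (
    "D-tip",
    "S-tip",
    "arterial",
    "venous",
    "prolif-1",
    "prolif-2",
    "pan-EC",
)

#: Types that carry their own marker-gene program.  The pan-endothelial pool is
#: deliberately marker-free: real pan-EC cells are defined by *absence* of
#: subset markers, and the cell-typing stage labels them by fallback.
MARKED_TYPES = CELL_TYPES[:-1]

# Default per-condition cell-type composition.  The D-tip analog collapses in
# the knockout and is largely restored by the rescue; the S-tip analog drops
# mildly in the knockout and is NOT restored.  The pan-EC pool absorbs the rest.
DEFAULT_PROPORTIONS = {
    "WT": {
        "D-tip": 0.15, "S-tip": 0.10, "arterial": 0.17, "venous": 0.17,
        "prolif-1": 0.12, "prolif-2": 0.11, "pan-EC": 0.18,
    },
    "KO": {
        "D-tip": 0.02, "S-tip": 0.07, "arterial": 0.19, "venous": 0.19,
        "prolif-1": 0.13, "prolif-2": 0.12, "pan-EC": 0.28,
    },
    "rescue": {
        "D-tip": 0.12, "S-tip": 0.07, "arterial": 0.18, "venous": 0.18,
        "prolif-1": 0.12, "prolif-2": 0.11, "pan-EC": 0.22,
    },
}

#: Wildcard cell-type key in activity_effects: the shift applies to all types.
ALL_TYPES = "*"


class SimulationSizingError(ValueError):
    """Marker, regulator and target requests exceed the available gene pool."""


def _default_regulator_classes(regulators: list[str]) -> dict[str, list[str]]:
    """Partition regulators into the four regulator classes used for network
    inference (transcription factors, co-factors, signaling, surface)."""
    n = len(regulators)
    q = [regulators[i::4] for i in range(4)]
    return {"TF": q[0], "coTF": q[1], "signaling": q[2], "surface": q[3]}


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    Defaults define the package's reference scenario: 2,000 genes, 20
    regulators with 30 targets each, three conditions of 1,500 cells (within
    the 1,200-2,800 cells-per-channel range typical of droplet loading), seven
    endothelial subpopulations, negative-binomial counts with dispersion
    theta = 2, and ~5% "damaged" cells with elevated mitochondrial content for
    the QC stage to remove.
    """

    n_genes: int = 2000
    n_regulators: int = 20
    targets_per_regulator: int = 30
    n_cells_per_condition: int = 1500
    proportions: dict = field(default_factory=lambda: {
        c: dict(t) for c, t in DEFAULT_PROPORTIONS.items()})
    marker_genes_per_type: int = 40
    marker_log_boost: float = 2.5
    regulator_classes: dict | None = None  # None -> default 4-way partition
    activity_effects: dict | None = None   # None -> default planted scenario
    effect_size: float = 1.0               # log-scale condition effect a
    activity_noise_sd: float = 0.75        # per-cell, per-regulator activity jitter
    mode_positive_prob: float = 0.7
    nb_dispersion: float = 2.0
    library_size_lognormal: tuple = (9.2, 0.35)  # meanlog, sdlog (~10k UMI)
    mito_gene_fraction: float = 0.05
    n_mito_genes: int = 13
    damaged_cell_fraction: float = 0.05
    damaged_mito_multiplier: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.nb_dispersion <= 0:
            raise ValueError(f"nb_dispersion must be positive, got {self.nb_dispersion}")
        if self.library_size_lognormal[1] < 0:
            raise ValueError("library_size_lognormal sdlog must be nonnegative")
        if not 0 <= self.mito_gene_fraction < 1:
            raise ValueError("mito_gene_fraction must be in [0, 1)")
        for cond, props in self.proportions.items():
            vals = np.array([props[t] for t in CELL_TYPES])
            if (vals < 0).any() or abs(vals.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"cell-type proportions for condition {cond!r} must be "
                    f"nonnegative and sum to 1 (sum={vals.sum()})")

    # --- derived gene naming -------------------------------------------------

    @property
    def regulator_names(self) -> list[str]:
        return [f"Reg{i + 1:02d}" for i in range(self.n_regulators)]

    @property
    def mito_names(self) -> list[str]:
        return [f"mt-{i + 1:02d}" for i in range(self.n_mito_genes)]

    @property
    def marker_names(self) -> dict[str, list[str]]:
        return {
            t: [f"Mk-{t}-{j + 1:02d}" for j in range(self.marker_genes_per_type)]
            for t in MARKED_TYPES
        }

    def gene_names(self) -> list[str]:
        special = (self.n_regulators + self.n_mito_genes
                   + self.marker_genes_per_type * len(MARKED_TYPES))
        n_filler = self.n_genes - special
        if n_filler < self.n_regulators * self.targets_per_regulator:
            raise SimulationSizingError(
                f"{self.n_genes} genes cannot host {special} special genes plus "
                f"{self.n_regulators * self.targets_per_regulator} disjoint targets")
        names = list(self.regulator_names)
        for t in MARKED_TYPES:
            names += self.marker_names[t]
        names += self.mito_names
        names += [f"G{i + 1:04d}" for i in range(n_filler)]
        return names

    def resolved_regulator_classes(self) -> dict[str, list[str]]:
        if self.regulator_classes is not None:
            classes = self.regulator_classes
        else:
            classes = _default_regulator_classes(self.regulator_names)
        members = [g for v in classes.values() for g in v]
        if len(members) != len(set(members)) or set(members) != set(self.regulator_names):
            raise ValueError("regulator_classes must partition the regulator set")
        return classes


def default_activity_effects(config: SimConfig) -> dict:
    """The planted scenario, keyed (regulator, condition, cell type).

    * Reg01-Reg06 form the WNT-analog module: active in the D-tip analog in WT,
      silenced there in KO, restored by the rescue.
    * Reg07 is the leakage-marker analog ("PLVAP-like"): induced everywhere in
      KO, suppressed back to baseline by the rescue.
    * Reg08-Reg10 are treatment-specific: induced only in the rescue condition.
    Remaining regulators carry no condition effect.
    """
    a = config.effect_size
    eff: dict = {}
    regs = config.regulator_names
    for r in regs[:6]:
        eff[(r, "WT", "D-tip")] = a
        eff[(r, "rescue", "D-tip")] = a
    if len(regs) > 6:
        eff[(regs[6], "KO", ALL_TYPES)] = a
    for r in regs[7:10]:
        eff[(r, "rescue", ALL_TYPES)] = a
    return eff


@dataclass
class GroundTruth:
    """Machine-readable truth for recovery tests."""

    regulons: dict               # regulator -> list of {"gene","mode","weight"}
    type_markers: dict           # type -> list of marker genes
    true_activity: pd.DataFrame  # regulators x (condition, type)
    true_proportions: pd.DataFrame  # condition x type
    rescued_regulators: list
    treatment_specific_regulators: list
    regulator_classes: dict
    gene_names: list
    mito_genes: list

    def __post_init__(self):
        if set(self.rescued_regulators) & set(self.treatment_specific_regulators):
            raise ValueError("rescued and treatment-specific regulator sets overlap")
        pool = set(self.gene_names)
        for r, targets in self.regulons.items():
            bad = [t["gene"] for t in targets if t["gene"] not in pool]
            if bad:
                raise ValueError(f"regulon {r} has unknown targets {bad[:3]}")

    def to_json(self) -> str:
        payload = {
            "note": ("synthetic ground truth; all distributional choices are "
                     "stand-ins, not estimates from real retinal data"),
            "regulons": self.regulons,
            "type_markers": self.type_markers,
            "true_activity": {
                r: {f"{c}|{t}": float(self.true_activity.loc[r, (c, t)])
                    for c, t in self.true_activity.columns}
                for r in self.true_activity.index
            },
            "true_proportions": {
                c: {t: float(self.true_proportions.loc[c, t])
                    for t in self.true_proportions.columns}
                for c in self.true_proportions.index
            },
            "rescued_regulators": list(self.rescued_regulators),
            "treatment_specific_regulators": list(self.treatment_specific_regulators),
            "regulator_classes": self.regulator_classes,
            "mito_genes": list(self.mito_genes),
            "gene_names": list(self.gene_names),
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        conds, types = CONDITIONS, CELL_TYPES
        cols = pd.MultiIndex.from_product([conds, types], names=["condition", "cell_type"])
        regs = sorted(d["true_activity"])
        act = pd.DataFrame(0.0, index=regs, columns=cols)
        for r, row in d["true_activity"].items():
            for key, v in row.items():
                c, t = key.split("|")
                act.loc[r, (c, t)] = v
        props = pd.DataFrame(d["true_proportions"]).T.reindex(
            index=list(conds), columns=list(types))
        return cls(
            regulons=d["regulons"], type_markers=d["type_markers"],
            true_activity=act, true_proportions=props,
            rescued_regulators=d["rescued_regulators"],
            treatment_specific_regulators=d["treatment_specific_regulators"],
            regulator_classes=d["regulator_classes"],
            gene_names=d["gene_names"], mito_genes=d["mito_genes"],
        )


def make_ground_truth(config: SimConfig) -> GroundTruth:
    """Plant regulons, markers, activities and compositions; deterministic in seed."""
    rng = np.random.default_rng([config.seed, 11])
    genes = config.gene_names()
    markers = config.marker_names

    special = set(config.regulator_names) | set(config.mito_names)
    for t in MARKED_TYPES:
        special |= set(markers[t])
    pool = [g for g in genes if g not in special]
    need = config.n_regulators * config.targets_per_regulator
    if need > len(pool):
        raise SimulationSizingError(
            f"need {need} target genes but only {len(pool)} non-marker genes available")
    chosen = rng.choice(len(pool), size=need, replace=False)

    regulons: dict = {}
    for i, r in enumerate(config.regulator_names):
        idx = chosen[i * config.targets_per_regulator:(i + 1) * config.targets_per_regulator]
        modes = np.where(rng.random(len(idx)) < config.mode_positive_prob, 1.0, -1.0)
        w = 1.0 / len(idx)
        regulons[r] = [
            {"gene": pool[j], "mode": float(m), "weight": w}
            for j, m in zip(idx, modes)
        ]

    effects = config.activity_effects
    if effects is None:
        effects = default_activity_effects(config)

    cols = pd.MultiIndex.from_product([CONDITIONS, CELL_TYPES],
                                      names=["condition", "cell_type"])
    act = pd.DataFrame(0.0, index=config.regulator_names, columns=cols)
    for (r, c, t), v in effects.items():
        if t == ALL_TYPES:
            for ct in CELL_TYPES:
                act.loc[r, (c, ct)] = v
        else:
            act.loc[r, (c, t)] = v

    props = pd.DataFrame(
        [[config.proportions[c][t] for t in CELL_TYPES] for c in CONDITIONS],
        index=list(CONDITIONS), columns=list(CELL_TYPES))

    # Classify planted regulators from the activity table itself so custom
    # effect dictionaries stay consistent with the labels.
    rescued, treat = [], []
    for r in config.regulator_names:
        wt, ko, rs = (act.loc[r, (c, slice(None))].to_numpy() for c in CONDITIONS)
        ko_shift = np.abs(ko - wt).max()
        rs_shift = np.abs(rs - wt).max()
        if ko_shift > 0 and rs_shift <= 0.5 * ko_shift:
            rescued.append(r)
        elif ko_shift == 0 and rs_shift > 0:
            treat.append(r)

    return GroundTruth(
        regulons=regulons,
        type_markers={t: list(markers[t]) for t in MARKED_TYPES},
        true_activity=act,
        true_proportions=props,
        rescued_regulators=rescued,
        treatment_specific_regulators=treat,
        regulator_classes=config.resolved_regulator_classes(),
        gene_names=genes,
        mito_genes=config.mito_names,
    )


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p)


def simulate_counts(gt: GroundTruth, config: SimConfig) -> ad.AnnData:
    """Draw the count matrix; cells x genes AnnData with condition / true-type
    metadata and a mitochondrial flag per gene."""
    if config.nb_dispersion <= 0:
        raise ValueError("nb_dispersion must be positive")
    rng = np.random.default_rng([config.seed, 23])
    genes = gt.gene_names
    gi = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)
    regs = list(gt.true_activity.index)

    base = rng.lognormal(0.0, 1.0, n_genes)
    mito_idx = np.array([gi[g] for g in gt.mito_genes], dtype=int)
    f = config.mito_gene_fraction

    # Regulator -> gene effect map: each regulator drives its own transcript
    # (coefficient +1) and each target with the planted mode.
    M = np.zeros((len(regs), n_genes))
    for k, r in enumerate(regs):
        M[k, gi[r]] = 1.0
        for t in gt.regulons[r]:
            M[k, gi[t["gene"]]] = t["mode"]

    marker_boost = np.zeros((len(CELL_TYPES), n_genes))
    for ti, t in enumerate(CELL_TYPES):
        for g in gt.type_markers.get(t, []):
            marker_boost[ti, gi[g]] = config.marker_log_boost

    type_index = {t: i for i, t in enumerate(CELL_TYPES)}
    blocks, obs_rows = [], []
    for cond in CONDITIONS:
        n = config.n_cells_per_condition
        p = gt.true_proportions.loc[cond].to_numpy()
        # largest-remainder allocation: the realized composition equals the
        # planted one exactly, so abundance tests measure pipeline recovery
        # rather than multinomial sampling luck
        alloc = np.floor(n * p).astype(int)
        frac = n * p - alloc
        short = n - alloc.sum()
        alloc[np.argsort(-frac, kind="stable")[:short]] += 1
        types = np.repeat(np.arange(len(CELL_TYPES)), alloc)
        damaged = rng.random(n) < config.damaged_cell_fraction
        lib = rng.lognormal(*config.library_size_lognormal, n)

        # per-cell activity = planted (condition, type) level + cell jitter
        planted = gt.true_activity.loc[
            regs, (cond, slice(None))].to_numpy()          # regs x types
        A = planted[:, types].T + rng.normal(
            0.0, config.activity_noise_sd, (n, len(regs)))  # cells x regs

        logmu = np.log(base)[None, :] + marker_boost[types] + A @ M
        rel = np.exp(logmu)
        if len(mito_idx) and f > 0:
            # pin the expected mito share per cell: baseline fraction f for
            # healthy cells, damaged_mito_multiplier * f for damaged ones,
            # regardless of marker/activity boosts elsewhere
            target = np.where(damaged,
                              min(f * config.damaged_mito_multiplier, 0.9), f)
            non = np.delete(rel, mito_idx, axis=1).sum(axis=1)
            scale = (target / (1 - target)) * non / rel[:, mito_idx].sum(axis=1)
            rel[:, mito_idx] *= scale[:, None]
        mean = rel * (lib / rel.sum(axis=1))[:, None]
        counts = _nb_sample(rng, mean, config.nb_dispersion)
        blocks.append(sp.csr_matrix(counts))
        for j in range(n):
            obs_rows.append((
                f"{cond}-{j + 1:05d}", cond, CELL_TYPES[types[j]], bool(damaged[j])))

    X = sp.vstack(blocks).tocsr()
    obs = pd.DataFrame(obs_rows, columns=["barcode", "condition", "true_type", "is_damaged"])
    obs = obs.set_index("barcode")
    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    var["is_mito"] = [g.startswith("mt-") for g in genes]
    var["is_regulator"] = [g in set(regs) for g in genes]
    adata = ad.AnnData(X=X, obs=obs, var=var)
    adata.uns["conditions"] = list(CONDITIONS)
    return adata


def simulate_dataset(config: SimConfig | None = None) -> tuple[ad.AnnData, GroundTruth]:
    """Convenience wrapper: ground truth plus counts under one config."""
    config = config or SimConfig()
    gt = make_ground_truth(config)
    return simulate_counts(gt, config), gt
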