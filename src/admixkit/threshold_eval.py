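"""Membership-threshold classification and its power analysis.

Given posterior membership coefficients qi from a K=2 admixture analysis
of the simulated eight-class design, individuals are called non-admixed
toward a cluster when their qi toward it strictly exceeds a threshold t,
and admixed otherwise.  Misassignment is scored per hybrid class and
threshold: pure classes err when called admixed (or pure of the wrong
cluster); hybrid classes err when called non-admixed of either cluster.
The operating threshold is the largest candidate at which the pure, F1
and F2 classes are all assigned without error — maximising backcross
detection subject to zero error on the classes the panel can separate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .hybrid_sim import DESIGN_ORDER, HybridClass, SimulatedDataset

PURE_CLASSES = {HybridClass.PURE_A, HybridClass.PURE_B}
DEFAULT_THRESHOLDS = (0.8, 0.85, 0.9, 0.95)

#: Cluster whose qi is reported as a class's "own" coefficient (the
#: parental lineage the class is closest to; A by convention for F1/F2).
CLASS_REPORT_CLUSTER = {
    HybridClass.PURE_A: "A",
    HybridClass.BC_A: "A",
    HybridClass.BC2_A: "A",
    HybridClass.F1: "A",
    HybridClass.F2: "A",
    HybridClass.PURE_B: "B",
    HybridClass.BC_B: "B",
    HybridClass.BC2_B: "B",
}


def classify(qi_a: float, threshold: float) -> str:
    """Call one individual from its qi toward cluster A.

    Strict rule: ``qi_a > t`` -> ``non-admixed-A``; ``1 - qi_a > t`` ->
    ``non-admixed-B``; otherwise ``admixed``.  A qi exactly equal to the
    threshold is admixed.
    """
    if not 0.5 < threshold < 1.0:
        raise ValueError("threshold must lie in (0.5, 1); calls are ambiguous otherwise")
    if not 0.0 <= qi_a <= 1.0:
        raise ValueError("qi must lie in [0, 1]")
    if qi_a > threshold:
        return "non-admixed-A"
    if 1.0 - qi_a > threshold:
        return "non-admixed-B"
    return "admixed"


def _cluster_a_column(sim: SimulatedDataset, Q: np.ndarray) -> np.ndarray:
    """qi toward the cluster matching pool A, identified from the pure-A
    class's mean membership."""
    Q = np.asarray(Q, dtype=float)
    if Q.shape[1] != 2:
        raise ValueError("threshold evaluation expects a K=2 Q matrix")
    is_a = np.array([c is HybridClass.PURE_A for c in sim.true_class])
    col = int(np.argmax(Q[is_a].mean(axis=0)))
    return Q[:, col]


def accuracy_table(
    sim: SimulatedDataset,
    Q: np.ndarray,
    thresholds=DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Per-class, per-threshold misassignment summary.

    Columns: ``hybrid_class, threshold, n, n_misassigned,
    percent_misassigned, qi_min, qi_max``; qi bounds are toward the
    class's own parental cluster (A for F1/F2).
    """
    qa = _cluster_a_column(sim, Q)
    if len(qa) != sim.genotypes.n_individuals:
        raise ValueError("Q and simulated dataset cover different individuals")
    classes = np.asarray([getattr(c, "value", c) for c in sim.true_class])
    known = {c.value for c in HybridClass}
    unknown = set(classes) - known
    if unknown:
        raise ValueError(f"unknown hybrid class labels: {sorted(unknown)}")
    rows = []
    for cls in DESIGN_ORDER:
        idx = np.flatnonzero(classes == cls.value)
        if idx.size == 0:
            continue
        q_cls = qa[idx]
        q_own = q_cls if CLASS_REPORT_CLUSTER[cls] == "A" else 1.0 - q_cls
        for t in thresholds:
            calls = np.array([classify(q, t) for q in q_cls])
            if cls is HybridClass.PURE_A:
                bad = calls != "non-admixed-A"
            elif cls is HybridClass.PURE_B:
                bad = calls != "non-admixed-B"
            else:
                bad = calls != "admixed"
            rows.append(
                {
                    "hybrid_class": cls.value,
                    "threshold": t,
                    "n": idx.size,
                    "n_misassigned": int(bad.sum()),
                    "percent_misassigned": 100.0 * bad.mean(),
                    "qi_min": float(q_own.min()),
                    "qi_max": float(q_own.max()),
                }
            )
    return pd.DataFrame(rows)


def select_threshold(table: pd.DataFrame) -> float:
    """Operating-threshold rule.

    Return the largest candidate threshold at which the pure, F1 and F2
    classes all have exactly 0% misassignment (maximising backcross
    detection subject to zero error there); if no candidate qualifies,
    the one minimising their summed misassignment, ties to the lower
    threshold.
    """
    if table.empty:
        raise ValueError("empty accuracy table")
    core = {
        HybridClass.PURE_A.value,
        HybridClass.PURE_B.value,
        HybridClass.F1.value,
        HybridClass.F2.value,
    }
    sub = table[table["hybrid_class"].isin(core)]
    missing = core - set(sub["hybrid_class"])
    if missing:
        raise ValueError(f"accuracy table lacks core classes: {sorted(missing)}")
    sums = sub.groupby("threshold")["percent_misassigned"].sum().sort_index()
    perfect = sums[sums == 0.0]
    if len(perfect):
        return float(perfect.index.max())
    return float(sums[sums == sums.min()].index.min())


def apply_to_samples(
    q_table: pd.DataFrame,
    threshold: float,
    label_column: str = "label",
    qi_column: str = "q_A",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify empirical samples and summarise per label group.

    ``q_table`` needs an ``individual_id`` column, a qi-toward-cluster-A
    column and a group label column (e.g. known vs putative hybrids).
    Returns (per-individual calls, per-group summary with admixed counts
    and percentages).
    """
    calls = q_table.copy()
    calls["call"] = [classify(q, threshold) for q in calls[qi_column]]
    calls["threshold"] = threshold
    rows = []
    for label, grp in calls.groupby(label_column, sort=False):
        n = len(grp)
        n_adm = int((grp["call"] == "admixed").sum())
        rows.append(
            {
                label_column: label,
                "n": n,
                "n_admixed": n_adm,
                "percent_admixed": 100.0 * n_adm / n,
            }
        )
    return calls, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "seed": 0,
    "n_loci": 27,
    "allele_range": (3, 17),
    "fst": 0.165,
    "concentration": 1.0,
    "n_ref": (30, 30),
    "n_per_class": 60,
    "k": 2,
    "reps": 20_000,
    "burnin": 5_000,
    "replicates": 3,
    "model": "correlated",
    "thresholds": list(DEFAULT_THRESHOLDS),
    "threshold_grid_step": None,  # e.g. 0.01 for continuous-style curves
}


def run_full_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Simulate -> admix -> score -> select, writing CSVs, plots and a
    manifest under ``out_dir``.  Deterministic given the config seed."""
    import json

    import yaml

    from . import admixture, differentiation, hybrid_sim, io_formats, synthetic_pops

    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    cfg = {**DEFAULT_CONFIG, **config}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    stage = "simulate-pops"
    try:
        refs = synthetic_pops.simulate_parental_pair(
            n_loci=cfg["n_loci"],
            allele_range=tuple(cfg["allele_range"]),
            fst=cfg["fst"],
            n_per_pop=tuple(cfg["n_ref"]),
            concentration=cfg["concentration"],
            seed=seed,
        )
        io_formats.write_structure(refs, out / "reference_pops.str")

        stage = "simulate-hybrids"
        sim = hybrid_sim.build_design(
            refs.subset_population("A"),
            refs.subset_population("B"),
            n_per_class=cfg["n_per_class"],
            seed=seed + 1,
        )
        io_formats.write_structure(sim.genotypes, out / "simulated_design.str")
        io_formats.write_csv(sim.truth_table(), out / "truth.csv")

        stage = "admixture"
        runs = [
            admixture.run_mcmc(
                sim.genotypes,
                K=cfg["k"],
                reps=cfg["reps"],
                burnin=cfg["burnin"],
                seed=seed + 100 + rep,
                model=cfg["model"],
            )
            for rep in range(cfg["replicates"])
        ]
        _, q_mean = admixture.align_replicates([r.Q for r in runs])
        q_df = pd.DataFrame(
            {
                "individual_id": sim.genotypes.individual_ids,
                "true_class": [c.value for c in sim.true_class],
                **{f"q_{k + 1}": q_mean[:, k] for k in range(q_mean.shape[1])},
            }
        )
        io_formats.write_csv(q_df, out / "qmatrix.csv")

        stage = "accuracy"
        thresholds = list(cfg["thresholds"])
        if cfg["threshold_grid_step"]:
            lo = min(thresholds)
            grid = np.arange(lo, 1.0, cfg["threshold_grid_step"])
            thresholds = sorted(set(np.round(grid, 10)) | set(thresholds))
        table = accuracy_table(sim, q_mean, thresholds)
        io_formats.write_csv(table, out / "accuracy.csv")
        chosen = select_threshold(
            table[table["threshold"].isin(cfg["thresholds"])]
        )

        stage = "pca"
        pca_res = differentiation.pca(refs)
        pca_df = pd.DataFrame(
            {
                "individual_id": pca_res.individual_ids,
                "population": refs.population_labels,
                "axis1": pca_res.coordinates[:, 0],
                "axis2": pca_res.coordinates[:, 1],
            }
        )
        io_formats.write_csv(pca_df, out / "pca.csv")

        stage = "plots"
        _plots(table, q_df, pca_df, pca_res.percent_variance, out)

        manifest = {
            "config": {
                k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg.items()
            },
            "selected_threshold": chosen,
            "ln_prob_data": [r.ln_prob_data for r in runs],
            "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as exc:  # noqa: BLE001 - annotate failing stage
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return manifest


def _plots(table, q_df, pca_df, pca_pct, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for cls, grp in table.groupby("hybrid_class", sort=False):
        g = grp.sort_values("threshold")
        ax.plot(g["threshold"], g["percent_misassigned"], marker="o", label=cls)
    ax.set_xlabel("membership threshold qi")
    ax.set_ylabel("% misassigned")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "misassignment_curves.png", dpi=150)
    plt.close(fig)

    qcols = [c for c in q_df.columns if c.startswith("q_")]
    fig, ax = plt.subplots(figsize=(9, 3))
    bottom = np.zeros(len(q_df))
    x = np.arange(len(q_df))
    for c in qcols:
        ax.bar(x, q_df[c], bottom=bottom, width=1.0, label=c)
        bottom += q_df[c].to_numpy()
    ax.set_xlim(-0.5, len(q_df) - 0.5)
    ax.set_ylabel("qi")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "q_barplot.png", dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4.5))
    for pop, grp in pca_df.groupby("population", sort=False):
        ax.scatter(grp["axis1"], grp["axis2"], s=12, label=pop)
    ax.set_xlabel(f"axis 1 ({pca_pct[0]:.1f}%)")
    ax.set_ylabel(f"axis 2 ({pca_pct[1]:.1f}%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out / "pca.png", dpi=150)
    plt.close(fig)
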