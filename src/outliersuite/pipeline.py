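"""End-to-end orchestration: gate -> detect -> consensus -> characterize
-> cluster -> predict -> stability, with every stage's tables written to
an output directory and a single machine-readable JSON summary linking
them.  Reproducible from config + seed alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, compare, network, rpca
from .consensus import apply_consensus, summarize_convergence
from .detectors import DetectorParams, detect_all
from .io import standardize, validate_dataset
from .normality import assess_normality
from .predict import MIN_MINORITY_CLASS, RFConfig, bootstrap_stability, train_classifier

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    output_dir: str = "outliersuite_run"
    seed: int = 0
    normality_alpha: float = 0.05
    gate_fraction: float = 0.05
    detector_params: DetectorParams | None = None
    network_r_cut: float = 0.5
    network_p_cut: float = 0.05
    k_range: tuple[int, int] = (2, 10)
    rf: RFConfig | None = None
    bootstrap_B: int = 200
    run_stability: bool = True
    cluster_on_outliers: bool = True

    def detector(self) -> DetectorParams:
        p = self.detector_params or DetectorParams()
        p.seed = self.seed
        return p


def _write(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, sep="\t")
    return path.name


def run_pipeline(
    m: pd.DataFrame, meta: pd.DataFrame | None = None, cfg: RunConfig | None = None
) -> dict:
    """Run the complete framework on one feature matrix.

    Stages that are inapplicable at the data's scale (supervised
    prediction with a minority class below 8, clustering-tendency on tiny
    outlier subsets, networks on groups below 5 samples) are skipped with
    an explanatory notice in the summary rather than failing the run.
    """
    cfg = cfg or RunConfig()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed, "stages": {}, "notices": [], "artifacts": {}}

    report = validate_dataset(m, meta)
    summary["stages"]["validate"] = {
        "n_samples": report.n_samples, "n_features": report.n_features,
        "constant_features": report.constant_features,
    }

    gate = assess_normality(m, alpha=cfg.normality_alpha, gate_fraction=cfg.gate_fraction)
    summary["stages"]["normality"] = gate.to_dict()

    det = detect_all(m, cfg.detector())
    summary["artifacts"]["detection_matrix"] = _write(
        det.sample_flags.astype(int), out / "detection_matrix.tsv")
    scores = pd.DataFrame(det.scores)
    summary["artifacts"]["method_scores"] = _write(scores, out / "method_scores.tsv")

    cons = apply_consensus(det.sample_flags, gate)
    labels = cons.labels
    label_table = pd.DataFrame({
        "outlier": labels.astype(int),
        "criteria": cons.criteria.apply(
            lambda r: ",".join(c for c in ("C1", "C2", "C3") if r[c]), axis=1),
        "votes": cons.votes,
    })
    summary["artifacts"]["consensus_labels"] = _write(label_table, out / "consensus_labels.tsv")
    summary["stages"]["consensus"] = summarize_convergence(det.sample_flags, cons)

    n_out = int(labels.sum())
    n_norm = int((~labels).sum())

    if n_out and n_norm:
        desc = compare.describe_by_group(m, labels)
        summary["artifacts"]["descriptives"] = _write(desc, out / "descriptives.tsv")
        if n_out >= 2 and n_norm >= 2:
            mw = compare.mann_whitney_panel(m, labels, alpha=cfg.normality_alpha)
            summary["artifacts"]["mann_whitney"] = _write(mw, out / "mann_whitney.tsv")
            summary["stages"]["comparison"] = {
                "n_significant": int(mw["significant"].sum())}
        if meta is not None:
            assoc = {}
            for factor in meta.columns:
                tbl = pd.crosstab(labels, meta[factor].reindex(m.index))
                try:
                    res = compare.categorical_association(
                        tbl, mode="monte_carlo", seed=cfg.seed)
                    assoc[factor] = {"chi2": round(res.chi2, 4), "df": res.df,
                                     "p": round(res.p_value, 4),
                                     res.effect_name: round(res.effect_size, 4)}
                except ValueError as exc:
                    summary["notices"].append(f"association for {factor!r} skipped: {exc}")
            summary["stages"]["categorical_association"] = assoc
    else:
        summary["notices"].append("degenerate labeling: group comparison skipped")

    std = standardize(m)
    model = rpca.fit_robust_pca(std.values)
    var_table = pd.DataFrame({
        "explained_percent": np.round(
            100 * model.robust_eigenvalues / model.robust_eigenvalues.sum(), 1)
    }, index=[f"PC{i + 1}" for i in range(len(model.robust_eigenvalues))])
    var_table["cumulative_percent"] = var_table["explained_percent"].cumsum().round(1)
    summary["artifacts"]["pca_variance"] = _write(var_table, out / "pca_variance.tsv")
    summary["artifacts"]["pca_loadings"] = _write(model.loadings, out / "pca_loadings.tsv")
    summary["artifacts"]["pca_scores"] = _write(model.scores, out / "pca_scores.tsv")
    summary["stages"]["robust_pca"] = {
        "explained_percent": var_table["explained_percent"].head(5).tolist()}

    if n_out >= 5 and n_norm >= 5:
        net_out = network.build_network(m.loc[labels], cfg.network_r_cut, cfg.network_p_cut)
        net_norm = network.build_network(m.loc[~labels], cfg.network_r_cut, cfg.network_p_cut)
        delta = network.compare_centrality(net_out, net_norm)
        summary["artifacts"]["network_edges_outlier"] = _write(
            net_out.edges, out / "network_edges_outlier.tsv")
        summary["artifacts"]["network_edges_normal"] = _write(
            net_norm.edges, out / "network_edges_normal.tsv")
        summary["artifacts"]["centrality_delta"] = _write(delta, out / "centrality_delta.tsv")
        summary["stages"]["network"] = {
            "edges_outlier": net_out.n_edges, "edges_normal": net_norm.n_edges}
    else:
        summary["notices"].append("co-expression networks skipped: a group has < 5 samples")

    cluster_data = std.values.loc[labels] if (cfg.cluster_on_outliers and n_out >= 3) \
        else std.values
    cluster_scope = "outliers" if (cfg.cluster_on_outliers and n_out >= 3) else "cohort"
    nc = cluster_data.shape[0]
    cluster_summary: dict = {"scope": cluster_scope, "n": nc}
    if nc >= 10:
        hop = clustering.hopkins(cluster_data, seed=cfg.seed)
        cluster_summary["hopkins"] = round(hop.H, 4)
    else:
        summary["notices"].append("Hopkins statistic skipped: fewer than 10 samples")
    if nc >= 4:
        k_lo, k_hi = cfg.k_range
        ks = clustering.k_selection(
            cluster_data, range(k_lo, min(k_hi, nc - 1) + 1), seed=cfg.seed)
        summary["artifacts"]["k_selection"] = _write(ks, out / "k_selection.tsv")
        k_opt = int(ks["silhouette"].idxmax())
        cluster_summary["k_optimal_silhouette"] = k_opt
        km = clustering.kmeans(cluster_data, k_opt, seed=cfg.seed)
        hc = clustering.hierarchical(cluster_data, k_opt)
        pca_scores = model.scores.loc[cluster_data.index]
        profile = clustering.profile_clusters(cluster_data, km.labels, pca_scores)
        summary["artifacts"]["cluster_labels"] = _write(
            pd.DataFrame({"kmeans": km.labels, "hierarchical": hc.labels}),
            out / "cluster_labels.tsv")
        summary["artifacts"]["cluster_profiles"] = _write(profile, out / "cluster_profiles.tsv")
        newick = clustering.merge_tree_newick(hc.merge_tree, list(cluster_data.index))
        (out / "dendrogram.nwk").write_text(newick + "\n")
        summary["artifacts"]["dendrogram"] = "dendrogram.nwk"
        cluster_summary["cluster_sizes"] = km.labels.value_counts().sort_index().tolist()
    else:
        summary["notices"].append("clustering skipped: fewer than 4 samples in scope")
    summary["stages"]["clustering"] = cluster_summary

    minority = min(n_out, n_norm)
    if minority >= MIN_MINORITY_CLASS:
        rf_cfg = cfg.rf or RFConfig(seed=cfg.seed)
        rf_cfg.seed = cfg.seed
        rf = train_classifier(m, labels, rf_cfg)
        summary["artifacts"]["rf_importances"] = _write(
            rf.importances.to_frame("gini_importance"), out / "rf_importances.tsv")
        summary["stages"]["prediction"] = {
            "confusion": rf.confusion, "metrics": rf.metrics, "auc": round(rf.auc, 3)}
    else:
        summary["notices"].append(
            f"supervised prediction skipped: minority class has {minority} samples "
            f"(< {MIN_MINORITY_CLASS}), which would invite extreme overfitting")
        summary["stages"]["prediction"] = {"skipped": True}

    if cfg.run_stability and cfg.bootstrap_B > 0:
        stab = bootstrap_stability(
            m, cfg.detector(), B=cfg.bootstrap_B, seed=cfg.seed,
            alpha=cfg.normality_alpha, gate_fraction=cfg.gate_fraction)
        summary["artifacts"]["stability"] = _write(
            stab.per_sample, out / "stability.tsv")
        summary["stages"]["stability"] = {
            "mean_stability": round(stab.mean_stability, 4), "B": stab.n_iterations}

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
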