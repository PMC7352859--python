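"""End-to-end analysis pipeline.

Runs simulate -> preprocess -> univariate -> clustering -> network -> dbp
-> scca -> association in dependency order under a single seed, writing
per-stage CSV/JSON/GraphML/Newick outputs plus a manifest and a
machine-readable report. One global seed deterministically spawns per-stage
substreams, so toggling a stage never perturbs another stage's randomness.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .association import adjusted_marker_model, association_model, marker_roc
from .cluster import bootstrap_support, grade_profile_matrix
from .cohort import CohortConfig, default_study_config, generate_cohort
from .io import log10_zscore, read_panel, write_panel
from .network import bootstrap_network, node_degree_table
from .panel import BiomarkerPanel
from .perturbation import classify_perturbed, dbp_fold_table, dbp_scores
from .scca import canonical_coefficients, encode_groups, fit_scca, scca_discriminant_roc
from .univariate import mann_whitney, univariate_table

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "preprocess", "univariate", "clustering",
               "network", "dbp", "scca", "association")
_DEPENDENCIES = {
    "univariate": {"preprocess"}, "clustering": {"preprocess"},
    "network": {"preprocess"}, "dbp": {"preprocess"},
    "scca": {"preprocess"}, "association": {"preprocess"},
}


@dataclass
class RunConfig:
    input: str = "simulate"            # path to a panel CSV or "simulate"
    cohort: CohortConfig | None = None
    alpha_network: float = 0.05
    n_boot: int = 100
    scca_penalties: tuple[float, float] | None = None
    alpha_entry: float = 0.2
    roc_marker: str = "TGF-β"
    seed: int = 0
    output_dir: str = "bioperturb_out"
    stages: tuple[str, ...] = STAGE_ORDER[1:]

    def validate(self) -> "RunConfig":
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        requested = set(self.stages) | ({"simulate"} if self.input == "simulate"
                                        else set())
        for stage in requested:
            missing = _DEPENDENCIES.get(stage, set()) - requested
            if missing:
                raise ValueError(f"stage {stage!r} requires {sorted(missing)}")
        return self


@dataclass
class AnalysisReport:
    config: dict
    manifest: dict[str, str] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    version: str = __version__


def _spawn_seeds(seed: int) -> dict[str, int]:
    """Per-stage integer substream seeds from the single run seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(STAGE_ORDER))
    return {stage: int(child.generate_state(1)[0] % (2 ** 31))
            for stage, child in zip(STAGE_ORDER, children)}


def run(config: RunConfig) -> AnalysisReport:
    """Execute the requested stages; identical config => identical outputs."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _spawn_seeds(config.seed)
    report = AnalysisReport(config=_config_dict(config))
    requested = set(config.stages)

    # --- input ------------------------------------------------------------
    if config.input == "simulate":
        cohort = config.cohort or default_study_config()
        panel = generate_cohort(cohort, seed=seeds["simulate"])
        path = out / "panel.csv"
        write_panel(panel, path)
        report.manifest["panel"] = path.name
    else:
        panel = read_panel(config.input)
        report.manifest["panel"] = str(config.input)

    if "preprocess" in requested:
        transformed = log10_zscore(panel.complete_rows())
        path = out / "transformed.csv"
        transformed.values.to_csv(path, float_format="%.12g")
        report.manifest["transformed"] = path.name
    else:
        return _finalize(report, out)

    complete = panel.complete_rows()

    if "univariate" in requested:
        table = univariate_table(complete)
        path = out / "univariate.csv"
        table.to_csv(path, index=False, float_format="%.12g")
        report.manifest["univariate"] = path.name
        report.summary["holm_significant_markers"] = \
            table.loc[table["significant"], "marker"].tolist()

    if "clustering" in requested:
        dendro = bootstrap_support(
            transformed.values.to_numpy().T, labels=complete.marker_names,
            n_boot=config.n_boot, seed=seeds["clustering"])
        (out / "marker_dendrogram.nwk").write_text(dendro.to_newick(),
                                                   encoding="utf-8")
        dendro.support_table().to_csv(out / "marker_dendrogram_support.csv",
                                      index=False, float_format="%.12g")
        report.manifest["marker_dendrogram"] = "marker_dendrogram.nwk"
        report.manifest["marker_dendrogram_support"] = "marker_dendrogram_support.csv"
        if set(complete.grade.unique()) == {0, 1, 2}:
            profile = grade_profile_matrix(complete)
            profile.to_csv(out / "grade_profiles.csv", float_format="%.12g")
            report.manifest["grade_profiles"] = "grade_profiles.csv"

    if "network" in requested:
        nets = []
        for value, label in ((0, "no_steatosis"), (1, "steatosis")):
            net = bootstrap_network(
                complete.group_panel(value), n_boot=config.n_boot,
                alpha=config.alpha_network, group=label,
                seed=seeds["network"] + value)
            nets.append(net)
            nx.write_graphml(net.to_graph(), out / f"network_{label}.graphml")
            net.edge_table().to_csv(out / f"edges_{label}.csv", index=False,
                                    float_format="%.12g")
            report.manifest[f"network_{label}"] = f"network_{label}.graphml"
            report.manifest[f"edges_{label}"] = f"edges_{label}.csv"
        degrees = node_degree_table(nets)
        degrees.to_csv(out / "node_degrees.csv", float_format="%.12g")
        report.manifest["node_degrees"] = "node_degrees.csv"
        report.summary["network_edges"] = {
            net.group: {"total": len(net.edges), "positive": net.n_positive,
                        "negative": net.n_negative} for net in nets}

    if "dbp" in requested:
        result = classify_perturbed(dbp_scores(complete))
        dbp_df = pd.DataFrame({
            "sample_id": complete.data["sample_id"],
            "steatosis": complete.steatosis,
            "dbp_score": result.sample_score,
            "perturbed": result.perturbed.astype(int),
        })
        dbp_df.to_csv(out / "dbp_scores.csv", index=False, float_format="%.12g")
        result.z_matrix.to_csv(out / "dbp_z_matrix.csv", float_format="%.12g")
        dbp_fold_table(result).to_csv(out / "dbp_folds.csv", index=False,
                                      float_format="%.12g")
        for key in ("dbp_scores", "dbp_z_matrix", "dbp_folds"):
            report.manifest[key] = f"{key}.csv"
        case_scores = result.sample_score[~result.reference_mask].to_numpy()
        ref_scores = result.sample_score[result.reference_mask].to_numpy()
        mw = mann_whitney(case_scores, ref_scores)
        report.summary["dbp"] = {
            "threshold": result.threshold,
            "perturbed_fraction_cases": float(
                result.perturbed[~result.reference_mask].mean()),
            "perturbed_fraction_controls": float(
                result.perturbed[result.reference_mask].mean()),
            "group_comparison_p": mw.p_raw,
        }

    if "scca" in requested:
        pen_u, pen_v = (config.scca_penalties or (None, None))
        X = log10_zscore(complete).values.to_numpy()
        labels = complete.steatosis.to_numpy()
        roc, model = scca_discriminant_roc(X, labels, penalty_u=pen_u,
                                           penalty_v=pen_v,
                                           mode="resubstitution")
        coeffs = canonical_coefficients(
            fit_scca(X, encode_groups(labels), pen_u, pen_v,
                     marker_names=complete.marker_names))
        coeffs.to_csv(out / "scca_coefficients.csv", index=False,
                      float_format="%.12g")
        model_json = {
            "u": model.u.tolist(), "v": model.v.tolist(),
            "penalty_u": model.penalty_u, "penalty_v": model.penalty_v,
            "canonical_correlation": model.canonical_correlation,
            "iterations": model.iterations, "converged": model.converged,
        }
        (out / "scca_model.json").write_text(json.dumps(model_json, indent=1))
        report.manifest["scca_coefficients"] = "scca_coefficients.csv"
        report.manifest["scca_model"] = "scca_model.json"
        report.summary["scca"] = {
            "auc_resubstitution": roc.auc,
            "canonical_correlation": model.canonical_correlation,
            "top_markers": coeffs.loc[~coeffs["excluded"], "marker"].head(6).tolist(),
        }

    if "association" in requested:
        model = association_model(complete, alpha_entry=config.alpha_entry)
        model.terms.to_csv(out / "odds_ratios.csv", index=False,
                           float_format="%.12g")
        report.manifest["odds_ratios"] = "odds_ratios.csv"
        roc_res = marker_roc(complete, config.roc_marker)
        roc_json = {
            "marker": config.roc_marker, "auc": roc_res.auc,
            "auc_ci": list(roc_res.auc_ci),
            "youden_cutoff": roc_res.youden_cutoff,
            "sensitivity": roc_res.sens_at_cutoff,
            "specificity": roc_res.spec_at_cutoff,
        }
        (out / "roc_summary.json").write_text(json.dumps(roc_json, indent=1))
        pd.DataFrame({"threshold": roc_res.thresholds,
                      "sensitivity": roc_res.sensitivity,
                      "specificity": roc_res.specificity}).to_csv(
            out / "roc_curve.csv", index=False, float_format="%.12g")
        report.manifest["roc_summary"] = "roc_summary.json"
        report.manifest["roc_curve"] = "roc_curve.csv"
        adjusted = adjusted_marker_model(complete, config.roc_marker)
        row = adjusted.terms[adjusted.terms["term"]
                             == f"log10_{config.roc_marker}"]
        report.summary["association"] = {
            "marker": config.roc_marker,
            "adjusted_odds_ratio_per_log10": float(row["odds_ratio"].iloc[0]),
            "or_ci": [float(row["ci_low"].iloc[0]),
                      float(row["ci_high"].iloc[0])],
            "auc": roc_res.auc, "auc_ci": list(roc_res.auc_ci),
            "youden_cutoff": roc_res.youden_cutoff,
            "full_model_separation_flag": model.separation,
        }

    return _finalize(report, out)


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    if d.get("cohort") is not None:
        cohort = d["cohort"]
        for k, v in list(cohort.items()):
            if isinstance(v, np.ndarray):
                cohort[k] = v.tolist()
    return json.loads(json.dumps(d, default=str))


def _finalize(report: AnalysisReport, out: Path) -> AnalysisReport:
    for key, path in report.manifest.items():
        p = Path(path) if Path(path).is_absolute() else out / path
        if not p.exists() or p.stat().st_size == 0:
            raise RuntimeError(f"manifest entry {key} missing or empty: {path}")
    (out / "manifest.json").write_text(json.dumps(report.manifest, indent=1))
    (out / "report.json").write_text(
        json.dumps(dataclasses.asdict(report), indent=1, default=str))
    return report
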