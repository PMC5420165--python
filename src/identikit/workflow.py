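"""End-to-end identifiability workflow as a model/results pair.

:class:`IdentifiabilityAnalysis` is built from a kinetic model, its
experimental designs and a measurement set; ``fit()`` runs the full pipeline
in order — calibrate (optional), forward sensitivities, influence filter,
collinearity normalization, largest-subset search, enumeration of all
largest subsets, minimal collinear groups, network assembly — and returns an
:class:`IdentifiabilityResults` carrying every intermediate product, with a
``summary()`` table, export helpers and plotting.  :func:`run_workflow`
wraps the same pipeline for the command line, writing all artifacts plus a
JSON summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import DEFAULT_ALPHA, CalibrationProblem, CalibrationResult
from .collinearity import (DEFAULT_CI_THRESHOLD, NormalizedSensitivityMatrix,
                           normalize, pairwise_ci_table)
from .enumeration import (EnumerationResult, all_largest_subsets,
                          groups_table, smallest_collinear_groups)
from .graph import build_graph, structural_jacobians, write_graph
from .model import ExperimentDesign, KineticModel, MeasurementSet
from .sensitivity import DEFAULT_CUTOFF_RATIO, SensitivityBundle, analyse_sensitivities
from .subset_selection import SubsetSelectionResult, threshold_sweep, vns_maximize

logger = logging.getLogger("identikit")


@dataclass
class RunConfig:
    """Workflow configuration; defaults follow the standard choices
    (CI* = 20, influence cutoff ratio 1e-4, alpha = 0.1, groups up to 6)."""

    model_path: str | None = None
    data_path: str | None = None
    outdir: str = "identikit_out"
    ci_threshold: float = DEFAULT_CI_THRESHOLD
    sens_cutoff_ratio: float = DEFAULT_CUTOFF_RATIO
    alpha: float = DEFAULT_ALPHA
    seed: int = 0
    calibration_budget: int = 4000
    vns_budget: int | None = None
    max_group_size: int = 6
    skip_calibrate: bool = False
    theta: list[float] | None = None      # used when skip_calibrate
    sweep: list[float] | None = None      # optional CI* grid


class IdentifiabilityResults:
    """Everything the pipeline computed, with reporting helpers."""

    def __init__(self, analysis: "IdentifiabilityAnalysis", theta_used: np.ndarray,
                 calibration: CalibrationResult | None,
                 bundle: SensitivityBundle, nsm: NormalizedSensitivityMatrix,
                 selection: SubsetSelectionResult, enumeration: EnumerationResult,
                 groups, graph, sweep: pd.DataFrame | None, seed: int):
        self.analysis = analysis
        self.theta_used = np.asarray(theta_used, float)
        self.calibration = calibration
        self.sensitivities = bundle
        self.nsm = nsm
        self.selection = selection
        self.enumeration = enumeration
        self.groups = groups
        self.graph = graph
        self.sweep = sweep
        self.seed = seed

    # -- reporting ---------------------------------------------------------
    @property
    def largest_subset(self):
        return self.selection.best_subset

    def summary(self) -> str:
        b = self.sensitivities
        sel = self.selection
        lines = [
            "Practical identifiability analysis",
            "==================================",
            f"parameters analysed:        {len(b.msqr)}",
            f"influential (msqr filter):  {len(b.influential_params)} "
            f"(cutoff {b.cutoff_used:.3g})",
            f"non-influential:            {b.non_influential_params or 'none'}",
            f"CI threshold:               {sel.threshold:g} (identifiable iff CI < CI*)",
            f"largest identifiable set:   {sel.best_subset.size} parameters, "
            f"CI = {sel.best_subset.ci:.4g}",
            f"  members: {', '.join(sel.best_subset.members)}",
            f"all largest subsets:        {self.enumeration.n_subsets} of size "
            f"{self.enumeration.max_size}, CI in "
            f"[{self.enumeration.ci_range[0]:.4g}, {self.enumeration.ci_range[1]:.4g}]",
            f"minimal collinear groups:   {len(self.groups)}",
        ]
        for g in self.groups:
            lines.append(f"  {g.label:<8} CI = {g.ci:<12.4g} {{{', '.join(g.members)}}}")
        if self.calibration is not None:
            lines += ["", self.calibration.summary()]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "theta_used": [float(v) for v in self.theta_used],
            "n_parameters": int(len(self.sensitivities.msqr)),
            "non_influential": list(self.sensitivities.non_influential_params),
            "cutoff_used": float(self.sensitivities.cutoff_used),
            "ci_threshold": float(self.selection.threshold),
            "largest_subset": {
                "size": self.largest_subset.size,
                "members": list(self.largest_subset.members),
                "ci": float(self.largest_subset.ci),
            },
            "all_largest_subsets": {
                "count": self.enumeration.n_subsets,
                "max_size": self.enumeration.max_size,
                "ci_range": [float(c) for c in self.enumeration.ci_range],
            },
            "collinear_groups": [
                {"label": g.label, "ci": float(g.ci), "members": list(g.members)}
                for g in self.groups],
        }

    # -- plotting -----------------------------------------------------------
    def plot_msqr(self, ax=None):
        """Bar plot of per-parameter root-mean-square sensitivities (log scale)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        s = self.sensitivities.msqr
        ax.bar(range(len(s)), s.values)
        ax.axhline(self.sensitivities.cutoff_used, color="r", ls="--",
                   label="influence cutoff")
        ax.set_yscale("log")
        ax.set_xticks(range(len(s)), s.index, rotation=90)
        ax.set_ylabel("msqr sensitivity")
        ax.legend()
        return ax

    def plot_sweep(self, ax=None):
        """Largest-subset size versus CI threshold."""
        import matplotlib.pyplot as plt
        if self.sweep is None:
            raise ValueError("no threshold sweep was computed")
        if ax is None:
            _, ax = plt.subplots()
        ax.step(self.sweep["ci_threshold"], self.sweep["max_size"], where="post")
        ax.axvline(self.selection.threshold, color="r", ls="--")
        ax.set_xlabel("collinearity threshold CI*")
        ax.set_ylabel("max identifiable parameters")
        return ax


class IdentifiabilityAnalysis:
    """Model object for the calibrate-then-analyse identifiability workflow."""

    def __init__(self, model: KineticModel, designs, data: MeasurementSet,
                 ci_threshold: float = DEFAULT_CI_THRESHOLD,
                 sens_cutoff_ratio: float = DEFAULT_CUTOFF_RATIO,
                 alpha: float = DEFAULT_ALPHA, theta_ref=None,
                 max_group_size: int = 6):
        if isinstance(designs, ExperimentDesign):
            designs = [designs]
        self.model = model
        self.designs = list(designs)
        self.data = data
        self.ci_threshold = float(ci_threshold)
        self.sens_cutoff_ratio = float(sens_cutoff_ratio)
        self.alpha = float(alpha)
        self.theta_ref = theta_ref
        self.max_group_size = int(max_group_size)
        data.validate_against(self.designs)

    def fit(self, seed: int = 0, theta=None, calibration_budget: int = 4000,
            vns_budget: int | None = None, sweep=None,
            compute_graph: bool = True) -> IdentifiabilityResults:
        """Run the full pipeline.

        If ``theta`` is supplied calibration is skipped and the analysis is
        performed at that vector; otherwise the regularized hybrid estimator
        runs first and the analysis uses the estimate.
        """
        calibration = None
        if theta is None:
            problem = CalibrationProblem(self.model, self.designs, self.data,
                                         alpha=self.alpha, theta_ref=self.theta_ref)
            calibration = problem.fit(seed=seed, budget=calibration_budget)
            theta = calibration.theta_hat
            logger.info("calibration done: Q_LS=%.4g", calibration.q_ls)
        theta = np.asarray(theta, float)

        bundle = analyse_sensitivities(self.model, self.designs, self.data,
                                       theta, ratio=self.sens_cutoff_ratio,
                                       check_bounds=False)
        logger.info("influential parameters: %s", bundle.influential_params)
        nsm = normalize(bundle.stacked_matrix, bundle.influential_mask)
        selection = vns_maximize(nsm, self.ci_threshold, seed=seed,
                                 budget=vns_budget)
        enumeration = all_largest_subsets(nsm, self.ci_threshold)
        groups = smallest_collinear_groups(nsm, self.ci_threshold,
                                           self.max_group_size)
        sweep_table = None
        if sweep is not None:
            sweep_table = threshold_sweep(nsm, sweep, seed=seed, budget=vns_budget)
        graph = None
        if compute_graph:
            graph = build_graph(self.model, structural_jacobians(self.model),
                                selection.best_subset.members, nsm=nsm,
                                groups=groups, ci_threshold=self.ci_threshold)
        return IdentifiabilityResults(self, theta, calibration, bundle, nsm,
                                      selection, enumeration, groups, graph,
                                      sweep_table, seed)


def run_workflow(config: RunConfig, model: KineticModel | None = None,
                 designs=None, data: MeasurementSet | None = None) -> dict:
    """CLI-facing pipeline: load inputs, fit, write artifacts + JSON summary.

    Model/designs/data may be passed directly (tests, fixtures) or loaded
    from the paths in ``config``.  Any stage failure raises with the stage
    name; artifacts of completed stages are left on disk.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if model is None:
        if config.model_path is None:
            raise ValueError("run_workflow needs a model or config.model_path")
        model = KineticModel.from_yaml(config.model_path)
    if data is None:
        if config.data_path is None:
            raise ValueError("run_workflow needs data or config.data_path")
        data = MeasurementSet.from_csv(config.data_path)
    if designs is None:
        # default single design spanning the data's time range per experiment
        designs = []
        for exp, sub in data.records.groupby("experiment", sort=True):
            times = np.unique(sub["time"].to_numpy())
            designs.append(ExperimentDesign(
                str(exp), float(min(times.min(), 0.0)), float(times.max()),
                times, sorted(sub["observable"].unique())))

    analysis = IdentifiabilityAnalysis(
        model, designs, data, ci_threshold=config.ci_threshold,
        sens_cutoff_ratio=config.sens_cutoff_ratio, alpha=config.alpha,
        max_group_size=config.max_group_size)
    theta = np.asarray(config.theta, float) if (config.skip_calibrate
                                                and config.theta is not None) else None
    results = analysis.fit(seed=config.seed, theta=theta,
                           calibration_budget=config.calibration_budget,
                           vns_budget=config.vns_budget, sweep=config.sweep)

    manifest = {}

    def _write(name, writer):
        path = outdir / name
        writer(path)
        manifest[name] = str(path)

    _write("stacked_sensitivities.tsv",
           lambda p: results.sensitivities.stacked_matrix.to_csv(p, sep="\t", index=False))
    _write("msqr.tsv", lambda p: pd.DataFrame({
        "parameter": results.sensitivities.msqr.index,
        "msqr": results.sensitivities.msqr.values,
        "influential": results.sensitivities.influential_mask.values,
    }).to_csv(p, sep="\t", index=False))
    _write("pairwise_ci.tsv",
           lambda p: pairwise_ci_table(results.nsm).to_csv(p, sep="\t", index=False))
    _write("largest_subsets.tsv", lambda p: pd.DataFrame(
        [(s.size, s.ci, " ".join(s.members)) for s in results.enumeration.subsets],
        columns=["size", "ci", "members"]).to_csv(p, sep="\t", index=False))
    _write("collinear_groups.tsv",
           lambda p: groups_table(results.groups).to_csv(p, sep="\t", index=False))
    if results.sweep is not None:
        _write("threshold_sweep.tsv",
               lambda p: results.sweep.to_csv(p, sep="\t", index=False))
    if results.graph is not None:
        _write("network.graphml", lambda p: write_graph(results.graph, p, "graphml"))
        _write("network.sif", lambda p: write_graph(results.graph, p, "sif"))
    if results.calibration is not None:
        _write("calibration_trace.tsv", lambda p: pd.DataFrame(
            results.calibration.trace,
            columns=["evaluations", "best_objective"]).to_csv(p, sep="\t", index=False))

    summary = results.to_dict()
    summary["config"] = asdict(config)
    summary["version"] = __version__
    summary["manifest"] = manifest
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(outdir / "run.log", "w") as fh:
        fh.write(f"identikit {__version__}\nseed={config.seed}\n"
                 f"ci_threshold={config.ci_threshold}\nalpha={config.alpha}\n"
                 f"sens_cutoff_ratio={config.sens_cutoff_ratio}\n")
    return summary
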