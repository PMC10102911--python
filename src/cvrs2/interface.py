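"""File I/O, end-to-end analysis, and the command-line surface.

Trial tables are CSV/TSV with one row per patient and columns ``id``,
``treat``, ``y1``, ``y2`` (optional in single-outcome mode), the covariate
columns, and optionally ``true_cluster``.  Reports are JSON; scores and
assignments are written as CSV with columns ``id, fold, rs1[, rs2],
cluster``.

Subcommands: ``simulate`` (write a scenario dataset), ``analyze``
(scores -> clusters -> tests), ``permute`` (permutation p-value for the
treatment-sensitivity interaction), ``opchar`` (Monte-Carlo operating
characteristics).  Exit codes: 0 success, 2 input error, 3 pipeline error.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from dataclasses import dataclass

import click
import numpy as np
import pandas as pd
import yaml

from ._exceptions import InputError, PipelineError
from .bivariate_model import FULL_SPEC, REDUCED_SPEC, BivariateModelSpec
from .inference import (
    TestConfig,
    interaction_test,
    overall_decision,
    permutation_pvalue,
    sensitive_group_test,
    trial_population_test,
)
from .risk_scores import (
    TrialDataset,
    cluster_scores,
    compute_cvrs2_scores,
    compute_cvrs_scores,
    make_folds,
)
from .simulate import scenario_preset, simulate_trial

__all__ = ["RunConfig", "read_trial_csv", "write_trial_csv", "analyze",
           "interaction_pipeline", "main"]

_RESERVED = ("id", "treat", "y1", "y2", "true_cluster")


@dataclass
class RunConfig:
    """Parameters of one analysis run; embedded verbatim in every report."""

    k: int = 2
    r_folds: int = 10
    model: str = "full"               # "full" (observed data) or "reduced"
    alpha1: float = 0.04
    alpha2: float = 0.01
    n_perm: int = 0
    seed: int = 0
    prefilter_alpha: float | None = None
    mode: str = "cvrs2"               # "cvrs2" or "cvrs1"/"cvrs2-marginal" variants

    def model_spec(self) -> BivariateModelSpec:
        if self.model == "full":
            return FULL_SPEC
        if self.model == "reduced":
            return REDUCED_SPEC
        raise InputError("model must be 'full' or 'reduced'")

    def test_config(self) -> TestConfig:
        return TestConfig(alpha1=self.alpha1, alpha2=self.alpha2)


def read_trial_csv(path, require_y2: bool = True) -> TrialDataset:
    """Read a patient-level trial table (CSV or TSV by extension)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    required = ["id", "treat", "y1"] + (["y2"] if require_y2 else [])
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required column(s) {missing}")
    covariate_cols = [c for c in df.columns if c not in _RESERVED]
    if not covariate_cols:
        raise InputError(f"{path}: no covariate columns found")
    if df.isna().any().any():
        row = int(df[df.isna().any(axis=1)].index[0])
        raise InputError(f"{path}: missing value at row {row}")
    for col in ("treat", "y1") + (("y2",) if "y2" in df.columns else ()):
        bad = ~df[col].isin((0, 1))
        if bad.any():
            raise InputError(
                f"{path}: column {col!r} must be binary 0/1; offending row "
                f"{int(df.index[bad][0])}")
    return TrialDataset(
        covariates=df[covariate_cols].to_numpy(dtype=float),
        treatment=df["treat"].to_numpy(),
        y1=df["y1"].to_numpy(),
        y2=df["y2"].to_numpy() if "y2" in df.columns else None,
        true_cluster=df["true_cluster"].to_numpy() if "true_cluster" in df.columns else None,
        covariate_names=covariate_cols,
    )


def write_trial_csv(data: TrialDataset, path) -> None:
    cols = {"id": np.arange(1, data.n_patients + 1),
            "treat": data.treatment, "y1": data.y1}
    if data.y2 is not None:
        cols["y2"] = data.y2
    if data.true_cluster is not None:
        cols["true_cluster"] = data.true_cluster
    for j, name in enumerate(data.covariate_names):
        cols[name] = data.covariates[:, j]
    # 17 significant digits + round_trip parsing make write/read lossless
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def _scores_frame(data, scores, assignment):
    df = pd.DataFrame({"id": np.arange(1, data.n_patients + 1),
                       "fold": scores.fold_of,
                       "rs1": scores.scores[:, 0]})
    if scores.d == 2:
        df["rs2"] = scores.scores[:, 1]
    df["cluster"] = assignment.label
    return df


def analyze(data: TrialDataset, run: RunConfig,
            scores_out=None, assignment_out=None) -> dict:
    """Full pipeline: folds -> cross-validated scores -> k-means clusters
    -> alpha-split tests (plus optional permutation inference).

    Returns a JSON-serializable report with per-cluster sizes, per-arm
    response rates, all test results and the run configuration.
    """
    from . import __version__

    spec = run.model_spec()
    cfg = run.test_config()
    ss = np.random.SeedSequence(run.seed)
    s_fold, s_km, s_perm = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(3)]
    folds = make_folds(data.n_patients, run.r_folds, s_fold)
    if run.mode == "cvrs1":
        scores = compute_cvrs_scores(data, 1, spec, folds,
                                     prefilter_alpha=run.prefilter_alpha)
    else:
        scores = compute_cvrs2_scores(data, spec, folds,
                                      prefilter_alpha=run.prefilter_alpha)
    assignment = cluster_scores(scores, run.k, s_km)

    outcomes = [("y1", data.y1)]
    if data.y2 is not None:
        outcomes.append(("y2", data.y2))

    report: dict = {
        "package_version": __version__,
        "run_config": dataclasses.asdict(run),
        "n_patients": int(data.n_patients),
        "n_covariates": int(data.n_covariates),
        "clusters": {},
        "tests": {"trial_population": {}, "sensitive_group": {}, "interaction": {}},
    }
    n_small = max(5, int(0.02 * data.n_patients))
    for c in range(1, run.k + 1):
        member = assignment.membership(c)
        entry = {
            "size": int(member.sum()),
            "n_control": int(np.sum(member & (data.treatment == 0))),
            "n_treatment": int(np.sum(member & (data.treatment == 1))),
            "near_empty": bool(member.sum() < n_small),
        }
        for name, y in outcomes:
            for arm, armname in ((0, "control"), (1, "treatment")):
                sel = member & (data.treatment == arm)
                entry[f"rate_{name}_{armname}"] = (
                    float(np.mean(y[sel])) if sel.any() else None)
        report["clusters"][str(c)] = entry
    if assignment.degenerate_folds:
        report["degenerate_folds"] = assignment.degenerate_folds
    # near-empty clusters or quadrant-labelling fallbacks both indicate the
    # scores support fewer than k clusters
    report["cluster_structure_warning"] = bool(
        assignment.fallback_folds
        or any(report["clusters"][str(c)]["near_empty"] for c in range(1, run.k + 1)))
    if assignment.fallback_folds:
        report["fallback_folds"] = assignment.fallback_folds

    sensitive = assignment.membership(run.k if run.k == 2 else 1)
    # for k=2 the sensitive group is cluster 2; for k=4 report per-cluster
    for name, y in outcomes:
        tp = trial_population_test(y, data.treatment, cfg.alpha1)
        report["tests"]["trial_population"][name] = _test_dict(tp)
        per_cluster = {}
        for c in range(1, run.k + 1):
            res = sensitive_group_test(y, data.treatment,
                                       assignment.membership(c), cfg.alpha2)
            entry = _test_dict(res)
            entry["overall_positive"] = overall_decision(tp, res)
            per_cluster[str(c)] = entry
        report["tests"]["sensitive_group"][name] = per_cluster
        report["tests"]["interaction"][name] = {
            str(c): _test_dict(interaction_test(
                y, data.treatment, assignment.membership(c)))
            for c in range(1, run.k + 1)}

    if run.n_perm > 0:
        report["permutation"] = {}
        for idx, (name, _) in enumerate(outcomes, start=1):
            closure = interaction_pipeline(run, outcome=idx,
                                           sensitive_cluster=2 if run.k == 2 else 1)
            res = permutation_pvalue(data, closure, run.n_perm, s_perm)
            report["permutation"][name] = {
                "p0": res.p0, "p_perm": res.p_perm, "n_perm": res.n_perm}

    if scores_out is not None:
        _scores_frame(data, scores, assignment).to_csv(scores_out, index=False)
    if assignment_out is not None:
        pd.DataFrame({"id": np.arange(1, data.n_patients + 1),
                      "cluster": assignment.label}).to_csv(assignment_out, index=False)
    return report


def _test_dict(res):
    return {"p_value": None if not np.isfinite(res.p_value) else float(res.p_value),
            "statistic": None if not np.isfinite(res.statistic) else float(res.statistic),
            "reject": bool(res.reject),
            "evaluable": bool(res.evaluable),
            "test": res.test_name}


def interaction_pipeline(run: RunConfig, outcome: int = 1,
                         sensitive_cluster: int | None = None):
    """Closure running scores -> clusters -> interaction test; suitable for
    :func:`cvrs2.inference.permutation_pvalue`."""
    spec = run.model_spec()
    cluster = sensitive_cluster if sensitive_cluster is not None else (
        2 if run.k == 2 else 1)

    def _run(data: TrialDataset, seed: int) -> float:
        ss = np.random.SeedSequence(seed)
        s_fold, s_km = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(2)]
        folds = make_folds(data.n_patients, run.r_folds, s_fold)
        if run.mode == "cvrs1":
            scores = compute_cvrs_scores(data, outcome, spec, folds,
                                         prefilter_alpha=run.prefilter_alpha)
        else:
            scores = compute_cvrs2_scores(data, spec, folds,
                                          prefilter_alpha=run.prefilter_alpha)
        assignment = cluster_scores(scores, run.k, s_km)
        y = data.y1 if outcome == 1 else data.y2
        res = interaction_test(y, data.treatment, assignment.membership(cluster))
        return res.p_value if res.evaluable else float("nan")

    return _run


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

_CONFIG_ALIASES = {"n": "n_patients", "input": "input_path", "overlap": "overlap",
                   "sensitive_fraction": "sensitive_fraction"}


def _apply_config_file(ctx, params):
    """Fill parameters left at their defaults from a YAML config file."""
    path = params.pop("config", None)
    if not path:
        return params
    with open(path) as fh:
        overrides = yaml.safe_load(fh) or {}
    for key, value in overrides.items():
        key = key.replace("-", "_")
        key = _CONFIG_ALIASES.get(key, key)
        if key in params and ctx.get_parameter_source(key) == click.core.ParameterSource.DEFAULT:
            params[key] = value
    return params


def _emit(report: dict, out):
    text = json.dumps(report, indent=2, sort_keys=True)
    if out:
        with open(out, "w") as fh:
            fh.write(text + "\n")
    else:
        click.echo(text)


@click.group()
@click.version_option()
def main():
    """Cross-validated (bivariate) risk-score trial design."""


_config_opt = click.option("--config", type=click.Path(exists=True), default=None,
                           help="YAML file supplying defaults for the options.")


@main.command("simulate")
@click.option("--scenario", default="I", show_default=True)
@click.option("--n", "n_patients", default=400, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--overlap", default=5, show_default=True)
@click.option("--sensitive-fraction", default=0.2, show_default=True)
@click.option("--out", required=True, type=click.Path())
@_config_opt
@click.pass_context
def simulate_cmd(ctx, **params):
    """Simulate a scenario trial and write it as CSV."""
    params = _apply_config_file(ctx, params)
    config = scenario_preset(params["scenario"], n_patients=params["n_patients"],
                             sensitive_fraction=params["sensitive_fraction"],
                             n_overlap=params["overlap"])
    data = simulate_trial(config, params["seed"])
    write_trial_csv(data, params["out"])
    click.echo(f"wrote {data.n_patients} patients x {data.n_covariates} covariates "
               f"to {params['out']}", err=True)


def _run_config_from(params):
    return RunConfig(k=params["k"], r_folds=params["r_folds"], model=params["model"],
                     alpha1=params["alpha1"], alpha2=params["alpha2"],
                     n_perm=params.get("n_perm", 0), seed=params["seed"],
                     prefilter_alpha=params.get("prefilter_alpha"))


@main.command("analyze")
@click.option("--input", "input_path", required=True, type=click.Path(exists=True))
@click.option("--k", default=2, show_default=True)
@click.option("--r-folds", default=10, show_default=True)
@click.option("--model", default="full", show_default=True,
              type=click.Choice(["full", "reduced"]))
@click.option("--alpha1", default=0.04, show_default=True)
@click.option("--alpha2", default=0.01, show_default=True)
@click.option("--n-perm", default=0, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--prefilter-alpha", default=None, type=float,
              help="Keep covariates with training-fold univariate interaction "
                   "p below this threshold (off by default).")
@click.option("--out", default=None, type=click.Path())
@click.option("--scores-out", default=None, type=click.Path())
@click.option("--assignment-out", default=None, type=click.Path())
@_config_opt
@click.pass_context
def analyze_cmd(ctx, **params):
    """Run the full scoring/clustering/testing pipeline on a trial CSV."""
    params = _apply_config_file(ctx, params)
    run = _run_config_from(params)
    data = read_trial_csv(params["input_path"])
    report = analyze(data, run, scores_out=params["scores_out"],
                     assignment_out=params["assignment_out"])
    _emit(report, params["out"])


@main.command("permute")
@click.option("--input", "input_path", required=True, type=click.Path(exists=True))
@click.option("--n-perm", default=99, show_default=True)
@click.option("--k", default=2, show_default=True)
@click.option("--r-folds", default=10, show_default=True)
@click.option("--model", default="full", show_default=True,
              type=click.Choice(["full", "reduced"]))
@click.option("--alpha1", default=0.04, show_default=True)
@click.option("--alpha2", default=0.01, show_default=True)
@click.option("--outcome", default=1, show_default=True)
@click.option("--cluster", default=None, type=int,
              help="Cluster assumed sensitive (default: 2 for k=2, 1 for k=4).")
@click.option("--seed", default=0, show_default=True)
@click.option("--out", default=None, type=click.Path())
@_config_opt
@click.pass_context
def permute_cmd(ctx, **params):
    """Permutation p-value for the treatment-sensitivity interaction."""
    params = _apply_config_file(ctx, params)
    run = _run_config_from(params)
    data = read_trial_csv(params["input_path"])
    closure = interaction_pipeline(run, outcome=params["outcome"],
                                   sensitive_cluster=params["cluster"])
    res = permutation_pvalue(data, closure, params["n_perm"], params["seed"])
    _emit({"p0": res.p0, "p_perm": res.p_perm, "n_perm": res.n_perm,
           "seed": res.seed, "run_config": dataclasses.asdict(run)}, params["out"])


@main.command("opchar")
@click.option("--scenario", default="I", show_default=True)
@click.option("--n", "n_patients", default=400, show_default=True)
@click.option("--k", default=2, show_default=True)
@click.option("--reps", default=100, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--overlap", default=5, show_default=True)
@click.option("--sensitive-fraction", default=0.2, show_default=True)
@click.option("--out", default=None, type=click.Path(),
              help="CSV of the tidy operating-characteristics table.")
@click.option("--json-out", default=None, type=click.Path())
@_config_opt
@click.pass_context
def opchar_cmd(ctx, **params):
    """Monte-Carlo operating characteristics for a named scenario."""
    from . import __version__
    from .evaluate import run_operating_characteristics

    params = _apply_config_file(ctx, params)
    config = scenario_preset(params["scenario"], n_patients=params["n_patients"],
                             sensitive_fraction=params["sensitive_fraction"],
                             n_overlap=params["overlap"])
    oc = run_operating_characteristics(config, k=params["k"],
                                       n_reps=params["reps"], seed=params["seed"])
    frame = oc.to_frame()
    if params["out"]:
        frame.to_csv(params["out"], index=False)
    else:
        click.echo(frame.to_string(index=False))
    if params["json_out"]:
        summary = {
            "package_version": __version__,
            "scenario": params["scenario"], "n": params["n_patients"],
            "k": params["k"], "n_reps": oc.n_reps, "seed": params["seed"],
            "n_failures": oc.n_failures,
            "power_tp": oc.power_tp.tolist(),
            "power_sens": oc.power_sens.tolist(),
            "power_overall": oc.power_overall.tolist(),
            "selection_sensitivity": oc.selection_sensitivity.tolist(),
            "selection_specificity": oc.selection_specificity.tolist(),
            "est_rate": np.where(np.isfinite(oc.est_rate), oc.est_rate, None).tolist(),
        }
        with open(params["json_out"], "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)


def _cli_entry():  # pragma: no cover - exercised via console script
    try:
        main(standalone_mode=False)
    except click.ClickException as exc:
        exc.show()
        sys.exit(exc.exit_code)
    except click.Abort:
        sys.exit(130)
    except InputError as exc:
        click.echo(f"input error: {exc}", err=True)
        sys.exit(2)
    except PipelineError as exc:
        click.echo(f"pipeline error: {exc}", err=True)
        sys.exit(3)


if __name__ == "__main__":  # pragma: no cover
    _cli_entry()
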