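"""Reproducible run harness tying the pipeline stages together.

Each subcommand (``simulate``, ``preprocess``, ``train``, ``evaluate``,
``report``) reads the artifacts of its upstream stage from a run directory
scoped by the configuration digest, writes its own artifacts plus a manifest,
and is deterministic given the same inputs, config and seed. Timestamps live
only in the manifest so reports are byte-identical across reruns.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifier, evaluate, io, mrgf, preprocess, simulate
from .config import PipelineConfig, stage_seed

__all__ = ["run", "preprocess_cohort", "evaluate_cohort"]

SUBCOMMANDS = ("simulate", "preprocess", "train", "evaluate", "report")
UPSTREAM = {"preprocess": "simulate", "train": "preprocess", "evaluate": "train", "report": "evaluate"}


class MissingArtifactError(FileNotFoundError):
    pass


def _require(path: Path, producer: str):
    if not path.exists():
        raise MissingArtifactError(
            f"missing artifact {path.name}: run the {producer!r} subcommand first"
        )
    return path


def _labels(meta: pd.DataFrame) -> np.ndarray:
    return np.where(meta["class"].to_numpy() == "OC", "OC", "control")


def preprocess_cohort(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    config: PipelineConfig,
    gene_set=None,
    n_sv_max: int = 5,
):
    """QC + normalization + confounder correction for one cohort.

    ``gene_set`` pins the retained genes (validation cohorts reuse the
    training cohort's gene set so panel genes are always present); otherwise
    the cohort's own gene filters apply. The nuisance design holds age
    (cohort-median imputed), log10 raw total reads, batch indicators and the
    surrogate variables, with the OC/control contrast protected.
    """
    log_total = np.log10(counts.sum(axis=0).astype(float))  # before sample filtering
    filtered, sample_report = preprocess.filter_samples(counts, min_total=config.sample_min_reads)
    meta = meta.set_index("sample_id").loc[list(filtered.columns)].reset_index()
    if gene_set is None:
        filtered, gene_report = preprocess.filter_genes(
            filtered,
            min_reads=config.gene_min_reads,
            max_low_frac=config.gene_max_low_frac,
            cv_max=config.gene_cv_max,
        )
    else:
        filtered = filtered.loc[[g for g in gene_set if g in filtered.index]]
        gene_report = None
    sf = preprocess.size_factors(filtered)
    expr = preprocess.vst(filtered, sf)
    labels = _labels(meta)

    sv = preprocess.estimate_surrogates(
        expr, labels, n_sv_max=n_sv_max, seed=stage_seed(config.seed, "sva")
    )
    age = meta["age"].astype(float)
    if age.isna().any():
        warnings.warn(f"imputing {int(age.isna().sum())} missing ages with the cohort median")
        age = age.fillna(age.median())
    nuisance = pd.DataFrame({"age": age.to_numpy(), "log_total_reads": log_total.loc[filtered.columns].to_numpy()})
    batches = pd.get_dummies(meta["batch"], drop_first=True, dtype=float)
    nuisance = pd.concat([nuisance, batches.reset_index(drop=True)], axis=1)
    if sv.k > 0:
        nuisance = pd.concat([nuisance, sv.surrogates.reset_index(drop=True)], axis=1)
    corrected = preprocess.remove_nuisance(expr, nuisance, labels)
    reports = {
        "samples": sample_report,
        "genes": gene_report,
        "n_surrogates": sv.k,
    }
    return corrected, meta, reports


def evaluate_cohort(
    meta: pd.DataFrame,
    tep_probs: pd.Series,
    combined_probs: pd.Series,
    config: PipelineConfig,
) -> dict:
    """Marker-level diagnostic report for one cohort (TEP, CA125, combined)."""
    y = (meta["class"].to_numpy() == "OC").astype(int)
    ca = meta["ca125"].to_numpy(dtype=float)
    tep = tep_probs.to_numpy(dtype=float)
    comb = combined_probs.to_numpy(dtype=float)
    ca_ok = ~np.isnan(ca)

    out = {"n_pos": int(y.sum()), "n_neg": int(len(y) - y.sum()), "markers": {}}
    marker_scores = {"tep": (tep, tep >= config.threshold)}
    if ca_ok.any() and len(np.unique(y[ca_ok])) == 2:
        marker_scores["ca125"] = (ca, ca >= config.ca125_cutoff)
    marker_scores["combined"] = (comb, comb >= config.threshold)

    for name, (scores, calls) in marker_scores.items():
        if name == "ca125":
            m = evaluate._marker_metrics(scores[ca_ok], calls[ca_ok], y[ca_ok])
        else:
            m = evaluate._marker_metrics(scores, calls, y)
        if "ca125" in marker_scores and name != "ca125" and ca_ok.sum() >= 4 and len(np.unique(y[ca_ok])) == 2:
            _, p = evaluate.delong_test(scores[ca_ok], ca[ca_ok], y[ca_ok])
            m.auc_pvalue = p
        out["markers"][name] = m

    sn, sp_att, thr = evaluate.sens_at_spec(tep, y, spec=config.fixed_specificity)
    out["tep_sens_at_fixed_spec"] = {"sensitivity": sn, "specificity": sp_att, "threshold": thr}
    out["tep_permutation_p"] = evaluate.permutation_test(
        tep, y, B=config.permutation_B, seed=stage_seed(config.seed, "permutation")
    )
    out["calibration"] = evaluate.calibration_curve(tep, y).to_dict(orient="records")
    dc = evaluate.decision_curve(tep, y, np.linspace(0.05, 0.95, 19))
    out["decision_curve"] = {
        "thresholds": dc.thresholds.tolist(),
        "net_benefit": dc.net_benefit.tolist(),
        "treat_all": dc.treat_all.tolist(),
    }
    return out


# ---------------------------------------------------------------------------
# the run() harness
# ---------------------------------------------------------------------------


def _digest_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_manifest(run_dir: Path, config: PipelineConfig, stage: str, t0: float, inputs: list):
    manifest = {
        "stage": stage,
        "config_digest": config.digest(),
        "config": asdict(config),
        "seed": config.seed,
        "elapsed_s": round(time.time() - t0, 3),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "input_digests": {p.name: _digest_file(p) for p in inputs if p.exists()},
    }
    (run_dir / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=1))


def run(
    config: PipelineConfig,
    subcommand: str,
    workdir,
    sim_config: simulate.SimConfig | None = None,
) -> Path:
    """Execute one pipeline stage inside ``workdir/<config digest>``.

    Returns the run directory. Artifact filenames are fixed so downstream
    stages can locate their inputs; a stage raises
    :class:`MissingArtifactError` naming the producing subcommand when its
    upstream artifacts are absent.
    """
    if subcommand not in SUBCOMMANDS:
        raise ValueError(f"unknown subcommand {subcommand!r}; expected one of {SUBCOMMANDS}")
    config.validate()
    t0 = time.time()
    run_dir = Path(workdir) / config.digest()
    run_dir.mkdir(parents=True, exist_ok=True)
    data_dir = run_dir / "data"

    if subcommand == "simulate":
        sim = sim_config or simulate.default_config(seed=stage_seed(config.seed, "simulate"))
        study = simulate.simulate_study(sim)
        io.write_study(study, data_dir)
        cohort_names = [c.name for c in sim.cohorts]
        (run_dir / "cohorts.json").write_text(json.dumps(cohort_names))
        _write_manifest(run_dir, config, "simulate", t0, [])
        return run_dir

    cohorts = json.loads(_require(run_dir / "cohorts.json", "simulate").read_text())
    training, validations = cohorts[0], cohorts[1:]

    if subcommand == "preprocess":
        gene_set = None
        for name in cohorts:
            counts = io.read_counts(_require(data_dir / f"{name}_counts.tsv", "simulate"))
            meta = io.read_metadata(data_dir / f"{name}_meta.csv", counts)
            expr, meta2, _ = preprocess_cohort(counts, meta, config, gene_set=gene_set)
            if name == training:
                gene_set = list(expr.values.index)
            expr.values.to_csv(run_dir / f"{name}_expr.tsv", sep="\t")
            io.write_metadata(meta2, run_dir / f"{name}_meta_qc.csv")
        _write_manifest(run_dir, config, "preprocess", t0, [data_dir / f"{n}_counts.tsv" for n in cohorts])
        return run_dir

    if subcommand == "train":
        expr_path = _require(run_dir / f"{training}_expr.tsv", "preprocess")
        expr = pd.read_csv(expr_path, sep="\t", index_col=0)
        meta = io.read_metadata(run_dir / f"{training}_meta_qc.csv")
        counts = io.read_counts(data_dir / f"{training}_counts.tsv").loc[expr.index, expr.columns]
        labels = _labels(meta)
        params = mrgf.MrgfParams(
            correlation_cutoff=config.correlation_cutoff,
            n_lambda=config.n_lambda,
            folds=config.folds,
            mrmr_bins=config.mrmr_bins,
            n_boot=config.mrmr_n_boot,
            seed=stage_seed(config.seed, "mrgf"),
        )
        panel = mrgf.run_mrgf(
            preprocess.ExprMatrix(expr, "precomputed", preprocess.size_factors(counts)),
            labels,
            params,
            counts=counts,
        )
        X = expr.loc[panel.genes].T
        hp = classifier.tune_svm(
            X, labels, n_draws=config.svm_n_draws, folds=config.folds,
            seed=stage_seed(config.seed, "tune"),
        )
        model = classifier.train_svm(X, labels, hp, seed=stage_seed(config.seed, "platt"))
        model.threshold = config.threshold
        tep_probs, _ = classifier.predict(model, X)
        combiner = classifier.fit_combiner(tep_probs, meta["ca125"], labels)

        (run_dir / "model.json").write_text(classifier.model_to_json(model))
        (run_dir / "combiner.json").write_text(json.dumps(asdict(combiner)))
        pd.DataFrame(
            {
                "rank": range(1, len(panel.genes) + 1),
                "gene_id": panel.genes,
            }
        ).merge(panel.mrmr_scores, on="gene_id", how="left", suffixes=("", "_mrmr")).to_csv(
            run_dir / "panel.tsv", sep="\t", index=False
        )
        (run_dir / "panel_provenance.json").write_text(
            json.dumps(
                {
                    "stage_sizes": panel.stage_sizes,
                    "cv_accuracy_curve": {int(k): v for k, v in panel.cv_accuracy_curve.items()},
                    "hyperparams": {"cost": hp.cost, "sigma": hp.sigma},
                },
                indent=1,
            )
        )
        _write_manifest(run_dir, config, "train", t0, [expr_path])
        return run_dir

    if subcommand == "evaluate":
        model = classifier.model_from_json(_require(run_dir / "model.json", "train").read_text())
        combiner_d = json.loads(_require(run_dir / "combiner.json", "train").read_text())
        combiner = classifier.CombinedModel(**combiner_d)
        report = {}
        pooled = []
        for name in validations:
            expr = pd.read_csv(_require(run_dir / f"{name}_expr.tsv", "preprocess"), sep="\t", index_col=0)
            meta = io.read_metadata(run_dir / f"{name}_meta_qc.csv")
            probs, _ = classifier.predict(model, expr.T)
            ca = pd.Series(meta.set_index("sample_id").loc[probs.index, "ca125"].to_numpy(), index=probs.index)
            comb = classifier.predict_combined(combiner, probs, ca)
            report[name] = evaluate_cohort(meta, probs, comb, config)
            pooled.append((meta, probs, comb))
        meta_all = pd.concat([m for m, _, _ in pooled], ignore_index=True)
        probs_all = pd.concat([p for _, p, _ in pooled])
        comb_all = pd.concat([c for _, _, c in pooled])
        report["all_validation"] = evaluate_cohort(meta_all, probs_all, comb_all, config)
        meta_idx = meta_all.set_index(probs_all.index)
        report["subgroups"] = {
            name: {
                "n_pos": entry["n_pos"],
                "n_neg": entry["n_neg"],
                "markers": {k: m.as_dict() for k, m in entry["markers"].items()},
            }
            for name, entry in evaluate.subgroup_report(
                meta_idx, probs_all, meta_idx["ca125"], comb_all, threshold=config.threshold
            ).items()
        }
        for name in list(report):
            if name != "subgroups" and isinstance(report[name].get("markers"), dict):
                report[name]["markers"] = {k: m.as_dict() for k, m in report[name]["markers"].items()}
        (run_dir / "diagnostic_report.json").write_text(json.dumps(report, indent=1, default=float))
        _write_manifest(run_dir, config, "evaluate", t0, [run_dir / "model.json"])
        return run_dir

    # report: human-readable TSV mirroring the diagnostic-table column order
    rep_path = _require(run_dir / "diagnostic_report.json", "evaluate")
    report = json.loads(rep_path.read_text())
    rows = []
    for cohort, entry in report.items():
        if cohort == "subgroups":
            continue
        for marker, m in entry["markers"].items():
            rows.append(
                {
                    "cohort": cohort,
                    "marker": marker,
                    "auc": m["auc"],
                    "auc_ci_low": m["auc_ci"][0],
                    "auc_ci_high": m["auc_ci"][1],
                    "acc": m["acc"],
                    "sn": m["sn"],
                    "sp": m["sp"],
                    "ppv": m["ppv"],
                    "npv": m["npv"],
                    "kappa": m["kappa"],
                    "f1": m["f1"],
                    "auc_pvalue": m["auc_pvalue"],
                }
            )
    pd.DataFrame(rows).to_csv(run_dir / "diagnostic_report.tsv", sep="\t", index=False)
    _write_manifest(run_dir, config, "report", t0, [rep_path])
    return run_dir
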