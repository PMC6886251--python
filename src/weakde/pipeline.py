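"""End-to-end orchestration: preprocess → screen → classify → evaluate.

A run is driven by one config mapping (YAML/JSON-friendly) and leaves a
directory of file-mediated stage outputs plus a manifest that records the
config snapshot, seeds, package versions and timings, so a run can be
reproduced bit-for-bit from its manifest.

The gene-view transposition — genes become the data points for the
difference-kernel/TSVM stage, samples having been the data points during
screening — happens exactly once, here.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .io import (filter_low_variance, filter_unexpressed,
                 normalize_samples, read_expression_table, read_gene_labels,
                 write_expression_table)
from .l21 import L21Params
from .screening import (GBDTConfig, ScreeningResult,
                        default_single_label_config,
                        default_two_label_configs, run_screening,
                        run_two_label)
from .diffkernel import gram as diff_gram
from .evaluation import kfold_cv
from .synth import config_from_dict, generate, write_fixture
from .tsvm import (TSVMParams, fit_tsvm, linear_gram, predict_disease_genes,
                   rbf_gram)

__all__ = ["RunManifest", "run_pipeline", "gene_gram", "tsvm_cv_accuracy"]


@dataclass
class RunManifest:
    config: dict
    seed: int
    versions: dict
    outputs: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"config": self.config, "seed": self.seed,
             "versions": self.versions, "outputs": self.outputs,
             "timings": self.timings}, indent=1, default=str))


def gene_gram(
    genes_a: np.ndarray,
    genes_b: np.ndarray | None,
    sample_qs: np.ndarray,
    q_order,
    kernel: str,
    rbf_bandwidth: float | None = None,
) -> np.ndarray:
    """Gram matrix between gene expression rows under the named kernel."""
    if kernel == "difference":
        return diff_gram(genes_a, genes_a if genes_b is None else genes_b,
                         sample_qs, q_order)
    if kernel == "linear":
        return linear_gram(genes_a, genes_b)
    if kernel == "rbf":
        return rbf_gram(genes_a, genes_b, bandwidth=rbf_bandwidth)
    raise ValueError(f"unknown kernel {kernel!r}")


def tsvm_cv_accuracy(
    gene_rows: np.ndarray,
    y: np.ndarray,
    sample_qs: np.ndarray,
    q_order,
    kernel: str,
    k: int = 10,
    seed: int = 0,
    c: float = 1.0,
    rbf_bandwidth: float | None = None,
):
    """Stratified k-fold CV of a TSVM on labeled genes.

    Each fold's test genes enter the TSVM as the unlabeled set (the
    transductive setting), with the positive fraction taken from the
    training fold; accuracy scores the transduced labels against truth.
    """
    y = np.asarray(y, float)
    k_all = gene_gram(gene_rows, None, sample_qs, q_order, kernel,
                      rbf_bandwidth)

    def fit_predict(train_idx, test_idx):
        idx = np.concatenate([train_idx, test_idx])
        sub = k_all[np.ix_(idx, idx)]
        model = fit_tsvm(sub, y[train_idx], TSVMParams(c=c))
        return model.decision_unlabeled, model.transduced_labels

    return kfold_cv(np.arange(len(y)), y, fit_predict, k=k, seed=seed)


def _load_input(cfg: dict, out: Path, manifest: RunManifest):
    if "synth" in cfg:
        scfg = config_from_dict(cfg["synth"])
        x, truth = generate(scfg)
        paths = write_fixture(x, truth, out / "input")
        manifest.outputs["input"] = {k: str(v) for k, v in paths.items()}
        return x, truth.labels
    inp = cfg["input"]
    x = read_expression_table(inp["expression"])
    labels = read_gene_labels(inp["labels"])
    manifest.outputs["input"] = dict(inp)
    return x, labels


def run_pipeline(cfg: dict | str | Path) -> RunManifest:
    """Execute the full mining pipeline from a config mapping or YAML path.

    Stages: load/synthesize data, preprocess, weakly supervised DE
    screening (two-label or single-label scheme), difference-kernel TSVM
    classification of the DE genes, and k-fold CV evaluation of the
    configured kernels on the labeled gene panel.  Every stage writes its
    artifact under ``cfg["out"]``; errors abort with the stage name while
    earlier outputs remain on disk.
    """
    if not isinstance(cfg, dict):
        cfg = yaml.safe_load(Path(cfg).read_text())
    out = Path(cfg.get("out", "weakde_run"))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    manifest = RunManifest(
        config=cfg, seed=seed,
        versions={"weakde": __version__, "numpy": np.__version__},
    )

    stage = "input"
    try:
        t0 = time.perf_counter()
        x_raw, labels = _load_input(cfg, out, manifest)
        manifest.timings[stage] = time.perf_counter() - t0

        stage = "preprocess"
        t0 = time.perf_counter()
        pp = cfg.get("preprocess", {})
        x = filter_unexpressed(x_raw, pp.get("zero_filter", "all"))
        keep = pp.get("variance_keep")
        if keep:
            x = filter_low_variance(x, int(keep))
        x = normalize_samples(x, pp.get("normalize", "zscore"))
        write_expression_table(x, out / "preprocessed.tsv")
        manifest.outputs["preprocessed"] = str(out / "preprocessed.tsv")
        manifest.timings[stage] = time.perf_counter() - t0

        stage = "screen"
        t0 = time.perf_counter()
        sc = cfg.get("screen", {})
        l21 = L21Params(**sc.get("l21", {}))
        gbdt = GBDTConfig(seed=int(sc.get("classifier_seed", seed)),
                          **sc.get("classifier", {}))
        knobs = dict(m_genes=int(sc.get("m_genes", 1500)),
                     theta=float(sc.get("theta", 0.05)),
                     max_rounds=int(sc.get("max_rounds", 10)))
        scheme = sc.get("scheme", "two-label")
        if scheme == "two-label":
            cfg_late, cfg_mid = default_two_label_configs(
                gbdt, q_order=x.q_order, **knobs)
            late, mid, de_set = run_two_label(x, cfg_late, cfg_mid, l21)
            _write_trace(late, out / "trace_late.tsv")
            _write_trace(mid, out / "trace_mid.tsv")
        elif scheme == "single-label":
            cfg_one = default_single_label_config(gbdt, q_order=x.q_order,
                                                  **knobs)
            res = run_screening(x, cfg_one, l21)
            _write_trace(res, out / "trace.tsv")
            de_set = res.de_genes
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
        (out / "de_genes.txt").write_text(
            "\n".join(sorted(de_set)) + "\n")
        manifest.outputs["de_genes"] = str(out / "de_genes.txt")
        manifest.timings[stage] = time.perf_counter() - t0

        stage = "classify"
        t0 = time.perf_counter()
        cl = cfg.get("classify", {})
        kernel = cl.get("kernel", "difference")
        gid_index = x.gene_index()
        labeled = sorted((labels.positives | labels.negatives) & set(x.gene_ids))
        unlabeled = sorted(de_set - set(labeled))
        y_lab = np.array([1.0 if g in labels.positives else -1.0
                          for g in labeled])
        rows = x.values[[gid_index[g] for g in labeled + unlabeled]]
        k_full = gene_gram(rows, None, x.sample_qs, x.q_order, kernel,
                           cl.get("rbf_bandwidth"))
        params = TSVMParams(c=float(cl.get("c", 1.0)),
                            pos_fraction=cl.get("pos_fraction"))
        model = fit_tsvm(k_full, y_lab, params)
        preds = predict_disease_genes(model, unlabeled)
        with (out / "predictions.tsv").open("w") as fh:
            fh.write("gene_id\tdecision_value\tpredicted_label\n")
            for gid, f, lbl in preds:
                fh.write(f"{gid}\t{f:.6g}\t{lbl}\n")
        manifest.outputs["predictions"] = str(out / "predictions.tsv")
        manifest.outputs["n_predicted_disease"] = sum(
            1 for _, _, lbl in preds if lbl > 0)
        manifest.timings[stage] = time.perf_counter() - t0

        stage = "evaluate"
        t0 = time.perf_counter()
        ev = cfg.get("evaluate", {})
        metrics = {}
        lab_rows = x.values[[gid_index[g] for g in labeled]]
        for kname in ev.get("kernels", ["difference", "linear", "rbf"]):
            rep = tsvm_cv_accuracy(
                lab_rows, y_lab, x.sample_qs, x.q_order, kname,
                k=int(ev.get("k", 10)), seed=seed,
                c=float(cl.get("c", 1.0)))
            metrics[kname] = {
                "mean_accuracy": rep.mean_accuracy,
                "fold_accuracies": rep.fold_accuracies,
                "auc": rep.auc,
                "aupr": rep.aupr,
            }
        (out / "metrics.json").write_text(json.dumps(metrics, indent=1))
        manifest.outputs["metrics"] = str(out / "metrics.json")
        manifest.timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest.write(out / "manifest.json")
    manifest.outputs["manifest"] = str(out / "manifest.json")
    return manifest


def _write_trace(res: ScreeningResult, path: Path) -> None:
    with path.open("w") as fh:
        fh.write("round\tn_added\tn_absorbed\tupdate_fraction\n")
        for rec in res.trace:
            fh.write(f"{rec.round}\t{rec.n_added}\t{rec.n_absorbed}"
                     f"\t{rec.update_fraction:.6g}\n")
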