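"""End-to-end pipeline orchestration with manifests.

A :class:`PipelineConfig` names the inputs, the stage parameters and a mode;
:func:`run_pipeline` executes the mode's stage chain, writes every stage
output under the output directory and finishes with an atomically written
:class:`RunManifest` (config snapshot, input hashes, seed, wall times,
warnings).  All stochastic stages draw from the manifest seed, so re-running
from a manifest reproduces deterministic outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .discovery import (
    differential_expression,
    discover_signature,
    hps_signature,
    Signature,
    validate_signature,
)
from .io import (
    load_clinical,
    load_expression,
    load_gmt,
    save_cohort,
    write_gmt,
    write_scores,
)
from .scoring import fibroblast_geneset, ssgsea_score
from .simulate import CohortConfig, generate_cohort
from .survival import StratumLabels, median_split, optimal_cox_cutoff, top_fraction_split

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]

MODES = ("simulate", "score", "stratify", "gsea", "discover", "validate", "de", "report")

_KNOWN_KEYS = {
    "mode", "out_dir", "seed", "expression", "clinical", "genesets", "labels",
    "signature_name", "fibroblast_set", "alpha", "weight_p", "n_perm",
    "q_threshold", "min_sets", "p_uni", "p_multi", "horizon_months",
    "stratify_method", "top_fraction", "min_tail_frac", "covariates",
    "cohort", "logfc_threshold", "de_p_adj", "duplicates",
}


@dataclass
class PipelineConfig:
    mode: str
    out_dir: str
    seed: int = 0
    expression: str | None = None
    clinical: str | None = None
    genesets: str | None = None
    labels: str | None = None  # TSV with sample, label columns
    signature_name: str | None = None  # gene set to use as signature (default: shipped 7-gene)
    fibroblast_set: str = "MCP_FIBROBLAST"
    alpha: float = 0.25
    weight_p: float = 1.0
    n_perm: int = 1000
    q_threshold: float = 0.15
    min_sets: int = 2
    p_uni: float = 0.20
    p_multi: float = 0.05
    horizon_months: float = 60.0
    stratify_method: str = "optimal_cox"  # or top_fraction / median
    top_fraction: float = 0.20
    min_tail_frac: float = 0.10
    covariates: tuple[str, ...] = ()
    cohort: dict = field(default_factory=dict)  # CohortConfig overrides for simulate
    logfc_threshold: float = 2.0
    de_p_adj: float = 0.001
    duplicates: str = "error"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.n_perm < 100:
            raise ValueError("n_perm must be at least 100")
        for name, lo, hi, closed in (
            ("q_threshold", 0, 1, False), ("p_uni", 0, 1, True), ("p_multi", 0, 1, True),
            ("top_fraction", 0, 1, False), ("min_tail_frac", 0, 0.5, False), ("alpha", 0, 5, False),
        ):
            v = getattr(self, name)
            ok = (lo < v <= hi) if closed else (lo < v < hi)
            if not ok:
                raise ValueError(f"{name}={v} outside its legal range ({lo}, {hi})")
        if self.horizon_months <= 0:
            raise ValueError("horizon_months must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown pipeline-config keys: {sorted(unknown)}")
        d = dict(d)
        if "covariates" in d:
            d["covariates"] = tuple(d["covariates"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    input_hashes: dict[str, str]
    stage_seconds: dict[str, float]
    warnings: list[str]
    outputs: dict[str, str]

    def write(self, path: str | Path) -> None:
        path = Path(path)
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True, default=str))
        os.replace(tmp, path)


def _hash_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_labels(path: str | Path) -> StratumLabels:
    df = pd.read_csv(path, sep="\t")
    labels = pd.Series(df["label"].to_numpy(), index=df["sample"])
    return StratumLabels(labels=labels, cutoff=float("nan"), method="file")


def _write_labels(labels: StratumLabels, path: Path) -> None:
    pd.DataFrame({"sample": labels.labels.index, "label": labels.labels.values}).to_csv(
        path, sep="\t", index=False
    )


def _stratify(cfg: PipelineConfig, expr, surv, sets) -> StratumLabels:
    if cfg.labels:
        return _load_labels(cfg.labels)
    fset = fibroblast_geneset(sets[cfg.fibroblast_set])
    score = ssgsea_score(expr, fset, alpha=cfg.alpha)
    if cfg.stratify_method == "optimal_cox":
        return optimal_cox_cutoff(score, surv, min_tail_frac=cfg.min_tail_frac)
    if cfg.stratify_method == "top_fraction":
        return top_fraction_split(score, cfg.top_fraction)
    if cfg.stratify_method == "median":
        return median_split(score)
    raise ValueError(f"unknown stratify_method {cfg.stratify_method!r}")


def run_pipeline(config: PipelineConfig) -> RunManifest:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    hashes: dict[str, str] = {}
    for key in ("expression", "clinical", "genesets", "labels"):
        p = getattr(config, key)
        if p:
            if not Path(p).exists():
                raise FileNotFoundError(f"{key} input not found: {p}")
            hashes[key] = _hash_file(p)
    stage_seconds: dict[str, float] = {}
    outputs: dict[str, str] = {}
    caught: list[str] = []

    def _run(stage: str, fn):
        t0 = time.perf_counter()
        with warnings.catch_warnings(record=True) as ws:
            warnings.simplefilter("always")
            try:
                result = fn()
            except Exception as exc:
                manifest = RunManifest(
                    config=dataclasses.asdict(config), version=__version__, seed=config.seed,
                    input_hashes=hashes, stage_seconds=stage_seconds,
                    warnings=caught + [f"stage {stage} failed: {exc}"], outputs=outputs,
                )
                manifest.write(out_dir / "manifest.partial.json")
                raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
            caught.extend(f"{stage}: {w.message}" for w in ws)
        stage_seconds[stage] = round(time.perf_counter() - t0, 3)
        return result

    mode = config.mode
    if mode == "simulate":
        cc = CohortConfig.from_dict({**config.cohort, "seed": config.seed})
        cohort = _run("simulate", lambda: generate_cohort(cc))
        paths = _run("write", lambda: save_cohort(cohort, out_dir))
        (out_dir / "report.json").write_text(json.dumps(cohort.report, indent=1, default=float))
        outputs.update(paths, report=str(out_dir / "report.json"))
    elif mode in ("score", "stratify", "gsea", "discover", "validate", "de"):
        expr = _run("load_expression", lambda: load_expression(config.expression, duplicates=config.duplicates))
        sets = _run("load_genesets", lambda: load_gmt(config.genesets)) if config.genesets else {}
        surv = _run("load_clinical", lambda: load_clinical(config.clinical)) if config.clinical else None

        if mode == "score":
            for name, gs in sets.items():
                sv = _run(f"score:{name}", lambda gs=gs: ssgsea_score(expr, gs, alpha=config.alpha))
                p = out_dir / f"score_{name}.tsv"
                write_scores(sv, p)
                outputs[f"score_{name}"] = str(p)
        else:
            labels = _run("stratify", lambda: _stratify(config, expr, surv, sets))
            _write_labels(labels, out_dir / "strata.tsv")
            outputs["strata"] = str(out_dir / "strata.tsv")
            if mode == "stratify":
                pass
            elif mode == "gsea":
                from .gsea import gsea as _gsea
                from .survival import relapse_labels

                idx = labels.high.intersection(surv.index)
                rl = relapse_labels(surv.loc[idx], horizon_months=config.horizon_months)
                res = _run("gsea", lambda: _gsea(expr[idx], rl, sets, n_perm=config.n_perm,
                                                 seed=config.seed, weight_p=config.weight_p))
                tab = res.table.copy()
                tab["leading_edge"] = [";".join(res.leading_edges[n]) for n in tab.index]
                tab.to_csv(out_dir / "gsea.tsv", sep="\t")
                outputs["gsea"] = str(out_dir / "gsea.tsv")
            elif mode == "discover":
                rep = _run("discover", lambda: discover_signature(
                    expr, surv, sets, labels, covariates=list(config.covariates) or None,
                    horizon_months=config.horizon_months, q_threshold=config.q_threshold,
                    min_sets=config.min_sets, n_perm=config.n_perm, seed=config.seed,
                    p_uni=config.p_uni, p_multi=config.p_multi))
                rep.gsea_table.to_csv(out_dir / "gsea.tsv", sep="\t")
                rep.per_gene.to_csv(out_dir / "per_gene_cox.tsv", sep="\t")
                summary = {
                    "signature": list(rep.signature.genes),
                    "candidates": list(rep.candidates),
                    "unmeasured": list(rep.unmeasured),
                    "thresholds": rep.thresholds,
                    "n_relapse": int((rep.relapse.labels == 1).sum()),
                    "n_non_relapse": int((rep.relapse.labels == 0).sum()),
                    "excluded_late_events": list(rep.relapse.excluded),
                }
                (out_dir / "discovery.json").write_text(json.dumps(summary, indent=1, default=str))
                if len(rep.signature):
                    write_gmt({rep.signature.name: rep.signature.as_geneset()},
                              out_dir / "signature.gmt")
                    outputs["signature"] = str(out_dir / "signature.gmt")
                outputs.update(gsea=str(out_dir / "gsea.tsv"),
                               per_gene_cox=str(out_dir / "per_gene_cox.tsv"),
                               discovery=str(out_dir / "discovery.json"))
            elif mode == "validate":
                if config.signature_name and config.signature_name in sets:
                    gs = sets[config.signature_name]
                    sig = Signature(gs.name, gs.members, scoring_rule="mean_z")
                else:
                    sig = hps_signature()
                res = _run("validate", lambda: validate_signature(
                    sig, expr, surv, labels, covariates=list(config.covariates) or None,
                    horizon_months=config.horizon_months))
                for stratum, rec in res["strata"].items():
                    km = rec.pop("km", None)
                    if km:
                        for grp, frame in km.items():
                            p = out_dir / f"km_{stratum}_{grp}.tsv"
                            frame.to_csv(p, sep="\t", index=False)
                            outputs[f"km_{stratum}_{grp}"] = str(p)
                (out_dir / "validation.json").write_text(json.dumps(res, indent=1, default=float))
                outputs["validation"] = str(out_dir / "validation.json")
            elif mode == "de":
                de = _run("de", lambda: differential_expression(expr, labels))
                de.table.to_csv(out_dir / "de.tsv", sep="\t")
                outputs["de"] = str(out_dir / "de.tsv")
    elif mode == "report":
        # renders from existing stage outputs; recomputes nothing
        lines = [f"# stromasig run report", ""]
        for name in ("report.json", "discovery.json", "validation.json"):
            p = out_dir / name
            if p.exists():
                lines += [f"## {name}", "```json", p.read_text().strip(), "```", ""]
        for name in ("gsea.tsv", "per_gene_cox.tsv", "de.tsv", "strata.tsv"):
            p = out_dir / name
            if p.exists():
                n_rows = sum(1 for _ in open(p)) - 1
                lines.append(f"- `{name}`: {n_rows} rows")
        (out_dir / "report.md").write_text("\n".join(lines) + "\n")
        outputs["report_md"] = str(out_dir / "report.md")

    manifest = RunManifest(
        config=dataclasses.asdict(config), version=__version__, seed=config.seed,
        input_hashes=hashes, stage_seconds=stage_seconds, warnings=caught, outputs=outputs,
    )
    manifest.write(out_dir / "manifest.json")
    return manifest
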