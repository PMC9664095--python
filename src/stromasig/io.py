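"""Readers and writers for the pipeline's plain-text formats.

Expression: tab-separated gene-by-sample tables or GCT 1.2; gene symbols are
uppercased at load and duplicates are an error unless a keep-max-variance
policy is requested.  Clinical: TSV with mandatory ``sample``, ``rfs_months``
and ``event`` columns, extra covariate columns carried through untouched.
Gene sets: GMT (name, description, members).  All TSVs are UTF-8 with '.'
decimals and a header row.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .scoring import GeneSet, ScoreVector, validate_expression
from .survival import validate_survival

__all__ = [
    "load_expression",
    "write_expression",
    "load_clinical",
    "write_clinical",
    "load_gmt",
    "write_gmt",
    "write_scores",
    "save_cohort",
]

LOG2_PLAUSIBLE_MAX = 50.0


def load_expression(path: str | Path, fmt: str | None = None, duplicates: str = "error") -> pd.DataFrame:
    """Read a log2 expression matrix from TSV or GCT 1.2.

    ``duplicates='error'`` (default) raises on repeated gene symbols;
    ``'keep_max_variance'`` keeps, per symbol, the row with highest variance.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if fmt == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise ValueError(f"unsupported GCT version line {version!r}")
            dims = fh.readline().split()
            n_rows, n_cols = int(dims[0]), int(dims[1])
            df = pd.read_csv(fh, sep="\t", index_col=0)
        df = df.drop(columns=[df.columns[0]])  # Description column
        if df.shape != (n_rows, n_cols):
            raise ValueError(f"GCT header promises {n_rows}x{n_cols}, file has {df.shape}")
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
    else:
        raise ValueError(f"unknown expression format {fmt!r}")

    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric expression cells in {path}: {exc}") from exc
    df.index = df.index.astype(str).str.upper()
    df.index.name = "gene"

    if df.index.has_duplicates:
        if duplicates == "error":
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise ValueError(f"duplicated gene symbols in {path}: {dups[:10]}")
        if duplicates == "keep_max_variance":
            var = df.var(axis=1)
            order = np.argsort(-var.to_numpy(), kind="stable")
            df = df.iloc[order]
            df = df[~df.index.duplicated(keep="first")]
            df = df.sort_index()
        else:
            raise ValueError(f"unknown duplicate policy {duplicates!r}")
    if np.nanmax(df.to_numpy()) > LOG2_PLAUSIBLE_MAX:
        warnings.warn(
            f"expression maximum {np.nanmax(df.to_numpy()):.1f} > {LOG2_PLAUSIBLE_MAX}; "
            "values may not be log2-scaled", stacklevel=2,
        )
    if df.isna().any().any():
        raise ValueError(f"missing values in expression matrix {path}")
    return validate_expression(df)


def write_expression(expr: pd.DataFrame, path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    if fmt is None:
        fmt = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if fmt == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{expr.shape[0]}\t{expr.shape[1]}\n")
            out = expr.copy()
            out.insert(0, "Description", "na")
            out.index.name = "NAME"
            out.to_csv(fh, sep="\t")
    else:
        expr.to_csv(path, sep="\t")


def load_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical/survival TSV (sample, rfs_months, event, covariates)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample", "rfs_months", "event"):
        if col not in df.columns:
            raise ValueError(f"clinical table {path} lacks mandatory column {col!r}")
    bad_t = df.index[pd.to_numeric(df["rfs_months"], errors="coerce") <= 0]
    if len(bad_t):
        raise ValueError(f"non-positive rfs_months at data row(s) {[int(i) + 2 for i in bad_t]} of {path}")
    bad_e = df.index[~df["event"].isin([0, 1])]
    if len(bad_e):
        raise ValueError(f"event flag outside {{0,1}} at data row(s) {[int(i) + 2 for i in bad_e]} of {path}")
    df = df.set_index("sample")
    df["rfs_months"] = df["rfs_months"].astype(float)
    df["event"] = df["event"].astype(int)
    return validate_survival(df)


def write_clinical(surv: pd.DataFrame, path: str | Path) -> None:
    out = surv.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


def load_gmt(path: str | Path) -> dict[str, GeneSet]:
    """Read a GMT gene-set collection (tab-separated name, description, members)."""
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description and >=1 member")
            name, desc, members = parts[0], parts[1], [p for p in parts[2:] if p]
            if len(set(m.upper() for m in members)) < len(members):
                warnings.warn(f"{path}:{lineno}: duplicate members in set {name!r} deduplicated",
                              stacklevel=2)
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            sets[name] = GeneSet(name, tuple(members), desc)
    if not sets:
        raise ValueError(f"no gene sets in {path}")
    return sets


def write_gmt(sets: dict[str, GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in sets.values():
            fh.write("\t".join([gs.name, gs.description or "na", *gs.members]) + "\n")


def write_scores(score: ScoreVector, path: str | Path) -> None:
    score.to_frame().to_csv(path, sep="\t", index=False)


def save_cohort(cohort, out_dir: str | Path) -> dict[str, str]:
    """Serialise a synthetic cohort: GCT + TSV expression, TSV clinical, GMT, JSON truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression_tsv": out / "expression.tsv",
        "expression_gct": out / "expression.gct",
        "clinical": out / "clinical.tsv",
        "genesets": out / "genesets.gmt",
        "truth": out / "truth.json",
    }
    write_expression(cohort.expression, paths["expression_tsv"])
    write_expression(cohort.expression, paths["expression_gct"])
    write_clinical(cohort.clinical, paths["clinical"])
    write_gmt(cohort.genesets, paths["genesets"])
    paths["truth"].write_text(cohort.truth.to_json())
    return {k: str(v) for k, v in paths.items()}
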