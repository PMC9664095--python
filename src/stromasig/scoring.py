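"""Single-sample gene-set scoring and composite score utilities.

The central object is the single-sample GSEA (ssGSEA) score: for one sample,
genes are ranked by expression and the score is the summed difference between
a weighted empirical CDF over the set members and the uniform CDF over
non-members.  Because it is a function of within-sample ranks only, the score
is invariant to any strictly monotone transform of a sample's expression
values, which is what makes it usable across platforms.

Expression matrices are plain :class:`pandas.DataFrame` objects with unique,
uppercase gene symbols as the index and sample ids as columns, on log2 scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSet",
    "ScoreVector",
    "ssgsea_score",
    "fibroblast_geneset",
    "signature_score",
    "score_correlation",
    "validate_expression",
]

#: Canonical fibroblast marker genes added on top of the MCP fibroblast set.
FIBROBLAST_MARKERS = ("ACTA2", "FAP")


@dataclass(frozen=True)
class GeneSet:
    """A named gene set with GMT semantics (name, description, members)."""

    name: str
    members: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        # dedupe preserving first occurrence; normalise symbols to uppercase
        seen: dict[str, None] = {}
        for m in self.members:
            seen.setdefault(str(m).upper(), None)
        object.__setattr__(self, "members", tuple(seen))
        if len(self.members) < 1:
            raise ValueError(f"gene set {self.name!r} has no members")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.members


@dataclass
class ScoreVector:
    """Per-sample scores plus a record of how they were computed."""

    scores: pd.Series
    method: str
    alpha: float | None = None
    normalized: bool = False
    fraction_found: float = 1.0
    name: str = ""
    missing: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction_found <= 1.0:
            raise ValueError("fraction_found must lie in (0, 1]")
        if self.scores.index.has_duplicates:
            raise ValueError("duplicate sample ids in score vector")

    def to_frame(self) -> pd.DataFrame:
        tag = self.method if self.alpha is None else f"{self.method}(alpha={self.alpha})"
        return pd.DataFrame({"sample": self.scores.index, "score": self.scores.values, "method": tag})


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Check an expression matrix: unique symbols, finite values."""
    if expr.index.has_duplicates:
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicated gene symbols: {dups[:10]}")
    if expr.columns.has_duplicates:
        raise ValueError("duplicated sample ids")
    if not np.isfinite(expr.to_numpy(dtype=float)).all():
        raise ValueError("expression matrix contains non-finite values")
    return expr


def _present_members(expr_index: pd.Index, gene_set: GeneSet, min_fraction: float) -> tuple[list[str], list[str]]:
    present = [g for g in gene_set.members if g in expr_index]
    missing = [g for g in gene_set.members if g not in expr_index]
    frac = len(present) / len(gene_set.members)
    if frac < min_fraction or not present:
        raise ValueError(
            f"gene set {gene_set.name!r}: only {len(present)}/{len(gene_set.members)} members present "
            f"(minimum fraction {min_fraction}); missing: {sorted(missing)}"
        )
    if missing:
        warnings.warn(
            f"gene set {gene_set.name!r}: {len(missing)} members absent from matrix: {sorted(missing)}",
            stacklevel=3,
        )
    return present, missing


def ssgsea_score(
    expr: pd.DataFrame,
    gene_set: GeneSet,
    alpha: float = 0.25,
    normalize: bool = False,
    min_fraction: float = 0.5,
) -> ScoreVector:
    """Single-sample GSEA score of ``gene_set`` for every column of ``expr``.

    For each sample, genes are ordered by decreasing expression (ties broken
    by gene symbol so scores are deterministic).  A gene at position ``i`` of
    ``N`` carries rank value ``N - i`` (top gene largest).  The score is

        sum_i [ P_hit(i) - P_miss(i) ]

    where ``P_hit`` is the ECDF over set members weighted by ``rank**alpha``
    (normalised to 1) and ``P_miss`` is the uniform ECDF over non-members.
    With ``normalize=True`` the whole score matrix is rescaled by its global
    (max - min); downstream median splits and correlations are unaffected.
    """
    validate_expression(expr)
    present, missing = _present_members(expr.index, gene_set, min_fraction)
    n_genes, n_samples = expr.shape
    if n_genes < 2 * len(present):
        raise ValueError(
            f"matrix has {n_genes} genes; need at least twice the {len(present)} present set members"
        )

    symbols = expr.index.to_numpy(dtype=object)
    values = expr.to_numpy(dtype=float)
    hit = expr.index.isin(present).astype(float)  # per-gene membership indicator
    n_hit = len(present)
    n_miss = n_genes - n_hit

    scores = np.empty(n_samples)
    # lexsort: primary key descending expression, secondary ascending symbol
    sym_order = np.argsort(symbols, kind="stable")
    for j in range(n_samples):
        col = values[:, j]
        if np.ptp(col) == 0.0:
            warnings.warn(f"sample {expr.columns[j]!r} has constant expression; ties broken by symbol")
        order = sym_order[np.argsort(-col[sym_order], kind="stable")]
        ranks = np.arange(n_genes, 0, -1, dtype=float)  # N..1 down the ordering
        hits = hit[order]
        w = np.where(hits > 0, ranks**alpha, 0.0)
        p_hit = np.cumsum(w) / w.sum()
        p_miss = np.cumsum(1.0 - hits) / n_miss
        scores[j] = float(np.sum(p_hit - p_miss))

    if normalize:
        span = scores.max() - scores.min()
        if span > 0:
            scores = scores / span

    return ScoreVector(
        scores=pd.Series(scores, index=expr.columns, name=gene_set.name),
        method="ssgsea",
        alpha=alpha,
        normalized=normalize,
        fraction_found=n_hit / len(gene_set.members),
        name=gene_set.name,
        missing=tuple(sorted(missing)),
    )


def fibroblast_geneset(mcp_fibroblast: GeneSet) -> GeneSet:
    """Composite fibroblast set: the MCP fibroblast signature plus ACTA2 and FAP."""
    if len(mcp_fibroblast) == 0:
        raise ValueError("MCP fibroblast set is empty")
    members = tuple(mcp_fibroblast.members) + FIBROBLAST_MARKERS
    return GeneSet(
        name="FIBROBLAST_SCORE",
        members=members,
        description="MCP fibroblast signature augmented with ACTA2 and FAP",
    )


def signature_score(
    expr: pd.DataFrame,
    signature: GeneSet,
    rule: str = "mean_z",
) -> ScoreVector:
    """Aggregate a signature's expression into one score per sample.

    ``mean_z``: mean over present genes of within-cohort z-scored expression
    (the default for prognostic-signature application).  ``sum``: the plain
    per-sample sum of log2 values ("cumulative gene expression").
    """
    validate_expression(expr)
    present = [g for g in signature.members if g in expr.index]
    missing = sorted(set(signature.members) - set(present))
    if not present:
        raise ValueError(f"no genes of signature {signature.name!r} present in matrix")
    if missing:
        warnings.warn(f"signature {signature.name!r}: missing genes {missing}", stacklevel=2)
    sub = expr.loc[present]
    if rule == "mean_z":
        sd = sub.std(axis=1, ddof=1)
        if (sd == 0).any():
            zero = sub.index[sd == 0].tolist()
            raise ValueError(f"zero-variance genes cannot be z-scored: {zero}")
        z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
        vals = z.mean(axis=0)
    elif rule == "sum":
        vals = sub.sum(axis=0)
    else:
        raise ValueError(f"unknown scoring rule {rule!r}; expected 'mean_z' or 'sum'")
    return ScoreVector(
        scores=pd.Series(vals.to_numpy(), index=expr.columns, name=signature.name),
        method=rule,
        fraction_found=len(present) / len(signature.members),
        name=signature.name,
        missing=tuple(missing),
    )


def score_correlation(x: ScoreVector | pd.Series, y: ScoreVector | pd.Series) -> tuple[float, float]:
    """Pearson correlation between two score vectors with two-sided p-value."""
    xs = x.scores if isinstance(x, ScoreVector) else x
    ys = y.scores if isinstance(y, ScoreVector) else y
    if not xs.index.equals(ys.index):
        ys = ys.reindex(xs.index)
        if ys.isna().any():
            raise ValueError("score vectors are not defined on the same samples")
    if len(xs) < 3:
        raise ValueError("need at least 3 samples for a correlation")
    if np.ptp(xs.to_numpy()) == 0 or np.ptp(ys.to_numpy()) == 0:
        raise ValueError("zero variance score vector")
    r, p = stats.pearsonr(xs.to_numpy(dtype=float), ys.to_numpy(dtype=float))
    return float(r), float(p)
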