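"""Signature discovery and validation.

Discovery takes candidate genes (from leading-edge overlap), dichotomises
each at its median expression within the analysis stratum, and applies a
two-stage Cox filter: univariate likelihood-ratio p below ``p_uni`` (0.20),
then covariate-adjusted multivariate gene-term Wald p below ``p_multi``
(0.05).  Survivors form the prognostic signature.  Validation scores the
signature, median-splits each stratum and asks whether the split is
prognostic there — the headline claim being that the signature separates
outcomes in the stromal-high stratum and not in the stromal-low one.

Thresholds in the two-stage filter are applied raw, without multiplicity
correction (configurable), matching common practice for this style of
per-gene survival filtering; the selection is expected to be anticonservative
and is validated out-of-cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import GeneSet, ScoreVector, signature_score
from .survival import (
    CoxFit,
    RelapseLabel,
    StratumLabels,
    cox_fit,
    km_estimate,
    logrank_test,
    median_split,
    relapse_labels,
    youden_cutoff,
)

__all__ = [
    "Signature",
    "DEResult",
    "DiscoveryReport",
    "HPS_GENES",
    "hps_signature",
    "survival_filter",
    "validate_signature",
    "differential_expression",
    "intersect_de",
    "build_de_signature",
    "discover_signature",
]

#: The published 7-gene stromal-subtype prognostic signature (read-only fixture).
HPS_GENES = ("FGL2", "PSME1", "SP110", "WARS", "CCND2", "CCND3", "PNPT1")


@dataclass(frozen=True)
class Signature:
    name: str
    genes: tuple[str, ...]
    scoring_rule: str = "mean_z"
    provenance: dict = field(default_factory=dict, hash=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(dict.fromkeys(g.upper() for g in self.genes)))

    def __len__(self) -> int:
        return len(self.genes)

    def as_geneset(self) -> GeneSet:
        return GeneSet(self.name, self.genes, "prognostic signature")


def hps_signature() -> Signature:
    """The canonical published 7-gene signature, as shipped fixture data."""
    return Signature(name="HPS", genes=HPS_GENES, scoring_rule="mean_z",
                     provenance={"source": "published 7-gene stromal-subtype signature"})


@dataclass
class DEResult:
    """Per-gene two-group differential expression (Welch t on log2 values)."""

    table: pd.DataFrame  # index gene; log2_fc, fc, t, p, p_adj, direction
    group_high: str = "High"
    group_low: str = "Low"

    def significant(self, p_adj_threshold: float = 0.05, direction: str | None = None) -> pd.DataFrame:
        sub = self.table[self.table["p_adj"] < p_adj_threshold]
        if direction is not None:
            sub = sub[sub["direction"] == direction]
        return sub


@dataclass
class DiscoveryReport:
    stratum_labels: StratumLabels
    relapse: RelapseLabel
    gsea_table: pd.DataFrame
    candidates: tuple[str, ...]
    per_gene: pd.DataFrame  # uni/multi fits per candidate
    signature: Signature
    unmeasured: tuple[str, ...]
    thresholds: dict

    def __post_init__(self) -> None:
        if not set(self.signature.genes) <= set(self.candidates):
            raise ValueError("final signature must be a subset of the LEA candidates")
        kept = self.per_gene.loc[list(self.signature.genes)]
        if not (kept["uni_lr_p"] < self.thresholds["p_uni"]).all():
            raise ValueError("a kept gene violates the univariate threshold")
        if not (kept["multi_p"] < self.thresholds["p_multi"]).all():
            raise ValueError("a kept gene violates the multivariate threshold")


def _covariate_design(surv: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Numeric design matrix from clinical covariates (categoricals dummied)."""
    missing = [c for c in covariates if c not in surv.columns]
    if missing:
        raise ValueError(f"covariates absent from survival table: {missing}")
    design = pd.get_dummies(surv[covariates], drop_first=True, dtype=float)
    keep = [c for c in design.columns if design[c].nunique() > 1]
    return design[keep].astype(float)


def survival_filter(
    candidates: list[str],
    expr: pd.DataFrame,
    surv: pd.DataFrame,
    covariates: list[str] | None = None,
    p_uni: float = 0.20,
    p_multi: float = 0.05,
    ties: str = "efron",
) -> tuple[Signature, pd.DataFrame, tuple[str, ...]]:
    """Two-stage Cox filter over candidate genes.

    Each gene is dichotomised at its median expression across the supplied
    samples (High = above-or-equal median).  Stage 1 keeps genes whose
    univariate Cox likelihood-ratio p is below ``p_uni``; stage 2 keeps those
    whose gene-term Wald p in the covariate-adjusted model is below
    ``p_multi``.  Returns (signature, per-gene table, unmeasured genes).
    """
    unmeasured = tuple(g for g in candidates if g not in expr.index)
    measured = [g for g in candidates if g in expr.index]
    if unmeasured:
        warnings.warn(f"{len(unmeasured)} candidate genes not in the matrix: {sorted(unmeasured)}",
                      stacklevel=2)
    design = _covariate_design(surv, list(covariates)) if covariates else None

    rows = []
    for gene in measured:
        vals = expr.loc[gene, surv.index]
        med = float(np.median(vals))
        high = (vals >= med).astype(float)
        rec: dict = {"gene": gene, "median": med, "n_high": int(high.sum()),
                     "n_low": int((1 - high).sum())}
        if high.nunique() < 2:
            rec.update(uni_lr_p=np.nan, uni_hr=np.nan, multi_p=np.nan, multi_hr=np.nan,
                       kept=False, note="degenerate median split")
            rows.append(rec)
            continue
        term = high.rename("gene_high")
        try:
            uni = cox_fit(surv, term, ties=ties)
        except Exception as exc:  # non-convergence etc.
            rec.update(uni_lr_p=np.nan, uni_hr=np.nan, multi_p=np.nan, multi_hr=np.nan,
                       kept=False, note=f"univariate fit failed: {exc}")
            rows.append(rec)
            continue
        rec.update(uni_lr_p=uni.lr_p, uni_hr=uni.hr("gene_high"),
                   uni_ci_low=float(uni.summary.loc["gene_high", "ci_low"]),
                   uni_ci_high=float(uni.summary.loc["gene_high", "ci_high"]))
        if uni.lr_p >= p_uni:
            rec.update(multi_p=np.nan, multi_hr=np.nan, kept=False, note="failed univariate")
            rows.append(rec)
            continue
        if design is None or design.shape[1] == 0:
            rec.update(multi_p=uni.p("gene_high"), multi_hr=uni.hr("gene_high"))
        else:
            try:
                multi = cox_fit(surv, pd.concat([term, design], axis=1), ties=ties)
                rec.update(multi_p=multi.p("gene_high"), multi_hr=multi.hr("gene_high"),
                           multi_ci_low=float(multi.summary.loc["gene_high", "ci_low"]),
                           multi_ci_high=float(multi.summary.loc["gene_high", "ci_high"]))
            except Exception as exc:
                rec.update(multi_p=np.nan, multi_hr=np.nan, kept=False,
                           note=f"multivariate fit failed: {exc}")
                rows.append(rec)
                continue
        rec["kept"] = bool(rec["multi_p"] < p_multi)
        rec["note"] = "" if rec["kept"] else "failed multivariate"
        rows.append(rec)

    per_gene = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=["median", "uni_lr_p", "multi_p", "kept"])
    kept_genes = tuple(per_gene.index[per_gene.get("kept", pd.Series(dtype=bool)) == True])  # noqa: E712
    if kept_genes:
        sig = Signature(
            name="DISCOVERED_SIGNATURE",
            genes=kept_genes,
            scoring_rule="mean_z",
            provenance={"p_uni": p_uni, "p_multi": p_multi, "covariates": list(covariates or []),
                        "n_candidates": len(candidates), "ties": ties},
        )
    else:
        warnings.warn("no candidate survived the two-stage Cox filter; signature is empty",
                      stacklevel=2)
        sig = _empty_signature(p_uni, p_multi, covariates, len(candidates))
    return sig, per_gene, unmeasured


def _empty_signature(p_uni, p_multi, covariates, n_candidates) -> Signature:
    sig = Signature.__new__(Signature)
    object.__setattr__(sig, "name", "DISCOVERED_SIGNATURE")
    object.__setattr__(sig, "genes", ())
    object.__setattr__(sig, "scoring_rule", "mean_z")
    object.__setattr__(sig, "provenance", {"p_uni": p_uni, "p_multi": p_multi,
                                           "covariates": list(covariates or []),
                                           "n_candidates": n_candidates, "empty": True})
    return sig


def validate_signature(
    sig: Signature,
    expr: pd.DataFrame,
    surv: pd.DataFrame,
    strata: StratumLabels,
    covariates: list[str] | None = None,
    horizon_months: float = 60.0,
    min_stratum: int = 10,
) -> dict:
    """Per-stratum prognostic assessment of a signature.

    Within each stratum: median-split of the signature score, log-rank test,
    Kaplan–Meier curves, univariate Cox and (if covariates given) adjusted
    Cox of the split, plus concordance of the median split with the
    ROC/Youden-optimal cutoff on the relapse-within-horizon contrast.  The
    direction convention (high signature = protective, HR < 1) is checked and
    reported, never silently flipped.
    """
    if len(sig) == 0:
        raise ValueError("cannot validate an empty signature")
    out: dict = {"signature": sig.name, "genes": list(sig.genes), "strata": {}}
    for stratum in ("High", "Low"):
        idx = strata.labels.index[strata.labels == stratum].intersection(surv.index)
        if len(idx) < min_stratum:
            warnings.warn(f"stratum {stratum} has {len(idx)} samples (<{min_stratum}); skipped",
                          stacklevel=2)
            out["strata"][stratum] = {"skipped": True, "n": int(len(idx))}
            continue
        sub_expr = expr[idx]
        sub_surv = surv.loc[idx]
        score = signature_score(sub_expr, sig.as_geneset(), rule=sig.scoring_rule)
        try:
            split = median_split(score)
        except ValueError as exc:
            raise ValueError(f"median split failed in stratum {stratum}: {exc}") from exc
        lr = logrank_test(sub_surv, split)
        km = km_estimate(sub_surv, split)
        term = (split.labels == "High").astype(float).rename("sig_high")
        uni = cox_fit(sub_surv, term)
        rec: dict = {
            "n": int(len(idx)),
            "events": int(sub_surv["event"].sum()),
            "logrank_p": lr.p,
            "logrank_chi2": lr.statistic,
            "uni_hr": uni.hr("sig_high"),
            "uni_p": uni.p("sig_high"),
            "protective_direction": bool(uni.hr("sig_high") < 1.0),
            "km": {g: c.to_frame() for g, c in km.items()},
        }
        if covariates:
            design = _covariate_design(sub_surv, list(covariates))
            if design.shape[1]:
                multi = cox_fit(sub_surv, pd.concat([term, design], axis=1))
                rec["multi_hr"] = multi.hr("sig_high")
                rec["multi_p"] = multi.p("sig_high")
        try:
            rl = relapse_labels(sub_surv, horizon_months=horizon_months)
            cutoff, auroc = youden_cutoff(
                ScoreVector(score.scores.reindex(rl.labels.index), method=score.method),
                rl,
            )
            # Youden rule: score >= cutoff predicts relapse class iff AUROC >= 0.5
            youden_high = score.scores.reindex(rl.labels.index) >= cutoff
            med_high = split.labels.reindex(rl.labels.index) == "High"
            rec["youden_auroc"] = auroc
            rec["youden_cutoff"] = cutoff
            rec["youden_median_concordance"] = float(
                max((youden_high == med_high).mean(), (youden_high != med_high).mean())
            )
        except ValueError:
            rec["youden_auroc"] = np.nan
        out["strata"][stratum] = rec
    return out


def differential_expression(expr: pd.DataFrame, groups: StratumLabels) -> DEResult:
    """Welch t-test per gene between High and Low groups on log2 values."""
    hi = groups.high.intersection(expr.columns)
    lo = groups.low.intersection(expr.columns)
    if len(hi) < 3 or len(lo) < 3:
        raise ValueError("each group needs at least 3 samples")
    A = expr[hi].to_numpy(dtype=float)
    B = expr[lo].to_numpy(dtype=float)
    log2_fc = A.mean(axis=1) - B.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(A, B, axis=1, equal_var=False)
    flat = (A.std(axis=1) == 0) & (B.std(axis=1) == 0)
    p = np.where(flat, 1.0, p)
    t = np.where(flat, 0.0, t)
    from statsmodels.stats.multitest import multipletests

    p_adj = multipletests(p, method="fdr_bh")[1]
    table = pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "fc": 2.0**log2_fc,
            "t": t,
            "p": p,
            "p_adj": p_adj,
            "direction": np.where(log2_fc >= 0, "up", "down"),
            "flat": flat,
        },
        index=expr.index,
    )
    return DEResult(table=table)


def intersect_de(de_a: DEResult, de_b: DEResult, p_adj_threshold: float = 0.05) -> dict:
    """Genes significant in both results with consistent direction.

    Returns ``{"up": [...], "down": [...], "discordant": [...]}``; discordant
    genes (significant in both but with opposite sign) are reported, not
    silently dropped.
    """
    shared = de_a.table.index.intersection(de_b.table.index)
    if len(shared) == 0:
        raise ValueError("DE results have disjoint gene universes")
    a = de_a.table.loc[shared]
    b = de_b.table.loc[shared]
    sig = (a["p_adj"] < p_adj_threshold) & (b["p_adj"] < p_adj_threshold)
    same = a["direction"] == b["direction"]
    up = sorted(shared[sig & same & (a["direction"] == "up")])
    down = sorted(shared[sig & same & (a["direction"] == "down")])
    discordant = sorted(shared[sig & ~same])
    return {"up": up, "down": down, "discordant": discordant}


def build_de_signature(
    de: DEResult,
    logfc_threshold: float = 2.0,
    p_adj_threshold: float = 0.001,
    direction: str = "up",
    orthology: pd.DataFrame | None = None,
) -> tuple[Signature, tuple[str, ...]]:
    """Threshold-based signature from a DE table (log2 FC and adjusted p).

    ``orthology`` is an optional two-column table (source, target symbol) for
    cross-species mapping; unmapped genes are returned alongside the mapped
    signature rather than dropped silently.
    """
    tab = de.table
    if direction == "up":
        mask = (tab["log2_fc"] > logfc_threshold) & (tab["p_adj"] < p_adj_threshold)
    elif direction == "down":
        mask = (tab["log2_fc"] < -logfc_threshold) & (tab["p_adj"] < p_adj_threshold)
    else:
        raise ValueError("direction must be 'up' or 'down'")
    genes = [str(g).upper() for g in tab.index[mask]]
    unmapped: tuple[str, ...] = ()
    if orthology is not None:
        if orthology.shape[1] != 2:
            raise ValueError("orthology table must have exactly two columns")
        mapping = dict(zip(orthology.iloc[:, 0].str.upper(), orthology.iloc[:, 1].str.upper()))
        unmapped = tuple(g for g in genes if g not in mapping)
        genes = [mapping[g] for g in genes if g in mapping]
    if not genes:
        warnings.warn("no genes pass the DE-signature thresholds; signature is empty", stacklevel=2)
        return _empty_signature(np.nan, p_adj_threshold, None, int(mask.sum())), unmapped
    sig = Signature(
        name="DE_SIGNATURE",
        genes=tuple(genes),
        scoring_rule="mean_z",
        provenance={"logfc_threshold": logfc_threshold, "p_adj_threshold": p_adj_threshold,
                    "direction": direction},
    )
    return sig, unmapped


def discover_signature(
    expr: pd.DataFrame,
    surv: pd.DataFrame,
    genesets: dict[str, GeneSet],
    strata: StratumLabels,
    analysis_stratum: str = "High",
    covariates: list[str] | None = None,
    horizon_months: float = 60.0,
    q_threshold: float = 0.15,
    min_sets: int = 2,
    n_perm: int = 1000,
    seed: int = 0,
    p_uni: float = 0.20,
    p_multi: float = 0.05,
) -> DiscoveryReport:
    """Full discovery chain inside one stratum.

    relapse labels -> supervised GSEA -> leading-edge overlap candidates ->
    two-stage Cox filter -> signature, with every intermediate recorded.
    GSEA contrasts relapse vs never-relapsed, so sets enriched in the
    never-relapsed class carry the good-prognosis candidates.
    """
    from .gsea import gsea, lea_overlap

    idx = strata.labels.index[strata.labels == analysis_stratum].intersection(surv.index)
    sub_expr = expr[idx]
    sub_surv = surv.loc[idx]
    relapse = relapse_labels(sub_surv, horizon_months=horizon_months)
    res = gsea(sub_expr, relapse, genesets, n_perm=n_perm, seed=seed)
    overlap = lea_overlap(res, q_threshold=q_threshold, direction="non_relapse", min_sets=min_sets)
    contrast_surv = sub_surv.loc[relapse.labels.index]
    sig, per_gene, unmeasured = survival_filter(
        list(overlap.candidates), sub_expr, contrast_surv,
        covariates=covariates, p_uni=p_uni, p_multi=p_multi,
    )
    return DiscoveryReport(
        stratum_labels=strata,
        relapse=relapse,
        gsea_table=res.table,
        candidates=overlap.candidates,
        per_gene=per_gene,
        signature=sig,
        unmeasured=unmeasured,
        thresholds={"p_uni": p_uni, "p_multi": p_multi, "q_threshold": q_threshold,
                    "min_sets": min_sets, "horizon_months": horizon_months,
                    "n_perm": n_perm, "seed": seed},
    )
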