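"""Two-class gene set enrichment analysis with leading-edge extraction.

Implements the weighted Kolmogorov–Smirnov-style running-sum enrichment
statistic over a signal-to-noise gene ranking, a phenotype-permutation null
(with a gene-set-permutation fallback at small sample sizes), normalised
enrichment scores, GSEA-style FDR, and leading-edge overlap analysis for
candidate-gene selection.

Everything is vectorised so that the permutation null is computed without a
per-permutation Python loop over genes: for each gene set only the ranked
positions of its members are needed to locate the running-sum extremum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .scoring import GeneSet
from .survival import RelapseLabel

__all__ = [
    "RankedList",
    "GseaResult",
    "LeaOverlap",
    "rank_genes",
    "enrichment_score",
    "gsea",
    "lea_overlap",
]

SIGMA_FLOOR_FRAC = 0.2  # per-class sd floored at max(0.2*|mean|, 0.2), GSEA convention
MIN_CLASS_FOR_PHENOTYPE_PERM = 7


@dataclass
class RankedList:
    """Genes ordered by a two-class ranking metric (descending)."""

    genes: np.ndarray  # object array of symbols, metric-descending
    metric: np.ndarray  # aligned metric values
    class_a: str = "A"
    class_b: str = "B"

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GseaResult:
    """Per-set enrichment results plus the permutation machinery's record."""

    table: pd.DataFrame  # index set name; columns es, nes, p, q, size, enriched_in
    leading_edges: dict[str, tuple[str, ...]]
    n_perm: int
    seed: int
    perm_type: str  # phenotype | gene_set
    class_a: str = "A"
    class_b: str = "B"

    def significant(self, q_threshold: float = 0.15, direction: str | None = None) -> pd.DataFrame:
        sub = self.table[self.table["q"] < q_threshold]
        if direction is not None:
            sub = sub[sub["enriched_in"] == direction]
        return sub


@dataclass
class LeaOverlap:
    candidates: tuple[str, ...]
    membership: dict[str, tuple[str, ...]]  # gene -> contributing set names
    min_sets: int = 2

    def __post_init__(self) -> None:
        for g in self.candidates:
            if len(self.membership.get(g, ())) < self.min_sets:
                raise ValueError(f"candidate {g} has fewer than {self.min_sets} contributing sets")


def _signal_to_noise(values: np.ndarray, a_mask: np.ndarray) -> np.ndarray:
    """s2n metric per gene row: (mu_A - mu_B) / (sd_A + sd_B), sds floored."""
    A = values[:, a_mask]
    B = values[:, ~a_mask]
    mu_a, mu_b = A.mean(axis=1), B.mean(axis=1)
    sd_a = np.maximum(A.std(axis=1, ddof=1), np.maximum(SIGMA_FLOOR_FRAC * np.abs(mu_a), SIGMA_FLOOR_FRAC))
    sd_b = np.maximum(B.std(axis=1, ddof=1), np.maximum(SIGMA_FLOOR_FRAC * np.abs(mu_b), SIGMA_FLOOR_FRAC))
    return (mu_a - mu_b) / (sd_a + sd_b)


def _order_genes(symbols: np.ndarray, metric: np.ndarray) -> np.ndarray:
    """Indices ordering genes by metric descending, ties by symbol ascending."""
    return np.lexsort((symbols, -metric))


def rank_genes(expr: pd.DataFrame, labels: RelapseLabel | pd.Series) -> RankedList:
    """Signal-to-noise ranking contrasting relapse (A) vs non-relapse (B).

    Accepts a :class:`RelapseLabel` or any binary sample-indexed series; class
    A is label 1.  Each class needs at least 3 samples.
    """
    lab = labels.labels if isinstance(labels, RelapseLabel) else labels
    lab = lab.reindex(expr.columns.intersection(lab.index))
    sub = expr[lab.index]
    a_mask = (lab == 1).to_numpy() if lab.dtype != object else (lab == lab.unique()[0]).to_numpy()
    if a_mask.sum() < 3 or (~a_mask).sum() < 3:
        raise ValueError("each class needs at least 3 samples for the s2n metric")
    m = _signal_to_noise(sub.to_numpy(dtype=float), a_mask)
    symbols = expr.index.to_numpy(dtype=object)
    order = _order_genes(symbols, m)
    return RankedList(genes=symbols[order], metric=m[order], class_a="relapse", class_b="non_relapse")


def _es_from_positions(
    positions: np.ndarray, weights: np.ndarray, n_genes: int
) -> tuple[float, int]:
    """Enrichment score from sorted member positions (0-based) and weights.

    The running sum is piecewise linear between hits, so its extrema occur
    immediately after a hit (candidate maxima) or just before one (candidate
    minima); both are evaluated in O(set size).  Returns (ES, extremum hit
    index k*) where the leading edge is members[:k*+1] for ES>0 and
    members[k*:] for ES<0.
    """
    n = len(positions)
    w = weights / weights.sum()
    cum_hit = np.cumsum(w)
    n_miss = n_genes - n
    miss_after = (positions + 1 - np.arange(1, n + 1)) / n_miss  # P_miss just after hit k
    miss_before = (positions - np.arange(n)) / n_miss  # P_miss just before hit k
    dev_after = cum_hit - miss_after
    dev_before = np.concatenate([[0.0], cum_hit[:-1]]) - miss_before
    i_max = int(np.argmax(dev_after))
    i_min = int(np.argmin(dev_before))
    if dev_after[i_max] >= -dev_before[i_min]:
        return float(dev_after[i_max]), i_max
    return float(dev_before[i_min]), i_min


def enrichment_score(
    ranked: RankedList, gene_set: GeneSet, weight_p: float = 1.0
) -> tuple[float, tuple[str, ...], np.ndarray]:
    """ES of ``gene_set`` on a ranked list, with leading edge and running sum.

    Hits increment the running sum by ``|metric|**weight_p`` normalised over
    the members; misses decrement uniformly.  ES is the signed maximum
    deviation; the leading edge is the members up to (positive ES) or after
    (negative ES) the extremum.  Returns (es, leading_edge, running_sum).
    """
    in_set = np.isin(ranked.genes, list(gene_set.members))
    n = int(in_set.sum())
    if n == 0:
        raise ValueError(f"no members of {gene_set.name!r} in the ranked list")
    if n == len(ranked.genes):
        raise ValueError(f"{gene_set.name!r} covers every ranked gene; no misses to score against")
    w = np.abs(ranked.metric[in_set]) ** weight_p
    if w.sum() == 0:
        w = np.ones(n)
    positions = np.flatnonzero(in_set)
    es, k = _es_from_positions(positions, w, len(ranked.genes))
    members_in_order = ranked.genes[in_set]
    leading = tuple(members_in_order[: k + 1]) if es >= 0 else tuple(members_in_order[k:])
    # full running sum, for plotting/debugging
    full_w = np.zeros(len(ranked.genes))
    full_w[in_set] = w / w.sum()
    running = np.cumsum(full_w - (~in_set) / (len(ranked.genes) - n))
    return es, leading, running


def _perm_es_matrix(
    values: np.ndarray,
    symbols: np.ndarray,
    a_masks: np.ndarray,
    set_members: Sequence[np.ndarray],
    weight_p: float,
) -> np.ndarray:
    """ES for every (permutation, set) pair under phenotype permutation."""
    n_perm = a_masks.shape[0]
    out = np.empty((n_perm, len(set_members)))
    for p in range(n_perm):
        m = _signal_to_noise(values, a_masks[p])
        order = _order_genes(symbols, m)
        pos_of_gene = np.empty(len(symbols), dtype=int)
        pos_of_gene[order] = np.arange(len(symbols))
        m_abs = np.abs(m)
        for s, members_idx in enumerate(set_members):
            positions = np.sort(pos_of_gene[members_idx])
            w = m_abs[members_idx][np.argsort(pos_of_gene[members_idx], kind="stable")] ** weight_p
            if w.sum() == 0:
                w = np.ones(len(w))
            out[p, s], _ = _es_from_positions(positions, w, len(symbols))
    return out


def gsea(
    expr: pd.DataFrame,
    labels: RelapseLabel | pd.Series,
    sets: Mapping[str, GeneSet] | Sequence[GeneSet],
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
    min_size: int = 2,
    fdr_method: str = "gsea",
) -> GseaResult:
    """Two-class GSEA over a gene-set collection.

    The null is built from seeded phenotype-label permutations; NES is
    ES / mean(|permuted ES| of the same sign); nominal p is the same-sign
    tail fraction; FDR q compares each NES with the pooled permuted-NES
    distribution (``fdr_method='gsea'``) or applies Benjamini–Hochberg to the
    nominal p-values (``fdr_method='bh'``).  With fewer than 7 samples in a
    class the null falls back to gene-set (random-member) permutation.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if isinstance(sets, Mapping):
        collection = list(sets.values())
    else:
        collection = list(sets)
    lab = labels.labels if isinstance(labels, RelapseLabel) else labels
    lab = lab.reindex(expr.columns.intersection(lab.index))
    sub = expr[lab.index]
    a_mask = (lab == 1).to_numpy()
    n_a, n_b = int(a_mask.sum()), int((~a_mask).sum())
    if min(n_a, n_b) < 3:
        raise ValueError("each class needs at least 3 samples")

    symbols = expr.index.to_numpy(dtype=object)
    values = sub.to_numpy(dtype=float)
    idx_of = {g: i for i, g in enumerate(symbols)}

    usable: list[GeneSet] = []
    member_idx: list[np.ndarray] = []
    for gs in collection:
        mi = np.array([idx_of[g] for g in gs.members if g in idx_of], dtype=int)
        if min_size <= len(mi) < len(symbols):
            usable.append(gs)
            member_idx.append(mi)
    if not usable:
        raise ValueError("no gene set has enough members in the matrix")

    ranked = rank_genes(sub, lab)
    es_obs = np.empty(len(usable))
    leading: dict[str, tuple[str, ...]] = {}
    for i, gs in enumerate(usable):
        es, le, _ = enrichment_score(ranked, gs, weight_p=weight_p)
        es_obs[i] = es
        leading[gs.name] = le

    rng = np.random.default_rng(seed)
    perm_type = "phenotype"
    if min(n_a, n_b) < MIN_CLASS_FOR_PHENOTYPE_PERM:
        perm_type = "gene_set"
        warnings.warn(
            f"class sizes {n_a}/{n_b} below {MIN_CLASS_FOR_PHENOTYPE_PERM}; "
            "falling back to gene-set permutation for the null", stacklevel=2,
        )

    if perm_type == "phenotype":
        n_samples = len(lab)
        a_masks = np.zeros((n_perm, n_samples), dtype=bool)
        for p in range(n_perm):
            a_masks[p, rng.choice(n_samples, size=n_a, replace=False)] = True
        es_null = _perm_es_matrix(values, symbols, a_masks, member_idx, weight_p)
    else:
        # random member sets of matched size on the observed ranking
        m_abs = np.abs(ranked.metric)
        es_null = np.empty((n_perm, len(usable)))
        for s, mi in enumerate(member_idx):
            k = len(mi)
            for p in range(n_perm):
                pos = np.sort(rng.choice(len(symbols), size=k, replace=False))
                w = m_abs[pos] ** weight_p
                if w.sum() == 0:
                    w = np.ones(k)
                es_null[p, s], _ = _es_from_positions(pos, w, len(symbols))

    nes_obs = np.empty(len(usable))
    p_nom = np.empty(len(usable))
    nes_null = np.full_like(es_null, np.nan)
    for s in range(len(usable)):
        null = es_null[:, s]
        pos_mean = np.abs(null[null > 0]).mean() if (null > 0).any() else np.nan
        neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
        if es_obs[s] >= 0:
            same = null[null >= 0]
            p_nom[s] = ((same >= es_obs[s]).sum() + 1) / (len(same) + 1)
            nes_obs[s] = es_obs[s] / pos_mean if np.isfinite(pos_mean) else np.nan
        else:
            same = null[null <= 0]
            p_nom[s] = ((same <= es_obs[s]).sum() + 1) / (len(same) + 1)
            nes_obs[s] = -np.abs(es_obs[s]) / neg_mean if np.isfinite(neg_mean) else np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            nes_null[:, s] = np.where(null >= 0, null / pos_mean, -np.abs(null) / neg_mean)

    q = _gsea_fdr(nes_obs, nes_null) if fdr_method == "gsea" else _bh(p_nom)

    table = pd.DataFrame(
        {
            "es": es_obs,
            "nes": nes_obs,
            "p": p_nom,
            "q": q,
            "size": [len(mi) for mi in member_idx],
            "enriched_in": np.where(es_obs >= 0, ranked.class_a, ranked.class_b),
        },
        index=[gs.name for gs in usable],
    )
    return GseaResult(
        table=table,
        leading_edges=leading,
        n_perm=n_perm,
        seed=seed,
        perm_type=perm_type,
        class_a=ranked.class_a,
        class_b=ranked.class_b,
    )


def _gsea_fdr(nes_obs: np.ndarray, nes_null: np.ndarray) -> np.ndarray:
    """GSEA-style FDR q: pooled same-sign permuted-NES tail ratio, clipped."""
    pooled = nes_null[np.isfinite(nes_null)]
    q = np.empty(len(nes_obs))
    for s, nes in enumerate(nes_obs):
        if not np.isfinite(nes):
            q[s] = 1.0
            continue
        if nes >= 0:
            null_frac_all = (pooled >= 0).sum()
            null_tail = (pooled >= nes).sum() / max(null_frac_all, 1)
            obs_pos = nes_obs[np.isfinite(nes_obs) & (nes_obs >= 0)]
            obs_tail = (obs_pos >= nes).sum() / max(len(obs_pos), 1)
        else:
            null_frac_all = (pooled <= 0).sum()
            null_tail = (pooled <= nes).sum() / max(null_frac_all, 1)
            obs_neg = nes_obs[np.isfinite(nes_obs) & (nes_obs <= 0)]
            obs_tail = (obs_neg <= nes).sum() / max(len(obs_neg), 1)
        q[s] = min(null_tail / obs_tail, 1.0) if obs_tail > 0 else 1.0
    return q


def _bh(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def lea_overlap(
    result: GseaResult,
    q_threshold: float = 0.15,
    direction: str | None = None,
    min_sets: int = 2,
) -> LeaOverlap:
    """Leading-edge overlap: genes contributing to >= ``min_sets`` passing sets.

    ``direction`` restricts to sets enriched in that class (e.g. the
    good-prognosis class); default counts every set below the q threshold.
    """
    passing = result.significant(q_threshold=q_threshold, direction=direction)
    if len(passing) < 2:
        warnings.warn(
            f"only {len(passing)} gene sets pass q<{q_threshold}"
            + (f" toward {direction}" if direction else "")
            + "; leading-edge overlap is empty",
            stacklevel=2,
        )
        return LeaOverlap(candidates=(), membership={}, min_sets=min_sets)
    counts: dict[str, list[str]] = {}
    for name in passing.index:
        for g in result.leading_edges[name]:
            counts.setdefault(g, []).append(name)
    candidates = tuple(sorted(g for g, sets_in in counts.items() if len(sets_in) >= min_sets))
    membership = {g: tuple(v) for g, v in counts.items() if len(v) >= min_sets}
    return LeaOverlap(candidates=candidates, membership=membership, min_sets=min_sets)
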