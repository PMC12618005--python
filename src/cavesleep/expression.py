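"""Downstream expression-response computations.

Works from per-gene differential-expression summary tables (gene, log2fc,
pvalue, padj) produced upstream by a count-based DE model; a gene responds
significantly to treatment when its BH-adjusted p-value is below 0.05.
This module implements

* Benjamini–Hochberg adjustment (step-up FDR),
* bidirectional response classification across two populations (shared vs
  population-specific responders, with per-population direction),
* DEG counting across tissue/population tables,
* the signed ranking statistic  score = -log10(p) * sign(log2FC), which
  orders genes by both magnitude and direction of response,
* a preranked gene-set enrichment statistic (weighted Kolmogorov–Smirnov
  running sum) with a gene-label permutation null, and
* the ΔΔCt method for qPCR fold changes against a housekeeping gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSet",
    "QPCRResult",
    "bh_adjust",
    "classify_population_response",
    "count_degs",
    "rank_genes",
    "enrichment_score",
    "preranked_gsea",
    "delta_delta_ct",
    "read_gmt",
]


# ---------------------------------------------------------------------------
# Multiple testing and response classification
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any(np.isnan(p)):
        raise ValueError("NaN p-values are not allowed")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def _check_table(df: pd.DataFrame) -> None:
    for col in ("gene", "log2fc", "padj"):
        if col not in df.columns:
            raise ValueError(f"DE table missing column {col!r}")
    if df["gene"].duplicated().any():
        raise ValueError("duplicated gene ids in DE table")


def classify_population_response(
    surface: pd.DataFrame, cave: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Classify each gene's treatment response across the two populations.

    A gene is ``shared`` when padj < alpha in both populations,
    ``surface_specific`` / ``cave_specific`` when significant in exactly one,
    else ``nonresponsive``.  Genes present in only one table are treated as
    non-significant in the other.  Directions are the sign of log2fc.
    Returns a DataFrame: gene, category, surface_direction, cave_direction.
    """
    _check_table(surface)
    _check_table(cave)
    m = surface.merge(cave, on="gene", how="outer", suffixes=("_surface", "_cave"))
    sig_s = (m["padj_surface"] < alpha).fillna(False)
    sig_c = (m["padj_cave"] < alpha).fillna(False)
    category = np.select(
        [sig_s & sig_c, sig_s & ~sig_c, ~sig_s & sig_c],
        ["shared", "surface_specific", "cave_specific"],
        default="nonresponsive",
    )

    def direction(lfc: pd.Series) -> np.ndarray:
        return np.where(lfc.isna(), None, np.where(lfc > 0, "up", "down"))

    return pd.DataFrame(
        {
            "gene": m["gene"],
            "category": category,
            "surface_direction": direction(m["log2fc_surface"]),
            "cave_direction": direction(m["log2fc_cave"]),
        }
    )


def count_degs(tables: Mapping[str, pd.DataFrame], alpha: float = 0.05) -> pd.Series:
    """Count genes with padj < alpha per table (e.g. per tissue x population)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return pd.Series(
        {name: int((df["padj"] < alpha).sum()) for name, df in tables.items()},
        name="n_deg",
    )


# ---------------------------------------------------------------------------
# Signed ranking and preranked enrichment
# ---------------------------------------------------------------------------

def rank_genes(table: pd.DataFrame, p_floor: float = 1e-300) -> pd.Series:
    """Rank genes by score = -log10(p) * sign(log2fc), descending.

    p = 0 is clamped to the smallest positive p-value in the table (never
    below ``p_floor``) so the score stays finite; log2fc = 0 gives score 0.
    Ties are broken lexicographically by gene id so the order is a strict
    deterministic total order.  Returns a Series (index gene, value score).
    """
    for col in ("gene", "log2fc", "pvalue"):
        if col not in table.columns:
            raise ValueError(f"DE table missing column {col!r}")
    if table["log2fc"].isna().any():
        raise ValueError("missing log2fc")
    p = table["pvalue"].to_numpy(dtype=float)
    if np.any(~np.isfinite(p)):
        raise ValueError("p-values must be finite")
    pos = p[p > 0]
    floor = max(float(pos.min()) if pos.size else p_floor, p_floor)
    score = -np.log10(np.clip(p, floor, None)) * np.sign(table["log2fc"].to_numpy(dtype=float))
    out = pd.DataFrame({"gene": table["gene"], "score": score})
    out = out.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
    return pd.Series(out["score"].to_numpy(), index=out["gene"].to_numpy(), name="score")


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("gene set must be non-empty")


def read_gmt(path: str) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets.append(GeneSet(name=parts[0], genes=frozenset(parts[2:])))
    return sets


def enrichment_score(scores: np.ndarray, hits: np.ndarray, weight: float = 1.0) -> float:
    """Weighted KS enrichment score of a hit set against a ranked score list.

    ``scores`` must already be sorted descending; ``hits`` flags set members.
    The running sum increments by |score|^weight / (sum over hits) at hits
    and decrements by 1/(#misses) at misses; ES is the running-sum value of
    largest magnitude (signed), so ES in [-1, 1].  A set covering the whole
    universe has no misses and ES = 1 by convention.
    """
    s = np.asarray(scores, dtype=float)
    h = np.asarray(hits, dtype=bool)
    n, k = s.size, int(h.sum())
    if k == 0:
        raise ValueError("hit set is empty in the ranked universe")
    if k == n:
        return 1.0
    w = np.abs(s[h]) ** weight
    total = w.sum()
    if total == 0.0:
        raise ValueError("all hit scores are zero; ES undefined at this weight")
    running = np.full(n, -1.0 / (n - k))
    running[h] = w / total
    running = np.cumsum(running)
    return float(running[np.argmax(np.abs(running))])


def _null_es(
    abs_scores_w: np.ndarray, k: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """ES distribution under gene-label permutation (k random hit positions)."""
    n = abs_scores_w.size
    hitpos = np.argsort(rng.random((n_perm, n)), axis=1)[:, :k]
    run = np.full((n_perm, n), -1.0 / (n - k))
    w = abs_scores_w[hitpos]
    run[np.arange(n_perm)[:, None], hitpos] = w / w.sum(axis=1, keepdims=True)
    run = np.cumsum(run, axis=1)
    idx = np.argmax(np.abs(run), axis=1)
    return run[np.arange(n_perm), idx]


def preranked_gsea(
    ranked: pd.Series,
    sets: Sequence[GeneSet],
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    min_size: int = 10,
    max_size: int = 500,
) -> pd.DataFrame:
    """Preranked enrichment of gene sets against a signed ranked list.

    For each set intersecting the ranked universe (intersection size within
    [min_size, max_size]), computes the weighted KS enrichment score, a
    normalized score NES = ES / mean(|null ES| of matching sign), and a
    two-sided permutation p-value from ``n_perm`` gene-label permutations
    (shared null per set size); p-values are BH-adjusted across sets.
    Returns a DataFrame: set, size, ES, NES, pval, padj.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    scores = ranked.to_numpy(dtype=float)
    if np.all(scores == 0):
        raise ValueError("all ranking scores are zero")
    universe = pd.Index(ranked.index)
    rng = np.random.default_rng(seed)
    abs_w = np.abs(scores) ** weight
    null_cache: dict[int, np.ndarray] = {}
    rows = []
    for gs in sets:
        hits = universe.isin(gs.genes)
        k = int(hits.sum())
        if k == 0:
            warnings.warn(f"gene set {gs.name!r} has no members in the universe; skipped",
                          stacklevel=2)
            continue
        if not (min_size <= k <= max_size):
            continue
        es = enrichment_score(scores, hits, weight)
        if k not in null_cache:
            null_cache[k] = _null_es(abs_w, k, n_perm, rng)
        null = null_cache[k]
        pval = (1.0 + np.sum(np.abs(null) >= abs(es) - 1e-12)) / (n_perm + 1.0)
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        nes = es / np.mean(np.abs(same_sign)) if same_sign.size else float("nan")
        rows.append({"set": gs.name, "size": k, "ES": es, "NES": nes, "pval": pval})
    res = pd.DataFrame(rows, columns=["set", "size", "ES", "NES", "pval"])
    res["padj"] = bh_adjust(res["pval"].to_numpy()) if len(res) else []
    return res


# ---------------------------------------------------------------------------
# qPCR ΔΔCt
# ---------------------------------------------------------------------------

@dataclass
class QPCRResult:
    """ΔΔCt analysis output.

    delta_ct: per (sample, gene) ΔCt = Ct_target - Ct_housekeeping after
    averaging technical replicates on the Ct scale.  summary: per
    (condition, gene) mean ΔCt, ΔΔCt against the reference condition, and
    fold change 2^(-ΔΔCt); the reference condition's fold change is 1.
    """

    delta_ct: pd.DataFrame
    summary: pd.DataFrame


def delta_delta_ct(
    ct: pd.DataFrame,
    housekeeping_gene: str = "rpl13a",
    reference_condition: str = "control",
) -> QPCRResult:
    """ΔΔCt relative quantification for a long-format qPCR table.

    ``ct`` columns: sample, condition, gene, ct (one row per technical
    replicate).  Replicates are averaged on the Ct scale; ΔCt is taken per
    sample against the housekeeping gene; ΔΔCt per condition against the
    reference condition; fold change = 2^(-ΔΔCt).
    """
    for col in ("sample", "condition", "gene", "ct"):
        if col not in ct.columns:
            raise ValueError(f"qPCR table missing column {col!r}")
    mean_ct = ct.groupby(["sample", "condition", "gene"], as_index=False)["ct"].mean()
    hk = mean_ct[mean_ct["gene"] == housekeeping_gene].set_index("sample")["ct"]
    targets = mean_ct[mean_ct["gene"] != housekeeping_gene].copy()
    missing = set(targets["sample"]) - set(hk.index)
    if missing:
        raise ValueError(
            f"missing housekeeping gene {housekeeping_gene!r} for sample(s): "
            + ", ".join(sorted(map(str, missing)))
        )
    targets["delta_ct"] = targets["ct"].to_numpy() - hk.loc[targets["sample"]].to_numpy()
    cond = targets.groupby(["condition", "gene"], as_index=False)["delta_ct"].mean()
    ref = cond[cond["condition"] == reference_condition].set_index("gene")["delta_ct"]
    if ref.empty:
        raise ValueError(f"reference condition {reference_condition!r} not found")
    missing_ref = set(cond["gene"]) - set(ref.index)
    if missing_ref:
        raise ValueError(
            "gene(s) absent from the reference condition: " + ", ".join(sorted(missing_ref))
        )
    cond["delta_delta_ct"] = cond["delta_ct"].to_numpy() - ref.loc[cond["gene"]].to_numpy()
    cond["fold_change"] = 2.0 ** (-cond["delta_delta_ct"])
    cond = cond.rename(columns={"delta_ct": "mean_delta_ct"})
    return QPCRResult(delta_ct=targets[["sample", "condition", "gene", "delta_ct"]],
                      summary=cond)
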