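"""Differential-isoform statistics and summary reporting.

Expression is quantified as FPKM; differential isoforms are called with a
documented stand-in for a negative-binomial GLM: median-of-ratios library
normalization followed by a Welch t-test on log2-transformed normalized
counts, Benjamini-Hochberg FDR adjustment, and the joint fold-change /
FDR gate (|log2FC| >= 1 and FDR <= 0.05 by default). Enrichment of DEI
gene sets against term maps uses the upper-tail hypergeometric test.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_FC_THRESHOLD = 2.0
DEFAULT_FDR_THRESHOLD = 0.05
PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    k: int  # DEI genes in term
    K: int  # background genes in term
    n: int  # DEI gene count
    N: int  # background size
    p_value: float


def _check_design(counts: pd.DataFrame, design: pd.Series) -> tuple[list[str], list[str]]:
    groups = design.loc[list(counts.columns)]
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    a = [s for s in counts.columns if groups[s] == labels[0]]
    b = [s for s in counts.columns if groups[s] == labels[1]]
    if min(len(a), len(b)) < 2:
        raise ValueError(
            "each group needs at least 2 replicates for the differential test"
        )
    return a, b


def compute_fpkm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """FPKM[i, s] = counts[i, s] * 1e9 / (length[i] * total_counts[s])."""
    lengths = lengths.loc[counts.index].astype(float)
    if (lengths <= 0).any():
        raise ValueError("transcript lengths must be positive")
    totals = counts.sum(axis=0).astype(float)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero library size for samples {bad}")
    return counts.astype(float).mul(1e9).div(lengths, axis=0).div(totals, axis=1)


def median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style size factors: per-sample median of count ratios to the
    per-isoform geometric mean over rows expressed in every sample.
    Falls back to relative library size when no row qualifies."""
    mat = counts.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_mat = np.log(mat)
    row_ok = np.all(np.isfinite(log_mat), axis=1)
    if row_ok.any():
        log_gm = log_mat[row_ok].mean(axis=1)
        sf = np.exp(np.median(log_mat[row_ok] - log_gm[:, None], axis=0))
    else:
        totals = mat.sum(axis=0)
        sf = totals / np.exp(np.mean(np.log(totals)))
    return pd.Series(sf, index=counts.columns)


def test_differential(
    counts: pd.DataFrame, design: pd.Series
) -> pd.DataFrame:
    """Per-isoform log2 fold change (first group over second, groups in
    sorted label order) and two-sided p-value.

    Stand-in test: Welch t on log2(normalized + 0.5). All-zero isoforms
    get log2FC = 0, p = 1; so do zero-variance degenerate comparisons.
    """
    samples_a, samples_b = _check_design(counts, design)
    sf = median_of_ratios(counts)
    norm = counts.astype(float).div(sf, axis=1)
    a = norm[samples_a].to_numpy()
    b = norm[samples_b].to_numpy()
    log2fc = np.log2((a.mean(axis=1) + PSEUDOCOUNT) / (b.mean(axis=1) + PSEUDOCOUNT))
    la, lb = np.log2(a + PSEUDOCOUNT), np.log2(b + PSEUDOCOUNT)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(la, lb, axis=1, equal_var=False)
    p = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
    all_zero = (a.sum(axis=1) == 0) & (b.sum(axis=1) == 0)
    p[all_zero] = 1.0
    log2fc[all_zero] = 0.0
    return pd.DataFrame(
        {"log2fc": log2fc, "p_value": p}, index=counts.index
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_deis(
    results: pd.DataFrame,
    fc_threshold: float = DEFAULT_FC_THRESHOLD,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
) -> pd.DataFrame:
    """Add fdr / significant / direction columns to test_differential output.

    significant <=> |log2FC| >= log2(fc_threshold) AND fdr <= fdr_threshold.
    """
    out = results.copy()
    out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    out["significant"] = (np.abs(out["log2fc"]) >= np.log2(fc_threshold)) & (
        out["fdr"] <= fdr_threshold
    )
    out["direction"] = np.where(out["log2fc"] >= 0, "up", "down")
    return out


def hypergeometric_enrichment(
    dei_genes: set[str],
    term_map: dict[str, set[str]],
    background: set[str],
    p_threshold: float = 0.05,
    term_fdr: bool = False,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a DEI gene set.

    p = P(X >= k) with population N = |background|, K = |term ∩ background|,
    draws n = |dei_genes|, successes k. Terms are reported sorted by p.
    """
    stray = sorted(dei_genes - background)
    if stray:
        raise ValueError(f"DEI genes outside the background: {stray[:5]}")
    N, n = len(background), len(dei_genes)
    rows = []
    for term, members in sorted(term_map.items()):
        members = members & background
        K = len(members)
        k = len(members & dei_genes)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {"term_id": term, "k": k, "K": K, "n": n, "N": N, "p_value": min(p, 1.0)}
        )
    out = pd.DataFrame(rows, columns=["term_id", "k", "K", "n", "N", "p_value"])
    if term_fdr and len(out):
        out["fdr"] = bh_adjust(out["p_value"].to_numpy())
        out["significant"] = out["fdr"] <= p_threshold
    elif len(out):
        out["significant"] = out["p_value"] <= p_threshold
    return out.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)


def ppi_degree(edges: list[tuple[str, str]]) -> pd.DataFrame:
    """Node degrees (distinct neighbors) of an undirected edge list,
    sorted by descending degree then node id; duplicate edges count once."""
    import networkx as nx

    g = nx.Graph()
    for u, v in edges:
        if u == v:
            raise ValueError(f"self-loop on node {u!r}")
        g.add_edge(u, v)
    rows = [{"node": n, "degree": d} for n, d in g.degree()]
    out = pd.DataFrame(rows, columns=["node", "degree"])
    return out.sort_values(
        ["degree", "node"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def summarize_percentages(
    category_counts: dict[str, int],
    decimals: int = 2,
    total: int | None = None,
) -> dict[str, float]:
    """Percent of total per category, rounded half-even to ``decimals``.

    ``total`` defaults to the sum of the counts; pass it explicitly when
    categories overlap (e.g. Venn-diagram set sizes over one universe).
    """
    if any(c < 0 for c in category_counts.values()):
        raise ValueError("counts must be non-negative")
    denom = sum(category_counts.values()) if total is None else total
    if denom <= 0:
        raise ValueError("total count must be positive")
    q = Decimal(1).scaleb(-decimals)
    return {
        label: float(
            (Decimal(count) * 100 / Decimal(denom)).quantize(q, rounding=ROUND_HALF_EVEN)
        )
        for label, count in category_counts.items()
    }
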