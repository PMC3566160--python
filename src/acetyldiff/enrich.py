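"""Functional-class fold enrichment with EASE/Fisher p-values.

Re-implements the annotation-chart statistic of DAVID-style functional
analysis against user-supplied class annotations: for a class containing
K of the N background genes and k of the n query genes, the fold
enrichment is (k/n) / (K/N) — the percentage of query genes in the class
over the percentage of background genes in it — and significance comes
from the upper-tail hypergeometric (Fisher exact) probability, by
default in the conservative EASE variant that removes one query hit
before computing the tail. P-values are Benjamini–Hochberg adjusted
across the tested classes and a class passes at fold enrichment >= 1.5
and adjusted p <= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

FE_MIN = 1.5
BENJAMINI_MAX = 0.05


@dataclass(frozen=True)
class ClassEnrichmentRow:
    """Enrichment result for one functional class."""

    class_name: str
    k: int            # query genes in class
    n: int            # query genes total
    K: int            # background genes in class
    N: int            # background genes total
    fold_enrichment: float
    p_raw: float
    p_benjamini: float
    passes: bool


def _validate_counts(k: int, n: int, K: int, N: int) -> None:
    if n < 1 or N < 1:
        raise ValidationError("n and N must be >= 1")
    if K < 0 or k < 0:
        raise ValidationError("counts must be non-negative")
    if K > N or n > N or k > min(n, K):
        raise ValidationError(
            f"inconsistent contingency margins: k={k}, n={n}, K={K}, N={N}")


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """(k/n) / (K/N): query-class percentage over background-class percentage."""
    _validate_counts(k, n, K, N)
    if K == 0:
        if k > 0:
            raise ValidationError("class absent from background but hit in query")
        return 0.0
    return (k / n) / (K / N)


def ease_pvalue(k: int, n: int, K: int, N: int, *, mode: str = "ease") -> float:
    """Upper-tail hypergeometric probability of the class overlap.

    ``mode="fisher"`` gives the plain one-sided Fisher exact tail
    P(X >= k); ``mode="ease"`` first replaces k by max(k - 1, 0), the
    conservative EASE score, so a single-hit class is never significant.
    """
    _validate_counts(k, n, K, N)
    if mode not in ("ease", "fisher"):
        raise ValidationError("mode must be 'ease' or 'fisher'")
    k_eff = max(k - 1, 0) if mode == "ease" else k
    return float(min(1.0, stats.hypergeom.sf(k_eff - 1, N, K, n)))


def benjamini_hochberg(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Standard step-up FDR adjustment, returned in input order."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_classes(gene_list: Iterable[str],
                   class_annotation: Mapping[str, Iterable[str]] | pd.DataFrame,
                   background: Iterable[str], *,
                   mode: str = "ease",
                   fe_min: float = FE_MIN,
                   benjamini_max: float = BENJAMINI_MAX) -> pd.DataFrame:
    """Test every functional class hit by the query gene list.

    ``class_annotation`` maps class name to member genes (or a two-column
    frame class/gene_id); ``background`` is the gene universe. Symbols
    are compared case-insensitively after uppercasing. Classes with zero
    query hits are excluded from testing and from the BH family, matching
    the convention of reporting only represented terms. Rows are sorted
    by fold enrichment descending.
    """
    query = {str(g).upper() for g in gene_list}
    if not query:
        raise ValidationError("empty gene list")
    universe = {str(g).upper() for g in background}
    if not query <= universe:
        missing = sorted(query - universe)[:5]
        raise ValidationError(f"query genes outside background universe: {missing}")

    if isinstance(class_annotation, pd.DataFrame):
        classes: dict[str, set[str]] = {}
        name_col, gene_col = class_annotation.columns[:2]
        for cls, sub in class_annotation.groupby(name_col, sort=False):
            classes[str(cls)] = {str(g).upper() for g in sub[gene_col]}
    else:
        classes = {str(c): {str(g).upper() for g in members}
                   for c, members in class_annotation.items()}
    if not classes:
        raise ValidationError("no functional classes supplied")

    n, N = len(query), len(universe)
    rows = []
    for cls, members in sorted(classes.items()):
        members = members & universe
        k = len(query & members)
        if k == 0:
            continue
        K = len(members)
        rows.append((cls, k, K, fold_enrichment(k, n, K, N),
                     ease_pvalue(k, n, K, N, mode=mode)))
    if not rows:
        return pd.DataFrame(columns=["class_name", "k", "n", "K", "N",
                                     "fold_enrichment", "p_raw", "p_benjamini",
                                     "passes"])
    adj = benjamini_hochberg([r[4] for r in rows])
    out = pd.DataFrame({
        "class_name": [r[0] for r in rows],
        "k": [r[1] for r in rows],
        "n": n,
        "K": [r[2] for r in rows],
        "N": N,
        "fold_enrichment": [r[3] for r in rows],
        "p_raw": [r[4] for r in rows],
        "p_benjamini": adj,
    })
    out["passes"] = (out["fold_enrichment"] >= fe_min) & (out["p_benjamini"] <= benjamini_max)
    return (out.sort_values(["fold_enrichment", "class_name"],
                            ascending=[False, True], kind="mergesort")
            .reset_index(drop=True))
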