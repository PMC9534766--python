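"""Gene-level aggregation of per-cell p-values.

Each gene is tested in several cells — the (annotation mask, maximum-MAF
cutoff) grid — and the per-cell p-values are combined into one gene-level
p-value with the Cauchy combination (ACAT), which is robust to dependence
among the cells.  The Cauchy transform is undefined at p = 1, so whenever any
cell has p exactly 1 the combination falls back to the minimum p-value with a
Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .set_tests import SetTestResult

EXOME_WIDE_THRESHOLD = 2.5e-6

# Cauchy tangent blows up as p -> 1; representation noise just under 1 is
# clamped here.  Exact p = 1 routes to the min-P fallback instead.
_P_CLAMP_HIGH = 1.0 - 1e-15


@dataclass
class GeneResult:
    """Combined p-value for one gene across all tested cells."""

    gene_id: str
    p_combined: float
    n_cells: int
    fallback_minp: bool
    best_cell: tuple[str, float]
    cells: list[SetTestResult]

    def __post_init__(self) -> None:
        if not (0.0 < self.p_combined <= 1.0):
            raise ValueError("p_combined must lie in (0, 1]")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


def cauchy_combine(pvals) -> float:
    """ACAT combination ``p = 1/2 - arctan(mean_i tan((1/2 - p_i) pi)) / pi``.

    Requires every p strictly in (0, 1); tiny p-values use the asymptote
    ``tan((1/2 - p) pi) ~ 1/(p pi)`` for numerical stability.  Identical
    inputs are returned unchanged (k = 1 is the identity).
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any(p >= 1.0) or np.any(p <= 0.0):
        raise ValueError(
            "cauchy_combine requires p strictly in (0,1); "
            "route p = 1 through combine_gene's min-P fallback"
        )
    tiny = p < 1e-15
    terms = np.empty_like(p)
    terms[~tiny] = np.tan((0.5 - p[~tiny]) * np.pi)
    terms[tiny] = 1.0 / (p[tiny] * np.pi)
    t = terms.mean()
    if t > 1e15:  # same asymptote on the way back
        out = 1.0 / (t * np.pi)
    else:
        out = 0.5 - np.arctan(t) / np.pi
    return float(min(max(out, np.finfo(float).tiny), _P_CLAMP_HIGH))


def combine_gene(cells: list[SetTestResult], which: str = "skato") -> GeneResult:
    """Combine one gene's per-cell p-values into a :class:`GeneResult`.

    ``which`` selects the per-cell test (skato / skat / burden).  Cells with
    p exactly 1 break the Cauchy transform, so in that case the combined
    value is ``min(min_p * n_cells, 1)`` (min-P with Bonferroni) and
    ``fallback_minp`` is set.  Untested cells must not be passed in: an
    absent test carries no evidence and is excluded from the count.
    """
    if not cells:
        raise ValueError("gene has no tested cells")
    if which not in ("skato", "skat", "burden"):
        raise ValueError("which must be one of skato, skat, burden")
    ps = np.array([getattr(c, f"p_{which}") for c in cells], dtype=float)
    i_best = int(np.argmin(ps))
    best = (cells[i_best].mask.label(), cells[i_best].mask.max_maf)
    k = ps.size
    if np.any(ps >= 1.0):
        p_comb = float(min(ps.min() * k, 1.0))
        fallback = True
    else:
        p_comb = cauchy_combine(np.minimum(ps, _P_CLAMP_HIGH))
        fallback = False
    return GeneResult(
        gene_id=cells[0].gene_id, p_combined=p_comb, n_cells=k,
        fallback_minp=fallback, best_cell=best, cells=list(cells),
    )


def significance_flag(gr: GeneResult, threshold: float = EXOME_WIDE_THRESHOLD) -> bool:
    """True iff the combined p-value is strictly below the exome-wide
    significance threshold (default 2.5e-6)."""
    return bool(gr.p_combined < threshold)
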