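"""Expression-context analysis of enriched terms.

Two steps: (1) reduce a raw gene × sample expression matrix to a gene ×
context log2 fold-change of *percent-expressing* values — the share of
samples (cells) in a context where the gene clears a detection threshold,
contrasted against the median share over the remaining contexts; (2) for
each enriched term and context, test whether the miRNA-targeted term genes
are expression-shifted relative to the non-targeted ones (MWU by default,
one-sided "less" to capture miRNA repression; KS and two-sided available).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import ExpressionContextMatrix, TermCollection
from .enrichment import EnrichmentRow
from .errors import DomainError
from .stats import bh_adjust, ks_test, mwu_test

logger = logging.getLogger("mirenrich")


@dataclass(frozen=True)
class PercentExpressingSpec:
    """Detection threshold and pseudocount for the percent-expressing metric.

    ``single_cell_counts`` counts a cell as expressing at >= 1 read;
    ``tissue_tpm`` counts a sample at >= 10 TPM; ``generic`` takes a user
    threshold. ``epsilon`` (percentage points) keeps log ratios finite when a
    gene is undetected everywhere.
    """

    threshold: float = 1.0
    epsilon: float = 0.01
    mode: str = "generic"

    def __post_init__(self):
        if self.threshold < 0:
            raise DomainError("threshold must be nonnegative")
        if self.epsilon <= 0:
            raise DomainError("epsilon must be positive")
        if self.mode not in ("single_cell_counts", "tissue_tpm", "generic"):
            raise DomainError(f"unknown mode: {self.mode}")

    @classmethod
    def single_cell(cls, epsilon: float = 0.01) -> "PercentExpressingSpec":
        return cls(threshold=1.0, epsilon=epsilon, mode="single_cell_counts")

    @classmethod
    def tissue(cls, epsilon: float = 0.01) -> "PercentExpressingSpec":
        return cls(threshold=10.0, epsilon=epsilon, mode="tissue_tpm")


@dataclass
class ContextTestRow:
    term_id: str
    context_id: str
    resource_tag: str
    test: str
    alternative: str
    statistic: float
    p_raw: float
    p_adjusted: float
    n_targeted: int
    n_nontargeted: int
    direction_note: str


def percent_expressing_log2fc(
    raw: pd.DataFrame,
    sample_contexts: Mapping[str, str],
    spec: PercentExpressingSpec,
) -> ExpressionContextMatrix:
    """Percent-expressing log2FC per gene and context.

    For gene g and context c, p_gc = 100 * (fraction of c's samples with
    value >= threshold) and the reported value is
    log2((p_gc + eps) / (median_{c' != c} p_gc' + eps)).
    """
    contexts = sorted(set(sample_contexts.values()))
    if len(contexts) < 2:
        raise DomainError("percent-expressing log2FC needs >= 2 contexts")
    by_ctx: dict[str, list[str]] = {c: [] for c in contexts}
    for s in raw.columns:
        if s in sample_contexts:
            by_ctx[sample_contexts[s]].append(s)
    for c, samples in by_ctx.items():
        if not samples:
            raise DomainError(f"context {c} has no samples in the matrix")
    pct = pd.DataFrame(
        {
            c: 100.0 * (raw[by_ctx[c]].to_numpy(dtype=float) >= spec.threshold).mean(axis=1)
            for c in contexts
        },
        index=raw.index,
    )
    eps = spec.epsilon
    vals = {}
    arr = pct.to_numpy()
    for j, c in enumerate(contexts):
        others = np.delete(arr, j, axis=1)
        med = np.median(others, axis=1)
        vals[c] = np.log2((arr[:, j] + eps) / (med + eps))
    out = pd.DataFrame(vals, index=raw.index)
    return ExpressionContextMatrix(out)


@dataclass
class ContextTestReport:
    """Tested rows plus an explicit record of terms skipped for small groups."""

    rows: list[ContextTestRow]
    skipped: list[tuple[str, str]]  # (term_id, reason)


def context_test(
    enriched: Sequence[EnrichmentRow],
    terms: TermCollection,
    expr: ExpressionContextMatrix,
    test: str = "mwu",
    alternative: str = "less",
    min_group: int = 3,
    adjust: str = "within_term",
) -> ContextTestReport:
    """Compare targeted vs non-targeted term genes across every context.

    For each enrichment row, the term's genes present in the expression
    matrix are split by the row's ``targeted_gene_ids``; both groups need
    >= min_group members or the term is skipped (recorded, not silent). The
    default alternative "less" asks whether targeted genes sit at *lower*
    log2FC — the repressive footprint of the miRNAs. BH adjustment is within
    each term across contexts (``adjust="global"`` pools every row instead).
    """
    if test not in ("mwu", "ks"):
        raise DomainError(f"unknown test: {test}")
    if adjust not in ("within_term", "global"):
        raise DomainError(f"unknown adjustment scope: {adjust}")
    expr_genes = set(expr.genes)
    testfun = mwu_test if test == "mwu" else ks_test

    all_rows: list[ContextTestRow] = []
    skipped: list[tuple[str, str]] = []
    for row in enriched:
        term = terms.get(row.term_id)
        present = term.genes & expr_genes
        n_missing = len(term.genes) - len(present)
        targeted = sorted(present & row.targeted_gene_ids)
        nontargeted = sorted(present - row.targeted_gene_ids)
        if len(targeted) < min_group or len(nontargeted) < min_group:
            reason = (
                f"group sizes targeted={len(targeted)} nontargeted={len(nontargeted)}"
                f" below min_group={min_group}"
            )
            warnings.warn(f"term {row.term_id} skipped: {reason}", stacklevel=2)
            skipped.append((row.term_id, reason))
            continue
        note = f"genes_missing_from_expr={n_missing}"
        term_rows: list[ContextTestRow] = []
        for ctx in expr.contexts:
            xv = expr.values.loc[targeted, ctx].to_numpy()
            yv = expr.values.loc[nontargeted, ctx].to_numpy()
            res = testfun(xv, yv, alternative=alternative)
            term_rows.append(
                ContextTestRow(
                    term_id=row.term_id,
                    context_id=ctx,
                    resource_tag=expr.tag(ctx),
                    test=test,
                    alternative=alternative,
                    statistic=res.statistic,
                    p_raw=res.p_value,
                    p_adjusted=1.0,
                    n_targeted=len(targeted),
                    n_nontargeted=len(nontargeted),
                    direction_note=note,
                )
            )
        if adjust == "within_term":
            adj = bh_adjust([r.p_raw for r in term_rows])
            for r, a in zip(term_rows, adj):
                r.p_adjusted = a
        term_rows.sort(key=lambda r: (r.p_raw, r.context_id))
        all_rows.extend(term_rows)
    if adjust == "global" and all_rows:
        adj = bh_adjust([r.p_raw for r in all_rows])
        for r, a in zip(all_rows, adj):
            r.p_adjusted = a
    return ContextTestReport(rows=all_rows, skipped=skipped)
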