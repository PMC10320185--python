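"""miRNA-centric term over-representation analysis.

Three combination designs over a set of query miRNAs:

* **targets union** — pool the targets of all query miRNAs and test each term
  once (combined regulatory effect);
* **targets intersection** — keep only genes targeted by at least
  ``n_required`` of the query miRNAs (co-targeting / functional redundancy);
* **pathways union** — test each miRNA's target set separately per term and
  merge the per-miRNA p-values with Fisher's method (potent term regulators).

Counts are taken against the term collection's gene universe (annotated
genes); the test is the one-sided Fisher exact upper tail, or its Wallenius
biased-urn generalisation when a per-gene targeting-bias covariate is given.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .datamodel import InteractionSet, MirnaQuery, TermCollection
from .errors import DomainError, EmptyInputError
from .stats import (
    UrnSpec,
    bh_adjust,
    estimate_bias_odds,
    fisher_combine,
    hypergeom_upper_tail,
    wallenius_upper_tail,
)

logger = logging.getLogger("mirenrich")


@dataclass
class TargetSet:
    """Genes selected from the query miRNAs, with per-gene provenance."""

    genes: frozenset[str]
    provenance: dict[str, frozenset[str]]
    mode: str  # union | intersection_n
    n_required: int = 1
    missing_mirnas: tuple[str, ...] = ()


@dataclass
class EnrichmentRow:
    term_id: str
    term_name: str
    genes_in_term: int
    targeted_in_term: int
    targets_in_universe: int
    universe_size: int
    p_raw: float
    p_adjusted: float
    method: str
    odds: float
    targeted_gene_ids: frozenset[str]
    contributing_mirnas: frozenset[str]


@dataclass
class PathwaysUnionRow:
    """Per-term Fisher-combined significance with per-miRNA drill-down."""

    term_id: str
    term_name: str
    combined_statistic: float
    combined_p: float
    p_adjusted: float
    n_combined: int
    sub_rows: list = field(default_factory=list)  # (mirna_id, EnrichmentRow)


def build_target_set(
    query: MirnaQuery,
    interactions: InteractionSet,
    mode: str = "union",
    n_required: int = 2,
) -> TargetSet:
    """Assemble the combined target set of the query miRNAs.

    ``union`` keeps genes targeted by >= 1 query miRNA; ``intersection_n``
    keeps genes targeted by >= ``n_required`` of them (n_required = 1
    coincides with the union by definition). Query miRNAs absent from the
    interaction set are reported in ``missing_mirnas``, never silently
    dropped.
    """
    if mode not in ("union", "intersection_n"):
        raise DomainError(f"unknown target-set mode: {mode}")
    found = [m for m in query if m in interactions.index]
    missing = tuple(m for m in query if m not in interactions.index)
    if missing:
        warnings.warn(
            f"query miRNAs absent from interactions: {', '.join(missing)}",
            stacklevel=2,
        )
    if not found:
        raise EmptyInputError("no query miRNA found in the interaction set")
    if mode == "intersection_n":
        if n_required < 1 or n_required > len(query):
            raise DomainError(
                f"n_required={n_required} outside [1, {len(query)}]"
            )
    else:
        n_required = 1
    prov: dict[str, set[str]] = {}
    for m in found:
        for g in interactions.targets(m):
            prov.setdefault(g, set()).add(m)
    kept = {g: frozenset(ms) for g, ms in prov.items() if len(ms) >= n_required}
    return TargetSet(
        genes=frozenset(kept),
        provenance=kept,
        mode=mode,
        n_required=n_required,
        missing_mirnas=missing,
    )


def enrich(
    targets: TargetSet,
    terms: TermCollection,
    method: str = "classic",
    bias: Optional[Mapping[str, float]] = None,
    min_overlap: int = 1,
) -> list[EnrichmentRow]:
    """Test every term for over-representation of the target set.

    The universe is the term collection's annotated-gene universe; target
    genes outside it are excluded (and counted in a log line). ``classic``
    uses the exact hypergeometric upper tail; ``wallenius`` additionally
    requires ``bias`` (a nonnegative per-gene covariate over the universe,
    e.g. the per-gene count of interacting miRNAs) and fits per-term odds via
    :func:`mirenrich.stats.estimate_bias_odds`. Rows are BH-adjusted across
    all tested terms and sorted by (p_raw, term_id).
    """
    if method not in ("classic", "wallenius"):
        raise DomainError(f"unknown enrichment method: {method}")
    if method == "wallenius" and bias is None:
        raise DomainError("wallenius enrichment requires a bias covariate")
    universe = terms.universe_set
    in_uni = targets.genes & universe
    dropped = len(targets.genes) - len(in_uni)
    if dropped:
        logger.info("enrich: %d target genes outside the term universe excluded", dropped)
    if not in_uni:
        raise EmptyInputError("no target gene overlaps the term universe")
    N, n = len(universe), len(in_uni)
    flags = {g: 1 for g in in_uni}

    rows: list[EnrichmentRow] = []
    for t in terms.terms:
        overlap = t.genes & in_uni
        k = len(overlap)
        if k < min_overlap:
            continue
        K = len(t.genes)
        if method == "classic":
            res = hypergeom_upper_tail(UrnSpec(N, K, n, k))
            odds = 1.0
        else:
            odds = estimate_bias_odds(t.genes, flags, bias, universe)
            res = wallenius_upper_tail(UrnSpec(N, K, n, k, odds))
        contributing = frozenset(
            m for g in overlap for m in targets.provenance.get(g, ())
        )
        rows.append(
            EnrichmentRow(
                term_id=t.term_id,
                term_name=t.term_name,
                genes_in_term=K,
                targeted_in_term=k,
                targets_in_universe=n,
                universe_size=N,
                p_raw=res.p_value,
                p_adjusted=1.0,
                method=method,
                odds=odds,
                targeted_gene_ids=frozenset(overlap),
                contributing_mirnas=contributing,
            )
        )
    if not rows:
        warnings.warn("no term passed the min_overlap filter", stacklevel=2)
        return rows
    adj = bh_adjust([r.p_raw for r in rows])
    for r, a in zip(rows, adj):
        r.p_adjusted = max(a, r.p_raw)
    rows.sort(key=lambda r: (r.p_raw, r.term_id))
    return rows


def pathways_union(
    query: MirnaQuery,
    interactions: InteractionSet,
    terms: TermCollection,
    method: str = "classic",
    bias: Optional[Mapping[str, float]] = None,
    min_overlap: int = 1,
    combine_filter: str = "all",
    alpha: float = 0.05,
) -> list[PathwaysUnionRow]:
    """Per-miRNA enrichment merged per term with Fisher's method.

    Each query miRNA is tested individually against every term; per term,
    the per-miRNA p-values are combined into one significance level. With
    ``combine_filter="all"`` (default) every tested miRNA's p enters the
    combination; ``"significant_only"`` combines only p < alpha (a more
    aggressive reading that inflates significance — the number combined is
    reported in ``n_combined``). Combined p-values are BH-adjusted across
    terms.
    """
    if combine_filter not in ("all", "significant_only"):
        raise DomainError(f"unknown combine_filter: {combine_filter}")
    per_term: dict[str, list[tuple[str, EnrichmentRow]]] = {}
    for m in query:
        if m not in interactions.index:
            warnings.warn(f"query miRNA {m} absent from interactions", stacklevel=2)
            continue
        tset = build_target_set(MirnaQuery([m]), interactions, mode="union")
        try:
            rows = enrich(tset, terms, method=method, bias=bias, min_overlap=min_overlap)
        except EmptyInputError:
            logger.info("pathways_union: %s has no targets in the universe", m)
            continue
        for r in rows:
            per_term.setdefault(r.term_id, []).append((m, r))

    out: list[PathwaysUnionRow] = []
    for term_id, subs in per_term.items():
        pvals = [r.p_raw for _, r in subs]
        if combine_filter == "significant_only":
            kept = [(m, r) for m, r in subs if r.p_raw < alpha]
            if not kept:
                warnings.warn(
                    f"term {term_id}: no per-miRNA p < {alpha}; term dropped",
                    stacklevel=2,
                )
                continue
            subs_used = kept
        else:
            subs_used = subs
        comb = fisher_combine([r.p_raw for _, r in subs_used])
        out.append(
            PathwaysUnionRow(
                term_id=term_id,
                term_name=subs[0][1].term_name,
                combined_statistic=comb.statistic,
                combined_p=comb.p_value,
                p_adjusted=1.0,
                n_combined=len(subs_used),
                sub_rows=list(subs),
            )
        )
    if not out:
        return out
    adj = bh_adjust([r.combined_p for r in out])
    for r, a in zip(out, adj):
        r.p_adjusted = max(a, r.combined_p)
    out.sort(key=lambda r: (r.combined_p, r.term_id))
    return out


def default_bias_covariate(
    interactions: InteractionSet, universe: Sequence[str]
) -> dict[str, float]:
    """Targeting-bias covariate: distinct interacting miRNAs per gene.

    Genes never seen in the interaction resource get 0. This is the default
    Wallenius covariate — the most direct measure of unequal targeting
    propensity across genes.
    """
    counts = interactions.mirnas_per_gene()
    return {g: float(counts.get(g, 0)) for g in universe}
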