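"""Shared in-memory containers for interaction, term, expression and screen data.

Identifiers are opaque, case-sensitive strings throughout; no ID-version
conversion is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, EmptyInputError, FormatError


@dataclass(frozen=True)
class Interaction:
    """One miRNA → gene regulatory edge."""

    mirna: str
    gene: str
    evidence: Optional[str] = None
    score: Optional[float] = None


class InteractionSet:
    """Deduplicated miRNA → gene edge table with a per-miRNA target index.

    Duplicate (mirna, gene) pairs are collapsed on construction; distinct
    evidence tags are concatenated with ';' and the first non-null score is
    kept. ``n_collapsed`` records how many raw edges were merged away.
    """

    def __init__(self, edges: Iterable[Interaction]):
        merged: dict[tuple[str, str], Interaction] = {}
        n_raw = 0
        for e in edges:
            n_raw += 1
            if not e.mirna or not e.gene:
                raise FormatError("interaction ids must be non-empty strings")
            key = (e.mirna, e.gene)
            if key in merged:
                old = merged[key]
                tags = [t for t in (old.evidence, e.evidence) if t]
                # keep distinct tags, input order
                seen: list[str] = []
                for t in ";".join(tags).split(";") if tags else []:
                    if t and t not in seen:
                        seen.append(t)
                merged[key] = Interaction(
                    e.mirna,
                    e.gene,
                    evidence=";".join(seen) if seen else None,
                    score=old.score if old.score is not None else e.score,
                )
            else:
                merged[key] = e
        self.edges: list[Interaction] = list(merged.values())
        self.n_collapsed: int = n_raw - len(self.edges)
        index: dict[str, set[str]] = {}
        for e in self.edges:
            index.setdefault(e.mirna, set()).add(e.gene)
        self.index: dict[str, frozenset[str]] = {
            m: frozenset(g) for m, g in index.items()
        }

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def mirnas(self) -> frozenset[str]:
        return frozenset(self.index)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(e.gene for e in self.edges)

    def targets(self, mirna: str) -> frozenset[str]:
        return self.index.get(mirna, frozenset())

    def mirnas_per_gene(self) -> dict[str, int]:
        """Number of distinct miRNAs targeting each gene.

        This is the default targeting-bias covariate for Wallenius testing.
        """
        counts: dict[str, int] = {}
        for e in self.edges:
            counts[e.gene] = counts.get(e.gene, 0) + 1
        return counts


@dataclass(frozen=True)
class Term:
    term_id: str
    term_name: str
    genes: frozenset[str]


class TermCollection:
    """Named gene sets plus the derived gene universe (union of all sets)."""

    def __init__(self, terms: Sequence[Term]):
        if not terms:
            raise EmptyInputError("term collection is empty")
        ids = [t.term_id for t in terms]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate term_id(s): {', '.join(dup)}")
        for t in terms:
            if not t.genes:
                raise FormatError(f"term {t.term_id} has an empty gene set")
        self.terms: list[Term] = list(terms)
        self._by_id = {t.term_id: t for t in terms}
        universe: set[str] = set()
        for t in terms:
            universe |= t.genes
        self.universe: tuple[str, ...] = tuple(sorted(universe))
        self.universe_set: frozenset[str] = frozenset(universe)

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self._by_id

    def get(self, term_id: str) -> Term:
        try:
            return self._by_id[term_id]
        except KeyError:
            raise KeyError(f"unknown term_id: {term_id}") from None


class ExpressionContextMatrix:
    """Gene × context matrix of log2 fold-change values.

    ``values`` is a pandas DataFrame indexed by gene_id with context_id
    columns; ``resource_tags`` optionally labels each context with its
    originating resource.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        resource_tags: Optional[Mapping[str, str]] = None,
    ):
        if values.columns.duplicated().any():
            raise FormatError("duplicate context_ids in expression matrix")
        if values.index.duplicated().any():
            raise FormatError("duplicate gene_ids in expression matrix")
        arr = values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise FormatError("expression matrix contains non-finite values")
        self.values = values.astype(float)
        self.resource_tags: dict[str, str] = dict(resource_tags or {})

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def contexts(self) -> list[str]:
        return list(self.values.columns)

    def tag(self, context_id: str) -> str:
        return self.resource_tags.get(context_id, "")


#: columns every ScreenTable dataframe carries, in canonical order
SCREEN_COLUMNS = [
    "element_id",
    "element_type",
    "neg_score",
    "neg_p",
    "neg_rank",
    "pos_score",
    "pos_p",
    "pos_rank",
]


class ScreenTable:
    """Ranked positive/negative selection results for genes and miRNAs.

    Rows mirror a MAGeCK gene_summary: per element, a score, p-value and rank
    in each selection direction. Ranks within each direction form a
    permutation of 1..n; smaller rank means stronger selection.
    """

    def __init__(self, df: pd.DataFrame, dialect: str = "rra"):
        if dialect not in ("rra", "mle"):
            raise DomainError(f"unknown screen dialect: {dialect}")
        missing = [c for c in SCREEN_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"screen table missing columns: {', '.join(missing)}")
        df = df[SCREEN_COLUMNS].reset_index(drop=True)
        for col in ("neg_p", "pos_p"):
            p = df[col].to_numpy(dtype=float)
            if np.any((p < 0) | (p > 1)):
                raise FormatError(f"{col} outside [0, 1]")
        n = len(df)
        for col in ("neg_rank", "pos_rank"):
            r = df[col].to_numpy()
            if sorted(r) != list(range(1, n + 1)):
                raise FormatError(f"{col} is not a permutation of 1..{n}")
        self.df = df
        self.dialect = dialect

    def __len__(self) -> int:
        return len(self.df)

    def gene_rows(self) -> pd.DataFrame:
        return self.df[self.df["element_type"] == "gene"]

    def mirna_rows(self) -> pd.DataFrame:
        return self.df[self.df["element_type"] == "mirna"]


@dataclass
class MirnaQuery:
    """Ordered, duplicate-free list of query miRNA identifiers."""

    mirnas: list[str]
    annotation_scheme: str = "custom"

    def __post_init__(self):
        if not self.mirnas:
            raise EmptyInputError("miRNA query is empty")
        if len(set(self.mirnas)) != len(self.mirnas):
            raise DomainError("miRNA query contains duplicates")
        if self.annotation_scheme not in ("mirbase", "mirgenedb", "custom"):
            raise DomainError(f"unknown annotation scheme: {self.annotation_scheme}")

    def __len__(self) -> int:
        return len(self.mirnas)

    def __iter__(self):
        return iter(self.mirnas)
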