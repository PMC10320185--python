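"""Readers and writers for every external format the engine touches.

Formats: interaction TSV (header required, configurable column names), GMT
term collections, expression TSV matrices with a sample→context map, MAGeCK
gene_summary screen tables (RRA or MLE dialect), and TSV/JSON result tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .datamodel import (
    SCREEN_COLUMNS,
    ExpressionContextMatrix,
    Interaction,
    InteractionSet,
    ScreenTable,
    Term,
    TermCollection,
)
from .errors import EmptyInputError, FormatError

logger = logging.getLogger("mirenrich")

DEFAULT_INTERACTION_COLUMNS = {
    "mirna": "mirna",
    "gene": "gene",
    "evidence": "evidence",
    "score": "score",
}

#: default pattern classifying screen elements as miRNAs: miRBase-style
#: species prefixes or a "mir" substring, case-insensitive
DEFAULT_MIRNA_PATTERN = r"(?i)(^hsa-|^mmu-|mir)"


def read_interactions(
    path: Union[str, Path],
    column_spec: Optional[Mapping[str, str]] = None,
) -> InteractionSet:
    """Load a miRNA→gene interaction TSV into a deduplicated InteractionSet."""
    spec = dict(DEFAULT_INTERACTION_COLUMNS)
    if column_spec:
        spec.update(column_spec)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: empty interaction file") from None
    for key in ("mirna", "gene"):
        if spec[key] not in df.columns:
            raise FormatError(f"{path}: missing mandatory column '{spec[key]}'")
    if len(df) == 0:
        raise EmptyInputError(f"{path}: interaction file has a header but no rows")
    has_ev = spec["evidence"] in df.columns
    has_sc = spec["score"] in df.columns
    edges = []
    for row in df.itertuples(index=False):
        d = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        ev = d.get(spec["evidence"]) if has_ev else None
        sc = d.get(spec["score"]) if has_sc else None
        edges.append(
            Interaction(
                str(d[spec["mirna"]]),
                str(d[spec["gene"]]),
                evidence=None if ev is None or pd.isna(ev) else str(ev),
                score=None if sc is None or pd.isna(sc) else float(sc),
            )
        )
    iset = InteractionSet(edges)
    if iset.n_collapsed:
        logger.info("read_interactions: collapsed %d duplicate edges", iset.n_collapsed)
    return iset


def write_interactions(iset: InteractionSet, path: Union[str, Path]) -> None:
    rows = [
        {
            "mirna": e.mirna,
            "gene": e.gene,
            "evidence": e.evidence if e.evidence is not None else "",
            "score": e.score if e.score is not None else "",
        }
        for e in sorted(iset.edges, key=lambda e: (e.mirna, e.gene))
    ]
    pd.DataFrame(rows, columns=["mirna", "gene", "evidence", "score"]).to_csv(
        path, sep="\t", index=False
    )


def read_gmt(path: Union[str, Path]) -> TermCollection:
    """Parse a GMT file: term_id TAB term_name TAB gene [TAB gene ...]."""
    terms: list[Term] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs term_id, name and >=1 gene"
                )
            term_id, name = fields[0], fields[1]
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise FormatError(f"{path}:{lineno}: term {term_id} has no genes")
            if term_id in seen:
                raise FormatError(f"{path}:{lineno}: duplicate term_id {term_id}")
            seen.add(term_id)
            terms.append(Term(term_id, name, genes))
    if not terms:
        raise EmptyInputError(f"{path}: GMT file contains no terms")
    return TermCollection(terms)


def write_gmt(terms: TermCollection, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for t in terms.terms:
            fh.write("\t".join([t.term_id, t.term_name, *sorted(t.genes)]) + "\n")


def read_expression_matrix(
    path: Union[str, Path],
    metadata_path: Optional[Union[str, Path]] = None,
) -> ExpressionContextMatrix:
    """Read a precomputed gene × context log2FC TSV (first column = gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise FormatError(f"{path}: expression matrix has no context columns")
    tags: dict[str, str] = {}
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
        if not {"context_id", "resource_tag"} <= set(meta.columns):
            raise FormatError(f"{metadata_path}: needs context_id and resource_tag columns")
        tags = dict(zip(meta["context_id"], meta["resource_tag"]))
    return ExpressionContextMatrix(df, resource_tags=tags)


def write_expression_matrix(
    expr: ExpressionContextMatrix, path: Union[str, Path]
) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id")


def read_raw_expression(
    matrix_path: Union[str, Path], context_map_path: Union[str, Path]
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a raw gene × sample matrix plus its sample→context map TSV."""
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0)
    cmap = pd.read_csv(context_map_path, sep="\t", dtype=str)
    if not {"sample_id", "context_id"} <= set(cmap.columns):
        raise FormatError(f"{context_map_path}: needs sample_id and context_id columns")
    mapping = dict(zip(cmap["sample_id"], cmap["context_id"]))
    missing = [s for s in raw.columns if s not in mapping]
    if missing:
        raise FormatError(
            f"{context_map_path}: no context for sample(s) {', '.join(missing[:5])}"
        )
    return raw, mapping


_RRA_REQUIRED = {
    "neg_score": "neg|score",
    "neg_p": "neg|p-value",
    "pos_score": "pos|score",
    "pos_p": "pos|p-value",
}
_RRA_RANKS = {"neg_rank": "neg|rank", "pos_rank": "pos|rank"}


def read_mageck(
    path: Union[str, Path],
    dialect: str = "rra",
    mirna_pattern: str = DEFAULT_MIRNA_PATTERN,
    column_spec: Optional[Mapping[str, str]] = None,
) -> ScreenTable:
    """Parse a MAGeCK gene_summary table into a ScreenTable.

    RRA dialect expects the pipe-separated columns ("neg|p-value", ...);
    ranks are re-derived from scores (ascending, ties broken by element id)
    when the rank columns are absent. The MLE dialect maps a beta column and
    per-direction p-values via ``column_spec`` (keys: beta, neg_p, pos_p, or
    a single p); negative selection is the beta's ascending order. Rows are
    classified gene vs mirna by ``mirna_pattern`` matched on the element id.
    """
    df = pd.read_csv(path, sep="\t")
    if "id" not in df.columns:
        raise FormatError(f"{path}: missing 'id' column")
    n = len(df)
    if n == 0:
        raise EmptyInputError(f"{path}: screen file has no rows")
    out = pd.DataFrame({"element_id": df["id"].astype(str)})

    if dialect == "rra":
        missing = [c for c in _RRA_REQUIRED.values() if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: missing RRA column(s): {', '.join(missing)}")
        for key, col in _RRA_REQUIRED.items():
            out[key] = df[col].astype(float)
        for key, col in _RRA_RANKS.items():
            if col in df.columns:
                out[key] = df[col].astype(int)
            else:
                score = key.split("_")[0] + "_score"
                order = np.lexsort((out["element_id"].to_numpy(), out[score].to_numpy()))
                ranks = np.empty(n, dtype=int)
                ranks[order] = np.arange(1, n + 1)
                out[key] = ranks
                logger.info("read_mageck: %s re-derived from %s", col, score)
    elif dialect == "mle":
        spec = dict(column_spec or {})
        beta_col = spec.get("beta")
        if beta_col is None:
            cand = [c for c in df.columns if c.endswith("|beta")]
            if len(cand) != 1:
                raise FormatError(f"{path}: MLE beta column ambiguous; pass column_spec")
            beta_col = cand[0]
        if beta_col not in df.columns:
            raise FormatError(f"{path}: missing beta column '{beta_col}'")
        beta = df[beta_col].astype(float)
        p_col = spec.get("p")
        neg_p_col, pos_p_col = spec.get("neg_p", p_col), spec.get("pos_p", p_col)
        if neg_p_col is None or pos_p_col is None:
            cand = [c for c in df.columns if c.endswith("|wald-p-value") or c.endswith("|p-value")]
            if len(cand) != 1:
                raise FormatError(f"{path}: MLE p-value column ambiguous; pass column_spec")
            neg_p_col = pos_p_col = cand[0]
        for c in (neg_p_col, pos_p_col):
            if c not in df.columns:
                raise FormatError(f"{path}: missing p-value column '{c}'")
        # ascending score = stronger selection in both directions
        out["neg_score"] = beta
        out["pos_score"] = -beta
        out["neg_p"] = df[neg_p_col].astype(float)
        out["pos_p"] = df[pos_p_col].astype(float)
        for key in ("neg_rank", "pos_rank"):
            score = key.split("_")[0] + "_score"
            order = np.lexsort((out["element_id"].to_numpy(), out[score].to_numpy()))
            ranks = np.empty(n, dtype=int)
            ranks[order] = np.arange(1, n + 1)
            out[key] = ranks
    else:
        raise FormatError(f"unknown MAGeCK dialect: {dialect}")

    pat = re.compile(mirna_pattern)
    out["element_type"] = [
        "mirna" if pat.search(e) else "gene" for e in out["element_id"]
    ]
    if not (out["element_type"] == "mirna").any():
        logger.warning(
            "read_mageck: no element matched the miRNA pattern %r", mirna_pattern
        )
    return ScreenTable(out[SCREEN_COLUMNS], dialect=dialect)


def write_screen(screen: ScreenTable, path: Union[str, Path]) -> None:
    """Write a ScreenTable back out in MAGeCK RRA gene_summary dialect."""
    df = screen.df
    out = pd.DataFrame(
        {
            "id": df["element_id"],
            "num": 1,
            "neg|score": df["neg_score"],
            "neg|p-value": df["neg_p"],
            "neg|rank": df["neg_rank"],
            "pos|score": df["pos_score"],
            "pos|p-value": df["pos_p"],
            "pos|rank": df["pos_rank"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def _row_to_dict(row) -> dict:
    if dataclasses.is_dataclass(row):
        d = dataclasses.asdict(row)
    elif isinstance(row, Mapping):
        d = dict(row)
    else:
        raise FormatError(f"cannot serialize row of type {type(row).__name__}")
    out = {}
    for k, v in d.items():
        if isinstance(v, (set, frozenset)):
            out[k] = sorted(v)
        elif isinstance(v, dict):
            out[k] = {kk: vv for kk, vv in sorted(v.items())}
        else:
            out[k] = v
    return out


def write_results(
    rows: Sequence,
    path: Union[str, Path],
    format: str = "tsv",
    columns: Optional[Sequence[str]] = None,
) -> None:
    """Serialize a result table (dataclass rows or dicts) as TSV or JSON.

    Floats are written in shortest round-trip form (full double precision,
    well beyond 12 significant digits), so re-reading reproduces every
    p-value exactly. TSV set-valued fields are joined with ';'.
    """
    if rows is None:
        raise FormatError("rows must not be None")
    dicts = [_row_to_dict(r) for r in rows]
    if columns is None:
        if dicts:
            columns = list(dicts[0].keys())
        elif rows is not None and hasattr(rows, "columns"):
            columns = list(rows.columns)  # pragma: no cover
        else:
            columns = []
    if format == "json":
        with open(path, "w") as fh:
            json.dump(dicts, fh, indent=1, default=str)
            fh.write("\n")
        return
    if format != "tsv":
        raise FormatError(f"unknown output format: {format}")
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for d in dicts:
            cells = []
            for c in columns:
                v = d.get(c, "")
                if isinstance(v, list):
                    cells.append(";".join(str(x) for x in v))
                elif isinstance(v, dict):
                    cells.append(";".join(f"{k}={x}" for k, x in v.items()))
                elif isinstance(v, float):
                    cells.append(repr(v))
                else:
                    cells.append(str(v))
            fh.write("\t".join(cells) + "\n")
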