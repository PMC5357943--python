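"""Over-representation analysis of gene lists against annotation term sets.

One-sided Fisher exact test per term (equivalently the hypergeometric upper
tail of the overlap), Benjamini-Hochberg adjustment across terms, and a
significance call at a configurable FDR.  Term sets come from GMT-style
files; the universe defaults to the tested gene population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["AnnotationCatalog", "read_gmt", "fisher_pvalue", "fisher_enrichment"]


@dataclass
class AnnotationCatalog:
    """term id -> (term name, gene set), restricted to a gene universe."""

    terms: dict
    universe: frozenset

    @classmethod
    def from_terms(cls, terms: dict, universe) -> "AnnotationCatalog":
        universe = frozenset(universe)
        restricted = {}
        for tid, (name, genes) in terms.items():
            inside = frozenset(genes) & universe
            if inside:
                restricted[tid] = (name, inside)
        return cls(terms=restricted, universe=universe)


def read_gmt(path: str | Path, universe) -> AnnotationCatalog:
    """Read a GMT file (term <tab> description <tab> gene...), restricting
    every term to the universe and dropping terms that empty out."""
    terms = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        terms[fields[0]] = (fields[1], frozenset(fields[2:]))
    return AnnotationCatalog.from_terms(terms, universe)


def fisher_pvalue(overlap, query_size, term_size, universe_size):
    """One-sided (over-representation) Fisher exact p-value(s).

    Equals the hypergeometric upper tail P(X >= overlap) for X ~
    Hypergeom(universe_size, term_size, query_size); vectorized over array
    inputs.
    """
    overlap = np.asarray(overlap)
    p = hypergeom.sf(overlap - 1, universe_size, term_size, query_size)
    return np.clip(p, 0.0, 1.0)


def fisher_enrichment(
    query, catalog: AnnotationCatalog, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-term over-representation table for a query gene set.

    Genes outside the universe are dropped with a warning; an empty
    effective query is a hard error.  Columns: term, name, overlap,
    term_size, odds_ratio, p, q, significant (q <= alpha).
    """
    query = set(query)
    outside = query - catalog.universe
    if outside:
        warnings.warn(f"dropping {len(outside)} query genes outside the universe")
        query &= catalog.universe
    if not query:
        raise ValueError("query has no genes inside the universe")
    n_u, n_q = len(catalog.universe), len(query)
    rows = []
    for tid, (name, genes) in sorted(catalog.terms.items()):
        a = len(query & genes)                 # query & term
        b = n_q - a                            # query \ term
        c = len(genes) - a                     # term \ query
        d = n_u - n_q - c                      # rest
        with np.errstate(divide="ignore", invalid="ignore"):
            odds = (a * d) / (b * c) if b * c else np.inf if a * d else np.nan
        rows.append(
            {"term": tid, "name": name, "overlap": a, "term_size": len(genes),
             "odds_ratio": odds,
             "p": float(fisher_pvalue(a, n_q, len(genes), n_u))}
        )
    table = pd.DataFrame(rows)
    table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    table["significant"] = table["q"] <= alpha
    return table.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
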