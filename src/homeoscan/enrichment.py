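"""GO-term over/under-representation of event gene sets.

For each GO term annotated in the reference set, a 2x2 table (annotated
vs not, test set vs reference set) is tested with a two-sided Fisher's
exact test; p-values are Benjamini-Hochberg adjusted over the universe
of tested terms.  The reference group is the full set of analyzed genes,
so "Under" flags functions depleted among, say, silenced homeologs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .stats import adjust_pvalues_bh, fisher_exact_2x2

__all__ = ["EnrichmentRow", "fisher_exact_2x2", "enrich_groups", "load_annotations"]


@dataclass(frozen=True)
class EnrichmentRow:
    go_id: str
    term: str
    category: str  # P (process) / F (function) / C (component), "" if unknown
    a: int  # test-set genes annotated with the term
    b: int  # reference-set genes annotated
    c: int  # test-set genes not annotated
    d: int  # reference-set genes not annotated
    p_value: float
    fdr: float
    direction: str  # Over / Under


def load_annotations(path) -> dict[str, set[str]]:
    """Read a two-column (gene_id, go_id) TSV into gene -> set-of-terms."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, set[str]] = {}
    for gene, term in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(str(gene), set()).add(str(term))
    return out


def enrich_groups(
    test_genes: Iterable[str],
    reference_genes: Iterable[str],
    annotations: Mapping[str, set[str]],
    term_info: Mapping[str, tuple[str, str]] | None = None,
) -> list[EnrichmentRow]:
    """Fisher enrichment of ``test_genes`` against ``reference_genes``.

    The test set must be a subset of the reference group, which is used
    as given (conventionally the full set of analyzed genes, test genes
    included); a test set equal to the reference therefore yields p = 1
    for every term.  ``term_info`` optionally maps a GO id to
    (name, category) for display.  Rows come back sorted by p-value.
    """
    test = set(test_genes)
    reference = set(reference_genes)
    if not test:
        raise ValueError("empty test set")
    if not test <= reference:
        raise ValueError("test set is not a subset of the reference gene universe")

    terms = sorted({t for g in reference for t in annotations.get(g, ())})
    if not terms:
        raise ValueError("no annotated terms in the reference universe")
    rows = []
    for term in terms:
        a = sum(1 for g in test if term in annotations.get(g, ()))
        b = sum(1 for g in reference if term in annotations.get(g, ()))
        c = len(test) - a
        d = len(reference) - b
        p, direction = fisher_exact_2x2(a, b, c, d)
        rows.append((term, a, b, c, d, p, direction))

    fdrs = adjust_pvalues_bh([r[5] for r in rows])
    out = []
    for (term, a, b, c, d, p, direction), fdr in zip(rows, fdrs):
        name, cat = (term_info or {}).get(term, ("", ""))
        out.append(
            EnrichmentRow(
                go_id=term, term=name, category=cat,
                a=a, b=b, c=c, d=d,
                p_value=p, fdr=float(fdr), direction=direction,
            )
        )
    out.sort(key=lambda r: (r.p_value, r.go_id))
    return out


def enrichment_to_frame(rows: Iterable[EnrichmentRow]) -> pd.DataFrame:
    """Significance-table layout: GO-ID, Term, Category, FDR, P-Value,
    Test, Ref, notAnnotTest, notAnnotRef, Over/Under."""
    return pd.DataFrame(
        [
            {
                "GO-ID": r.go_id,
                "Term": r.term,
                "Category": r.category,
                "FDR": r.fdr,
                "P-Value": r.p_value,
                "Test": r.a,
                "Ref": r.b,
                "notAnnotTest": r.c,
                "notAnnotRef": r.d,
                "Over/Under": r.direction,
            }
            for r in rows
        ]
    )
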