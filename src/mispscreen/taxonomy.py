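"""Lineage comparison and per-peptide taxonomic categorisation.

Whether a MISP's LCA is a problem depends on how it relates to the input
peptide's LCA.  Comparing the ordered root→leaf lineages gives four
mutually exclusive relations: *identical* (same taxon), *more specific*
(the input LCA is a proper ancestor of the MISP LCA), *less specific*
(the reverse), or *different* (neither is an ancestor of the other — the
lineages diverge).

Per peptide, those relations roll up to one category.  A single "less
specific" MISP dominates the call — an alternative reading that widens the
taxonomic assignment undermines a specific claim no matter what else the
peptide matches — followed by "different", then "more specific".
"""

from __future__ import annotations

from collections import Counter
from enum import Enum
from typing import Iterable, Optional

import pandas as pd

from .lca_backend import LcaResult


class TaxonRelation(Enum):
    IDENTICAL = "identical"
    MORE_SPECIFIC = "more_specific"
    LESS_SPECIFIC = "less_specific"
    DIFFERENT = "different"


class PeptideCategory(Enum):
    NO_ALTERNATE = "no_alternate"
    ALL_IDENTICAL = "all_identical"
    DIFFERENT = "different"
    MORE_SPECIFIC = "more_specific"
    LESS_SPECIFIC = "less_specific"


def relation(input_lca: LcaResult, other_lca: LcaResult) -> TaxonRelation:
    """Relate a MISP's LCA to the input peptide's LCA by lineage ancestry.

    Ancestry is decided by lineage-prefix comparison on taxon ids (ranks can
    be absent, so rank names are never consulted): ``a`` is an ancestor of
    ``b`` iff ``a``'s id chain is a strict prefix of ``b``'s.
    """
    if not input_lca.lineage.entries or not other_lca.lineage.entries:
        raise ValueError("cannot compare empty lineages")
    if input_lca.taxon_id == other_lca.taxon_id:
        return TaxonRelation.IDENTICAL
    a = input_lca.lineage.taxon_ids()
    b = other_lca.lineage.taxon_ids()
    if len(a) < len(b) and b[: len(a)] == a:
        return TaxonRelation.MORE_SPECIFIC
    if len(b) < len(a) and a[: len(b)] == b:
        return TaxonRelation.LESS_SPECIFIC
    return TaxonRelation.DIFFERENT


def categorize_peptide(
    input_lca: Optional[LcaResult], misp_lcas: Iterable[LcaResult]
) -> PeptideCategory:
    """Collapse the relations of all (non-identity) MISP LCAs to one category.

    Empty ``misp_lcas`` → ``NO_ALTERNATE``.  All-identical relations →
    ``ALL_IDENTICAL``.  Otherwise priority is less_specific > different >
    more_specific.  A MISP LCA with no input LCA to compare against is an
    anomalous but real situation; it is reported as ``DIFFERENT`` (callers
    flag it separately).
    """
    misp_lcas = list(misp_lcas)
    if not misp_lcas:
        return PeptideCategory.NO_ALTERNATE
    if input_lca is None:
        return PeptideCategory.DIFFERENT
    relations = {relation(input_lca, lca) for lca in misp_lcas}
    if relations == {TaxonRelation.IDENTICAL}:
        return PeptideCategory.ALL_IDENTICAL
    if TaxonRelation.LESS_SPECIFIC in relations:
        return PeptideCategory.LESS_SPECIFIC
    if TaxonRelation.DIFFERENT in relations:
        return PeptideCategory.DIFFERENT
    return PeptideCategory.MORE_SPECIFIC


def all_identical(lcas: Iterable[LcaResult]) -> bool:
    """True iff every LCA in the list shares one taxon id (vacuously true)."""
    ids = [lca.taxon_id for lca in lcas]
    return len(set(ids)) <= 1


def confusion_matrix(rows: Iterable[tuple[str, str]]) -> pd.DataFrame:
    """Count (input LCA name, MISP LCA name) pairs.

    Rows are input taxa, columns MISP taxa, cells pair counts; label sets
    are the unions of observed names, sorted for a stable CSV layout.
    """
    counts = Counter(rows)
    if not counts:
        return pd.DataFrame()
    input_names = sorted({a for a, _ in counts})
    misp_names = sorted({b for _, b in counts})
    matrix = pd.DataFrame(0, index=input_names, columns=misp_names, dtype=int)
    for (a, b), n in counts.items():
        matrix.loc[a, b] = n
    matrix.index.name = "input_lca"
    return matrix
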