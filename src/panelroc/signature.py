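"""Per-cell gene-signature score for whole signatures.

The score rewards both the expression level and the co-expression of a
signature's genes within each single cell.  For a cell c and a gene set G
(after intersection with the matrix's genes):

    score_c = (k_c / |G|) * sum_{g in G} x_gc

where k_c is the number of signature genes expressed in the cell — strictly
above ``expressed_threshold`` (0 by default, the same strict-inequality
convention used everywhere in this package).  The score is therefore
directly proportional to the number of expressed signature genes and to
their summed expression; a cell expressing none of them scores exactly 0.
This product form is this package's concrete definition of the score; the
formula is kept behind a single function so an alternative arithmetic can
be swapped in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GeneSubsetError


@dataclass(frozen=True)
class GeneSet:
    """A named list of unique gene symbols."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise GeneSubsetError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise GeneSubsetError(f"gene set {self.name!r} has duplicate symbols")


@dataclass
class SignatureScoreResult:
    cell_ids: list[str]
    score: np.ndarray
    n_genes_used: int
    geneset_name: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "score": self.score,
                "n_genes_used": self.n_genes_used,
            }
        )


def signature_score_per_cell(
    expression: pd.DataFrame,
    geneset: GeneSet,
    expressed_threshold: float = 0.0,
) -> SignatureScoreResult:
    """Compute the gene-signature score for every cell of a gene-by-cell
    matrix.  Signature genes absent from the matrix are dropped with a
    warning and |G| shrinks accordingly; an empty intersection raises."""
    present = [g for g in geneset.genes if g in expression.index]
    absent = [g for g in geneset.genes if g not in expression.index]
    if not present:
        raise GeneSubsetError(
            f"no gene of set {geneset.name!r} found in the expression matrix"
        )
    if absent:
        warnings.warn(
            f"gene set {geneset.name!r}: dropping {len(absent)} gene(s) absent "
            "from the matrix: " + ", ".join(absent),
            stacklevel=2,
        )
    sub = expression.loc[present].to_numpy(dtype=float)  # genes x cells
    k = (sub > expressed_threshold).sum(axis=0)
    total = sub.sum(axis=0)
    score = (k / len(present)) * total
    return SignatureScoreResult(
        cell_ids=[str(c) for c in expression.columns],
        score=np.asarray(score, dtype=float),
        n_genes_used=len(present),
        geneset_name=geneset.name,
    )
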