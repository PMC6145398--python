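"""Somatic mutation data: binary gene x sample matrices and per-gene mutation scores.

The central quantity is the mutation score

    M(i) = sum over samples k carrying a mutation in gene i of 1/N_k

where N_k is the number of mutated genes in sample k.  Every sample thus
contributes a total weight of exactly 1, spread equally over its mutated
genes, which prevents hypermutated samples from dominating the score.
Genes never observed mutated receive the background mutation score (BMS)
1/N_max, where N_max is the largest per-sample mutated-gene count, so no
mutated gene can score below an unmutated one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyDataError, FormatError

#: Variant classifications retained under ``nonsilent_only`` (standard MAF terms
#: for nonsense, missense, frame-shift indel, splice-site and stop-loss events).
DEFAULT_NONSILENT: frozenset[str] = frozenset(
    {
        "Nonsense_Mutation",
        "Missense_Mutation",
        "Frame_Shift_Del",
        "Frame_Shift_Ins",
        "Splice_Site",
        "Nonstop_Mutation",
    }
)

#: Default MAF column names (TCGA dialect); all are configurable in load_maf.
MAF_GENE_COL = "Hugo_Symbol"
MAF_SAMPLE_COL = "Tumor_Sample_Barcode"
MAF_CLASS_COL = "Variant_Classification"


@dataclass(frozen=True)
class MutationMatrix:
    """Binary mutation indicator matrix, genes as rows and samples as columns.

    ``data`` holds 0/1 integers; per-sample burdens N_k and N_max are always
    recomputed from the entries, never trusted from file metadata.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if vals.size and not np.isin(vals, (0, 1)).all():
            raise FormatError("mutation matrix entries must be 0 or 1")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise FormatError(f"duplicate gene identifier: {dup!r}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise FormatError(f"duplicate sample identifier: {dup!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def indicator(self) -> np.ndarray:
        return self.data.to_numpy(dtype=np.int64)

    @property
    def burden(self) -> pd.Series:
        """N_k: number of mutated genes per sample."""
        return self.data.sum(axis=0)

    @property
    def n_max(self) -> int:
        """N_max: largest per-sample mutated-gene count (0 for an all-zero matrix)."""
        return int(self.burden.max()) if len(self.samples) else 0

    @property
    def gene_counts(self) -> pd.Series:
        """|K_i|: number of samples in which each gene is mutated."""
        return self.data.sum(axis=1)

    def subset_samples(self, samples: Sequence[str]) -> "MutationMatrix":
        return MutationMatrix(self.data.loc[:, list(samples)])


@dataclass(frozen=True)
class GeneScoreTable:
    """Per-gene mutation scores M(i) plus the background mutation score 1/N_max."""

    scores: pd.Series
    bms: float

    def get(self, gene: str) -> float:
        """Score of ``gene``; a gene outside the table has empty K_i, hence BMS."""
        val = self.scores.get(gene)
        return float(val) if val is not None else self.bms

    def __contains__(self, gene: str) -> bool:
        return gene in self.scores.index


def load_maf(
    path: str | Path,
    nonsilent_only: bool = True,
    gene_col: str = MAF_GENE_COL,
    sample_col: str = MAF_SAMPLE_COL,
    class_col: str = MAF_CLASS_COL,
    nonsilent_classes: Iterable[str] = DEFAULT_NONSILENT,
) -> MutationMatrix:
    """Read a tab-separated MAF and binarize it to a :class:`MutationMatrix`.

    M(i,j) = 1 iff gene i has at least one retained mutation record in sample j;
    duplicate (gene, sample) records collapse to a single 1.  With
    ``nonsilent_only`` only records whose variant classification is in
    ``nonsilent_classes`` are retained (use ``nonsilent_only=False`` for data
    that includes noncoding genes, where any mutation counts).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = [gene_col, sample_col] + ([class_col] if nonsilent_only else [])
    for col in required:
        if col not in df.columns:
            raise FormatError(f"MAF file {path} is missing required column {col!r}")
    if nonsilent_only:
        df = df[df[class_col].isin(set(nonsilent_classes))]
    if df.empty:
        raise EmptyDataError(f"no mutation records retained from {path}")
    table = pd.crosstab(df[gene_col], df[sample_col]).clip(upper=1)
    table.index.name = None
    table.columns.name = None
    return MutationMatrix(table.astype(np.int64))


def load_binary_matrix(path: str | Path) -> MutationMatrix:
    """Read a gene x sample 0/1 TSV (first column gene IDs, header = sample IDs)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    arr = df.to_numpy()
    bad = ~np.isin(arr, (0, 1))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise FormatError(
            f"non-binary entry {arr[r, c]!r} at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r} in {path}"
        )
    m = MutationMatrix(df.astype(np.int64))
    if m.n_max < 1:
        raise EmptyDataError(f"matrix in {path} contains no mutations")
    return m


def write_binary_matrix(m: MutationMatrix, path: str | Path) -> None:
    m.data.to_csv(path, sep="\t")


def compute_mutation_scores(
    m: MutationMatrix, universe: Sequence[str] | None = None
) -> GeneScoreTable:
    """Compute M(i) for every gene of ``m`` (and of ``universe``, if given).

    Genes listed in ``universe`` but absent from the matrix have empty K_i and
    receive the BMS.  Raises :class:`EmptyDataError` when the matrix holds no
    mutations at all (N_max = 0 would make the BMS undefined).
    """
    if m.n_max < 1:
        raise EmptyDataError("cannot score a mutation matrix with no mutations")
    burden = m.burden.to_numpy(dtype=float)
    # All-zero samples contribute nothing; masking avoids a 0-division warning.
    inv = np.divide(1.0, burden, out=np.zeros_like(burden), where=burden > 0)
    raw = m.indicator @ inv
    bms = 1.0 / m.n_max
    scores = pd.Series(raw, index=m.data.index, dtype=float)
    scores[m.gene_counts == 0] = bms
    if universe is not None:
        extra = pd.Index(pd.unique(pd.Series(list(universe)))).difference(scores.index)
        if len(extra):
            scores = pd.concat([scores, pd.Series(bms, index=extra, dtype=float)])
    return GeneScoreTable(scores=scores, bms=bms)
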