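"""Evaluation of a ranking against reference cancer gene sets.

Three criteria are provided: ROC/AUC for recovering reference genes (with the
paired DeLong test for comparing two score vectors on the same universe), the
F1 score as a function of rank cutoff, and the cumulative number of reference
genes recovered at fixed cutoffs.  The recall used inside F1 divides by the
FULL reference-set size, not only the members present in the scoring universe;
this deliberately caps attainable recall so that methods scoring different
universes remain comparable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve

from .errors import DegenerateInputError, EmptyDataError

DEFAULT_CUTOFFS: tuple[int, ...] = (20, 50, 100, 200, 500)


@dataclass(frozen=True)
class ReferenceGeneSet:
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise EmptyDataError(f"reference gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)


def load_gene_set(path: str | Path, name: str | None = None) -> ReferenceGeneSet:
    """Read a plain-text gene list (one ID per line, '#' comments)."""
    members = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            members.add(line)
    return ReferenceGeneSet(name=name or Path(path).stem, members=frozenset(members))


def write_gene_set(ref: ReferenceGeneSet, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(ref.members)))


def _labels_scores(
    ranking: pd.DataFrame, ref: ReferenceGeneSet
) -> tuple[np.ndarray, np.ndarray]:
    y = ranking["gene"].isin(ref.members).to_numpy()
    s = ranking["s_maxmif"].to_numpy(dtype=float)
    return y, s


def roc_auc(
    ranking: pd.DataFrame, ref: ReferenceGeneSet
) -> tuple[np.ndarray, float]:
    """ROC points and AUC for recovering reference genes from the ranking.

    The AUC uses midrank tie handling, i.e. it equals the Mann-Whitney U
    statistic normalized by n_pos * n_neg.  Returns an (n, 2) array of
    (FPR, TPR) points from (0, 0) to (1, 1) and the AUC.
    """
    y, s = _labels_scores(ranking, ref)
    if not y.any():
        raise DegenerateInputError("no reference genes present in the scoring universe")
    if y.all():
        raise DegenerateInputError("every universe gene is a reference gene")
    fpr, tpr, _ = _roc_curve(y, s, drop_intermediate=False)
    return np.column_stack([fpr, tpr]), float(_trapezoid_auc(fpr, tpr))


@dataclass(frozen=True)
class DeLongResult:
    auc_a: float
    auc_b: float
    z: float
    p_value: float


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Midrank placement values V10 (per positive), V01 (per negative), and AUC."""
    m, n = len(pos), len(neg)
    allv = np.concatenate([pos, neg])
    r = rankdata(allv)
    r_pos = rankdata(pos)
    r_neg = rankdata(neg)
    v10 = (r[:m] - r_pos) / n
    v01 = 1.0 - (r[m:] - r_neg) / m
    return v10, v01, float(v10.mean())


def delong_compare(
    scores_a: pd.Series, scores_b: pd.Series, ref: ReferenceGeneSet
) -> DeLongResult:
    """Paired DeLong test of H0: AUC_a = AUC_b on the same gene universe.

    Both score vectors must be indexed by the same genes.  The covariance of
    the two AUC estimators is computed from midrank placement values; the
    two-sided p-value comes from the standard normal.  A zero-variance
    difference with equal AUCs yields p = 1 by convention; a zero-variance
    nonzero difference is a degenerate input.
    """
    if set(scores_a.index) != set(scores_b.index):
        raise DegenerateInputError("score vectors must cover the same gene universe")
    scores_b = scores_b.reindex(scores_a.index)
    y = scores_a.index.isin(ref.members)
    if not y.any() or y.all():
        raise DegenerateInputError("both classes must be present in the universe")
    a, b = scores_a.to_numpy(dtype=float), scores_b.to_numpy(dtype=float)
    v10a, v01a, auc_a = _placements(a[y], a[~y])
    v10b, v01b, auc_b = _placements(b[y], b[~y])
    m, n = int(y.sum()), int((~y).sum())
    s10 = np.cov(np.vstack([v10a, v10b]))
    s01 = np.cov(np.vstack([v01a, v01b]))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 0 or np.isclose(var_diff, 0.0, atol=1e-300):
        if np.isclose(diff, 0.0):
            return DeLongResult(auc_a, auc_b, 0.0, 1.0)
        raise DegenerateInputError(
            "zero variance of the AUC difference with unequal AUCs"
        )
    z = diff / np.sqrt(var_diff)
    p = float(2 * norm.sf(abs(z)))
    return DeLongResult(auc_a, auc_b, float(z), p)


def f1_curve(
    ranking: pd.DataFrame, ref: ReferenceGeneSet, max_rank: int = 500
) -> pd.Series:
    """F1 at every rank cutoff 1..max_rank.

    precision(k) = hits(k)/k; recall(k) = hits(k)/|ref| with |ref| the FULL
    reference-set size; F1 = 0 where precision + recall = 0.
    """
    if ranking.empty:
        raise EmptyDataError("ranking is empty")
    kmax = min(max_rank, len(ranking))
    hits = ranking["gene"].head(kmax).isin(ref.members).to_numpy().cumsum()
    k = np.arange(1, kmax + 1)
    precision = hits / k
    recall = hits / len(ref)
    denom = precision + recall
    f1 = np.divide(2 * precision * recall, denom, out=np.zeros(kmax), where=denom > 0)
    return pd.Series(f1, index=pd.RangeIndex(1, kmax + 1, name="rank_cutoff"))


def cumulative_recovery(
    ranking: pd.DataFrame,
    ref: ReferenceGeneSet,
    cutoffs: Sequence[int] = DEFAULT_CUTOFFS,
) -> dict[int, int]:
    """Number of reference genes among the top-k candidates at each cutoff."""
    is_ref = ranking["gene"].isin(ref.members).to_numpy()
    return {int(k): int(is_ref[: min(k, len(is_ref))].sum()) for k in cutoffs}


@dataclass(frozen=True)
class EvaluationReport:
    reference: str
    roc: np.ndarray
    auc: float
    f1: pd.Series
    recovery: dict[int, int]
    n_positives_in_universe: int
    n_reference_total: int

    def summary(self) -> dict:
        return {
            "reference": self.reference,
            "auc": self.auc,
            "recovery": {str(k): v for k, v in self.recovery.items()},
            "f1_at_max_rank": float(self.f1.iloc[-1]),
            "max_f1": float(self.f1.max()),
            "n_positives_in_universe": self.n_positives_in_universe,
            "n_reference_total": self.n_reference_total,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2) + "\n")


def evaluate(
    ranking: pd.DataFrame,
    ref: ReferenceGeneSet,
    max_rank: int = 500,
    cutoffs: Sequence[int] = DEFAULT_CUTOFFS,
) -> EvaluationReport:
    """Run all three criteria against one reference set."""
    roc, auc_val = roc_auc(ranking, ref)
    return EvaluationReport(
        reference=ref.name,
        roc=roc,
        auc=auc_val,
        f1=f1_curve(ranking, ref, max_rank=max_rank),
        recovery=cumulative_recovery(ranking, ref, cutoffs=cutoffs),
        n_positives_in_universe=int(ranking["gene"].isin(ref.members).sum()),
        n_reference_total=len(ref),
    )
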