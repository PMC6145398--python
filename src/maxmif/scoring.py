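"""MIF and MaxMIF scoring.

The mutational impact function between two interacting genes is a
gravity-style product of their mutation scores attenuated by the squared
interaction distance:

    MIF(i,j) = M(i) * M(j) / r_ij^2 = M(i) * M(j) * W(i,j)^2

A gene's MaxMIF score is the strongest impact it shares with any network
neighbor; a gene with no neighbors falls back to M(i)^2 / r_max^2, i.e. the
impact it would have with a copy of itself at the largest distance present in
the network.  Ranking genes by this score pushes rarely mutated genes that sit
next to strongly mutated interactors ahead of frequently mutated loners.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import MaxMIFError
from .mutation import GeneScoreTable, MutationMatrix, compute_mutation_scores
from .network import WeightedNetwork, neighbors

Scorer = Literal["max", "mean", "frequency"]

RANKING_COLUMNS = ["rank", "gene", "s_maxmif", "mutation_score", "best_neighbor", "mif_best"]


def mif(scores: GeneScoreTable, net: WeightedNetwork, i: str, j: str) -> float:
    """MIF(i,j) = M(i)*M(j)*W(i,j)^2 for an existing edge (i, j)."""
    w = net.weight(i, j)  # raises AbsentEdgeError for non-edges
    return scores.get(i) * scores.get(j) * w * w


def _isolated_score(scores: GeneScoreTable, net: WeightedNetwork, i: str) -> float:
    m = scores.get(i)
    return m * m / net.r_max**2


def maxmif_score(scores: GeneScoreTable, net: WeightedNetwork, i: str) -> float:
    """S_MaxMIF(i): max MIF over neighbors, or M(i)^2/r_max^2 if isolated."""
    nbrs = neighbors(net, i)
    if not nbrs:
        return _isolated_score(scores, net, i)
    return max(mif(scores, net, i, j) for j in nbrs)


def meanmif_score(scores: GeneScoreTable, net: WeightedNetwork, i: str) -> float:
    """Arithmetic-mean variant of :func:`maxmif_score` (same isolated fallback)."""
    nbrs = neighbors(net, i)
    if not nbrs:
        return _isolated_score(scores, net, i)
    vals = [mif(scores, net, i, j) for j in nbrs]
    return float(np.mean(vals))


def _best_neighbor(
    scores: GeneScoreTable, net: WeightedNetwork, i: str
) -> tuple[str | None, float]:
    """Argmax neighbor and its MIF; ties broken toward the smaller gene ID."""
    nbrs = neighbors(net, i)
    if not nbrs:
        return None, _isolated_score(scores, net, i)
    best_j, best_v = None, -np.inf
    for j in sorted(nbrs):
        v = mif(scores, net, i, j)
        if v > best_v:
            best_j, best_v = j, v
    return best_j, best_v


def rank_genes(
    scores: GeneScoreTable,
    net: WeightedNetwork,
    universe: Sequence[str],
    scorer: Scorer = "max",
    counts: pd.Series | None = None,
) -> pd.DataFrame:
    """Rank every universe gene by the chosen scorer.

    Ties are broken by descending mutation score M(i), then ascending gene ID,
    so the output is deterministic.  ``counts`` (per-gene mutated-sample counts
    |K_i|) is required only for the frequency baseline, which ranks genes by
    raw mutation frequency and ignores the network.

    Returns a DataFrame with columns rank, gene, s_maxmif, mutation_score,
    best_neighbor, mif_best; ``best_neighbor`` is None exactly when the gene
    has no neighbors, and is only populated for the max scorer.
    """
    genes = list(dict.fromkeys(universe))
    if not genes:
        raise MaxMIFError("scoring universe is empty")
    mscore = np.array([scores.get(g) for g in genes])
    best_nbr: list[str | None] = [None] * len(genes)
    best_mif = np.full(len(genes), np.nan)
    if scorer == "max":
        s = np.empty(len(genes))
        for idx, g in enumerate(genes):
            nb, v = _best_neighbor(scores, net, g)
            best_nbr[idx] = nb
            best_mif[idx] = v
            s[idx] = v
    elif scorer == "mean":
        s = np.array([meanmif_score(scores, net, g) for g in genes])
    elif scorer == "frequency":
        if counts is None:
            raise MaxMIFError("frequency scorer requires per-gene mutated-sample counts")
        s = counts.reindex(genes).fillna(0).to_numpy(dtype=float)
    else:
        raise MaxMIFError(f"unknown scorer {scorer!r}")
    df = pd.DataFrame(
        {
            "gene": genes,
            "s_maxmif": s,
            "mutation_score": mscore,
            "best_neighbor": best_nbr,
            "mif_best": best_mif,
        }
    )
    df = df.sort_values(
        ["s_maxmif", "mutation_score", "gene"], ascending=[False, False, True]
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df


UniversePolicy = Literal["union", "mutated_only", "network_only"]


def scoring_universe(
    m: MutationMatrix, net: WeightedNetwork, policy: UniversePolicy = "union"
) -> list[str]:
    """Genes to rank: mutation-data genes, network genes, or their union.

    The union is the default: network-only genes carry the BMS (empty K_i) and
    mutation-only genes use the isolated-gene fallback, so both score branches
    stay meaningful.
    """
    mut = m.genes
    netg = sorted(net.nodes)
    if policy == "union":
        return sorted(set(mut) | set(netg))
    if policy == "mutated_only":
        return sorted(mut)
    if policy == "network_only":
        return netg
    raise MaxMIFError(f"unknown universe policy {policy!r}")


def prioritize(
    m: MutationMatrix,
    net: WeightedNetwork,
    scorer: Scorer = "max",
    universe_policy: UniversePolicy = "union",
) -> pd.DataFrame:
    """Full pipeline: mutation scores -> per-gene scoring -> ranked table."""
    universe = scoring_universe(m, net, universe_policy)
    scores = compute_mutation_scores(m, universe=universe)
    return rank_genes(scores, net, universe, scorer=scorer, counts=m.gene_counts)


def write_ranking(ranking: pd.DataFrame, path: str | Path) -> None:
    """Write the ranked table as TSV (byte-identical for identical inputs)."""
    out = ranking.copy()
    out["best_neighbor"] = out["best_neighbor"].fillna("")
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_ranking(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "best_neighbor": str})
    df["gene"] = df["gene"].astype(str)
    return df
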