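"""Perturbation scenarios for probing ranking stability.

Three scenarios, mirroring the standard stress tests for network-based
prioritizers: random subsampling of mutation samples, random subsampling of
network edges, and Gaussian noise added to edge weights.  Subsampled or
noised networks keep their original standardized weights (re-standardizing
would confound the perturbation with a global rescale), but r_max is always
recomputed on the perturbed network because the isolated-gene fallback refers
to the current network.  Noised weights are clamped from below at 1e-20 so
every interaction distance stays finite; no upper clamp is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .errors import EmptyDataError, MaxMIFError
from .evaluation import DEFAULT_CUTOFFS, ReferenceGeneSet, cumulative_recovery, roc_auc
from .mutation import MutationMatrix
from .network import WeightedNetwork
from .scoring import Scorer, prioritize

WEIGHT_FLOOR = 1e-20

KINDS = ("sample_subsample", "edge_subsample", "weight_noise")


@dataclass(frozen=True)
class PerturbationSpec:
    """One robustness scenario: what to perturb, how hard, how often.

    ``level`` is the fraction of samples/edges retained for the subsampling
    kinds (the reference protocol uses 0.5 and 0.1) or the Gaussian noise
    standard deviation for weight noise (0.1 and 0.2).
    """

    kind: str
    level: float
    repeats: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise MaxMIFError(f"unknown perturbation kind {self.kind!r}")
        if self.kind == "weight_noise":
            if self.level < 0:
                raise MaxMIFError("noise standard deviation must be >= 0")
        elif not 0 < self.level <= 1:
            raise MaxMIFError("retained fraction must be in (0, 1]")
        if self.repeats < 1:
            raise MaxMIFError("repeats must be >= 1")


def perturb_samples(m: MutationMatrix, fraction: float, seed: int) -> MutationMatrix:
    """Retain round(fraction * n_samples) columns (min 1), chosen uniformly.

    Column order is preserved, so fraction 1.0 is an exact identity.
    """
    if not 0 < fraction <= 1:
        raise MaxMIFError("fraction must be in (0, 1]")
    n = len(m.samples)
    k = max(1, round(fraction * n))
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=k, replace=False))
    return MutationMatrix(m.data.iloc[:, idx])


def perturb_edges(net: WeightedNetwork, fraction: float, seed: int) -> WeightedNetwork:
    """Uniform edge subsample without replacement; node set kept intact."""
    if not 0 < fraction <= 1:
        raise MaxMIFError("fraction must be in (0, 1]")
    edges = net.edges()
    if not edges:
        raise EmptyDataError("network has no edges")
    k = max(1, round(fraction * len(edges)))
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(edges), size=k, replace=False))
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes)
    for i in idx:
        a, b, w = edges[i]
        g.add_edge(a, b, weight=w)
    return WeightedNetwork(g)


def perturb_weights(net: WeightedNetwork, sd: float, seed: int) -> WeightedNetwork:
    """Add N(0, sd) noise to every weight independently; clamp below at 1e-20."""
    if sd < 0:
        raise MaxMIFError("noise standard deviation must be >= 0")
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes)
    for a, b, w in net.edges():
        noised = w + rng.normal(0.0, sd)
        g.add_edge(a, b, weight=max(noised, WEIGHT_FLOOR))
    return WeightedNetwork(g)


def _apply(
    m: MutationMatrix, net: WeightedNetwork, spec: PerturbationSpec, seed: int
) -> tuple[MutationMatrix, WeightedNetwork]:
    if spec.kind == "sample_subsample":
        return perturb_samples(m, spec.level, seed), net
    if spec.kind == "edge_subsample":
        return m, perturb_edges(net, spec.level, seed)
    return m, perturb_weights(net, spec.level, seed)


def run_robustness(
    m: MutationMatrix,
    net: WeightedNetwork,
    ref: ReferenceGeneSet,
    spec: PerturbationSpec,
    scorer: Scorer = "max",
    cutoffs: Sequence[int] = DEFAULT_CUTOFFS,
) -> dict:
    """Perturb-score-evaluate ``spec.repeats`` times and summarize the AUCs.

    Repeat r uses seed ``spec.seed + r``, so repeats are independent yet each
    reproducible in isolation (repeats=1 equals one manual run at spec.seed).
    Returns a JSON-ready dict with per-repeat AUCs, their mean and quantiles,
    mean cumulative recovery per cutoff, and the unperturbed baseline.
    """
    baseline = prioritize(m, net, scorer=scorer)
    _, base_auc = roc_auc(baseline, ref)
    base_rec = cumulative_recovery(baseline, ref, cutoffs=cutoffs)
    aucs: list[float] = []
    recs: list[dict[int, int]] = []
    for r in range(spec.repeats):
        try:
            pm, pn = _apply(m, net, spec, spec.seed + r)
            ranking = prioritize(pm, pn, scorer=scorer)
            _, a = roc_auc(ranking, ref)
            recs.append(cumulative_recovery(ranking, ref, cutoffs=cutoffs))
            aucs.append(a)
        except MaxMIFError as exc:
            raise MaxMIFError(f"repeat {r} failed: {exc}") from exc
    arr = np.asarray(aucs)
    qs = np.quantile(arr, [0.0, 0.25, 0.5, 0.75, 1.0])
    return {
        "kind": spec.kind,
        "level": spec.level,
        "repeats": spec.repeats,
        "seed": spec.seed,
        "scorer": scorer,
        "baseline_auc": base_auc,
        "baseline_recovery": {str(k): v for k, v in base_rec.items()},
        "aucs": [float(a) for a in aucs],
        "mean_auc": float(arr.mean()),
        "auc_quantiles": {
            "min": float(qs[0]),
            "q25": float(qs[1]),
            "median": float(qs[2]),
            "q75": float(qs[3]),
            "max": float(qs[4]),
        },
        "mean_recovery": {
            str(k): float(np.mean([rc[k] for rc in recs])) for k in base_rec
        },
        "delta_mean_auc": float(arr.mean() - base_auc),
    }
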