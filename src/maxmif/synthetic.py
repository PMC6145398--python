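"""Synthetic mutation matrices, networks and reference sets with planted drivers.

The generator emulates the two features of real tumor cohorts that make driver
identification hard and that network scoring exploits:

* a long-tailed per-gene mutation frequency spectrum — a handful of passenger
  genes mutated in very many samples while most mutated genes appear in only
  one or two samples (passenger per-sample probabilities follow a power law
  over frequency rank);
* highly variable per-sample mutation burdens (a lognormal per-sample burden
  multiplier).

Planted drivers carry BOTH signals the scoring method integrates: a moderate,
flat per-sample mutation rate AND membership in a connected, strongly weighted
network module, so they sit next to other mutated genes.  The background
network is scale-free (preferential attachment), matching the degree
heterogeneity of real PPI networks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import MaxMIFError
from .evaluation import ReferenceGeneSet
from .mutation import MAF_CLASS_COL, MAF_GENE_COL, MAF_SAMPLE_COL, MutationMatrix
from .network import WeightedNetwork, build_network


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic cohort + network instance.

    Defaults describe a mid-sized exome cohort: 2000 genes, 200 samples,
    20 drivers each mutated in ~15% of samples, a passenger frequency tail
    with exponent 1.5, a mean of ~30 mutated genes per sample with lognormal
    sd 0.5 across samples, and driver-adjacent edge weights centered at 0.8.
    """

    n_genes: int = 2000
    n_samples: int = 200
    n_drivers: int = 20
    driver_mut_rate: float = 0.15
    passenger_tail_shape: float = 1.5
    burden_dispersion: float = 0.5
    mean_passenger_burden: float = 30.0
    network_model: str = "scale_free_with_planted_module"
    driver_module_weight: float = 0.8
    attachment_edges: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_drivers < self.n_genes:
            raise MaxMIFError("need 0 <= n_drivers < n_genes")
        if not 0 <= self.driver_mut_rate <= 1:
            raise MaxMIFError("driver_mut_rate must be in [0, 1]")
        if self.n_genes < 2:
            raise MaxMIFError("need at least 2 genes")
        if self.network_model != "scale_free_with_planted_module":
            raise MaxMIFError(f"unknown network model {self.network_model!r}")

    @property
    def driver_genes(self) -> list[str]:
        return [f"DRV{i + 1:03d}" for i in range(self.n_drivers)]

    @property
    def passenger_genes(self) -> list[str]:
        return [f"PSG{i + 1:05d}" for i in range(self.n_genes - self.n_drivers)]

    @property
    def genes(self) -> list[str]:
        return self.driver_genes + self.passenger_genes

    def _rng(self, stream: int) -> np.random.Generator:
        # independent reproducible streams per generated artifact
        return np.random.default_rng([self.seed, stream])


def gen_mutation_matrix(spec: SyntheticSpec) -> MutationMatrix:
    """Sample a binary mutation matrix with planted drivers and a passenger tail.

    Passenger gene at frequency rank g mutates in sample k with probability
    min(1, b_k * c * g^-shape) where b_k is a lognormal burden multiplier with
    mean 1 and c scales the tail so the expected per-sample passenger burden
    equals ``mean_passenger_burden``.  Drivers mutate at the flat rate
    ``driver_mut_rate``.  Resamples if the matrix comes out all-zero.
    """
    rng = spec._rng(0)
    n_pass = spec.n_genes - spec.n_drivers
    ranks = np.arange(1, n_pass + 1, dtype=float)
    tail = ranks**-spec.passenger_tail_shape
    if spec.n_drivers == 0 and (spec.mean_passenger_burden <= 0 or n_pass == 0):
        raise MaxMIFError("infeasible spec: all mutation probabilities are zero")
    base = spec.mean_passenger_burden * tail / tail.sum()
    sigma = spec.burden_dispersion
    for _ in range(100):
        mult = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=spec.n_samples)
        p_pass = np.clip(base[:, None] * mult[None, :], 0.0, 1.0)
        p_drv = np.full((spec.n_drivers, spec.n_samples), spec.driver_mut_rate)
        probs = np.vstack([p_drv, p_pass])
        if probs.max() == 0:
            raise MaxMIFError("infeasible spec: all mutation probabilities are zero")
        mat = (rng.random(probs.shape) < probs).astype(np.int64)
        if mat.any():
            break
    else:  # pragma: no cover - probability ~0 under any sane spec
        raise MaxMIFError("failed to sample a nonempty mutation matrix")
    samples = [f"S{j + 1:04d}" for j in range(spec.n_samples)]
    return MutationMatrix(pd.DataFrame(mat, index=spec.genes, columns=samples))


def gen_network(spec: SyntheticSpec) -> WeightedNetwork:
    """Scale-free background plus a connected, strongly weighted driver module.

    Gene labels are assigned to preferential-attachment nodes in random order,
    then the drivers are wired into a connected module (a random driver path
    plus extra random driver-driver edges).  Edges touching a driver draw
    their raw weight from N(driver_module_weight, 0.1) clipped to (0, 1];
    background edges are Uniform(0, 1].  Weights are standardized by the
    maximum, as for any loaded network.
    """
    rng = spec._rng(1)
    n = spec.n_genes
    m = min(spec.attachment_edges, n - 1)
    if n <= m + 1:
        g = nx.complete_graph(n)
    else:
        g = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31)))
    names = np.array(spec.genes)
    rng.shuffle(names)
    relabel = {i: names[i] for i in g.nodes}
    g = nx.relabel_nodes(g, relabel)
    drivers = spec.driver_genes
    if len(drivers) >= 2:
        order = list(rng.permutation(drivers))
        for a, b in itertools.pairwise(order):
            g.add_edge(a, b)
        extra = spec.n_drivers
        for _ in range(extra):
            a, b = rng.choice(drivers, size=2, replace=False)
            g.add_edge(a, b)
    driver_set = set(drivers)
    edges = []
    for a, b in sorted((min(u, v), max(u, v)) for u, v in g.edges):
        if a in driver_set or b in driver_set:
            w = float(np.clip(rng.normal(spec.driver_module_weight, 0.1), 1e-3, 1.0))
        else:
            w = float(1.0 - rng.random())  # Uniform(0, 1]
        edges.append((a, b, w))
    return build_network(edges)


def gen_reference_set(
    spec: SyntheticSpec, contamination: float = 0.0
) -> ReferenceGeneSet:
    """The planted drivers, with a fraction swapped for random passengers.

    Contamination models imperfect curated gene lists; the set size is always
    ``n_drivers``.
    """
    if not 0 <= contamination < 1:
        raise MaxMIFError("contamination must be in [0, 1)")
    rng = spec._rng(2)
    drivers = list(spec.driver_genes)
    n_swap = int(round(contamination * len(drivers)))
    out = np.array(drivers, dtype=object)
    if n_swap:
        victims = rng.choice(len(drivers), size=n_swap, replace=False)
        replacements = rng.choice(spec.passenger_genes, size=n_swap, replace=False)
        out[victims] = replacements
    return ReferenceGeneSet(
        name=f"planted_seed{spec.seed}", members=frozenset(out.tolist())
    )


def write_maf(m: MutationMatrix, path: str | Path) -> None:
    """Write one Missense_Mutation MAF record per (gene, sample) with M=1."""
    rows, cols = np.nonzero(m.indicator)
    df = pd.DataFrame(
        {
            MAF_GENE_COL: np.array(m.genes, dtype=object)[rows],
            MAF_SAMPLE_COL: np.array(m.samples, dtype=object)[cols],
            MAF_CLASS_COL: "Missense_Mutation",
        }
    )
    df.to_csv(path, sep="\t", index=False)
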