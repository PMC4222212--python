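"""Reference P(wild) distributions, logit transforms, F_ST and PCoA.

The per-individual P(wild) values of the wild and farm reference samples form
the yardsticks against which contemporary samples are judged: their means
anchor the calibration of "proportion of wild genome left", and their 5th/95th
percentiles bound what a pure wild or pure farm individual typically looks
like.  Downstream tests operate on logit-transformed values (variance
stabilization for proportions), with a clamp epsilon keeping the transform
finite at 0/1.

The module also provides the workflow's visual sanity check: pairwise
Weir–Cockerham F_ST between populations (and optionally the synthesized center
points) ordinated by classical metric scaling (PCoA), which should place each
center point inside its own group's cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from skbio.stats.distance import DistanceMatrix
from skbio.stats.ordination import pcoa as _skbio_pcoa

from .admixture import AdmixtureResult
from .centerpoint import CenterPoint
from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "ReferenceDistribution",
    "build_reference_distribution",
    "logit",
    "inv_logit",
    "weir_cockerham_fst",
    "pairwise_fst",
    "PcoaResult",
    "pairwise_fst_pcoa",
]


def logit(p: np.ndarray | float, epsilon: float = 0.001) -> np.ndarray | float:
    """ln(p / (1-p)) after clamping p into [epsilon, 1-epsilon]."""
    p = np.clip(np.asarray(p, dtype=float), epsilon, 1.0 - epsilon)
    return np.log(p / (1.0 - p))


def inv_logit(x: np.ndarray | float) -> np.ndarray | float:
    x = np.asarray(x, dtype=float)
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class ReferenceDistribution:
    """A collection of per-individual P(wild) values with summaries.

    Percentiles use linear interpolation between closest order statistics
    (numpy's default, inclusive scheme).  ``logit_values`` are clamped at
    ``epsilon`` before transforming so they are always finite.
    """

    values: np.ndarray
    individual_ids: list[str]
    population_labels: list[str]
    role: str
    epsilon: float = 0.001

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            raise ValueError("a reference distribution needs at least one value")
        if (self.values < 0).any() or (self.values > 1).any():
            raise ValueError("P(wild) values must lie in [0, 1]")
        if self.role not in ("wild", "farm", "admixed"):
            raise ValueError("role must be wild, farm or admixed")
        if len(self.individual_ids) != self.values.size:
            raise ValueError("one individual id per value required")
        if len(self.population_labels) != self.values.size:
            raise ValueError("one population label per value required")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def percentile_5(self) -> float:
        return float(np.percentile(self.values, 5))

    @property
    def percentile_95(self) -> float:
        return float(np.percentile(self.values, 95))

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.values, q))

    @property
    def logit_values(self) -> np.ndarray:
        return logit(self.values, self.epsilon)

    @property
    def per_population_means(self) -> dict[str, float]:
        s = pd.Series(self.values, index=self.population_labels)
        return s.groupby(level=0, sort=False).mean().to_dict()

    def population_groups(self) -> dict[str, np.ndarray]:
        """Logit values grouped by population label."""
        labels = np.asarray(self.population_labels)
        lv = self.logit_values
        return {pop: lv[labels == pop] for pop in dict.fromkeys(self.population_labels)}

    def summary(self) -> dict:
        return {
            "role": self.role,
            "n": self.n,
            "mean": self.mean,
            "percentile_5": self.percentile_5,
            "percentile_95": self.percentile_95,
            "epsilon": self.epsilon,
            "per_population_means": self.per_population_means,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": self.individual_ids,
                "population": self.population_labels,
                "p_wild": self.values,
            }
        )


def build_reference_distribution(
    results: Sequence[AdmixtureResult] | Sequence[float] | np.ndarray,
    role: str,
    population_labels: Sequence[str] | None = None,
    epsilon: float = 0.001,
) -> ReferenceDistribution:
    """Collect per-individual P(wild) values into a ReferenceDistribution.

    ``results`` may be AdmixtureResult objects (ids taken from them) or plain
    values (ids synthesized); ``population_labels`` defaults to the role.
    """
    results = list(results)
    if not results:
        raise ValueError("no results supplied")
    if isinstance(results[0], AdmixtureResult):
        values = np.array([r.p_wild for r in results])
        ids = [r.individual_id for r in results]
    else:
        values = np.asarray(results, dtype=float)
        ids = [f"{role}_{i + 1}" for i in range(values.size)]
    if population_labels is None:
        population_labels = [role] * values.size
    return ReferenceDistribution(values, ids, list(population_labels), role, epsilon)


def weir_cockerham_fst(
    matrix: GenotypeMatrix, pop_a: str, pop_b: str
) -> float:
    """Multi-locus Weir–Cockerham theta between two populations.

    Per-locus variance components a (between populations), b (between
    individuals within populations) and c (within individuals) are summed over
    loci before taking the ratio sum(a) / sum(a+b+c); loci with fewer than two
    genotyped individuals in either population are skipped.
    """
    comp = _wc_components(matrix, pop_a, pop_b)
    a, abc = comp
    if abc == 0:
        return 0.0
    return a / abc


def _wc_components(matrix: GenotypeMatrix, pop_a: str, pop_b: str) -> tuple[float, float]:
    r = 2
    sum_a = 0.0
    sum_abc = 0.0
    G = matrix.genotypes
    idx = [matrix.population_indices(pop_a), matrix.population_indices(pop_b)]
    for l in range(matrix.n_loci):
        n_i, p_i, h_i = [], [], []
        for rows in idx:
            g = G[rows, l]
            g = g[g != MISSING]
            if g.size < 2:
                break
            n_i.append(g.size)
            p_i.append(g.sum() / (2 * g.size))
            h_i.append(np.mean(g == 1))
        else:
            n_i = np.array(n_i, float)
            p_i = np.array(p_i, float)
            h_i = np.array(h_i, float)
            nbar = n_i.mean()
            if nbar <= 1:
                continue
            nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
            pbar = (n_i * p_i).sum() / (r * nbar)
            s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (n_i * h_i).sum() / (r * nbar)
            if nc == 0:
                continue
            a = (nbar / nc) * (
                s2
                - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - (r - 1) / r * s2
                - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2
            sum_a += a
            sum_abc += a + b + c
    return sum_a, sum_abc


def pairwise_fst(
    matrix: GenotypeMatrix, populations: Sequence[str] | None = None
) -> pd.DataFrame:
    """Symmetric matrix of pairwise multi-locus Weir–Cockerham F_ST estimates."""
    pops = list(populations) if populations is not None else matrix.populations
    out = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, pa in enumerate(pops):
        for pb in pops[i + 1 :]:
            f = weir_cockerham_fst(matrix, pa, pb)
            out.loc[pa, pb] = out.loc[pb, pa] = f
    return out


@dataclass
class PcoaResult:
    """Pairwise F_ST distances ordinated by classical metric scaling."""

    distances: pd.DataFrame
    coordinates: pd.DataFrame  # populations x axes (>= 2 columns)
    variance_explained: np.ndarray  # per retained axis, over positive eigenvalues


def pairwise_fst_pcoa(
    matrix: GenotypeMatrix,
    populations: Sequence[str] | None = None,
    centerpoints: Sequence[CenterPoint] | None = None,
    n_axes: int = 2,
) -> PcoaResult:
    """Pairwise F_ST + PCoA sanity check of the reference panel layout.

    Negative F_ST estimates (possible for undifferentiated pairs) are floored
    at 0 so the matrix is a valid dissimilarity.  Variance explained per axis
    is eigenvalue / sum of positive eigenvalues.  Center points, if given, are
    stacked in as extra populations so the plot can confirm each lies inside
    its own group's cluster.
    """
    if centerpoints:
        cp_labels = [f"{cp.role}_centerpoint" for cp in centerpoints]
        matrix = GenotypeMatrix.concat(
            [matrix]
            + [cp.genotypes.relabel(lbl) for cp, lbl in zip(centerpoints, cp_labels)]
        )
        if populations is not None:
            populations = list(populations) + cp_labels
    pops = list(populations) if populations is not None else matrix.populations
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    for p in pops:
        if matrix.population_indices(p).size < 2:
            raise ValueError(f"population {p!r} has fewer than 2 individuals")
    fst = pairwise_fst(matrix, pops)
    dist = np.maximum(fst.to_numpy(), 0.0)
    np.fill_diagonal(dist, 0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # skbio warns on negative eigenvalues
        ord_res = _skbio_pcoa(DistanceMatrix(dist, ids=pops), method="eigh")
    eig = np.asarray(ord_res.eigvals, dtype=float)
    pos = eig[eig > 1e-12]
    k = min(n_axes, max(pos.size, 1))
    coords = ord_res.samples.iloc[:, :k].copy()
    coords.columns = [f"axis_{i + 1}" for i in range(k)]
    if k < n_axes:  # pad degenerate cases so callers always get n_axes columns
        for i in range(k, n_axes):
            coords[f"axis_{i + 1}"] = 0.0
    var_exp = (pos[:k] / pos.sum()) if pos.size else np.zeros(k)
    return PcoaResult(fst, coords, np.asarray(var_exp))
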