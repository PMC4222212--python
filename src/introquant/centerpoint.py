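"""In silico reference center points.

A center point is a synthetic Hardy–Weinberg-equilibrium population standing in
for a whole group of reference populations (wild or farm).  It is built by
pooling an equal random subsample from each reference population and then
"random mating" the pool: every offspring allele copy is an independent
Bernoulli draw conditioned on the pooled allele frequency at its locus.  This
restores Hardy–Weinberg and linkage equilibrium by construction, so the
center point anchors one cluster of the admixture model without the biases a
heterogeneous multi-population reference would introduce.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genotype_io import AlleleFrequencies, GenotypeMatrix, allele_frequencies

DEFAULT_CENTERPOINT_SIZE = 100

__all__ = [
    "CenterPoint",
    "subsample_equal",
    "synthesize_centerpoint",
    "build_centerpoint",
    "DEFAULT_CENTERPOINT_SIZE",
]


@dataclass
class CenterPoint:
    """A synthetic HWE reference population with provenance.

    All individuals carry ``role`` ("wild" or "farm") as their population
    label.  ``provenance`` records the source populations, per-population
    subsample size and the seed, so a run can be reproduced exactly.
    """

    genotypes: GenotypeMatrix
    role: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ("wild", "farm"):
            raise ValueError("role must be 'wild' or 'farm'")
        labels = set(self.genotypes.population_labels)
        if labels and labels != {self.role}:
            raise ValueError(
                f"center-point individuals must all be labeled {self.role!r}"
            )

    @property
    def n_individuals(self) -> int:
        return self.genotypes.n_individuals

    def frequencies(self) -> AlleleFrequencies:
        return allele_frequencies(self.genotypes)


def subsample_equal(
    matrix: GenotypeMatrix,
    populations: Sequence[str],
    n_per_pop: int,
    seed: int,
) -> GenotypeMatrix:
    """Sample ``n_per_pop`` individuals without replacement from each population.

    Equal subsampling prevents large reference populations from dominating the
    pooled allele frequencies.
    """
    if n_per_pop < 1:
        raise ValueError("n_per_pop must be >= 1")
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    for pop in populations:
        idx = matrix.population_indices(pop)
        if idx.size < n_per_pop:
            raise ValueError(
                f"population {pop!r} has {idx.size} individuals, "
                f"fewer than n_per_pop={n_per_pop}"
            )
        chosen.extend(sorted(rng.choice(idx, size=n_per_pop, replace=False)))
    return matrix.select_individuals(chosen)


def synthesize_centerpoint(
    pooled: GenotypeMatrix,
    role: str,
    n_offspring: int = DEFAULT_CENTERPOINT_SIZE,
    seed: int = 0,
    provenance: dict | None = None,
) -> CenterPoint:
    """Random-mate a pooled sample into an HWE center point.

    Each offspring genotype at each locus is the sum of two independent
    Bernoulli(freq_A) allele draws from the pooled frequency, so expected
    offspring frequencies equal the pooled frequencies and genotypes are in
    Hardy–Weinberg proportions.
    """
    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    freqs = allele_frequencies(pooled)
    undefined = [l for l, ok in zip(freqs.locus_ids, freqs.defined) if not ok]
    if undefined:
        raise ValueError(
            f"no non-missing alleles in the pool at loci: {undefined}"
        )
    rng = np.random.default_rng(seed)
    p = freqs.freq_A
    dosage = (rng.random((2, n_offspring, p.size)) < p).sum(axis=0)
    genotypes = GenotypeMatrix(
        [f"{role}_cp_{i + 1:03d}" for i in range(n_offspring)],
        [role] * n_offspring,
        list(pooled.locus_ids),
        dosage,
    )
    prov = dict(provenance or {})
    prov.setdefault("seed", seed)
    prov.setdefault("n_offspring", n_offspring)
    prov.setdefault("pool_size", pooled.n_individuals)
    return CenterPoint(genotypes, role, prov)


def build_centerpoint(
    matrix: GenotypeMatrix,
    populations: Sequence[str],
    role: str,
    n_per_pop: int | None = None,
    n_offspring: int = DEFAULT_CENTERPOINT_SIZE,
    seed: int = 0,
) -> CenterPoint:
    """Subsample equally, pool and random-mate in one step.

    ``n_per_pop=None`` uses the smallest listed population's size (the
    equal-subsampling rule is then as inclusive as it can be).
    """
    populations = list(populations)
    if not populations:
        raise ValueError("at least one source population required")
    if n_per_pop is None:
        n_per_pop = min(matrix.population_indices(p).size for p in populations)
    pooled = subsample_equal(matrix, populations, n_per_pop, seed)
    return synthesize_centerpoint(
        pooled,
        role,
        n_offspring=n_offspring,
        seed=seed + 1,
        provenance={
            "source_populations": populations,
            "n_per_pop": n_per_pop,
            "seed": seed,
            "n_offspring": n_offspring,
        },
    )
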