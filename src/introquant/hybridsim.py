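"""Gamete-level hybrid simulation and synthetic diverged reference panels.

Crosses are simulated at the gamete level: one allele sampled uniformly per
locus from each parent, the two gametes merged into an offspring genotype.
Composing crosses yields the standard two-generation hybrid groups — F1 (H),
backcrosses to wild (BCW) and farm (BCF), and F1 x F1 (2GH) — whose expected
wild-genome fractions follow from the pedigree: 0.5, 0.75, 0.25 and 0.5.

Synthetic reference panels use the Balding–Nichols model: per locus an
ancestral frequency pi is drawn, then the wild and farm group frequencies are
drawn independently from Beta(pi (1-F)/F, (1-pi)(1-F)/F), giving an expected
between-group F_ST of F; individuals are drawn in Hardy–Weinberg proportions
from their group frequency.  With the default L = 59 loci and F = 0.3 the
panel emulates a diagnostic SNP panel that collectively (not per-locus)
separates the two groups.

The scenario machinery consumes externally supplied cross-group proportions
(e.g. from a demographic/fitness projection of repeated escapee intrusion) and
resamples observed per-group P(wild) pools conditional on those proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genotype_io import MISSING, AlleleFrequencies, GenotypeMatrix

__all__ = [
    "GROUP_WILD_FRACTIONS",
    "ScenarioSpec",
    "SyntheticPanelSpec",
    "ScenarioEstimate",
    "cross_populations",
    "build_cross_groups",
    "scenario_expected_wild_fraction",
    "resample_scenario",
    "simulate_reference_populations",
    "simulate_admixed_individual",
    "simulate_admixed_cohort",
]

# Pedigree-expected wild-genome fraction per cross group.
GROUP_WILD_FRACTIONS: dict[str, float] = {
    "pure_wild": 1.0,
    "H": 0.5,
    "BCW": 0.75,
    "BCF": 0.25,
    "2GH": 0.5,
    "pure_farm": 0.0,
}


@dataclass
class ScenarioSpec:
    """Cross-group composition of an admixed population.

    ``proportions`` maps group names (keys of :data:`GROUP_WILD_FRACTIONS`) to
    population fractions.  Fractions must be non-negative; if they do not sum
    to 1 within 1e-9 they are renormalized with a warning.
    """

    proportions: dict[str, float]
    sample_size: int = 30
    n_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.proportions) - set(GROUP_WILD_FRACTIONS)
        if unknown:
            raise ValueError(f"unknown cross groups: {sorted(unknown)}")
        vals = np.array(list(self.proportions.values()), dtype=float)
        if (vals < 0).any():
            raise ValueError("group proportions must be non-negative")
        total = vals.sum()
        if total <= 0:
            raise ValueError("group proportions sum to zero")
        if abs(total - 1.0) > 1e-9:
            warnings.warn(
                f"group proportions sum to {total:.6g}; renormalizing",
                stacklevel=2,
            )
            self.proportions = {
                g: v / total for g, v in self.proportions.items()
            }
        if self.sample_size < 1:
            raise ValueError("sample_size must be >= 1")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass
class SyntheticPanelSpec:
    """Balding–Nichols panel of two diverged groups.

    fst
        Expected differentiation F between the wild and farm group; 0 makes
        both groups share the ancestral frequency exactly.
    ancestral_low, ancestral_high
        Uniform bounds of the ancestral frequency distribution; the default
        [0.05, 0.95] avoids near-fixed uninformative loci.
    n_wild_pops / n_farm_pops
        Number of labeled populations per group (labels ``wild_1``, ...);
        each population of a group draws from the same group frequency.
    """

    n_loci: int = 59
    fst: float = 0.3
    ancestral_low: float = 0.05
    ancestral_high: float = 0.95
    n_wild: int = 100
    n_farm: int = 100
    n_wild_pops: int = 1
    n_farm_pops: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fst < 1:
            raise ValueError("fst must lie in [0, 1)")
        if not 0 < self.ancestral_low < self.ancestral_high < 1:
            raise ValueError("ancestral bounds must satisfy 0 < low < high < 1")
        if min(self.n_loci, self.n_wild, self.n_farm) < 1:
            raise ValueError("n_loci and group sizes must be >= 1")
        if min(self.n_wild_pops, self.n_farm_pops) < 1:
            raise ValueError("population counts must be >= 1")


@dataclass
class ScenarioEstimate:
    """Resampled estimate of wild genome left under a scenario."""

    mean: float
    ci_low: float
    ci_high: float
    expected: float
    n_reps: int
    sample_size: int
    replicate_values: np.ndarray = field(repr=False)


def _sample_gametes(
    parents: GenotypeMatrix, rows: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One gamete (A-allele indicator per locus, MISSING propagated) per row."""
    G = parents.genotypes[rows]
    u = rng.random(G.shape)
    # dosage 2 -> always A; 1 -> coin flip; 0 -> never A
    gam = (u < G / 2.0).astype(np.int8)
    gam[G == MISSING] = MISSING
    return gam


def cross_populations(
    parents_a: GenotypeMatrix,
    parents_b: GenotypeMatrix,
    n_offspring_per_pair: int = 5,
    pairing: str = "all_pairs",
    seed: int = 0,
    label: str = "hybrid",
) -> GenotypeMatrix:
    """Gamete-level crosses between two parent pools.

    pairing="all_pairs"
        Every (population of A) x (population of B) pair contributes
        ``n_offspring_per_pair`` offspring, each from a random parent of each
        population (e.g. 260 population pairs x 5 = 1300 offspring).
    pairing="random"
        ``n_offspring_per_pair`` offspring total, each from one random parent
        of each pool.

    A parent missing at a locus contributes a missing allele, which makes the
    offspring genotype missing there.
    """
    if parents_a.n_individuals == 0 or parents_b.n_individuals == 0:
        raise ValueError("both parent pools must be non-empty")
    if parents_a.locus_ids != parents_b.locus_ids:
        raise ValueError("parent pools must share the same locus set")
    if n_offspring_per_pair < 1:
        raise ValueError("n_offspring_per_pair must be >= 1")
    rng = np.random.default_rng(seed)

    if pairing == "all_pairs":
        rows_a: list[int] = []
        rows_b: list[int] = []
        for pa in parents_a.populations:
            ia = parents_a.population_indices(pa)
            for pb in parents_b.populations:
                ib = parents_b.population_indices(pb)
                rows_a.extend(rng.choice(ia, size=n_offspring_per_pair))
                rows_b.extend(rng.choice(ib, size=n_offspring_per_pair))
        rows_a = np.asarray(rows_a)
        rows_b = np.asarray(rows_b)
    elif pairing == "random":
        rows_a = rng.integers(0, parents_a.n_individuals, n_offspring_per_pair)
        rows_b = rng.integers(0, parents_b.n_individuals, n_offspring_per_pair)
    else:
        raise ValueError("pairing must be 'all_pairs' or 'random'")

    gam_a = _sample_gametes(parents_a, rows_a, rng)
    gam_b = _sample_gametes(parents_b, rows_b, rng)
    offspring = gam_a + gam_b
    offspring[(gam_a == MISSING) | (gam_b == MISSING)] = MISSING
    n = offspring.shape[0]
    return GenotypeMatrix(
        [f"{label}_{i + 1:04d}" for i in range(n)],
        [label] * n,
        list(parents_a.locus_ids),
        offspring,
    )


def build_cross_groups(
    wild: GenotypeMatrix,
    farm: GenotypeMatrix,
    n_per_group: int = 30,
    seed: int = 0,
) -> GenotypeMatrix:
    """All two-generation cross groups, ``n_per_group`` offspring each.

    pure_wild = wild x wild, pure_farm = farm x farm, H = wild x farm,
    BCW = H x wild, BCF = H x farm, 2GH = H x H; the group name becomes the
    population label.  Backcrosses and 2GH draw from a fresh F1 pool of the
    same size.
    """
    if wild.n_individuals == 0 or farm.n_individuals == 0:
        raise ValueError("both parent pools must be non-empty")
    rng = np.random.default_rng(seed)

    def _cross(a, b, name, n):
        return cross_populations(
            a, b, n, pairing="random",
            seed=int(rng.integers(2**31)), label=name,
        )

    f1_pool = _cross(wild, farm, "H_pool", max(n_per_group, 30))
    groups = [
        _cross(wild, wild, "pure_wild", n_per_group),
        _cross(farm, farm, "pure_farm", n_per_group),
        _cross(wild, farm, "H", n_per_group),
        _cross(f1_pool, wild, "BCW", n_per_group),
        _cross(f1_pool, farm, "BCF", n_per_group),
        _cross(f1_pool, f1_pool, "2GH", n_per_group),
    ]
    return GenotypeMatrix.concat(groups)


def scenario_expected_wild_fraction(spec: ScenarioSpec) -> float:
    """Pedigree-expected wild-genome fraction of the scenario mixture."""
    return float(
        sum(p * GROUP_WILD_FRACTIONS[g] for g, p in spec.proportions.items())
    )


def resample_scenario(
    group_pwild: Mapping[str, Sequence[float] | np.ndarray],
    spec: ScenarioSpec,
    wild_ref: float,
    farm_ref: float,
    level: float = 0.95,
) -> ScenarioEstimate:
    """Resample per-group P(wild) pools conditional on scenario proportions.

    Each replicate draws ``sample_size`` individuals with group membership
    multinomial in the scenario proportions, samples a P(wild) value from the
    drawn group's pool with replacement, and calibrates the replicate mean to
    a wild-genome proportion.  Reports the replicate mean and the central
    ``level`` percentile interval.
    """
    groups = [g for g, p in spec.proportions.items() if p > 0]
    pools = {}
    for g in groups:
        pool = np.asarray(group_pwild.get(g, ()), dtype=float)
        if pool.size == 0:
            raise ValueError(f"no P(wild) pool for group {g!r}")
        pools[g] = pool
    probs = np.array([spec.proportions[g] for g in groups])
    rng = np.random.default_rng(spec.seed)
    reps = np.empty(spec.n_reps)
    for r in range(spec.n_reps):
        counts = rng.multinomial(spec.sample_size, probs)
        draws = [
            rng.choice(pools[g], size=c, replace=True)
            for g, c in zip(groups, counts)
            if c > 0
        ]
        mean_p = float(np.concatenate(draws).mean())
        reps[r] = (mean_p - farm_ref) / (wild_ref - farm_ref)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(reps, [100 * alpha, 100 * (1 - alpha)])
    return ScenarioEstimate(
        mean=float(reps.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        expected=scenario_expected_wild_fraction(spec),
        n_reps=spec.n_reps,
        sample_size=spec.sample_size,
        replicate_values=reps,
    )


def simulate_reference_populations(
    spec: SyntheticPanelSpec,
) -> tuple[GenotypeMatrix, dict[str, np.ndarray]]:
    """Balding–Nichols wild and farm groups; returns (genotypes, true freqs).

    The true group frequencies are returned so parameter-recovery oracles can
    condition on them rather than on sample estimates.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.n_loci
    pi = rng.uniform(spec.ancestral_low, spec.ancestral_high, L)
    if spec.fst == 0:
        wild_f = pi.copy()
        farm_f = pi.copy()
    else:
        scale = (1.0 - spec.fst) / spec.fst
        wild_f = rng.beta(pi * scale, (1.0 - pi) * scale)
        farm_f = rng.beta(pi * scale, (1.0 - pi) * scale)

    blocks = []
    for group, freq, n_total, n_pops in (
        ("wild", wild_f, spec.n_wild, spec.n_wild_pops),
        ("farm", farm_f, spec.n_farm, spec.n_farm_pops),
    ):
        base, extra = divmod(n_total, n_pops)
        for p in range(n_pops):
            n = base + (1 if p < extra else 0)
            dosage = (rng.random((2, n, L)) < freq).sum(axis=0)
            label = f"{group}_{p + 1}" if n_pops > 1 else group
            blocks.append(
                GenotypeMatrix(
                    [f"{label}_{i + 1:03d}" for i in range(n)],
                    [label] * n,
                    [f"locus_{l + 1}" for l in range(L)],
                    dosage,
                )
            )
    matrix = GenotypeMatrix.concat(blocks)
    return matrix, {"wild": wild_f, "farm": farm_f}


def simulate_admixed_individual(
    q: float,
    wild_freqs: AlleleFrequencies,
    farm_freqs: AlleleFrequencies,
    seed: int = 0,
    individual_id: str = "admixed_1",
    label: str = "admixed",
) -> GenotypeMatrix:
    """One individual with a known admixture proportion ``q``.

    Each allele copy independently originates from the wild gene pool with
    probability q (then Bernoulli(wild freq)) or from the farm pool otherwise.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    if wild_freqs.locus_ids != farm_freqs.locus_ids:
        raise ValueError("frequency locus sets differ")
    rng = np.random.default_rng(seed)
    L = len(wild_freqs.locus_ids)
    origin_wild = rng.random((2, L)) < q
    freq = np.where(origin_wild, wild_freqs.freq_A, farm_freqs.freq_A)
    dosage = (rng.random((2, L)) < freq).sum(axis=0)
    return GenotypeMatrix(
        [individual_id], [label], list(wild_freqs.locus_ids), dosage[None, :]
    )


def simulate_admixed_cohort(
    q: float,
    wild_freqs: AlleleFrequencies,
    farm_freqs: AlleleFrequencies,
    n: int,
    seed: int = 0,
    label: str = "admixed",
) -> GenotypeMatrix:
    """``n`` independent individuals with the same known admixture proportion."""
    individuals = [
        simulate_admixed_individual(
            q, wild_freqs, farm_freqs, seed=seed + i,
            individual_id=f"{label}_{i + 1:03d}", label=label,
        )
        for i in range(n)
    ]
    return GenotypeMatrix.concat(individuals)
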