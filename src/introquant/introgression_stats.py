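"""Hypothesis tests and estimators for farm-to-wild introgression.

Given reference distributions of P(wild), three questions are answered:

1. *Has this population been introgressed?*  A one-sided two-sample comparison
   of mean logit P(wild) between a contemporary sample and either (a) a
   historical sample from the same population, or (b) the whole wild reference
   panel.  In case (b) an extra between-population variance component accounts
   for not knowing the population's own historical mean.
2. *How small must the contemporary mean be to call introgression?*  The
   critical-value curve as a function of contemporary sample size, drawn on
   the P(wild) scale.
3. *How much wild genome is left?*  The calibration
   (P_adm - Farm_ref) / (Wild_ref - Farm_ref), which rescales the admixed
   sample mean so that the wild reference mean maps to 1 and the farm
   reference mean to 0, with a percentile bootstrap over individuals for
   confidence intervals.

All comparisons run on the logit scale (variance stabilization); critical
values are back-transformed for reporting.  The test statistic is a one-sided
z-test: the within-population variance is pooled over the many wild reference
individuals, so its degrees of freedom are large and the normal approximation
is appropriate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .refdist import ReferenceDistribution, inv_logit

__all__ = [
    "TestResult",
    "IntrogressionEstimate",
    "wild_genome_proportion",
    "test_mean_pwild",
    "critical_value_curve",
    "bootstrap_ci",
]


@dataclass
class TestResult:
    """One-sided test of reduced mean P(wild) in a contemporary sample."""

    mode: str  # "with_reference" | "without_reference"
    reference_mean_logit: float
    contemporary_mean_logit: float
    sigma2_within: float
    sigma2_between: float
    n_contemporary: int
    n_reference: int
    critical_value_logit: float
    critical_value: float  # back-transformed to the P(wild) scale
    p_value: float
    level: float
    reject: bool

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class IntrogressionEstimate:
    """Calibrated proportion of wild genome left, with bootstrap CI."""

    p_adm_mean: float
    wild_ref: float
    farm_ref: float
    wild_genome_left: float
    ci_low: float
    ci_high: float
    n_boot: int
    level: float
    seed: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def wild_genome_proportion(
    p_adm_mean: float, wild_ref: float, farm_ref: float
) -> float:
    """(P_adm - Farm_ref) / (Wild_ref - Farm_ref).

    Rescales the admixed-sample mean P(wild) between the farm (0) and wild (1)
    reference anchors.  Sampling noise can push the result outside [0, 1];
    such values are returned unchanged but flagged with a warning.
    """
    if wild_ref <= farm_ref:
        raise ValueError(
            f"wild_ref ({wild_ref}) must exceed farm_ref ({farm_ref})"
        )
    prop = (p_adm_mean - farm_ref) / (wild_ref - farm_ref)
    if not 0.0 <= prop <= 1.0:
        warnings.warn(
            f"wild-genome proportion {prop:.4f} outside [0, 1] "
            "(sample mean beyond a calibration anchor)",
            stacklevel=2,
        )
    return prop


def _pooled_within_variance(
    wild_panel: Sequence[ReferenceDistribution],
) -> float:
    """Pooled within-population variance of logit P(wild) across the panel."""
    ss = 0.0
    df = 0
    for dist in wild_panel:
        for vals in dist.population_groups().values():
            if vals.size >= 2:
                ss += float(((vals - vals.mean()) ** 2).sum())
                df += vals.size - 1
    if df == 0:
        raise ValueError(
            "within-population variance needs a population with >= 2 individuals"
        )
    return ss / df


def _panel_population_means(
    wild_panel: Sequence[ReferenceDistribution],
) -> tuple[np.ndarray, np.ndarray]:
    means, sizes = [], []
    for dist in wild_panel:
        for vals in dist.population_groups().values():
            means.append(float(vals.mean()))
            sizes.append(vals.size)
    return np.asarray(means), np.asarray(sizes)


def _between_variance(
    wild_panel: Sequence[ReferenceDistribution], sigma2_within: float
) -> tuple[float, float, int]:
    """Method-of-moments between-population variance of mean logit P(wild).

    Var(observed pop means) overestimates the true between-population variance
    by the average sampling variance s2w/n_j of the means; that contribution is
    subtracted and the result floored at 0.
    """
    means, sizes = _panel_population_means(wild_panel)
    if means.size < 2:
        raise ValueError(
            "between-population variance needs >= 2 wild reference populations"
        )
    grand_mean = float(means.mean())
    raw = float(means.var(ddof=1))
    s2b = max(0.0, raw - sigma2_within * float(np.mean(1.0 / sizes)))
    return s2b, grand_mean, means.size


def _null_sd(
    mode: str,
    n_contemporary: int,
    n_reference: int,
    sigma2_within: float,
    sigma2_between: float,
) -> float:
    if mode == "with_reference":
        return float(
            np.sqrt(sigma2_within * (1.0 / n_reference + 1.0 / n_contemporary))
        )
    return float(np.sqrt(sigma2_between + sigma2_within / n_contemporary))


def test_mean_pwild(
    contemporary: ReferenceDistribution,
    historical: ReferenceDistribution | None = None,
    wild_panel: Sequence[ReferenceDistribution] = (),
    level: float = 0.05,
) -> TestResult:
    """One-sided test for a reduced mean P(wild) in a contemporary sample.

    With a historical reference (same population), the null mean is the
    historical mean logit and the variance of the mean difference is
    ``s2w * (1/n_hist + 1/n_cont)`` with s2w pooled over the wild panel (over
    the historical sample alone if no panel is given).  Without one, the null
    mean is the grand mean of wild-population means and the contemporary mean's
    variance gains the between-population component:
    ``s2b + s2w / n_cont``.  Rejection at ``level`` when the contemporary mean
    logit falls below the critical value (equivalently p_value < level).
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    m_c = float(contemporary.logit_values.mean())
    n_c = contemporary.n

    if historical is not None:
        mode = "with_reference"
        panel = list(wild_panel) if wild_panel else [historical]
        s2w = _pooled_within_variance(panel)
        s2b = 0.0
        null_mean = float(historical.logit_values.mean())
        n_ref = historical.n
    else:
        mode = "without_reference"
        if not wild_panel:
            raise ValueError("without a historical sample, a wild panel is required")
        s2w = _pooled_within_variance(wild_panel)
        s2b, null_mean, n_pops = _between_variance(wild_panel, s2w)
        n_ref = sum(d.n for d in wild_panel)

    sd = _null_sd(mode, n_c, n_ref, s2w, s2b)
    z = (m_c - null_mean) / sd
    p_value = float(stats.norm.cdf(z))
    crit_logit = null_mean + stats.norm.ppf(level) * sd
    return TestResult(
        mode=mode,
        reference_mean_logit=null_mean,
        contemporary_mean_logit=m_c,
        sigma2_within=s2w,
        sigma2_between=s2b,
        n_contemporary=n_c,
        n_reference=n_ref,
        critical_value_logit=float(crit_logit),
        critical_value=float(inv_logit(crit_logit)),
        p_value=p_value,
        level=level,
        reject=bool(m_c < crit_logit),
    )


def critical_value_curve(
    wild_panel: Sequence[ReferenceDistribution],
    historical: ReferenceDistribution | None = None,
    n_range: Sequence[int] = tuple(range(2, 101)),
    level: float = 0.05,
) -> dict[int, float]:
    """Largest contemporary mean P(wild) that still rejects, per sample size.

    The inverse of :func:`test_mean_pwild`, back-transformed to the P(wild)
    scale.  The curve is monotone non-decreasing in n: a larger sample pins
    the contemporary mean down more precisely, so smaller deficits become
    detectable.  As n grows without bound the without-reference curve tends to
    ``grand_mean + z_level * sqrt(s2b)`` on the logit scale.
    """
    wild_panel = list(wild_panel)
    if historical is not None:
        panel = wild_panel if wild_panel else [historical]
        s2w = _pooled_within_variance(panel)
        s2b = 0.0
        null_mean = float(historical.logit_values.mean())
        n_ref = historical.n
        mode = "with_reference"
    else:
        s2w = _pooled_within_variance(wild_panel)
        s2b, null_mean, _ = _between_variance(wild_panel, s2w)
        n_ref = sum(d.n for d in wild_panel)
        mode = "without_reference"
    z = stats.norm.ppf(level)
    out: dict[int, float] = {}
    for n in n_range:
        if n < 2:
            raise ValueError("sample sizes in n_range must be >= 2")
        sd = _null_sd(mode, int(n), n_ref, s2w, s2b)
        out[int(n)] = float(inv_logit(null_mean + z * sd))
    return out


def bootstrap_ci(
    values: Sequence[float] | np.ndarray,
    wild_ref: float,
    farm_ref: float,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> IntrogressionEstimate:
    """Percentile-bootstrap CI for the proportion of wild genome left.

    Individuals are resampled with replacement ``n_boot`` times; the
    calibration is applied to each replicate's mean P(wild); the central
    ``level`` interval of the replicate values is reported.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no P(wild) values supplied")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    point = wild_genome_proportion(float(values.mean()), wild_ref, farm_ref)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    boot_means = values[idx].mean(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # replicates may cross the anchors
        boot_props = (boot_means - farm_ref) / (wild_ref - farm_ref)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(boot_props, [100 * alpha, 100 * (1 - alpha)])
    return IntrogressionEstimate(
        p_adm_mean=float(values.mean()),
        wild_ref=wild_ref,
        farm_ref=farm_ref,
        wild_genome_left=point,
        ci_low=float(lo),
        ci_high=float(hi),
        n_boot=n_boot,
        level=level,
        seed=seed,
    )
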