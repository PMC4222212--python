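"""Two-cluster Bayesian admixture assignment against the center points.

Each query individual is analyzed *one by one* together with the full wild and
farm center points (201 individuals for 100-individual center points).  A K=2
Gibbs sampler over the no-admixture-prior, independent-allele-frequency model
estimates every individual's admixture proportion q; the query's posterior mean
membership in the wild-aligned cluster is reported as P(wild).  Analyzing
individuals singly, rather than a whole sample at once, keeps the estimate for
one individual independent of the composition of the rest of the sample.

Model (per sweep):

* allele-copy origins z ~ categorical ∝ q_i * p_{k,l} (A copy) or
  q_i * (1 - p_{k,l}) (B copy);
* cluster frequencies p_{k,l} ~ Beta(lambda + n_A, lambda + n_B);
* individual proportions q_i ~ Beta(alpha + c_{i,wild}, alpha + c_{i,farm});
* the shared Dirichlet concentration alpha by a Metropolis step with a
  uniform(0, alpha_max) prior.

Cluster labels are arbitrary during sampling; they are aligned afterwards by
comparing the mean posterior membership of wild- versus farm-center-point
individuals, which is unambiguous when 100 individuals anchor each cluster.

A fixed-frequency maximum-likelihood estimator (:func:`ml_admixture`) maximizes
the same likelihood with cluster frequencies pinned to the center-point values;
it serves as a fast mode and as an independent check on the MCMC.

:class:`AdmixtureAssigner` wraps both in a scikit-learn estimator: ``fit`` on
the labeled center-point genotypes, ``predict_proba`` for P(wild).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from sklearn.base import BaseEstimator, ClassifierMixin

from .centerpoint import CenterPoint
from .genotype_io import MISSING, AlleleFrequencies, GenotypeMatrix

__all__ = [
    "MCMCSettings",
    "AdmixtureResult",
    "AdmixtureAssigner",
    "assign_individual",
    "assign_batch",
    "ml_admixture",
]

_FREQ_CLIP = 1e-6  # keeps the fixed-frequency likelihood finite at diagnostic loci


@dataclass(frozen=True)
class MCMCSettings:
    """Sampler settings; K is fixed at 2 (wild vs farm).

    Defaults follow common practice for this assignment problem: 50,000
    burn-in sweeps and 100,000 retained sweeps, a Dirichlet(1) prior on
    cluster allele frequencies, and a shared admixture concentration alpha
    updated by Metropolis under a uniform(0, alpha_max) prior.
    """

    burn_in: int = 50_000
    reps: int = 100_000
    lambda_: float = 1.0
    alpha_init: float = 1.0
    alpha_proposal_sd: float = 0.05
    alpha_max: float = 10.0
    seed: int = 0

    K = 2

    def __post_init__(self) -> None:
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.lambda_ <= 0:
            raise ValueError("lambda_ must be > 0")
        if not 0 < self.alpha_init < self.alpha_max:
            raise ValueError("alpha_init must lie in (0, alpha_max)")
        if self.alpha_proposal_sd <= 0:
            raise ValueError("alpha_proposal_sd must be > 0")


@dataclass
class AdmixtureResult:
    """Posterior membership of one individual in the wild-aligned cluster."""

    individual_id: str
    p_wild: float
    p_wild_se: float
    settings: MCMCSettings | None
    label_alignment: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_wild <= 1.0:
            raise ValueError("p_wild must lie in [0, 1]")


def _derive_seed(seed: int, individual_id: str) -> int:
    """Stable per-individual chain seed.

    Keying on the individual id (not batch position) makes every assignment
    independent of batch composition and order: adding, removing or permuting
    queries never changes another query's chain.
    """
    return int((seed * 0x9E3779B1 + zlib.crc32(individual_id.encode())) % 2**31)


def _dosage_row(query: GenotypeMatrix) -> np.ndarray:
    if query.n_individuals != 1:
        raise ValueError("query must contain exactly one individual")
    x = query.genotypes[0]
    if (x == MISSING).all():
        raise ValueError(f"query {query.individual_ids[0]!r} is missing at every locus")
    return x


def _check_loci(*matrices: GenotypeMatrix) -> None:
    loci = matrices[0].locus_ids
    for m in matrices[1:]:
        if m.locus_ids != loci:
            raise ValueError("locus sets do not match between query and center points")


def _gibbs_chain(
    X: np.ndarray,
    query_rows: np.ndarray,
    wild_rows: np.ndarray,
    farm_rows: np.ndarray,
    settings: MCMCSettings,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Run the K=2 Gibbs sampler on the stacked dosage matrix ``X``.

    Returns (p_wild per query row, Monte-Carlo SE per query row, alignment
    record).  ``query_rows`` individuals get running first and second moments
    for the SE; center-point rows only accumulate means (for alignment).
    """
    rng = np.random.default_rng(settings.seed)
    N, L = X.shape
    # Stack the two allele copies of each genotype as 2N rows of A-indicators:
    # dosage 2 -> (A, A); 1 -> (A, B); 0 -> (B, B); missing excluded entirely.
    valid_g = X != MISSING
    isA = np.vstack([valid_g & (X >= 1), valid_g & (X == 2)])
    valid = np.vstack([valid_g, valid_g])
    isB = valid & ~isA
    tot_A = isA.sum(axis=0)  # per-locus copy totals are sweep-invariant
    tot_B = isB.sum(axis=0)
    c_valid = valid_g.sum(axis=1) * 2
    # float A-indicator turns the per-copy emission where(isA, p, 1-p) into
    # (1-p) + isA*(2p-1); missing copies are masked out of z0 afterwards
    isAf = isA.astype(float)

    lam = settings.lambda_
    alpha = settings.alpha_init
    q = np.full(N, 0.5)
    p = rng.random((2, L))

    sum_q = np.zeros(N)
    sum_q2 = np.zeros(query_rows.size)
    n_kept = 0
    u = np.empty((2 * N, L))

    for sweep in range(settings.burn_in + settings.reps):
        qq = np.concatenate([q, q])[:, None]
        w0 = qq * ((1.0 - p[0]) + isAf * (2.0 * p[0] - 1.0))
        w1 = (1.0 - qq) * ((1.0 - p[1]) + isAf * (2.0 * p[1] - 1.0))
        rng.random(out=u)
        z0 = (u * (w0 + w1) < w0) & valid
        nA0 = (z0 & isA).sum(axis=0)
        n0 = z0.sum(axis=0)
        nB0 = n0 - nA0
        p = rng.beta(
            lam + np.array([nA0, tot_A - nA0]),
            lam + np.array([nB0, tot_B - nB0]),
        )
        c0 = z0[:N].sum(axis=1) + z0[N:].sum(axis=1)
        q = rng.beta(alpha + c0, alpha + (c_valid - c0))
        np.clip(q, 1e-12, 1.0 - 1e-12, out=q)
        alpha = _update_alpha(alpha, q, settings, rng)
        if sweep >= settings.burn_in:
            sum_q += q
            sum_q2 += q[query_rows] ** 2
            n_kept += 1

    mean_q = sum_q / n_kept
    wild_mean0 = float(mean_q[wild_rows].mean())
    farm_mean0 = float(mean_q[farm_rows].mean())
    wild_is_cluster0 = wild_mean0 >= farm_mean0
    alignment = {
        "wild_cluster": 0 if wild_is_cluster0 else 1,
        "wild_cp_mean_membership": wild_mean0 if wild_is_cluster0 else 1 - wild_mean0,
        "farm_cp_mean_membership": farm_mean0 if wild_is_cluster0 else 1 - farm_mean0,
    }
    m = mean_q[query_rows]
    var = np.maximum(sum_q2 / n_kept - m**2, 0.0)
    se = np.sqrt(var / n_kept)  # naive (autocorrelation ignored)
    p_wild = m if wild_is_cluster0 else 1.0 - m
    return p_wild, se, alignment


def _update_alpha(
    alpha: float, q: np.ndarray, settings: MCMCSettings, rng: np.random.Generator
) -> float:
    prop = rng.normal(alpha, settings.alpha_proposal_sd)
    if not 0.0 < prop < settings.alpha_max:
        rng.random()  # keep the draw count fixed for reproducibility
        return alpha
    s = float(np.log(q).sum() + np.log1p(-q).sum())
    N = q.size

    def logpost(a: float) -> float:
        return N * (gammaln(2 * a) - 2 * gammaln(a)) + (a - 1.0) * s

    if np.log(rng.random()) < logpost(prop) - logpost(alpha):
        return prop
    return alpha


class AdmixtureAssigner(ClassifierMixin, BaseEstimator):
    """Scikit-learn estimator for center-point membership probabilities.

    Fit on the stacked center-point genotypes (A-allele dosages, missing as
    -1) with labels naming each reference cluster; ``predict_proba`` then
    returns per-query membership probabilities, the ``wild_label`` column
    being P(wild).

    Parameters
    ----------
    mode : {"mcmc", "ml"}
        "mcmc" runs the full Bayesian sampler per query individual (each
        query analyzed singly together with all reference individuals);
        "ml" maximizes the same likelihood with cluster allele frequencies
        fixed at the reference values — orders of magnitude faster, no
        posterior uncertainty.
    burn_in, reps, lambda_, alpha_init, alpha_proposal_sd, alpha_max
        See :class:`MCMCSettings`.
    wild_label : str
        Which of the two classes is the wild cluster.
    random_state : int
        Base seed; query i in a batch uses ``random_state + i``.
    """

    def __init__(
        self,
        mode: str = "mcmc",
        burn_in: int = 50_000,
        reps: int = 100_000,
        lambda_: float = 1.0,
        alpha_init: float = 1.0,
        alpha_proposal_sd: float = 0.05,
        alpha_max: float = 10.0,
        wild_label: str = "wild",
        random_state: int = 0,
    ) -> None:
        self.mode = mode
        self.burn_in = burn_in
        self.reps = reps
        self.lambda_ = lambda_
        self.alpha_init = alpha_init
        self.alpha_proposal_sd = alpha_proposal_sd
        self.alpha_max = alpha_max
        self.wild_label = wild_label
        self.random_state = random_state

    def _settings(self, seed: int) -> MCMCSettings:
        return MCMCSettings(
            burn_in=self.burn_in,
            reps=self.reps,
            lambda_=self.lambda_,
            alpha_init=self.alpha_init,
            alpha_proposal_sd=self.alpha_proposal_sd,
            alpha_max=self.alpha_max,
            seed=seed,
        )

    @staticmethod
    def _validate_X(X: np.ndarray) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (individuals x loci)")
        if not np.isin(X, (0, 1, 2, MISSING)).all():
            raise ValueError("dosages must be 0, 1, 2 or -1 (missing)")
        return X.astype(np.int8)

    def fit(self, X, y) -> "AdmixtureAssigner":
        if self.mode not in ("mcmc", "ml"):
            raise ValueError("mode must be 'mcmc' or 'ml'")
        X = self._validate_X(X)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y lengths differ")
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("exactly two reference classes required")
        if self.wild_label not in self.classes_:
            raise ValueError(f"wild_label {self.wild_label!r} not among classes")
        self.X_ref_ = X
        self.y_ref_ = y
        wild = y == self.wild_label
        self.wild_rows_ = np.flatnonzero(wild)
        self.farm_rows_ = np.flatnonzero(~wild)
        self.wild_freqs_ = _dosage_freqs(X[wild])
        self.farm_freqs_ = _dosage_freqs(X[~wild])
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Membership probabilities, columns ordered as ``classes_``."""
        p_wild, _ = self.membership(X)
        out = np.column_stack([1.0 - p_wild, p_wild])
        if self.classes_[1] != self.wild_label:
            out = out[:, ::-1]
        return out

    def membership(self, X) -> tuple[np.ndarray, np.ndarray]:
        """P(wild) and its Monte-Carlo SE (zeros in ML mode) per query row."""
        if not hasattr(self, "X_ref_"):
            raise ValueError("fit the assigner before predicting")
        X = self._validate_X(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("query locus count differs from the reference panel")
        if self.mode == "ml":
            p = np.array(
                [_ml_q(x, self.wild_freqs_, self.farm_freqs_) for x in X]
            )
            return p, np.zeros_like(p)
        p_wild = np.empty(X.shape[0])
        se = np.empty(X.shape[0])
        for i, x in enumerate(X):
            stacked = np.vstack([x[None, :], self.X_ref_])
            pw, s, _ = _gibbs_chain(
                stacked,
                np.array([0]),
                self.wild_rows_ + 1,
                self.farm_rows_ + 1,
                self._settings(self.random_state + i),
            )
            p_wild[i], se[i] = pw[0], s[0]
        return p_wild, se

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]


def _dosage_freqs(X: np.ndarray) -> np.ndarray:
    observed = X != MISSING
    n = 2 * observed.sum(axis=0)
    if (n == 0).any():
        raise ValueError("reference class has loci with no non-missing alleles")
    return np.where(observed, X, 0).sum(axis=0) / n


def _ml_q(
    x: np.ndarray, wild_freq: np.ndarray, farm_freq: np.ndarray, tol: float = 1e-9
) -> float:
    """Maximize the fixed-frequency admixture likelihood over q in [0, 1].

    Each allele copy contributes log(q*pw + (1-q)*pf) for an A copy and the
    complementary term for a B copy; missing loci drop out.  The log-likelihood
    is concave in q, so a bounded scalar minimization suffices.
    """
    obs = x != MISSING
    if not obs.any():
        raise ValueError("all query loci missing")
    pw = np.clip(wild_freq[obs], _FREQ_CLIP, 1.0 - _FREQ_CLIP)
    pf = np.clip(farm_freq[obs], _FREQ_CLIP, 1.0 - _FREQ_CLIP)
    dos = x[obs]
    nA = dos.astype(float)  # number of A copies per locus
    nB = 2.0 - nA

    def nll(qv: float) -> float:
        mixA = qv * pw + (1.0 - qv) * pf
        mixB = qv * (1.0 - pw) + (1.0 - qv) * (1.0 - pf)
        return -float(nA @ np.log(mixA) + nB @ np.log(mixB))

    res = minimize_scalar(nll, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": tol})
    q_hat = float(res.x)
    # concavity means interior optimum is global, but compare endpoints anyway
    for edge in (0.0, 1.0):
        if nll(edge) < nll(q_hat):
            q_hat = edge
    return q_hat


def ml_admixture(
    query: GenotypeMatrix,
    wild_freqs: AlleleFrequencies,
    farm_freqs: AlleleFrequencies,
) -> float:
    """Fixed-frequency maximum-likelihood admixture proportion of one individual."""
    if wild_freqs.locus_ids != query.locus_ids or farm_freqs.locus_ids != query.locus_ids:
        raise ValueError("frequency locus sets do not match the query")
    x = _dosage_row(query)
    obs = x != MISSING
    if not (wild_freqs.defined[obs].all() and farm_freqs.defined[obs].all()):
        raise ValueError("undefined reference frequency at a non-missing query locus")
    return _ml_q(x, wild_freqs.freq_A, farm_freqs.freq_A)


def assign_individual(
    query: GenotypeMatrix,
    wild_cp: CenterPoint,
    farm_cp: CenterPoint,
    settings: MCMCSettings | None = None,
) -> AdmixtureResult:
    """P(wild) for one individual analyzed together with both center points."""
    settings = settings or MCMCSettings()
    _check_loci(query, wild_cp.genotypes, farm_cp.genotypes)
    x = _dosage_row(query)
    nw = wild_cp.n_individuals
    nf = farm_cp.n_individuals
    X = np.vstack([x[None, :], wild_cp.genotypes.genotypes, farm_cp.genotypes.genotypes])
    chain_settings = replace(
        settings, seed=_derive_seed(settings.seed, query.individual_ids[0])
    )
    p_wild, se, alignment = _gibbs_chain(
        X,
        np.array([0]),
        np.arange(1, 1 + nw),
        np.arange(1 + nw, 1 + nw + nf),
        chain_settings,
    )
    return AdmixtureResult(
        query.individual_ids[0], float(p_wild[0]), float(se[0]), settings, alignment
    )


def assign_batch(
    queries: GenotypeMatrix,
    wild_cp: CenterPoint,
    farm_cp: CenterPoint,
    settings: MCMCSettings | None = None,
) -> list[AdmixtureResult]:
    """Independent single-individual assignments.

    Each query runs its own chain with a seed derived from (settings.seed,
    individual id), so adding or removing queries never changes another
    query's result and permuting the input permutes the output identically.
    """
    settings = settings or MCMCSettings()
    results = []
    for i in range(queries.n_individuals):
        one = queries.select_individuals([i])
        results.append(assign_individual(one, wild_cp, farm_cp, settings))
    return results
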