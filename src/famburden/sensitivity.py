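"""Family-structure sensitivity analyses.

Intrafamilial controls violate the independence assumption of the exact
test, so three complementary robustness checks accompany the primary scan:

1. leave-one-per-family subsampling — drop one randomly chosen member from
   every family with two or more sequenced members and re-test;
2. within-family label permutation — an empirical null that shuffles
   case/control labels only inside each family block, preserving every
   family's label multiset and hence the between-family structure;
3. a logistic model of case status on carrier state with a family-level
   random intercept, fitted by Gauss-Hermite-quadrature maximum likelihood.

Permutation empirical p-values use the add-one rule (b + 1) / (B + 1) and
can therefore never be zero.  The permuted statistic is the one-sided
Fisher p; "as or more extreme" means a permuted p no larger than the
observed one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import norm

from .cohort import Cohort, CohortError, Group
from .enrichment import fisher_one_sided_vector

__all__ = [
    "PermutationResult",
    "GlmmResult",
    "leave_one_per_family",
    "within_family_permutation",
    "family_glmm_pvalue",
]


@dataclass
class PermutationResult:
    observed_stat: float
    B: int
    n_as_or_more_extreme: int
    seed: int

    @property
    def empirical_p(self) -> float:
        return (self.n_as_or_more_extreme + 1) / (self.B + 1)


@dataclass
class GlmmResult:
    """Carrier-effect estimate from the family random-intercept model."""

    beta: float
    se: float
    p_value: float
    tau: float  # random-intercept SD
    converged: bool
    separation: bool = False
    message: str = ""


def leave_one_per_family(cohort: Cohort, seed: int) -> Cohort:
    """Drop one uniformly chosen member from each multi-member family.

    Singleton families are untouched, so no family ever loses its last
    member.  Deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    drop: set[str] = set()
    for fam_id, members in cohort.families().items():
        if len(members) >= 2:
            victim = members[int(rng.integers(len(members)))]
            drop.add(victim.subject_id)
    keep = [s.subject_id for s in cohort.subjects
            if s.subject_id not in drop]
    return cohort.subset(keep)


def _permute_within_families(
    labels: np.ndarray,
    family_ids: np.ndarray,
    B: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(B, n) matrix of label vectors permuted inside each family block."""
    n = labels.shape[0]
    out = np.empty((B, n), dtype=labels.dtype)
    keys = rng.random((B, n))
    for fam in np.unique(family_ids):
        idx = np.nonzero(family_ids == fam)[0]
        order = np.argsort(keys[:, idx], axis=1)
        out[:, idx] = labels[idx][order]
    return out


def within_family_permutation(
    carrier_vector: Sequence[int],
    labels: Sequence[Group],
    family_ids: Sequence[str],
    B: int = 10_000,
    seed: int = 42,
) -> PermutationResult:
    """Empirical one-sided enrichment p under within-family label shuffling.

    Each permutation independently re-orders labels inside every family,
    leaving between-family assignment fixed; the one-sided Fisher p is
    recomputed for each permuted labelling.
    """
    if B < 1:
        raise CohortError("B must be >= 1")
    carrier = np.asarray(carrier_vector, dtype=np.int8)
    is_case = np.array([g is Group.CASE or g == Group.CASE.value
                        for g in labels], dtype=np.int8)
    fams = np.asarray(family_ids)
    if not carrier.shape == is_case.shape == fams.shape:
        raise CohortError("carrier, labels and family_ids must align")
    n1 = int(is_case.sum())
    n2 = int(is_case.size - n1)
    if n1 == 0 or n2 == 0:
        raise CohortError("both groups must be present")
    a_obs = int(carrier[is_case == 1].sum())
    c_obs = int(carrier.sum()) - a_obs
    p_obs = float(fisher_one_sided_vector(
        np.array([a_obs]), n1, np.array([c_obs]), n2)[0])

    rng = np.random.default_rng(seed)
    perms = _permute_within_families(is_case, fams, B, rng)
    a_perm = perms @ carrier  # case-carrier count per permutation
    c_perm = int(carrier.sum()) - a_perm
    p_perm = fisher_one_sided_vector(a_perm, n1, c_perm, n2)
    n_extreme = int((p_perm <= p_obs).sum())
    return PermutationResult(
        observed_stat=p_obs, B=B,
        n_as_or_more_extreme=n_extreme, seed=seed,
    )


# ------------------------------------------------------------------- GLMM


def _wald_se(nll, mle: np.ndarray, full: bool, h: float = 1e-4) -> float:
    """SE of the carrier coefficient from a finite-difference Hessian.

    ``full=True`` differentiates over (b0, b1, log tau); ``full=False``
    profiles only the fixed effects with log tau fixed at its MLE.
    """
    dims = (0, 1, 2) if full else (0, 1)
    k = len(dims)
    info = np.empty((k, k))
    f0 = nll(mle)
    for ii, i in enumerate(dims):
        for jj, j in enumerate(dims):
            if jj < ii:
                info[ii, jj] = info[jj, ii]
                continue
            ei = np.zeros_like(mle)
            ej = np.zeros_like(mle)
            ei[i] = h
            ej[j] = h
            if i == j:
                info[ii, jj] = (nll(mle + ei) - 2 * f0 + nll(mle - ei)) / h**2
            else:
                info[ii, jj] = (
                    nll(mle + ei + ej) - nll(mle + ei - ej)
                    - nll(mle - ei + ej) + nll(mle - ei - ej)
                ) / (4 * h**2)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return float("nan")
    var = cov[1, 1]
    return math.sqrt(var) if var > 0 else float("nan")


def _glmm_negloglik(
    params: np.ndarray,
    y: np.ndarray,
    x: np.ndarray,
    fam_index: np.ndarray,
    n_families: int,
    nodes: np.ndarray,
    log_weights: np.ndarray,
) -> float:
    """Negative marginal log-likelihood by Gauss-Hermite quadrature.

    Integrates the family random intercept u ~ N(0, tau^2) out of the
    binomial likelihood using probabilists' Hermite nodes.
    """
    b0, b1, log_tau = params
    tau = math.exp(min(log_tau, 10.0))  # clamp against optimizer excursions
    eta = b0 + b1 * x  # (n,)
    # (n_nodes, n): linear predictor at each quadrature point
    etas = eta[None, :] + tau * nodes[:, None]
    # log Bernoulli likelihood, numerically stable
    loglik_obs = -np.logaddexp(0.0, np.where(y == 1, -etas, etas))
    # sum within family -> (n_nodes, n_families)
    fam_sums = np.zeros((nodes.size, n_families))
    np.add.at(fam_sums.T, fam_index, loglik_obs.T)
    # integrate: log sum_k w_k exp(fam_sums[k, j])
    log_int = np.logaddexp.reduce(log_weights[:, None] + fam_sums, axis=0)
    return -float(log_int.sum())


def family_glmm_pvalue(
    carrier_vector: Sequence[int],
    labels: Sequence[Group],
    family_ids: Sequence[str],
    n_quadrature: int = 25,
) -> GlmmResult:
    """Wald p for carrier status in a family random-intercept logistic model.

    Fits ``logit P(case) = b0 + b1 * carrier + u_family`` with
    ``u ~ N(0, tau^2)`` by maximum likelihood (Gauss-Hermite quadrature over
    the random intercept), and returns the two-sided Wald p for ``b1``.
    When the fitted tau is zero the model collapses exactly to ordinary
    logistic regression.  Perfect separation is detected and flagged rather
    than reported as a spuriously tiny p.
    """
    carrier = np.asarray(carrier_vector, dtype=float)
    y = np.array([1.0 if (g is Group.CASE or g == Group.CASE.value) else 0.0
                  for g in labels])
    fams = np.asarray(family_ids)
    if not carrier.shape == y.shape == fams.shape:
        raise CohortError("carrier, labels and family_ids must align")
    if np.unique(fams).size < 2:
        raise CohortError("family GLMM needs >= 2 families")
    if np.ptp(carrier) == 0 or np.ptp(y) == 0:
        raise CohortError("carrier and label vectors must both vary")

    # perfect separation: carrier status determines the label
    sep = ((y[carrier == 1].min(initial=1.0) == 1.0
            and y[carrier == 0].max(initial=0.0) == 0.0)
           or (y[carrier == 1].max(initial=0.0) == 0.0
               and y[carrier == 0].min(initial=1.0) == 1.0))

    uniq, fam_index = np.unique(fams, return_inverse=True)
    nodes, weights = hermegauss(n_quadrature)
    log_weights = np.log(weights / math.sqrt(2 * math.pi))

    def nll(params: np.ndarray) -> float:
        return _glmm_negloglik(params, y, carrier, fam_index, uniq.size,
                               nodes, log_weights)

    best = None
    for tau0 in (0.05, 0.5, 1.5):
        res = minimize(nll, x0=np.array([0.0, 0.0, math.log(tau0)]),
                       method="Nelder-Mead",
                       options={"xatol": 1e-6, "fatol": 1e-9,
                                "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    b0, b1, log_tau = best.x
    tau = math.exp(min(log_tau, 10.0))

    # Wald SE from the observed information.  Use the full 3-parameter
    # Hessian (so tau uncertainty propagates into the fixed-effect SE, as
    # in standard mixed-model software); when tau has collapsed to the
    # boundary the log-tau direction is flat, so fall back to the
    # fixed-effect block with tau held at its MLE — there the model has
    # reduced to plain logistic regression anyway.
    converged = bool(best.success)
    se = _wald_se(nll, best.x, full=tau > 1e-3)
    if not math.isfinite(se):
        se = _wald_se(nll, best.x, full=False)
    if not math.isfinite(se):
        converged = False
    if sep or not math.isfinite(se) or se == 0.0 or abs(b1) > 15:
        return GlmmResult(beta=b1, se=se, p_value=float("nan"), tau=tau,
                          converged=converged, separation=True,
                          message="perfect or quasi-perfect separation")
    p = 2 * float(norm.sf(abs(b1 / se)))
    return GlmmResult(beta=b1, se=se, p_value=p, tau=tau,
                      converged=converged,
                      message=best.message if not converged else "")
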