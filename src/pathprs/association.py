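"""Case-control association statistics for polygenic risk scores.

Each PRS is evaluated by logistic regression of case-control status on the
standardized score with the first few genotype principal components as
ancestry covariates.  Reported per configuration: odds ratio per SD of PRS
with a 95% Wald confidence interval and two-sided Wald p-value; Nagelkerke
pseudo-R-squared of the PRS term (full minus covariates-only model);
variance explained re-expressed on the liability scale with an
ascertainment correction for oversampled cases (Lee et al.-style
transformation at a configurable population prevalence, 0.7% by default);
and the covariate-free AUROC.

A fast Newton/IRLS logistic solver (`_logistic_fit`) backs the permutation
machinery, where tens of thousands of small fits are needed; the public
``fit_logistic`` uses statsmodels and the two agree to numerical precision
(tested).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .io import DosageMatrix
from .scoring import ScoreVector

__all__ = [
    "Phenotype",
    "LiabilityParams",
    "LogisticFit",
    "AssociationResult",
    "compute_pcs",
    "fit_logistic",
    "nagelkerke_r2",
    "nagelkerke_delta_r2",
    "liability_r2",
    "auroc",
    "bonferroni_threshold",
    "batch_negative_control_filter",
    "associate_prs",
]


@dataclass
class Phenotype:
    """Case-control status (1 = case) and covariate matrix, sample-aligned."""

    sample_ids: list[str]
    status: np.ndarray
    covariates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=int)
        if self.status.shape != (len(self.sample_ids),):
            raise ValueError("status length does not match sample count")
        if not np.isin(self.status, (0, 1)).all():
            raise ValueError("status must be 0/1")
        if 0 < self.status.sum() < len(self.status):
            pass
        else:
            raise ValueError("both cases and controls must be present")
        if self.covariates is not None:
            self.covariates = np.asarray(self.covariates, dtype=float)
            if self.covariates.ndim != 2 or self.covariates.shape[0] != len(
                self.sample_ids
            ):
                raise ValueError("covariate rows do not align with samples")

    @property
    def case_fraction(self) -> float:
        return float(self.status.mean())


@dataclass(frozen=True)
class LiabilityParams:
    """Population prevalence K and sample case proportion P."""

    prevalence: float = 0.007
    case_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must lie in (0, 1)")
        if not (0 < self.case_fraction < 1):
            raise ValueError("case_fraction must lie in (0, 1)")


@dataclass
class LogisticFit:
    """Coefficient-level summary of a logistic fit for one predictor."""

    coef: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    pval: float
    llf: float  # fitted model log-likelihood
    llf_null: float  # model without the predictor (covariates + intercept)
    llf_intercept: float  # intercept-only model
    n: int
    converged: bool


@dataclass
class AssociationResult:
    """All reported columns for one PRS configuration."""

    or_per_sd: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    nagelkerke_r2: float
    liability_r2: float
    auroc: float
    converged: bool = True

    def __post_init__(self) -> None:
        if self.converged and not (self.ci_low <= self.or_per_sd <= self.ci_high):
            raise ValueError("CI does not bracket the odds ratio")
        if not (0 <= self.auroc <= 1):
            raise ValueError("AUROC outside [0, 1]")


# ---------------------------------------------------------------------------
# principal components
# ---------------------------------------------------------------------------


def compute_pcs(dosages: DosageMatrix, k: int = 5) -> np.ndarray:
    """Top-k principal component scores of the column-standardized dosages.

    Computed from the eigendecomposition of the sample-by-sample Gram
    matrix, which is exact and deterministic.  Each component's sign is
    fixed so its largest-magnitude entry is positive, making results
    invariant (up to that convention) to variant order.
    """
    n, m = dosages.n_samples, dosages.n_variants
    if k > min(n, m):
        raise ValueError(f"k={k} exceeds matrix dimensions {n}x{m}")
    x = dosages.dosages
    z = x - x.mean(axis=0)
    sd = x.std(axis=0)
    nz = sd > 0
    z[:, nz] /= sd[nz]
    z[:, ~nz] = 0.0
    gram = z @ z.T
    eigval, eigvec = np.linalg.eigh(gram)
    order = np.argsort(eigval)[::-1][:k]
    eigval = eigval[order]
    if eigval[-1] <= 1e-9 * max(eigval[0], 1.0):
        raise ValueError(f"k={k} exceeds the rank of the dosage matrix")
    pcs = eigvec[:, order] * np.sqrt(eigval)
    flip = np.abs(pcs).argmax(axis=0)
    pcs *= np.sign(pcs[flip, np.arange(k)])
    return pcs


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------


def _logistic_fit(
    X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Newton-Raphson ML logistic fit with step halving.

    Returns (beta, covariance, log-likelihood, converged).  ``X`` must
    already contain an intercept column.
    """
    n, p = X.shape
    beta = np.zeros(p)
    ybar = y.mean()
    beta[np.flatnonzero((X == 1).all(axis=0))[:1]] = np.log(ybar / (1 - ybar))

    def loglik(b: np.ndarray) -> tuple[float, np.ndarray]:
        eta = X @ b
        # log(1 + e^eta) computed stably
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        return ll, eta

    ll, eta = loglik(beta)
    converged = False
    for _ in range(max_iter):
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        hess = (X * w[:, None]).T @ X
        hess[np.diag_indices_from(hess)] += 1e-10  # guards singular Hessians
        step = np.linalg.solve(hess, grad)
        new_ll, new_eta = loglik(beta + step)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step *= 0.5
            halvings += 1
            new_ll, new_eta = loglik(beta + step)
        beta = beta + step
        improvement = new_ll - ll
        ll, eta = new_ll, new_eta
        if abs(improvement) < tol and np.abs(step).max() < 1e-6:
            converged = True
            break
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    hess = (X * w[:, None]).T @ X
    hess[np.diag_indices_from(hess)] += 1e-10
    cov = np.linalg.inv(hess)
    if not np.isfinite(beta).all() or np.abs(beta).max() > 50:
        converged = False  # effectively separated
    return beta, cov, ll, converged


def _intercept_loglik(y: np.ndarray) -> float:
    n1 = y.sum()
    n = len(y)
    p = n1 / n
    return float(n1 * np.log(p) + (n - n1) * np.log(1 - p))


def fit_logistic(
    pheno: Phenotype, score: ScoreVector, with_covariates: bool = True
) -> LogisticFit:
    """ML logistic regression of status on the standardized PRS.

    Uses statsmodels' Logit.  ``llf_null`` refits without the PRS term so
    Nagelkerke's delta-R-squared can be formed.  Perfect separation or
    non-convergence is flagged via ``converged`` rather than raised.
    """
    import statsmodels.api as sm

    if pheno.sample_ids != score.sample_ids:
        raise ValueError("phenotype and score sample ids differ")
    y = pheno.status.astype(float)
    cols = [np.ones(len(y))]
    if with_covariates and pheno.covariates is not None:
        cols.extend(pheno.covariates.T)
    x_null = np.column_stack(cols)
    x_full = np.column_stack(cols + [score.std_score])

    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            full = sm.Logit(y, x_full).fit(disp=0)
            null = sm.Logit(y, x_null).fit(disp=0) if x_null.shape[1] > 1 else None
            if not full.mle_retvals.get("converged", True):
                converged = False
        except Exception:  # statsmodels raises on hard separation
            beta, cov, llf, _ = _logistic_fit(x_full, y)
            se = float(np.sqrt(cov[-1, -1]))
            with np.errstate(over="ignore"):
                return LogisticFit(
                    float(beta[-1]), se, float(np.exp(beta[-1])),
                    float(np.exp(beta[-1] - 1.96 * se)),
                    float(np.exp(beta[-1] + 1.96 * se)),
                    float("nan"), llf, float("nan"), _intercept_loglik(y),
                    len(y), False,
                )
    coef = float(full.params[-1])
    se = float(full.bse[-1])
    llf_null = float(null.llf) if null is not None else _intercept_loglik(y)
    with np.errstate(over="ignore"):  # separated fits give inf CIs, not errors
        return LogisticFit(
            coef=coef,
            se=se,
            odds_ratio=float(np.exp(coef)),
            ci_low=float(np.exp(coef - 1.96 * se)),
            ci_high=float(np.exp(coef + 1.96 * se)),
            pval=float(2 * sps.norm.sf(abs(coef / se))),
            llf=float(full.llf),
            llf_null=llf_null,
            llf_intercept=_intercept_loglik(y),
            n=len(y),
            converged=converged,
        )


# ---------------------------------------------------------------------------
# pseudo-R2 and liability transformation
# ---------------------------------------------------------------------------


def nagelkerke_r2(llf: float, llf_intercept: float, n: int) -> float:
    """Nagelkerke pseudo-R2: Cox-Snell rescaled to a [0, 1] maximum."""
    cox_snell = 1.0 - np.exp(2.0 * (llf_intercept - llf) / n)
    max_cs = 1.0 - np.exp(2.0 * llf_intercept / n)
    return float(cox_snell / max_cs)


def nagelkerke_delta_r2(
    llf_full: float, llf_null: float, llf_intercept: float, n: int
) -> float:
    """R2(full) - R2(null) for nested logistic models sharing an intercept.

    ``llf_null`` is the covariates-only model; ``llf_intercept`` the
    intercept-only model.  A full model that fits worse than its nested
    null (beyond numerical slack) is a caller error.
    """
    if llf_full < llf_null - 1e-8:
        raise ValueError("llf_full < llf_null: models are not nested as claimed")
    return nagelkerke_r2(llf_full, llf_intercept, n) - nagelkerke_r2(
        llf_null, llf_intercept, n
    )


def liability_r2(r2_observed: float, params: LiabilityParams) -> float:
    """Observed-scale R2 transformed to the liability scale.

    Ascertainment-corrected transformation for case-control studies: with
    population prevalence K, sample case proportion P, liability threshold
    ``t = Phi^-1(1-K)`` and normal density ``z = phi(t)``,

        C     = K(1-K)/z^2 * K(1-K)/(P(1-P))
        theta = m (P-K)/(1-K) * (m (P-K)/(1-K) - t),  m = z/K
        R2_l  = C R2_o / (1 + C theta R2_o)

    With P = K (no ascertainment) this reduces to multiplying by
    K^2 (1-K)^2 / (z^2 K(1-K)).
    """
    if not (0 <= r2_observed <= 1):
        raise ValueError("r2_observed must lie in [0, 1]")
    K = params.prevalence
    P = params.case_fraction
    t = sps.norm.isf(K)
    z = sps.norm.pdf(t)
    m = z / K
    C = (K * (1 - K) / z**2) * (K * (1 - K) / (P * (1 - P)))
    theta = m * (P - K) / (1 - K) * (m * (P - K) / (1 - K) - t)
    return float(C * r2_observed / (1 + C * theta * r2_observed))


def auroc(score: ScoreVector | np.ndarray, status: np.ndarray) -> float:
    """Probability a random case outscores a random control (ties count 1/2)."""
    s = score.std_score if isinstance(score, ScoreVector) else np.asarray(score)
    y = np.asarray(status)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to compute AUROC")
    return float(roc_auc_score(y, s))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha/m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


# ---------------------------------------------------------------------------
# batch negative-control QC
# ---------------------------------------------------------------------------


def batch_negative_control_filter(
    case_dosages: DosageMatrix,
    batch_labels: Sequence[str | int],
    fdr_q: float = 0.05,
) -> list[str]:
    """Variants whose dosage differs between genotyping batches (cases only).

    Runs a per-variant logistic regression of batch membership on dosage and
    returns the variant ids significant after Benjamini-Hochberg control at
    ``fdr_q`` — candidates for removal as batch artifacts.  Using cases only
    avoids discarding true case-control signal.  A single batch yields an
    empty list with a warning.
    """
    labels = np.asarray(batch_labels)
    if labels.shape != (case_dosages.n_samples,):
        raise ValueError("batch_labels length does not match sample count")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        warnings.warn("single batch: negative-control filter removes nothing")
        return []
    if len(uniq) > 2:
        raise ValueError("negative-control filter supports exactly two batches")
    if fdr_q <= 0:
        return []
    y = (labels == uniq[1]).astype(float)
    pvals = np.ones(case_dosages.n_variants)
    ones = np.ones(case_dosages.n_samples)
    for j in range(case_dosages.n_variants):
        x = case_dosages.dosages[:, j]
        if x.std() == 0:
            continue
        X = np.column_stack([ones, x])
        beta, cov, _, converged = _logistic_fit(X, y)
        if not converged:
            pvals[j] = 0.0  # frequencies fully separate the batches
            continue
        zstat = beta[1] / np.sqrt(cov[1, 1])
        pvals[j] = 2 * sps.norm.sf(abs(zstat))
    reject, _, _, _ = multipletests(pvals, alpha=fdr_q, method="fdr_bh")
    return [case_dosages.variant_ids[j] for j in np.flatnonzero(reject)]


# ---------------------------------------------------------------------------
# one-call association summary
# ---------------------------------------------------------------------------


def associate_prs(
    pheno: Phenotype,
    score: ScoreVector,
    liability: LiabilityParams | None = None,
    liability_input: str = "nagelkerke",
) -> AssociationResult:
    """Full association summary for one PRS configuration.

    ``liability_input`` selects the observed-scale R2 fed to the liability
    transformation: ``"nagelkerke"`` (default, the pseudo-R2 of the PRS
    term) or ``"linear"`` (delta R2 from ordinary least squares of status
    on PRS given covariates, the scale the correction is derived for).
    """
    fit = fit_logistic(pheno, score, with_covariates=True)
    d_r2 = nagelkerke_delta_r2(fit.llf, fit.llf_null, fit.llf_intercept, fit.n)
    d_r2 = max(d_r2, 0.0)
    if liability is None:
        liability = LiabilityParams(case_fraction=pheno.case_fraction)
    if liability_input == "nagelkerke":
        r2_obs = d_r2
    elif liability_input == "linear":
        r2_obs = _linear_delta_r2(pheno, score)
    else:
        raise ValueError("liability_input must be 'nagelkerke' or 'linear'")
    return AssociationResult(
        or_per_sd=fit.odds_ratio,
        ci_low=fit.ci_low,
        ci_high=fit.ci_high,
        pval=fit.pval,
        n_snps=score.n_snps_used,
        nagelkerke_r2=d_r2,
        liability_r2=liability_r2(min(r2_obs, 1.0), liability),
        auroc=auroc(score, pheno.status),
        converged=fit.converged,
    )


def _linear_delta_r2(pheno: Phenotype, score: ScoreVector) -> float:
    """OLS delta-R2 of 0/1 status on PRS, given the covariates."""
    y = pheno.status.astype(float)
    ones = np.ones(len(y))
    base = [ones] if pheno.covariates is None else [ones, *pheno.covariates.T]

    def r2(xcols: list[np.ndarray]) -> float:
        X = np.column_stack(xcols)
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        return 1.0 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))

    return max(r2(base + [score.std_score]) - r2(base), 0.0)
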