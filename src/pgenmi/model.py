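"""Beta-uniform mixture model of TWAS p-values with a logistic evidence prior.

The model scores a single transcription factor (TF) against a quantitative
phenotype.  Each gene ``g`` carries an observed TWAS p-value ``p_g`` and a
binary evidence vector ``r_g`` (one bit per evidence channel, e.g. a
significant cis-eQTL or cis-eQTM inside a ChIP peak of the TF).  A latent
indicator ``z_g`` says whether the gene mediates the TF's influence on the
phenotype:

    Pr(z_g = 1 | r_g) = logistic(w0 + sum_m w_m * r_gm)
    p_g | z_g = 0  ~  Uniform(0, 1)
    p_g | z_g = 1  ~  Beta(alpha, 1),   alpha in (0, 1]

Parameters (alpha, w) are estimated by EM.  The alternative hypothesis
(H = 1) frees all weights; the null (H = 0) removes w1..wM so the prior is
shared across genes.  The TF's association score is the log2 likelihood
ratio between the two fits, with a chi-square approximation on M degrees
of freedom for an approximate p-value.  Fits with negative evidence
weights are flagged post hoc as spurious rather than predicted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import chi2

logger = logging.getLogger(__name__)

#: Floor applied to p-values before density evaluation.  With alpha < 1 the
#: Beta(alpha, 1) density diverges at 0, so exact zeros must be lifted.
EPS_P = 1e-12

#: Lower clamp for the Beta shape parameter; the admissible range is (0, 1].
EPS_ALPHA = 1e-6

LN2 = float(np.log(2.0))


class InputError(ValueError):
    """Invalid data passed to a model fit."""


class ParameterError(ValueError):
    """Model parameters outside their admissible range."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise InputError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class PvalueVector:
    """Per-gene TWAS p-values for one phenotype."""

    values: np.ndarray
    gene_ids: np.ndarray

    def __post_init__(self):
        values = _as_float_array(self.values, "values")
        gene_ids = np.asarray(self.gene_ids)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gene_ids", gene_ids)
        if len(values) != len(gene_ids):
            raise InputError(
                f"{len(values)} p-values but {len(gene_ids)} gene ids"
            )
        if np.any(~np.isfinite(values)) or np.any(values < 0) or np.any(values > 1):
            raise InputError("p-values must be finite and within [0, 1]")
        if len(np.unique(gene_ids)) != len(gene_ids):
            raise InputError("duplicate gene ids in PvalueVector")

    def __len__(self) -> int:
        return len(self.values)

    def clamped(self, eps: float = EPS_P) -> np.ndarray:
        """Values clipped to [eps, 1], safe for density evaluation."""
        return np.clip(self.values, eps, 1.0)


@dataclass(frozen=True)
class EvidenceMatrix:
    """G x M binary matrix of regulatory evidence for one TF.

    ``entries[g, m] = 1`` iff gene ``g`` carries evidence of kind ``m``
    (e.g. a significant in-peak cis-eQTL).
    """

    entries: np.ndarray
    gene_ids: np.ndarray
    evidence_names: tuple[str, ...]

    def __post_init__(self):
        entries = np.asarray(self.entries)
        gene_ids = np.asarray(self.gene_ids)
        names = tuple(self.evidence_names)
        if entries.ndim != 2:
            raise InputError(f"evidence must be 2-D, got shape {entries.shape}")
        if not np.isin(entries, (0, 1)).all():
            raise InputError("evidence entries must be strictly binary")
        entries = entries.astype(np.int8)
        if entries.shape[0] != len(gene_ids):
            raise InputError("evidence rows do not match gene_ids")
        if entries.shape[1] != len(names):
            raise InputError("evidence columns do not match evidence_names")
        if len(np.unique(gene_ids)) != len(gene_ids):
            raise InputError("duplicate gene ids in EvidenceMatrix")
        object.__setattr__(self, "entries", entries)
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "evidence_names", names)

    @property
    def n_genes(self) -> int:
        return self.entries.shape[0]

    @property
    def n_kinds(self) -> int:
        return self.entries.shape[1]

    def select_kinds(self, kinds) -> "EvidenceMatrix":
        """Subset evidence channels, preserving order of ``kinds``."""
        idx = []
        for kind in kinds:
            if kind not in self.evidence_names:
                raise InputError(
                    f"evidence kind {kind!r} not available; "
                    f"have {list(self.evidence_names)}"
                )
            idx.append(self.evidence_names.index(kind))
        return EvidenceMatrix(self.entries[:, idx], self.gene_ids, tuple(kinds))


@dataclass(frozen=True)
class ModelParams:
    """Beta shape alpha and logistic-prior weights [w0, w1..wM]."""

    alpha: float
    weights: np.ndarray

    def __post_init__(self):
        weights = _as_float_array(self.weights, "weights")
        object.__setattr__(self, "weights", weights)
        if not (EPS_ALPHA <= self.alpha <= 1.0):
            raise ParameterError(
                f"alpha={self.alpha} outside [{EPS_ALPHA}, 1]"
            )
        if not np.all(np.isfinite(weights)):
            raise ParameterError("weights must be finite")

    @property
    def n_kinds(self) -> int:
        return len(self.weights) - 1


@dataclass(frozen=True)
class FitResult:
    """Converged EM fit under one hypothesis."""

    params: ModelParams
    loglik: float
    responsibilities: np.ndarray
    hypothesis: int
    n_iter: int
    converged: bool
    loglik_trace: np.ndarray | None = None
    gene_ids: np.ndarray | None = None


@dataclass(frozen=True)
class EMConfig:
    """Tolerances and iteration limits for EM and its inner Newton solver."""

    tol: float = 1e-8
    max_iter: int = 1000
    alpha_init: float = 0.5
    ridge: float = 1e-6
    newton_max_iter: int = 50
    newton_tol: float = 1e-8
    warm_start_from_null: bool = True
    #: relative loglik step below which the quasi-Newton polish kicks in
    polish_trigger: float = 1e-6


DEFAULT_CONFIG = EMConfig()


def gene_prior(weights, evidence_row) -> float:
    """Pr(z_g = 1 | r_g, w) = logistic(w0 + sum_m w_m * r_gm)."""
    w = _as_float_array(weights, "weights")
    r = _as_float_array(evidence_row, "evidence_row")
    if len(w) != len(r) + 1:
        raise InputError(
            f"weights length {len(w)} does not match evidence length {len(r)} + 1"
        )
    return float(expit(w[0] + r @ w[1:]))


def _design(evidence: EvidenceMatrix | None, n_genes: int) -> np.ndarray:
    """Design matrix [1 | r] for the logistic prior; H=0 when evidence is None."""
    ones = np.ones((n_genes, 1))
    if evidence is None:
        return ones
    return np.hstack([ones, evidence.entries.astype(float)])


def _beta_density(p: np.ndarray, alpha: float) -> np.ndarray:
    """Beta(alpha, 1) density alpha * p^(alpha-1), on clamped p."""
    return alpha * np.exp((alpha - 1.0) * np.log(p))


def _loglik(p: np.ndarray, X: np.ndarray, alpha: float, w: np.ndarray) -> float:
    pi = expit(X @ w)
    f = (1.0 - pi) + pi * _beta_density(p, alpha)
    return float(np.sum(np.log(f)))


def _check_alignment(pvals: PvalueVector, evidence: EvidenceMatrix | None) -> None:
    if evidence is not None and not np.array_equal(pvals.gene_ids, evidence.gene_ids):
        raise InputError("gene_ids of p-values and evidence are not aligned")


def mixture_loglik(
    pvals: PvalueVector,
    evidence: EvidenceMatrix | None,
    params: ModelParams,
) -> float:
    """Observed-data log-likelihood (natural log) of the two-group mixture.

    ``evidence=None`` means the null parameterisation: a single prior
    ``logistic(w0)`` shared by all genes.
    """
    _check_alignment(pvals, evidence)
    n_kinds = 0 if evidence is None else evidence.n_kinds
    if params.n_kinds != n_kinds:
        raise ParameterError(
            f"params have {params.n_kinds} evidence weights, expected {n_kinds}"
        )
    p = pvals.clamped()
    X = _design(evidence, len(pvals))
    return _loglik(p, X, params.alpha, params.weights)


def e_step(
    pvals: PvalueVector,
    evidence: EvidenceMatrix | None,
    params: ModelParams,
) -> np.ndarray:
    """Posterior responsibilities gamma_g = Pr(z_g = 1 | p_g, r_g, theta)."""
    _check_alignment(pvals, evidence)
    p = pvals.clamped()
    X = _design(evidence, len(pvals))
    pi = expit(X @ params.weights)
    b = _beta_density(p, params.alpha)
    num = pi * b
    return num / ((1.0 - pi) + num)


def m_step_alpha(
    responsibilities,
    pvals: PvalueVector,
    current_alpha: float = 0.5,
) -> float:
    """Closed-form maximiser of the Beta-arm term of the EM Q function.

    Maximising sum_g gamma_g * (ln alpha + (alpha - 1) ln p_g) over alpha
    gives alpha = -sum(gamma) / sum(gamma * ln p), clamped to [EPS_ALPHA, 1].
    """
    gamma = _as_float_array(responsibilities, "responsibilities")
    p = pvals.clamped()
    total = gamma.sum()
    if total <= 0.0:
        logger.warning("m_step_alpha: zero total responsibility; alpha unchanged")
        return current_alpha
    denom = float(gamma @ np.log(p))
    if denom == 0.0:  # all weighted p-values equal 1
        return 1.0
    raw = -total / denom
    return float(np.clip(raw, EPS_ALPHA, 1.0))


def _newton_weights(
    gamma: np.ndarray,
    X: np.ndarray,
    w0: np.ndarray,
    cfg: EMConfig,
) -> tuple[np.ndarray, bool]:
    """Penalised weighted-logistic M-step by damped Newton-Raphson.

    Maximises sum_g [gamma ln pi + (1 - gamma) ln(1 - pi)] minus a tiny
    ridge penalty on w1..wM (never the intercept), which keeps the optimum
    finite under complete separation of the binary evidence.
    """
    n_coef = X.shape[1]
    pen = np.zeros(n_coef)
    pen[1:] = cfg.ridge

    def objective(w):
        eta = X @ w
        # numerically stable sum of gamma*log(pi) + (1-gamma)*log(1-pi)
        ll = float(gamma @ eta - np.sum(np.logaddexp(0.0, eta)))
        return ll - 0.5 * float(pen @ (w * w))

    w = w0.astype(float).copy()
    obj = objective(w)
    converged = False
    for _ in range(cfg.newton_max_iter):
        pi = expit(X @ w)
        grad = X.T @ (gamma - pi) - pen * w
        if np.linalg.norm(grad) < cfg.newton_tol:
            converged = True
            break
        wdiag = pi * (1.0 - pi) + 1e-12
        hess = X.T @ (X * wdiag[:, None]) + np.diag(pen)
        step = np.linalg.solve(hess, grad)
        t = 1.0
        while t > 1e-10:
            w_new = w + t * step
            obj_new = objective(w_new)
            if obj_new >= obj - 1e-12:
                break
            t *= 0.5
        w, obj = w_new, obj_new
    else:
        logger.warning("m_step_weights: Newton did not converge; best iterate kept")
    return w, converged


def m_step_weights(
    responsibilities,
    evidence: EvidenceMatrix | np.ndarray | None,
    init_weights,
    config: EMConfig = DEFAULT_CONFIG,
) -> np.ndarray:
    """Weighted logistic regression of responsibilities on evidence."""
    gamma = _as_float_array(responsibilities, "responsibilities")
    if evidence is None:
        X = _design(None, len(gamma))
    elif isinstance(evidence, EvidenceMatrix):
        X = _design(evidence, len(gamma))
    else:
        X = np.hstack([np.ones((len(gamma), 1)), np.asarray(evidence, dtype=float)])
    w0 = _as_float_array(init_weights, "init_weights")
    if len(w0) != X.shape[1]:
        raise InputError(
            f"init_weights length {len(w0)} does not match design width {X.shape[1]}"
        )
    w, _ = _newton_weights(gamma, X, w0, config)
    return w


def _polish(
    p: np.ndarray,
    X: np.ndarray,
    alpha: float,
    w: np.ndarray,
    cfg: EMConfig,
) -> tuple[float, np.ndarray]:
    """Quasi-Newton refinement of the (ridge-penalised) observed loglik.

    EM converges sublinearly along the near-degenerate alpha -> 1 ridge, so
    once its steps stall the optimum is finished off with L-BFGS-B using
    analytic gradients.  The caller only accepts the result if it improves
    the unpenalised log-likelihood, so monotonicity is preserved.
    """
    from scipy.optimize import minimize

    pen = np.zeros(len(w))
    pen[1:] = cfg.ridge
    lp = np.log(p)

    def neg(theta):
        a, wv = theta[0], theta[1:]
        pi = expit(X @ wv)
        b = a * np.exp((a - 1.0) * lp)
        f = (1.0 - pi) + pi * b
        obj = np.log(f).sum() - 0.5 * pen @ (wv * wv)
        db_da = b * (1.0 / a + lp)
        g_alpha = np.sum(pi * db_da / f)
        g_w = X.T @ ((b - 1.0) * pi * (1.0 - pi) / f) - pen * wv
        return -obj, -np.concatenate([[g_alpha], g_w])

    bounds = [(EPS_ALPHA, 1.0)] + [(None, None)] * len(w)
    res = minimize(
        neg,
        np.concatenate([[alpha], w]),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-15, "gtol": 1e-12},
    )
    return float(res.x[0]), res.x[1:]


def _em(
    p: np.ndarray,
    X: np.ndarray,
    alpha: float,
    w: np.ndarray,
    cfg: EMConfig,
) -> tuple[float, np.ndarray, float, int, bool, np.ndarray]:
    """Run EM from the given start; returns (alpha, w, loglik, iters, conv, trace).

    EM converges sublinearly on this likelihood's flat ridges, so the loop
    interleaves chunks of EM iterations with quasi-Newton polish steps
    (:func:`_polish`): whenever the relative loglik step falls below
    ``polish_trigger`` — or a chunk ends without convergence — the current
    point is refined and EM resumes.  Polish results are only adopted when
    they do not decrease the log-likelihood, so the trace stays monotone.
    """
    ll = _loglik(p, X, alpha, w)
    trace = [ll]
    converged = False
    n_iter = 0
    chunk = 100
    while n_iter < cfg.max_iter and not converged:
        for _ in range(chunk):
            if n_iter >= cfg.max_iter:
                break
            n_iter += 1
            pi = expit(X @ w)
            b = _beta_density(p, alpha)
            num = pi * b
            gamma = num / ((1.0 - pi) + num)
            alpha = _m_alpha_raw(gamma, p, alpha)
            w_new, _ = _newton_weights(gamma, X, w, cfg)
            ll_new = _loglik(p, X, alpha, w_new)
            if ll_new >= ll:
                w = w_new
            else:
                # The weight update maximises the *ridge-penalised* Q, so a
                # shrinking weight norm can dip the observed loglik by
                # O(ridge).  Keep the previous weights in that case; the
                # alpha-only update is a plain EM step and never decreases.
                ll_new = _loglik(p, X, alpha, w)
                if ll_new < ll:
                    ll_new = ll
            trace.append(ll_new)
            step = abs(ll_new - ll)
            ll = ll_new
            if step < cfg.tol * max(1.0, abs(ll_new)):
                converged = True
                break
            if step < cfg.polish_trigger * max(1.0, abs(ll_new)):
                break  # stalled: hand over to the polish below
        if converged:
            break
        a_try, w_try = _polish(p, X, alpha, w, cfg)
        ll_try = _loglik(p, X, a_try, w_try)
        if ll_try >= ll:
            alpha, w, ll = a_try, w_try, ll_try
            trace.append(ll)
    return alpha, w, ll, n_iter, converged, np.asarray(trace)


def _m_alpha_raw(gamma: np.ndarray, p: np.ndarray, current: float) -> float:
    total = gamma.sum()
    if total <= 0.0:
        return current
    denom = float(gamma @ np.log(p))
    if denom == 0.0:
        return 1.0
    return float(np.clip(-total / denom, EPS_ALPHA, 1.0))


def _validate_fit_inputs(pvals: PvalueVector) -> None:
    if len(pvals) < 2:
        raise InputError("at least two genes are required to fit the mixture")
    if np.any(np.isnan(pvals.values)):
        raise InputError("NaN p-values are not allowed")


#: Extra EM starts probing the sparse-mediator regime (small alpha, strongly
#: negative intercept): the likelihood surface is multimodal and the cold
#: start often stalls on the degenerate alpha = 1 ridge.
_SPARSE_ALPHA = 0.1
_SPARSE_W0 = -4.0


def fit_null(pvals: PvalueVector, config: EMConfig = DEFAULT_CONFIG) -> FitResult:
    """EM fit of the null model (H = 0): shared prior, no evidence weights."""
    _validate_fit_inputs(pvals)
    p = pvals.clamped()
    X = _design(None, len(pvals))
    best = None
    for alpha0, w0 in (
        (config.alpha_init, np.zeros(1)),
        (_SPARSE_ALPHA, np.array([_SPARSE_W0])),
    ):
        run = _em(p, X, alpha0, w0, config)
        if best is None or run[2] > best[2]:
            best = run
    alpha, w, ll, n_iter, conv, trace = best
    params = ModelParams(alpha, w)
    return FitResult(
        params=params,
        loglik=ll,
        responsibilities=e_step(pvals, None, params),
        hypothesis=0,
        n_iter=n_iter,
        converged=conv,
        loglik_trace=trace,
        gene_ids=pvals.gene_ids,
    )


def fit(
    pvals: PvalueVector,
    evidence: EvidenceMatrix,
    config: EMConfig = DEFAULT_CONFIG,
    null: FitResult | None = None,
) -> FitResult:
    """EM fit of the alternative model (H = 1) with all weights free.

    Several starts are used and the best optimum kept: a cold start
    (alpha = alpha_init, zero weights), a warm start at the null solution
    with w1..wM = 0, and two sparse-regime starts (small alpha, negative
    intercept, evidence weights +/-1) that reach modes the cold start
    misses.  The warm start guarantees the fitted log-likelihood is never
    below the null's, so the likelihood ratio is non-negative.
    """
    _validate_fit_inputs(pvals)
    _check_alignment(pvals, evidence)
    p = pvals.clamped()
    X = _design(evidence, len(pvals))
    n_coef = X.shape[1]

    starts = [(config.alpha_init, np.zeros(n_coef))]
    w_pos = np.full(n_coef, 1.0)
    w_pos[0] = _SPARSE_W0
    w_neg = np.full(n_coef, -1.0)
    w_neg[0] = _SPARSE_W0
    starts += [(_SPARSE_ALPHA, w_pos), (_SPARSE_ALPHA, w_neg)]
    if config.warm_start_from_null:
        if null is None:
            null = fit_null(pvals, config)
        w_warm = np.zeros(n_coef)
        w_warm[0] = null.params.weights[0]
        starts.append((null.params.alpha, w_warm))

    best = None
    for alpha0, w0 in starts:
        run = _em(p, X, alpha0, w0, config)
        if best is None or run[2] > best[2]:
            best = run
    alpha, w, ll, n_iter, conv, trace = best
    params = ModelParams(alpha, w)
    return FitResult(
        params=params,
        loglik=ll,
        responsibilities=e_step(pvals, evidence, params),
        hypothesis=1,
        n_iter=n_iter,
        converged=conv,
        loglik_trace=trace,
        gene_ids=pvals.gene_ids,
    )


def llr(alt: FitResult, null: FitResult) -> float:
    """Log2 likelihood ratio between the alternative and null fits."""
    if alt.hypothesis != 1 or null.hypothesis != 0:
        raise InputError("llr expects (alternative, null) fits in that order")
    if (
        alt.gene_ids is not None
        and null.gene_ids is not None
        and not np.array_equal(alt.gene_ids, null.gene_ids)
    ):
        raise InputError("alt and null fits cover different gene sets")
    return (alt.loglik - null.loglik) / LN2


def llr_chisq_pvalue(llr_value: float, df: int) -> float:
    """Upper-tail chi-square approximation of the nested-model test.

    The deviance is 2 * ln(2) * LLR (the LLR is reported in log2), referred
    to a chi-square with df = M, the number of evidence weights removed
    under the null.
    """
    if df < 1:
        raise InputError("df must be >= 1")
    if llr_value < 0:
        logger.warning("negative LLR %.3g treated as 0 for the chi-square test", llr_value)
        llr_value = 0.0
    return float(chi2.sf(2.0 * LN2 * llr_value, df))


def classify_fit(alt: FitResult) -> str:
    """Post-hoc label from the signs of the fitted evidence weights.

    'predicted' when every evidence weight is positive (presence of
    regulatory evidence raises the mediation prior, consistent with a
    genuine regulator); 'spurious' when every weight is negative (absence
    of evidence is the better marker, so the association is discarded);
    'mixed' otherwise.
    """
    if alt.hypothesis != 1:
        raise InputError("classification applies to alternative-hypothesis fits")
    w = alt.params.weights[1:]
    if w.size == 0:
        raise InputError("fit has no evidence weights to classify")
    if np.all(w > 0):
        return "predicted"
    if np.all(w < 0):
        return "spurious"
    return "mixed"
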