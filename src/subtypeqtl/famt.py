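"""Factor Analysis for Multiple Testing (FAMT).

Models the component of expression variation that is shared across genes and
independent of the trait as ``q`` latent Gaussian factors:

    x_gi = m_g + beta_g * y_i + b_g' f_i + e_gi,   f_i ~ N(0, I_q),
    e_gi ~ N(0, psi_g),

fitted by an ECM algorithm.  Because the factor scores are estimated from
residuals that are orthogonal to the trait, the fitted scores are exactly
uncorrelated with the trait.  "Factor-adjusted expression" is the raw matrix
minus the linear dependence kernel ``B F'``; trait-association tests
recomputed on it are the factor-adjusted tests.

The model is exposed statsmodels-style: build :class:`FactorAnalysisMT` from
data, call :meth:`~FactorAnalysisMT.fit`, and work with the returned
:class:`FAMTResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import gene_test_table

__all__ = [
    "FactorAnalysisMT",
    "FAMTResults",
    "fit_factor_model",
    "estimate_n_factors",
    "factor_adjusted_tests",
]


class ConvergenceError(RuntimeError):
    """EM failed to converge; carries the log-likelihood trace."""

    def __init__(self, message, trace):
        super().__init__(message)
        self.trace = np.asarray(trace)


def _marginal_loglik(R, B, psi):
    """Gaussian factor-model log-likelihood of residuals R (n x m).

    Uses the matrix determinant lemma and Woodbury identity so the m x m
    covariance is never formed.
    """
    n, m = R.shape
    q = B.shape[1]
    inv_psi = 1.0 / psi
    if q == 0:
        quad = float(np.sum(R ** 2 * inv_psi[None, :]))
        logdet = float(np.sum(np.log(psi)))
    else:
        Bp = B * inv_psi[:, None]  # m x q
        M = np.eye(q) + B.T @ Bp
        A = R @ Bp  # n x q
        sign, logdet_m = np.linalg.slogdet(M)
        logdet = float(np.sum(np.log(psi)) + logdet_m)
        quad = float(np.sum(R ** 2 * inv_psi[None, :]) - np.sum(A * np.linalg.solve(M, A.T).T))
    return -0.5 * (n * m * np.log(2.0 * np.pi) + n * logdet + quad)


class FactorAnalysisMT:
    """FAMT model of a genes x animals expression matrix and a trait.

    Parameters
    ----------
    expr : DataFrame, genes x animals (log scale)
    trait : Series indexed by animal
    q : int or None
        Number of latent factors.  ``None`` defers the choice to
        :meth:`select_n_factors` / the ``q`` argument of :meth:`fit`.
    """

    def __init__(self, expr: pd.DataFrame, trait: pd.Series, q: int | None = None):
        self.expr = expr
        self.trait = trait.reindex(expr.columns)
        if self.trait.isna().any():
            raise ValueError("trait missing for some animals in the expression matrix")
        self.q = q
        self._X = expr.to_numpy(dtype=float).T  # n x m
        self._y = self.trait.to_numpy(dtype=float)
        n, m = self._X.shape
        if np.isclose(self._y.std(), 0.0):
            raise ValueError("trait is constant")
        self.nobs = n
        self.n_genes = m

    # -- fitting ---------------------------------------------------------
    def fit(self, q: int | None = None, tol: float = 1e-6, max_iter: int = 500) -> "FAMTResults":
        """Fit the model by ECM.

        E step: posterior factor-score moments given (B, psi).  CM steps:
        per-gene intercept/trait coefficients given the kernel, then loadings
        and specific variances.  Converged when the relative change in the
        marginal log-likelihood of the trait residuals falls below ``tol``.
        Initialization is a deterministic principal-component start on the
        trait residuals.
        """
        q = self.q if q is None else q
        if q is None:
            raise ValueError("q not set; pass q or use select_n_factors()")
        n, m = self.nobs, self.n_genes
        if q < 0 or (q > 0 and q >= min(n - 2, m)):
            raise ValueError("q must satisfy 0 <= q < min(n_animals - 2, n_genes)")
        X, y = self._X, self._y
        D = np.column_stack([np.ones(n), y])
        DtD_inv = np.linalg.inv(D.T @ D)

        coef = DtD_inv @ (D.T @ X)  # 2 x m: intercept, beta
        R = X - D @ coef
        if q == 0:
            psi = R.var(axis=0, ddof=0)
            ll = _marginal_loglik(R, np.zeros((m, 0)), np.maximum(psi, 1e-8))
            return FAMTResults(
                model=self,
                q=0,
                loadings=np.zeros((m, 0)),
                scores=np.zeros((n, 0)),
                psi=np.maximum(psi, 1e-8),
                beta=coef[1],
                intercept=coef[0],
                trait_alignment=np.zeros(0),
                loglik_trace=np.array([ll]),
                converged=True,
                n_iter=0,
            )

        # PCA start on the trait residuals
        U, S, Vt = np.linalg.svd(R, full_matrices=False)
        B = (Vt[:q].T * (S[:q] / np.sqrt(n))[None, :])
        psi = np.maximum(R.var(axis=0, ddof=0) - (B ** 2).sum(axis=1), 1e-4)

        trace = []
        F = np.zeros((n, q))
        prev = -np.inf
        converged = False
        for it in range(max_iter):
            # E step: posterior factor moments
            inv_psi = 1.0 / psi
            Bp = B * inv_psi[:, None]
            M = np.eye(q) + B.T @ Bp
            Minv = np.linalg.inv(M)
            F = R @ Bp @ Minv  # n x q posterior means
            # CM 1: intercept and trait coefficient on the kernel-adjusted data
            coef = DtD_inv @ (D.T @ (X - F @ B.T))
            R = X - D @ coef
            # CM 2: loadings and specific variances
            G = n * Minv + F.T @ F  # q x q = sum of posterior second moments
            B = np.linalg.solve(G, F.T @ R).T  # m x q
            psi = np.maximum(
                (R ** 2).sum(axis=0) / n - np.einsum("mq,qm->m", B, (F.T @ R)) / n,
                1e-8,
            )
            ll = _marginal_loglik(R, B, psi)
            trace.append(ll)
            if np.isfinite(prev) and abs(ll - prev) <= tol * (abs(prev) + 1e-12):
                converged = True
                break
            prev = ll
        if not converged:
            raise ConvergenceError(
                f"FAMT EM did not converge in {max_iter} iterations", trace
            )
        # final posterior scores under the converged parameters
        inv_psi = 1.0 / psi
        Bp = B * inv_psi[:, None]
        M = np.eye(q) + B.T @ Bp
        F = R @ Bp @ np.linalg.inv(M)
        # The trait-orthogonal scores F miss the factors' in-sample alignment
        # with the trait: the fitted per-gene slope is beta_g + b_g' gamma
        # with gamma shared across genes, so gamma is identified by
        # cross-gene regression of the slopes on the loadings (the true
        # trait effects, being sparse and independent of the loadings, end
        # up in the residual).  The full scores carry that aligned
        # component, so subtracting the kernel also removes the factor noise
        # along the trait and the adjusted statistics are calibrated.
        beta_hat = coef[1]
        gamma, *_ = np.linalg.lstsq(B, beta_hat, rcond=None)
        yc = y - y.mean()
        scores = F + np.outer(yc, gamma)
        beta_clean = beta_hat - B @ gamma
        return FAMTResults(
            model=self,
            q=q,
            loadings=B,
            scores=scores,
            psi=psi,
            beta=beta_clean,
            intercept=coef[0],
            trait_alignment=gamma,
            loglik_trace=np.asarray(trace),
            converged=True,
            n_iter=len(trace),
        )

    # -- model selection -------------------------------------------------
    def select_n_factors(
        self,
        q_max: int = 8,
        tol: float = 1e-5,
        max_iter: int = 200,
        slack: float = 0.15,
        max_genes: int = 500,
    ):
        """Choose q by a variance-inflation criterion.

        Correlation among genes inflates the variance of multiple-testing
        error counts; the inflation is driven by the mean squared inter-gene
        correlation of the (trait-residual, factor-adjusted) data.  For each
        q in 0..q_max the criterion is

            vi(q) = (n - 2 - q) * mean off-diagonal rho^2 of the adjusted
                    trait residuals,

        which equals 1 in expectation for independent genes (sample rho^2
        has mean ~ 1/df) and exceeds 1 while common factors remain.  The
        selected q is the smallest one with ``vi(q) <= 1 + slack``; if none
        qualifies, the q minimizing |vi - 1|.  For speed the criterion uses
        at most ``max_genes`` genes (deterministic subsample).

        Returns ``(q_hat, criterion_by_q)``.
        """
        if q_max < 0:
            raise ValueError("q_max must be >= 0")
        n = self.nobs
        keep = None
        if self.n_genes > max_genes:
            keep = np.linspace(0, self.n_genes - 1, max_genes).astype(int)
        y = self._y
        yc = y - y.mean()
        crits = {}
        for q in range(q_max + 1):
            try:
                res = self.fit(q=q, tol=tol, max_iter=max_iter)
            except ConvergenceError:
                crits[q] = np.inf
                continue
            A = res.adjusted_expression.to_numpy()  # genes x animals
            if keep is not None:
                A = A[keep]
            A = A - A.mean(axis=1, keepdims=True)
            A = A - np.outer((A @ yc) / (yc @ yc), yc)  # trait residuals
            norms = np.sqrt((A ** 2).sum(axis=1))
            ok = norms > 0
            An = A[ok] / norms[ok, None]
            G = An @ An.T
            m = G.shape[0]
            mean_rho2 = (np.sum(G ** 2) - m) / (m * (m - 1))
            crits[q] = (n - 2 - q) * mean_rho2
        eligible = [q for q, v in crits.items() if v <= 1.0 + slack]
        if eligible:
            q_hat = min(eligible)
        else:
            q_hat = min(crits, key=lambda q: abs(crits[q] - 1.0))
        return q_hat, crits


@dataclass
class FAMTResults:
    """Fitted FAMT model.

    Attributes
    ----------
    loadings : ndarray (genes x q)
    scores : ndarray (animals x q)
        Posterior factor scores.  The latent factors are independent of the
        trait in the population; the scores retain the (shared, estimated)
        in-sample alignment ``trait_alignment`` so that the dependence
        kernel removes factor noise along the trait as well.  Removing that
        alignment leaves scores exactly uncorrelated with the trait.
    psi : ndarray (genes,), strictly positive specific variances
    beta : ndarray (genes,), per-gene trait coefficients (alignment-corrected)
    trait_alignment : ndarray (q,), in-sample factor-trait regression
    """

    model: FactorAnalysisMT
    q: int
    loadings: np.ndarray
    scores: np.ndarray
    psi: np.ndarray
    beta: np.ndarray
    intercept: np.ndarray
    trait_alignment: np.ndarray
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    _adjusted: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    @property
    def adjusted_expression(self) -> pd.DataFrame:
        """Raw expression minus the dependence kernel B F' (genes x animals).

        With q = 0 the kernel is empty and the input matrix is returned
        unchanged, so downstream tests reduce to the classical ones exactly.
        """
        if self.q == 0:
            return self.model.expr
        if self._adjusted is None:
            kernel = (self.scores @ self.loadings.T).T  # m x n
            self._adjusted = self.model.expr - kernel
        return self._adjusted

    def test_statistics(self, k: int = 10) -> pd.DataFrame:
        """Factor-adjusted association tests (correlation + extreme-group t).

        The correlation p-values use ``n - 2 - q`` degrees of freedom: the q
        factor directions are estimated from the same animals, and ignoring
        that loss leaves the adjusted statistics overdispersed.
        """
        return gene_test_table(
            self.adjusted_expression, self.model.trait, k=k, extra_df_loss=self.q
        )

    def significant_genes(self, alpha: float = 0.05) -> list:
        """The factor-adjusted correlation gene list at an uncorrected cutoff."""
        stats = self.test_statistics()
        return list(stats.index[(stats["p_corr"] < alpha).fillna(False)])

    def summary(self) -> str:
        n, m = self.model.nobs, self.model.n_genes
        communality = (self.loadings ** 2).sum(axis=1)
        share = communality / (communality + self.psi)
        lines = [
            "Factor Analysis for Multiple Testing",
            "=" * 44,
            f"genes: {m}    animals: {n}    factors: {self.q}",
            f"EM iterations: {self.n_iter}    log-likelihood: {self.loglik:.2f}",
            f"mean variance share of factors: {share.mean():.3f}",
            f"mean |trait coefficient|: {np.mean(np.abs(self.beta)):.4f}",
        ]
        return "\n".join(lines)


# -- functional surface ---------------------------------------------------

def fit_factor_model(expr, trait, q, tol=1e-6, max_iter=500) -> FAMTResults:
    """Fit the FAMT model (functional wrapper over :class:`FactorAnalysisMT`)."""
    return FactorAnalysisMT(expr, trait).fit(q=q, tol=tol, max_iter=max_iter)


def estimate_n_factors(expr, trait, q_max=8) -> int:
    """Select the number of hidden factors (0 is a legal answer)."""
    if q_max == 0:
        return 0
    q_hat, _ = FactorAnalysisMT(expr, trait).select_n_factors(q_max=q_max)
    return q_hat


def factor_adjusted_tests(results: FAMTResults, k: int = 10) -> pd.DataFrame:
    """Per-gene tests recomputed on factor-adjusted expression."""
    return results.test_statistics(k=k)
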