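"""Covariate-only multivariate linear null model.

Both the multivariate score test (MURAT) and the univariate SKAT comparator
are score tests: they only ever need the model fitted *without* genotypes.
For sample ``i`` with ``K`` phenotypes and ``m`` covariates the null model is

    Y_ik = alpha_0k + alpha_k' X_i + eps_ik,       Cov(eps_i) = Sigma_eps

with the same design ``[1, X]`` for every phenotype, so per-phenotype
ordinary least squares is also the generalised-least-squares fit.  The
residual covariance ``Sigma_eps`` is estimated from the residual
cross-products with denominator ``n - m - 1``.

The API follows the Model / Results pattern:

>>> model = MultivariateLinearModel(Y, X, phenotype_names=["logSBP", "logDBP"])
>>> fit = model.fit()
>>> fit.sigma_eps            # K x K residual covariance
>>> result = fit.murat_test(G, mafs)   # score test for a variant region
"""

from __future__ import annotations

import numpy as np

__all__ = ["MultivariateLinearModel", "NullModelResults", "fit_null", "projection_apply"]


class MultivariateLinearModel:
    """K correlated continuous phenotypes regressed on shared covariates.

    Parameters
    ----------
    Y : (n, K) array
        Phenotype matrix, no missing values.
    X : (n, m) array or None
        Covariate matrix (without intercept; one is always added).
    """

    def __init__(self, Y, X=None, phenotype_names=None, covariate_names=None):
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n = Y.shape[0]
        if X is None:
            X = np.empty((n, 0))
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != n:
            raise ValueError("X and Y row counts differ")
        if np.isnan(Y).any() or np.isnan(X).any():
            raise ValueError("null model requires complete data; drop incomplete samples first")
        self.Y = Y
        self.X = X
        self.nobs, self.k_phenotypes = Y.shape
        self.phenotype_names = list(phenotype_names or [f"y{k+1}" for k in range(self.k_phenotypes)])
        self.covariate_names = list(covariate_names or [f"x{j+1}" for j in range(X.shape[1])])
        if self.nobs <= X.shape[1] + 1:
            raise ValueError("need n > m + 1 samples to fit the null model")

    @classmethod
    def from_block(cls, block) -> "MultivariateLinearModel":
        """Build from a :class:`~murat.containers.PhenotypeBlock`."""
        return cls(
            block.Y,
            block.X,
            phenotype_names=block.phenotype_names,
            covariate_names=block.covariate_names,
        )

    def fit(self) -> "NullModelResults":
        n, m = self.nobs, self.X.shape[1]
        design = np.column_stack([np.ones(n), self.X])
        # QR once; reused for coefficients, residuals and later projections
        Qd, Rd = np.linalg.qr(design)
        diag = np.abs(np.diag(Rd))
        tol = diag.max() * n * np.finfo(float).eps
        if (diag < tol).any():
            bad = [
                (["intercept"] + self.covariate_names)[j]
                for j in np.where(diag < tol)[0]
            ]
            raise ValueError(f"design matrix rank deficient; collinear columns: {bad}")
        coefs = np.linalg.solve(Rd, Qd.T @ self.Y)  # (1+m) x K
        fitted = design @ coefs
        resid = self.Y - fitted
        dof = n - m - 1
        sigma = resid.T @ resid / dof
        sigma = (sigma + sigma.T) / 2
        return NullModelResults(self, design, Qd, coefs, resid, sigma, dof)


class NullModelResults:
    """Fitted null model: coefficients, residuals and residual covariance.

    Attributes
    ----------
    alpha0 : (K,) intercepts
    alpha : (m, K) covariate coefficients
    resid : (n, K) residual matrix
    sigma_eps : (K, K) residual covariance (denominator n - m - 1)
    design : (n, 1+m) design matrix actually used
    """

    #: condition-number bound beyond which sigma_eps is ridge-regularised
    _COND_MAX = 1e12

    def __init__(self, model, design, Qd, coefs, resid, sigma_eps, df_resid):
        self.model = model
        self.design = design
        self._Qd = Qd  # orthonormal basis of the design column space
        self.params = coefs
        self.alpha0 = coefs[0]
        self.alpha = coefs[1:]
        self.resid = resid
        self.sigma_eps = sigma_eps
        self.df_resid = df_resid

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def k_phenotypes(self) -> int:
        return self.model.k_phenotypes

    def sigma_eps_regularized(self) -> np.ndarray:
        """sigma_eps, ridge-stabilised if nearly singular.

        Adds ``1e-8 * mean(diag)`` to the diagonal when the condition
        number exceeds 1e12, so near-degenerate phenotype pairs fail soft.
        """
        sigma = self.sigma_eps
        if sigma.shape[0] == 1:
            if sigma[0, 0] <= 0:
                raise ValueError("zero residual variance: phenotype is constant under the null")
            return sigma
        ev = np.linalg.eigvalsh(sigma)
        if ev[0] <= 0 or ev[-1] / max(ev[0], np.finfo(float).tiny) > self._COND_MAX:
            ridge = 1e-8 * np.mean(np.diag(sigma))
            if ridge <= 0:
                raise ValueError("residual covariance is identically zero")
            sigma = sigma + ridge * np.eye(sigma.shape[0])
            ev = np.linalg.eigvalsh(sigma)
            if ev[0] <= 0 or ev[-1] / ev[0] > self._COND_MAX:
                raise ValueError("residual covariance singular even after regularization")
        return sigma

    def residualize(self, M: np.ndarray) -> np.ndarray:
        """Remove the least-squares projection of each column of M onto the design."""
        M = np.asarray(M, dtype=float)
        squeeze = M.ndim == 1
        if squeeze:
            M = M[:, None]
        if M.shape[0] != self.nobs:
            raise ValueError("row count does not match the fitted sample size")
        out = M - self._Qd @ (self._Qd.T @ M)
        return out[:, 0] if squeeze else out

    # score tests live in association.py; exposed here statsmodels-style
    def murat_test(self, G, mafs, spec=None, resamples=1000, seed=0):
        """MURAT multivariate score test of the region G; see murat.association."""
        from .association import murat_pvalue

        return murat_pvalue(self, G, mafs, spec=spec, resamples=resamples, seed=seed)

    def skat_test(self, G, mafs, phenotype=0, spec=None):
        """Univariate SKAT for one phenotype column; see murat.association."""
        from .association import skat_pvalue_from_fit

        return skat_pvalue_from_fit(self, G, mafs, phenotype=phenotype, spec=spec)

    def summary(self) -> str:
        """Plain-text summary of coefficients and residual covariance."""
        names = ["intercept"] + self.model.covariate_names
        lines = [
            "Multivariate linear null model",
            f"  n = {self.nobs}, K = {self.k_phenotypes}, "
            f"m = {len(self.model.covariate_names)}, df_resid = {self.df_resid}",
            "",
            "Coefficients (rows: design columns; columns: phenotypes)",
            "  " + "\t".join([""] + self.model.phenotype_names),
        ]
        for name, row in zip(names, self.params):
            lines.append("  " + "\t".join([name] + [f"{b: .5g}" for b in row]))
        lines.append("")
        lines.append("Residual covariance (sigma_eps)")
        for pname, row in zip(self.model.phenotype_names, self.sigma_eps):
            lines.append("  " + "\t".join([pname] + [f"{v: .5g}" for v in row]))
        return "\n".join(lines)


def fit_null(Y, X=None) -> NullModelResults:
    """Fit the covariate-only null model (functional wrapper)."""
    return MultivariateLinearModel(Y, X).fit()


def projection_apply(fit: NullModelResults, M: np.ndarray) -> np.ndarray:
    """Residualize M against the null design (functional wrapper)."""
    return fit.residualize(M)
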