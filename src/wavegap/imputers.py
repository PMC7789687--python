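"""Univariate imputation models used inside the chained-equations engine.

Two drawing models, matching the variable forms the engine supports:

* :class:`DiscriminantImputer` — for binary, ordinal and nominal
  variables.  Fits linear-discriminant class posteriors (proportional
  priors, pooled within-class covariance of the predictor scores) and
  draws each missing value from its posterior class probabilities.
  Parameter uncertainty is propagated by refitting on a bootstrap
  resample of the complete rows for every imputation ("approximate
  proper" imputation).
* :class:`BayesianLinearImputer` — for continuous variables.  Draws the
  residual variance from its scaled inverse chi-square posterior and the
  coefficients from their normal posterior, then makes a predictive draw.

Both are deliberately small, dependency-free numerical cores: the
discriminant posterior is the contribution under test, so it is written
out explicitly (reduced-rank whitening of the pooled covariance, ridge
guard against singularity) rather than delegated to a classifier library.
"""

from __future__ import annotations

import numpy as np

__all__ = ["DiscriminantImputer", "BayesianLinearImputer"]


class DiscriminantImputer:
    """Linear-discriminant posterior draws for a categorical variable.

    Parameters
    ----------
    ridge : float
        Added to the diagonal of the pooled within-class covariance to
        guard against singularity.
    rank_tol : float
        Relative eigenvalue cutoff; discriminant scores are computed on
        the reduced-rank basis spanned by eigenvalues above
        ``rank_tol * max eigenvalue`` (near-collinear predictor sets, e.g.
        a composite screen plus its own items, are handled this way).
    bootstrap : bool
        Refit on a bootstrap resample of the training rows (parameter-
        uncertainty propagation).  Disable for deterministic posterior
        checks against the closed-form Bayes rule.
    """

    def __init__(self, ridge: float = 1e-6, rank_tol: float = 1e-10, bootstrap: bool = True):
        self.ridge = ridge
        self.rank_tol = rank_tol
        self.bootstrap = bootstrap

    def fit(self, X: np.ndarray, y: np.ndarray, rng: np.random.Generator | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n, p) with one label per row")
        n = X.shape[0]
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("need at least two observed classes to fit")

        if self.bootstrap:
            if rng is None:
                raise ValueError("bootstrap resampling requires an rng")
            idx = rng.integers(0, n, size=n)
            Xb, yb = X[idx], y[idx]
            # Classes can drop out of a resample of a rare category; such a
            # class gets posterior mass 0 for this imputation.
            present = np.unique(yb)
            if present.size < 2:
                Xb, yb, present = X, y, classes
        else:
            Xb, yb, present = X, y, classes

        self.classes_ = present
        k, p = present.size, X.shape[1]
        self.priors_ = np.array([(yb == c).mean() for c in present])
        self.means_ = np.vstack([Xb[yb == c].mean(axis=0) for c in present])

        S = np.zeros((p, p))
        for i, c in enumerate(present):
            Xc = Xb[yb == c] - self.means_[i]
            S += Xc.T @ Xc
        S /= max(Xb.shape[0] - k, 1)
        S[np.diag_indices_from(S)] += self.ridge

        evals, evecs = np.linalg.eigh(S)
        keep = evals > self.rank_tol * max(evals.max(), 1.0)
        if not keep.any():
            raise np.linalg.LinAlgError("pooled covariance numerically zero")
        self.rank_ = int(keep.sum())
        # Whitening on the non-degenerate subspace: ||W^T (x - mu)||^2 is the
        # Mahalanobis distance under the (reduced-rank) pooled covariance.
        self._whiten = evecs[:, keep] / np.sqrt(evals[keep])
        return self

    def posterior(self, X: np.ndarray) -> np.ndarray:
        """Class posterior probabilities, rows summing to one."""
        X = np.asarray(X, dtype=float)
        Z = X @ self._whiten
        M = self.means_ @ self._whiten
        d2 = ((Z[:, None, :] - M[None, :, :]) ** 2).sum(axis=2)
        logp = np.log(self.priors_)[None, :] - 0.5 * d2
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)

    def draw(self, X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        p = self.posterior(X)
        u = rng.random(p.shape[0])
        idx = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
        return self.classes_[idx]


class BayesianLinearImputer:
    """Posterior-predictive draws from a normal linear model.

    Fits ordinary least squares on the complete rows (an intercept is
    appended internally), draws sigma^2 from SSR / chi2(n - rank) and the
    coefficients from N(beta_hat, sigma^2 (X'X)^-1), then returns
    X_new beta_draw + sigma N(0, 1).  A small ridge stabilizes (X'X)^-1
    for rank-deficient designs.
    """

    def __init__(self, ridge: float = 1e-8):
        self.ridge = ridge

    def fit(self, X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
        X = np.column_stack([np.ones(len(X)), np.asarray(X, dtype=float)])
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        XtX = X.T @ X
        XtX[np.diag_indices_from(XtX)] += self.ridge
        beta_hat = np.linalg.solve(XtX, X.T @ y)
        resid = y - X @ beta_hat
        rank = np.linalg.matrix_rank(X)
        df = max(n - rank, 1)
        ssr = float(resid @ resid)
        sigma2 = ssr / rng.chisquare(df)
        cov = np.linalg.inv(XtX) * sigma2
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(p))
        self.beta_ = beta_hat + L @ rng.standard_normal(p)
        self.sigma_ = np.sqrt(sigma2)
        return self

    def draw(self, X: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        X = np.column_stack([np.ones(len(X)), np.asarray(X, dtype=float)])
        return X @ self.beta_ + self.sigma_ * rng.standard_normal(X.shape[0])
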