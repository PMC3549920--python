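"""Three subject classifiers: Gaussian Naive Bayes, a linear max-margin
classifier, and a sparse Gaussian Markov-random-field classifier built on
ℓ1-penalized inverse-covariance (precision) estimation.

The sparse MRF fits, per class, the maximizer of

    log det C - trace(S C) - λ ‖C‖₁        over positive definite C,

where S is the class's empirical covariance and ‖C‖₁ is the elementwise
(vector) ℓ1 norm over *all* entries, diagonal included — the Laplace-prior
MAP estimate of the precision matrix.  The solver is block coordinate
descent on the dual covariance estimate (the COVSEL / graphical-lasso
family) with a duality-gap certificate.  Test samples are labelled by the
larger class-conditional Gaussian log-density (equal priors).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .group_stats import FeatureTable

__all__ = [
    "SparsePrecisionResult",
    "fit_sparse_precision",
    "GnbModel",
    "LinearMarginModel",
    "GmrfModel",
    "fit_classifier",
    "predict",
]

GMRF_FEATURE_CAP = 500  # covariance from ~tens of samples: keep p modest


@dataclass
class SparsePrecisionResult:
    precision: np.ndarray
    covariance: np.ndarray  # dual estimate W, with C = W^-1
    duality_gap: float
    n_iter: int
    lam: float


@njit(cache=True)
def _lasso_cd(w11: np.ndarray, s12: np.ndarray, lam: float, beta0: np.ndarray,
              tol: float, max_iter: int = 1000) -> np.ndarray:
    """Coordinate descent for min_b  0.5 b'W11 b - s12'b + lam*|b|_1."""
    beta = beta0.copy()
    p = len(s12)
    grad = w11 @ beta  # maintained incrementally
    for _ in range(max_iter):
        delta = 0.0
        for j in range(p):
            resid = grad[j] - w11[j, j] * beta[j] - s12[j]
            new = -resid
            mag = abs(new) - lam
            new = (np.sign(new) * mag / w11[j, j]) if mag > 0.0 else 0.0
            step = new - beta[j]
            if step != 0.0:
                grad += w11[:, j] * step
                beta[j] = new
            if abs(step) > delta:
                delta = abs(step)
        if delta < tol:
            break
    return beta


def fit_sparse_precision(
    s: np.ndarray,
    lam: float,
    tol: float = 1e-5,
    max_iter: int = 200,
    penalize_diagonal: bool = True,
) -> SparsePrecisionResult:
    """ℓ1-penalized maximum-likelihood precision matrix.

    Block coordinate descent on the dual variable W (the regularized
    covariance): W's diagonal is fixed at S_ii + λ (S_ii when the diagonal is
    unpenalized) and each column's off-diagonal block solves a lasso
    subproblem.  Stops when the duality gap

        trace(S C) + λ‖C‖₁ - p        (all-entry penalty)

    drops below ``tol``; raises if ``max_iter`` sweeps do not get there.
    """
    s = np.asarray(s, dtype=float)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError("S must be square")
    if not np.allclose(s, s.T, atol=1e-10):
        raise ValueError("S must be symmetric")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    p = s.shape[0]

    if lam == 0.0:
        c = np.linalg.inv(s)
        c = (c + c.T) / 2.0
        return SparsePrecisionResult(c, s.copy(), 0.0, 0, lam)

    diag_shift = lam if penalize_diagonal else 0.0
    w = s.copy()
    np.fill_diagonal(w, np.diag(s) + diag_shift)
    betas = np.zeros((p, p))  # row j: lasso coefficients for column j

    def current_gap() -> tuple[float, np.ndarray]:
        c = np.linalg.inv(w)
        c = (c + c.T) / 2.0
        if penalize_diagonal:
            l1 = np.abs(c).sum()
        else:
            l1 = np.abs(c).sum() - np.abs(np.diag(c)).sum()
        return float(np.sum(s * c) + lam * l1 - p), c

    n_iter = 0
    gap, c = current_gap()
    inner_tol = tol * 1e-2
    for sweep in range(max_iter):
        if gap <= tol:
            break
        for j in range(p):
            rest = np.arange(p) != j
            w11 = w[np.ix_(rest, rest)]
            s12 = s[rest, j]
            beta = _lasso_cd(w11, s12, lam, betas[j, rest], inner_tol)
            betas[j, rest] = beta
            w12 = w11 @ beta
            w[rest, j] = w12
            w[j, rest] = w12
        n_iter = sweep + 1
        gap, c = current_gap()
    if gap > tol:
        raise RuntimeError(
            f"sparse precision solver did not converge: duality gap {gap:.3e} "
            f"> tol {tol:.1e} after {n_iter} sweeps"
        )
    # snap near-zero entries so the recovered sparsity pattern is exact
    off_floor = tol * 1e-1
    c[np.abs(c) < off_floor] = 0.0
    return SparsePrecisionResult(c, w, gap, n_iter, lam)


# --------------------------------------------------------------------------
# classifier models

@dataclass
class GnbModel:
    clf: GaussianNB
    classes: np.ndarray


@dataclass
class LinearMarginModel:
    clf: SVC
    classes: np.ndarray

    @property
    def weights(self) -> np.ndarray:
        return self.clf.coef_.ravel()

    @property
    def bias(self) -> float:
        return float(self.clf.intercept_[0])


@dataclass
class GmrfModel:
    classes: np.ndarray
    means: dict
    precisions: dict
    covariances: dict  # empirical S per class
    lam: float
    diagnostics: dict = field(default_factory=dict)

    def log_likelihood(self, x: np.ndarray) -> np.ndarray:
        """n x 2 Gaussian log-densities (constant term dropped)."""
        x = np.atleast_2d(x)
        out = np.empty((x.shape[0], len(self.classes)))
        for k, cls in enumerate(self.classes):
            c = self.precisions[cls]
            sign, logdet = np.linalg.slogdet(c)
            if sign <= 0:
                raise np.linalg.LinAlgError("precision matrix not PD")
            d = x - self.means[cls]
            out[:, k] = 0.5 * logdet - 0.5 * np.einsum("ni,ij,nj->n", d, c, d)
        return out


def _split_xy(train):
    if isinstance(train, FeatureTable):
        return train.values, train.labels
    x, y = train
    return np.asarray(x, dtype=float), np.asarray(y)


def fit_classifier(kind: str, train, params: dict | None = None):
    """Fit one of {"gnb", "linear_margin", "gmrf"} on a training table.

    gnb: per-class feature means/variances with a 1e-9 relative variance
    floor, equal priors.  linear_margin: hinge-loss linear separator at the
    default regularization constant (C=1).  gmrf: per-class mean plus
    fit_sparse_precision on the class's empirical (1/n, class-centered)
    covariance with a shared λ (params: lam, tol, penalize_diagonal).
    """
    params = dict(params or {})
    x, y = _split_xy(train)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("training data must contain exactly two classes")

    if kind == "gnb":
        clf = GaussianNB(
            priors=[0.5, 0.5],
            var_smoothing=params.get("var_smoothing", 1e-9),
        )
        clf.fit(x, y)
        return GnbModel(clf=clf, classes=clf.classes_)
    if kind == "linear_margin":
        clf = SVC(kernel="linear", C=params.get("C", 1.0))
        clf.fit(x, y)
        return LinearMarginModel(clf=clf, classes=clf.classes_)
    if kind == "gmrf":
        if x.shape[1] > GMRF_FEATURE_CAP:
            raise ValueError(
                f"{x.shape[1]} features exceeds the MRF cap ({GMRF_FEATURE_CAP}); "
                "select features first"
            )
        lam = params.get("lam", 0.01)
        tol = params.get("tol", 1e-5)
        penalize_diagonal = params.get("penalize_diagonal", True)
        means, precisions, covariances, diags = {}, {}, {}, {}
        for cls in classes:
            xc = x[y == cls]
            mu = xc.mean(axis=0)
            centered = xc - mu
            s = centered.T @ centered / xc.shape[0]
            res = fit_sparse_precision(
                s, lam, tol=tol, penalize_diagonal=penalize_diagonal
            )
            means[cls] = mu
            precisions[cls] = res.precision
            covariances[cls] = s
            diags[cls] = {"duality_gap": res.duality_gap, "n_iter": res.n_iter}
        return GmrfModel(
            classes=classes, means=means, precisions=precisions,
            covariances=covariances, lam=lam, diagnostics=diags,
        )
    raise ValueError(f"unknown classifier kind {kind!r}")


def predict(model, x: np.ndarray) -> np.ndarray:
    """Predict class labels; ties break toward the lexicographically first
    class (argmax over classes sorted ascending returns the first maximum)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if isinstance(model, (GnbModel, LinearMarginModel)):
        expected = model.clf.n_features_in_
        if x.shape[1] != expected:
            raise ValueError(f"expected {expected} features, got {x.shape[1]}")
        return model.clf.predict(x)
    if isinstance(model, GmrfModel):
        if x.shape[1] != len(next(iter(model.means.values()))):
            raise ValueError("feature count does not match the model")
        ll = model.log_likelihood(x)  # equal priors: drop the prior term
        return model.classes[np.argmax(ll, axis=1)]
    raise TypeError(f"unknown model type {type(model)!r}")
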