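"""PCA, VAST scaling, PLS-DA and VIP scores, implemented from first principles.

The scaling is the *modified* variable-stability (VAST) form: variables
are mean-centered (not autoscaled) and then multiplied by the stability
weight ``mean / sd``, both statistics estimated on training data only
and re-applied unchanged to test data.

PLS-DA is PLS1 with NIPALS-style component extraction on the scaled
matrix X and the centered 0/1 class code y:

    w_a = X'y / ||X'y||      (unit weight vector)
    t_a = X w_a              (x-scores)
    p_a = X't_a / t_a't_a    (x-loadings)
    q_a = y't_a / t_a't_a    (y-loading)
    X <- X - t_a p_a',  y <- y - q_a t_a

The regression vector is b = W (P'W)^-1 q and predictions are
``y_hat = intercept + X_scaled b``; a sample is called tumor when
``y_hat >= threshold`` (default 0.5, ties to tumor).

Variable importance in projection:

    VIP_j = sqrt( P * sum_a SSY_a w_ja^2 / sum_a SSY_a ),
    SSY_a = q_a^2 t_a't_a

which satisfies mean_j VIP_j^2 = 1 for unit-norm weight vectors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass(frozen=True)
class ScalingParams:
    """Per-variable mean, sd and VAST weight (mean/sd), from training data."""

    mean: np.ndarray
    sd: np.ndarray
    weight: np.ndarray


@dataclass
class PCAResult:
    scores: np.ndarray  # (n, A)
    loadings: np.ndarray  # (p, A), orthonormal columns
    explained: np.ndarray  # fraction of total variance per component
    mean: np.ndarray  # column means removed before decomposition


@dataclass
class PLSModel:
    """Fitted PLS1 discriminant model (see module docstring for symbols)."""

    A: int
    W: np.ndarray  # (p, A) unit weight vectors
    P: np.ndarray  # (p, A) x-loadings
    q: np.ndarray  # (A,) y-loadings
    T: np.ndarray  # (n, A) training x-scores
    b: np.ndarray  # (p,) regression vector
    intercept: float
    threshold: float = 0.5
    scaling: ScalingParams | None = None
    x_explained: np.ndarray | None = None  # fraction of X variance per LV
    y_explained: np.ndarray | None = None  # fraction of y variance per LV
    reduced: bool = False  # True when extraction stopped before requested A

    def regression_vector(self, A: int | None = None) -> np.ndarray:
        """Regression vector using only the first ``A`` latent variables."""
        A = self.A if A is None else A
        if not 1 <= A <= self.A:
            raise ValueError(f"A must be in [1, {self.A}]")
        W, P, q = self.W[:, :A], self.P[:, :A], self.q[:A]
        return W @ np.linalg.solve(P.T @ W, q)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "A": self.A,
            "W": self.W.tolist(),
            "P": self.P.tolist(),
            "q": self.q.tolist(),
            "b": self.b.tolist(),
            "intercept": self.intercept,
            "threshold": self.threshold,
            "scaling": None
            if self.scaling is None
            else {
                "mean": self.scaling.mean.tolist(),
                "sd": self.scaling.sd.tolist(),
                "weight": self.scaling.weight.tolist(),
            },
        }
        text = json.dumps(doc)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PLSModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        scaling = None
        if doc["scaling"] is not None:
            scaling = ScalingParams(
                np.array(doc["scaling"]["mean"]),
                np.array(doc["scaling"]["sd"]),
                np.array(doc["scaling"]["weight"]),
            )
        W = np.array(doc["W"])
        return cls(
            A=doc["A"],
            W=W,
            P=np.array(doc["P"]),
            q=np.array(doc["q"]),
            T=np.zeros((0, doc["A"])),
            b=np.array(doc["b"]),
            intercept=doc["intercept"],
            threshold=doc["threshold"],
            scaling=scaling,
        )


def pca(X: np.ndarray, n_components: int) -> PCAResult:
    """Principal component analysis of the (internally centered) matrix X."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n_components > min(n, p):
        raise ValueError(f"n_components {n_components} exceeds min(n, p) = {min(n, p)}")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s**2))
    k = n_components
    return PCAResult(
        scores=U[:, :k] * s[:k],
        loadings=Vt[:k].T,
        explained=(s[:k] ** 2) / total if total > 0 else np.zeros(k),
        mean=mean,
    )


def vast_fit(X_train: np.ndarray, eps_factor: float = 1e-12) -> ScalingParams:
    """Estimate modified-VAST scaling parameters on training rows only.

    Variables whose sd falls below ``eps_factor * max(sd)`` get weight 0
    (effectively dropped) with a warning.
    """
    X_train = np.asarray(X_train, dtype=float)
    if X_train.shape[0] < 2:
        raise ValueError("need at least 2 training rows to estimate sd")
    m = X_train.mean(axis=0)
    s = X_train.std(axis=0, ddof=1)
    eps = eps_factor * (s.max() if s.size else 0.0)
    degenerate = s <= eps
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} near-constant variables get VAST weight 0",
            RuntimeWarning,
            stacklevel=2,
        )
    weight = np.where(degenerate, 0.0, m / np.where(degenerate, 1.0, s))
    return ScalingParams(mean=m, sd=s, weight=weight)


def vast_apply(X: np.ndarray, params: ScalingParams) -> np.ndarray:
    """Apply training-set scaling: ``(x - mean) * (mean / sd)`` per variable."""
    return (np.asarray(X, dtype=float) - params.mean) * params.weight


def pls_fit(X: np.ndarray, y: np.ndarray, A: int, threshold: float = 0.5,
            scaling: ScalingParams | None = None) -> PLSModel:
    """Fit a PLS1 discriminant model on a (scaled) matrix X and 0/1 labels y.

    ``X`` is used as given (apply VAST beforehand; pass the params via
    ``scaling`` so prediction can reproduce them); y is centered
    internally and its mean becomes the intercept.  If a deflation step
    leaves no usable y-covariance the extraction stops early with
    ``model.reduced = True`` and a smaller A.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("y length must match X rows")
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))) or classes.size < 2:
        raise ValueError("y must contain both classes coded 0/1")
    if A < 1:
        raise ValueError("A must be >= 1")
    intercept = float(y.mean())
    Xd = X.copy()
    yd = y - intercept
    ss_x_total = float(np.sum(Xd**2))
    ss_y_total = float(np.sum(yd**2))
    W = np.zeros((p, A))
    P = np.zeros((p, A))
    T = np.zeros((n, A))
    q = np.zeros(A)
    x_expl = np.zeros(A)
    y_expl = np.zeros(A)
    a_done = 0
    tiny = 1e-12
    for a in range(A):
        w = Xd.T @ yd
        wn = np.linalg.norm(w)
        if wn <= tiny * max(1.0, np.abs(Xd).max()):
            break
        w /= wn
        t = Xd @ w
        tt = float(t @ t)
        if tt <= tiny:
            break
        pa = Xd.T @ t / tt
        qa = float(yd @ t / tt)
        W[:, a], P[:, a], T[:, a], q[a] = w, pa, t, qa
        x_expl[a] = tt * float(pa @ pa) / ss_x_total if ss_x_total > 0 else 0.0
        y_expl[a] = qa * qa * tt / ss_y_total if ss_y_total > 0 else 0.0
        Xd -= np.outer(t, pa)
        yd = yd - qa * t
        a_done = a + 1
    if a_done == 0:
        raise ValueError("no PLS component could be extracted (X'y is zero)")
    reduced = a_done < A
    if reduced:
        warnings.warn(
            f"PLS extraction stopped at A={a_done} (requested {A})",
            RuntimeWarning,
            stacklevel=2,
        )
    W, P, T, q = W[:, :a_done], P[:, :a_done], T[:, :a_done], q[:a_done]
    b = W @ np.linalg.solve(P.T @ W, q)
    return PLSModel(
        A=a_done, W=W, P=P, q=q, T=T, b=b,
        intercept=intercept, threshold=threshold, scaling=scaling,
        x_explained=x_expl[:a_done], y_explained=y_expl[:a_done],
        reduced=reduced,
    )


def pls_predict(model: PLSModel, X_new: np.ndarray, A: int | None = None) -> np.ndarray:
    """Continuous class predictions for new samples.

    If the model carries ScalingParams they are applied here, so test
    statistics never enter the scaling; otherwise ``X_new`` must already
    be on the training scale.  ``A`` truncates the model to its first A
    latent variables.
    """
    X_new = np.asarray(X_new, dtype=float)
    p = model.W.shape[0]
    if X_new.shape[1] != p:
        raise ValueError(f"expected {p} variables, got {X_new.shape[1]}")
    Xs = vast_apply(X_new, model.scaling) if model.scaling is not None else X_new
    b = model.b if A is None else model.regression_vector(A)
    return model.intercept + Xs @ b


def classify(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Hard 0/1 labels; a score exactly at threshold is called tumor (1)."""
    return (np.asarray(scores, dtype=float) >= threshold).astype(int)


def fit_plsda(
    X: np.ndarray, y: np.ndarray, A: int, threshold: float = 0.5
) -> PLSModel:
    """VAST-scale X (fit on these rows) then fit the PLS-DA model."""
    params = vast_fit(X)
    return pls_fit(vast_apply(X, params), y, A, threshold=threshold, scaling=params)


def vip_scores(model: PLSModel) -> np.ndarray:
    """Variable importance in projection; mean squared VIP equals 1."""
    p = model.W.shape[0]
    ssy = model.q**2 * np.einsum("ij,ij->j", model.T, model.T)
    denom = float(ssy.sum())
    if denom <= 0:
        return np.ones(p)
    wnorm2 = np.sum(model.W**2, axis=0)
    wnorm2[wnorm2 == 0] = 1.0
    contrib = (model.W**2 / wnorm2) @ ssy
    return np.sqrt(p * contrib / denom)
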