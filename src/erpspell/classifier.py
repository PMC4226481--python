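"""Regularized LDA with analytic shrinkage of the covariance matrix.

With 232 features and a few thousand training epochs, the empirical
covariance is ill-conditioned; plain LDA overfits its smallest
eigenvalues.  The covariance is therefore shrunk toward a scaled
identity nu*I (nu = mean empirical variance), with the shrinkage
intensity gamma computed analytically from the data (Schaefer-Strimmer
/ Ledoit-Wolf style) rather than cross-validated:

    sigma_hat = (1 - gamma) * S + gamma * nu * I
    gamma*    = clamp( sum_ij Var(s_ij) / sum_ij (s_ij - t_ij)^2, 0, 1 )

where Var(s_ij) is the unbiased estimate of the sampling variance of
the covariance entries.  The target nu*I preserves the trace of S.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .features import DiscriminativeIntervals


@dataclass
class ShrinkageCovariance:
    sigma_hat: np.ndarray
    gamma: float
    nu: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must lie in [0, 1]")


def analytic_shrinkage_covariance(X: np.ndarray,
                                  assume_centered: bool = False,
                                  ) -> ShrinkageCovariance:
    """Analytic-shrinkage covariance estimate of row-sample data ``X``.

    ``X`` is (n, p); rows are observations.  S is the usual
    divide-by-(n-1) covariance of the (centered) data.  The sampling
    variance of each covariance entry is estimated as

        Var(s_ij) = n / (n-1)^3 * sum_k (w_kij - wbar_ij)^2,
        w_kij = x_ki * x_kj  (x centered),

    and gamma* = sum_ij Var(s_ij) / sum_ij (s_ij - t_ij)^2 with target
    T = nu*I, clamped to [0, 1].  A zero denominator (S already equals
    nu*I) yields gamma = 1.  Memory stays O(n p + p^2): the numerator
    reduces to sum_k ||x_k||^4 - n * ||Wbar||_F^2.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (observations x features)")
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 observations")
    Xc = X if assume_centered else X - X.mean(axis=0)

    wbar = (Xc.T @ Xc) / n                    # (p, p), mean of x_k x_k^T
    S = wbar * (n / (n - 1))
    nu = float(np.trace(S) / p)

    sq_norms = np.einsum("ij,ij->i", Xc, Xc)  # ||x_k||^2
    sum_sq_dev = float(np.sum(sq_norms**2) - n * np.sum(wbar**2))
    numerator = n / (n - 1) ** 3 * sum_sq_dev

    T = nu * np.eye(p)
    denominator = float(np.sum((S - T) ** 2))
    if denominator <= 0:
        gamma = 1.0
    else:
        gamma = float(np.clip(numerator / denominator, 0.0, 1.0))

    sigma_hat = (1.0 - gamma) * S + gamma * T
    return ShrinkageCovariance(sigma_hat=sigma_hat, gamma=gamma, nu=nu)


@dataclass
class RLDAModel:
    """Binary target/non-target linear discriminant.

    Scores are w.x + b with w = sigma_hat^-1 (mu_t - mu_nt) and the bias
    placed at the class-mean midpoint, so score(mu_t) = -score(mu_nt)
    and 0 is the natural decision threshold.
    """

    w: np.ndarray
    b: float
    gamma: float
    mu_target: np.ndarray
    mu_nontarget: np.ndarray
    intervals: DiscriminativeIntervals | None = None
    channels: tuple[str, ...] | None = None

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.w.size:
            raise ValueError(f"expected {self.w.size} features, "
                             f"got {X.shape[1]}")
        return X @ self.w + self.b

    def to_json(self, path: str | Path) -> None:
        payload = {
            "w": self.w.tolist(), "b": self.b, "gamma": self.gamma,
            "mu_target": self.mu_target.tolist(),
            "mu_nontarget": self.mu_nontarget.tolist(),
            "intervals": (self.intervals.to_list()
                          if self.intervals else None),
            "channels": list(self.channels) if self.channels else None,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "RLDAModel":
        d = json.loads(Path(path).read_text())
        return cls(
            w=np.array(d["w"]), b=float(d["b"]), gamma=float(d["gamma"]),
            mu_target=np.array(d["mu_target"]),
            mu_nontarget=np.array(d["mu_nontarget"]),
            intervals=(DiscriminativeIntervals.from_list(d["intervals"])
                       if d["intervals"] else None),
            channels=tuple(d["channels"]) if d["channels"] else None)


def train_rlda(X: np.ndarray, y: np.ndarray,
               intervals: DiscriminativeIntervals | None = None,
               channels: tuple[str, ...] | None = None) -> RLDAModel:
    """Fit the shrinkage-LDA on features ``X`` with binary labels ``y``.

    The covariance is pooled within-class: each class is centered by its
    own mean before the shrinkage estimate.  Positive scores indicate
    the target class.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(bool)
    if X.shape[0] != y.size:
        raise ValueError("X and y must have the same number of rows")
    if y.all() or not y.any():
        raise ValueError("both classes must be present for training")

    mu_t = X[y].mean(axis=0)
    mu_nt = X[~y].mean(axis=0)
    Xw = X.copy()
    Xw[y] -= mu_t
    Xw[~y] -= mu_nt
    cov = analytic_shrinkage_covariance(Xw, assume_centered=True)
    diff = mu_t - mu_nt
    if not diff.any():
        # identical class means: no direction to discriminate along
        return RLDAModel(w=np.zeros_like(diff), b=0.0, gamma=cov.gamma,
                         mu_target=mu_t, mu_nontarget=mu_nt,
                         intervals=intervals, channels=channels)
    try:
        w = np.linalg.solve(cov.sigma_hat, diff)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"singular shrunk covariance (gamma={cov.gamma:.3g}); "
            "more training data or regularization required") from err
    b = float(-0.5 * w @ (mu_t + mu_nt))
    return RLDAModel(w=w, b=b, gamma=cov.gamma, mu_target=mu_t,
                     mu_nontarget=mu_nt, intervals=intervals,
                     channels=channels)


def rlda_score(model: RLDAModel, X: np.ndarray) -> np.ndarray:
    """Linear score per row; higher = more target-like."""
    return model.score(X)
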