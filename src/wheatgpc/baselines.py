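"""Comparison regressions: ordinary least squares and principal-components regression.

Both are implemented from first principles (normal equations;
eigen-decomposition of the predictor correlation matrix) so that the
latent-variable model can be benchmarked against the traditional
algorithms on identical splits. Under strong predictor
multicollinearity OLS coefficients inflate and generalize poorly, and
PCR discards response-relevant directions when they carry little
predictor variance — the two failure modes PLS is designed to avoid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ModelFitError
from .pls import _as_matrix, _autoscale


@dataclass
class LinearModel:
    """An affine predictor ``yhat = intercept + X @ coefficients``.

    ``method`` is ``"ols"`` or ``"pcr"``; ``n_components`` is 0 for OLS
    and the retained component count for PCR.
    """

    predictor_names: list[str]
    coefficients: np.ndarray
    intercept: float
    method: str
    n_components: int = 0

    def predict(self, X) -> np.ndarray:
        mat, _ = _as_matrix(X, self.predictor_names)
        return self.intercept + mat @ self.coefficients

    def to_dict(self) -> dict:
        return {
            "model": self.method,
            "predictor_names": list(self.predictor_names),
            "coefficients": self.coefficients.tolist(),
            "intercept": float(self.intercept),
            "n_components": int(self.n_components),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearModel":
        return cls(
            predictor_names=list(d["predictor_names"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
            method=d["model"],
            n_components=int(d.get("n_components", 0)),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "LinearModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _rank_deficient_columns(Xc: np.ndarray, names: list[str]) -> list[str]:
    """Greedy scan naming columns that add no rank to the centered design."""
    offenders = []
    basis: list[int] = []
    rank = 0
    for j in range(Xc.shape[1]):
        trial = Xc[:, basis + [j]]
        r = np.linalg.matrix_rank(trial)
        if r > rank:
            basis.append(j)
            rank = r
        else:
            offenders.append(names[j])
    return offenders


def fit_ols(X, y, predictor_names: list[str] | None = None) -> LinearModel:
    """Multiple linear regression by the normal equations.

    Requires ``n > p`` and a full-column-rank centered design; on rank
    deficiency the offending columns are named in the error.
    """
    mat, names = _as_matrix(X, predictor_names)
    yv = np.asarray(y, dtype=float).ravel()
    n, p = mat.shape
    if yv.size != n:
        raise ModelFitError(f"X has {n} rows but y has {yv.size}")
    if n <= p:
        raise ModelFitError(f"OLS needs n > p, got n={n}, p={p}")
    Xc = mat - mat.mean(axis=0)
    if np.linalg.matrix_rank(Xc) < p:
        raise ModelFitError(
            "rank-deficient design; offending column(s): "
            f"{_rank_deficient_columns(Xc, names)}"
        )
    yc = yv - yv.mean()
    coef = np.linalg.solve(Xc.T @ Xc, Xc.T @ yc)
    intercept = yv.mean() - mat.mean(axis=0) @ coef
    return LinearModel(
        predictor_names=names,
        coefficients=coef,
        intercept=float(intercept),
        method="ols",
        n_components=0,
    )


def fit_pcr(X, y, n_components: int, predictor_names: list[str] | None = None) -> LinearModel:
    """Principal-components regression on autoscaled predictors.

    PCA is the eigen-decomposition of the predictor correlation matrix;
    the response is regressed on the leading ``n_components`` scores and
    the coefficients back-transformed to the original variable scale.
    """
    mat, names = _as_matrix(X, predictor_names)
    yv = np.asarray(y, dtype=float).ravel()
    n, p = mat.shape
    if yv.size != n:
        raise ModelFitError(f"X has {n} rows but y has {yv.size}")
    if not (1 <= n_components <= p):
        raise ModelFitError(f"n_components must be in [1, {p}], got {n_components}")
    if n <= n_components:
        raise ModelFitError(f"PCR needs n > n_components, got n={n}")
    scales_probe = mat.std(axis=0, ddof=1)
    zero_var = [names[j] for j in np.nonzero(scales_probe == 0)[0]]
    if zero_var:
        raise ModelFitError(f"zero-variance predictor column(s): {zero_var}")
    Xs, means, scales = _autoscale(mat)
    corr = Xs.T @ Xs / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    V = eigvecs[:, :n_components]
    scores = Xs @ V
    yc = yv - yv.mean()
    gamma = np.linalg.solve(scores.T @ scores, scores.T @ yc)
    coef = (V @ gamma) / scales
    intercept = yv.mean() - means @ coef
    model = LinearModel(
        predictor_names=names,
        coefficients=coef,
        intercept=float(intercept),
        method="pcr",
        n_components=int(n_components),
    )
    model.eigenvalues = eigvals  # retained for diagnostics/tests
    return model
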