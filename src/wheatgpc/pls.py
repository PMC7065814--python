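"""PLS1 regression with PRESS-based latent-component selection.

Partial least squares builds orthogonal score vectors t_a = X w_a that
maximize covariance with the response, deflating X after each
component. With a single response (PLS1) the NIPALS recursion needs no
inner iteration: per component,

    w = X'y / ||X'y||      (weights)
    t = X w                (scores)
    p = X't / t't          (X loadings)
    q = y't / t't          (y loading)
    X <- X - t p'          (deflation)
    y <- y - q t

Predictors are autoscaled (centered, unit variance) and the response
centered before the recursion; the final regression coefficients are
back-transformed to the original variable scale, so the fitted model
reads directly as

    GPC = a0 + a1 x1 + ... + ap xp    (% of dry matter).

The number of components is chosen by the minimum of the PRESS curve,
PRESS(a) = sum_i (y_i - yhat_{i,-i})^2 over leave-one-out folds, with
centering/scaling re-estimated inside every fold to avoid leakage.
Too few components underfit; too many chase noise and PRESS rises
again — the minimum marks the usable model complexity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ModelFitError

# NIPALS guards: a weight vector with norm below this carries no
# remaining X-y covariance and cannot define a component.
_W_TOL = 1e-12


@dataclass
class PLSModel:
    """A fitted PLS1 regression model.

    Coefficients and intercept are on the original variable scale;
    ``weights``, ``x_loadings`` (p x a) and ``y_loadings``, ``score_norms``
    (length a) describe the latent basis on the autoscaled data.
    """

    predictor_names: list[str]
    n_components: int
    x_means: np.ndarray
    x_scales: np.ndarray
    y_mean: float
    weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    score_norms: np.ndarray
    coefficients: np.ndarray
    intercept: float

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "model": "pls1",
            "predictor_names": list(self.predictor_names),
            "n_components": int(self.n_components),
            "x_means": self.x_means.tolist(),
            "x_scales": self.x_scales.tolist(),
            "y_mean": float(self.y_mean),
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "score_norms": self.score_norms.tolist(),
            "coefficients": self.coefficients.tolist(),
            "intercept": float(self.intercept),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModel":
        return cls(
            predictor_names=list(d["predictor_names"]),
            n_components=int(d["n_components"]),
            x_means=np.asarray(d["x_means"], dtype=float),
            x_scales=np.asarray(d["x_scales"], dtype=float),
            y_mean=float(d["y_mean"]),
            weights=np.asarray(d["weights"], dtype=float),
            x_loadings=np.asarray(d["x_loadings"], dtype=float),
            y_loadings=np.asarray(d["y_loadings"], dtype=float),
            score_norms=np.asarray(d["score_norms"], dtype=float),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            intercept=float(d["intercept"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PLSModel":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def from_coefficients(
        cls, predictor_names: list[str], coefficients, intercept: float
    ) -> "PLSModel":
        """Build a prediction-only model from published coefficients."""
        p = len(predictor_names)
        coefficients = np.asarray(coefficients, dtype=float)
        if coefficients.shape != (p,):
            raise ModelFitError(f"need {p} coefficients, got shape {coefficients.shape}")
        return cls(
            predictor_names=list(predictor_names),
            n_components=p,
            x_means=np.zeros(p),
            x_scales=np.ones(p),
            y_mean=float(intercept),
            weights=np.zeros((p, 0)),
            x_loadings=np.zeros((p, 0)),
            y_loadings=np.zeros(0),
            score_norms=np.zeros(0),
            coefficients=coefficients,
            intercept=float(intercept),
        )


@dataclass
class PRESSCurve:
    """PRESS value for each candidate component count 1..a_max (LOO, k = n)."""

    a_values: np.ndarray
    press: np.ndarray
    k: int

    @property
    def argmin_a(self) -> int:
        return int(self.a_values[int(np.argmin(self.press))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n_components": self.a_values, "press": self.press})


def _as_matrix(X, predictor_names=None) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        mat = X.to_numpy(dtype=float)
    else:
        mat = np.asarray(X, dtype=float)
        if mat.ndim == 1:
            mat = mat[:, None]
        names = list(predictor_names) if predictor_names is not None else [
            f"x{i + 1}" for i in range(mat.shape[1])
        ]
    if predictor_names is not None and list(predictor_names) != names:
        raise ModelFitError(f"predictor names {names} do not match expected {list(predictor_names)}")
    return mat, names


def _autoscale(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    means = X.mean(axis=0)
    scales = X.std(axis=0, ddof=1)
    return (X - means) / scales, means, scales


def _nipals_pls1(Xs: np.ndarray, yc: np.ndarray, a: int):
    """Run the PLS1 recursion for ``a`` components on autoscaled data.

    Returns (W, P, q, score_norms); raises when the residual X carries
    no covariance with y before ``a`` components are extracted.
    """
    n, p = Xs.shape
    X = Xs.copy()
    y = yc.copy()
    W = np.zeros((p, a))
    P = np.zeros((p, a))
    q = np.zeros(a)
    tt = np.zeros(a)
    for k in range(a):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < _W_TOL:
            raise ModelFitError(
                f"no X-y covariance left after {k} components; cannot extract component {k + 1}"
            )
        w /= nw
        t = X @ w
        t_norm2 = t @ t
        if t_norm2 < _W_TOL:
            raise ModelFitError(f"degenerate score vector at component {k + 1}")
        pvec = X.T @ t / t_norm2
        qk = y @ t / t_norm2
        X = X - np.outer(t, pvec)
        y = y - qk * t
        W[:, k], P[:, k], q[k], tt[k] = w, pvec, qk, t_norm2
    return W, P, q, tt


def _coefficients_scaled(W: np.ndarray, P: np.ndarray, q: np.ndarray) -> np.ndarray:
    # B = W (P'W)^{-1} q on the autoscaled data; P'W is upper triangular
    # with unit-ish diagonal for NIPALS, always invertible here.
    return W @ np.linalg.solve(P.T @ W, q)


def fit_pls(X, y, a: int, predictor_names: list[str] | None = None) -> PLSModel:
    """Fit a PLS1 model with ``a`` latent components.

    ``X`` may be a DataFrame (column names become predictor names) or a
    2-D array. Requires ``n >= a + 1``, positive variance in every
    column, and ``a`` no larger than the rank of the centered X.
    """
    mat, names = _as_matrix(X, predictor_names)
    yv = np.asarray(y, dtype=float).ravel()
    n, p = mat.shape
    if yv.size != n:
        raise ModelFitError(f"X has {n} rows but y has {yv.size}")
    if a < 1:
        raise ModelFitError(f"need at least 1 component, got a={a}")
    if n < a + 1:
        raise ModelFitError(f"need n >= a + 1 samples (a={a}), got n={n}")
    if not np.all(np.isfinite(mat)) or not np.all(np.isfinite(yv)):
        raise ModelFitError("X and y must be finite with no missing values")
    scales_probe = mat.std(axis=0, ddof=1)
    zero_var = [names[j] for j in np.nonzero(scales_probe == 0)[0]]
    if zero_var:
        raise ModelFitError(f"zero-variance predictor column(s): {zero_var}")
    Xs, means, scales = _autoscale(mat)
    rank = np.linalg.matrix_rank(Xs)
    if a > rank:
        raise ModelFitError(f"a={a} exceeds rank {rank} of the centered predictor matrix")
    y_mean = yv.mean()
    W, P, q, tt = _nipals_pls1(Xs, yv - y_mean, a)
    b_scaled = _coefficients_scaled(W, P, q)
    coef = b_scaled / scales
    intercept = y_mean - means @ coef
    return PLSModel(
        predictor_names=names,
        n_components=a,
        x_means=means,
        x_scales=scales,
        y_mean=float(y_mean),
        weights=W,
        x_loadings=P,
        y_loadings=q,
        score_norms=tt,
        coefficients=coef,
        intercept=float(intercept),
    )


def predict(model: PLSModel, X) -> np.ndarray:
    """Predict GPC (% dry matter) as intercept + X @ coefficients."""
    mat, _ = _as_matrix(X, model.predictor_names)
    if mat.shape[1] != len(model.predictor_names):
        raise ModelFitError(
            f"X has {mat.shape[1]} columns, model expects {len(model.predictor_names)}"
        )
    return model.intercept + mat @ model.coefficients


def transform(model: PLSModel, X) -> np.ndarray:
    """Project new samples onto the latent score space (n x a)."""
    if model.weights.shape[1] == 0:
        raise ModelFitError("model carries no latent basis (coefficient-only model)")
    mat, _ = _as_matrix(X, model.predictor_names)
    Xs = (mat - model.x_means) / model.x_scales
    R = model.weights @ np.linalg.inv(model.x_loadings.T @ model.weights)
    return Xs @ R


def predict_via_latent(model: PLSModel, X) -> np.ndarray:
    """Prediction through the latent path t = X_s R, yhat = y_mean + t q.

    Must agree with :func:`predict` to high precision; exposed so that
    the equivalence is directly testable.
    """
    T = transform(model, X)
    return model.y_mean + T @ model.y_loadings


def press_curve(X, y, a_max: int, predictor_names: list[str] | None = None) -> PRESSCurve:
    """Leave-one-out PRESS for component counts 1..a_max.

    Each fold re-estimates centering and scaling on its n-1 training
    samples; all ``a_max`` truncations are evaluated in one NIPALS pass
    per fold. Requires ``n >= a_max + 2`` and ``a_max`` within the rank
    of every fold's centered design.
    """
    mat, names = _as_matrix(X, predictor_names)
    yv = np.asarray(y, dtype=float).ravel()
    n, p = mat.shape
    if a_max < 1:
        raise ModelFitError(f"a_max must be >= 1, got {a_max}")
    if n < a_max + 2:
        raise ModelFitError(f"need n >= a_max + 2 (a_max={a_max}), got n={n}")
    press = np.zeros(a_max)
    for i in range(n):
        keep = np.arange(n) != i
        Xtr, ytr = mat[keep], yv[keep]
        Xs, means, scales = _autoscale(Xtr)
        if np.any(scales == 0):
            bad = [names[j] for j in np.nonzero(scales == 0)[0]]
            raise ModelFitError(f"zero-variance column(s) {bad} in fold {i}")
        rank = np.linalg.matrix_rank(Xs)
        if a_max > rank:
            raise ModelFitError(f"a_max={a_max} exceeds rank {rank} of fold {i}")
        y_mean = ytr.mean()
        W, P, q, _ = _nipals_pls1(Xs, ytr - y_mean, a_max)
        xs_held = (mat[i] - means) / scales
        # incremental coefficients for each truncation a
        for a in range(1, a_max + 1):
            b = _coefficients_scaled(W[:, :a], P[:, :a], q[:a])
            yhat = y_mean + xs_held @ b
            press[a - 1] += (yv[i] - yhat) ** 2
    return PRESSCurve(a_values=np.arange(1, a_max + 1), press=press, k=n)


def select_components(curve: PRESSCurve) -> int:
    """Component count at the PRESS minimum; ties break to the smallest."""
    if curve.press.size == 0:
        raise ModelFitError("empty PRESS curve")
    return curve.argmin_a


def vip_scores(model: PLSModel) -> pd.Series:
    """Variable importance in projection over the retained components.

    VIP_j = sqrt( p * sum_a SS_a w_ja^2 / sum_a SS_a ) with
    SS_a = q_a^2 * t_a't_a the response variance captured by component
    a. Squared VIPs average to 1; predictors above 1 carry more than
    their share of the model.
    """
    if model.weights.shape[1] == 0:
        raise ModelFitError("VIP requires a model fitted with a latent basis")
    W = model.weights  # columns unit-norm by construction
    ss = model.y_loadings**2 * model.score_norms
    p = W.shape[0]
    denom = ss.sum()
    if denom <= 0:
        raise ModelFitError("model explains no response variance; VIP undefined")
    vip = np.sqrt(p * (W**2 @ ss) / denom)
    return pd.Series(vip, index=model.predictor_names, name="VIP")
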