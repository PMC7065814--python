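"""Sample splitting, summary statistics, correlation screening and model scoring.

The study design this mirrors: pooled field samples are split 3:2 into
a modeling and a verification set, with the global minimum- and
maximum-GPC samples forced into the modeling set so every model is fit
over the full response range. Candidate predictors are screened by
Pearson correlation against GPC (with two-sided significance flags),
and fitted models are scored on both sets via the 1:1
predicted-vs-measured plot: RMSE, the R^2 of the fitted
predicted-vs-measured line, and a relative accuracy in percent.

Two accuracy definitions are available. ``"relative"`` (default) is
(1 - MAE / mean(y)) * 100 — a percentage score where perfect
prediction gives 100. ``"mae"`` is the mean absolute error itself, in
% GPC units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EvaluationError
from .indices import VariableTable


@dataclass(frozen=True)
class SplitAssignment:
    """Disjoint modeling/verification index sets covering all samples."""

    modeling_ids: np.ndarray
    verification_ids: np.ndarray
    ratio: float
    seed: int | None

    @property
    def n(self) -> int:
        return self.modeling_ids.size + self.verification_ids.size


def split_samples(y, ratio: float = 0.6, seed: int | None = None) -> SplitAssignment:
    """Randomly split samples with the extremes forced into the modeling set.

    ``|modeling| = round(ratio * n)`` (3:2 by default). The argmin and
    argmax of ``y`` always land in the modeling set; the remaining
    samples are assigned by a seeded permutation.
    """
    yv = np.asarray(y, dtype=float).ravel()
    n = yv.size
    if n < 5:
        raise EvaluationError(f"need at least 5 samples to split, got {n}")
    n_model = int(round(ratio * n))
    forced = np.unique([int(np.argmin(yv)), int(np.argmax(yv))])
    if n_model < forced.size:
        raise EvaluationError(f"modeling set of {n_model} cannot hold the forced extremes")
    rng = np.random.default_rng(seed)
    rest = np.setdiff1d(np.arange(n), forced)
    rest = rng.permutation(rest)
    modeling = np.sort(np.concatenate([forced, rest[: n_model - forced.size]]))
    verification = np.sort(rest[n_model - forced.size :])
    return SplitAssignment(
        modeling_ids=modeling, verification_ids=verification, ratio=ratio, seed=seed
    )


def standard_error(sd: float, n: int) -> float:
    """Standard error of the mean, SD / sqrt(n)."""
    return sd / np.sqrt(n)


def summary_stats(y) -> dict:
    """n, range, mean, SD (n-1 denominator) and SE of a GPC subset."""
    yv = np.asarray(y, dtype=float).ravel()
    if yv.size < 2:
        raise EvaluationError(f"need at least 2 samples for summary statistics, got {yv.size}")
    sd = float(np.std(yv, ddof=1))
    return {
        "n": int(yv.size),
        "min": float(yv.min()),
        "max": float(yv.max()),
        "mean": float(yv.mean()),
        "sd": sd,
        "se": float(standard_error(sd, yv.size)),
    }


def summary_table(y, split: SplitAssignment) -> pd.DataFrame:
    """Modeling/verification summary rows (values unrounded; round at render)."""
    yv = np.asarray(y, dtype=float).ravel()
    rows = {
        "modeling": summary_stats(yv[split.modeling_ids]),
        "verification": summary_stats(yv[split.verification_ids]),
    }
    return pd.DataFrame(rows).T


@dataclass
class CorrelationScreen:
    """Pearson correlations among GPC and the candidate variables."""

    r: pd.DataFrame
    p: pd.DataFrame

    @property
    def sig_05(self) -> pd.DataFrame:
        return self.p < 0.05

    @property
    def sig_01(self) -> pd.DataFrame:
        return self.p < 0.01


def correlation_matrix(table: VariableTable) -> CorrelationScreen:
    """Pearson r for every variable pair and each variable vs GPC.

    Significance p-values use the two-sided t approximation
    ``t = r sqrt((n-2)/(1-r^2))`` on n-2 degrees of freedom.
    """
    if table.y is None:
        raise EvaluationError("variable table has no GPC response attached")
    frame = table.data.copy()
    frame.insert(0, "GPC", table.y.to_numpy())
    n = len(frame)
    if n < 3:
        raise EvaluationError(f"need at least 3 samples for correlations, got {n}")
    sds = frame.std(ddof=1)
    zero_var = list(sds.index[sds == 0])
    if zero_var:
        raise EvaluationError(f"zero-variance column(s): {zero_var}")
    r = frame.corr(method="pearson")
    rv = r.to_numpy().clip(-1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rv * np.sqrt((n - 2) / (1.0 - rv**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 0.0)
    p = pd.DataFrame(p, index=r.index, columns=r.columns)
    return CorrelationScreen(r=r, p=p)


@dataclass
class FitReport:
    """Skill of one model on one sample set, via the 1:1 plot.

    ``r2`` is the R^2 of the fitted predicted-vs-measured regression
    line (squared Pearson correlation); ``r2_identity`` is
    1 - SSE/SST about the identity line. ``accuracy`` follows the
    tagged definition.
    """

    label: str
    n: int
    rmse: float
    mae: float
    r2: float
    r2_identity: float
    accuracy: float
    accuracy_definition: str
    slope: float
    intercept: float

    def to_dict(self) -> dict:
        return asdict(self)


def score(
    y_measured,
    y_predicted,
    accuracy_definition: str = "relative",
    label: str = "",
) -> FitReport:
    """Score predictions against measurements.

    RMSE = sqrt(mean((y - yhat)^2)); MAE = mean(|y - yhat|);
    accuracy per ``accuracy_definition`` ("relative" or "mae").
    """
    ym = np.asarray(y_measured, dtype=float).ravel()
    yp = np.asarray(y_predicted, dtype=float).ravel()
    if ym.size != yp.size:
        raise EvaluationError(f"length mismatch: {ym.size} measured vs {yp.size} predicted")
    if ym.size < 2:
        raise EvaluationError("need at least 2 samples to score")
    if accuracy_definition not in ("relative", "mae"):
        raise EvaluationError(f"unknown accuracy definition {accuracy_definition!r}")
    resid = ym - yp
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    sst = float(np.sum((ym - ym.mean()) ** 2))
    sse = float(np.sum(resid**2))
    r2_identity = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else 0.0)
    # fitted line of the 1:1 scatter: predicted ~ measured
    if sst > 0:
        slope = float(np.sum((ym - ym.mean()) * (yp - yp.mean())) / sst)
        intercept = float(yp.mean() - slope * ym.mean())
        sp = np.std(yp)
        r2 = float(np.corrcoef(ym, yp)[0, 1] ** 2) if sp > 0 else (1.0 if rmse == 0 else 0.0)
    else:
        slope, intercept = 0.0, float(yp.mean())
        r2 = 1.0 if rmse == 0 else 0.0
    if accuracy_definition == "relative":
        accuracy = (1.0 - mae / float(np.mean(ym))) * 100.0
    else:
        accuracy = mae
    return FitReport(
        label=label,
        n=int(ym.size),
        rmse=rmse,
        mae=mae,
        r2=r2,
        r2_identity=r2_identity,
        accuracy=float(accuracy),
        accuracy_definition=accuracy_definition,
        slope=slope,
        intercept=intercept,
    )


@dataclass
class ModelComparison:
    """Side-by-side skill table plus pairwise accuracy differences."""

    table: pd.DataFrame
    accuracy_deltas: pd.DataFrame


def compare_models(reports: dict[str, dict[str, FitReport]]) -> ModelComparison:
    """Compare >= 2 algorithms scored on identical splits.

    ``reports`` maps algorithm name -> {set label -> FitReport}. All
    algorithms must cover the same set labels with the same sample
    counts (same splits). Accuracy deltas are in percentage points,
    ``delta = accuracy(A) - accuracy(B)`` for every ordered pair on
    each set.
    """
    if len(reports) < 2:
        raise EvaluationError("need at least 2 algorithms to compare")
    algorithms = list(reports)
    labels = [list(r) for r in reports.values()]
    if any(l != labels[0] for l in labels):
        raise EvaluationError(f"mismatched set labels across algorithms: {labels}")
    set_labels = labels[0]
    for lab in set_labels:
        ns = {alg: reports[alg][lab].n for alg in algorithms}
        if len(set(ns.values())) != 1:
            raise EvaluationError(f"mismatched splits on set {lab!r}: sample counts {ns}")
    rows = []
    for alg in algorithms:
        for lab in set_labels:
            rep = reports[alg][lab]
            rows.append(
                {
                    "algorithm": alg,
                    "set": lab,
                    "n": rep.n,
                    "r2": rep.r2,
                    "rmse": rep.rmse,
                    "accuracy": rep.accuracy,
                }
            )
    table = pd.DataFrame(rows)
    deltas = []
    for a in algorithms:
        for b in algorithms:
            if a == b:
                continue
            for lab in set_labels:
                deltas.append(
                    {
                        "algorithm_a": a,
                        "algorithm_b": b,
                        "set": lab,
                        "accuracy_delta": reports[a][lab].accuracy - reports[b][lab].accuracy,
                    }
                )
    return ModelComparison(table=table, accuracy_deltas=pd.DataFrame(deltas))


def render_markdown(table: pd.DataFrame, floatfmt: int = 2) -> str:
    """Render a report table as a Markdown pipe table with fixed decimals."""
    def fmt(v) -> str:
        if isinstance(v, (float, np.floating)):
            return f"{v:.{floatfmt}f}"
        return str(v)

    cols = [str(c) for c in table.columns]
    lines = ["| " + " | ".join(cols) + " |", "| " + " | ".join("---" for _ in cols) + " |"]
    for _, row in table.iterrows():
        lines.append("| " + " | ".join(fmt(v) for v in row) + " |")
    return "\n".join(lines)
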