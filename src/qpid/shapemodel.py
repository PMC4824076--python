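"""Multiple linear regression of affinities on flank shape features.

The response is the affinity 1/Kd (or a per-oligo affinity difference);
predictors are (feature, position) shape values over the flank positions
of each half-site.  Feature importance is the standardized coefficient
magnitude |weight * sd(column) / sd(response)|, a scale-free criterion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .shape import FEATURES


def default_flank_positions(w: int, k: int, flank: int = 5) -> list[int]:
    """0-based indices (within a 2k+w block) of the ``flank`` bp
    immediately 5' and 3' of the core."""
    if flank > k:
        raise ValueError(f"flank {flank} exceeds available context k={k}")
    return list(range(k - flank, k)) + list(range(k + w, k + w + flank))


def build_design_matrix(vectors: dict, positions, w: int, k: int) -> pd.DataFrame:
    """Design matrix: rows = oligos, columns = (feature, position) pairs.

    ``vectors`` maps oligo id -> :class:`~qpid.shape.FeatureVector` (or a
    raw 4(2k+w) array); ``positions`` are 0-based indices into the 2k+w
    feature block.  Column labels read e.g. ``MGW@7``.
    """
    positions = list(positions)
    if not positions:
        raise ValueError("empty position set")
    block = 2 * k + w
    if any(p < 0 or p >= block for p in positions):
        raise ValueError(f"positions must lie in [0, {block})")
    ids = list(vectors)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate oligo ids")
    columns = [f"{feat}@{p}" for feat in FEATURES for p in positions]
    rows = []
    for oid in ids:
        vec = vectors[oid]
        values = vec.values if hasattr(vec, "values") else np.asarray(vec, dtype=float)
        if len(values) != 4 * block:
            raise ValueError(f"vector for {oid!r} has length {len(values)}, expected {4 * block}")
        if not np.all(np.isfinite(values)):
            raise ValueError(f"vector for {oid!r} contains undefined values")
        row = []
        for fi in range(4):
            base = fi * block
            row.extend(values[base + p] for p in positions)
        rows.append(row)
    return pd.DataFrame(rows, index=ids, columns=columns, dtype=float)


@dataclass
class ShapeRegressionModel:
    intercept: float
    weights: pd.Series
    r_squared: float
    standardized_weights: pd.Series
    response_label: str
    ridge_alpha: float = 0.0  # nonzero marks the rank-deficiency fallback

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.intercept + X[self.weights.index].to_numpy(float) @ self.weights.to_numpy(float)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "response": self.response_label,
                    "intercept": self.intercept,
                    "r_squared": self.r_squared,
                    "ridge_alpha": self.ridge_alpha,
                    "weights": self.weights.to_dict(),
                    "standardized_weights": self.standardized_weights.to_dict(),
                },
                indent=2,
            )
            + "\n"
        )


def fit_model(
    X: pd.DataFrame,
    response,
    response_label: str = "affinity_A",
    allow_ridge: bool = False,
    ridge_alpha: float = 1e-6,
) -> ShapeRegressionModel:
    """Ordinary least squares of the response on the design matrix.

    Requires rows >= columns + 2 for a determinate fit; with fewer rows a
    ridge fallback is used when ``allow_ridge`` is set (flagged in the
    model), otherwise an error is raised.  Training r-squared is reported.
    """
    y = np.asarray(response, dtype=float)
    if len(y) != len(X):
        raise ValueError("response length does not match design matrix")
    A = np.column_stack([np.ones(len(X)), X.to_numpy(float)])
    alpha = 0.0
    if len(X) < X.shape[1] + 2:
        if not allow_ridge:
            raise ValueError(
                f"underdetermined fit: {len(X)} rows for {X.shape[1]} columns; enable ridge fallback"
            )
        alpha = ridge_alpha
    if alpha > 0:
        reg = alpha * np.eye(A.shape[1])
        reg[0, 0] = 0.0  # never shrink the intercept
        coef = np.linalg.solve(A.T @ A + reg, A.T @ y)
    else:
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    pred = A @ coef
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot if ss_tot > 0 else 0.0
    weights = pd.Series(coef[1:], index=X.columns)
    y_sd = float(y.std(ddof=0))
    col_sd = X.std(ddof=0)
    std_w = weights * col_sd / y_sd if y_sd > 0 else weights * 0.0
    if ss_tot == 0:
        # constant response: weights may be numerically nonzero under
        # lstsq's minimum-norm solution, but carry no signal
        weights[:] = 0.0
        std_w[:] = 0.0
        coef[0] = float(y.mean())
    return ShapeRegressionModel(
        intercept=float(coef[0]),
        weights=weights,
        r_squared=r2,
        standardized_weights=std_w,
        response_label=response_label,
        ridge_alpha=alpha,
    )


def fit_difference_model(
    X: pd.DataFrame, affinity_a, affinity_b, allow_ridge: bool = False
) -> ShapeRegressionModel:
    """Model of the per-oligo affinity difference a - b on shape features."""
    a = np.asarray(affinity_a, dtype=float)
    b = np.asarray(affinity_b, dtype=float)
    if len(a) != len(b) or len(a) != len(X):
        raise ValueError("affinity vectors must match the design matrix rows")
    return fit_model(X, a - b, response_label="affinity_difference", allow_ridge=allow_ridge)


def rank_features(model: ShapeRegressionModel) -> pd.DataFrame:
    """Columns ranked by |standardized weight|, ties kept in column order.

    Returns a frame with feature, position, weight and standardized weight;
    a negative MGW weight on the top row reads as a preference for a
    narrower minor groove.
    """
    order = np.argsort(-model.standardized_weights.abs().to_numpy(), kind="stable")
    rows = []
    for i in order:
        label = model.standardized_weights.index[i]
        feat, pos = label.split("@")
        rows.append(
            {
                "feature": feat,
                "position": int(pos),
                "weight": float(model.weights.iloc[i]),
                "standardized_weight": float(model.standardized_weights.iloc[i]),
            }
        )
    return pd.DataFrame(rows)
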