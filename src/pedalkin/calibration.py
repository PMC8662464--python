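"""Frequency→load calibration and error statistics.

The inductive load sensor reports four LC-tank resonance frequencies
f = (f0, f1, f2, f3); each load channel (forward shear Fx, normal force
Fz, torque Mx) gets its own L1-regularized (LASSO) affine map F̂ = w·f + b.
Following the bench protocol, each channel is fitted on a seeded 70/30
train/test split with the regularization strength α chosen by 10-fold
cross-validation over 25 log-spaced points in [1e−10, 1e2]; ties in CV
error break toward the larger (sparser) α.  Features are standardized
before fitting and coefficients reported back in raw units (Hz⁻¹·N or
Hz⁻¹·Nm).

Error statistics use the population convention: for errors e = x − x̂,
μ = E[e], σ = population std, MAE = E|e|, RMSE = √E[e²] (so RMSE² =
μ² + σ² identically) and R² = 1 − Σe²/Σ(x − x̄)².
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold, train_test_split

from .errors import InsufficientDataError, PedalkinError, UnfittedChannelError
from .io_session import CalibrationRecord

CHANNELS = ("Fx", "Fz", "Mx")

#: the bench protocol's regularization grid
ALPHA_GRID = np.logspace(-10, 2, 25)
CV_FOLDS = 10
TEST_FRACTION = 0.3


@dataclass
class ErrorStats:
    """μ, σ, MAE, RMSE, R² of an estimate against a reference."""

    mu: float
    sigma: float
    mae: float
    rmse: float
    r2: float | None  # None when the reference has zero variance
    n: int

    def as_dict(self) -> dict:
        return {
            "mu": self.mu,
            "sigma": self.sigma,
            "mae": self.mae,
            "rmse": self.rmse,
            "r2": self.r2,
            "n": self.n,
        }


def error_stats(reference: np.ndarray, estimate: np.ndarray) -> ErrorStats:
    """Population error statistics of ``estimate`` against ``reference``."""
    x = np.asarray(reference, float)
    xhat = np.asarray(estimate, float)
    if x.shape != xhat.shape:
        raise PedalkinError("reference and estimate must have equal length")
    if x.size < 2:
        raise PedalkinError("need at least 2 samples for error statistics")
    e = x - xhat
    mu = float(np.mean(e))
    sigma = float(np.std(e))  # population
    mae = float(np.mean(np.abs(e)))
    rmse = float(np.sqrt(np.mean(e**2)))
    ss_tot = float(np.sum((x - np.mean(x)) ** 2))
    if ss_tot == 0.0:
        r2 = None
    else:
        r2 = float(1.0 - np.sum(e**2) / ss_tot)
    return ErrorStats(mu=mu, sigma=sigma, mae=mae, rmse=rmse, r2=r2, n=int(x.size))


@dataclass
class ChannelFit:
    weights: np.ndarray  # (4,) raw-unit coefficients over (f0..f3)
    intercept: float
    alpha: float


@dataclass
class CalibrationModel:
    """Three affine frequency→load maps with their fit metadata."""

    channels: dict[str, ChannelFit] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "channels": {
                name: {
                    "weights": list(map(float, fit.weights)),
                    "intercept": float(fit.intercept),
                    "alpha": float(fit.alpha),
                }
                for name, fit in self.channels.items()
            },
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationModel":
        payload = json.loads(Path(path).read_text())
        channels = {
            name: ChannelFit(
                weights=np.asarray(d["weights"], float),
                intercept=float(d["intercept"]),
                alpha=float(d["alpha"]),
            )
            for name, d in payload["channels"].items()
        }
        return cls(channels=channels, metadata=payload.get("metadata", {}))


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = [
        {"f0": r.freqs[0], "f1": r.freqs[1], "f2": r.freqs[2], "f3": r.freqs[3],
         "load": r.load, "channel": r.channel}
        for r in records
    ]
    return pd.DataFrame(rows)


def _cv_alpha(
    X: np.ndarray, y: np.ndarray, alpha_grid: np.ndarray, folds: int, seed: int
) -> float:
    """α minimizing mean K-fold CV MSE; ties break toward the larger α."""
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    best_alpha, best_mse = None, np.inf
    for alpha in np.sort(alpha_grid):  # ascending: later ties win -> larger α
        mses = []
        for tr, va in splits:
            model = Lasso(alpha=alpha, max_iter=100_000, tol=1e-10)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # tiny-α convergence chatter
                model.fit(X[tr], y[tr])
            resid = y[va] - model.predict(X[va])
            mses.append(np.mean(resid**2))
        mse = float(np.mean(mses))
        if mse <= best_mse:
            best_mse, best_alpha = mse, alpha
    return float(best_alpha)


def fit_calibration(
    records,
    folds: int = CV_FOLDS,
    test_fraction: float = TEST_FRACTION,
    alpha_grid: np.ndarray = ALPHA_GRID,
    seed: int = 0,
) -> tuple[CalibrationModel, dict[str, ErrorStats]]:
    """Fit the per-channel LASSO maps and report held-out test error.

    ``records`` is a list of :class:`CalibrationRecord` or an equivalent
    DataFrame (columns f0..f3, load, channel).  Channels are fitted
    independently; a missing channel is flagged in the metadata rather
    than failing the others.  Returns the model and per-channel test-set
    :class:`ErrorStats`.
    """
    df = _records_frame(records)
    alpha_grid = np.asarray(alpha_grid, float)
    model = CalibrationModel(
        metadata={
            "cv_folds": folds,
            "test_fraction": test_fraction,
            "alpha_grid": {
                "n": int(alpha_grid.size),
                "min": float(alpha_grid.min()),
                "max": float(alpha_grid.max()),
                "spacing": "log",
            },
            "seed": seed,
            "standardized_features": True,
            "error_convention": "population",
            "missing_channels": [],
        }
    )
    stats: dict[str, ErrorStats] = {}
    for channel in CHANNELS:
        sub = df[df["channel"] == channel]
        if len(sub) == 0:
            model.metadata["missing_channels"].append(channel)
            continue
        n_min = max(2 * folds, 20)
        if len(sub) < n_min:
            raise InsufficientDataError(
                f"channel {channel}: {len(sub)} records < required {n_min}"
            )
        X = sub[["f0", "f1", "f2", "f3"]].to_numpy(float)
        y = sub["load"].to_numpy(float)
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=test_fraction, random_state=seed, shuffle=True
        )
        mean = X_tr.mean(axis=0)
        std = X_tr.std(axis=0)
        degenerate = std == 0.0
        if degenerate.any():
            warnings.warn(
                f"channel {channel}: constant frequency column(s) "
                f"{np.flatnonzero(degenerate).tolist()} (retained)",
                stacklevel=2,
            )
            std = np.where(degenerate, 1.0, std)
        Z_tr = (X_tr - mean) / std
        alpha = _cv_alpha(Z_tr, y_tr, alpha_grid, folds, seed)
        final = Lasso(alpha=alpha, max_iter=100_000, tol=1e-10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            final.fit(Z_tr, y_tr)
        w_raw = final.coef_ / std
        b_raw = float(final.intercept_ - np.dot(final.coef_, mean / std))
        model.channels[channel] = ChannelFit(weights=w_raw, intercept=b_raw, alpha=alpha)
        y_pred = X_te @ w_raw + b_raw
        stats[channel] = error_stats(y_te, y_pred)
    return model, stats


def predict_loads(model: CalibrationModel, freqs: np.ndarray) -> np.ndarray:
    """Evaluate the three affine maps on an (n, 4) frequency series → (n, 3)."""
    freqs = np.atleast_2d(np.asarray(freqs, float))
    if freqs.shape[1] != 4:
        raise PedalkinError("freqs must be (n, 4)")
    out = np.empty((freqs.shape[0], 3))
    for j, channel in enumerate(CHANNELS):
        if channel not in model.channels:
            raise UnfittedChannelError(f"channel {channel!r} was never fitted")
        fit = model.channels[channel]
        out[:, j] = freqs @ fit.weights + fit.intercept
    return out
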