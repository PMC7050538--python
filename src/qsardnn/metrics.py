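"""Evaluation formulas: squared Pearson R², MSE, and Cheng-Prusoff IC50.

The benchmark protocol scores a model by the squared Pearson
correlation between observed activities x_i and predictions y_i on the
test set,

    R² = [Σ (x_i - x̄)(y_i - ȳ)]² / [Σ (x_i - x̄)² · Σ (y_i - ȳ)²],

and trains by minimising the mean squared error Σ (x_i - y_i)² / N.
R² is invariant under affine maps of either vector and symmetric in its
arguments; it measures linear association, not quantitative agreement.
"""

from __future__ import annotations

import logging

import numpy as np

__all__ = ["r_squared", "mse", "cheng_prusoff_ic50"]

logger = logging.getLogger(__name__)


def _as_pair(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(observed, dtype=np.float64).ravel()
    y = np.asarray(predicted, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape[0]} observed vs {y.shape[0]} predicted")
    return x, y


def r_squared(observed, predicted) -> float:
    """Squared Pearson correlation between observed and predicted values.

    Returns a float in [0, 1]. If either vector has zero variance the
    correlation is undefined; by convention this returns 0.0 with a
    logged warning, so a collapsed (constant-output) model scores worst
    instead of aborting a long training run.
    """
    x, y = _as_pair(observed, predicted)
    if x.size < 2:
        raise ValueError("r_squared needs at least 2 points")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        logger.warning(
            "zero variance in %s vector; R^2 undefined, returning 0.0",
            "observed" if sxx == 0.0 else "predicted",
        )
        return 0.0
    sxy = float(dx @ dy)
    return min(1.0, (sxy * sxy) / (sxx * syy))


def mse(observed, predicted) -> float:
    """Mean squared error Σ (x_i - y_i)² / N."""
    x, y = _as_pair(observed, predicted)
    if x.size == 0:
        raise ValueError("mse needs at least 1 point")
    d = x - y
    return float(d @ d) / x.size


def cheng_prusoff_ic50(ki: float, substrate_conc: float, km: float) -> float:
    """IC50 of a competitive inhibitor: IC50 = Ki · (1 + [S]/Km).

    Parameters are molar concentrations: ``ki`` the enzyme-inhibitor
    dissociation constant, ``substrate_conc`` the substrate
    concentration [S] (0 allowed), ``km`` the Michaelis constant of the
    substrate. Valid for single-substrate competitive inhibition; shows
    why measured IC50 values drift with assay conditions while Ki does
    not.
    """
    if km <= 0:
        raise ValueError("Km must be > 0")
    if ki <= 0:
        raise ValueError("Ki must be > 0")
    if substrate_conc < 0:
        raise ValueError("[S] must be >= 0")
    return ki * (1.0 + substrate_conc / km)
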