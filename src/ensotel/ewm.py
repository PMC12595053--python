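"""Entropy Weight Method (EWM) aggregation of teleconnection magnitudes.

Given m variables observed over n pixels, the EWM assigns each variable a
weight from the Shannon entropy of its spatial distribution and combines the
variables into a single per-pixel exposure index:

    P_ij = X_ij / sum_j X_ij                (share of variable i at pixel j)
    E_i  = -k * sum_j P_ij ln P_ij,  k = 1/ln(n),  0·ln 0 := 0
    d_i  = 1 - E_i                          (degree of diversification)
    w_i  = d_i / sum_i d_i                  (weights, sum to 1)
    exp_j = sum_i w_i * Xs_ij               (exposure, Xs min-max scaled)

Spatially concentrated variables (low entropy) receive high weight; a
spatially uniform variable carries no information and gets weight 0.  Here
X_ij is |r| of the significant index-variable correlation at pixel j (zero
where not significant), so the exposure index in [0, 1] summarizes how
strongly a pixel's climate co-varies with the ocean index during one phase.

The estimator class :class:`EntropyWeightModel` wraps the same computation in
scikit-learn fit/transform form (samples = pixels, features = variables) so
it composes with sklearn pipelines; the module-level functions are the
canonical implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from ensotel.cube import check_same_grid
from ensotel.oni import LA_NINA
from ensotel.teleconnection import CorrelationMap, significance_mask


@dataclass(frozen=True)
class EwmInputs:
    """Exposure-signal matrix plus bookkeeping to map pixels back to the grid.

    X has one row per variable and one column per retained pixel; entries are
    |r| where the variable is significant at that pixel, else 0.  The
    direction table records the per-pixel stress direction (sign of r, with
    La Niña flipped so +1 always means drought-side stress under warming).
    """

    X: np.ndarray                       # (m, n) non-negative
    variables: tuple[str, ...]
    pixel_index: np.ndarray             # (n, 2) row/col of each pixel
    grid_shape: tuple[int, int]
    directions: np.ndarray              # (m, n) in {-1, 0, +1}
    phase: str = ""

    def __post_init__(self):
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (variables x pixels)")
        if not np.all(np.isfinite(self.X)) or np.any(self.X < 0):
            raise ValueError("X must be finite and non-negative")
        if self.X.shape[0] != len(self.variables):
            raise ValueError("one row per variable required")

    @property
    def n_pixels(self) -> int:
        return self.X.shape[1]

    @property
    def empty(self) -> bool:
        return self.n_pixels == 0


@dataclass(frozen=True)
class EwmResult:
    """Weights, entropies, and the per-pixel exposure index of one EWM run."""

    variables: tuple[str, ...]
    P: np.ndarray
    entropy: np.ndarray                 # E_i in [0, 1]
    diversification: np.ndarray         # d_i = 1 - E_i
    weights: np.ndarray                 # w_i, sum 1
    exposure: np.ndarray                # per-pixel index, aligned with inputs
    exposure_grid: np.ndarray | None = None   # NaN outside the domain
    k: float = np.nan
    phase: str = ""
    status: str = "ok"
    dropped: tuple[str, ...] = field(default_factory=tuple)

    def weight_table(self) -> "Mapping[str, float]":
        return dict(zip(self.variables, self.weights))


def normalize(X: np.ndarray) -> np.ndarray:
    """Share matrix P_ij = X_ij / sum_j X_ij, one row per variable.

    An all-zero row has no defined shares; callers should drop such
    variables first (see :func:`ewm_weights`), so here it raises.
    """
    X = np.asarray(X, dtype=float)
    sums = X.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        bad = np.flatnonzero(sums.ravel() <= 0).tolist()
        raise ValueError(f"variable row(s) {bad} sum to zero; drop them first")
    return X / sums


def entropy(P: np.ndarray, n: int | None = None) -> np.ndarray:
    """Normalized Shannon entropy E_i = -k sum_j P_ij ln P_ij, k = 1/ln(n).

    Zero shares contribute zero.  n defaults to the number of pixels
    (columns); n >= 2 is required for k to exist.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    if n is None:
        n = P.shape[1]
    if n < 2:
        raise ValueError("entropy scaling needs at least 2 pixels (n >= 2)")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * np.log(P), 0.0)
    return -terms.sum(axis=1) / np.log(n)


def weights_from_entropy(E: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Diversification d_i = 1 - E_i and weights w_i = d_i / sum d_i."""
    E = np.asarray(E, dtype=float)
    if np.any(E < -1e-12) or np.any(E > 1 + 1e-12):
        raise ValueError("entropies must lie in [0, 1]")
    d = 1.0 - E
    total = d.sum()
    if total <= 0:
        raise ValueError(
            "all entropies equal 1 (perfectly uniform variables): the EWM "
            "carries no information; supply variables with spatial contrast"
        )
    return d, d / total


def minmax_scale_rows(X: np.ndarray) -> np.ndarray:
    """Min-max scale each variable row to [0, 1]; constant rows map to 0."""
    X = np.asarray(X, dtype=float)
    lo = X.min(axis=1, keepdims=True)
    hi = X.max(axis=1, keepdims=True)
    span = hi - lo
    span = np.where(span > 0, span, 1.0)
    return (X - lo) / span


def exposure_index(w: np.ndarray, X_scaled: np.ndarray) -> np.ndarray:
    """Per-pixel exposure exp_j = sum_i w_i * X_scaled_ij, in [0, 1]."""
    w = np.asarray(w, dtype=float)
    X_scaled = np.asarray(X_scaled, dtype=float)
    if X_scaled.shape[0] != len(w):
        raise ValueError("weight vector and X rows disagree")
    if np.any(X_scaled < -1e-12) or np.any(X_scaled > 1 + 1e-12):
        raise ValueError("X_scaled rows must lie in [0, 1]")
    return w @ X_scaled


def build_inputs(
    corr_maps: Sequence[CorrelationMap],
    mask: np.ndarray | None = None,
    retention: str = "union",
) -> EwmInputs:
    """Assemble the EWM signal matrix from one phase's correlation maps.

    A masked pixel enters the domain if at least one variable is significant
    there (``retention="union"``, the default) or only if all are
    (``"intersection"``).  X_ij = |r_ij| where variable i is significant at
    pixel j, else 0.  The stress direction is sign(r) under El Niño and
    -sign(r) under La Niña, carried separately for map colouring.
    """
    if not corr_maps:
        raise ValueError("need at least one correlation map")
    phases = {m.phase for m in corr_maps}
    if len(phases) != 1:
        raise ValueError(f"maps mix phases {sorted(phases)}")
    lags = {m.lag for m in corr_maps}
    if len(lags) != 1:
        raise ValueError(f"maps mix lags {sorted(lags)}")
    phase = corr_maps[0].phase
    shape = check_same_grid(*[m.r for m in corr_maps])
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError("mask shape mismatch")

    sig = np.stack([significance_mask(m, m.alpha) for m in corr_maps])
    if retention == "union":
        domain = mask & sig.any(axis=0)
    elif retention == "intersection":
        domain = mask & sig.all(axis=0)
    else:
        raise ValueError("retention must be 'union' or 'intersection'")

    rows, cols = np.nonzero(domain)
    X = np.zeros((len(corr_maps), len(rows)))
    directions = np.zeros_like(X, dtype=int)
    flip = -1 if phase == LA_NINA else 1
    for i, m in enumerate(corr_maps):
        r_vals = m.r[rows, cols]
        s_vals = sig[i][rows, cols]
        X[i] = np.where(s_vals, np.abs(np.nan_to_num(r_vals)), 0.0)
        directions[i] = np.where(s_vals, flip * np.sign(np.nan_to_num(r_vals)), 0)

    return EwmInputs(
        X=X,
        variables=tuple(m.variable for m in corr_maps),
        pixel_index=np.column_stack([rows, cols]),
        grid_shape=shape,
        directions=directions,
        phase=phase,
    )


def ewm_weights(
    X: np.ndarray, variables: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Run normalize -> entropy -> weights, dropping all-zero variable rows.

    Returns (P, E, d, w, dropped) where dropped rows get weight 0 and
    entropy/diversification NaN in the full-length outputs.
    """
    X = np.asarray(X, dtype=float)
    m, n = X.shape
    keep = X.sum(axis=1) > 0
    dropped = [v for v, k in zip(variables, keep) if not k]
    if dropped:
        warnings.warn(
            f"variable(s) with no significant signal dropped from EWM: {dropped}",
            stacklevel=2,
        )
    if not keep.any():
        raise ValueError("no variable carries any exposure signal")
    P = np.full((m, n), np.nan)
    P[keep] = normalize(X[keep])
    E = np.full(m, np.nan)
    E[keep] = entropy(P[keep], n)
    d = np.full(m, np.nan)
    w = np.zeros(m)
    d_kept, w_kept = weights_from_entropy(E[keep])
    d[keep] = d_kept
    w[keep] = w_kept
    return P, E, d, w, dropped


def ewm_pipeline(
    corr_maps: Sequence[CorrelationMap],
    mask: np.ndarray | None = None,
    phase: str | None = None,
    retention: str = "union",
) -> EwmResult:
    """Full EWM run for one phase: inputs -> weights -> exposure grid.

    The exposure index uses |r| min-max scaled to [0, 1] per variable over
    the domain, so exp_j itself lies in [0, 1]; the stress-direction signs
    are carried in the inputs, not multiplied into the magnitude.
    """
    if phase is not None:
        bad = [m.variable for m in corr_maps if m.phase != phase]
        if bad:
            raise ValueError(f"maps not in phase {phase!r}: {bad}")
    inputs = build_inputs(corr_maps, mask=mask, retention=retention)
    if inputs.empty:
        return EwmResult(
            variables=inputs.variables,
            P=np.zeros((len(inputs.variables), 0)),
            entropy=np.full(len(inputs.variables), np.nan),
            diversification=np.full(len(inputs.variables), np.nan),
            weights=np.zeros(len(inputs.variables)),
            exposure=np.zeros(0),
            exposure_grid=np.full(inputs.grid_shape, np.nan),
            phase=inputs.phase,
            status="empty-domain",
        )
    n = inputs.n_pixels
    if n < 2:
        raise ValueError("EWM needs at least 2 retained pixels (k = 1/ln n)")
    P, E, d, w, dropped = ewm_weights(inputs.X, inputs.variables)
    Xs = minmax_scale_rows(inputs.X)
    exp_j = exposure_index(w, Xs)
    grid = np.full(inputs.grid_shape, np.nan)
    grid[inputs.pixel_index[:, 0], inputs.pixel_index[:, 1]] = exp_j
    return EwmResult(
        variables=inputs.variables,
        P=P, entropy=E, diversification=d, weights=w,
        exposure=exp_j, exposure_grid=grid,
        k=1.0 / np.log(n), phase=inputs.phase,
        status="ok", dropped=tuple(dropped),
    )


class EntropyWeightModel(BaseEstimator, TransformerMixin):
    """Entropy-weighted exposure index as a scikit-learn transformer.

    Follows the sklearn convention: X has shape (n_pixels, m_variables)
    (samples are pixels).  ``fit`` learns the entropy weights from the
    spatial distribution of each variable; ``transform`` returns the
    per-pixel exposure index as an (n, 1) column.

    Parameters
    ----------
    scale : {"minmax", "none"}
        How to scale variables before the weighted sum.  "minmax" (default)
        rescales each variable to [0, 1] over the fitted domain so the
        exposure index itself lies in [0, 1].

    Attributes
    ----------
    weights_ : (m,) EWM weights, sum to 1 (dropped variables get 0).
    entropy_ : (m,) normalized Shannon entropies in [0, 1].
    diversification_ : (m,) d_i = 1 - E_i.
    k_ : the 1/ln(n) scaling constant of the fit.
    n_features_in_ : number of variables seen at fit.
    """

    def __init__(self, scale: str = "minmax"):
        self.scale = scale

    def _validate(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_pixels, m_variables)")
        if not np.all(np.isfinite(X)) or np.any(X < 0):
            raise ValueError("X must be finite and non-negative")
        return X

    def fit(self, X, y=None):
        X = self._validate(X)
        n, m = X.shape
        if n < 2:
            raise ValueError("EWM needs at least 2 pixels")
        if self.scale not in ("minmax", "none"):
            raise ValueError("scale must be 'minmax' or 'none'")
        P, E, d, w, dropped = ewm_weights(X.T, [f"x{i}" for i in range(m)])
        self.n_features_in_ = m
        self.entropy_ = E
        self.diversification_ = d
        self.weights_ = w
        self.k_ = 1.0 / np.log(n)
        self.scale_min_ = X.min(axis=0)
        self.scale_max_ = X.max(axis=0)
        self.dropped_ = tuple(dropped)
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "weights_")
        X = self._validate(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count changed between fit and transform")
        if self.scale == "minmax":
            span = np.where(self.scale_max_ > self.scale_min_,
                            self.scale_max_ - self.scale_min_, 1.0)
            Xs = np.clip((X - self.scale_min_) / span, 0.0, 1.0)
        else:
            Xs = X
        return (Xs @ self.weights_)[:, None]
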