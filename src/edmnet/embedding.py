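"""State-space reconstruction primitives: delay embedding, k-NN regression,
simplex-style forecasting, and embedding-dimension selection.

All downstream causality and interaction-strength estimators share these
primitives.  Delay vectors are built within site segments only (a vector never
spans the concatenation boundary between two sites) and rows touching a
missing value are dropped, not interpolated.

Conditional predictive densities are Gaussian with mean equal to the
leave-one-out nearest-neighbour regression prediction and variance equal to
that model's leave-one-out residual variance; the log-likelihood-ratio of two
such models, averaged over the reconstructed points, is the transfer-entropy
estimate used throughout (see :mod:`edmnet.uic`).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .quantify import StandardizedPanel

__all__ = [
    "EmbeddingSpec",
    "StateSpace",
    "delay_block",
    "time_delay_embed",
    "loo_knn_predict",
    "loo_knn_weights",
    "knn_regress",
    "gaussian_lr",
    "bootstrap_p",
    "residualize",
    "select_embedding_dimension",
]

VAR_FLOOR = 1e-12


@dataclass(frozen=True)
class EmbeddingSpec:
    """Embedding dimension E, lag unit tau, prediction step tp, conditioning set.

    Negative ``tp`` probes lagged causal influence; in pipeline use the scan
    covers tp = 0..-6 (three months at half-monthly sampling).
    """

    E: int
    tau: int = 1
    tp: int = 1
    conditionals: tuple[str, ...] = ()
    E_R: int | None = None

    def __post_init__(self):
        if self.E < 1 or self.tau < 1:
            raise ValueError("E and tau must be >= 1")
        if self.E_R is not None and not (1 <= self.E_R < self.E):
            raise ValueError("E_R must satisfy 1 <= E_R < E")


@dataclass
class StateSpace:
    """Valid (delay vector, target) pairs with their provenance.

    ``rows`` maps each point back to the merged-panel row of its time ``t``;
    ``site`` carries the site label.  ``coords`` records the (variable, lag)
    made into each column.
    """

    points: np.ndarray
    targets: np.ndarray
    rows: np.ndarray
    site: np.ndarray
    coords: tuple
    target: tuple

    def __len__(self) -> int:
        return len(self.targets)


def _shift(arr: np.ndarray, s: int) -> np.ndarray:
    """Value at index t+s, NaN-padded at the ends."""
    out = np.full(arr.shape, np.nan)
    if s == 0:
        return arr.astype(float).copy()
    if s > 0:
        out[:-s] = arr[s:]
    else:
        out[-s:] = arr[:s]
    return out


def delay_block(
    panel: StandardizedPanel,
    coords: list[tuple[str, int]],
    target: tuple[str, int],
) -> StateSpace:
    """Assemble all valid (delay vector, target) pairs over every site segment.

    ``coords`` are (variable, lag>=0) pairs read at t-lag; the target is read
    at t+tp.  A row is valid when every index stays inside the site segment of
    t and no value is missing.
    """
    seg = panel.segment_id.astype(float)
    cols, segcols = [], []
    for var, lag in coords:
        if lag < 0:
            raise ValueError("coordinate lags must be >= 0")
        cols.append(_shift(panel.values(var), -lag))
        segcols.append(_shift(seg, -lag))
    tvar, tp = target
    tcol = _shift(panel.values(tvar), tp)
    segcols.append(_shift(seg, tp))

    pts = np.column_stack(cols) if cols else np.empty((len(seg), 0))
    segmat = np.column_stack(segcols)
    valid = np.all(segmat == seg[:, None], axis=1) & np.isfinite(tcol)
    if cols:
        valid &= np.all(np.isfinite(pts), axis=1)
    if not valid.any():
        max_lag = max((lag for _, lag in coords), default=0)
        raise ValueError(
            f"no valid embedded points: coords need {max_lag} past steps and the target "
            f"{tp} forward steps, but segment lengths are "
            f"{[b - a for a, b in panel.segments]}"
        )
    idx = np.flatnonzero(valid)
    return StateSpace(
        points=pts[idx],
        targets=tcol[idx],
        rows=idx,
        site=panel.site[idx],
        coords=tuple(coords),
        target=target,
    )


def time_delay_embed(
    panel: StandardizedPanel,
    spec: EmbeddingSpec,
    embed_var: str,
    target_var: str | None = None,
) -> StateSpace:
    """Delay-embed ``embed_var`` (E lags spaced tau, plus conditionals at lag 0)
    against ``target_var`` read at t+tp."""
    target_var = target_var or embed_var
    coords = [(embed_var, k * spec.tau) for k in range(spec.E)]
    coords += [(z, 0) for z in spec.conditionals]
    return delay_block(panel, coords, (target_var, spec.tp))


def _neighbor_weights(d: np.ndarray, mean_dist: float) -> np.ndarray:
    """Exponential simplex weights w_i = exp(-d_i/d_1) with the zero-distance
    tie rule: if the nearest distance is 0, zero-distance neighbours get weight
    1 and the rest decay on an epsilon floor scale."""
    d1 = d[:, [0]]
    w = np.empty_like(d)
    pos = (d1 > 0).ravel()
    if pos.any():
        w[pos] = np.exp(-d[pos] / d1[pos])
    if (~pos).any():
        eps = VAR_FLOOR * max(mean_dist, 1.0)
        with np.errstate(under="ignore"):
            wz = np.where(d[~pos] == 0, 1.0, np.exp(-d[~pos] / eps))
        w[~pos] = wz
    return w


def loo_knn_weights(
    points: np.ndarray,
    k: int,
    *,
    theiler: int = 0,
    rows: np.ndarray | None = None,
    site: np.ndarray | None = None,
    weighting: str = "exp",
) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out neighbour indices and weights for every point.

    Ties at identical distance resolve to the earlier library row (stable
    argsort), making results platform-deterministic.  ``theiler`` excludes
    temporal neighbours within the given radius at the same site.  The
    prediction for any target vector y is ``(w * y[order]).sum(1) / w.sum(1)``.
    """
    n = len(points)
    if n < 2:
        raise ValueError("library too small for leave-one-out prediction")
    k = max(1, min(k, n - 1))
    D = cdist(points, points)
    np.fill_diagonal(D, np.inf)
    if theiler > 0 and rows is not None:
        close = np.abs(rows[:, None] - rows[None, :]) <= theiler
        if site is not None:
            close &= site[:, None] == site[None, :]
        D[close] = np.inf
        np.fill_diagonal(D, np.inf)
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    d = np.take_along_axis(D, order, axis=1)
    if not np.all(np.isfinite(d[:, 0])):
        raise ValueError("exclusion removed all neighbours for some points")
    if weighting == "uniform":
        w = np.ones_like(d)
    else:
        finite = D[np.isfinite(D)]
        w = _neighbor_weights(d, float(finite.mean()) if finite.size else 1.0)
    return order, w


def loo_knn_predict(
    points: np.ndarray,
    targets: np.ndarray,
    k: int,
    *,
    theiler: int = 0,
    rows: np.ndarray | None = None,
    site: np.ndarray | None = None,
    weighting: str = "exp",
) -> np.ndarray:
    """Leave-one-out nearest-neighbour prediction of every point's target."""
    order, w = loo_knn_weights(
        points, k, theiler=theiler, rows=rows, site=site, weighting=weighting
    )
    return (w * targets[order]).sum(axis=1) / w.sum(axis=1)


def knn_regress(
    space: StateSpace,
    query: np.ndarray,
    k: int,
    *,
    exclude: np.ndarray | list | tuple = (),
    weighting: str = "exp",
) -> tuple[float, np.ndarray, np.ndarray]:
    """Predict the target at an arbitrary query point from the library.

    ``exclude`` lists library indices removed from the search (e.g. the
    query's own point and temporal neighbours).  Returns (prediction,
    neighbour indices, weights).
    """
    lib = space.points
    d = cdist(query.reshape(1, -1), lib).ravel()
    if len(exclude):
        d[np.asarray(exclude, dtype=int)] = np.inf
    usable = np.isfinite(d).sum()
    if usable == 0:
        raise ValueError("empty library after exclusion")
    k = max(1, min(k, usable))
    order = np.argsort(d, kind="stable")[:k]
    dk = d[order]
    if weighting == "uniform":
        w = np.ones_like(dk)
    else:
        w = _neighbor_weights(dk.reshape(1, -1), float(np.mean(d[np.isfinite(d)]))).ravel()
    pred = float((w * space.targets[order]).sum() / w.sum())
    return pred, order, w


def _loo_mean(targets: np.ndarray) -> np.ndarray:
    s = targets.sum()
    return (s - targets) / (len(targets) - 1)


def gaussian_lr(
    points_full: np.ndarray,
    points_red: np.ndarray,
    targets: np.ndarray,
    *,
    k_full: int | None = None,
    k_red: int | None = None,
    theiler: int = 0,
    rows: np.ndarray | None = None,
    site: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Gaussian log-likelihood ratio of a full vs a reduced cross-map model.

    Each model's conditional density of the target is Gaussian with mean the
    LOO k-NN prediction and variance the LOO residual variance; with no
    reduced coordinates the reduced model is the marginal (LOO mean/variance).
    Returns (mean log-ratio, per-point contributions).
    """
    t = np.asarray(targets, dtype=float)
    n = len(t)
    kf = k_full if k_full is not None else points_full.shape[1] + 1
    pf = loo_knn_predict(points_full, t, kf, theiler=theiler, rows=rows, site=site)
    if points_red.shape[1] > 0:
        kr = k_red if k_red is not None else points_red.shape[1] + 1
        pr = loo_knn_predict(points_red, t, kr, theiler=theiler, rows=rows, site=site)
    else:
        pr = _loo_mean(t)
    ef, er = t - pf, t - pr
    tvar = max(float(t.var()), 1.0)
    vf = max(float(np.mean(ef**2)), VAR_FLOOR * tvar)
    vr = max(float(np.mean(er**2)), VAR_FLOOR * tvar)
    contrib = 0.5 * np.log(vr / vf) + er**2 / (2 * vr) - ef**2 / (2 * vf)
    return float(contrib.mean()), contrib


def bootstrap_p(
    contrib: np.ndarray, n_boot: int, rng: np.random.Generator
) -> float:
    """One-sided bootstrap p-value for H1: TE > 0.

    Embedded (state, target) pairs are resampled with replacement; with the
    fitted conditional densities held fixed this reduces to resampling the
    per-point log-ratio contributions.  p = fraction of resamples whose mean
    is <= 0.
    """
    n = len(contrib)
    idx = rng.integers(0, n, size=(n_boot, n))
    te_star = contrib[idx].mean(axis=1)
    return float(np.mean(te_star <= 0.0))


def residualize(
    panel: StandardizedPanel,
    variables: tuple[str, ...],
    conditionals: tuple[str, ...],
    lags: tuple[int, ...] = (0, 1, 2),
) -> StandardizedPanel:
    """Partial the conditioning variables out of the named series.

    Each variable is replaced by its residual from a leave-one-out k-NN
    regression on the conditioning variables at the given lags (k of the
    order of sqrt(T), so the fit is a smooth of the shared-driver response
    rather than an interpolation).  Residuals are re-standardized; rows where
    the conditioning lags are unavailable become missing.  Conditioning a
    causality test this way removes what the drivers explain of *both*
    series, which is what makes a shared environmental forcing stop looking
    like interspecific information flow.
    """
    data = panel.data.copy()
    raw = panel.raw.copy()
    means, sds = dict(panel.scale.loc["mean"]), dict(panel.scale.loc["sd"])
    for v in variables:
        coords = [(z, lag) for z in conditionals for lag in lags]
        block = delay_block(panel, coords, (v, 0))
        k = max(block.points.shape[1] + 1, int(np.sqrt(len(block))))
        pred = loo_knn_predict(block.points, block.targets, k)
        resid = np.full(len(panel.data), np.nan)
        resid[block.rows] = block.targets - pred
        mu, sd = np.nanmean(resid), np.nanstd(resid)
        if not sd > 0:
            raise ValueError(f"residual of {v!r} has zero variance")
        raw[v] = resid
        data[v] = (resid - mu) / sd
        means[v], sds[v] = float(mu), float(sd)
    return StandardizedPanel(
        data=data,
        raw=raw,
        site=panel.site,
        time_index=panel.time_index,
        segments=list(panel.segments),
        species=list(panel.species),
        env=list(panel.env),
        scale=pd.DataFrame([means, sds], index=["mean", "sd"]),
    )


def select_embedding_dimension(
    panel: StandardizedPanel,
    effect: str,
    cause: str | None = None,
    conditionals: tuple[str, ...] = (),
    E_max: int = 6,
    tau: int = 1,
    *,
    tp: int = 1,
    alpha: float = 0.05,
    n_boot: int = 200,
    rng: np.random.Generator | None = None,
    min_points: int = 20,
) -> tuple[int, list[tuple[int, float, float]]]:
    """Choose the embedding dimension of the effect series by predictive gain.

    For E = 2..E_max the E-lag model (optionally augmented with the cause at
    lag 0 and conditionals, present in both models) is compared against the
    best accepted lower-dimensional model via one-step-ahead (tp=1) Gaussian
    likelihood-ratio TE; E grows while the gain is statistically clear
    (bootstrap, one-sided) and the scan stops at the first unclear step.
    Returns (selected E, [(E, te, p), ...]).
    """
    if E_max < 1:
        raise ValueError("E_max must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(0)
    extras = ([(cause, 0)] if cause is not None else []) + [(z, 0) for z in conditionals]
    best = 1
    history: list[tuple[int, float, float]] = []
    for E in range(2, E_max + 1):
        coords = [(effect, k * tau) for k in range(E)] + extras
        try:
            block = delay_block(panel, coords, (effect, tp))
        except ValueError:
            break
        if len(block) < min_points:
            break
        n_extra = len(extras)
        red_cols = list(range(best)) + list(range(E, E + n_extra))
        # same k for both models: with per-model k = dim+1 the larger model
        # smooths over more neighbours, which masquerades as predictive gain
        k = block.points.shape[1] + 1
        te, contrib = gaussian_lr(
            block.points, block.points[:, red_cols], block.targets,
            k_full=k, k_red=k,
        )
        p = bootstrap_p(contrib, n_boot, rng)
        history.append((E, te, p))
        if p < alpha:
            best = E
        else:
            break
    return best, history
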