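"""Multiview-distance regularized S-map: time-varying interaction strengths.

For each target species a causally informed state space is assembled from its
own delay coordinates, its detected causes (at their retained lags), and its
environmental conditioning variables.  At every target time point a locally
weighted ridge regression

    x_hat_{1,t*+1} = IS_0 + sum_j IS_j * x_{j,t*}

is solved with weights exp(-theta * d(t_i, t*) / dbar(t*)); the coefficient
``IS_j`` is read as the interaction strength exerted by coordinate j at time
t*.  Because Euclidean distance degrades in higher-dimensional coordinate
sets, neighbourhoods are defined by the multiview distance: an ensemble
average of per-view Euclidean distances over low-dimensional coordinate
subsets ranked by one-step forecast skill.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .embedding import delay_block, loo_knn_predict, select_embedding_dimension
from .quantify import StandardizedPanel
from .uic import InteractionSet

logger = logging.getLogger(__name__)

__all__ = [
    "MultiviewConfig",
    "SmapFit",
    "multiview_distance",
    "mdr_smap_fit",
    "interaction_strengths",
    "edge_summary",
    "DEFAULT_LAMBDA_GRID",
]

DEFAULT_LAMBDA_GRID = (0.0, 1e-3, 1e-2, 1e-1, 1.0)


@dataclass(frozen=True)
class MultiviewConfig:
    """Ensemble settings for the multiview distance.

    ``view_dim`` defaults to ceil(sqrt(#candidate coordinates)); all views are
    enumerated when their number does not exceed ``n_views_evaluated``,
    otherwise that many are sampled without replacement.  The top
    ceil(sqrt(#views evaluated)) views by one-step forecast correlation are
    kept (overridable via ``n_views_kept``).
    """

    view_dim: int | None = None
    n_views_evaluated: int = 2000
    n_views_kept: int | None = None


@dataclass
class SmapFit:
    """Local linear coefficients per target time point.

    ``coef`` has one row per state-space point: column 0 is the intercept
    IS_0, the rest align with the coordinate columns.  Rows are NaN where the
    weighted design was singular even at the largest ridge penalty.
    """

    coef: np.ndarray
    lam: float
    theta: float
    skill: float
    predictions: np.ndarray
    n_skipped: int = 0


def _candidate_views(
    n_coords: int,
    view_dim: int,
    target_mask: np.ndarray,
    n_eval: int,
    rng: np.random.Generator,
) -> list[tuple[int, ...]]:
    total = math.comb(n_coords, view_dim)
    if total <= max(n_eval, 200_000):
        views = [
            v for v in itertools.combinations(range(n_coords), view_dim)
            if target_mask[list(v)].any()
        ]
        if len(views) > n_eval:
            keep = rng.choice(len(views), size=n_eval, replace=False)
            views = [views[i] for i in sorted(keep)]
        return views
    # combinatorially large: rejection-sample distinct views
    seen: set[tuple[int, ...]] = set()
    views = []
    attempts = 0
    while len(views) < n_eval and attempts < 50 * n_eval:
        v = tuple(sorted(rng.choice(n_coords, size=view_dim, replace=False)))
        attempts += 1
        if v in seen or not target_mask[list(v)].any():
            continue
        seen.add(v)
        views.append(v)
    return views


def multiview_distance(
    coords: np.ndarray,
    target: np.ndarray,
    target_mask: np.ndarray | None = None,
    config: MultiviewConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, dict]:
    """Ensemble distance matrix over skill-ranked low-dimensional views.

    Each view's pairwise Euclidean distances are normalized by their own mean
    (off-diagonal) before averaging, so views over different coordinate
    subsets contribute comparably.  Views must contain at least one of the
    target's own lag coordinates (``target_mask``; all coordinates qualify if
    omitted).  Returns (distance matrix, report).
    """
    coords = np.asarray(coords, dtype=float)
    T, C = coords.shape
    if C < 1:
        raise ValueError("need at least one candidate coordinate")
    config = config or MultiviewConfig()
    rng = rng if rng is not None else np.random.default_rng(0)
    if target_mask is None:
        target_mask = np.ones(C, dtype=bool)
    target_mask = np.asarray(target_mask, dtype=bool)
    m = config.view_dim if config.view_dim is not None else math.ceil(math.sqrt(C))
    m = max(1, min(m, C))
    views = _candidate_views(C, m, target_mask, config.n_views_evaluated, rng)
    if not views:
        raise ValueError("no admissible views (none contains a target lag)")

    skills = np.full(len(views), -np.inf)
    for i, v in enumerate(views):
        pred = loo_knn_predict(coords[:, list(v)], target, k=len(v) + 1)
        if np.std(pred) > 0 and np.std(target) > 0:
            r = float(np.corrcoef(pred, target)[0, 1])
            if np.isfinite(r):
                skills[i] = r
    if not np.isfinite(skills).any():
        raise ValueError("no view achieved finite forecast skill")

    n_kept = config.n_views_kept or math.ceil(math.sqrt(len(views)))
    n_kept = min(n_kept, int(np.isfinite(skills).sum()))
    order = sorted(range(len(views)), key=lambda i: (-skills[i], views[i]))[:n_kept]

    offdiag = ~np.eye(T, dtype=bool)
    D = np.zeros((T, T))
    for i in order:
        Dv = cdist(coords[:, list(views[i])], coords[:, list(views[i])])
        mv = Dv[offdiag].mean()
        if mv > 0:
            Dv = Dv / mv
        D += Dv
    D /= len(order)
    report = {
        "views": views,
        "skills": skills,
        "kept": [views[i] for i in order],
        "view_dim": m,
    }
    return D, report


def _weighted_ridge(Xa, y, w, lam, penalty):
    G = (Xa * w[:, None]).T @ Xa + lam * penalty
    b = (Xa * w[:, None]).T @ y
    try:
        return np.linalg.solve(G, b)
    except np.linalg.LinAlgError:
        return None


def mdr_smap_fit(
    coords: np.ndarray,
    y: np.ndarray,
    distances: np.ndarray,
    theta: float | tuple[float, ...] = 1.0,
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
    *,
    rng: np.random.Generator | None = None,
) -> SmapFit:
    """Locally weighted ridge S-map over every target point.

    The penalty applies to the coordinate coefficients only (never the
    intercept), and each point's own pair is excluded from its local fit, so
    the reported predictions are leave-one-out.  One (theta, lambda) pair is
    chosen for the whole series by leave-one-out forecast error — ``theta``
    may be a scalar or a grid such as (0, 0.5, 1, 2, 4); ties resolve to the
    smaller penalty / bandwidth.  Points whose weighted design is singular
    even at the largest penalty are skipped with a warning count.
    """
    coords = np.asarray(coords, dtype=float)
    y = np.asarray(y, dtype=float)
    T, C = coords.shape
    if distances.shape != (T, T):
        raise ValueError("distance matrix must be (T, T)")
    if T < C + 2:
        raise ValueError("too few points for the local regression")
    Xa = np.column_stack([np.ones(T), coords])
    penalty = np.eye(C + 1)
    penalty[0, 0] = 0.0
    theta_grid = (theta,) if np.isscalar(theta) else tuple(theta)

    offdiag = ~np.eye(T, dtype=bool)
    dmean = distances[offdiag].reshape(T, T - 1).mean(axis=1)
    dbar = np.where(dmean > 0, dmean, 1.0)

    def _weights(th):
        with np.errstate(under="ignore"):
            W = np.exp(-th * distances / dbar[:, None])
        np.fill_diagonal(W, 0.0)
        return W

    def _pass(W, lam, want_coef):
        preds = np.full(T, np.nan)
        coefs = np.full((T, C + 1), np.nan) if want_coef else None
        skipped = 0
        for t in range(T):
            b = _weighted_ridge(Xa, y, W[t], lam, penalty)
            if b is None and lam < max(lambda_grid):
                b = _weighted_ridge(Xa, y, W[t], max(lambda_grid), penalty)
            if b is None or not np.all(np.isfinite(b)):
                skipped += 1
                continue
            preds[t] = Xa[t] @ b
            if want_coef:
                coefs[t] = b
        return preds, coefs, skipped

    best, best_mse = None, np.inf
    for th in theta_grid:
        W = _weights(th)
        for lam in lambda_grid:
            preds, _, _ = _pass(W, lam, want_coef=False)
            ok = np.isfinite(preds)
            if not ok.any():
                continue
            mse = float(np.mean((preds[ok] - y[ok]) ** 2))
            if mse < best_mse - 1e-15:
                best, best_mse = (th, lam), mse
    if best is None:
        raise ValueError("singular weighted design at every penalty in the grid")
    best_theta, best_lam = best

    preds, coefs, skipped = _pass(_weights(best_theta), best_lam, want_coef=True)
    if skipped:
        logger.warning("mdr_smap_fit: %d target point(s) skipped (singular design)", skipped)
    ok = np.isfinite(preds)
    if ok.sum() > 2 and np.std(preds[ok]) > 0 and np.std(y[ok]) > 0:
        skill = float(np.corrcoef(preds[ok], y[ok])[0, 1])
    else:
        skill = np.nan
    return SmapFit(coef=coefs, lam=float(best_lam), theta=float(best_theta),
                   skill=skill, predictions=preds, n_skipped=skipped)


def _cause_lag(tp: int) -> int:
    """Coordinate lag (>=0, relative to t*) of a cause retained at UIC lag tp.

    An edge at tp means cause_(t+tp) influences effect_t; predicting
    effect_(t*+1) the cause is read at t* + min(tp+1, 0), i.e. lag
    -(min(tp+1, 0)).  tp = -1 maps to the contemporaneous coordinate, tp = 0
    is clamped so no future value enters the state vector.
    """
    return -min(tp + 1, 0)


def interaction_strengths(
    panel: StandardizedPanel,
    interactions: InteractionSet,
    config: MultiviewConfig | None = None,
    seed: int | None = None,
    *,
    targets: list[str] | None = None,
    E_max: int = 6,
    tau: int = 1,
    theta: float | tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 4.0),
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID,
    min_points: int = 20,
) -> tuple[pd.DataFrame, dict]:
    """S-map coefficients for every detected edge, at every valid time point.

    Per target species the coordinate set is its own optimal-E delay
    coordinates, its statistically clear causes at their retained lags, and
    its clear environmental conditionals; neighbourhoods use the multiview
    distance and fits are ridge-penalized.  Returns a long frame of IS records
    (kind: intercept / self / cause / conditional) mapped back to (site, time,
    raw temperature), plus a per-target report (E, lambda, skill, counts).
    """
    if not interactions.results:
        raise ValueError("InteractionSet is empty")
    ss = np.random.SeedSequence(seed)
    clear = interactions.clear_edges()
    if targets is None:
        targets = sorted({r.effect for r in clear}) or sorted({r.effect for r in interactions.results})
    rngs = {t: np.random.default_rng(ch) for t, ch in zip(targets, ss.spawn(len(targets)))}

    has_temp = "temperature" in panel.raw.columns
    frames, report = [], {}
    for tgt in targets:
        rng = rngs[tgt]
        conds = tuple(interactions.conditionals.get(tgt, ()))
        E, _ = select_embedding_dimension(
            panel, tgt, cause=None, conditionals=conds, E_max=E_max, tau=tau,
            rng=rng, min_points=min_points,
        )
        causes = [r for r in clear if r.effect == tgt and r.cause in panel.species]
        coords = [(tgt, k * tau) for k in range(E)]
        labels = [("self", tgt, k * tau) for k in range(E)]
        for r in causes:
            lag = _cause_lag(r.tp)
            coords.append((r.cause, lag))
            labels.append(("cause", r.cause, lag))
        for z in conds:
            coords.append((z, 0))
            labels.append(("conditional", z, 0))

        block = delay_block(panel, coords, (tgt, 1))
        if len(block) < min_points:
            raise ValueError(f"only {len(block)} embedded points for target {tgt!r}")
        target_mask = np.array([k == "self" for k, _, _ in labels])
        D, _rep = multiview_distance(block.points, block.targets, target_mask,
                                     config=config, rng=rng)
        fit = mdr_smap_fit(block.points, block.targets, D, theta=theta,
                           lambda_grid=lambda_grid, rng=rng)

        # record-count bound: per site, points <= segment length - E + 1
        seg_counts = pd.Series(block.site).value_counts()
        for (a, b), site_name in zip(panel.segments, sorted(set(panel.site))):
            n_here = int(seg_counts.get(site_name, 0))
            assert n_here <= (b - a) - E + 1, "record count exceeds T - E + 1"

        temp = (
            panel.raw["temperature"].to_numpy(dtype=float)[block.rows]
            if has_temp else np.full(len(block), np.nan)
        )
        base = pd.DataFrame(
            {
                "target": tgt,
                "site": block.site,
                "time_index": panel.time_index[block.rows],
                "temperature": temp,
            }
        )
        recs = [base.assign(cause="(intercept)", kind="intercept", lag=0,
                            value=fit.coef[:, 0])]
        for j, (kind, name, lag) in enumerate(labels):
            recs.append(base.assign(cause=name, kind=kind, lag=lag,
                                    value=fit.coef[:, j + 1]))
        frames.append(pd.concat(recs, ignore_index=True))
        report[tgt] = {
            "E": E,
            "lambda": fit.lam,
            "skill": fit.skill,
            "n_points": len(block),
            "n_causes": len(causes),
            "n_skipped": fit.n_skipped,
        }

    out = pd.concat(frames, ignore_index=True).dropna(subset=["value"])
    return out.reset_index(drop=True), report


def edge_summary(is_frame: pd.DataFrame) -> pd.DataFrame:
    """Median and IQR of IS per directed cross-species edge."""
    cross = is_frame[is_frame["kind"] == "cause"]
    g = cross.groupby(["cause", "target"])["value"]
    return pd.DataFrame(
        {
            "median_is": g.median(),
            "iqr_is": g.quantile(0.75) - g.quantile(0.25),
            "n": g.size(),
        }
    ).reset_index()
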