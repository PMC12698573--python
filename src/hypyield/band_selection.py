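"""Characteristic-band selection for collinear reflectance spectra.

Six selectors share one cross-validated fitness oracle (PLS CV-RMSE on the
candidate columns): particle swarm optimisation (PSO) with continuous
positions decoded to their top-k bands; its attention-augmented variant
(PSAMA) whose social attractor is a scaled-dot-product attention consensus
over the swarm's personal bests; the successive projections algorithm
(SPA); PCA-loading ranking; LASSO with a penalty bisected to a target
support size; and competitive adaptive reweighted sampling (CARS) with an
exponentially decreasing retention schedule.

All selectors are deterministic under their seed and return a
:class:`BandSubset` recording the chosen channels, their wavelengths, the
achieved fitness and the configuration.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.linear_model import Lasso
from sklearn.model_selection import KFold

from hypyield.errors import ConfigurationError, DataError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Fitness oracle


def cv_fitness(
    X: np.ndarray,
    y: np.ndarray,
    channel_subset,
    folds: int = 5,
    seed: int = 0,
    max_components: int = 10,
) -> float:
    """Mean k-fold CV RMSE of a PLS regression restricted to the subset columns.

    The component count is ``min(max_components, |subset|, fold-train rank)``,
    reduced with a logged warning when the subset outruns the sample count.
    """
    subset = np.asarray(list(channel_subset), dtype=int)
    if subset.size == 0:
        raise ConfigurationError("channel subset must be non-empty")
    if folds < 2:
        raise ConfigurationError("need at least 2 CV folds")
    X = np.atleast_2d(np.asarray(X, dtype=float))[:, subset]
    y = np.asarray(y, dtype=float).ravel()
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    min_train = min(len(tr) for tr, _ in cv.split(X))
    n_comp = min(max_components, subset.size, min_train - 1)
    if n_comp < min(max_components, subset.size):
        log.warning("cv_fitness: components reduced to %d (rank limit)", n_comp)
    n_comp = max(1, n_comp)
    errors = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tr, te in cv.split(X):
            pls = PLSRegression(n_components=n_comp, scale=False)
            pls.fit(X[tr], y[tr])
            pred = pls.predict(X[te]).ravel()
            errors.append(np.sqrt(np.mean((y[te] - pred) ** 2)))
    return float(np.mean(errors))


# ---------------------------------------------------------------------------
# Swarm machinery


@dataclass
class SwarmConfig:
    """Swarm hyperparameters: inertia w, cognitive c1 and social c2 factors."""

    n_particles: int = 30
    w: float = 0.7
    c1: float = 1.5
    c2: float = 1.5
    max_iter: int = 100
    k_bands: int = 10
    seed: int = 0

    def validate(self, n_bands: int | None = None) -> None:
        if self.w < 0 or self.c1 < 0 or self.c2 < 0:
            raise ConfigurationError("w, c1, c2 must be >= 0")
        if self.n_particles < 1 or self.max_iter < 1:
            raise ConfigurationError("n_particles and max_iter must be >= 1")
        if n_bands is not None and not 1 <= self.k_bands <= n_bands:
            raise ConfigurationError("k_bands must be within [1, band count]")


def pso_update(
    x: np.ndarray,
    v: np.ndarray,
    pbest: np.ndarray,
    gbest: np.ndarray,
    config: SwarmConfig,
    r1,
    r2,
    bounds: tuple[float, float] = (0.0, 1.0),
) -> tuple[np.ndarray, np.ndarray]:
    """One velocity/position update of a particle.

    ``v' = w v + c1 r1 (pbest - x) + c2 r2 (gbest - x)``, ``x' = x + v'``,
    with the position clipped to ``bounds`` per dimension.  ``r1``/``r2``
    may be scalars or arrays matching ``x``.
    """
    x = np.asarray(x, dtype=float)
    v = np.asarray(v, dtype=float)
    v_new = (
        config.w * v
        + config.c1 * np.asarray(r1) * (np.asarray(pbest) - x)
        + config.c2 * np.asarray(r2) * (np.asarray(gbest) - x)
    )
    x_new = np.clip(x + v_new, bounds[0], bounds[1])
    return x_new, v_new


def attention_pool(query: np.ndarray, keys: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Scaled-dot-product attention: softmax(q.k_i/sqrt(d)) weighted value sum."""
    query = np.asarray(query, dtype=float)
    keys = np.atleast_2d(np.asarray(keys, dtype=float))
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if keys.shape[0] < 1:
        raise ConfigurationError("attention needs at least one key-value pair")
    sims = keys @ query / np.sqrt(query.size)
    sims = sims - sims.max()  # numerically stable softmax
    w = np.exp(sims)
    w = w / w.sum()
    return w @ values


def attention_weights(query: np.ndarray, keys: np.ndarray) -> np.ndarray:
    """The softmax similarity weights used by :func:`attention_pool`."""
    query = np.asarray(query, dtype=float)
    keys = np.atleast_2d(np.asarray(keys, dtype=float))
    sims = keys @ query / np.sqrt(query.size)
    sims = sims - sims.max()
    w = np.exp(sims)
    return w / w.sum()


class ParticleSwarm:
    """Generic continuous PSO minimiser with an optional attention attractor.

    With ``attention=False`` the social term pulls toward the global best;
    with ``attention=True`` it pulls toward the attention-weighted consensus
    of all personal bests (query = global best, keys = values = personal
    bests).  A single-particle swarm is identical in both modes.
    """

    def __init__(self, config: SwarmConfig, attention: bool = False):
        self.config = config
        self.attention = attention

    def minimize(
        self,
        objective,
        dim: int,
        bounds: tuple[float, float] = (0.0, 1.0),
        init_positions: np.ndarray | None = None,
    ) -> tuple[np.ndarray, float, list[float]]:
        """Returns (best position, best fitness, per-iteration best trace)."""
        cfg = self.config
        cfg.validate()
        rng = np.random.default_rng(cfg.seed)
        lo, hi = bounds
        n = cfg.n_particles
        x = rng.uniform(lo, hi, (n, dim))
        if init_positions is not None:
            init_positions = np.atleast_2d(init_positions)
            x[: init_positions.shape[0]] = np.clip(init_positions, lo, hi)
        v = rng.uniform(-1.0, 1.0, (n, dim)) * 0.1 * (hi - lo)
        fitness = np.array([objective(xi) for xi in x], dtype=float)
        pbest = x.copy()
        pbest_f = fitness.copy()
        g = int(np.argmin(pbest_f))
        gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])
        trace = [gbest_f]
        for _ in range(cfg.max_iter):
            attractor = (
                attention_pool(gbest, pbest, pbest) if self.attention else gbest
            )
            r1 = rng.random((n, dim))
            r2 = rng.random((n, dim))
            v = (
                cfg.w * v
                + cfg.c1 * r1 * (pbest - x)
                + cfg.c2 * r2 * (attractor - x)
            )
            x = np.clip(x + v, lo, hi)
            fitness = np.array([objective(xi) for xi in x], dtype=float)
            improved = fitness < pbest_f
            pbest[improved] = x[improved]
            pbest_f[improved] = fitness[improved]
            g = int(np.argmin(pbest_f))
            if pbest_f[g] < gbest_f:
                gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])
            trace.append(gbest_f)
        return gbest, gbest_f, trace


# ---------------------------------------------------------------------------
# Band subsets


@dataclass
class BandSubset:
    """Channels chosen by a named selector, with fitness and configuration."""

    method: str
    channel_indices: list[int]
    wavelengths_nm: list[float]
    fitness: float
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.channel_indices)) != len(self.channel_indices):
            raise ConfigurationError("channel indices must be unique")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "BandSubset":
        return cls(**json.loads(Path(path).read_text()))


def _decode_topk(position: np.ndarray, k: int) -> tuple[int, ...]:
    """Indices of the k largest position weights, reported in channel order."""
    order = np.argsort(-position, kind="stable")[:k]
    return tuple(sorted(int(i) for i in order))


def _correlation_warm_start(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Particle position seeded from the |correlation with y| ranking."""
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = Xc.std(axis=0)
    sy = yc.std()
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs((Xc * yc[:, None]).mean(axis=0) / (sx * sy))
    corr = np.nan_to_num(corr)
    if corr.max() > corr.min():
        return (corr - corr.min()) / (corr.max() - corr.min())
    return np.full(X.shape[1], 0.5)


def _swarm_select(
    X: np.ndarray,
    y: np.ndarray,
    config: SwarmConfig,
    attention: bool,
    method: str,
    folds: int,
    warm_start: bool,
) -> BandSubset:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n_bands = X.shape[1]
    config.validate(n_bands)
    cache: dict[tuple[int, ...], float] = {}

    def objective(position: np.ndarray) -> float:
        subset = _decode_topk(position, config.k_bands)
        if subset not in cache:
            cache[subset] = cv_fitness(X, y, subset, folds=folds, seed=config.seed)
        return cache[subset]

    init = _correlation_warm_start(X, y)[None, :] if warm_start else None
    swarm = ParticleSwarm(config, attention=attention)
    gbest, gbest_f, _ = swarm.minimize(objective, n_bands, (0.0, 1.0), init)
    indices = list(_decode_topk(gbest, config.k_bands))
    return BandSubset(
        method=method,
        channel_indices=indices,
        wavelengths_nm=[],  # filled by callers that know the grid
        fitness=gbest_f,
        config={**asdict(config), "folds": folds, "warm_start": warm_start},
    )


def pso_select(
    X: np.ndarray,
    y: np.ndarray,
    config: SwarmConfig | None = None,
    folds: int = 5,
    warm_start: bool = True,
) -> BandSubset:
    """PSO band selection: continuous positions decoded to their top-k bands.

    One particle is warm-started from the |correlation-with-y| ranking (the
    rest are uniform); disable with ``warm_start=False`` for a fully random
    swarm.  Default subset size is 10 bands.
    """
    config = config or SwarmConfig(k_bands=10)
    return _swarm_select(X, y, config, False, "pso", folds, warm_start)


def psama_select(
    X: np.ndarray,
    y: np.ndarray,
    config: SwarmConfig | None = None,
    folds: int = 5,
    warm_start: bool = True,
) -> BandSubset:
    """Attention-augmented PSO: the social attractor is the attention-weighted
    consensus of the swarm's personal bests instead of the single global best.

    Identical to :func:`pso_select` in every other respect (fitness, top-k
    decoding, seeding); default subset size is 20 bands.
    """
    config = config or SwarmConfig(k_bands=20)
    return _swarm_select(X, y, config, True, "psama", folds, warm_start)


# ---------------------------------------------------------------------------
# SPA


def spa_chain(X: np.ndarray, k: int, start: int) -> list[int]:
    """The successive-projections selection chain from one start column.

    At each step every remaining column is projected onto the orthogonal
    complement of the span of the selected columns and the column with the
    largest residual norm is appended; columns whose residual collapses
    (linearly dependent on the selection) are skipped.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n_bands = X.shape[1]
    if not 0 <= start < n_bands:
        raise ConfigurationError("start column out of range")
    R = X.astype(float).copy()
    selected = [start]
    for _ in range(k - 1):
        ref = R[:, selected[-1]].copy()
        denom = ref @ ref
        if denom <= 1e-30:
            break
        R = R - np.outer(ref, ref @ R) / denom
        norms = np.linalg.norm(R, axis=0)
        norms[selected] = -1.0
        norms[norms < 1e-12] = -1.0  # dependent candidates are unavailable
        j = int(np.argmax(norms))
        if norms[j] < 0:
            break
        selected.append(j)
    return selected


def spa_select(
    X: np.ndarray,
    k: int = 10,
    start: int | None = None,
    y: np.ndarray | None = None,
    folds: int = 5,
    seed: int = 0,
) -> BandSubset:
    """SPA band selection; with no fixed start, every start column is tried
    and the chain with the lowest CV fitness wins (requires ``y``)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n_bands = X.shape[1]
    if not 1 <= k <= min(n_bands, X.shape[0]):
        raise ConfigurationError("k must satisfy 1 <= k <= min(bands, samples)")
    if start is not None:
        chain = spa_chain(X, k, start)
        fit = (
            cv_fitness(X, y, chain, folds=folds, seed=seed) if y is not None else np.nan
        )
        return BandSubset("spa", sorted(chain), [], float(fit), {"k": k, "start": start})
    if y is None:
        raise ConfigurationError("automatic start selection requires y")
    best = None
    best_len = 0
    for s in range(n_bands):
        chain = spa_chain(X, k, s)
        if len(chain) < best_len:
            continue
        f = cv_fitness(X, y, chain, folds=folds, seed=seed)
        if len(chain) > best_len or best is None or f < best[0]:
            best = (f, s, chain)
            best_len = len(chain)
    if best_len < k:
        # rank-deficient spectra: every chain collapsed early
        warnings.warn(
            f"SPA: spectra support only {best_len} independent bands; "
            f"returning a chain shorter than the requested {k}",
            stacklevel=2,
        )
    f, s, chain = best
    return BandSubset("spa", sorted(chain), [], float(f), {"k": k, "start": s})


# ---------------------------------------------------------------------------
# PCA loading selection


def pca_select(
    X: np.ndarray, k: int = 21, explained_variance: float = 0.95
) -> BandSubset:
    """Rank bands by their maximal absolute PCA loading.

    Components are taken on the centred matrix until the target explained
    variance is reached; each band's score is its largest absolute loading
    across those components; ties break toward the lower channel index.
    Bands are centred but not variance-scaled — reflectance bands share a
    common scale, and scaling would erase the variance structure the
    loadings are meant to capture.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n_bands = X.shape[1]
    if k > n_bands:
        raise ConfigurationError("k exceeds band count")
    Xs = X - X.mean(axis=0)
    pca = PCA(n_components=min(n_bands, X.shape[0]))
    pca.fit(Xs)
    cum = np.cumsum(pca.explained_variance_ratio_)
    m = int(np.searchsorted(cum, explained_variance) + 1)
    m = min(m, pca.components_.shape[0])
    scores = np.abs(pca.components_[:m]).max(axis=0)
    # round away SVD jitter so degenerate bands tie exactly, then let the
    # stable sort break ties toward the lower channel index
    order = np.argsort(-np.round(scores, 10), kind="stable")[:k]
    indices = sorted(int(i) for i in order)
    return BandSubset(
        "pca", indices, [], float("nan"),
        {"k": k, "explained_variance": explained_variance, "n_components": m},
    )


# ---------------------------------------------------------------------------
# LASSO


def lasso_select(
    X: np.ndarray,
    y: np.ndarray,
    k_target: int = 20,
    n_bisect: int = 40,
    folds: int = 5,
    seed: int = 0,
    alpha_range: tuple[float, float] | None = None,
) -> BandSubset:
    """L1-penalised selection with the penalty bisected to a target support size.

    Bands are standardised; the penalty is bisected on a log scale until
    the non-zero coefficient count is as close as possible to ``k_target``
    (preferring counts <= target).  Returns the support ordered by
    decreasing |coefficient|.  If every probed penalty shrinks all
    coefficients away, the smallest non-empty support found while relaxing
    the penalty is returned with a warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if k_target > X.shape[1]:
        raise ConfigurationError("k_target exceeds band count")
    sd = X.std(axis=0)
    Xs = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    yc = y - y.mean()
    alpha_max = np.max(np.abs(Xs.T @ yc)) / len(y)
    if alpha_max == 0:
        raise DataError("y is orthogonal to every band; LASSO support undefined")

    def support(alpha: float) -> tuple[np.ndarray, np.ndarray]:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = Lasso(alpha=alpha, max_iter=5000)
            model.fit(Xs, yc)
        idx = np.flatnonzero(model.coef_)
        return idx, model.coef_[idx]

    if alpha_range is None:
        lo, hi = np.log(alpha_max * 1e-6), np.log(alpha_max * 1.01)
    else:
        lo, hi = np.log(alpha_range[0]), np.log(alpha_range[1])
    best = None  # (preference key, idx, coefs, alpha)

    def consider(alpha: float) -> int:
        nonlocal best
        idx, coefs = support(alpha)
        n = idx.size
        if n > 0:
            key = (0 if n <= k_target else 1, abs(n - k_target), -alpha)
            if best is None or key < best[0]:
                best = (key, idx, coefs, alpha)
        return n

    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        n = consider(float(np.exp(mid)))
        if n == k_target:
            break
        if n > k_target:
            lo = mid  # need more shrinkage
        else:
            hi = mid
    if best is None:
        # full-shrinkage fallback: relax the penalty until bands appear
        warnings.warn(
            "LASSO penalty shrank all coefficients to zero; returning the "
            "smallest non-empty support found while relaxing the penalty",
            stacklevel=2,
        )
        alpha = alpha_max
        for _ in range(60):
            alpha *= 0.5
            idx, coefs = support(alpha)
            if idx.size:
                best = (None, idx, coefs, alpha)
                break
        else:
            raise DataError("LASSO produced no non-empty support")
    _, idx, coefs, alpha = best
    order = np.argsort(-np.abs(coefs), kind="stable")
    indices = [int(idx[i]) for i in order]
    fit = cv_fitness(X, y, indices, folds=folds, seed=seed)
    return BandSubset(
        "lasso", indices, [], float(fit), {"k_target": k_target, "alpha": float(alpha)}
    )


# ---------------------------------------------------------------------------
# CARS


def cars_retention_schedule(n_bands: int, n_runs: int) -> np.ndarray:
    """Retained-band counts per iteration: r_i = a exp(-k i) with r_1 = 1
    and a final retained count of exactly 2."""
    if n_runs < 2:
        raise ConfigurationError("CARS needs at least 2 runs")
    N, p = n_runs, n_bands
    a = (p / 2.0) ** (1.0 / (N - 1))
    kk = np.log(p / 2.0) / (N - 1)
    i = np.arange(1, N + 1)
    ratios = a * np.exp(-kk * i)
    counts = np.round(ratios * p).astype(int)
    counts = np.clip(counts, 2, p)
    counts[0] = p
    counts[-1] = 2
    return counts


def cars_select(
    X: np.ndarray,
    y: np.ndarray,
    n_runs: int = 50,
    mc_frac: float = 0.8,
    folds: int = 5,
    seed: int = 0,
    max_components: int = 10,
) -> BandSubset:
    """Competitive adaptive reweighted sampling.

    At each of ``n_runs`` iterations a Monte-Carlo sample of rows fits a
    PLS model on the surviving bands; bands are weighted by |regression
    coefficient|, the exponentially decreasing schedule fixes how many
    survive, and adaptive reweighted sampling (weighted draw without
    replacement) picks them.  The iteration whose survivors minimise the
    CV fitness wins.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    rng = np.random.default_rng(seed)
    counts = cars_retention_schedule(p, n_runs)
    candidates = np.arange(p)
    best: tuple[float, np.ndarray] | None = None
    n_mc = max(2, int(round(mc_frac * n)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for n_keep in counts:
            rows = rng.choice(n, size=n_mc, replace=False)
            n_comp = min(max_components, candidates.size, n_mc - 1)
            if n_comp < min(max_components, candidates.size):
                log.warning("cars_select: PLS components reduced to %d", n_comp)
            pls = PLSRegression(n_components=max(1, n_comp), scale=False)
            pls.fit(X[np.ix_(rows, candidates)], y[rows])
            weight = np.abs(np.asarray(pls.coef_).ravel())
            n_keep = min(n_keep, candidates.size)
            wsum = weight.sum()
            probs = (weight + 1e-12) / (wsum + 1e-12 * weight.size)
            pick = rng.choice(candidates.size, size=n_keep, replace=False, p=probs)
            candidates = np.sort(candidates[pick])
            f = cv_fitness(X, y, candidates, folds=folds, seed=seed)
            if best is None or f < best[0]:
                best = (f, candidates.copy())
    fit, subset = best
    return BandSubset(
        "cars", [int(i) for i in subset], [], float(fit),
        {"n_runs": n_runs, "mc_frac": mc_frac, "seed": seed},
    )


# ---------------------------------------------------------------------------
# Dispatch


def select(
    method: str,
    X: np.ndarray,
    y: np.ndarray,
    k_bands: int | None = None,
    wavelengths: np.ndarray | None = None,
    seed: int = 0,
    **kwargs,
) -> BandSubset:
    """Run one selector by name and attach wavelengths if a grid is given."""
    method = method.lower()
    defaults = {"pso": 10, "psama": 20, "spa": 10, "pca": 21, "lasso": 20, "cars": 23}
    if method not in defaults:
        raise ConfigurationError(f"unknown selection method {method!r}")
    k = defaults[method] if k_bands is None else k_bands
    if method == "pso":
        subset = pso_select(X, y, SwarmConfig(k_bands=k, seed=seed), **kwargs)
    elif method == "psama":
        subset = psama_select(X, y, SwarmConfig(k_bands=k, seed=seed), **kwargs)
    elif method == "spa":
        subset = spa_select(X, k=k, y=y, seed=seed, **kwargs)
    elif method == "pca":
        subset = pca_select(X, k=k, **kwargs)
    elif method == "lasso":
        subset = lasso_select(X, y, k_target=k, seed=seed, **kwargs)
    else:
        subset = cars_select(X, y, seed=seed, **kwargs)
    if wavelengths is not None:
        wl = np.asarray(wavelengths, dtype=float)
        subset.wavelengths_nm = [float(wl[i]) for i in subset.channel_indices]
    return subset
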