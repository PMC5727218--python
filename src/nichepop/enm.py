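"""Maximum-entropy presence-background niche modelling.

The model is the Gibbs distribution ``q(x) proportional to exp(w . f(x))``
over a background sample of landscape cells, with features f(x) the
standardized linear and quadratic terms of each environmental layer.  The
weights maximize the L1-penalized presence log-likelihood::

    mean_presence(w . f) - log E_background[exp(w . f)] - sum_j beta_j |w_j|

which is concave; at the optimum the KKT conditions bound the gap between
each feature's empirical presence mean and its model expectation by beta_j.
Regularization defaults to ``beta_j = reg_multiplier * sd_j(background) /
sqrt(n_presences)``, a simplified analogue of Maxent's tuned defaults.

Raw output sums to 1 over the unmasked background universe.  A min-max
display transform is provided in :class:`SuitabilityMap` (labelled as such;
it is not Maxent's logistic/cloglog output).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import rankdata

from nichepop.geo_core import EnvGrid, OccurrenceSet, extract_cell_values, haversine_km

logger = logging.getLogger(__name__)

__all__ = [
    "MaxentModel",
    "SuitabilityMap",
    "ConvergenceError",
    "clean_occurrences",
    "fit_maxent",
    "fit_maxent_weights",
    "project_model",
    "auc",
    "auc_scores",
    "permutation_importance",
]


class ConvergenceError(RuntimeError):
    """Optimizer failed to reach the gradient tolerance."""

    def __init__(self, message: str, gradient_norm: float):
        super().__init__(f"{message} (last gradient norm {gradient_norm:.3g})")
        self.gradient_norm = gradient_norm


# ---------------------------------------------------------------------------
# Occurrence cleaning
# ---------------------------------------------------------------------------


def clean_occurrences(
    raw: OccurrenceSet,
    reference_points: list[tuple[float, float]] | None = None,
    max_km: float = 50.0,
) -> tuple[OccurrenceSet, list[dict]]:
    """Deduplicate and validate occurrence points.

    Exact-duplicate coordinates are collapsed to one; invalid coordinates
    (|lon| > 180 or |lat| > 90) are removed; if per-point
    ``reference_points`` are given, points farther than ``max_km``
    (great-circle) from their reference are removed.  Every rejection is
    listed in the report with its reason; the function never raises.
    """
    report: list[dict] = []
    kept: list[tuple[float, float]] = []
    seen: set[tuple[float, float]] = set()
    for i, (lon, lat) in enumerate(raw.points):
        if not (-180.0 <= lon <= 180.0 and -90.0 <= lat <= 90.0):
            report.append({"index": i, "point": (lon, lat), "reason": "invalid coordinate"})
            continue
        if (lon, lat) in seen:
            report.append({"index": i, "point": (lon, lat), "reason": "duplicate"})
            continue
        if reference_points is not None:
            d = haversine_km((lon, lat), reference_points[i])
            if d > max_km:
                report.append(
                    {
                        "index": i,
                        "point": (lon, lat),
                        "reason": f"distance to reference {d:.1f} km > {max_km} km",
                    }
                )
                continue
        seen.add((lon, lat))
        kept.append((lon, lat))
    return OccurrenceSet(raw.taxon, kept), report


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------


@dataclass
class SuitabilityMap:
    """Per-cell model output on an EnvGrid footprint.

    ``mode`` is ``"raw"`` (values sum to 1 over unmasked cells) or
    ``"minmax"`` (a display rescaling of raw to [0, 1]).
    """

    values: np.ndarray  # (n_rows, n_cols), NaN where masked
    mask: np.ndarray
    xllcorner: float
    yllcorner: float
    cellsize: float
    mode: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        unmasked = self.values[~self.mask]
        if self.mode == "raw":
            if unmasked.size and abs(unmasked.sum() - 1.0) > 1e-9:
                raise ValueError("raw suitability must sum to 1 over unmasked cells")
        elif self.mode == "minmax":
            if unmasked.size and (unmasked.min() < -1e-12 or unmasked.max() > 1 + 1e-12):
                raise ValueError("minmax suitability must lie in [0, 1]")
        else:
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def unmasked_values(self) -> np.ndarray:
        return self.values[~self.mask]

    def minmax(self) -> "SuitabilityMap":
        """Display transform: raw rescaled to [0, 1] (not a probability)."""
        v = self.values.copy()
        u = v[~self.mask]
        lo, hi = u.min(), u.max()
        v[~self.mask] = (u - lo) / (hi - lo) if hi > lo else 0.0
        return SuitabilityMap(v, self.mask, self.xllcorner, self.yllcorner,
                              self.cellsize, mode="minmax")

    def same_footprint(self, other: "SuitabilityMap") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.array_equal(self.mask, other.mask)
            and self.xllcorner == other.xllcorner
            and self.yllcorner == other.yllcorner
            and self.cellsize == other.cellsize
        )

    def to_layer(self):
        from nichepop.geo_core import GridLayer

        return GridLayer(
            np.where(self.mask, np.nan, self.values),
            self.mask.copy(),
            self.xllcorner,
            self.yllcorner,
            self.cellsize,
        )


@dataclass
class MaxentModel:
    """Fitted feature weights plus everything needed to re-project.

    Features are, per layer, the standardized value z and z**2 with
    standardization constants (mean, sd) taken from the training background;
    ``weights`` is ordered [linear terms..., quadratic terms...].
    """

    layer_names: list[str]
    layer_means: np.ndarray
    layer_sds: np.ndarray
    weights: np.ndarray
    betas: np.ndarray
    reg_multiplier: float
    n_presences: int
    background_rows: np.ndarray
    background_cols: np.ndarray

    @property
    def n_features(self) -> int:
        return 2 * len(self.layer_names)

    def features_from_layers(self, layer_values: np.ndarray) -> np.ndarray:
        """(n, n_layers) raw layer values -> (n, 2*n_layers) feature matrix."""
        z = (layer_values - self.layer_means) / self.layer_sds
        return np.column_stack([z, z**2])

    def score_points(self, env: EnvGrid, points: list[tuple[float, float]]) -> np.ndarray:
        vals, masked = extract_cell_values(env, points)
        vals = vals[:, [env.layer_names.index(n) for n in self.layer_names]]
        scores = self.features_from_layers(vals) @ self.weights
        scores[masked] = np.nan
        return scores

    def background_points(self, env: EnvGrid) -> list[tuple[float, float]]:
        lon, lat = env.cell_center(self.background_rows, self.background_cols)
        return list(zip(lon, lat))

    # -- serialization --------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        obj = {
            "layer_names": self.layer_names,
            "layer_means": self.layer_means.tolist(),
            "layer_sds": self.layer_sds.tolist(),
            "weights": self.weights.tolist(),
            "betas": self.betas.tolist(),
            "reg_multiplier": self.reg_multiplier,
            "n_presences": self.n_presences,
            "background_rows": self.background_rows.tolist(),
            "background_cols": self.background_cols.tolist(),
        }
        text = json.dumps(obj, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "MaxentModel":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        obj = json.loads(text)
        return cls(
            layer_names=list(obj["layer_names"]),
            layer_means=np.array(obj["layer_means"]),
            layer_sds=np.array(obj["layer_sds"]),
            weights=np.array(obj["weights"]),
            betas=np.array(obj["betas"]),
            reg_multiplier=float(obj["reg_multiplier"]),
            n_presences=int(obj["n_presences"]),
            background_rows=np.array(obj["background_rows"], dtype=int),
            background_cols=np.array(obj["background_cols"], dtype=int),
        )


# ---------------------------------------------------------------------------
# Core fit
# ---------------------------------------------------------------------------


def fit_maxent_weights(
    presence_features: np.ndarray,
    background_features: np.ndarray,
    betas: np.ndarray | float = 0.0,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> np.ndarray:
    """Solve the penalized maximum-entropy problem for a given feature matrix.

    Minimizes ``-(mean_pres(w.f) - log E_bg[exp(w.f)]) + sum beta_j |w_j|``
    by L-BFGS-B on the split ``w = u - v`` (u, v >= 0), which makes the L1
    term smooth.  Raises :class:`ConvergenceError` if the KKT residual
    ``max_j(|presence mean_j - model expectation_j| - beta_j)`` exceeds
    ``tol`` at the returned point.
    """
    F_pres = np.asarray(presence_features, dtype=float)
    F_bg = np.asarray(background_features, dtype=float)
    k = F_bg.shape[1]
    betas = np.broadcast_to(np.asarray(betas, dtype=float), (k,)).copy()
    fbar = F_pres.mean(axis=0)
    log_nbg = np.log(F_bg.shape[0])

    def nll_grad(w: np.ndarray) -> tuple[float, np.ndarray]:
        s = F_bg @ w
        lse = logsumexp(s) - log_nbg
        q = np.exp(s - logsumexp(s))
        expect = q @ F_bg
        return float(lse - fbar @ w), expect - fbar

    def obj(z: np.ndarray) -> tuple[float, np.ndarray]:
        u, v = z[:k], z[k:]
        val, g = nll_grad(u - v)
        return val + betas @ (u + v), np.concatenate([g + betas, -g + betas])

    z0 = np.zeros(2 * k)
    res = minimize(
        obj,
        z0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0, None)] * (2 * k),
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-9},
    )
    w = res.x[:k] - res.x[k:]
    _, g = nll_grad(w)
    kkt = np.abs(g) - betas
    if np.max(kkt) > tol:
        raise ConvergenceError(
            f"maxent fit did not reach KKT tolerance {tol}", float(np.max(np.abs(g)))
        )
    return w


def fit_maxent(
    env: EnvGrid,
    presences: OccurrenceSet,
    background_size: int = 10_000,
    reg_multiplier: float = 1.0,
    seed: int = 0,
    tol: float = 1e-6,
) -> MaxentModel:
    """Fit the niche model for one taxon on an environmental grid.

    The background is a uniform random sample of unmasked cells without
    replacement (all cells if fewer than ``background_size``).  Presences in
    masked cells are dropped with a warning; at least 5 usable presence
    points in more than one distinct cell are required.
    """
    rng = np.random.default_rng(seed)
    rows, cols = env.unmasked_indices()
    n_cells = rows.size
    if background_size >= n_cells:
        bg_idx = np.arange(n_cells)
    else:
        bg_idx = rng.choice(n_cells, size=background_size, replace=False)
    b_rows, b_cols = rows[bg_idx], cols[bg_idx]

    cells = []
    for lon, lat in presences.points:
        r, c = env.cell_of(lon, lat)
        if env.mask[r, c]:
            warnings.warn(f"presence at ({lon:.4f}, {lat:.4f}) in masked cell; dropped",
                          stacklevel=2)
            continue
        cells.append((r, c))
    if len(cells) < 5:
        raise ValueError(f"need >= 5 presence points in unmasked cells, have {len(cells)}")
    if len(set(cells)) < 2:
        raise ValueError("all presences fall in a single cell: degenerate likelihood")

    names = env.layer_names
    stack = env.stack(names)
    bg_vals = stack[:, b_rows, b_cols].T
    pr, pc = np.array([c[0] for c in cells]), np.array([c[1] for c in cells])
    pres_vals = stack[:, pr, pc].T

    mu = bg_vals.mean(axis=0)
    sd = bg_vals.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)  # constant layers give all-zero features

    def feats(vals: np.ndarray) -> np.ndarray:
        z = (vals - mu) / sd
        return np.column_stack([z, z**2])

    F_bg = feats(bg_vals)
    F_pres = feats(pres_vals)
    feat_sd = F_bg.std(axis=0)
    betas = reg_multiplier * feat_sd / np.sqrt(len(cells))

    w = fit_maxent_weights(F_pres, F_bg, betas, tol=tol)
    return MaxentModel(
        layer_names=list(names),
        layer_means=mu,
        layer_sds=sd,
        weights=w,
        betas=betas,
        reg_multiplier=reg_multiplier,
        n_presences=len(cells),
        background_rows=b_rows,
        background_cols=b_cols,
    )


def project_model(model: MaxentModel, env: EnvGrid) -> SuitabilityMap:
    """Project a fitted model onto a compatible grid (raw mode).

    The target must supply every layer the model names; extra layers are
    ignored with a logged warning.  Raw output is renormalized over the
    target grid's unmasked cells.
    """
    missing = [n for n in model.layer_names if n not in env.layers]
    if missing:
        raise KeyError(f"target grid missing model layer(s): {missing}")
    extra = [n for n in env.layer_names if n not in model.layer_names]
    if extra:
        logger.warning("ignoring layers not in model: %s", extra)
    rows, cols = env.unmasked_indices()
    vals = env.stack(model.layer_names)[:, rows, cols].T
    scores = model.features_from_layers(vals) @ model.weights
    q = np.exp(scores - logsumexp(scores))
    out = np.full((env.n_rows, env.n_cols), np.nan)
    out[rows, cols] = q
    return SuitabilityMap(out, env.mask.copy(), env.xllcorner, env.yllcorner, env.cellsize)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def auc_scores(presence_scores: np.ndarray, background_scores: np.ndarray) -> float:
    """Rank-based AUC: P(random presence outscores random background), ties 0.5."""
    ps = np.asarray(presence_scores, dtype=float)
    bs = np.asarray(background_scores, dtype=float)
    ps, bs = ps[~np.isnan(ps)], bs[~np.isnan(bs)]
    if ps.size == 0 or bs.size == 0:
        raise ValueError("need at least one presence and one background score")
    allv = np.concatenate([ps, bs])
    ranks = rankdata(allv)  # average ranks handle ties as 0.5
    u = ranks[: ps.size].sum() - ps.size * (ps.size + 1) / 2.0
    return float(u / (ps.size * bs.size))


def auc(
    model: MaxentModel,
    env: EnvGrid,
    presences: OccurrenceSet,
    background_points: list[tuple[float, float]] | None = None,
) -> float:
    """Training AUC of the model: presences vs (default: training) background."""
    if background_points is None:
        background_points = model.background_points(env)
    return auc_scores(
        model.score_points(env, presences.points),
        model.score_points(env, background_points),
    )


def permutation_importance(
    model: MaxentModel,
    env: EnvGrid,
    presences: OccurrenceSet,
    background_points: list[tuple[float, float]] | None = None,
    n_reps: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """Permutation importance of each layer, as percentages summing to 100.

    For each layer, its values are permuted jointly across the pooled
    presence + background evaluation points, scores recomputed with the
    fixed model, and the AUC drop averaged over ``n_reps`` permutations.
    Drops are floored at 0 and normalized to sum to 100 (all-zero vector if
    every drop is 0, e.g. for constant layers).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    if background_points is None:
        background_points = model.background_points(env)
    pres_vals, pres_masked = extract_cell_values(env, presences.points)
    bg_vals, bg_masked = extract_cell_values(env, background_points)
    order = [env.layer_names.index(n) for n in model.layer_names]
    pres_vals, bg_vals = pres_vals[:, order], bg_vals[:, order]
    n_pres = pres_vals.shape[0]
    pooled = np.vstack([pres_vals, bg_vals])
    keep = ~np.concatenate([pres_masked, bg_masked])

    def auc_of(vals: np.ndarray) -> float:
        scores = model.features_from_layers(vals) @ model.weights
        scores = np.where(keep, scores, np.nan)
        return auc_scores(scores[:n_pres], scores[n_pres:])

    base = auc_of(pooled)
    drops = np.zeros(len(model.layer_names))
    for j in range(len(model.layer_names)):
        acc = 0.0
        for _ in range(n_reps):
            perm = pooled.copy()
            perm[:, j] = perm[rng.permutation(perm.shape[0]), j]
            acc += base - auc_of(perm)
        drops[j] = max(0.0, acc / n_reps)
    total = drops.sum()
    pct = drops / total * 100.0 if total > 0 else drops
    return dict(zip(model.layer_names, pct))
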