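"""Niche-overlap metrics and the background-randomization similarity test.

Overlap between two raw (sum-to-1) suitability surfaces is measured with
Schoener's D and the Hellinger-based I::

    D = 1 - 1/2 * sum_cells |qA - qB|
    I = 1 - 1/2 * sum_cells (sqrt(qA) - sqrt(qB))**2

Both range from 0 (disjoint supports) to 1 (identical surfaces).  The
background similarity test asks whether the observed overlap differs from
the overlap expected when one taxon's occurrences are replaced by random
points drawn from its own spatially smoothed background: for each of
``n_iterations`` draws the model is refitted and D, I recomputed against the
other taxon's observed surface.  The verdict is two-sided at level alpha
(alpha/2 per tail): "similar" above the upper quantile of the null,
"divergent" below the lower, else "ns".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from nichepop.enm import ConvergenceError, MaxentModel, SuitabilityMap, fit_maxent, project_model
from nichepop.geo_core import EnvGrid, OccurrenceSet, haversine_km_matrix

__all__ = [
    "OverlapResult",
    "schoener_D",
    "hellinger_I",
    "gaussian_background",
    "sample_background_points",
    "background_similarity_test",
]


def _check_pair(qA: SuitabilityMap, qB: SuitabilityMap) -> None:
    if qA.mode != "raw" or qB.mode != "raw":
        raise ValueError("overlap metrics require raw-normalized maps")
    if not qA.same_footprint(qB):
        raise ValueError("suitability maps are on different grids/masks")


def schoener_D(qA: SuitabilityMap, qB: SuitabilityMap) -> float:
    """Schoener's D between two raw suitability surfaces (symmetric)."""
    _check_pair(qA, qB)
    return float(1.0 - 0.5 * np.abs(qA.unmasked_values - qB.unmasked_values).sum())


def hellinger_I(qA: SuitabilityMap, qB: SuitabilityMap) -> float:
    """Hellinger-based overlap I between two raw surfaces (symmetric)."""
    _check_pair(qA, qB)
    diff = np.sqrt(qA.unmasked_values) - np.sqrt(qB.unmasked_values)
    return float(1.0 - 0.5 * (diff**2).sum())


def gaussian_background(
    points: OccurrenceSet, env: EnvGrid, bandwidth_km: float = 200.0
) -> SuitabilityMap:
    """Kernel-density background surface from a taxon's occurrence points.

    A Gaussian kernel in great-circle distance (sd = ``bandwidth_km``) is
    summed over the points at every unmasked cell center and normalized to
    sum to 1.  Raises if the points put no mass on any unmasked cell.
    """
    if len(points) < 1:
        raise ValueError("need at least one occurrence point")
    if bandwidth_km <= 0:
        raise ValueError("bandwidth must be positive")
    rows, cols = env.unmasked_indices()
    lon, lat = env.cell_center(rows, cols)
    centers = np.column_stack([lon, lat])
    d = haversine_km_matrix(centers, points.lonlat_array())
    dens = np.exp(-0.5 * (d / bandwidth_km) ** 2).sum(axis=1)
    total = dens.sum()
    if total <= 0:
        raise ValueError("background density has no mass on unmasked cells")
    out = np.full((env.n_rows, env.n_cols), np.nan)
    out[rows, cols] = dens / total
    return SuitabilityMap(out, env.mask.copy(), env.xllcorner, env.yllcorner, env.cellsize)


def sample_background_points(
    density: SuitabilityMap, env: EnvGrid, n: int, rng: np.random.Generator
) -> OccurrenceSet:
    """Draw n pseudo-occurrence points from a background density surface."""
    rows, cols = env.unmasked_indices()
    p = density.values[rows, cols]
    idx = rng.choice(p.size, size=n, replace=True, p=p / p.sum())
    lon, lat = env.cell_center(rows[idx], cols[idx])
    jitter = (rng.random((n, 2)) - 0.5) * env.cellsize * 0.98
    return OccurrenceSet("background", list(zip(lon + jitter[:, 0], lat + jitter[:, 1])))


@dataclass
class OverlapResult:
    """Observed D and I plus the per-direction null distributions."""

    taxon_a: str
    taxon_b: str
    D_observed: float
    I_observed: float
    null_D: dict[str, np.ndarray]  # direction -> vector of length n_iterations
    null_I: dict[str, np.ndarray]
    verdicts: dict[str, dict[str, str]]  # direction -> metric -> verdict
    n_iterations: int
    alpha: float
    failed_iterations: dict[str, int] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "taxon_a": self.taxon_a,
            "taxon_b": self.taxon_b,
            "D_observed": self.D_observed,
            "I_observed": self.I_observed,
            "null_D": {k: list(map(float, v)) for k, v in self.null_D.items()},
            "null_I": {k: list(map(float, v)) for k, v in self.null_I.items()},
            "verdicts": self.verdicts,
            "n_iterations": self.n_iterations,
            "alpha": self.alpha,
            "failed_iterations": self.failed_iterations,
            "metadata": self.metadata,
        }


def _verdict(observed: float, null: np.ndarray, alpha: float) -> str:
    null = null[~np.isnan(null)]
    if null.size == 0:
        return "ns"
    lo = np.quantile(null, alpha / 2)
    hi = np.quantile(null, 1 - alpha / 2)
    if observed > hi:
        return "similar"
    if observed < lo:
        return "divergent"
    return "ns"


def background_similarity_test(
    occ_a: OccurrenceSet,
    occ_b: OccurrenceSet,
    env: EnvGrid,
    n_iterations: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    bandwidth_km: float = 200.0,
    background_size: int = 10_000,
    reg_multiplier: float = 1.0,
    max_retries: int = 3,
) -> OverlapResult:
    """Background-randomization niche similarity test, both directions.

    Direction ``"a_vs_b_background"`` keeps taxon A's observed model and
    compares it with models refitted to random draws from taxon B's
    Gaussian background (and vice versa).  A failed refit is retried up to
    ``max_retries`` times with a fresh draw, then recorded as missing (NaN)
    and counted in ``failed_iterations``.
    """
    rng = np.random.default_rng(seed)
    model_a = fit_maxent(env, occ_a, background_size, reg_multiplier, seed=int(rng.integers(2**31)))
    model_b = fit_maxent(env, occ_b, background_size, reg_multiplier, seed=int(rng.integers(2**31)))
    qa = project_model(model_a, env)
    qb = project_model(model_b, env)
    D_obs = schoener_D(qa, qb)
    I_obs = hellinger_I(qa, qb)

    dens = {
        "a": gaussian_background(occ_a, env, bandwidth_km),
        "b": gaussian_background(occ_b, env, bandwidth_km),
    }
    fixed_map = {"a_vs_b_background": qa, "b_vs_a_background": qb}
    randomized = {"a_vs_b_background": ("b", len(occ_b)), "b_vs_a_background": ("a", len(occ_a))}

    null_D: dict[str, np.ndarray] = {}
    null_I: dict[str, np.ndarray] = {}
    failed: dict[str, int] = {}
    for direction in ("a_vs_b_background", "b_vs_a_background"):
        which, n_pts = randomized[direction]
        dvec = np.full(n_iterations, np.nan)
        ivec = np.full(n_iterations, np.nan)
        nfail = 0
        for it in range(n_iterations):
            for _attempt in range(max_retries + 1):
                pts = sample_background_points(dens[which], env, n_pts, rng)
                try:
                    m = fit_maxent(
                        env, pts, background_size, reg_multiplier,
                        seed=int(rng.integers(2**31)),
                    )
                except (ConvergenceError, ValueError):
                    continue
                qn = project_model(m, env)
                dvec[it] = schoener_D(fixed_map[direction], qn)
                ivec[it] = hellinger_I(fixed_map[direction], qn)
                break
            else:
                nfail += 1
        null_D[direction] = dvec
        null_I[direction] = ivec
        failed[direction] = nfail

    verdicts = {
        direction: {
            "D": _verdict(D_obs, null_D[direction], alpha),
            "I": _verdict(I_obs, null_I[direction], alpha),
        }
        for direction in null_D
    }
    return OverlapResult(
        taxon_a=occ_a.taxon,
        taxon_b=occ_b.taxon,
        D_observed=D_obs,
        I_observed=I_obs,
        null_D=null_D,
        null_I=null_I,
        verdicts=verdicts,
        n_iterations=n_iterations,
        alpha=alpha,
        failed_iterations=failed,
        metadata={
            "bandwidth_km": bandwidth_km,
            "background_size": background_size,
            "reg_multiplier": reg_multiplier,
            "seed": seed,
            "directions": "both",
        },
    )
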