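"""Ensemble fitting of scattering profiles against a conformer pool.

At intermediate salt the sample is heterogeneous, so a single model
rarely fits; instead a non-negative weighted mixture of pool-member
profiles is sought that minimizes

    chi^2 = 1/(N-1) sum_k ( (s I_mix(q_k) - I_data(q_k)) / sigma_k )^2 .

For a pool of a few dozen rigid conformers the optimum over weights is
a non-negative least-squares problem and is solved exactly; a seeded
genetic-algorithm solver is retained behind a flag for parity with
classic ensemble-optimization workflows.  The asymmetric fraction --
total weight on conformers released predominantly from one end -- is
the summary statistic of interest, since P(R) alone cannot distinguish
mirror-related release patterns (left/right swaps are degenerate and
are reported with a warning when their profiles differ by less than
the noise).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .conformers import Conformer, classify_symmetry
from .scatter import ScatteringProfile

__all__ = ["EnsembleFit", "chi2", "select_ensemble", "asymmetric_fraction"]

WEIGHT_FLOOR = 0.01  # weights below 1% are dropped from the report


@dataclass
class EnsembleFit:
    member_ids: list
    weights: np.ndarray
    chi2: float
    scale: float
    asym_fraction: float | None = None
    degenerate_pairs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < -1e-12):
            raise ValueError("weights must be non-negative")
        total = self.weights.sum()
        if total > 0 and abs(total - 1.0) > 1e-6:
            raise ValueError("weights must sum to 1")


def _common_grid(model: ScatteringProfile, data: ScatteringProfile) -> np.ndarray:
    if model.q[-1] < data.q[0] or model.q[0] > data.q[-1]:
        raise ValueError("model and data q-grids do not overlap")
    return np.interp(data.q, model.q, model.I)


def chi2(model: ScatteringProfile, data: ScatteringProfile,
         fit_scale: bool = True) -> float:
    """Reduced chi^2 of a model profile against data, with an optimal
    scalar intensity scale when ``fit_scale``."""
    Im = _common_grid(model, data)
    sig = np.where(data.sigma > 0, data.sigma, 1.0)
    if fit_scale:
        denom = np.sum(Im ** 2 / sig ** 2)
        s = np.sum(Im * data.I / sig ** 2) / denom if denom > 0 else 1.0
    else:
        s = 1.0
    resid = (s * Im - data.I) / sig
    return float(resid @ resid / max(len(resid) - 1, 1))


def _nnls_weights(M: np.ndarray, data: ScatteringProfile) -> np.ndarray:
    sig = np.where(data.sigma > 0, data.sigma, 1.0)
    A = M / sig[:, None]
    b = data.I / sig
    x, _ = nnls(A, b, maxiter=10 * max(M.shape))
    return x


def _mixture_profile(M: np.ndarray, x: np.ndarray,
                     data: ScatteringProfile) -> ScatteringProfile:
    return ScatteringProfile(data.q, M @ x, np.zeros_like(data.q))


def _ga_weights(M: np.ndarray, data: ScatteringProfile, seed: int,
                population: int = 50, generations: int = 100) -> np.ndarray:
    """Seeded genetic-algorithm weight search (parity option)."""
    rng = np.random.default_rng(seed)
    n = M.shape[1]
    sig = np.where(data.sigma > 0, data.sigma, 1.0)

    def cost(w):
        # scale-invariant: fit the overall intensity scalar analytically
        Iw = M @ w
        denom = np.sum((Iw / sig) ** 2)
        s = np.sum(Iw * data.I / sig ** 2) / denom if denom > 0 else 1.0
        resid = (s * Iw - data.I) / sig
        return resid @ resid

    pop = rng.dirichlet(np.ones(n), size=population)
    costs = np.array([cost(w) for w in pop])
    for _ in range(generations):
        order = np.argsort(costs)
        elite = pop[order[: population // 5]]
        children = []
        while len(children) < population - len(elite):
            a, b = elite[rng.integers(len(elite), size=2)]
            lam = rng.random()
            child = lam * a + (1 - lam) * b
            mut = rng.standard_normal(n) * 0.05 * child.mean()
            children.append(np.clip(child + mut, 0.0, None))
        pop = np.vstack([elite, children])
        costs = np.array([cost(w) for w in pop])
    return pop[int(np.argmin(costs))]


def select_ensemble(pool_profiles: list[ScatteringProfile],
                    data: ScatteringProfile,
                    max_members: int = 4,
                    pool: list[Conformer] | None = None,
                    method: str = "nnls",
                    seed: int = 0,
                    degeneracy_noise: float | None = None) -> EnsembleFit:
    """Best non-negative mixture of pool profiles for one data profile.

    Solves the full-pool weight problem (exact NNLS by default, seeded
    GA with ``method='ga'``), truncates to the ``max_members`` largest
    weights, and re-fits the reduced basis.  If ``pool`` conformers are
    supplied the asymmetric weight fraction is attached.
    """
    if max_members < 1:
        raise ValueError("max_members must be >= 1")
    if not pool_profiles:
        raise ValueError("empty pool")
    M = np.column_stack([_common_grid(p, data) for p in pool_profiles])
    if method == "nnls":
        x = _nnls_weights(M, data)
    elif method == "ga":
        x = _ga_weights(M, data, seed)
    else:
        raise ValueError(f"unknown solver {method!r}")
    # keep the strongest members and re-fit them exactly
    order = np.argsort(x)[::-1]
    keep = [i for i in order[:max_members] if x[i] > 0]
    if not keep:
        keep = [int(order[0])]
    xk = _nnls_weights(M[:, keep], data)
    full = np.zeros_like(x)
    full[keep] = xk
    total = full.sum()
    if total <= 0:
        raise RuntimeError("ensemble fit degenerate: all weights zero")
    mix = _mixture_profile(M, full, data)
    c2 = chi2(mix, data, fit_scale=True)
    weights = full / total
    drop = weights < WEIGHT_FLOOR
    if np.any(drop) and not np.all(drop):
        weights = np.where(drop, 0.0, weights)
        weights /= weights.sum()
    ids = [p.meta.get("label", str(i)) for i, p in enumerate(pool_profiles)]
    fit = EnsembleFit(member_ids=ids, weights=weights, chi2=c2,
                      scale=float(total))
    fit.degenerate_pairs = _degenerate_pairs(
        M, weights, data, degeneracy_noise)
    if fit.degenerate_pairs:
        names = [(ids[i], ids[j]) for i, j in fit.degenerate_pairs]
        warnings.warn(f"near-degenerate ensemble members: {names}",
                      stacklevel=2)
    if pool is not None:
        fit.asym_fraction = asymmetric_fraction(fit, pool)
    return fit


def _degenerate_pairs(M: np.ndarray, weights: np.ndarray,
                      data: ScatteringProfile,
                      noise: float | None) -> list[tuple[int, int]]:
    """Pairs (selected member, pool member) whose profiles differ by
    less than the data noise: weight placed on one could equally sit on
    the other (e.g. left/right mirror releases)."""
    sel = np.nonzero(weights > 0)[0]
    sig = np.where(data.sigma > 0, data.sigma, 1.0)
    if noise is None:
        noise = 1.0
    pairs = []
    for i in sel:
        for j in range(M.shape[1]):
            if j <= i and j in sel:
                continue  # avoid double-reporting selected pairs
            if j == i:
                continue
            scale = np.median(M[:, i] / np.maximum(M[:, j], 1e-300))
            diff = np.sqrt(np.mean(((M[:, i] - scale * M[:, j]) / sig) ** 2))
            if diff < noise:
                pairs.append((int(i), int(j)))
    return pairs


def asymmetric_fraction(fit: EnsembleFit, pool: list[Conformer]) -> float:
    """Total ensemble weight on conformers classified asymmetric."""
    if not np.any(fit.weights > 0):
        raise ValueError("degenerate fit: all weights zero")
    by_name = {c.name: c for c in pool}
    frac = 0.0
    for mid, w in zip(fit.member_ids, fit.weights):
        if w <= 0:
            continue
        if mid not in by_name:
            raise ValueError(f"unknown ensemble member id {mid!r}")
        if classify_symmetry(by_name[mid]) == "asymmetric":
            frac += w
    return float(frac)
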