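"""Pair-distance distributions: direct histograms and regularized IFT.

The pair-distance distribution P(R) is the histogram of all
intra-particle distances weighted by excess scattering; it relates to
the measured intensity through

    I(q) = 4 pi  int_0^Dmax  P(r) sin(qr)/(qr) dr .

Two routes produce a PDDF here.  ``pofr_from_model`` histograms a bead
model directly (with a Gaussian bead-size smear), which serves as the
ground-truth oracle.  ``ift_regularized`` inverts a measured profile by
regularized least squares: P >= 0 on a uniform r-grid with pinned
endpoints P(0) = P(Dmax) = 0, a second-difference smoothness penalty
alpha, and a discrepancy-principle default for alpha.  ``scan_dmax`` reproduces the
practitioner's Dmax protocol: scan candidates, keep the smallest one
that fits well, gives a stable P(R), and decays smoothly at the tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from scipy.spatial.distance import pdist

from .conformers import Conformer
from .scatter import ContrastModel, ScatteringProfile, Solvent, bead_weights

__all__ = [
    "PDDF",
    "pofr_from_model",
    "ift_regularized",
    "scan_dmax",
    "rg_i0_from_pofr",
]

ALPHA_GRID = np.geomspace(1e-6, 1e3, 19)
R_POINTS = 201
BEAD_SMEAR = 1.5  # A; Gaussian bead half-width used for model PDDFs


@dataclass
class PDDF:
    """P(R) on an r-grid with derived size parameters.

    ``chi2`` is the reduced chi^2 of the fit that produced it (zero for
    direct model histograms), ``alpha`` the regularization strength and
    ``qmax_used`` the upper end of the fitted q-window.  ``flags`` may
    contain 'unstable' (no Dmax candidate passed the scan) or
    'truncated' (dmax below the feature windows).
    """

    r: np.ndarray
    p: np.ndarray
    dmax: float
    rg: float
    i0: float
    chi2: float = 0.0
    alpha: float = 0.0
    qmax_used: float = 0.0
    flags: tuple[str, ...] = ()
    scan: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if len(self.r) != len(self.p):
            raise ValueError("r and p must have equal length")


def _moments(r: np.ndarray, p: np.ndarray) -> tuple[float, float]:
    """(i0, rg) from the P(R) moments: i0 = 4 pi int P, rg^2 = int r^2 P / 2 int P."""
    total = np.trapezoid(p, r)
    if total <= 0:
        raise ValueError("degenerate PDDF: non-positive integral")
    rg = float(np.sqrt(np.trapezoid(r ** 2 * p, r) / (2.0 * total)))
    return float(4.0 * np.pi * total), rg


def rg_i0_from_pofr(d: PDDF) -> tuple[float, float]:
    """Radius of gyration and forward intensity from P(R) moments."""
    i0, rg = _moments(d.r, d.p)
    return rg, i0


def pofr_from_model(c: Conformer, bin_width: float = 1.0,
                    solvent: Solvent | None = None,
                    model: ContrastModel | None = None,
                    smear: float = BEAD_SMEAR) -> PDDF:
    """Brute-force pair-distance histogram of a bead model.

    Pair weights are w_i w_j (uniform when no solvent/contrast given);
    each pair distance is spread by a Gaussian of width sqrt(2)*smear,
    the pair kernel of Gaussian beads of half-width ``smear``.
    Normalized so that 4 pi int P dr = I(0) = (sum w)^2.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be > 0")
    if len(c.beads) < 2:
        raise ValueError("need at least 2 beads")
    if solvent is None:
        w = np.ones(len(c.beads))
    else:
        w = bead_weights(c, solvent, model)
    keep = w != 0
    w = w[keep]
    xyz = c.beads[keep]
    if len(xyz) < 2:
        raise ValueError("fewer than 2 weighted beads")
    d = pdist(xyz)
    iu = np.triu_indices(len(w), k=1)
    ww = w[iu[0]] * w[iu[1]]
    pad = max(4.0 * smear, 2.0 * bin_width)
    edges = np.arange(0.0, d.max() + pad + 2 * bin_width, bin_width)
    hist, _ = np.histogram(d, bins=edges, weights=ww)
    hist = hist.astype(float)
    r = 0.5 * (edges[:-1] + edges[1:])
    if smear:
        s = np.sqrt(2.0) * smear
        kx = np.arange(-4.0 * s, 4.0 * s + bin_width, bin_width)
        kern = np.exp(-kx ** 2 / (2.0 * s * s))
        kern /= kern.sum()
        hist = np.convolve(hist, kern, mode="same")
    hist = np.clip(hist, 0.0, None)
    hist[0] = 0.0
    hist[-1] = 0.0
    i0_target = float(w.sum() ** 2)
    offdiag = float(2.0 * ww.sum())
    total = np.trapezoid(hist, r)
    p = hist * (i0_target / (4.0 * np.pi * total))
    _, rg_raw = _moments(r, p)
    # exact bead-set Rg: the second-moment denominator counts every
    # ordered pair including the zero-distance diagonal, so rescale the
    # continuous-body moment by the off-diagonal mass fraction
    rg = rg_raw * np.sqrt(offdiag / i0_target)
    # support endpoint = geometric maximum distance (the smear pad on
    # the r-grid is numerical, not structural)
    return PDDF(r=r, p=p, dmax=float(d.max()), rg=rg,
                i0=i0_target)


def _design_matrix(q: np.ndarray, r: np.ndarray) -> np.ndarray:
    dr = r[1] - r[0]
    qr = np.outer(q, r)
    with np.errstate(invalid="ignore"):
        sinc = np.where(qr > 0, np.sin(qr) / np.where(qr > 0, qr, 1.0), 1.0)
    # trapezoid quadrature weights on the uniform grid
    wq = np.full(len(r), dr)
    wq[0] = wq[-1] = dr / 2.0
    return 4.0 * np.pi * sinc * wq


def _second_difference(n: int) -> np.ndarray:
    D = np.zeros((n - 2, n))
    for i in range(n - 2):
        D[i, i:i + 3] = (1.0, -2.0, 1.0)
    return D


def _solve_alpha(A: np.ndarray, b: np.ndarray, D: np.ndarray,
                 alpha: float) -> tuple[np.ndarray, float, float]:
    stacked = np.vstack([A, np.sqrt(alpha) * D])
    rhs = np.concatenate([b, np.zeros(D.shape[0])])
    x, _ = nnls(stacked, rhs, maxiter=10 * stacked.shape[1])
    resid = A @ x - b
    return x, float(resid @ resid), float(np.sum((D @ x) ** 2))


def ift_regularized(profile: ScatteringProfile, dmax: float,
                    alpha: float | None = None,
                    r_points: int = R_POINTS,
                    qmax: float | None = None) -> PDDF:
    """Regularized indirect Fourier transform of a scattering profile.

    Minimizes chi^2 + alpha * ||second difference of P||^2 subject to
    P >= 0 with P(0) = P(dmax) = 0.  When ``alpha`` is None it is picked
    by the discrepancy rule over a log grid.  ``qmax`` trims high-q points
    before fitting.
    """
    if dmax <= 0:
        raise ValueError("dmax must be > 0")
    q, I, sig = profile.q, profile.I, profile.sigma
    if qmax is not None:
        sel = q <= qmax
        q, I, sig = q[sel], I[sel], sig[sel]
    if len(q) < 5:
        raise ValueError("too few points for IFT")
    if np.all(sig == 0):
        raise ValueError("invalid uncertainties: all sigma are zero")
    sig = np.where(sig > 0, sig, np.min(sig[sig > 0]))
    r = np.linspace(0.0, dmax, r_points)
    K = _design_matrix(q, r)
    # pin the endpoints to zero by removing them from the unknowns
    Ai = (K / sig[:, None])[:, 1:-1]
    b = I / sig
    # normalize so alpha is intensity-scale invariant
    s0 = float(np.max(np.abs(b)))
    if s0 <= 0:
        raise ValueError("profile has no signal")
    b = b / s0
    D = _second_difference(r_points)[:, 1:-1]
    dof = max(len(q) - 1, 1)
    if alpha is None:
        # chi2 is non-decreasing in alpha: scan upward and stop once the
        # discrepancy bound is crossed, keeping the smoothest acceptable fit
        bound = None
        chosen = None
        for a in ALPHA_GRID:
            x_a, rss_a, _ = _solve_alpha(Ai, b, D, a)
            c2 = rss_a / dof
            if bound is None:
                bound = max(1.0 / s0 ** 2, 1.10 * c2)
            if c2 <= bound:
                chosen = (a, x_a, rss_a)
            else:
                break
        alpha_used, x, rss = chosen
        alpha_used = float(alpha_used)
    else:
        alpha_used = float(alpha)
        x, rss, _ = _solve_alpha(Ai, b, D, alpha_used)
    rss *= s0 ** 2
    p = np.zeros(r_points)
    p[1:-1] = x * s0
    if not np.any(p > 0):
        raise RuntimeError("IFT solver failure: all-zero distribution")
    i0, rg = _moments(r, p)
    return PDDF(r=r, p=p, dmax=float(dmax), rg=rg, i0=i0,
                chi2=rss / dof, alpha=alpha_used,
                qmax_used=float(q[-1]))


def _l2_change(d1: PDDF, d2: PDDF) -> float:
    """Relative L2 difference of two PDDFs on a common grid."""
    rmax = max(d1.r[-1], d2.r[-1])
    grid = np.linspace(0.0, rmax, 256)
    a = np.interp(grid, d1.r, d1.p, right=0.0)
    b = np.interp(grid, d2.r, d2.p, right=0.0)
    a /= np.trapezoid(a, grid)
    b /= np.trapezoid(b, grid)
    denom = np.sqrt(np.trapezoid(a ** 2, grid))
    return float(np.sqrt(np.trapezoid((a - b) ** 2, grid)) / denom)


def scan_dmax(profile: ScatteringProfile, candidates,
              alpha: float | None = None,
              chi2_slack: float = 1.2,
              chi2_cap: float = 5.0,
              stability_tol: float = 0.05,
              tail_fraction: float = 0.10,
              tail_tol: float = 0.05,
              **ift_kwargs) -> PDDF:
    """Dmax selection: smallest candidate that fits, stabilizes, and decays.

    Criteria, in order: (i) chi2 within ``chi2_slack`` of the best over
    all candidates (or of the noise floor chi2 = 1 when the best is
    below it) and under the absolute cap ``chi2_cap``; (ii) P(R)
    changes by < ``stability_tol`` (L2)
    against the next-larger candidate; (iii) smooth decaying tail -- P
    non-increasing over the last ``tail_fraction`` of [0, dmax], up to
    ``tail_tol`` of the maximum.  If nothing passes, the best-chi2
    result is returned flagged 'unstable'.
    """
    candidates = sorted(float(c) for c in candidates)
    if len(candidates) < 3:
        raise ValueError("need at least 3 Dmax candidates")
    fits = [ift_regularized(profile, dm, alpha=alpha, **ift_kwargs)
            for dm in candidates]
    chi2s = np.array([f.chi2 for f in fits])
    # fits already at the noise floor (chi2 < 1) are all equally "good";
    # the slack factor only discriminates genuinely poor fits
    bound = min(chi2_slack * max(float(chi2s.min()), 1.0), chi2_cap)
    records = [{"dmax": dm, "chi2": float(f.chi2)}
               for dm, f in zip(candidates, fits)]
    winner = None
    for i, (dm, f) in enumerate(zip(candidates, fits)):
        rec = records[i]
        rec["chi2_ok"] = bool(f.chi2 <= bound)
        if i + 1 < len(fits):
            rec["stability"] = _l2_change(f, fits[i + 1])
            rec["stable"] = bool(rec["stability"] < stability_tol)
        else:
            rec["stable"] = True
        ntail = max(int(tail_fraction * len(f.r)), 2)
        tail = f.p[-ntail:]
        rises = np.diff(tail)
        rec["tail_ok"] = bool(np.all(rises <= tail_tol * f.p.max()))
        if winner is None and rec["chi2_ok"] and rec["stable"] and rec["tail_ok"]:
            winner = i
    if winner is None:
        winner = int(np.argmin(chi2s))
        out = fits[winner]
        out.flags = out.flags + ("unstable",)
    else:
        out = fits[winner]
    out.scan = records
    return out
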