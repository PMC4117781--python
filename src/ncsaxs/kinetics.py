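"""Time-resolved analysis: mixing, binning, SVD and rate fitting.

Stopped-flow SAXS follows salt-induced nucleosome disassembly after
rapid mixing (sample in low salt mixed with 3 M NaCl at 2:3 to a final
1.88 M).  Detector movie-mode frames (20 ms cadence) are binned in time
for signal to noise, the q x time matrix is decomposed by SVD to count
kinetically distinct components, and scalar traces -- I(0,t), Rg(t) --
are fit with single or double exponential decays to extract rate
constants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .ift import ift_regularized, rg_i0_from_pofr, scan_dmax
from .scatter import ScatteringProfile

__all__ = [
    "TimeSeries",
    "SVDResult",
    "KineticFit",
    "mixing_concentration",
    "bin_time",
    "svd_analysis",
    "trace_i0_rg",
    "fit_exponential",
    "model_selection",
]

FRAME_DURATION = 0.020  # s: 17 ms exposure + 3 ms readout


@dataclass
class TimeSeries:
    """Ordered scattering frames on a common q-grid."""

    frames: list
    times: np.ndarray
    frame_duration: float = FRAME_DURATION
    bin_map: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.frames) != len(self.times):
            raise ValueError("frames and times length mismatch")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if self.frame_duration <= 0:
            raise ValueError("frame_duration must be > 0")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def q(self) -> np.ndarray:
        return self.frames[0].q

    def intensity_matrix(self) -> np.ndarray:
        """(n_q, n_t) intensity matrix; raises on ragged q-grids."""
        q0 = self.frames[0].q
        for f in self.frames[1:]:
            if len(f.q) != len(q0) or not np.allclose(f.q, q0):
                raise ValueError("frames are not on a common q-grid")
        return np.column_stack([f.I for f in self.frames])

    def sigma_matrix(self) -> np.ndarray:
        return np.column_stack([f.sigma for f in self.frames])


@dataclass
class SVDResult:
    singular_values: np.ndarray
    left_vectors: np.ndarray   # (n_q, k) q-space basis
    right_vectors: np.ndarray  # (n_t, k) time-space amplitudes
    n_significant: int
    noise_floor: float


@dataclass
class KineticFit:
    n_exp: int
    rates: np.ndarray          # 1/s, descending
    rate_errors: np.ndarray
    amplitudes: np.ndarray
    amplitude_errors: np.ndarray
    baseline: float
    covariance: np.ndarray | None
    residual_rms: float
    redchi: float
    degenerate: bool = False

    def model(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.baseline)
        for A, k in zip(self.amplitudes, self.rates):
            out = out + A * np.exp(-k * t)
        return out


def mixing_concentration(c_sample: float, c_buffer: float,
                         ratio: tuple[float, float] = (2.0, 3.0)) -> float:
    """Final concentration after volumetric mixing at sample:buffer ratio."""
    if c_sample < 0 or c_buffer < 0:
        raise ValueError("concentrations must be >= 0")
    vs, vb = ratio
    if vs < 0 or vb < 0 or vs + vb <= 0:
        raise ValueError("mixing ratio parts must be positive")
    return (vs * c_sample + vb * c_buffer) / (vs + vb)


def _bin_edges(ts: TimeSeries, scheme: str, n_bins: int) -> np.ndarray:
    t0, t1 = ts.times[0], ts.times[-1]
    half = ts.frame_duration / 2.0
    if scheme == "fixed":
        return np.linspace(t0 - half, t1 + half, n_bins + 1)
    if scheme == "log":
        lo = max(t0 - half, 1e-4)
        return np.geomspace(lo, t1 + half, n_bins + 1)
    raise ValueError(f"unknown binning scheme {scheme!r}")


def bin_time(ts: TimeSeries, n_bins: int, scheme: str = "log",
             edges: np.ndarray | None = None) -> TimeSeries:
    """Bin frames in time with inverse-variance-weighted averaging.

    Bin times are exposure-weighted mean frame times; sigma combines as
    1/sigma^2 summation (total inverse variance is conserved).  Empty
    bins are dropped with a warning.
    """
    if len(ts) < 1:
        raise ValueError("empty time series")
    if edges is None:
        edges = _bin_edges(ts, scheme, n_bins)
    edges = np.asarray(edges, dtype=float)
    idx = np.digitize(ts.times, edges) - 1
    frames, times = [], []
    bin_map = np.full(len(ts), -1)
    for b in range(len(edges) - 1):
        members = np.nonzero(idx == b)[0]
        if len(members) == 0:
            continue
        bin_map[members] = len(frames)
        sub = [ts.frames[i] for i in members]
        I = np.column_stack([f.I for f in sub])
        S = np.column_stack([f.sigma for f in sub])
        if np.all(S > 0):
            w = 1.0 / S ** 2
            Ibar = np.sum(I * w, axis=1) / np.sum(w, axis=1)
            sbar = np.sqrt(1.0 / np.sum(w, axis=1))
        else:
            Ibar = I.mean(axis=1)
            sbar = S.mean(axis=1) / np.sqrt(len(sub))
        meta = dict(sub[0].meta)
        meta["n_frames"] = len(sub)
        tmean = float(np.mean(ts.times[members]))
        meta["time"] = tmean
        frames.append(ScatteringProfile(sub[0].q, Ibar, sbar, meta=meta))
        times.append(tmean)
    if not frames:
        raise ValueError("binning produced no occupied bins")
    if len(frames) < len(edges) - 1:
        warnings.warn(f"{len(edges) - 1 - len(frames)} empty time bins "
                      "dropped", stacklevel=2)
    out = TimeSeries(frames, np.asarray(times), ts.frame_duration)
    out.bin_map = bin_map
    return out


def _lag1_autocorr(v: np.ndarray) -> float:
    """Kinetic-SVD smoothness statistic: sum v_i v_{i+1} of the unit
    vector, without mean removal -- near 1 for smooth signal vectors,
    near 0 for noise."""
    v = np.asarray(v, dtype=float)
    if len(v) < 3:
        return 1.0
    denom = np.sum(v * v)
    if denom == 0:
        return 0.0
    return float(np.sum(v[:-1] * v[1:]) / denom)


def svd_analysis(ts: TimeSeries, sv_ratio: float = 3.0,
                 autocorr_min: float = 0.6) -> SVDResult:
    """SVD of the sigma-weighted q x time matrix with a significance count.

    Rows are weighted by their rms uncertainty so every q contributes
    on the noise scale.  A component is significant when its singular
    value exceeds ``sv_ratio`` times the noise floor (median of the
    lower half of the spectrum) and both its q- and time-vectors are
    smooth (lag-1 autocorrelation > ``autocorr_min``).
    """
    if len(ts) < 2:
        raise ValueError("need at least 2 frames for SVD")
    X = ts.intensity_matrix()
    S = ts.sigma_matrix()
    row_scale = np.sqrt(np.mean(S ** 2, axis=1))
    row_scale = np.where(row_scale > 0, row_scale, 1.0)
    U, s, Vt = np.linalg.svd(X / row_scale[:, None], full_matrices=False)
    tail = s[len(s) // 2:]
    floor = float(np.median(tail)) if len(tail) else 0.0
    floor = max(floor, s[0] * 1e-12)
    n_sig = 0
    for k in range(len(s)):
        if s[k] / floor <= sv_ratio:
            break
        if (_lag1_autocorr(U[:, k]) > autocorr_min
                and _lag1_autocorr(Vt[k]) > autocorr_min):
            n_sig += 1
        else:
            break
    return SVDResult(singular_values=s, left_vectors=U,
                     right_vectors=Vt.T, n_significant=n_sig,
                     noise_floor=floor)


def trace_i0_rg(ts: TimeSeries, method: str = "ift",
                dmax_candidates=None, dmax: float | None = None,
                alpha: float | None = None, qmax: float | None = None,
                **scan_kwargs):
    """Per-frame I(0) and Rg traces.

    ``method='ift'`` extrapolates I(0) = 4 pi int P and Rg from the
    regularized P(R) of each frame (the equilibrium strategy applied to
    each time point): either a full Dmax scan per frame
    (``dmax_candidates``) or a fixed generous ``dmax``, which is much
    faster and accurate for I(0,t) as long as dmax bounds every species.
    ``method='guinier'`` uses the low-q Guinier extrapolation -- fastest,
    but biased low for very extended species when q_min * Rg ~ 1.
    Frames whose analysis fails are flagged, not fatal.

    Returns (times, i0, rg, ok) arrays.
    """
    n = len(ts)
    i0 = np.full(n, np.nan)
    rg = np.full(n, np.nan)
    ok = np.zeros(n, dtype=bool)
    for i, f in enumerate(ts.frames):
        try:
            if method == "guinier":
                i0[i], rg[i] = f.guinier_i0_rg()
            elif method == "ift":
                if dmax is not None:
                    d = ift_regularized(f, dmax, alpha=alpha, qmax=qmax)
                elif dmax_candidates is not None:
                    d = scan_dmax(f, dmax_candidates, alpha=alpha,
                                  qmax=qmax, **scan_kwargs)
                else:
                    raise ValueError(
                        "ift method requires dmax or dmax_candidates")
                rg[i], i0[i] = rg_i0_from_pofr(d)
            else:
                raise ValueError(f"unknown method {method!r}")
            ok[i] = np.isfinite(i0[i]) and np.isfinite(rg[i])
        except (ValueError, RuntimeError) as err:
            warnings.warn(f"frame {i} (t={ts.times[i]:.3f}s) analysis "
                          f"failed: {err}", stacklevel=2)
    return ts.times.copy(), i0, rg, ok


def _exp_design(t: np.ndarray, rates: np.ndarray) -> np.ndarray:
    return np.column_stack([np.exp(-k * t) for k in rates]
                           + [np.ones_like(t)])


def _fit_rates_linear(t, y, sig, rates):
    """Weighted linear solve for amplitudes + baseline at fixed rates."""
    A = _exp_design(t, rates) / sig[:, None]
    coef, *_ = np.linalg.lstsq(A, y / sig, rcond=None)
    resid = A @ coef - y / sig
    return coef, float(resid @ resid)


def fit_exponential(t, y, sigma=None, n_exp: int = 1,
                    min_rate_ratio: float = 2.0) -> KineticFit:
    """Weighted least-squares fit of baseline + sum_i A_i exp(-k_i t).

    Multi-starts over decade-spaced rate initializations (pairs with
    ratio > ``min_rate_ratio`` for two exponentials) and polishes the
    best with the Levenberg-Marquardt fits of ``lmfit``.  Uncertainties
    come from the fit covariance.  A near-degenerate second component
    (rates within the ratio floor or vanishing amplitude) sets
    ``degenerate``.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if sigma is None:
        sigma = np.full_like(y, max(np.std(y) * 1e-2, 1e-12))
    sig = np.where(np.asarray(sigma, dtype=float) > 0, sigma, np.inf)
    sig = np.where(np.isfinite(sig), sig, np.nanmax(sig[np.isfinite(sig)]))
    good = np.isfinite(y)
    t, y, sig = t[good], y[good], sig[good]
    if len(t) < 2 * n_exp + 2:
        raise ValueError("too few points for the requested model")
    span = t.max() - t.min()
    kgrid = np.geomspace(0.1 / span, 300.0 / span, 12)
    starts = ([np.array([k]) for k in kgrid] if n_exp == 1 else
              [np.array([k1, k2]) for i, k1 in enumerate(kgrid)
               for k2 in kgrid[:i] if k1 / k2 > min_rate_ratio])
    best = None
    for k0 in starts:
        _, rss = _fit_rates_linear(t, y, sig, k0)
        if best is None or rss < best[1]:
            best = (k0, rss)
    import lmfit

    def residual(params):
        rates = np.array([params[f"k{i}"].value for i in range(n_exp)])
        A = _exp_design(t, rates)
        coef = np.array([params[f"A{i}"].value for i in range(n_exp)]
                        + [params["base"].value])
        return (A @ coef - y) / sig

    params = lmfit.Parameters()
    k0 = best[0]
    coef0, _ = _fit_rates_linear(t, y, sig, k0)
    for i in range(n_exp):
        params.add(f"k{i}", value=float(k0[i]), min=1e-6 / span)
        params.add(f"A{i}", value=float(coef0[i]))
    params.add("base", value=float(coef0[-1]))
    out = lmfit.minimize(residual, params, method="leastsq")
    if not out.success:
        raise RuntimeError("exponential fit failed to converge")
    rates = np.array([out.params[f"k{i}"].value for i in range(n_exp)])
    amps = np.array([out.params[f"A{i}"].value for i in range(n_exp)])
    kerr = np.array([out.params[f"k{i}"].stderr or np.nan
                     for i in range(n_exp)])
    aerr = np.array([out.params[f"A{i}"].stderr or np.nan
                     for i in range(n_exp)])
    order = np.argsort(rates)[::-1]
    rates, amps = rates[order], amps[order]
    kerr, aerr = kerr[order], aerr[order]
    resid = residual(out.params)
    dof = max(len(t) - (2 * n_exp + 1), 1)
    degenerate = False
    if n_exp == 2:
        amp_scale = max(np.max(np.abs(y)) - np.min(np.abs(y)), 1e-300)
        if (rates[0] / max(rates[1], 1e-300) < min_rate_ratio
                or np.min(np.abs(amps)) < 1e-3 * amp_scale):
            degenerate = True
    return KineticFit(
        n_exp=n_exp, rates=rates, rate_errors=kerr, amplitudes=amps,
        amplitude_errors=aerr, baseline=float(out.params["base"].value),
        covariance=getattr(out, "covar", None),
        residual_rms=float(np.sqrt(np.mean((resid * sig) ** 2))),
        redchi=float(resid @ resid / dof), degenerate=degenerate)


def model_selection(t, y, sigma=None, improvement: float = 0.15,
                    amp_sig: float = 3.0) -> int:
    """Pick 1 vs 2 exponentials for a trace.

    Two phases are accepted only when the reduced chi^2 improves by
    more than ``improvement`` and the smaller amplitude is significant
    at ``amp_sig`` standard errors (and the fit is not rate-degenerate).
    """
    f1 = fit_exponential(t, y, sigma, n_exp=1)
    try:
        f2 = fit_exponential(t, y, sigma, n_exp=2)
    except (RuntimeError, ValueError):
        return 1
    if f2.degenerate or f2.redchi <= 0:
        return 1
    better = (f1.redchi - f2.redchi) / max(f1.redchi, 1e-300) > improvement
    i_min = int(np.argmin(np.abs(f2.amplitudes)))
    err = f2.amplitude_errors[i_min]
    significant = np.isfinite(err) and err > 0 and (
        abs(f2.amplitudes[i_min]) > amp_sig * err)
    return 2 if (better and significant) else 1
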