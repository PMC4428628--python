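"""Bi-exponential TCSPC decay fitting.

Each pixel's photon-arrival histogram is modelled as

    I(t) = a1 exp(-t/tau1) + a2 exp(-t/tau2)

convolved with a Gaussian instrument response (IRF), with tau1 the short
instrumental component (~30 ps) and tau2 the diagnostic lifetime.  Fits are
weighted nonlinear least squares with Poisson (Neyman) weights 1/max(n, 1);
the amplitudes enter linearly and are solved by variable projection, so the
nonlinear search runs over (tau1, tau2) only.  Pixels with fewer than the
photon threshold (default 50 counts) are never fitted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import optimize
from scipy.special import erfcx

logger = logging.getLogger(__name__)

TAU1_BOUNDS = (5.0, 200.0)  # ps
TAU2_BOUNDS = (200.0, 5000.0)  # ps
_RESTART_FACTORS = (1.0, 0.6, 1.8, 3.0)  # jitter on the initial tau2

# 10-90% rise of a Gaussian CDF spans 2 * Phi^-1(0.9) = 2.5631 sigma
_RISE_1090_SIGMA = 2.5631


class DegenerateIRFError(ValueError):
    """The curve has no usable rising edge."""


@dataclass
class DecayCurve:
    """Photon counts per time bin for one pixel."""

    counts: np.ndarray
    bin_width: float  # ps
    t0_offset: float = 0.0  # ps, start of the window

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def times(self) -> np.ndarray:
        """Bin-center times in ps."""
        return self.t0_offset + (np.arange(len(self.counts)) + 0.5) * self.bin_width

    @property
    def total_photons(self) -> int:
        return int(self.counts.sum())


@dataclass
class FitResult:
    tau1: float  # ps
    tau2: float  # ps
    a1: float  # fractional photon contribution
    a2: float
    chi2_reduced: float
    converged: bool
    n_restarts: int = 0


@dataclass
class LifetimeImage:
    """Per-pixel tau2 map with photon counts and validity mask."""

    tau2_map: np.ndarray  # ps, NaN where invalid
    photon_map: np.ndarray
    valid_mask: np.ndarray
    pixel_size: float = 1.0  # um
    extras: dict = field(default_factory=dict)  # tau1/a1/a2/chi2 maps

    def to_tiff(self, path: str | Path) -> None:
        pages = np.stack(
            [
                self.tau2_map.astype(np.float32),
                self.photon_map.astype(np.float32),
                self.valid_mask.astype(np.float32),
            ]
        )
        tifffile.imwrite(
            path, pages, photometric="minisblack", metadata={"axes": "CYX"}
        )

    @classmethod
    def from_tiff(cls, path: str | Path, pixel_size: float = 1.0) -> "LifetimeImage":
        pages = tifffile.imread(path)
        return cls(pages[0], pages[1], pages[2] > 0.5, pixel_size)

    def fit_summary(self) -> pd.DataFrame:
        yy, xx = np.nonzero(self.valid_mask)
        cols = {"x_px": xx, "y_px": yy, "tau2_ps": self.tau2_map[yy, xx]}
        for key in ("tau1", "a1", "a2", "chi2"):
            if key in self.extras:
                cols[f"{key}"] = self.extras[key][yy, xx]
        return pd.DataFrame(cols)


def apply_photon_threshold(photon_map: np.ndarray, threshold: int = 50) -> np.ndarray:
    """Pixels with cumulative counts >= threshold are eligible for fitting."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    return np.asarray(photon_map) >= threshold


def _exp_gauss_conv(dt: np.ndarray, tau: np.ndarray | float, sigma: float) -> np.ndarray:
    """exp(-t/tau) (t >= 0) convolved with a unit Gaussian of width sigma,
    evaluated at dt = t - center.  Piecewise form keeps erfcx in range."""
    if sigma <= 1e-6:  # effectively no IRF blur at sub-femtosecond widths
        return np.where(dt >= 0, np.exp(-np.maximum(dt, 0) / (tau * np.ones_like(dt))), 0.0)
    z = (sigma / tau - dt / sigma) / np.sqrt(2.0)
    safe = z > -6.0
    out = np.empty(np.broadcast(dt, z).shape, dtype=float)
    out[safe] = 0.5 * erfcx(z[safe]) * np.exp(
        -(np.broadcast_to(dt, out.shape)[safe] ** 2) / (2 * sigma**2)
    )
    # far past the rise erfc(z) ~ 2: plain exponential, log-space for safety
    if np.any(~safe):
        tau_b = np.broadcast_to(tau * np.ones_like(out), out.shape)
        dt_b = np.broadcast_to(dt, out.shape)
        out[~safe] = np.exp(
            sigma**2 / (2 * tau_b[~safe] ** 2) - dt_b[~safe] / tau_b[~safe]
        )
    return out


def exgauss_basis(times: np.ndarray, tau: float, center: float, sigma: float) -> np.ndarray:
    """Exponential decay convolved with a Gaussian IRF, unit-sum normalized.

    Analytic per-bin evaluation (no FFT); sigma = 0 reduces to a stepped
    exponential.
    """
    dt = np.asarray(times, dtype=float) - center
    h = _exp_gauss_conv(dt, tau, sigma)
    s = h.sum(axis=-1, keepdims=h.ndim > 1)
    s = np.maximum(s, 1e-300)
    return h / s


def estimate_irf(curve: DecayCurve) -> tuple[float, float]:
    """Gaussian IRF parameters from the rising edge of a decay curve.

    The center is the half-maximum crossing of the rising edge; sigma comes
    from the 10-90% rise time divided by 2.5631.
    """
    y = np.asarray(curve.counts, dtype=float)
    t = curve.times
    peak = int(np.argmax(y))
    ymax = y[peak]
    if ymax <= 0 or np.all(y == y[0]):
        raise DegenerateIRFError("flat curve has no rising edge")
    if peak == 0:
        raise DegenerateIRFError("curve is monotonically decreasing")
    # monotone envelope of the rising edge; crossings by linear interpolation
    rise = np.maximum.accumulate(y[: peak + 1])

    def crossing(frac: float) -> float:
        level = frac * ymax
        idx = int(np.searchsorted(rise, level))
        if idx == 0:
            return t[0]
        y0, y1 = rise[idx - 1], rise[idx]
        w = 0.0 if y1 == y0 else (level - y0) / (y1 - y0)
        return t[idx - 1] + w * (t[idx] - t[idx - 1])

    t10, t50, t90 = crossing(0.1), crossing(0.5), crossing(0.9)
    sigma = max((t90 - t10) / _RISE_1090_SIGMA, 0.0)
    return float(t50), float(sigma)


def fit_channel_range(counts: np.ndarray) -> slice:
    """Contiguous channel range carrying the decay signal.

    TCSPC windows are mostly empty: bins before the excitation pulse and
    far down the tail hold no information but would dilute the reduced
    chi-square (the statistic can only approach unity over the channels
    actually fitted).  The range runs from where a 5-bin moving average
    first reaches 1 count (or 1% of peak) through the last such bin.
    """
    y = np.asarray(counts, dtype=float)
    sm = np.convolve(y, np.ones(5) / 5, mode="same")
    level = max(1.0, 0.01 * sm.max())
    above = np.nonzero(sm >= level)[0]
    if len(above) == 0:
        return slice(0, len(y))
    return slice(int(above[0]), int(above[-1]) + 1)


def refine_irf(
    curve: DecayCurve, irf0: tuple[float, float]
) -> tuple[float, float]:
    """Refine (center, sigma) of the IRF on a high-count pooled decay.

    The rising-edge estimate localizes the IRF to roughly one time bin; at
    coarse binning that residual offset biases every per-pixel lifetime, so
    the IRF is refined once per image by a weighted bi-exponential fit of
    the pooled curve with (center, sigma) free.  Per-pixel fits then keep
    the IRF fixed.
    """
    rng_ = fit_channel_range(curve.counts)
    y = np.asarray(curve.counts, dtype=float)[rng_]
    t = curve.times[rng_]
    w = 1.0 / np.maximum(y, 1.0)
    tau2_init = _tail_tau_estimate(y, t)
    bw = curve.bin_width

    def chi2_of(theta: np.ndarray) -> np.ndarray:
        center, sigma, tau1, tau2 = theta
        b1 = exgauss_basis(t, tau1, center, sigma)
        b2 = exgauss_basis(t, tau2, center, sigma)
        _, _, chi2 = _weighted_biexp_solve(y, w, b1, b2)
        return chi2

    def residuals(theta: np.ndarray) -> np.ndarray:
        center, sigma, tau1, tau2 = theta
        b1 = exgauss_basis(t, tau1, center, sigma)
        b2 = exgauss_basis(t, tau2, center, sigma)
        a1, a2, _ = _weighted_biexp_solve(y, w, b1, b2)
        return np.sqrt(w) * (y - a1 * b1 - a2 * b2)

    x0 = np.array(
        [irf0[0], max(irf0[1], 1.0), 30.0, np.clip(tau2_init, *TAU2_BOUNDS)]
    )
    lo = (max(irf0[0] - 2 * bw, 0.0), 0.5, TAU1_BOUNDS[0], TAU2_BOUNDS[0])
    hi = (irf0[0] + 2 * bw, max(4 * irf0[1], 2 * bw), TAU1_BOUNDS[1], TAU2_BOUNDS[1])
    x0 = np.clip(x0, lo, hi)
    sol = optimize.least_squares(
        residuals, x0, bounds=(lo, hi), method="trf", xtol=1e-10, max_nfev=300
    )
    if not sol.success or chi2_of(sol.x) > chi2_of(x0):
        return irf0
    return float(sol.x[0]), float(sol.x[1])


def _weighted_biexp_solve(
    y: np.ndarray, w: np.ndarray, b1: np.ndarray, b2: np.ndarray
) -> tuple[float, float, float]:
    """Non-negative weighted LS amplitudes for two fixed basis curves.

    Returns (A1, A2, weighted chi2).  The 2x2 normal equations are solved in
    closed form; negative solutions fall back to the better single-component
    fit (amplitude clipped at zero).
    """
    s11 = float(w @ (b1 * b1))
    s22 = float(w @ (b2 * b2))
    s12 = float(w @ (b1 * b2))
    r1 = float((w * y) @ b1)
    r2 = float((w * y) @ b2)
    syy = float(w @ (y * y))
    det = s11 * s22 - s12 * s12
    if det > 1e-30 * max(s11 * s22, 1e-300):
        a1 = (s22 * r1 - s12 * r2) / det
        a2 = (s11 * r2 - s12 * r1) / det
        if a1 >= 0 and a2 >= 0:
            return a1, a2, syy - a1 * r1 - a2 * r2
    cands = []
    if s11 > 0:
        a = max(r1 / s11, 0.0)
        cands.append((a, 0.0, syy - 2 * a * r1 + a * a * s11))
    if s22 > 0:
        a = max(r2 / s22, 0.0)
        cands.append((0.0, a, syy - 2 * a * r2 + a * a * s22))
    if not cands:
        return 0.0, 0.0, syy
    return min(cands, key=lambda c: c[2])


def _tail_tau_estimate(y: np.ndarray, t: np.ndarray) -> float:
    """Log-linear fit to the decay tail (last 60% of bins after the peak)."""
    peak = int(np.argmax(y))
    start = peak + int(0.4 * (len(y) - peak))
    sel = slice(start, len(y))
    yy, tt = y[sel], t[sel]
    pos = yy > 0
    if pos.sum() < 3:
        return float(np.sqrt(TAU2_BOUNDS[0] * TAU2_BOUNDS[1]))
    slope = np.polyfit(tt[pos], np.log(yy[pos]), 1)[0]
    if slope >= 0:
        return float(np.sqrt(TAU2_BOUNDS[0] * TAU2_BOUNDS[1]))
    return float(np.clip(-1.0 / slope, *TAU2_BOUNDS))


def fit_biexponential(
    curve: DecayCurve,
    irf: tuple[float, float],
    tau1_init: float = 30.0,
    max_restarts: int = 3,
) -> FitResult:
    """Weighted NLLS fit of the IRF-convolved bi-exponential model.

    The search runs over (tau1, tau2) with amplitudes solved linearly at
    every step (variable projection).  Components are ordered tau1 < tau2
    after the fit; a coincident pair collapses to a single exponential.
    Restarts jitter the initial tau2 deterministically before the pixel is
    declared non-converged.
    """
    rng_ = fit_channel_range(curve.counts)
    y = np.asarray(curve.counts, dtype=float)[rng_]
    t = curve.times[rng_]
    w = 1.0 / np.maximum(y, 1.0)
    center, sigma = irf
    dof = max(len(y) - 4, 1)
    tau2_init = _tail_tau_estimate(y, t)

    def residuals(theta: np.ndarray) -> np.ndarray:
        b1 = exgauss_basis(t, theta[0], center, sigma)
        b2 = exgauss_basis(t, theta[1], center, sigma)
        a1, a2, _ = _weighted_biexp_solve(y, w, b1, b2)
        return np.sqrt(w) * (y - a1 * b1 - a2 * b2)

    lo = (TAU1_BOUNDS[0], TAU2_BOUNDS[0])
    hi = (TAU1_BOUNDS[1], TAU2_BOUNDS[1])
    best = None
    n_restarts = 0
    for attempt, factor in enumerate(_RESTART_FACTORS[: max_restarts + 1]):
        x0 = np.array(
            [
                np.clip(tau1_init, *TAU1_BOUNDS),
                np.clip(tau2_init * factor, *TAU2_BOUNDS),
            ]
        )
        sol = optimize.least_squares(
            residuals, x0, bounds=(lo, hi), method="trf", xtol=1e-8, max_nfev=200
        )
        chi2 = 2 * sol.cost / dof
        if sol.success and (best is None or chi2 < best[1]):
            best = (sol, chi2)
            n_restarts = attempt
        if best is not None and best[1] < 2.0:
            break
    if best is None:
        return FitResult(np.nan, np.nan, 0.0, 0.0, np.nan, False, max_restarts)
    sol, chi2 = best
    tau1, tau2 = sol.x
    b1 = exgauss_basis(t, tau1, center, sigma)
    b2 = exgauss_basis(t, tau2, center, sigma)
    a1, a2, _ = _weighted_biexp_solve(y, w, b1, b2)
    # one model-based reweighting pass: counting weights 1/max(n,1) leave a
    # few-percent downward tau2 bias at low tail counts; refitting with
    # 1/max(model,1) (standard IRLS for Poisson data) removes it
    w = 1.0 / np.maximum(a1 * b1 + a2 * b2, 1.0)
    sol2 = optimize.least_squares(
        residuals, sol.x, bounds=(lo, hi), method="trf", xtol=1e-8, max_nfev=200
    )
    if sol2.success:
        sol = sol2
        chi2 = 2 * sol2.cost / dof
        tau1, tau2 = sol2.x
        b1 = exgauss_basis(t, tau1, center, sigma)
        b2 = exgauss_basis(t, tau2, center, sigma)
        a1, a2, _ = _weighted_biexp_solve(y, w, b1, b2)
    if tau1 > tau2:
        tau1, tau2, a1, a2 = tau2, tau1, a2, a1
    if np.isclose(tau1, tau2, rtol=1e-6):
        a1, a2 = a1 + a2, 0.0
    total = a1 + a2
    if total > 0:
        a1, a2 = a1 / total, a2 / total
    return FitResult(float(tau1), float(tau2), a1, a2, float(chi2), True, n_restarts)


def _grid_fit_image(
    curves: np.ndarray,
    times: np.ndarray,
    irf: tuple[float, float],
    n_tau1: int = 10,
    n_tau2: int = 36,
) -> dict[str, np.ndarray]:
    """Vectorized variable-projection NLLS over a (tau1, tau2) log grid with
    parabolic refinement, for a stack of decay curves (n_pixels, n_bins).

    Two weighted passes (counting weights, then one model-based reweighting,
    as in the per-curve fit).  Equivalent to the per-curve scipy fit up to
    the refinement resolution (~1% in tau2); used for whole images where
    hundreds of thousands of per-pixel scipy solves would be needlessly
    slow.
    """
    center, sigma = irf
    y = curves.astype(float)

    tau1_grid = np.geomspace(*TAU1_BOUNDS, n_tau1)
    tau2_grid = np.geomspace(*TAU2_BOUNDS, n_tau2)
    B1 = np.stack([exgauss_basis(times, tau, center, sigma) for tau in tau1_grid])
    B2 = np.stack([exgauss_basis(times, tau, center, sigma) for tau in tau2_grid])
    n_pix = len(y)
    pix = np.arange(n_pix)
    dof = max(curves.shape[1] - 4, 1)

    def solve_pass(w: np.ndarray) -> dict[str, np.ndarray]:
        wy = w * y
        syy = np.einsum("pt,pt,pt->p", w, y, y)
        S11 = w @ (B1 * B1).T  # (P, n_tau1)
        S22 = w @ (B2 * B2).T
        R1 = wy @ B1.T
        R2 = wy @ B2.T

        chi2_all = np.empty((n_pix, n_tau1, n_tau2))
        for i in range(n_tau1):
            cross = w @ (B1[i] * B2).T  # (P, n_tau2)
            s11 = S11[:, i : i + 1]
            det = s11 * S22 - cross**2
            det = np.where(det > 1e-30, det, np.inf)
            a1 = (S22 * R1[:, i : i + 1] - cross * R2) / det
            a2 = (s11 * R2 - cross * R1[:, i : i + 1]) / det
            chi2 = syy[:, None] - a1 * R1[:, i : i + 1] - a2 * R2
            # negative-amplitude cells fall back to the single-component fit
            bad = (a1 < 0) | (a2 < 0)
            single1 = syy[:, None] - np.maximum(R1[:, i : i + 1], 0) ** 2 / s11
            single2 = syy[:, None] - np.maximum(R2, 0) ** 2 / S22
            chi2 = np.where(bad, np.minimum(single1, single2), chi2)
            chi2_all[:, i, :] = chi2

        flat = chi2_all.reshape(n_pix, -1).argmin(axis=1)
        i_best, j_best = np.unravel_index(flat, (n_tau1, n_tau2))

        def parabolic(grid: np.ndarray, idx: np.ndarray, axis: int) -> np.ndarray:
            lo = np.maximum(idx - 1, 0)
            hi = np.minimum(idx + 1, len(grid) - 1)
            if axis == 0:
                c0, c1, c2 = (
                    chi2_all[pix, lo, j_best],
                    chi2_all[pix, idx, j_best],
                    chi2_all[pix, hi, j_best],
                )
            else:
                c0, c1, c2 = (
                    chi2_all[pix, i_best, lo],
                    chi2_all[pix, i_best, idx],
                    chi2_all[pix, i_best, hi],
                )
            denom = c0 - 2 * c1 + c2
            safe = np.where(np.abs(denom) > 1e-30, denom, 1.0)
            delta = np.where(np.abs(denom) > 1e-30, 0.5 * (c0 - c2) / safe, 0.0)
            delta = np.clip(delta, -1.0, 1.0)
            delta = np.where((idx == 0) | (idx == len(grid) - 1), 0.0, delta)
            step = np.log(grid[1] / grid[0])
            return grid[idx] * np.exp(delta * step)

        tau1 = parabolic(tau1_grid, i_best, axis=0)
        tau2 = parabolic(tau2_grid, j_best, axis=1)

        # final amplitudes and chi2 at the refined lifetimes
        b1 = _basis_rows(times, tau1, center, sigma)
        b2 = _basis_rows(times, tau2, center, sigma)
        s11 = np.einsum("pt,pt->p", w, b1 * b1)
        s22 = np.einsum("pt,pt->p", w, b2 * b2)
        s12 = np.einsum("pt,pt->p", w, b1 * b2)
        r1 = np.einsum("pt,pt->p", wy, b1)
        r2 = np.einsum("pt,pt->p", wy, b2)
        det = s11 * s22 - s12**2
        safe = det > 1e-30
        a1 = np.where(safe, (s22 * r1 - s12 * r2) / np.where(safe, det, 1), 0.0)
        a2 = np.where(safe, (s11 * r2 - s12 * r1) / np.where(safe, det, 1), 0.0)
        neg = (a1 < 0) | (a2 < 0) | ~safe
        if np.any(neg):
            one1 = np.maximum(r1 / np.maximum(s11, 1e-300), 0)
            one2 = np.maximum(r2 / np.maximum(s22, 1e-300), 0)
            use2 = (
                syy - 2 * one2 * r2 + one2**2 * s22
                < syy - 2 * one1 * r1 + one1**2 * s11
            )
            a1 = np.where(neg, np.where(use2, 0.0, one1), a1)
            a2 = np.where(neg, np.where(use2, one2, 0.0), a2)
        model = a1[:, None] * b1 + a2[:, None] * b2
        chi2 = np.einsum("pt,pt->p", w, (y - model) ** 2)
        total = np.maximum(a1 + a2, 1e-300)
        return {
            "tau1": tau1,
            "tau2": tau2,
            "a1": a1 / total,
            "a2": a2 / total,
            "chi2": chi2 / dof,
            "model": model,
        }

    first = solve_pass(1.0 / np.maximum(y, 1.0))
    result = solve_pass(1.0 / np.maximum(first["model"], 1.0))
    result.pop("model")
    return result


def _basis_rows(times: np.ndarray, taus: np.ndarray, center: float, sigma: float) -> np.ndarray:
    """exgauss_basis evaluated per row for a vector of lifetimes."""
    dt = np.broadcast_to(times[None, :] - center, (len(taus), len(times)))
    h = _exp_gauss_conv(dt, np.asarray(taus, float)[:, None], sigma)
    return h / np.maximum(h.sum(axis=1, keepdims=True), 1e-300)


def fit_image(
    cube: np.ndarray,
    bin_width: float,
    threshold: int = 50,
    irf: tuple[float, float] | None = None,
    pixel_size: float = 1.0,
    method: str = "fast",
) -> LifetimeImage:
    """Fit every above-threshold pixel of a decay cube (H, W, T).

    The IRF, unless supplied, is estimated once from the summed decay of
    all above-threshold pixels.  ``method="fast"`` uses the vectorized grid
    + parabolic NLLS; ``method="exact"`` loops the per-pixel scipy fit.
    """
    cube = np.asarray(cube)
    if cube.ndim != 3:
        raise ValueError("decay cube must be (H, W, T)")
    h, w_, n_bins = cube.shape
    photon_map = cube.sum(axis=2)
    mask = apply_photon_threshold(photon_map, threshold)
    tau2_map = np.full((h, w_), np.nan)
    valid = np.zeros((h, w_), dtype=bool)
    extras = {
        k: np.full((h, w_), np.nan) for k in ("tau1", "a1", "a2", "chi2")
    }
    n_sel = int(mask.sum())
    if n_sel == 0:
        logger.warning("no pixels pass the %d-photon threshold", threshold)
        return LifetimeImage(tau2_map, photon_map, valid, pixel_size, extras)

    times = (np.arange(n_bins) + 0.5) * bin_width
    pooled = DecayCurve(cube[mask].sum(axis=0), bin_width)
    if irf is None:
        irf = refine_irf(pooled, estimate_irf(pooled))

    yy, xx = np.nonzero(mask)
    curves = cube[yy, xx, :].astype(float)
    if method == "fast":
        # common signal-carrying channel range for the whole image
        rng_ = fit_channel_range(pooled.counts / max(n_sel, 1))
        res = _grid_fit_image(curves[:, rng_], times[rng_], irf)
        tau2_map[yy, xx] = res["tau2"]
        valid[yy, xx] = True
        for k in ("tau1", "a1", "a2", "chi2"):
            extras[k][yy, xx] = res[k]
        n_failed = 0
    elif method == "exact":
        n_failed = 0
        for y_i, x_i, counts in zip(yy, xx, curves):
            fit = fit_biexponential(DecayCurve(counts, bin_width), irf)
            if fit.converged:
                tau2_map[y_i, x_i] = fit.tau2
                valid[y_i, x_i] = True
                extras["tau1"][y_i, x_i] = fit.tau1
                extras["a1"][y_i, x_i] = fit.a1
                extras["a2"][y_i, x_i] = fit.a2
                extras["chi2"][y_i, x_i] = fit.chi2_reduced
            else:
                n_failed += 1
    else:
        raise ValueError(f"unknown fit method {method!r}")
    logger.info(
        "fit_image: %d fitted, %d below threshold, %d non-converged",
        int(valid.sum()),
        h * w_ - n_sel,
        n_failed,
    )
    return LifetimeImage(tau2_map, photon_map, valid, pixel_size, extras)
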