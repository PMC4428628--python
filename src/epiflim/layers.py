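"""Depth stratification of the epithelial ROI.

The epithelium is bounded by two annotated polylines: the basement membrane
(curve L, adjoining the basal layer) and the epithelial surface (curve M).
Each ROI pixel is assigned a normalized depth d_L / (d_L + d_M) from its
shortest distances to the two curves -- 0 on the membrane, 1 on the surface
-- and the ROI is partitioned into k equal-thickness layers along the growth
direction.  Layer 1 is basal, layer k superficial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from matplotlib.path import Path as MplPath

logger = logging.getLogger(__name__)

FEATURE_MODELS = ("whole", "three_layer", "ten_layer")


class OutsideROIError(ValueError):
    """Raised when a depth fraction is requested for a pixel outside the ROI."""


@dataclass
class EpitheliumGeometry:
    """Boundary annotation of one epithelium section.

    Polylines are (n, 2) arrays of (x, y) pixel coordinates (0-based pixel
    centers), ordered along the image width.  ``growth_direction`` is the
    sense from membrane toward surface and is informational only; depth is
    computed from distances, not from a translation.
    """

    membrane: np.ndarray  # curve L
    surface: np.ndarray  # curve M
    growth_direction: str = "membrane_to_surface"

    def __post_init__(self) -> None:
        self.membrane = np.atleast_2d(np.asarray(self.membrane, dtype=float))
        self.surface = np.atleast_2d(np.asarray(self.surface, dtype=float))
        for name, poly in (("membrane", self.membrane), ("surface", self.surface)):
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 2:
                raise ValueError(f"{name} polyline must be an (n>=2, 2) array")

    def smoothed(self, window: int = 5) -> "EpitheliumGeometry":
        """Moving-average smoothing of both polylines (edge-padded)."""
        if window <= 1:
            return self
        return EpitheliumGeometry(
            _smooth_polyline(self.membrane, window),
            _smooth_polyline(self.surface, window),
            self.growth_direction,
        )

    def roi_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean mask of pixels between the two curves (inclusive).

        The polygon is padded by half a pixel at its lateral ends so pixel
        centers on the first/last polyline column are counted as inside.
        """

        def _pad(poly: np.ndarray) -> np.ndarray:
            first = poly[0] + (poly[0] - poly[1]) * 0.5 / max(
                np.linalg.norm(poly[0] - poly[1]), 1e-9
            )
            last = poly[-1] + (poly[-1] - poly[-2]) * 0.5 / max(
                np.linalg.norm(poly[-1] - poly[-2]), 1e-9
            )
            return np.vstack([first, poly, last])

        poly = np.vstack([_pad(self.membrane), _pad(self.surface)[::-1]])
        path = MplPath(poly)
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        pts = np.column_stack([xx.ravel(), yy.ravel()])
        # radius nudge counts points exactly on the boundary as inside
        inside = path.contains_points(pts, radius=1e-9) | path.contains_points(
            pts, radius=-1e-9
        )
        return inside.reshape(shape)

    # -- I/O --------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        rows = [
            pd.DataFrame({"x_px": p[:, 0], "y_px": p[:, 1], "curve": c})
            for p, c in ((self.membrane, "L"), (self.surface, "M"))
        ]
        pd.concat(rows, ignore_index=True).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EpitheliumGeometry":
        df = pd.read_csv(path)
        get = lambda c: df.loc[df["curve"] == c, ["x_px", "y_px"]].to_numpy(float)
        return cls(get("L"), get("M"))


@dataclass
class LayerMap:
    """Integer raster of layer indices 1..k (0 outside the ROI)."""

    layer_index: np.ndarray
    k: int

    def to_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(path, self.layer_index.astype(np.int16))


@dataclass
class LayerFeatures:
    """Per-layer tau2 statistics of one sample (NaN = empty layer)."""

    mu: np.ndarray  # ps
    sigma: np.ndarray  # ps, population SD
    n_pixels: np.ndarray
    label: str = ""
    sample_id: str = ""

    @property
    def k(self) -> int:
        return len(self.mu)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "label": self.label,
                "layer": np.arange(1, self.k + 1),
                "mu_ps": self.mu,
                "sigma_ps": self.sigma,
                "n_pixels": self.n_pixels,
            }
        )


def _smooth_polyline(poly: np.ndarray, window: int) -> np.ndarray:
    pad = window // 2
    if len(poly) <= window:
        return poly.copy()
    # odd reflection = linear extrapolation at the ends, so endpoints (and
    # uniform vertex spacing) are preserved exactly
    padded = np.pad(poly, ((pad, pad), (0, 0)), mode="reflect", reflect_type="odd")
    kernel = np.ones(window) / window
    out = np.column_stack(
        [np.convolve(padded[:, j], kernel, mode="valid") for j in (0, 1)]
    )
    return out


def point_to_polyline_distance(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Exact minimum Euclidean distance from each point to a polyline.

    Evaluates every point-to-segment distance; chunked so memory stays
    bounded for full-frame pixel sets.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    a, b = poly[:-1], poly[1:]
    ab = b - a
    ab_len2 = np.maximum((ab**2).sum(axis=1), 1e-300)
    out = np.empty(len(points))
    for start in range(0, len(points), 4096):
        p = points[start : start + 4096]
        ap = p[:, None, :] - a[None, :, :]
        t = np.clip((ap * ab[None, :, :]).sum(-1) / ab_len2[None, :], 0.0, 1.0)
        proj = a[None, :, :] + t[:, :, None] * ab[None, :, :]
        d2 = ((p[:, None, :] - proj) ** 2).sum(-1)
        out[start : start + 4096] = np.sqrt(d2.min(axis=1))
    return out


def compute_depth_fraction(
    geometry: EpitheliumGeometry,
    pixels: np.ndarray,
    *,
    smooth_window: int = 5,
    check_roi: bool = True,
    roi_shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Normalized depth d_L / (d_L + d_M) of pixels inside the ROI.

    0 on the basement membrane, 1 on the epithelial surface.  Accepts a
    single (x, y) pair or an (n, 2) array; returns a scalar or vector.
    """
    pts = np.atleast_2d(np.asarray(pixels, dtype=float))
    scalar = np.asarray(pixels).ndim == 1
    geo = geometry.smoothed(smooth_window)
    if check_roi:
        shape = roi_shape
        if shape is None:
            hi = np.vstack([geo.membrane, geo.surface]).max(axis=0)
            shape = (int(np.ceil(hi[1])) + 2, int(np.ceil(hi[0])) + 2)
        mask = geo.roi_mask(shape)
        xi = np.clip(np.round(pts[:, 0]).astype(int), 0, shape[1] - 1)
        yi = np.clip(np.round(pts[:, 1]).astype(int), 0, shape[0] - 1)
        if not mask[yi, xi].all():
            raise OutsideROIError("pixel outside the epithelium ROI")
    d_l = point_to_polyline_distance(pts, geo.membrane)
    d_m = point_to_polyline_distance(pts, geo.surface)
    frac = d_l / np.maximum(d_l + d_m, 1e-300)
    return float(frac[0]) if scalar else frac


def _translation_depth_fraction(
    geo: EpitheliumGeometry, pts: np.ndarray
) -> np.ndarray:
    """Membrane-anchored depth: d_L over the thickness at the nearest
    membrane vertex (the literal normal-translation construction).  Kept as
    an alternative for comparison; can leave small gaps where boundaries
    converge."""
    d_l = point_to_polyline_distance(pts, geo.membrane)
    # thickness sampled at membrane vertices
    thickness = point_to_polyline_distance(geo.membrane, geo.surface)
    d2 = ((pts[:, None, :] - geo.membrane[None, :, :]) ** 2).sum(-1)
    nearest = d2.argmin(axis=1)
    local_t = np.maximum(thickness[nearest], 1e-300)
    return np.clip(d_l / local_t, 0.0, 1.0)


def assign_layers(
    geometry: EpitheliumGeometry,
    shape: tuple[int, int],
    k: int,
    *,
    method: str = "fraction",
    smooth_window: int = 5,
) -> LayerMap:
    """Partition the ROI into k equal-thickness layers.

    Layer index = min(floor(depth_fraction * k) + 1, k): half-open depth
    bins, with points exactly on the surface folded into layer k and points
    exactly on an internal boundary assigned to the deeper (higher) layer.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    geo = geometry.smoothed(smooth_window)
    mask = geo.roi_mask(shape)
    yy, xx = np.nonzero(mask)
    pts = np.column_stack([xx, yy]).astype(float)
    out = np.zeros(shape, dtype=np.int16)
    if len(pts):
        if method == "fraction":
            frac = compute_depth_fraction(
                geometry, pts, smooth_window=smooth_window, check_roi=False
            )
        elif method == "translate":
            frac = _translation_depth_fraction(geo, pts)
        else:
            raise ValueError(f"unknown layer-assignment method {method!r}")
        idx = np.minimum(np.floor(frac * k).astype(int) + 1, k)
        out[yy, xx] = idx
    return LayerMap(out, k)


def layer_statistics(lifetime, layers: LayerMap) -> LayerFeatures:
    """Mean and population SD of tau2 per layer, over valid pixels only."""
    tau2 = np.asarray(lifetime.tau2_map, dtype=float)
    valid = np.asarray(lifetime.valid_mask, dtype=bool)
    if tau2.shape != layers.layer_index.shape:
        raise ValueError("lifetime image and layer map shapes differ")
    k = layers.k
    mu = np.full(k, np.nan)
    sigma = np.full(k, np.nan)
    n = np.zeros(k, dtype=int)
    for j in range(1, k + 1):
        sel = (layers.layer_index == j) & valid
        n[j - 1] = sel.sum()
        if n[j - 1] == 0:
            logger.warning("layer %d/%d has no valid pixels", j, k)
            continue
        vals = tau2[sel]
        mu[j - 1] = vals.mean()
        sigma[j - 1] = vals.std(ddof=0)
    return LayerFeatures(mu=mu, sigma=sigma, n_pixels=n)


def build_feature_vector(
    features: LayerFeatures,
    model: str,
    cutoff: int | None = None,
    include_sigma: bool = False,
) -> np.ndarray:
    """Assemble the classifier input from per-layer statistics.

    whole        -> (mu, sigma) of the undivided ROI          (k = 1, len 2)
    three_layer  -> (mu_1[, sigma_1], mu_2[, ...], mu_3[, ...])
    ten_layer    -> (mu_10, mu_9, ..., mu_cutoff), surface downward
    """
    if model == "whole":
        if features.k != 1:
            raise ValueError("whole-epithelium features require k = 1")
        return np.array([features.mu[0], features.sigma[0]])
    if model == "three_layer":
        if features.k != 3:
            raise ValueError("three-layer features require k = 3")
        if include_sigma:
            return np.column_stack([features.mu, features.sigma]).ravel()
        return features.mu.copy()
    if model == "ten_layer":
        if features.k != 10:
            raise ValueError("ten-layer features require k = 10")
        if cutoff is None or not 1 <= cutoff <= 10:
            raise ValueError("ten_layer model requires cutoff in 1..10")
        if include_sigma:
            raise ValueError("sigma features are not defined for the cut-off sweep")
        return features.mu[::-1][: 11 - cutoff].copy()
    raise ValueError(f"unknown feature model {model!r}")


def features_to_csv(features: list[LayerFeatures], path: str | Path) -> None:
    pd.concat([f.to_frame() for f in features], ignore_index=True).to_csv(
        path, index=False
    )


def features_from_csv(path: str | Path) -> list[LayerFeatures]:
    df = pd.read_csv(path)
    out = []
    for sid, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("layer")
        out.append(
            LayerFeatures(
                mu=grp["mu_ps"].to_numpy(float),
                sigma=grp["sigma_ps"].to_numpy(float),
                n_pixels=grp["n_pixels"].to_numpy(int),
                label=str(grp["label"].iloc[0]),
                sample_id=str(sid),
            )
        )
    return out
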