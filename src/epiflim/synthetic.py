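"""Synthetic FLIM samples of stratified cervical epithelium.

Generates, per sample: a wavy epithelial band bounded by a basement-membrane
and a surface polyline; a ground-truth tau2 map built from a per-class depth
profile on a 10-layer grid; and a TCSPC decay cube in which every ROI pixel
emits an IRF-convolved bi-exponential decay that is Poisson-sampled at the
configured photon budget.  Sample pools mirror the study design: 10 normal,
8 CIN1, 6 CIN2 and 8 CIN3 sections.

The depth profiles encode a maturation model: in normal epithelium the
eosin lifetime tau2 rises steadily from the basal to the superficial layer;
CIN shortens it, most strongly near mid-epithelium, with full, nearly flat
shortening of the top half in CIN3.  Between-sample variability enters as
independent lognormal deviates per layer (configured relative SD); within a
layer, pixels jitter around the sampled layer mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

from .config import PATHOLOGY_CLASSES, InvalidConfigError, SyntheticConfig
from .decay import _basis_rows, exgauss_basis
from .layers import EpitheliumGeometry, compute_depth_fraction

N_LAYERS = 10
_MIN_TAU2 = 150.0  # ps, floor for pixel-level jitter draws


@dataclass
class GroundTruthSample:
    """One synthetic tissue section with known ground truth."""

    label: str
    geometry: EpitheliumGeometry
    true_tau2_map: np.ndarray  # ps, NaN outside the ROI
    decay_cube: np.ndarray | None  # (H, W, T) uint16 counts
    true_layer_means: np.ndarray  # 10-vector, ps
    sample_id: str = ""

    @property
    def roi_mask(self) -> np.ndarray:
        return np.isfinite(self.true_tau2_map)

    def save(self, directory: str | Path, config: SyntheticConfig) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        if self.decay_cube is not None:
            tifffile.imwrite(
                directory / f"{self.sample_id}_cube.tif",
                np.moveaxis(self.decay_cube, 2, 0),  # one page per time bin
            )
        self.geometry.to_csv(directory / f"{self.sample_id}_geometry.csv")
        sidecar = {
            "sample_id": self.sample_id,
            "label": self.label,
            "bin_width_ps": config.bin_width,
            "time_window_ns": config.time_window,
            "pixel_size_um": config.pixel_size,
            "photon_threshold": config.photon_threshold,
            "seed": config.seed,
            "true_layer_means_ps": self.true_layer_means.tolist(),
        }
        (directory / f"{self.sample_id}.json").write_text(
            json.dumps(sidecar, indent=2)
        )

    @classmethod
    def load(cls, directory: str | Path, sample_id: str) -> tuple["GroundTruthSample", dict]:
        directory = Path(directory)
        meta = json.loads((directory / f"{sample_id}.json").read_text())
        cube_path = directory / f"{sample_id}_cube.tif"
        cube = None
        if cube_path.exists():
            cube = np.moveaxis(tifffile.imread(cube_path), 0, 2)
        geometry = EpitheliumGeometry.from_csv(directory / f"{sample_id}_geometry.csv")
        sample = cls(
            label=meta["label"],
            geometry=geometry,
            true_tau2_map=np.full((1, 1), np.nan),
            decay_cube=cube,
            true_layer_means=np.asarray(meta["true_layer_means_ps"], float),
            sample_id=sample_id,
        )
        return sample, meta


def make_geometry(config: SyntheticConfig, rng: np.random.Generator) -> EpitheliumGeometry:
    """Draw the two boundary polylines of one epithelial band.

    The band is horizontal: the membrane undulates around a baseline and the
    surface sits one (waviness-modulated) thickness above it, so the local
    separation is thickness + A sin(2 pi x / P + phase).
    """
    config.validate()
    n = config.image_size
    extent = n * config.pixel_size
    amp_px = config.boundary_waviness_amplitude / config.pixel_size
    period_px = max(config.boundary_waviness_period / config.pixel_size, 4.0)
    max_t_px = 0.9 * n - 4 * amp_px - 4
    if max_t_px < 3:
        raise InvalidConfigError("band (thickness + waviness) exceeds the image")
    thickness_um = float(
        np.clip(
            rng.normal(config.epithelium_thickness_mean, config.epithelium_thickness_sd),
            10 * config.pixel_size,
            max_t_px * config.pixel_size,
        )
    )
    t_px = thickness_um / config.pixel_size

    x = np.arange(n, dtype=float)
    phase_base, phase_sep = rng.uniform(0, 2 * np.pi, size=2)
    center = n / 2 + rng.uniform(-0.05, 0.05) * n
    y_membrane = center + t_px / 2 + amp_px * np.sin(2 * np.pi * x / period_px + phase_base)
    separation = t_px + amp_px * np.sin(2 * np.pi * x / period_px + phase_sep)
    y_surface = y_membrane - separation
    # keep both curves safely inside the frame
    shift = 0.0
    if y_membrane.max() > n - 2:
        shift = n - 2 - y_membrane.max()
    if (y_surface + shift).min() < 1:
        shift += 1 - (y_surface + shift).min()
    return EpitheliumGeometry(
        np.column_stack([x, y_membrane + shift]),
        np.column_stack([x, y_surface + shift]),
    )


def _lognormal_deviate(rng: np.random.Generator, rsd, size=None) -> np.ndarray:
    """Mean-one multiplicative lognormal deviate(s) with relative SD rsd."""
    rsd = np.asarray(rsd, dtype=float)
    s = np.sqrt(np.log1p(rsd**2))
    return np.exp(rng.normal(-0.5 * s**2, s, size=size))


def sample_layer_means(
    label: str, config: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    """Class profile perturbed by multiplicative sample deviates.

    Default (structured) noise model: two independent zone factors -- one
    for the basal half (layers 1-5), one for the superficial half (6-10) --
    times independent per-layer deviates that are larger in the
    heterogeneous basal half.  If ``config.sample_rsd`` is set, the
    structure is replaced by i.i.d. per-layer deviates at that RSD
    (0 reproduces the profile exactly).
    """
    if label not in PATHOLOGY_CLASSES:
        raise ValueError(f"unknown pathology class {label!r}")
    profile = np.asarray(config.class_profile[label], dtype=float)
    if config.sample_rsd is not None:
        if config.sample_rsd == 0:
            return profile.copy()
        return profile * _lognormal_deviate(rng, config.sample_rsd, N_LAYERS)
    basal_f, top_f = _lognormal_deviate(rng, config.zone_rsd, 2)
    zone = np.concatenate([np.full(5, basal_f), np.full(5, top_f)])
    layer_rsd = np.concatenate(
        [np.full(5, config.layer_rsd_basal), np.full(5, config.layer_rsd_superficial)]
    )
    return profile * zone * _lognormal_deviate(rng, layer_rsd)


def render_tau2_map(
    geometry: EpitheliumGeometry,
    layer_means: np.ndarray,
    config: SyntheticConfig,
    rng: np.random.Generator,
    label: str,
) -> np.ndarray:
    """Ground-truth tau2 raster: layer mean + pixel jitter inside the ROI."""
    n = config.image_size
    mask = geometry.roi_mask((n, n))
    tau2 = np.full((n, n), np.nan)
    yy, xx = np.nonzero(mask)
    if len(yy) == 0:
        return tau2
    pts = np.column_stack([xx, yy]).astype(float)
    frac = compute_depth_fraction(geometry, pts, check_roi=False)
    layer = np.minimum(np.floor(frac * N_LAYERS).astype(int), N_LAYERS - 1)
    # jitter scale itself varies between samples (tissue heterogeneity)
    noise_sd = config.pixel_noise_for(label) * float(
        _lognormal_deviate(rng, config.pixel_noise_rsd)
    )
    vals = layer_means[layer] + rng.normal(0.0, noise_sd, size=len(layer))
    tau2[yy, xx] = np.maximum(vals, _MIN_TAU2)
    return tau2


def render_decay_cube(
    true_tau2_map: np.ndarray,
    config: SyntheticConfig,
    rng: np.random.Generator,
    poisson: bool = True,
) -> np.ndarray:
    """TCSPC decay cube for a ground-truth tau2 map.

    Every ROI pixel's expected histogram is the IRF-convolved two-component
    decay (tau1 instrumental, tau2 from the map), normalized so expected
    total counts equal ``photons_per_pixel``, then Poisson-sampled.
    Non-ROI pixels receive a weak uniform background (mean
    ``background_photons`` counts, below the photon threshold).
    """
    h, w = true_tau2_map.shape
    n_bins = config.n_time_bins
    times = (np.arange(n_bins) + 0.5) * config.bin_width
    f1 = config.amp_ratio / (1.0 + config.amp_ratio)
    f2 = 1.0 - f1
    b1 = exgauss_basis(times, config.tau1, config.irf_center, config.irf_sigma)

    expected = np.empty((h, w, n_bins), dtype=float)
    expected[:] = config.background_photons / n_bins
    mask = np.isfinite(true_tau2_map)
    yy, xx = np.nonzero(mask)
    for start in range(0, len(yy), 8192):
        sl = slice(start, start + 8192)
        taus = true_tau2_map[yy[sl], xx[sl]]
        b2 = _basis_rows(times, taus, config.irf_center, config.irf_sigma)
        expected[yy[sl], xx[sl], :] = config.photons_per_pixel * (f1 * b1 + f2 * b2)
    if not poisson:
        return expected
    counts = rng.poisson(expected)
    return np.minimum(counts, np.iinfo(np.uint16).max).astype(np.uint16)


def generate_sample(
    label: str,
    config: SyntheticConfig,
    rng: np.random.Generator,
    sample_id: str = "",
    render: bool = True,
) -> GroundTruthSample:
    geometry = make_geometry(config, rng)
    layer_means = sample_layer_means(label, config, rng)
    tau2_map = render_tau2_map(geometry, layer_means, config, rng, label)
    cube = render_decay_cube(tau2_map, config, rng) if render else None
    return GroundTruthSample(
        label=label,
        geometry=geometry,
        true_tau2_map=tau2_map,
        decay_cube=cube,
        true_layer_means=layer_means,
        sample_id=sample_id or label,
    )


def generate_pool(
    config: SyntheticConfig,
    seed: int | None = None,
    render: bool = True,
) -> list[GroundTruthSample]:
    """The full study pool, deterministic in (config, seed).

    Classes are generated in fixed order with ``pool_counts`` samples each
    (default 10 normal / 8 CIN1 / 6 CIN2 / 8 CIN3).  Each sample consumes an
    independent child RNG stream, so per-sample content does not depend on
    the generation order.  At full 256 px scale a rendered pool holds ~1 GB
    of cubes; use ``render=False`` or a reduced config when cubes are not
    needed all at once.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    n_total = sum(config.pool_counts.get(c, 0) for c in PATHOLOGY_CLASSES)
    children = root.spawn(n_total)
    pool = []
    i = 0
    for label in PATHOLOGY_CLASSES:
        for j in range(config.pool_counts.get(label, 0)):
            rng = np.random.default_rng(children[i])
            pool.append(
                generate_sample(
                    label, config, rng, sample_id=f"{label}_{j:02d}", render=render
                )
            )
            i += 1
    return pool
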