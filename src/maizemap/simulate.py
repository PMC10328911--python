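"""Synthetic Landsat-like scenes with class-separable crop phenology.

This module replaces the satellite archive and field surveys with a
seed-controlled simulator.  Each land-cover class (maize, soybean, rice,
others) carries a piecewise-linear seasonal reflectance trajectory per
spectral band; scenes are sampled from those trajectories on a fixed revisit
cadence, perturbed with Gaussian sensor/within-class noise, and contaminated
by clouds that get a bright signature (Blue >= 0.4) so that downstream cloud
handling is observable.  The landscape is a mosaic of rectangular
single-class parcels, emulating small-scale farmland; a block partition of
the grid stands in for prefectures when areas are aggregated.

Everything is a pure function of (scenario, seed): the same inputs yield
bit-identical rasters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calendar import BANDS, N_BANDS, scene_dates
from .compositing import SceneStack

CLASSES = ("maize", "soybean", "rice", "others")
CLASS_IDS = {name: i for i, name in enumerate(CLASSES)}
MAIZE_ID = CLASS_IDS["maize"]

#: Bare-soil reflectance used before green-up and after harvest.
_SOIL = {"blue": 0.08, "green": 0.11, "red": 0.14,
         "nir": 0.20, "swir1": 0.28, "swir2": 0.24}
#: Open-water reflectance for flooded rice paddies early in the season.
_WATER = {"blue": 0.06, "green": 0.08, "red": 0.07,
          "nir": 0.08, "swir1": 0.04, "swir2": 0.03}

# Per-class canopy peak reflectance and season timing (doy).  Maize greens up
# earlier and peaks in late July; soybean peaks later with a higher NIR
# plateau and brighter green; rice is flooded until transplanting and keeps
# low SWIR all season.  "others" is a low-amplitude grass/shrub/impervious
# mixture whose NIR seasonal range stays below 0.1.
_CROP_PEAK = {
    "maize": {"blue": 0.03, "green": 0.07, "red": 0.05,
              "nir": 0.52, "swir1": 0.16, "swir2": 0.09},
    "soybean": {"blue": 0.03, "green": 0.09, "red": 0.04,
                "nir": 0.57, "swir1": 0.19, "swir2": 0.11},
    "rice": {"blue": 0.04, "green": 0.08, "red": 0.05,
             "nir": 0.48, "swir1": 0.10, "swir2": 0.05},
}
_CROP_TIMING = {  # (greenup_start, peak_doy, harvest_doy)
    "maize": (135, 205, 268),
    "soybean": (150, 222, 281),
    "rice": (152, 215, 286),
}


@dataclass(frozen=True)
class PhenologyProfile:
    """Per-class seasonal mean reflectance trajectory with noise level.

    ``band_curves`` maps each band to ``(doys, values)`` knot arrays of a
    piecewise-linear curve over the Apr–Nov season; ``noise_sd`` is the
    additive Gaussian noise s.d. per band (reflectance units).
    """

    class_label: str
    band_curves: Mapping[str, tuple[np.ndarray, np.ndarray]]
    noise_sd: Mapping[str, float]
    harvest_doy: int | None

    def value(self, band: str, doy) -> np.ndarray:
        doys, vals = self.band_curves[band]
        return np.interp(doy, doys, vals)

    def validate(self) -> None:
        for band, (doys, vals) in self.band_curves.items():
            if not (np.all(np.diff(doys) > 0)):
                raise ValueError(f"{self.class_label}/{band}: knot doys not increasing")
            if vals.min() < 0 or vals.max() > 1:
                raise ValueError(f"{self.class_label}/{band}: values outside [0,1]")
            if self.noise_sd[band] < 0:
                raise ValueError(f"{self.class_label}/{band}: negative noise_sd")
        grid = np.arange(91, 335)
        nir = self.value("nir", grid)
        if self.class_label in ("maize", "soybean"):
            summer = nir[(grid >= 152) & (grid <= 273)]  # Jun–Sep
            if summer.max() - self.value("nir", 91) < 0.2:
                raise ValueError(f"{self.class_label}: NIR green-up contrast < 0.2")
        if self.class_label == "others" and nir.max() - nir.min() >= 0.1:
            raise ValueError("others: seasonal NIR range must be < 0.1")


def _crop_curve(band: str, pre: float, peak: float, timing, rng) -> tuple[np.ndarray, np.ndarray]:
    start, peak_doy, harvest = timing
    jit = lambda d: int(np.clip(d + rng.integers(-3, 4), 92, 333))
    doys = np.array([91, jit(start), jit(peak_doy), jit(harvest), jit(harvest + 10), 334], float)
    doys = np.maximum.accumulate(doys)
    doys += np.arange(6) * 1e-3  # keep strictly increasing after clipping
    soil = _SOIL[band]
    vals = np.array([pre, pre, peak, 0.5 * (peak + soil), soil, soil])
    vals = np.clip(vals + rng.normal(0.0, 0.004, size=vals.shape), 0.0, 1.0)
    # anchor the endpoints exactly so the jitter cannot erode the invariants
    vals[2] = np.clip(peak, 0.0, 1.0)
    return doys, vals


def default_profiles(seed: int = 0, nir_contrast: float = 1.0) -> dict[str, PhenologyProfile]:
    """One phenology profile per class, deterministic given ``seed``.

    ``nir_contrast`` scales the crops' NIR green-up amplitude (peak minus
    pre-season value) and acts as a class-separability dial; 1.0 is the
    default seasonal contrast.
    """
    rng = np.random.default_rng(seed)
    noise_sd = {b: 0.02 for b in BANDS}
    profiles: dict[str, PhenologyProfile] = {}
    for crop in ("maize", "soybean", "rice"):
        pre = _WATER if crop == "rice" else _SOIL
        timing = _CROP_TIMING[crop]
        curves = {}
        for band in BANDS:
            peak = _CROP_PEAK[crop][band]
            if band == "nir":
                peak = pre[band] + nir_contrast * (peak - pre[band])
            curves[band] = _crop_curve(band, pre[band], peak, timing, rng)
        profiles[crop] = PhenologyProfile(crop, curves, dict(noise_sd), timing[2])
    # "others": flat mixture with a mild summer bump, NIR range < 0.1
    curves = {}
    for band in BANDS:
        base = 0.5 * (_SOIL[band] + _CROP_PEAK["maize"][band])
        amp = 0.06 if band == "nir" else 0.02
        doys = np.array([91.0, 200.0, 334.0])
        vals = np.clip(np.array([base, base + amp, base - 0.01])
                       + rng.normal(0.0, 0.003, 3), 0.0, 1.0)
        curves[band] = (doys, vals)
    profiles["others"] = PhenologyProfile("others", curves, dict(noise_sd), None)
    for p in profiles.values():
        p.validate()
    return profiles


@dataclass(frozen=True)
class SimScenario:
    """Parameters of one synthetic acquisition campaign."""

    grid_shape: tuple[int, int] = (64, 64)
    revisit_days: int = 16
    cloud_prob: float = 0.05
    class_fractions: tuple[float, float, float, float] = (0.30, 0.25, 0.15, 0.30)
    cropland_fraction: float = 0.8
    parcel_size: int = 4
    year: int = 2019
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.class_fractions) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")
        if not (0.0 <= self.cloud_prob < 1.0):
            raise ValueError("cloud_prob must be in [0, 1)")
        if self.revisit_days < 1:
            raise ValueError("revisit_days must be >= 1")
        if min(self.grid_shape) < 1:
            raise ValueError("grid_shape must be positive")


def _parcel_edges(n: int, parcel_size: int, rng) -> np.ndarray:
    """Cut an axis of length n into runs of ~parcel_size pixels."""
    lo, hi = max(1, parcel_size - 2), parcel_size + 2
    edges = [0]
    while edges[-1] < n:
        edges.append(min(n, edges[-1] + int(rng.integers(lo, hi + 1))))
    return np.asarray(edges)


def _allocate(counts_total: int, fractions: Sequence[float]) -> np.ndarray:
    """Largest-remainder allocation of counts_total across fractions."""
    raw = np.asarray(fractions, float) * counts_total
    base = np.floor(raw).astype(int)
    rem = counts_total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return base


_CLOUD_MEAN = np.array([0.58, 0.56, 0.55, 0.50, 0.38, 0.28])


def simulate_scene_stack(scenario: SimScenario, profiles: Mapping[str, PhenologyProfile]):
    """Simulate one season of scenes over a parcel mosaic.

    Returns ``(stack, truth, cropland_mask, regions)`` where ``truth`` holds
    class ids (uint8, indices into :data:`CLASSES`), ``cropland_mask`` is a
    binary uint8 raster and ``regions`` labels four contiguous block
    "prefectures" (uint8, 0..3).
    """
    scenario.validate()
    h, w = scenario.grid_shape
    if (h // 2) * (w // 2) < 4:
        raise ValueError("grid too small: each of the 4 regions needs >= 4 pixels")
    ss = np.random.SeedSequence(scenario.seed)
    rng_parcel, rng_noise, rng_cloud = (np.random.default_rng(s) for s in ss.spawn(3))

    # --- landscape: rectangular single-class parcels -----------------------
    row_e = _parcel_edges(h, scenario.parcel_size, rng_parcel)
    col_e = _parcel_edges(w, scenario.parcel_size, rng_parcel)
    n_pr, n_pc = len(row_e) - 1, len(col_e) - 1
    n_parcels = n_pr * n_pc
    n_crop = int(round(scenario.cropland_fraction * n_parcels))
    class_counts = _allocate(n_crop, scenario.class_fractions)
    labels = np.concatenate([np.full(c, i, np.uint8) for i, c in enumerate(class_counts)]
                            + [np.full(n_parcels - n_crop, CLASS_IDS["others"], np.uint8)])
    is_crop = np.concatenate([np.ones(n_crop, bool), np.zeros(n_parcels - n_crop, bool)])
    perm = rng_parcel.permutation(n_parcels)
    labels, is_crop = labels[perm], is_crop[perm]

    row_id = np.repeat(np.arange(n_pr), np.diff(row_e))
    col_id = np.repeat(np.arange(n_pc), np.diff(col_e))
    parcel_of = row_id[:, None] * n_pc + col_id[None, :]
    truth = labels[parcel_of]
    cropland = is_crop[parcel_of].astype(np.uint8)

    regions = ((np.arange(h)[:, None] >= (h + 1) // 2).astype(np.uint8) * 2
               + (np.arange(w)[None, :] >= (w + 1) // 2).astype(np.uint8))

    # --- reflectance time series ------------------------------------------
    dates = np.asarray(scene_dates(scenario.revisit_days))
    t = len(dates)
    curves = np.empty((len(CLASSES), t, N_BANDS), np.float64)
    sds = np.empty((len(CLASSES), N_BANDS), np.float64)
    for ci, name in enumerate(CLASSES):
        prof = profiles[name]
        for bi, band in enumerate(BANDS):
            curves[ci, :, bi] = prof.value(band, dates)
            sds[ci, bi] = prof.noise_sd[band]
    clean = curves[truth]                       # (h, w, t, bands)
    noise = rng_noise.normal(0.0, 1.0, clean.shape) * sds[truth][:, :, None, :]
    data = np.clip(clean + noise, 0.0, 1.0).transpose(2, 3, 0, 1)  # (t, b, h, w)

    cloud_px = rng_cloud.random((t, h, w)) < scenario.cloud_prob
    flags = np.broadcast_to(cloud_px[:, None, :, :], (t, N_BANDS, h, w)).copy()
    if cloud_px.any():
        sig = _CLOUD_MEAN[:, None] + rng_cloud.normal(0.0, 0.03, (N_BANDS, int(cloud_px.sum())))
        sig[0] = np.maximum(sig[0], 0.4)        # bright Blue marks clouds
        sig = np.clip(sig, 0.0, 1.0)
        for bi in range(N_BANDS):
            band = data[:, bi, :, :]
            band[cloud_px] = sig[bi]
    stack = SceneStack(dates=list(map(int, dates)), data=data.astype(np.float32), cloud=flags)
    return stack, truth, cropland, regions


def simulate_samples(scenario: SimScenario, truth: np.ndarray,
                     n_per_class: int | Mapping[str, int] = 400,
                     train_fraction: float = 0.7) -> pd.DataFrame:
    """Draw labeled pixel samples stratified by class and split them 70/30.

    ``n_per_class`` may be a single count or a per-class mapping.  Sampling
    is without replacement from pixels of the matching truth class; the
    train/test split takes ``floor(n * train_fraction + 0.5)`` training
    samples per class.  Deterministic from ``scenario.seed``.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must be in (0, 1)")
    wanted = ({c: int(n_per_class) for c in CLASSES}
              if isinstance(n_per_class, (int, np.integer)) else dict(n_per_class))
    if min(wanted.values()) < 10:
        raise ValueError("need at least 10 samples per class")
    rng = np.random.default_rng(np.random.SeedSequence((scenario.seed, 0xA11CE)))
    rows = []
    for name in CLASSES:
        n = wanted[name]
        eligible = np.argwhere(truth == CLASS_IDS[name])
        if len(eligible) < n:
            raise ValueError(f"class {name!r}: only {len(eligible)} eligible pixels "
                             f"for {n} requested samples")
        pick = eligible[rng.choice(len(eligible), size=n, replace=False)]
        n_train = int(np.floor(n * train_fraction + 0.5))
        split = np.array(["train"] * n_train + ["test"] * (n - n_train))
        rng.shuffle(split)
        for (r, c), s in zip(pick, split):
            rows.append((int(r), int(c), scenario.year, name, s))
    return pd.DataFrame(rows, columns=["row", "col", "year", "class", "split"])


PIXEL_AREA_M2 = 900.0  # 30 m x 30 m


def simulate_reference_areas(truth: np.ndarray, regions: np.ndarray,
                             error_sd: float = 0.05, seed: int = 0,
                             year: int = 2019) -> pd.DataFrame:
    """Per-region maize reference areas (ha) with multiplicative noise.

    Emulates prefecture statistical-yearbook records: the true mapped maize
    area of each region is perturbed by a lognormal factor with the given
    s.d.; ``error_sd=0`` returns exact areas.
    """
    if truth.shape != regions.shape:
        raise ValueError("truth and region rasters must be aligned")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xCAFE)))
    recs = []
    for rid in np.unique(regions):
        px = int(np.sum((truth == MAIZE_ID) & (regions == rid)))
        area_ha = px * PIXEL_AREA_M2 / 10_000.0
        factor = float(rng.lognormal(mean=0.0, sigma=error_sd)) if error_sd > 0 else 1.0
        recs.append((int(rid), year, area_ha * factor))
    return pd.DataFrame(recs, columns=["region", "year", "area_ha"])
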