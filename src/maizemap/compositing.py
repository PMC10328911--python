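"""Cloud handling and two-month maximum-value compositing.

A season of 6-band scenes is reduced to a 4-period x 6-band feature cube per
pixel (24 values): scenes above a cloud-fraction threshold are dropped,
remaining cloud-contaminated observations are replaced from the nearest
clean date for the same pixel and band, and each two-month window keeps the
per-band maximum over the valid observations.  The maximum-value composite
(MVC) suppresses residual clouds and shadows — a contaminated bright-Blue
observation left unhandled is visible in the composite, which is exactly how
the cloud stages are tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .calendar import DEFAULT_PERIODS, N_BANDS

logger = logging.getLogger(__name__)


@dataclass
class SceneStack:
    """Time-ordered scenes: ``data`` (T, 6, H, W) float32 reflectance,
    ``cloud`` (T, 6, H, W) bool flags (True = contaminated / invalid)."""

    dates: list[int]
    data: np.ndarray
    cloud: np.ndarray

    def __post_init__(self) -> None:
        if self.data.shape != self.cloud.shape:
            raise ValueError("data and cloud flag arrays must share shape")
        if self.data.ndim != 4 or self.data.shape[1] != N_BANDS:
            raise ValueError(f"expected (T, {N_BANDS}, H, W) stack, got {self.data.shape}")
        if len(self.dates) != self.data.shape[0]:
            raise ValueError("one date per scene required")
        if np.any(np.diff(self.dates) <= 0):
            raise ValueError("scene dates must be strictly increasing")

    @property
    def n_scenes(self) -> int:
        return len(self.dates)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.data.shape[2:]

    def scene_cloud_fraction(self) -> np.ndarray:
        """Per scene, the fraction of pixels with any band flagged."""
        return self.cloud.any(axis=1).mean(axis=(1, 2))


@dataclass
class CompositeFeatures:
    """Per-pixel 4x6 MVC features: ``values`` (4, 6, H, W) float32 with NaN
    where invalid, ``valid`` (4, H, W) bool period-validity flags."""

    values: np.ndarray
    valid: np.ndarray
    periods: tuple[tuple[int, int], ...] = DEFAULT_PERIODS

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.values.shape[2:]

    @property
    def all_periods_valid(self) -> np.ndarray:
        return self.valid.all(axis=0)


def drop_cloudy_scenes(stack: SceneStack, max_cloud_fraction: float = 0.8,
                       periods=DEFAULT_PERIODS) -> SceneStack:
    """Remove whole scenes whose cloud fraction exceeds the threshold.

    Raises if any compositing period would be left without a scene.
    """
    if not (0.0 <= max_cloud_fraction <= 1.0):
        raise ValueError("max_cloud_fraction must be in [0, 1]")
    frac = stack.scene_cloud_fraction()
    keep = frac <= max_cloud_fraction
    dates = [d for d, k in zip(stack.dates, keep) if k]
    for lo, hi in periods:
        if not any(lo <= d <= hi for d in dates):
            raise ValueError(
                f"no scene with cloud fraction <= {max_cloud_fraction} left in "
                f"period [{lo}, {hi}]"
            )
    return SceneStack(dates=dates, data=stack.data[keep], cloud=stack.cloud[keep])


def replace_cloudy_bands(stack: SceneStack) -> SceneStack:
    """Fill flagged observations from the nearest-in-time clean date.

    Per (pixel, band), each cloud-flagged value is replaced by the value at
    the temporally closest date where that pixel/band is clean (ties broken
    toward the earlier date) and its flag is cleared.  Observations with no
    clean date anywhere in the stack stay flagged and are later excluded
    from compositing; their count is logged.
    """
    dates = np.asarray(stack.dates)
    data = stack.data.copy()
    cloud = stack.cloud.copy()
    t = stack.n_scenes
    for ti in range(t):
        need = stack.cloud[ti].copy()
        if not need.any():
            continue
        # candidate donors ordered by |dt|, earlier date first on ties
        order = sorted((s for s in range(t) if s != ti),
                       key=lambda s: (abs(dates[s] - dates[ti]), dates[s]))
        for s in order:
            if not need.any():
                break
            donor = ~stack.cloud[s] & need
            if donor.any():
                data[ti][donor] = stack.data[s][donor]
                cloud[ti][donor] = False
                need &= ~donor
    n_left = int(cloud.sum())
    if n_left:
        logger.info("replace_cloudy_bands: %d observations had no clean donor "
                    "and remain invalid", n_left)
    return SceneStack(dates=list(stack.dates), data=data, cloud=cloud)


def max_value_composite(stack: SceneStack,
                        periods=DEFAULT_PERIODS) -> CompositeFeatures:
    """Per-band maximum over valid observations in each two-month window."""
    dates = np.asarray(stack.dates)
    h, w = stack.grid_shape
    values = np.full((len(periods), N_BANDS, h, w), np.nan, np.float32)
    valid = np.zeros((len(periods), h, w), bool)
    for pi, (lo, hi) in enumerate(periods):
        in_win = (dates >= lo) & (dates <= hi)
        if not in_win.any():
            raise ValueError(f"no scenes fall in period [{lo}, {hi}]")
        vals = np.where(~stack.cloud[in_win], stack.data[in_win], -np.inf)
        best = vals.max(axis=0)                         # (bands, h, w)
        ok_band = np.isfinite(best)                     # >=1 valid obs per band
        values[pi][ok_band] = best[ok_band]
        valid[pi] = ok_band.all(axis=0)
    return CompositeFeatures(values=values, valid=valid, periods=tuple(periods))


def flatten_features(composite: CompositeFeatures) -> np.ndarray:
    """(H, W, 24) period-major feature vectors: period 1 bands 1–6, ..."""
    p, b, h, w = composite.values.shape
    return composite.values.transpose(2, 3, 0, 1).reshape(h, w, p * b)


def unflatten_features(flat: np.ndarray, valid: np.ndarray | None = None,
                       periods=DEFAULT_PERIODS) -> CompositeFeatures:
    """Inverse of :func:`flatten_features`."""
    h, w, d = flat.shape
    n_p = len(periods)
    if d != n_p * N_BANDS:
        raise ValueError(f"expected {n_p * N_BANDS}-dim features, got {d}")
    values = flat.reshape(h, w, n_p, N_BANDS).transpose(2, 3, 0, 1).astype(np.float32)
    if valid is None:
        valid = np.isfinite(values).all(axis=1)
    return CompositeFeatures(values=values, valid=valid, periods=tuple(periods))


def sample_sequences(composite: CompositeFeatures, rows, cols) -> np.ndarray:
    """Extract (N, 4, 6) model-input sequences at pixel locations."""
    return composite.values[:, :, rows, cols].transpose(2, 0, 1)


def append_indices(composite: CompositeFeatures) -> CompositeFeatures:
    """Stack NDVI/EVI/NDWI per period as channels 7–9 (ablation input).

    The final model uses bands only — stacking the indices was evaluated and
    did not improve accuracy — but the augmented input stays available
    behind a config flag so the ablation can be rerun.
    """
    b = composite.values  # (P, 6, H, W)
    ndvi, evi, ndwi = compute_indices(b[:, 0], b[:, 1], b[:, 2], b[:, 3])
    values = np.concatenate(
        [b, np.stack([ndvi, evi, ndwi], axis=1).astype(np.float32)], axis=1)
    return CompositeFeatures(values=values, valid=composite.valid.copy(),
                             periods=composite.periods)


def compute_indices(blue, green, red, nir, swir1=None, swir2=None):
    """NDVI, EVI and NDWI from band reflectances.

    NDVI = (NIR - Red)/(NIR + Red); EVI = 2.5 (NIR - Red)/(NIR + 6 Red -
    7.5 Blue + 1); NDWI = (Green - NIR)/(Green + NIR).  Zero denominators
    yield NaN, never an exception.  SWIR bands are accepted for signature
    symmetry but unused.
    """
    blue, green, red, nir = (np.asarray(a, float) for a in (blue, green, red, nir))
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = np.where(nir + red != 0, (nir - red) / (nir + red), np.nan)
        evi_den = nir + 6.0 * red - 7.5 * blue + 1.0
        evi = np.where(evi_den != 0, 2.5 * (nir - red) / evi_den, np.nan)
        ndwi = np.where(green + nir != 0, (green - nir) / (green + nir), np.nan)
    return ndvi, evi, ndwi
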