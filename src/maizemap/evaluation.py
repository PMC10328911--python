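"""Map validation: confusion matrices, UA/PA/F1/OA, and area consistency.

Conventions follow standard thematic-map accuracy assessment: the confusion
matrix has truth on rows and prediction on columns; user's accuracy (UA) is
the column-wise correct fraction (precision of the mapped class), producer's
accuracy (PA) the row-wise correct fraction (recall), F1 their harmonic
mean, and overall accuracy (OA) the trace over the total.  Area consistency
between mapped and reference (yearbook-style) areas is summarised by the
squared Pearson correlation R^2; agreement with the identity line
(1 - SSE/SST) is offered as a secondary statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .classifier import NODATA_BYTE
from .simulate import PIXEL_AREA_M2


@dataclass
class ConfusionMatrix:
    """Square count matrix, rows = truth, columns = prediction."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if len(self.classes) != self.counts.shape[0]:
            raise ValueError("one class label per matrix row required")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))


def confusion_matrix(truth: Sequence, predicted: Sequence,
                     classes: Sequence[str]) -> ConfusionMatrix:
    """Count matrix entry (A, B) = number of truth-A samples predicted B."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError("truth and prediction label lists must match in length")
    idx = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    try:
        ti = np.array([idx[t] for t in truth.tolist()])
        pi = np.array([idx[p] for p in predicted.tolist()])
    except KeyError as exc:
        raise ValueError(f"unknown label {exc.args[0]!r}") from None
    counts = np.bincount(ti * k + pi, minlength=k * k).reshape(k, k)
    return ConfusionMatrix(counts, tuple(classes))


def binarize_matrix(matrix: ConfusionMatrix, positive_class: str) -> ConfusionMatrix:
    """Collapse all non-positive classes into one; counts are conserved."""
    if positive_class not in matrix.classes:
        raise ValueError(f"{positive_class!r} not among {matrix.classes}")
    pos = matrix.classes.index(positive_class)
    neg = [i for i in range(len(matrix.classes)) if i != pos]
    m = matrix.counts
    counts = np.array([
        [m[pos, pos], m[pos, neg].sum()],
        [m[neg, pos].sum(), m[np.ix_(neg, neg)].sum()],
    ])
    return ConfusionMatrix(counts, (positive_class, f"non-{positive_class}"))


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up, matching how printed tables are rounded."""
    return float(Decimal(repr(float(x))).quantize(Decimal(1).scaleb(-ndigits),
                                                  rounding=ROUND_HALF_UP))


def accuracy_metrics(matrix: ConfusionMatrix) -> pd.DataFrame:
    """Per-class UA/PA/F1 and overall OA, full precision plus a rounding helper.

    Returns a tidy frame with one row per class (columns ``class, ua, pa,
    f1``) plus a final ``__overall__`` row carrying OA.  Undefined ratios
    (empty row or column) are NaN.
    """
    m = matrix.counts.astype(float)
    col = m.sum(axis=0)
    row = m.sum(axis=1)
    diag = np.diag(m)
    with np.errstate(divide="ignore", invalid="ignore"):
        ua = np.where(col > 0, diag / col, np.nan)
        pa = np.where(row > 0, diag / row, np.nan)
        f1 = np.where(ua + pa > 0, 2 * ua * pa / (ua + pa), np.nan)
    oa = diag.sum() / m.sum() if m.sum() > 0 else np.nan
    rows = [{"class": c, "ua": ua[i], "pa": pa[i], "f1": f1[i], "oa": np.nan}
            for i, c in enumerate(matrix.classes)]
    rows.append({"class": "__overall__", "ua": np.nan, "pa": np.nan,
                 "f1": np.nan, "oa": oa})
    return pd.DataFrame(rows)


def area_by_region(maize_map: np.ndarray, regions: np.ndarray | None = None,
                   pixel_area_m2: float = PIXEL_AREA_M2,
                   nodata: int = NODATA_BYTE, year: int = 2019) -> pd.DataFrame:
    """Mapped maize area per region in hectares (nodata pixels excluded)."""
    maize_map = np.asarray(maize_map)
    if regions is None:
        regions = np.zeros(maize_map.shape, np.uint8)
    if regions.shape != maize_map.shape:
        raise ValueError("map and region rasters must be aligned")
    is_maize = (maize_map == 1) & (maize_map != nodata)
    recs = [(int(rid), year,
             float(np.sum(is_maize & (regions == rid))) * pixel_area_m2 / 10_000.0)
            for rid in np.unique(regions)]
    return pd.DataFrame(recs, columns=["region", "year", "mapped_area_ha"])


def r_squared(mapped: Sequence[float], reference: Sequence[float]) -> float:
    """Squared Pearson correlation between mapped and reference areas."""
    mapped = np.asarray(mapped, float)
    reference = np.asarray(reference, float)
    if mapped.size != reference.size or mapped.size < 3:
        raise ValueError("need >= 3 paired area records")
    if np.ptp(mapped) == 0 or np.ptp(reference) == 0:
        return float("nan")
    # centered-sum form: exact 1.0 when the two vectors agree elementwise
    dx = mapped - mapped.mean()
    dy = reference - reference.mean()
    sxy = float(np.sum(dx * dy))
    return sxy * sxy / (float(np.sum(dx * dx)) * float(np.sum(dy * dy)))


def identity_r_squared(mapped: Sequence[float], reference: Sequence[float]) -> float:
    """1 - SSE/SST against the identity line (secondary agreement statistic)."""
    mapped = np.asarray(mapped, float)
    reference = np.asarray(reference, float)
    sst = np.sum((reference - reference.mean()) ** 2)
    if sst == 0:
        return float("nan")
    return float(1.0 - np.sum((mapped - reference) ** 2) / sst)
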