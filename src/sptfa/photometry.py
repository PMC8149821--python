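"""TIRF/epifluorescence photometry: membrane fraction and FA enrichment.

Both metrics use pixel means.  Background is the equal-weight mean of the
per-ROI means over at least three cell-free regions, and the same cell and
background regions are applied to both modalities of a pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

logger = logging.getLogger("sptfa")


class InvalidMeasurementError(ValueError):
    """A photometric ratio has a degenerate (<= 0) denominator."""


@dataclass
class IntensityMeasurement:
    fluo_tirf: float
    bg_tirf: float
    fluo_epi: float
    bg_epi: float

    @property
    def n_membrane(self) -> float:
        return self.fluo_tirf / self.bg_tirf

    @property
    def n_total(self) -> float:
        return self.fluo_epi / self.bg_epi

    @property
    def f_membrane(self) -> float:
        return self.n_membrane / self.n_total


@dataclass
class EnrichmentMeasurement:
    mean_in_fa: float
    mean_out_fa: float
    mean_bg: float

    @property
    def enrichment(self) -> float:
        return (self.mean_in_fa - self.mean_bg) / (self.mean_out_fa - self.mean_bg)


def _mean_roi(image: np.ndarray, roi: np.ndarray, saturation=None) -> float:
    vals = image[roi]
    if saturation is not None:
        sat = vals >= saturation
        if np.any(sat):
            logger.warning("excluding %d saturated pixels", int(sat.sum()))
            vals = vals[~sat]
    if vals.size == 0:
        raise InvalidMeasurementError("ROI empty after saturation exclusion")
    return float(vals.mean())


def _pooled_background(image: np.ndarray, bg_rois: Sequence[np.ndarray],
                       saturation=None) -> float:
    # equal-weight mean of ROI means, independent of ROI areas
    return float(np.mean([_mean_roi(image, roi, saturation) for roi in bg_rois]))


def _check_bg_rois(bg_rois, cell_mask, shape):
    if len(bg_rois) < 3:
        raise ValueError("need at least 3 background ROIs")
    for roi in bg_rois:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != shape:
            raise ValueError("background ROI shape mismatch")
        if np.any(roi & cell_mask):
            raise ValueError("background ROI overlaps the cell mask")


def membrane_fraction(
    tirf_image: np.ndarray,
    epi_image: np.ndarray,
    cell_mask: np.ndarray,
    bg_rois: Sequence[np.ndarray],
    saturation=None,
) -> IntensityMeasurement:
    """Membrane fraction from a paired TIRF/epi acquisition.

    ``f_membrane = (Fluo_TIRF / BG_TIRF) / (Fluo_epi / BG_epi)`` with the
    same cell region and the same >= 3 background ROIs in both images.
    """
    tirf_image = np.asarray(tirf_image, dtype=float)
    epi_image = np.asarray(epi_image, dtype=float)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if tirf_image.shape != epi_image.shape or tirf_image.shape != cell_mask.shape:
        raise ValueError("images and cell mask must share shape")
    _check_bg_rois(bg_rois, cell_mask, tirf_image.shape)
    bg_t = _pooled_background(tirf_image, bg_rois, saturation)
    bg_e = _pooled_background(epi_image, bg_rois, saturation)
    if bg_t <= 0 or bg_e <= 0:
        raise InvalidMeasurementError("background must be > 0")
    return IntensityMeasurement(
        fluo_tirf=_mean_roi(tirf_image, cell_mask, saturation),
        bg_tirf=bg_t,
        fluo_epi=_mean_roi(epi_image, cell_mask, saturation),
        bg_epi=bg_e,
    )


def fa_enrichment(
    image: np.ndarray,
    fa_mask: np.ndarray,
    cell_mask: np.ndarray,
    bg_rois: Sequence[np.ndarray],
    saturation=None,
) -> EnrichmentMeasurement:
    """Background-subtracted in-FA / out-FA intensity ratio.

    ``(mean inside FA - mean background) / (mean outside FA - mean
    background)`` where outside-FA is the cell mask minus the FA mask.  A
    denominator <= 0 raises :class:`InvalidMeasurementError` rather than
    being clipped.
    """
    image = np.asarray(image, dtype=float)
    fa_mask = np.asarray(fa_mask, dtype=bool)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if np.any(fa_mask & ~cell_mask):
        raise ValueError("fa_mask must be a subset of cell_mask")
    _check_bg_rois(bg_rois, cell_mask, image.shape)
    out_mask = cell_mask & ~fa_mask
    if not np.any(fa_mask) or not np.any(out_mask):
        raise ValueError("empty FA or outside-FA region")
    m = EnrichmentMeasurement(
        mean_in_fa=_mean_roi(image, fa_mask, saturation),
        mean_out_fa=_mean_roi(image, out_mask, saturation),
        mean_bg=_pooled_background(image, bg_rois, saturation),
    )
    if m.mean_out_fa - m.mean_bg <= 0:
        raise InvalidMeasurementError(
            "outside-FA mean must be strictly above background"
        )
    return m
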