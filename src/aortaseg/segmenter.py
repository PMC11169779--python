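"""Pluggable segmentation stage.

The deep-learning segmentation network is abstracted behind a small
contract: any callable that maps a normalized ImageVolume to a
LabelVolume on the same geometry and declares a name/version for
provenance.  The shipped :class:`ReferenceSegmenter` is a deterministic
threshold-and-geometry segmenter tuned to the phantom's HU palette so
the entire post-segmentation pipeline is exercisable without trained
weights or patient data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .volume import (
    LABEL_AA,
    LABEL_CALCIFICATION,
    LABEL_LEAFLET,
    LABEL_LV,
    ImageVolume,
    LabelVolume,
)


@dataclass(frozen=True)
class ReferenceSegmenter:
    """Threshold/morphology segmenter for phantom-palette images.

    Expects intensities on the normalized [0, 1] scale (clip window
    0..1200 HU, so blood ~ 0.33, leaflets ~ 0.125, calcium ~ 0.83,
    background ~ 0).  Calcification and blood are taken from raw
    intensity bands; the low-contrast leaflet band additionally uses a
    3x3x3 median-filtered image as its core (robust to noise) augmented
    with raw-band voxels adjacent to that core (recovers sheet rims the
    median filter erodes).  Candidates bordering the background are
    discarded to suppress partial-volume shells at the blood/air
    interface.  The blood pool is split into AA and LV by a plane
    orthogonal to its principal axis, placed just below the leaflets;
    the side holding more blood is the aorta.
    """

    name: str = "reference"
    version: str = "1.0"
    calc_threshold: float = 0.6
    blood_low: float = 0.24
    blood_high: float = 0.48
    leaflet_low: float = 0.06
    leaflet_high: float = 0.21
    background_high: float = 0.05

    def __call__(self, image: ImageVolume) -> LabelVolume:
        data = np.asarray(image.data, dtype=np.float64)
        if data.min() < -1e-6 or data.max() > 1 + 1e-6:
            raise ValidationError("reference segmenter expects a normalized [0,1] image")
        labels = np.zeros(data.shape, dtype=np.uint8)

        calc = data >= self.calc_threshold
        blood = (data > self.blood_low) & (data <= self.blood_high)

        med = ndimage.median_filter(data, size=3)
        core = (med > self.leaflet_low) & (med <= self.leaflet_high)
        raw_band = (data > self.leaflet_low) & (data <= self.leaflet_high)
        grown = raw_band & ndimage.binary_dilation(
            core, structure=ndimage.generate_binary_structure(3, 3)
        )
        leaflet = (core | grown) & ~blood & ~calc
        # drop partial-volume shell along the air interface
        background = med <= self.background_high
        near_bg = ndimage.binary_dilation(
            background, structure=ndimage.generate_binary_structure(3, 1)
        )
        leaflet &= ~near_bg

        if blood.any():
            spacing = np.asarray(image.spacing)
            bcoords = np.argwhere(blood) * spacing
            bmean = bcoords.mean(axis=0)
            centered = bcoords - bmean
            _, _, vt = np.linalg.svd(centered, full_matrices=False)
            axis = vt[0]
            s = centered @ axis
            if leaflet.any():
                s_leaf = (np.argwhere(leaflet) * spacing - bmean) @ axis
                # orient the axis toward the aorta (the heavier side of the valve)
                above = (s > np.median(s_leaf)).sum()
                if above < len(s) - above:
                    axis, s, s_leaf = -axis, -s, -s_leaf
                plane = np.percentile(s_leaf, 5.0) - 1.0
            else:
                plane = np.median(s)
            aa = np.zeros_like(blood)
            lv = np.zeros_like(blood)
            bidx = np.argwhere(blood)
            up = s >= plane
            aa[tuple(bidx[up].T)] = True
            lv[tuple(bidx[~up].T)] = True
            labels[aa] = LABEL_AA
            labels[lv] = LABEL_LV
        labels[leaflet] = LABEL_LEAFLET
        labels[calc] = LABEL_CALCIFICATION
        return LabelVolume(labels, image.spacing, image.origin, image.orientation)


SEGMENTERS = {"reference": ReferenceSegmenter}


def get_segmenter(name: str, params: dict | None = None):
    if name not in SEGMENTERS:
        raise ValidationError(f"unknown segmenter {name!r}; available: {sorted(SEGMENTERS)}")
    return SEGMENTERS[name](**(params or {}))
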