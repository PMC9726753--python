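"""Disk and annulus region-of-interest specifications.

Pixel indices are 0-based and row-major; masks are inclusive
(a pixel belongs to the ROI when its centre lies within the shape).
Annuli mirror the membrane-hugging ROIs drawn around cell outlines,
disks serve for somatic or background regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["DiskROI", "AnnulusROI"]


@dataclass(frozen=True)
class DiskROI:
    row: float
    col: float
    radius: float

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        return (rr - self.row) ** 2 + (cc - self.col) ** 2 <= self.radius**2


@dataclass(frozen=True)
class AnnulusROI:
    row: float
    col: float
    r_inner: float
    r_outer: float

    def __post_init__(self) -> None:
        if not 0 <= self.r_inner < self.r_outer:
            raise ValueError("annulus requires 0 <= r_inner < r_outer")

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        d2 = (rr - self.row) ** 2 + (cc - self.col) ** 2
        return (d2 >= self.r_inner**2) & (d2 <= self.r_outer**2)
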