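"""Shared domain types and constants.

The four gastric-biopsy categories of the WHO (5th ed.) grading, in
increasing order of malignancy risk, and the label-mask convention used
throughout the package:

====  =====================
mask  meaning
====  =====================
0     background (no tissue)
1     NED tissue (benign)
2     LGD lesion
3     HGD lesion
4     IIN lesion
====  =====================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Category names ordered by increasing severity.
CATEGORIES: tuple[str, ...] = ("NED", "LGD", "HGD", "IIN")

#: Categories regarded as positive (abnormal) in the screening mode.
POSITIVE_CATEGORIES: tuple[str, ...] = ("LGD", "HGD", "IIN")

#: Mask label carried by lesion pixels of each positive category.
LESION_LABEL: dict[str, int] = {"LGD": 2, "HGD": 3, "IIN": 4}

BACKGROUND_LABEL = 0
TISSUE_LABEL = 1


def category_index(category: str) -> int:
    """Severity rank of a category (NED=0 ... IIN=3)."""
    try:
        return CATEGORIES.index(category)
    except ValueError:
        raise ValueError(f"unknown category {category!r}; expected one of {CATEGORIES}") from None


@dataclass
class SlideImage:
    """An RGB slide raster together with its provenance.

    Attributes
    ----------
    slide_id:
        Unique identifier within a dataset.
    image:
        ``(H, W, 3)`` uint8 RGB raster.
    center:
        Identifier of the originating center (scanner/stain site).
    category:
        Ground-truth slide label when known, else ``None``.
    mask:
        Optional ``(H, W)`` uint8 label mask (see module docstring).
    """

    slide_id: str
    image: np.ndarray
    center: str = "C0"
    category: str | None = None
    mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        img = np.asarray(self.image)
        if img.ndim != 3 or img.shape[2] != 3:
            raise ValueError("image must be an (H, W, 3) RGB array")
        if self.mask is not None and self.mask.shape != img.shape[:2]:
            raise ValueError("mask shape must match image height/width")

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]
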