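"""2-D grayscale raster container and file I/O.

The package works on single-channel intensity grids such as one slice of a
joint MRI series.  Pixel values are held as floats internally; the declared
bit depth only matters on write (quantisation) and for metrics that need the
dynamic range ``MAX = 2**bit_depth - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageRaster", "read_raster", "write_raster"]


@dataclass(frozen=True)
class ImageRaster:
    """A 2-D grayscale image.

    Parameters
    ----------
    pixels : ndarray, shape (height, width)
        Intensities, stored as float64.  ``x`` indexes columns, ``y`` rows,
        with ``y`` increasing downward.
    bit_depth : int
        Declared bit depth; on write values are clipped and rounded to
        ``[0, 2**bit_depth - 1]``.
    """

    pixels: np.ndarray
    bit_depth: int = 8
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError(
                f"pixels must be a non-empty 2-D grid, got shape {arr.shape}"
            )
        if not (1 <= int(self.bit_depth) <= 32):
            raise ValueError(f"bit_depth must be in [1, 32], got {self.bit_depth}")
        object.__setattr__(self, "pixels", arr)
        object.__setattr__(self, "bit_depth", int(self.bit_depth))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def max_value(self) -> int:
        """Dynamic range ceiling, ``2**bit_depth - 1``."""
        return (1 << self.bit_depth) - 1

    def quantised(self) -> np.ndarray:
        """Pixels clipped and rounded to the declared integer range."""
        q = np.clip(np.rint(self.pixels), 0, self.max_value)
        dtype = np.uint8 if self.bit_depth <= 8 else (
            np.uint16 if self.bit_depth <= 16 else np.uint32
        )
        return q.astype(dtype)

    def with_pixels(self, pixels: np.ndarray) -> "ImageRaster":
        return ImageRaster(pixels, self.bit_depth, dict(self.meta))


def read_raster(path) -> ImageRaster:
    """Read a PNG (8/16-bit grayscale) or NIfTI raster.

    The format is inferred from the extension.  NIfTI volumes must be 2-D
    (or have trailing singleton dimensions).  A truncated or unreadable file
    raises ``ValueError`` without returning a partial raster.
    """
    p = str(path)
    low = p.lower()
    if low.endswith(".png"):
        from PIL import Image

        try:
            with Image.open(p) as im:
                im.load()
                if im.mode not in ("L", "I", "I;16", "P", "1"):
                    im = im.convert("L")
                arr = np.asarray(im, dtype=np.float64)
        except Exception as exc:  # pillow raises several types on bad files
            raise ValueError(f"cannot read PNG raster {p!r}: {exc}") from exc
        depth = 16 if arr.max(initial=0) > 255 else 8
        return ImageRaster(arr, bit_depth=depth)
    if low.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        try:
            img = nib.load(p)
            data = np.asarray(img.dataobj, dtype=np.float64)
        except Exception as exc:
            raise ValueError(f"cannot read NIfTI raster {p!r}: {exc}") from exc
        data = np.squeeze(data)
        if data.ndim != 2:
            raise ValueError(
                f"NIfTI raster {p!r} is {data.ndim}-D after squeeze; need 2-D"
            )
        depth = int(img.header.get("cal_max", 0)) or 0
        bit_depth = 16 if (depth > 255 or data.max(initial=0) > 255) else 8
        return ImageRaster(data, bit_depth=bit_depth)
    raise ValueError(
        f"unsupported raster format for {p!r}; supported: .png, .nii, .nii.gz"
    )


def write_raster(raster: ImageRaster, path) -> None:
    """Write a raster as PNG (bit depth <= 16) or NIfTI (any depth).

    The write is lossless for integer-valued pixels within the declared
    range, so write-then-read round-trips bit-identically.
    """
    p = str(path)
    low = p.lower()
    if low.endswith(".png"):
        from PIL import Image

        if raster.bit_depth > 16:
            raise ValueError(
                f"PNG supports bit depth <= 16, raster has {raster.bit_depth}; "
                "use NIfTI (.nii) instead"
            )
        q = raster.quantised()
        mode = "L" if raster.bit_depth <= 8 else "I;16"
        Image.fromarray(q, mode=mode).save(p)
        return
    if low.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.Nifti1Image(raster.quantised(), affine=np.eye(4))
        img.header["cal_max"] = raster.max_value
        nib.save(img, p)
        return
    raise ValueError(
        f"unsupported raster format for {p!r}; supported: .png, .nii, .nii.gz"
    )
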