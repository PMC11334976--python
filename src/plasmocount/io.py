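"""Reading, writing and projecting RGB darkfield image stacks.

A darkfield acquisition is a z-scan: several RGB slices of the same field of
view at different focal planes. The rest of the pipeline operates on a single
colour image obtained by collapsing the stack with a per-pixel, per-channel
maximum-intensity projection, which preserves the peak brightness of
diffraction-limited spots regardless of the slice they are focused in.

Conventions used throughout the package:

* pixel coordinates are 0-based ``(row, col)``, pixel-centre addressing;
* pixel values stay in native unsigned-integer units until feature
  extraction scales them to ``[0, 1]`` by the bit depth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile

from .errors import InvalidInputError, UnsupportedFormatError

__all__ = [
    "RGBStack",
    "ProjectedImage",
    "read_stack",
    "project_stack",
    "write_stack",
    "write_projection",
]

_ALLOWED_DEPTHS = (8, 16)


def _infer_bit_depth(data: np.ndarray) -> int:
    if data.dtype == np.uint8:
        return 8
    if data.dtype == np.uint16:
        # 16-bit containers sometimes hold 8-bit data; keep the container depth
        return 16
    raise UnsupportedFormatError(
        f"unsupported pixel dtype {data.dtype}; expected uint8 or uint16"
    )


@dataclass
class RGBStack:
    """A z-stack of RGB slices, axis order ``(slice, row, col, channel)``."""

    data: np.ndarray
    bit_depth: int
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4 or self.data.shape[-1] != 3:
            raise InvalidInputError(
                f"stack must have shape (slice, row, col, 3); got {self.data.shape}"
            )
        if self.data.shape[0] < 1:
            raise InvalidInputError("stack must contain at least one slice")
        if self.bit_depth not in _ALLOWED_DEPTHS:
            raise InvalidInputError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if self.data.dtype not in (np.uint8, np.uint16):
            raise InvalidInputError(
                f"stack dtype must be uint8/uint16, got {self.data.dtype}"
            )
        if self.data.size and int(self.data.max()) > self.max_value:
            raise InvalidInputError(
                f"pixel values exceed 2^{self.bit_depth} - 1"
            )

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1


@dataclass
class ProjectedImage:
    """A single RGB image, axis order ``(row, col, channel)``."""

    data: np.ndarray
    bit_depth: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[-1] != 3:
            raise InvalidInputError(
                f"image must have shape (row, col, 3); got {self.data.shape}"
            )
        if self.bit_depth not in _ALLOWED_DEPTHS:
            raise InvalidInputError(f"bit_depth must be 8 or 16, got {self.bit_depth}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1


def read_stack(path: str | Path, pixel_size_um: float | None = None) -> RGBStack:
    """Read a single- or multi-page TIFF (or a single PNG) as an :class:`RGBStack`.

    Pixel values are preserved bit-exactly; the slice axis length equals the
    page count. Greyscale or CMYK inputs are rejected with an error naming
    the channel count found.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        data = iio.imread(path)
        if data.ndim == 3 and data.shape[-1] == 4:  # drop PNG alpha
            data = data[..., :3]
    data = np.asarray(data)
    if data.ndim == 3 and data.shape[-1] in (3, 4):
        data = data[np.newaxis, ...]
    if data.ndim != 4:
        nchan = 1 if data.ndim <= 3 else data.shape[-1]
        raise UnsupportedFormatError(
            f"expected RGB image(s); found {nchan} channel(s) in {path.name}"
        )
    if data.shape[-1] != 3:
        raise UnsupportedFormatError(
            f"expected 3 colour channels; found {data.shape[-1]} in {path.name}"
        )
    return RGBStack(data=data, bit_depth=_infer_bit_depth(data), pixel_size_um=pixel_size_um)


def project_stack(stack: RGBStack, method: str = "max") -> ProjectedImage:
    """Collapse a z-stack to one image.

    ``method="max"`` takes the per-pixel, per-channel maximum over slices,
    the standard projection for darkfield spot stacks. The output dtype
    matches the input.
    """
    if method != "max":
        raise InvalidInputError(f"unknown projection method {method!r}; supported: 'max'")
    if stack.n_slices < 1:
        raise InvalidInputError("cannot project an empty stack")
    projected = stack.data.max(axis=0)
    return ProjectedImage(
        data=projected,
        bit_depth=stack.bit_depth,
        provenance={"method": "max", "n_slices": int(stack.n_slices)},
    )


def write_stack(stack: RGBStack, path: str | Path) -> None:
    """Write a stack as a multi-page TIFF (one page per slice)."""
    tifffile.imwrite(Path(path), stack.data, photometric="rgb")


def write_projection(image: ProjectedImage, path: str | Path) -> None:
    """Write a projected image as TIFF or PNG, with a JSON provenance sidecar."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.data, photometric="rgb")
    else:
        iio.imwrite(path, image.data)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"bit_depth": image.bit_depth, **image.provenance}))
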