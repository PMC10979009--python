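"""Multichannel image stacks and TIFF I/O.

The in-memory container is a plain ``(channel, z, y, x)`` float array plus the
physical pixel size.  Positions follow the usual image convention: ``(x, y)``
in pixel units with pixel *centers* at integer coordinates, arrays indexed
``[y, x]``, physical positions in nanometers obtained by multiplying with
``pixel_size_nm``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

from .errors import FormatError, InputError

# Canonical channel labels used throughout the package.
DNA = "DNA"
PARB = "PARB"
SMC = "SMC"
CELL = "CELL"
TER = "TER"


@dataclass
class ImageStack:
    """A multichannel, optionally z-stacked fluorescence image.

    Parameters
    ----------
    pixels
        Array of shape ``(n_channels, n_z, ny, nx)``; finite, non-negative.
    channel_labels
        One label per channel, e.g. ``["DNA", "PARB", "SMC", "CELL"]``.
    pixel_size_nm
        Physical size of one pixel (nm/px).
    z_step_nm
        Spacing between z planes; ``None`` for single-plane stacks.
    """

    pixels: np.ndarray
    channel_labels: list[str] = field(default_factory=list)
    pixel_size_nm: float = 65.35
    z_step_nm: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 4:
            raise InputError(
                f"pixels must be (channel, z, y, x); got ndim={self.pixels.ndim}"
            )
        if len(self.channel_labels) != self.pixels.shape[0]:
            raise InputError(
                f"{len(self.channel_labels)} channel labels for "
                f"{self.pixels.shape[0]} channels"
            )
        if not self.pixel_size_nm > 0:
            raise InputError("pixel_size_nm must be > 0")
        if not np.all(np.isfinite(self.pixels)):
            raise InputError("pixel values must be finite")
        if np.any(self.pixels < 0):
            raise InputError("pixel values must be >= 0")

    # -- accessors ---------------------------------------------------------

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_z(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.pixels.shape[2], self.pixels.shape[3]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise InputError(
                f"channel {label!r} not in stack (have {self.channel_labels})"
            ) from None

    def channel(self, label: str) -> np.ndarray:
        """Return the ``(z, y, x)`` sub-array for one channel."""
        return self.pixels[self.channel_index(label)]

    def plane(self, label: str, z: int = 0) -> np.ndarray:
        return self.pixels[self.channel_index(label), z]

    def with_pixels(self, pixels: np.ndarray) -> "ImageStack":
        return replace(self, pixels=pixels)


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as a single multipage TIFF.

    The full (channel, z, y, x) float64 array is stored page-per-plane so the
    round trip through :func:`read_stack` is bit exact; channel labels, pixel
    size and z step go into the image description as JSON.
    """
    meta = {
        "channel_labels": stack.channel_labels,
        "pixel_size_nm": stack.pixel_size_nm,
        "z_step_nm": stack.z_step_nm,
        "axes": "CZYX",
    }
    tifffile.imwrite(str(path), stack.pixels, description=json.dumps(meta))


def read_stack(
    path,
    channel_map: dict[str, int] | None = None,
    pixel_size_nm: float | None = None,
    z_step_nm: float | None = None,
) -> ImageStack:
    """Read a TIFF into an :class:`ImageStack` with axes ``(C, Z, Y, X)``.

    Axis interpretation: 2-D files become a single-channel single-plane
    stack; 3-D files are treated as ``(C, Y, X)`` with channels picked via
    ``channel_map`` (label -> axis-0 index); 4-D files as ``(C, Z, Y, X)``.
    Pixel size comes from the configuration (``pixel_size_nm``); embedded
    metadata, when present, is used only as a cross-check and a mismatch
    raises a warning, not an error.
    """
    try:
        with tifffile.TiffFile(str(path)) as tf:
            arr = tf.asarray()
            desc = tf.pages[0].description or ""
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot read TIFF {path}: {exc}") from exc

    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}

    if arr.ndim == 2:
        arr = arr[np.newaxis, np.newaxis]
    elif arr.ndim == 3:
        arr = arr[:, np.newaxis]  # (C, Y, X) -> (C, 1, Y, X)
    elif arr.ndim != 4:
        raise FormatError(
            f"{path}: cannot interpret a {arr.ndim}-D TIFF as (C, Z, Y, X)"
        )

    labels = meta.get("channel_labels")
    if channel_map is not None:
        for label, idx in channel_map.items():
            if not 0 <= idx < arr.shape[0]:
                raise FormatError(
                    f"{path}: channel {label!r} mapped to index {idx} but the "
                    f"file has {arr.shape[0]} channel(s)"
                )
        order = sorted(channel_map, key=channel_map.__getitem__)
        arr = arr[[channel_map[k] for k in order]]
        labels = order
    elif labels is None:
        labels = [f"C{i}" for i in range(arr.shape[0])]

    px = pixel_size_nm if pixel_size_nm is not None else meta.get("pixel_size_nm")
    if px is None:
        raise FormatError(f"{path}: pixel size not given and not in metadata")
    if meta.get("pixel_size_nm") is not None and pixel_size_nm is not None:
        if not np.isclose(meta["pixel_size_nm"], pixel_size_nm, rtol=1e-3):
            warnings.warn(
                f"{path}: configured pixel size {pixel_size_nm} nm/px differs "
                f"from file metadata {meta['pixel_size_nm']} nm/px; using the "
                "configured value",
                stacklevel=2,
            )
    zs = z_step_nm if z_step_nm is not None else meta.get("z_step_nm")
    return ImageStack(arr, list(labels), float(px), zs)
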