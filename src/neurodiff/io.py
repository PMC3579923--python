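"""Reading and writing of images, study manifests, feature tables and model files.

All I/O here is strictly order preserving: the row order of a manifest encodes
the scan order of the microscope, which downstream autocorrelation screening
depends on, so nothing in this module ever sorts or reorders rows.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import imageio.v3 as iio
import tifffile

from .errors import SchemaError, UnsupportedFormatError, ValidationError

MANIFEST_COLUMNS = ["image_path", "well", "day", "condition", "replicate", "scan_index"]

#: Metadata columns of a feature table, written before the feature columns.
TABLE_META_COLUMNS = MANIFEST_COLUMNS + ["is_outlier", "outlier_reason",
                                         "segment_valid", "total_px"]


@dataclasses.dataclass(frozen=True)
class Image:
    """A 2-D grayscale micrograph.

    Parameters
    ----------
    pixels : ndarray of shape (H, W)
        Non-negative intensities, at most ``2**bit_depth - 1``.
    bit_depth : int
        Bit depth of the acquisition (8, 12 or 16 are typical).
    pixel_size_um : float
        Physical edge length of one pixel in micrometres.
    """

    pixels: np.ndarray
    bit_depth: int = 12
    pixel_size_um: float = 0.078

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValidationError("image must be a non-empty 2-D grid")
        if px.min() < 0:
            raise ValidationError("image intensities must be non-negative")
        if px.max() > 2**self.bit_depth - 1:
            raise ValidationError(
                f"intensity {px.max()} exceeds 2**{self.bit_depth} - 1"
            )
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def max_intensity(self) -> int:
        return 2**self.bit_depth - 1

    def normalized(self) -> np.ndarray:
        """Intensities rescaled to [0, 1] by the bit depth."""
        return self.pixels.astype(np.float64) / self.max_intensity


def write_image(path, image: Image) -> None:
    """Write a 16-bit TIFF or PNG (by extension), preserving intensities exactly."""
    path = Path(path)
    data = np.asarray(image.pixels)
    if image.bit_depth <= 8:
        out = data.astype(np.uint8)
    else:
        out = data.astype(np.uint16)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, out)
    else:
        iio.imwrite(path, out)


def read_image(path, bit_depth: int | None = None, pixel_size_um: float = 0.078) -> Image:
    """Read a grayscale TIFF/PNG into an :class:`Image`.

    The bit depth is inferred from the dtype and the data range (a uint16
    container whose maximum fits 12 bits is reported as 12-bit) unless given
    explicitly. RGB input is rejected: the pipeline is defined on single
    channel phase-contrast intensities.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such image file: {path}")
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            data = tifffile.imread(path)
        else:
            data = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - normalize reader backends
        raise IOError(f"could not read image {path}: {exc}") from exc
    data = np.asarray(data)
    if data.ndim != 2:
        raise UnsupportedFormatError(
            f"{path}: expected single-channel grayscale, got shape {data.shape}"
        )
    if bit_depth is None:
        if data.dtype == np.uint8:
            bit_depth = 8
        else:
            # 12-bit acquisitions are stored in 16-bit containers
            bit_depth = 12 if data.max(initial=0) <= 4095 else 16
    return Image(pixels=data, bit_depth=bit_depth, pixel_size_um=pixel_size_um)


def write_manifest(path, manifest: pd.DataFrame) -> None:
    _check_manifest(manifest, check_files=False)
    manifest.to_csv(path, index=False)


def read_manifest(path, check_files: bool = True) -> pd.DataFrame:
    """Read a study manifest CSV, validating schema and scan-index uniqueness."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"well": str, "condition": str, "replicate": str})
    _check_manifest(df, check_files=check_files, base_dir=path.parent)
    df["day"] = df["day"].astype(int)
    df["scan_index"] = df["scan_index"].astype(int)
    return df


def _check_manifest(df: pd.DataFrame, check_files: bool, base_dir: Path | None = None):
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"manifest is missing required column {col!r}")
    dup = df.groupby(["well", "day"])["scan_index"].apply(lambda s: s.duplicated().any())
    if dup.any():
        raise ValidationError("duplicate scan_index within a (well, day) group")
    if check_files:
        for p in df["image_path"]:
            full = Path(p)
            if base_dir is not None and not full.is_absolute():
                full = base_dir / full
            if not full.exists():
                raise ValidationError(f"manifest references missing file: {p}")


def write_feature_table(path, table: pd.DataFrame) -> None:
    """Write a feature table as TSV: metadata columns, then feature columns.

    Full float precision is kept so that write/read round-trips are exact to
    the last representable digit.
    """
    cols = [c for c in TABLE_META_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"well": str, "condition": str, "replicate": str})
    if "day" in df.columns:
        df["day"] = df["day"].astype(int)
    return df


def save_json(path, payload: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)


def load_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
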