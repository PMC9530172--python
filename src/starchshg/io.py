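"""File formats, manifests and validated pipeline configuration.

Images are plain TIFF: a paired acquisition is a two-page 16-bit TIFF
(page 0 = TPF, page 1 = SHG); hyperspectral cubes are 3-D TIFF stacks
(wavelength-major pages) with a two-column wavelength CSV sidecar.  Photon
counts are integers by contract — float-valued image TIFFs are rejected.
Experiment manifests are CSV; configuration is a single validated YAML
document; provenance (config hash, seed, versions) is JSON.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .quantify import CHANNEL_SHG, CHANNEL_TPF, ChannelImage

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = [
    "image_id", "genotype", "leaf_id", "area_id", "zt_hour",
    "tpf_path", "shg_path", "tpf_dwell_ms", "shg_dwell_ms",
]

SATURATION_16BIT = 65535


class FormatError(ValueError):
    """A file violates one of the pipeline's format contracts."""


class ManifestError(ValueError):
    """An experiment manifest is malformed or references missing files."""


def _load_count_array(path, page: int | None) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    arr = tifffile.imread(path, key=page) if page is not None else tifffile.imread(path)
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(
            f"{path}: dtype {arr.dtype} violates the photon-count contract "
            "(counts must be integers; float-valued TIFFs are rejected)"
        )
    if arr.ndim != 2:
        raise FormatError(
            f"{path}: expected a single 2-D page, got shape {arr.shape} "
            "(pass page= to select one page of a multi-page TIFF)"
        )
    n_sat = int((arr == SATURATION_16BIT).sum())
    if n_sat:
        logger.warning("%s: %d saturated 16-bit pixel(s) (value 65535)", path, n_sat)
    return arr


def read_channel_tiff(
    path, channel: str, dwell_ms: float, page: int | None = None
) -> ChannelImage:
    """Read one photon-count channel image, preserving counts exactly."""
    arr = _load_count_array(path, page)
    return ChannelImage(arr, channel, dwell_ms, provenance=str(path))


def write_channel_tiff(path, img: ChannelImage) -> None:
    tifffile.imwrite(Path(path), img.pixels.astype(np.uint16))


def write_pair_tiff(path, tpf: ChannelImage, shg: ChannelImage) -> None:
    """Write a paired acquisition as a two-page TIFF (page 0 TPF, page 1 SHG)."""
    if tpf.shape != shg.shape:
        raise ValueError("TPF and SHG images of a pair must share a shape")
    stack = np.stack([tpf.pixels, shg.pixels]).astype(np.uint16)
    tifffile.imwrite(Path(path), stack)


def read_pair_tiff(
    path, tpf_dwell_ms: float = 0.016, shg_dwell_ms: float = 0.128
) -> tuple[ChannelImage, ChannelImage]:
    """Read a two-page (TPF, SHG) TIFF written by :func:`write_pair_tiff`."""
    return (
        read_channel_tiff(path, CHANNEL_TPF, tpf_dwell_ms, page=0),
        read_channel_tiff(path, CHANNEL_SHG, shg_dwell_ms, page=1),
    )


def write_cube(tiff_path, csv_path, cube) -> None:
    """Write a hyperspectral cube: wavelength-major TIFF + wavelength CSV."""
    tifffile.imwrite(Path(tiff_path), np.moveaxis(cube.data, 2, 0).astype(np.float32))
    pd.DataFrame(
        {"index": np.arange(cube.wavelengths.size), "wavelength_nm": cube.wavelengths}
    ).to_csv(csv_path, index=False)


def read_cube(tiff_path, csv_path, integration_s: float):
    """Read a cube written by :func:`write_cube`."""
    from .spectral import HyperCube

    stack = tifffile.imread(Path(tiff_path))
    if stack.ndim != 3:
        raise FormatError(f"{tiff_path}: expected a 3-D stack, got shape {stack.shape}")
    wl = pd.read_csv(csv_path)["wavelength_nm"].to_numpy(dtype=float)
    if wl.size != stack.shape[0]:
        raise FormatError(
            f"wavelength CSV has {wl.size} rows but the stack has "
            f"{stack.shape[0]} pages"
        )
    return HyperCube(np.moveaxis(stack, 0, 2), wl, integration_s)


def load_manifest(path, check_files: bool = True) -> pd.DataFrame:
    """Load and validate an experiment manifest CSV.

    Checks the required columns, image_id uniqueness, ZT domain [0, 24] and
    (by default) that every referenced image file exists.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"{path}: missing manifest columns {missing}")
    if df["image_id"].duplicated().any():
        dupes = df.loc[df["image_id"].duplicated(), "image_id"].tolist()
        raise ManifestError(f"{path}: duplicate image_id values {dupes}")
    zt = df["zt_hour"].to_numpy(dtype=float)
    if np.any(zt < 0) or np.any(zt > 24):
        raise ManifestError(f"{path}: zt_hour values must lie in [0, 24]")
    if check_files:
        for col in ("tpf_path", "shg_path"):
            for p in df[col].astype(str):
                candidate = Path(p)
                if not candidate.is_absolute():
                    candidate = path.parent / candidate
                if not candidate.exists():
                    raise ManifestError(f"{path}: referenced file not found: {p}")
    return df


def write_manifest(df: pd.DataFrame, path) -> None:
    df.to_csv(Path(path), index=False)


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable pipeline parameters in one validated document.

    Thresholds are photon counts at the reference dwell times (TPF 0.016 ms,
    SHG 0.128 ms); filters are (center, full width) in nm; the bootstrap and
    simulator draws are governed by ``seed``.
    """

    tpf_threshold: float = 50.0
    shg_background: float = 2.0
    strict_above: bool = True
    closing_radius_px: int = 2
    tpf_filter_center_nm: float = 670.0
    tpf_filter_width_nm: float = 30.0
    shg_filter_center_nm: float = 532.0
    shg_filter_width_nm: float = 3.0
    light_off_zt: float = 16.0
    bootstrap_reps: int = 2000
    dispersion_sigma: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tpf_threshold < 0 or self.shg_background < 0:
            raise ValueError("thresholds must be nonnegative")
        if self.closing_radius_px < 0:
            raise ValueError("closing_radius_px must be nonnegative")
        if self.tpf_filter_width_nm <= 0 or self.shg_filter_width_nm <= 0:
            raise ValueError("filter widths must be positive")
        if not 0 <= self.light_off_zt <= 24:
            raise ValueError("light_off_zt must lie in [0, 24]")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")
        if self.dispersion_sigma < 0:
            raise ValueError("dispersion_sigma must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        """Stable hash of the configuration for provenance records."""
        canonical = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()
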