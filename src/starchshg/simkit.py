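"""Synthetic multiphoton leaf scenes with known ground truth.

Emulates laser-scanning TPF/SHG microscopy of Arabidopsis mesophyll so the
whole analysis pipeline can be exercised without microscope data:

* chloroplast-shaped autofluorescent (TPF) regions containing TPF-dark
  stroma pockets, with starch-granule SHG confined to those pockets;
* per-pixel photon counts drawn from Poisson distributions whose means scale
  linearly with pixel dwell time;
* hyperspectral cubes built from three additive components — a chlorophyll
  emission band peaking near 678 nm, a narrow SHG line at half the excitation
  wavelength, and a weak ~590 nm fluorescence feature whose short-wavelength
  tail reaches the SHG band (the leakage contaminant);
* genotype-dependent diel starch kinetics over a 16 h light / 8 h dark
  photoperiod: wild-type (Col-0) starch rises during the light phase and is
  degraded at night back toward a small dawn baseline, while the starch
  excess 1 (sex1) mutant cannot degrade starch and stays high.

All randomness flows through a single numpy Generator, so a fixed seed gives
bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.draw import disk as _draw_disk

from .quantify import CHANNEL_SHG, CHANNEL_TPF, ChannelImage
from .spectral import Band, HyperCube, band_from_filter

COL0 = "col0"
SEX1 = "sex1"

#: Chlorophyll emission bump: split Gaussian peaking at 678 nm, steeper on the
#: blue side than the red tail (shape only; unit peak).
CHL_PEAK_NM = 678.0
CHL_SIGMA_LEFT_NM = 10.0
CHL_SIGMA_RIGHT_NM = 18.0

#: The ~590 nm contaminant: Gaussian bump plus exponential wings whose
#: short-wavelength tail reaches the 532 nm SHG band.
LEAK590_CENTER_NM = 590.0
LEAK590_SIGMA_NM = 15.0
LEAK590_TAIL_FRACTION = 0.25
LEAK590_TAIL_SCALE_NM = 40.0

#: SHG line width (Gaussian sigma, nm); narrow next to the 3 nm bandpass.
SHG_LINE_SIGMA_NM = 0.5

#: Spectral amplitudes per second of integration (unit-peak shapes):
#: chlorophyll on thylakoid pixels, SHG line on granule pixels.
CHL_SPECTRAL_AMPLITUDE = 60.0
SHG_SPECTRAL_AMPLITUDE = 40.0


class InvariantError(ValueError):
    """A generated or supplied scene violates a structural invariant."""


@dataclass(frozen=True)
class SceneConfig:
    """Geometry of one synthetic imaging field.

    Chloroplasts are random ellipses; each contains disk-shaped TPF-dark
    stroma sites; starch granules are disks placed only inside stroma sites.
    ``starch_area_px_per_unit`` converts model starch mass (arbitrary units)
    into total granule area in pixels.
    """

    image_shape: tuple[int, int] = (160, 160)
    n_chloroplasts: int = 12
    chloroplast_axes_px: tuple[float, float] = (7.0, 12.0)
    stroma_site_fraction: float = 0.2
    stroma_site_radius_px: tuple[float, float] = (1.2, 2.0)
    granule_radius_px: tuple[float, float] = (1.5, 2.4)
    starch_area_px_per_unit: float = 15.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_shape
        if h <= 0 or w <= 0 or self.n_chloroplasts < 0:
            raise ValueError("image shape and chloroplast count must be positive")
        if not 0.0 <= self.stroma_site_fraction <= 1.0:
            raise ValueError("stroma_site_fraction must be in [0, 1]")
        for name in ("chloroplast_axes_px", "stroma_site_radius_px", "granule_radius_px"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive (low, high) range")
        if not self.starch_area_px_per_unit > 0:
            raise ValueError("starch_area_px_per_unit must be positive")


@dataclass(frozen=True)
class DielModel:
    """Piecewise-linear diel starch kinetics under an entrained photoperiod.

    Starch mass rises linearly at ``synth_rate`` through the light phase and
    falls at ``degrade_rate`` in the dark, never below ``dawn_baseline`` (some
    starch remains at dawn).  The sex1 mutant is the same model constrained to
    ``degrade_rate = 0``: synthesis without nocturnal degradation.
    """

    genotype: str = COL0
    light_hours: float = 16.0
    dark_hours: float = 8.0
    synth_rate: float = 1.0
    degrade_rate: float = 2.0
    dawn_baseline: float = 0.2

    def __post_init__(self) -> None:
        if self.genotype not in (COL0, SEX1):
            raise ValueError(f"genotype must be {COL0!r} or {SEX1!r}")
        if abs(self.light_hours + self.dark_hours - 24.0) > 1e-9:
            raise ValueError("light_hours + dark_hours must equal 24")
        if self.synth_rate < 0 or self.degrade_rate < 0 or self.dawn_baseline < 0:
            raise ValueError("rates and baseline must be nonnegative")
        if self.genotype == SEX1 and self.degrade_rate != 0:
            raise ValueError("sex1 models must have degrade_rate = 0")

    @classmethod
    def col0(cls, **kwargs) -> "DielModel":
        """Wild-type defaults: rise through the day, decay back by next dawn."""
        kwargs.setdefault("synth_rate", 1.0)
        kwargs.setdefault("degrade_rate", 2.0)
        kwargs.setdefault("dawn_baseline", 0.2)
        return cls(genotype=COL0, **kwargs)

    @classmethod
    def sex1(cls, **kwargs) -> "DielModel":
        """Degradation-deficient defaults: persistently high starch."""
        kwargs.setdefault("synth_rate", 0.4)
        kwargs.setdefault("dawn_baseline", 10.0)
        return cls(genotype=SEX1, degrade_rate=0.0, **kwargs)


@dataclass(frozen=True)
class OpticsConfig:
    """Excitation, filters, dwell times and signal rates of the virtual scope.

    ``tpf_rate_per_ms`` / ``shg_rate_per_ms`` are expected photon counts per
    millisecond of dwell on thylakoid / granule pixels; realized counts are
    Poisson.  ``leak590_amplitude`` is the peak height of the 590 nm
    fluorescence feature relative to the SHG line peak; its tail under the
    SHG bandpass produces a small spurious SHG-channel count on
    autofluorescent pixels.
    """

    excitation_nm: float = 1064.0
    tpf_filter: tuple[float, float] = (670.0, 30.0)  # center, full width (nm)
    shg_filter: tuple[float, float] = (532.0, 3.0)
    tpf_dwell_ms: float = 0.016
    shg_dwell_ms: float = 0.128
    leak590_amplitude: float = 0.1
    tpf_rate_per_ms: float = 7500.0
    shg_rate_per_ms: float = 160.0

    def __post_init__(self) -> None:
        if not self.excitation_nm > 0:
            raise ValueError("excitation_nm must be positive")
        for name in ("tpf_filter", "shg_filter"):
            _, width = getattr(self, name)
            if not width > 0:
                raise ValueError(f"{name} full width must be positive")
        if not (self.tpf_dwell_ms > 0 and self.shg_dwell_ms > 0):
            raise ValueError("dwell times must be positive")
        if self.leak590_amplitude < 0:
            raise ValueError("leak590_amplitude must be nonnegative")
        if not (self.tpf_rate_per_ms > 0 and self.shg_rate_per_ms > 0):
            raise ValueError("signal rates must be positive")

    @property
    def shg_line_nm(self) -> float:
        """SHG emits at exactly half the excitation wavelength."""
        return self.excitation_nm / 2.0

    @property
    def shg_band(self) -> Band:
        return band_from_filter(*self.shg_filter)

    @property
    def tpf_band(self) -> Band:
        return band_from_filter(*self.tpf_filter)


@dataclass(frozen=True)
class GroundTruth:
    """True scene content behind a rendered image pair or cube.

    ``starch_mass`` is the model-truth mass the granule placement targeted
    (arbitrary units); masks record where chloroplasts, TPF-bright thylakoid
    and SHG-emitting granules actually are.
    """

    starch_mass: float
    zt_hour: float
    granule_centers: np.ndarray  # (n, 2) float (row, col)
    granule_radii: np.ndarray
    chloroplast_mask: np.ndarray
    thylakoid_mask: np.ndarray
    granule_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.starch_mass < 0:
            raise InvariantError("starch_mass must be nonnegative")
        if not 0.0 <= self.zt_hour <= 24.0:
            raise InvariantError("zt_hour must lie in [0, 24]")
        centers = np.asarray(self.granule_centers, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "granule_centers", centers)
        object.__setattr__(
            self, "granule_radii", np.asarray(self.granule_radii, dtype=float)
        )
        _check_granules_inside(centers, self.chloroplast_mask)

    @property
    def granule_area_px(self) -> int:
        return int(self.granule_mask.sum())


def _check_granules_inside(centers: np.ndarray, chloroplast_mask: np.ndarray) -> None:
    for r, c in centers:
        ri, ci = int(round(r)), int(round(c))
        if (
            not 0 <= ri < chloroplast_mask.shape[0]
            or not 0 <= ci < chloroplast_mask.shape[1]
            or not chloroplast_mask[ri, ci]
        ):
            raise InvariantError(
                f"granule center ({r:.1f}, {c:.1f}) lies outside every chloroplast"
            )


def starch_mass_at(model: DielModel, zt):
    """Model starch mass at Zeitgeber time ``zt`` (hours since lights-on).

    Piecewise linear: ``dawn_baseline + synth_rate * zt`` while the light is
    on, then linear decay at ``degrade_rate`` clamped at the dawn baseline.
    With ``degrade_rate = 0`` (sex1) the peak level persists through the dark
    phase.  Accepts scalars or arrays; ``zt`` must lie in [0, 24].
    """
    zt_arr = np.asarray(zt, dtype=float)
    if np.any(zt_arr < 0) or np.any(zt_arr > 24):
        raise ValueError("zt must lie in [0, 24] hours")
    peak = model.dawn_baseline + model.synth_rate * model.light_hours
    rising = model.dawn_baseline + model.synth_rate * zt_arr
    falling = np.maximum(
        model.dawn_baseline, peak - model.degrade_rate * (zt_arr - model.light_hours)
    )
    out = np.where(zt_arr <= model.light_hours, rising, falling)
    return float(out) if np.isscalar(zt) or zt_arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# scene geometry


def make_ground_truth(
    cfg: SceneConfig,
    starch_mass: float,
    zt_hour: float = 0.0,
    rng: np.random.Generator | None = None,
) -> GroundTruth:
    """Sample a scene: chloroplast ellipses, stroma sites, starch granules.

    Granules are placed one per stroma site (radius capped by the site) until
    their cumulative pixel area reaches ``starch_mass`` times the area scale,
    so realized granule area tracks the requested mass up to one granule of
    quantization and the capacity of the available stroma sites.
    """
    if starch_mass < 0:
        raise InvariantError("starch_mass must be nonnegative")
    rng = np.random.default_rng(cfg.rng_seed) if rng is None else rng
    h, w = cfg.image_shape
    chloro = np.zeros((h, w), dtype=bool)
    stroma = np.zeros((h, w), dtype=bool)
    sites: list[tuple[float, float, float]] = []
    r_hi = cfg.stroma_site_radius_px[1]

    for _ in range(cfg.n_chloroplasts):
        a = rng.uniform(*cfg.chloroplast_axes_px)
        b = rng.uniform(*cfg.chloroplast_axes_px)
        theta = rng.uniform(0.0, np.pi)
        margin = max(a, b) + 2.0
        if 2 * margin >= min(h, w):
            raise ValueError("chloroplast axes too large for the image shape")
        cr = rng.uniform(margin, h - margin)
        cc = rng.uniform(margin, w - margin)
        # rasterize the rotated ellipse over its bounding box
        r0, r1 = int(np.floor(cr - margin)), int(np.ceil(cr + margin)) + 1
        c0, c1 = int(np.floor(cc - margin)), int(np.ceil(cc + margin)) + 1
        rows, cols = np.mgrid[max(r0, 0) : min(r1, h), max(c0, 0) : min(c1, w)]
        dr, dc = rows - cr, cols - cc
        cos_t, sin_t = np.cos(theta), np.sin(theta)
        u = dr * cos_t + dc * sin_t
        v = -dr * sin_t + dc * cos_t
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        chloro[rows[inside], cols[inside]] = True
        # carve disjoint dark stroma pockets on a jittered lattice, so every
        # hole is a single disk of at most r_hi — closable by morphology
        target = cfg.stroma_site_fraction * np.pi * a * b
        spacing = 2.0 * r_hi + 1.0
        us = np.arange(-a, a + spacing, spacing) + rng.uniform(-1.0, 1.0)
        vs = np.arange(-b, b + spacing, spacing) + rng.uniform(-1.0, 1.0)
        uu, vv = (g.ravel() for g in np.meshgrid(us, vs))
        srs = rng.uniform(*cfg.stroma_site_radius_px, size=uu.size)
        ok = (uu / np.maximum(a - srs - 1.0, 1e-6)) ** 2 + (
            vv / np.maximum(b - srs - 1.0, 1e-6)
        ) ** 2 <= 1.0
        ok &= (a - srs - 1.0 > 0.5) & (b - srs - 1.0 > 0.5)
        order = rng.permutation(np.flatnonzero(ok))
        area = 0.0
        for k in order:
            if area >= target:
                break
            sr = float(srs[k])
            pr = cr + uu[k] * cos_t - vv[k] * sin_t
            pc = cc + uu[k] * sin_t + vv[k] * cos_t
            # sites of overlapping chloroplasts must stay disjoint too
            if any(
                (pr - er) ** 2 + (pc - ec) ** 2 <= (sr + esr + 1.0) ** 2
                for er, ec, esr in sites
            ):
                continue
            rr2, cc2 = _draw_disk((pr, pc), sr, shape=(h, w))
            stroma[rr2, cc2] = True
            sites.append((pr, pc, sr))
            area += np.pi * sr * sr

    granule_mask = np.zeros((h, w), dtype=bool)
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    target_px = starch_mass * cfg.starch_area_px_per_unit
    if target_px >= 1.0 and sites:
        filled = 0
        for k in rng.permutation(len(sites)):
            if filled >= target_px:
                break
            pr, pc, sr = sites[k]
            g = min(rng.uniform(*cfg.granule_radius_px), sr)
            rr3, cc3 = _draw_disk((pr, pc), g, shape=(h, w))
            fresh = int((~granule_mask[rr3, cc3]).sum())
            granule_mask[rr3, cc3] = True
            filled += fresh
            centers.append((pr, pc))
            radii.append(g)

    return GroundTruth(
        starch_mass=float(starch_mass),
        zt_hour=float(zt_hour),
        granule_centers=np.asarray(centers, dtype=float).reshape(-1, 2),
        granule_radii=np.asarray(radii, dtype=float),
        chloroplast_mask=chloro,
        thylakoid_mask=chloro & ~stroma,
        granule_mask=granule_mask,
    )


# ---------------------------------------------------------------------------
# channel-image rendering


def shg_band_leak_ratio(optics: OpticsConfig) -> float:
    """Expected SHG-channel count on a thylakoid pixel relative to a granule pixel.

    Integrates the 590 nm feature's tail and the SHG line over the SHG
    bandpass; the ratio converts the spectral contamination into the
    photon-count domain of the filtered images.  Zero when the 590 nm feature
    is switched off.
    """
    if optics.leak590_amplitude == 0:
        return 0.0
    band = optics.shg_band
    wl = np.linspace(band.low_nm, band.high_nm, 301)
    leak = optics.leak590_amplitude * _leak590_shape(wl)
    line = _shg_line_shape(wl, optics.shg_line_nm)
    return float(np.trapezoid(leak, wl) / np.trapezoid(line, wl))


def expected_scene(
    cfg: SceneConfig, optics: OpticsConfig, truth: GroundTruth
) -> tuple[np.ndarray, np.ndarray]:
    """Expected (Poisson-mean) TPF and SHG count images for a scene.

    TPF signal lives on thylakoid pixels only; SHG signal on granule pixels,
    plus the 590 nm-tail leakage term on thylakoid pixels when enabled.
    Means scale linearly with the per-channel dwell times.
    """
    _check_granules_inside(truth.granule_centers, truth.chloroplast_mask)
    tpf = np.zeros(truth.chloroplast_mask.shape, dtype=float)
    shg = np.zeros_like(tpf)
    tpf[truth.thylakoid_mask] = optics.tpf_rate_per_ms * optics.tpf_dwell_ms
    shg[truth.granule_mask] = optics.shg_rate_per_ms * optics.shg_dwell_ms
    leak = shg_band_leak_ratio(optics)
    if leak > 0:
        shg[truth.thylakoid_mask] += (
            leak * optics.shg_rate_per_ms * optics.shg_dwell_ms
        )
    return tpf, shg


def render_scene(
    cfg: SceneConfig,
    optics: OpticsConfig,
    truth: GroundTruth,
    rng: np.random.Generator | None = None,
) -> tuple[ChannelImage, ChannelImage]:
    """Draw one Poisson realization of a scene as a (TPF, SHG) image pair."""
    rng = np.random.default_rng(cfg.rng_seed) if rng is None else rng
    tpf_mean, shg_mean = expected_scene(cfg, optics, truth)
    tpf_counts = np.minimum(rng.poisson(tpf_mean), 65535).astype(np.uint16)
    shg_counts = np.minimum(rng.poisson(shg_mean), 65535).astype(np.uint16)
    return (
        ChannelImage(tpf_counts, CHANNEL_TPF, optics.tpf_dwell_ms, provenance="simkit"),
        ChannelImage(shg_counts, CHANNEL_SHG, optics.shg_dwell_ms, provenance="simkit"),
    )


# ---------------------------------------------------------------------------
# hyperspectral rendering


def _chlorophyll_shape(wl: np.ndarray) -> np.ndarray:
    d = wl - CHL_PEAK_NM
    sigma = np.where(d < 0, CHL_SIGMA_LEFT_NM, CHL_SIGMA_RIGHT_NM)
    return np.exp(-0.5 * (d / sigma) ** 2)


def _leak590_shape(wl: np.ndarray) -> np.ndarray:
    d = wl - LEAK590_CENTER_NM
    bump = np.exp(-0.5 * (d / LEAK590_SIGMA_NM) ** 2)
    wings = LEAK590_TAIL_FRACTION * np.exp(-np.abs(d) / LEAK590_TAIL_SCALE_NM)
    return (bump + wings) / (1.0 + LEAK590_TAIL_FRACTION)


def _shg_line_shape(wl: np.ndarray, center_nm: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center_nm) / SHG_LINE_SIGMA_NM) ** 2)


def render_cube(
    cfg: SceneConfig,
    optics: OpticsConfig,
    truth: GroundTruth,
    wavelengths: np.ndarray,
    integration_s: float,
    *,
    return_components: bool = False,
):
    """Render a noiseless hyperspectral cube (H, W, wavelength) of a scene.

    Per-pixel spectrum = chlorophyll band on thylakoid pixels + SHG line at
    half the excitation wavelength on granule pixels + the weak 590 nm
    feature (with its tail under the SHG band) on thylakoid pixels.  All
    amplitudes scale linearly with ``integration_s``.  With
    ``return_components=True`` also returns the three component fields, whose
    sum is exactly the cube.
    """
    wl = np.asarray(wavelengths, dtype=float)
    if wl.ndim != 1 or wl.size < 2 or not np.all(np.diff(wl) > 0):
        raise ValueError("wavelength grid must be 1-D and strictly increasing")
    if wl[0] > 520.0 or wl[-1] < 700.0:
        raise ValueError("wavelength grid must span at least [520, 700] nm")
    if not integration_s > 0:
        raise ValueError("integration_s must be positive")
    if float(np.diff(wl).max()) > 1.5:
        warnings.warn(
            f"wavelength spacing {float(np.diff(wl).max()):.2f} nm is too coarse "
            f"to resolve the {optics.shg_filter[1]:g} nm-wide SHG line",
            stacklevel=2,
        )
    thyl = truth.thylakoid_mask.astype(float)[:, :, None]
    gran = truth.granule_mask.astype(float)[:, :, None]
    continuum = integration_s * CHL_SPECTRAL_AMPLITUDE * thyl * _chlorophyll_shape(wl)
    leak590 = (
        integration_s
        * SHG_SPECTRAL_AMPLITUDE
        * optics.leak590_amplitude
        * thyl
        * _leak590_shape(wl)
    )
    shg_line = (
        integration_s
        * SHG_SPECTRAL_AMPLITUDE
        * gran
        * _shg_line_shape(wl, optics.shg_line_nm)
    )
    cube = HyperCube(continuum + leak590 + shg_line, wl, integration_s)
    if return_components:
        return cube, {
            "chlorophyll": continuum,
            "leak590": leak590,
            "shg_line": shg_line,
        }
    return cube


# ---------------------------------------------------------------------------
# full diel experiments


@dataclass(frozen=True)
class SimulatedImage:
    """One rendered imaging area with its metadata and ground truth."""

    image_id: str
    genotype: str
    leaf_id: int
    area_id: int
    zt_hour: float
    tpf: ChannelImage
    shg: ChannelImage
    truth: GroundTruth
    tpf_path: str = ""
    shg_path: str = ""


@dataclass(frozen=True)
class Experiment:
    """A simulated diel imaging experiment: images, manifest and truth table."""

    images: tuple[SimulatedImage, ...]
    manifest: pd.DataFrame
    truth_table: pd.DataFrame
    diel: DielModel
    scene: SceneConfig
    optics: OpticsConfig
    seed: int


def simulate_experiment(
    diel: DielModel,
    cfg: SceneConfig,
    optics: OpticsConfig,
    zt_grid,
    n_areas: int,
    n_leaves: int = 2,
    seed: int = 0,
    dispersion_sigma: float = 0.25,
    out_dir=None,
) -> Experiment:
    """Simulate a full diel imaging experiment with known ground truth.

    For every Zeitgeber time in ``zt_grid`` and every imaging area, the true
    starch mass is the diel-model value times a lognormal between-area
    multiplier (``exp(N(0, dispersion_sigma))``); a fresh scene is sampled so
    total granule area tracks that mass, and a Poisson image pair is rendered.
    Areas are distributed round-robin over ``n_leaves`` leaves.  With
    ``out_dir`` set, image pairs (multi-page TIFF), the manifest CSV and a
    ground-truth JSON sidecar are written there.
    """
    zt_list = [float(z) for z in np.atleast_1d(np.asarray(zt_grid, dtype=float))]
    if len(zt_list) == 0 or n_areas < 1:
        raise ValueError("empty experiment: need at least one ZT point and one area")
    if n_leaves < 1:
        raise ValueError("n_leaves must be >= 1")
    rng = np.random.default_rng(seed)
    images: list[SimulatedImage] = []
    manifest_rows = []
    truth_rows = []
    if out_dir is not None:
        from . import io as _io
        from pathlib import Path

        out_dir = Path(out_dir)
        (out_dir / "images").mkdir(parents=True, exist_ok=True)

    for zt in zt_list:
        base = starch_mass_at(diel, zt)
        for area in range(1, n_areas + 1):
            leaf = (area - 1) % n_leaves + 1
            mult = (
                float(np.exp(rng.normal(0.0, dispersion_sigma)))
                if dispersion_sigma > 0
                else 1.0
            )
            truth = make_ground_truth(cfg, base * mult, zt, rng)
            tpf, shg = render_scene(cfg, optics, truth, rng)
            image_id = f"{diel.genotype}_zt{zt:04.1f}_leaf{leaf}_area{area:02d}"
            tpf_path = shg_path = ""
            if out_dir is not None:
                pair_path = out_dir / "images" / f"{image_id}.tif"
                _io.write_pair_tiff(pair_path, tpf, shg)
                tpf_path = shg_path = str(pair_path)
            images.append(
                SimulatedImage(
                    image_id=image_id, genotype=diel.genotype, leaf_id=leaf,
                    area_id=area, zt_hour=zt, tpf=tpf, shg=shg, truth=truth,
                    tpf_path=tpf_path, shg_path=shg_path,
                )
            )
            manifest_rows.append(
                {
                    "image_id": image_id, "genotype": diel.genotype,
                    "leaf_id": leaf, "area_id": area, "zt_hour": zt,
                    "tpf_path": tpf_path, "shg_path": shg_path,
                    "tpf_dwell_ms": optics.tpf_dwell_ms,
                    "shg_dwell_ms": optics.shg_dwell_ms,
                }
            )
            truth_rows.append(
                {
                    "image_id": image_id, "zt_hour": zt,
                    "true_starch_mass": truth.starch_mass,
                    "granule_area_px": truth.granule_area_px,
                    "n_granules": len(truth.granule_radii),
                }
            )

    manifest = pd.DataFrame(manifest_rows)
    truth_table = pd.DataFrame(truth_rows)
    if out_dir is not None:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
        truth_table.to_json(out_dir / "ground_truth.json", orient="records", indent=2)
    return Experiment(
        images=tuple(images), manifest=manifest, truth_table=truth_table,
        diel=diel, scene=cfg, optics=optics, seed=seed,
    )
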