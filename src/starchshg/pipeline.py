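"""Umbrella pipeline: simulate (optional) → quantify → diurnal (→ spectral).

Ties the stages together behind one entry point, writes every product as CSV
/ JSON / PNG into a results directory, and records provenance (configuration
hash, seed, library versions) so runs are auditable and reproducible: with a
fixed seed the CSV outputs are byte-identical across reruns.
"""

from __future__ import annotations

import json
import logging
from contextlib import contextmanager
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, diurnal, io, quantify, simkit, spectral

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@contextmanager
def _stage(name: str):
    logger.info("stage %s: start", name)
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(name, exc) from exc
    logger.info("stage %s: done", name)


def quantify_experiment(
    experiment: simkit.Experiment, config: io.PipelineConfig | None = None
) -> pd.DataFrame:
    """Apply the ratio statistic to every image of a simulated experiment.

    Returns one row per imaging area (image_id, genotype, leaf, area, zt,
    i_shg, cnt_tpf, ratio, flags) with the simulator's true starch mass
    joined in for recovery checks.
    """
    config = config or io.PipelineConfig()
    rows = []
    for img in experiment.images:
        q = quantify.starch_ratio(
            img.tpf, img.shg,
            tpf_threshold=config.tpf_threshold,
            shg_background=config.shg_background,
            strict=config.strict_above,
        )
        rows.append(
            {
                "image_id": img.image_id, "genotype": img.genotype,
                "leaf_id": img.leaf_id, "area_id": img.area_id,
                "zt_hour": img.zt_hour, "i_shg": q.i_shg, "cnt_tpf": q.cnt_tpf,
                "ratio": q.ratio, "flags": ";".join(q.flags),
            }
        )
    df = pd.DataFrame(rows)
    truth = experiment.truth_table[["image_id", "true_starch_mass"]]
    return df.merge(truth, on="image_id", how="left")


def quantify_manifest(
    manifest: pd.DataFrame,
    config: io.PipelineConfig | None = None,
    base_dir: Path | None = None,
) -> pd.DataFrame:
    """Apply the ratio statistic to every image pair listed in a manifest."""
    config = config or io.PipelineConfig()
    rows = []
    for rec in manifest.to_dict("records"):
        tpf_path = Path(rec["tpf_path"])
        shg_path = Path(rec["shg_path"])
        if base_dir is not None:
            if not tpf_path.is_absolute():
                tpf_path = base_dir / tpf_path
            if not shg_path.is_absolute():
                shg_path = base_dir / shg_path
        if tpf_path == shg_path:  # simkit two-page layout
            tpf, shg = io.read_pair_tiff(
                tpf_path, rec["tpf_dwell_ms"], rec["shg_dwell_ms"]
            )
        else:
            tpf = io.read_channel_tiff(tpf_path, quantify.CHANNEL_TPF, rec["tpf_dwell_ms"])
            shg = io.read_channel_tiff(shg_path, quantify.CHANNEL_SHG, rec["shg_dwell_ms"])
        q = quantify.starch_ratio(
            tpf, shg,
            tpf_threshold=config.tpf_threshold,
            shg_background=config.shg_background,
            strict=config.strict_above,
        )
        rows.append(
            {
                "image_id": rec["image_id"], "genotype": rec["genotype"],
                "leaf_id": rec["leaf_id"], "area_id": rec["area_id"],
                "zt_hour": rec["zt_hour"], "i_shg": q.i_shg, "cnt_tpf": q.cnt_tpf,
                "ratio": q.ratio, "flags": ";".join(q.flags),
            }
        )
    return pd.DataFrame(rows)


def diurnal_analysis(
    quant: pd.DataFrame, config: io.PipelineConfig | None = None
) -> dict:
    """Per-genotype series, phase trends and pattern classification."""
    config = config or io.PipelineConfig()
    out: dict[str, dict] = {}
    for genotype, grp in quant.groupby("genotype"):
        series = diurnal.aggregate(grp, genotype, light_off_zt=config.light_off_zt)
        result: dict = {"series": series}
        try:
            light = diurnal.phase_trend(
                grp, "light", light_off_zt=config.light_off_zt,
                n_boot=config.bootstrap_reps, seed=config.seed,
            )
            dark = diurnal.phase_trend(
                grp, "dark", light_off_zt=config.light_off_zt,
                n_boot=config.bootstrap_reps, seed=config.seed + 1,
            )
            result["light"] = light
            result["dark"] = dark
            result["pattern"] = diurnal.classify_pattern(light, dark)
        except diurnal.InsufficientDataError as exc:
            logger.warning("%s: %s — no trend analysis", genotype, exc)
            result["pattern"] = diurnal.PATTERN_INDETERMINATE
        out[str(genotype)] = result
    return out


def run_pipeline(
    config: io.PipelineConfig,
    out_dir,
    *,
    manifest_path=None,
    simulate: dict | None = None,
    cube_paths: tuple | None = None,
) -> dict:
    """Run the full pipeline and write all products under ``out_dir``.

    Exactly one input source is required: a manifest CSV of existing images,
    or a ``simulate`` mapping (keys genotype, zt_grid, n_areas, and
    optionally n_leaves, scene, optics, diel) rendered on the fly.  When
    ``cube_paths`` = (cube_tiff, wavelength_csv, integration_s) is given, the
    spectral validation stage runs too.  Returns a dict of output paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    if (manifest_path is None) == (simulate is None):
        raise ValueError("provide exactly one of manifest_path or simulate")

    if simulate is not None:
        with _stage("simulate"):
            diel = simulate.get("diel") or (
                simkit.DielModel.sex1()
                if simulate["genotype"] == simkit.SEX1
                else simkit.DielModel.col0()
            )
            experiment = simkit.simulate_experiment(
                diel,
                simulate.get("scene", simkit.SceneConfig()),
                simulate.get("optics", simkit.OpticsConfig()),
                simulate["zt_grid"],
                n_areas=simulate["n_areas"],
                n_leaves=simulate.get("n_leaves", 2),
                seed=config.seed,
                dispersion_sigma=config.dispersion_sigma,
                out_dir=out_dir,
            )
            outputs["manifest"] = str(out_dir / "manifest.csv")
        with _stage("quantify"):
            quant = quantify_experiment(experiment, config)
    else:
        with _stage("quantify"):
            manifest = io.load_manifest(manifest_path)
            quant = quantify_manifest(
                manifest, config, base_dir=Path(manifest_path).parent
            )

    quant_path = out_dir / "quant.csv"
    quant.to_csv(quant_path, index=False)
    outputs["quant"] = str(quant_path)

    with _stage("diurnal"):
        analysis = diurnal_analysis(quant, config)
        summary = {}
        series_objects = []
        for genotype, result in analysis.items():
            series = result["series"]
            series_objects.append(series)
            series_path = out_dir / f"series_{genotype}.csv"
            series.table.to_csv(series_path, index=False)
            outputs[f"series_{genotype}"] = str(series_path)
            entry: dict = {"pattern": result["pattern"]}
            for phase in ("light", "dark"):
                if phase in result:
                    tr = result[phase]
                    entry[phase] = {
                        "slope": tr.slope,
                        "slope_ci": list(tr.slope_ci),
                        "n_points": tr.n_points,
                        "mean_level": tr.mean_level,
                    }
            summary[genotype] = entry
        (out_dir / "diurnal_summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True)
        )
        outputs["diurnal_summary"] = str(out_dir / "diurnal_summary.json")
        if series_objects:
            plot_path = out_dir / "diel_series.png"
            diurnal.plot_series(series_objects, path=plot_path)
            outputs["plot"] = str(plot_path)

    if cube_paths is not None:
        with _stage("spectral"):
            cube_tiff, wl_csv, integration_s = cube_paths
            cube = io.read_cube(cube_tiff, wl_csv, integration_s)
            tpf_band = spectral.band_from_filter(
                config.tpf_filter_center_nm, config.tpf_filter_width_nm
            )
            shg_band = spectral.band_from_filter(
                config.shg_filter_center_nm, config.shg_filter_width_nm
            )
            report = spectral.analyze_cube(cube, tpf_band, shg_band)
            report.to_csv(out_dir / "spectral_report.csv", index=False)
            outputs["spectral_report"] = str(out_dir / "spectral_report.csv")
            pc = spectral.pseudo_color(cube, tpf_band, shg_band)
            import tifffile

            tifffile.imwrite(
                out_dir / "pseudo_color_raw.tif",
                np.stack([pc.tpf, pc.shg]).astype(np.float32),
            )
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            plt.imsave(out_dir / "pseudo_color.png", np.clip(pc.rgb, 0, 1))
            outputs["pseudo_color"] = str(out_dir / "pseudo_color.png")

    provenance = {
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "versions": {
            "starchshg": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (out_dir / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True)
    )
    outputs["provenance"] = str(out_dir / "provenance.json")
    return outputs
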