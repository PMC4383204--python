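"""End-to-end orchestration: phantom (or input stack) → align → assemble →
segment → reslice → morphometry → report.

A single config dictionary (usually loaded from YAML) drives the whole run.
Every emitted CSV starts with a ``# config_sha256=...`` comment line and a
``manifest.json`` records the config, its hash and the produced files, so a
run is self-describing and reruns under the same seed are bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import phantom as ph
from . import registration as reg
from . import stack_io
from .containers import LUMEN, NEOINTIMA, LabelVolume
from .morphometry import (
    MorphometryResult,
    compare_series,
    morphometry_from_series,
    ni_from_label_section,
    nvi,
)
from .reslice import extract_centerline, perpendicular_series
from .segmentation import SeedSet, seeds_from_labels, segment

__all__ = ["config_hash", "load_config", "run_pipeline"]

DEFAULTS = {
    "seed": 0,
    "registration": {"enabled": True, "roi": None, "max_rotation_deg": 5.0},
    "segmentation": {"seeds_csv": None, "beta": 1.0, "n_seeds_per_class": 10,
                     "erosion_iterations": 2, "presmooth_sigma_um": 1.0},
    "reslice": {"step_um": None, "size_px": 160, "pixel_size_um": 1.0,
                "smoothing_window": 5},
    "morphometry": {"split_um": None},
    "outputs": {"write_volumes": False},
}


def _merge(base: dict, override: dict | None) -> dict:
    out = {k: (v.copy() if isinstance(v, dict) else v) for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def config_hash(config: dict) -> str:
    canon = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _write_csv(frame: pd.DataFrame, path: Path, chash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_sha256={chash}\n")
        frame.to_csv(fh, index=False)


def _vessel_spec(cfg: dict) -> ph.VesselSpec:
    cfg = dict(cfg)
    if "lumen_radius_um" in cfg:
        cfg["lumen_radius_profile"] = cfg.pop("lumen_radius_um")
    return ph.VesselSpec(**cfg)


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run the full workflow described by ``config`` into ``out_dir``.

    Config sections: ``phantom`` (synthetic input with ground truth) or
    ``input`` (paths to a real stack + seeds CSV), plus ``registration``,
    ``segmentation``, ``reslice``, ``morphometry``, ``outputs`` and the
    global ``seed``.  Returns a dict with the in-memory results and the
    paths of the report files.  Deterministic given the seed.
    """
    cfg = _merge(DEFAULTS, config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    log_lines: list[str] = [f"config_sha256={chash}"]

    def log(stage: str, msg: str) -> None:
        log_lines.append(f"[{stage}] {msg}")

    def fail(stage: str, exc: Exception) -> Exception:
        return RuntimeError(f"pipeline stage '{stage}' failed: {exc}")

    t0 = time.time()
    seed = int(cfg["seed"])
    truth_transforms = None
    gt_label_stack = None
    vessel_spec = None

    # ---- input: phantom or stack from disk -------------------------------
    try:
        if "phantom" in cfg and cfg["phantom"]:
            pcfg = cfg["phantom"]
            vessel_spec = _vessel_spec(pcfg["vessel"])
            spacing = tuple(pcfg.get("spacing_um", (1.0, 1.0, 1.0)))
            volume0, labels0 = ph.generate_vessel_volume(
                vessel_spec, spacing=spacing, seed=seed
            )
            plan = ph.SectioningSpec(**_merge(
                {"seed": seed}, pcfg.get("sectioning", {})
            ))
            img_stack, gt_label_stack, truth_transforms = ph.section_volume(
                volume0, labels0, plan
            )
            log("input", f"phantom {vessel_spec.centerline_kind}, "
                         f"{len(img_stack)} sections of {img_stack.section_shape}")
        elif "input" in cfg and cfg["input"]:
            img_stack = stack_io.read_stack(cfg["input"]["stack"])
            log("input", f"read stack {cfg['input']['stack']} ({len(img_stack)} sections)")
        else:
            raise ValueError("config must provide either 'phantom' or 'input'")
    except Exception as exc:  # noqa: BLE001 - report stage provenance
        raise fail("input", exc) from exc

    # ---- registration ----------------------------------------------------
    rcfg = cfg["registration"]
    try:
        if rcfg["enabled"]:
            transforms = reg.align_stack(
                img_stack,
                roi=tuple(rcfg["roi"]) if rcfg["roi"] else None,
                max_rotation_deg=float(rcfg["max_rotation_deg"]),
            )
            img_stack = reg.apply_transforms(img_stack, transforms, "linear")
            if gt_label_stack is not None:
                gt_label_stack = reg.apply_transforms(gt_label_stack, transforms, "nearest")
            _write_csv(reg.transforms_to_frame(transforms),
                       out_dir / "transforms_estimated.csv", chash)
            log("registration", f"aligned {len(transforms)} sections")
        else:
            transforms = None
            log("registration", "disabled")
        if truth_transforms is not None:
            _write_csv(reg.transforms_to_frame(truth_transforms),
                       out_dir / "transforms_truth.csv", chash)
    except Exception as exc:
        raise fail("registration", exc) from exc

    # ---- assembly --------------------------------------------------------
    try:
        volume = stack_io.assemble_volume(img_stack)
        log("assembly", f"volume shape {volume.shape}, spacing {volume.spacing}")
    except Exception as exc:
        raise fail("assembly", exc) from exc

    # ---- segmentation ----------------------------------------------------
    scfg = cfg["segmentation"]
    try:
        if scfg["seeds_csv"]:
            seeds = SeedSet.from_csv(scfg["seeds_csv"])
        elif gt_label_stack is not None:
            gt_labels = LabelVolume(
                data=gt_label_stack.as_array().astype(np.uint8),
                spacing=volume.spacing,
            )
            seeds = seeds_from_labels(
                gt_labels,
                n_per_class=int(scfg["n_seeds_per_class"]),
                erosion_iterations=int(scfg["erosion_iterations"]),
                seed=seed,
            )
        else:
            raise ValueError("no seeds: provide segmentation.seeds_csv")
        labels = segment(
            volume, seeds, beta=float(scfg["beta"]),
            presmooth_sigma_um=float(scfg["presmooth_sigma_um"]),
        )
        log("segmentation", f"{len(seeds.entries)} seeds, beta={scfg['beta']}")
    except Exception as exc:
        raise fail("segmentation", exc) from exc

    # ---- centerline + morphometry ---------------------------------------
    lcfg = cfg["reslice"]
    try:
        centerline = extract_centerline(
            labels, smoothing_window=int(lcfg["smoothing_window"])
        )
        _write_csv(centerline.to_frame(), out_dir / "centerline.csv", chash)

        # conventional: NI on the stack-plane sections (z slices), matched
        # to the arclength of the per-slice centerline point
        zs = [k for k in range(labels.shape[0]) if np.any(labels.data[k] == LUMEN)]
        conv_rows = []
        for i, k in enumerate(zs):
            sl = labels.data[k]
            if not np.any((sl == LUMEN) | (sl == NEOINTIMA)):
                continue
            a_n, a_l, value = ni_from_label_section(sl, pixel_area=volume.spacing[1] * volume.spacing[2])
            conv_rows.append(
                {"arclength_um": float(centerline.arclength[i]),
                 "area_neointima_um2": a_n, "area_lumen_um2": a_l,
                 "ni_percent": value}
            )
        segment_morph = nvi(labels)
        conventional = MorphometryResult(
            per_section=pd.DataFrame(conv_rows),
            segment=segment_morph,
            provenance="conventional_stack_plane",
        )

        # corrected: perpendicular virtual re-sections at the same arclengths
        arcs = conventional.per_section["arclength_um"].to_numpy()
        series = perpendicular_series(
            None, labels, centerline,
            arclengths=arcs,
            size=int(lcfg["size_px"]),
            pixel_size=float(lcfg["pixel_size_um"]),
        )
        corrected = morphometry_from_series(
            [lab for _, lab, _ in series], arcs,
            segment=segment_morph, provenance="corrected_perpendicular",
        )
        # keep the two series matched section-for-section
        keep = np.isin(arcs, corrected.per_section["arclength_um"].to_numpy())
        conventional.per_section = conventional.per_section[keep].reset_index(drop=True)
        log("morphometry",
            f"{len(conventional.per_section)} levels, NVI={segment_morph.nvi_rounded}")
    except Exception as exc:
        raise fail("morphometry", exc) from exc

    # ---- reporting -------------------------------------------------------
    try:
        conv_table = conventional.per_section.copy()
        corr_table = corrected.per_section.copy()
        if vessel_spec is not None:
            total = centerline.total_arclength
            for table in (conv_table, corr_table):
                s_frac = np.clip(table["arclength_um"] / total, 0.0, 1.0)
                table["ni_analytic"] = [ph.analytic_ni(vessel_spec, s) for s in s_frac]
                table["ni_error"] = table["ni_percent"] - table["ni_analytic"]
        _write_csv(conv_table, out_dir / "ni_conventional.csv", chash)
        _write_csv(corr_table, out_dir / "ni_corrected.csv", chash)

        comparison = compare_series(
            conventional, corrected,
            split_um=cfg["morphometry"]["split_um"],
        )
        _write_csv(comparison, out_dir / "comparison.csv", chash)

        summary = pd.DataFrame([
            {
                "nvi_percent": segment_morph.nvi_rounded,
                "neointima_voxels": segment_morph.neointima_voxels,
                "neointima_um3": segment_morph.neointima_um3,
                "neointima_plus_lumen_voxels": segment_morph.neointima_plus_lumen_voxels,
                "neointima_plus_lumen_um3": segment_morph.neointima_plus_lumen_um3,
                "nvi_analytic": (
                    round(ph.analytic_nvi(vessel_spec), 3) if vessel_spec else np.nan
                ),
                "n_levels": len(conventional.per_section),
            }
        ])
        _write_csv(summary, out_dir / "summary.csv", chash)

        if cfg["outputs"]["write_volumes"]:
            stack_io.write_volume(volume, out_dir / "volume.tif")
            stack_io.write_labels(labels, out_dir / "labels.tif")

        log("report", f"done in {time.time() - t0:.1f} s")
        manifest = {
            "config_sha256": chash,
            "config": cfg,
            "files": sorted(p.name for p in out_dir.iterdir() if p.is_file()),
        }
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        with open(out_dir / "pipeline.log", "w") as fh:
            fh.write("\n".join(log_lines) + "\n")
    except Exception as exc:
        raise fail("report", exc) from exc

    return {
        "config_hash": chash,
        "volume": volume,
        "labels": labels,
        "centerline": centerline,
        "conventional": conventional,
        "corrected": corrected,
        "comparison": comparison,
        "segment": segment_morph,
        "truth_transforms": truth_transforms,
        "transforms": transforms,
        "out_dir": out_dir,
    }
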