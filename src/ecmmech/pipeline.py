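"""End-to-end orchestration: generate or ingest data, fit, quantify, compare.

A run is driven by a single config (TOML file or dict) with per-stage blocks;
every randomized stage derives its seed from the master seed, so re-running
with the same config reproduces identical outputs.  Each run writes a
manifest JSON recording the config hash, seed, package versions, per-stage
row counts and warnings.

The synthetic demo emulates the study design at reduced scale: four groups
(young/aged x RV/FV) whose generative ground truths are the reported group
means — Young's moduli 0.47/0.26/0.36/0.54 kPa, adhesion 2.29/1.02/1.35/1.65
nN, ECM activated-fraction shifts +19% (collagen I), +15% (fibronectin),
-15% (laminin), and 97% live cells.
"""

from __future__ import annotations

import hashlib
import json
import os
import tomllib
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import afm, cells, intensity, io_formats, stats, synthetic
from .types import AGE_LEVELS, VOLUME_LEVELS

# Generative ground truths per (age, volume) group: the reported group means.
GROUP_TRUTH: dict[tuple[str, str], dict[str, float]] = {
    ("young", "RV"): {"E_Pa": 470.0, "F_adh_nN": 2.29},
    ("aged", "RV"): {"E_Pa": 260.0, "F_adh_nN": 1.02},
    ("young", "FV"): {"E_Pa": 360.0, "F_adh_nN": 1.35},
    ("aged", "FV"): {"E_Pa": 540.0, "F_adh_nN": 1.65},
}

# Aged-over-young multiplicative shifts of the activated-pixel fraction.
PROTEIN_SHIFTS: dict[str, float] = {
    "collagen_I": 1.19,
    "fibronectin": 1.15,
    "laminin": 0.85,
}

STAGES = ("gen-data", "afm-fit", "ecm-quant", "cell-quant", "stats")


class ConfigError(ValueError):
    """Invalid run configuration (exit code 2 at the CLI)."""


@dataclass
class RunConfig:
    seed: int = 7
    out_dir: str = "results"
    # scaled-down study design for the synthetic demo
    n_samples_per_group: int = 3
    n_regions: int = 2
    n_points: int = 2
    n_replicates: int = 2
    n_images_per_group: int = 3
    n_cell_fields_per_group: int = 2
    baseline_activated_fraction: float = 0.25
    fit: afm.FitOptions = field(default_factory=afm.FitOptions)
    intensity_thresholds: tuple[float, float] = (115.0, 255.0)
    cell_thresholds: dict[str, float] = field(default_factory=lambda: {
        "nuclei": 100.0, "ki67": 100.0, "live": 100.0, "dead": 100.0})
    min_diameter_px: float = 6.0
    dilation_radius_px: int = 2
    raw: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_toml(cls, path: str) -> "RunConfig":
        if not os.path.exists(path):
            raise ConfigError(f"config file not found: {path}")
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        cfg = cls(raw=raw)
        for key in ("seed", "out_dir", "n_samples_per_group", "n_regions",
                    "n_points", "n_replicates", "n_images_per_group",
                    "n_cell_fields_per_group", "baseline_activated_fraction",
                    "min_diameter_px", "dilation_radius_px"):
            if key in raw:
                setattr(cfg, key, raw[key])
        fit = raw.get("fit", {})
        for key, val in fit.items():
            if not hasattr(cfg.fit, key):
                raise ConfigError(f"unknown [fit] option {key!r}")
            setattr(cfg.fit, key, tuple(val) if isinstance(val, list) else val)
        if "intensity" in raw:
            blk = raw["intensity"]
            cfg.intensity_thresholds = (blk.get("lower", cfg.intensity_thresholds[0]),
                                        blk.get("upper", cfg.intensity_thresholds[1]))
        if "cell" in raw:
            cfg.cell_thresholds.update(raw["cell"])
        return cfg

    def digest(self) -> str:
        payload = {k: v for k, v in self.__dict__.items() if k not in ("fit", "raw")}
        payload["fit"] = self.fit.__dict__
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str)
                              .encode()).hexdigest()[:16]


def _subseed(master: int, *key) -> int:
    ss = np.random.SeedSequence((int(master),) + tuple(int(hashlib.sha256(
        str(k).encode()).hexdigest()[:8], 16) for k in key))
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_gen_data(cfg: RunConfig, outdir: str) -> dict:
    data_dir = os.path.join(outdir, "data")
    os.makedirs(data_dir, exist_ok=True)
    design_rows = []
    n_curves = 0
    for (age, vol), truth in GROUP_TRUTH.items():
        for s in range(cfg.n_samples_per_group):
            sample = f"{age}_{vol}_{s}"
            sdir = os.path.join(data_dir, "curves", sample)
            os.makedirs(sdir, exist_ok=True)
            spec = synthetic.CurveGenSpec(
                E_true=truth["E_Pa"], adhesion_depth=truth["F_adh_nN"] * 1e-9,
                seed=_subseed(cfg.seed, "afm", age, vol, s))
            batch = synthetic.generate_curve_batch(
                spec, cfg.n_regions, cfg.n_points, cfg.n_replicates,
                sample=sample, age=age, volume=vol)
            for rec in batch.records:
                fname = f"r{rec.region}_p{rec.point}_i{rec.replicate}.tsv"
                io_formats.write_force_curve_table(rec.curve, os.path.join(sdir, fname))
                with open(os.path.join(sdir, fname.replace(".tsv", ".truth.json")), "w") as fh:
                    fh.write(rec.truth.to_json() + "\n")
                n_curves += 1
            design_rows.append({"sample_id": sample, "age": age, "volume": vol,
                                "path": os.path.relpath(sdir, data_dir)})
    design = pd.DataFrame(design_rows)
    io_formats.write_group_design(design, os.path.join(data_dir, "design_afm.tsv"))

    n_images = 0
    img_index = []
    for protein, shift in PROTEIN_SHIFTS.items():
        for age in AGE_LEVELS:
            frac = cfg.baseline_activated_fraction * (shift if age == "aged" else 1.0)
            spec = synthetic.ImageGenSpec(
                activated_fraction_true=frac,
                seed=_subseed(cfg.seed, "ecm", protein, age))
            image_set = synthetic.generate_if_image_set(spec, cfg.n_images_per_group)
            for i, (img, truth) in enumerate(image_set):
                pdir = os.path.join(data_dir, "ecm", protein)
                os.makedirs(pdir, exist_ok=True)
                path = os.path.join(pdir, f"{age}_{i}.tiff")
                io_formats.write_multichannel_tiff(path, img)
                io_formats.write_json(truth, path + ".truth.json")
                img_index.append({"protein": protein, "age": age,
                                  "path": os.path.relpath(path, data_dir)})
                n_images += 1
    pd.DataFrame(img_index).to_csv(os.path.join(data_dir, "ecm_images.tsv"),
                                   sep="\t", index=False)

    n_fields = 0
    field_index = []
    for (age, vol) in GROUP_TRUTH:
        for i in range(cfg.n_cell_fields_per_group):
            spec = synthetic.CellImageGenSpec(
                n_nuclei=60, seed=_subseed(cfg.seed, "cells", age, vol, i))
            stack, truth = synthetic.generate_cell_image(spec)
            cdir = os.path.join(data_dir, "cells")
            os.makedirs(cdir, exist_ok=True)
            path = os.path.join(cdir, f"{age}_{vol}_{i}.tiff")
            io_formats.write_multichannel_tiff(path, stack)
            io_formats.write_json(truth, path + ".truth.json")
            field_index.append({"age": age, "volume": vol,
                                "path": os.path.relpath(path, data_dir)})
            n_fields += 1
    pd.DataFrame(field_index).to_csv(os.path.join(data_dir, "cell_fields.tsv"),
                                     sep="\t", index=False)
    return {"n_curves": n_curves, "n_ecm_images": n_images, "n_cell_fields": n_fields}


def load_curve_batches(design: io_formats.GroupDesign, base_dir: str):
    """Re-read generated (or external) curve tables into per-sample batches."""
    from .types import CurveBatch, CurveRecord
    batches = []
    for row in design:
        sdir = row.path if os.path.isabs(row.path) else os.path.join(base_dir, row.path)
        records = []
        for fname in sorted(os.listdir(sdir)):
            if not fname.endswith(".tsv"):
                continue
            curve = io_formats.read_force_curve_table(os.path.join(sdir, fname))
            stem = fname[:-4].split("_")
            r, p, i = (int(part[1:]) for part in stem[:3])
            records.append(CurveRecord(row.sample_id, r, p, i, curve))
        batches.append(CurveBatch(sample=row.sample_id, records=records,
                                  age=row.age, volume=row.volume))
    return batches


def stage_afm_fit(cfg: RunConfig, outdir: str) -> dict:
    data_dir = os.path.join(outdir, "data")
    design = io_formats.read_group_design(os.path.join(data_dir, "design_afm.tsv"))
    frames = [afm.analyze_batch(b, cfg.fit) for b in load_curve_batches(design, data_dir)]
    per_curve = pd.concat(frames, ignore_index=True)
    agg = afm.aggregate_hierarchy(per_curve)
    io_formats.write_results_tsv(per_curve, os.path.join(outdir, "afm_per_curve.tsv"))
    for level in ("point", "region", "sample", "group"):
        if level in agg:
            io_formats.write_results_tsv(agg[level],
                                         os.path.join(outdir, f"afm_{level}.tsv"))
    io_formats.write_json(agg["qc"], os.path.join(outdir, "afm_qc.json"))
    return {"n_curves": int(len(per_curve)), "n_flagged": agg["qc"]["n_flagged"]}


def stage_ecm_quant(cfg: RunConfig, outdir: str) -> dict:
    data_dir = os.path.join(outdir, "data")
    index = pd.read_csv(os.path.join(data_dir, "ecm_images.tsv"), sep="\t")
    lower, upper = cfg.intensity_thresholds
    prof_rows, cmp_rows = [], []
    for protein, sub in index.groupby("protein"):
        profs = {"young": [], "aged": []}
        for row in sub.itertuples(index=False):
            img = io_formats.read_multichannel_tiff(os.path.join(data_dir, row.path))
            prof = intensity.compute_intensity_profile(
                img.data[0], lower, upper, bit_depth=img.bit_depth,
                subsample_seed=_subseed(cfg.seed, "kde", row.path))
            profs[row.age].append(prof)
            prof_rows.append({
                "protein": protein, "age": row.age, "path": row.path,
                "peak_intensity": prof.peak_intensity, "weak_area": prof.weak_area,
                "intense_area": prof.intense_area,
                "activated_fraction": prof.activated_fraction,
                "flagged": prof.flagged})
        cmp_row = intensity.compare_protein_groups(profs["young"], profs["aged"])
        cmp_row["protein"] = protein
        cmp_rows.append(cmp_row)
    io_formats.write_results_tsv(pd.DataFrame(prof_rows),
                                 os.path.join(outdir, "ecm_profiles.tsv"))
    io_formats.write_results_tsv(pd.DataFrame(cmp_rows),
                                 os.path.join(outdir, "ecm_comparison.tsv"))
    return {"n_images": int(len(prof_rows)), "n_proteins": int(len(cmp_rows))}


def stage_cell_quant(cfg: RunConfig, outdir: str) -> dict:
    data_dir = os.path.join(outdir, "data")
    index = pd.read_csv(os.path.join(data_dir, "cell_fields.tsv"), sep="\t")
    thr = cfg.cell_thresholds
    rows = []
    for row in index.itertuples(index=False):
        img = io_formats.read_multichannel_tiff(os.path.join(data_dir, row.path))
        res = cells.quantify_field(
            img.data, field_id=os.path.basename(row.path),
            nuclei_threshold=thr["nuclei"], ki67_threshold=thr["ki67"],
            live_threshold=thr["live"], dead_threshold=thr["dead"],
            min_diameter_px=cfg.min_diameter_px,
            dilation_radius_px=cfg.dilation_radius_px)
        rows.append({"age": row.age, "volume": row.volume, **res.__dict__})
    df = pd.DataFrame(rows)
    io_formats.write_results_tsv(df, os.path.join(outdir, "cell_quant.tsv"))
    return {"n_fields": int(len(df))}


def stage_stats(cfg: RunConfig, outdir: str) -> dict:
    sample = pd.read_csv(os.path.join(outdir, "afm_sample.tsv"), sep="\t")
    n_terms = 0
    for metric in ("E_Pa", "F_adh_nN", "hysteresis_ratio"):
        table = stats.two_way_anova(sample, response=metric)
        table.insert(0, "term", table.index)
        io_formats.write_results_tsv(table.reset_index(drop=True),
                                     os.path.join(outdir, f"anova_{metric}.tsv"))
        n_terms += len(table)
        summaries = stats.summarize_groups(sample, metric, ["age", "volume"])
        io_formats.write_results_tsv(
            pd.DataFrame([{"age": s.group[0], "volume": s.group[1], "n": s.n,
                           "mean": s.mean, "se": s.se} for s in summaries]),
            os.path.join(outdir, f"summary_{metric}.tsv"))
    return {"n_anova_terms": n_terms}


_STAGE_FUNCS = {
    "gen-data": stage_gen_data,
    "afm-fit": stage_afm_fit,
    "ecm-quant": stage_ecm_quant,
    "cell-quant": stage_cell_quant,
    "stats": stage_stats,
}


def run_pipeline(cfg: RunConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Execute the requested stages in dependency order and write a manifest."""
    import ecmmech
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    outdir = cfg.out_dir
    os.makedirs(outdir, exist_ok=True)
    manifest: dict[str, Any] = {
        "seed": cfg.seed,
        "config_hash": cfg.digest(),
        "versions": {"ecmmech": ecmmech.__version__,
                     "numpy": np.__version__, "pandas": pd.__version__},
        "stages": {},
        "status": "running",
    }
    ordered = [s for s in STAGES if s in stages]
    try:
        for name in ordered:
            manifest["stages"][name] = _STAGE_FUNCS[name](cfg, outdir)
        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = f"failed at {name}: {exc}"
        io_formats.write_json(manifest, os.path.join(outdir, "manifest.json"))
        raise
    io_formats.write_json(manifest, os.path.join(outdir, "manifest.json"))
    return manifest
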