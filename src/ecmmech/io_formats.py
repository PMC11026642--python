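"""Readers and writers for every external artifact.

Formats
-------
* Force curve: one TSV table per curve, long format, ``segment / z_nm /
  deflection_nm`` columns, probe constants in ``# key: value`` header lines
  (``k_N_per_m``, ``R_um``). Units are nanometres on both axes; withdrawal
  rows are stored in acquisition order and normalized on read.
* Images: multi-channel TIFF (8- or 16-bit), channel-first planes; intensities
  are never rescaled on read — all thresholds downstream are in native units.
* Group design: TSV with columns ``sample_id / age / volume / path``; age and
  volume come from closed vocabularies.
* Results: TSV tables (pandas) and JSON run summaries.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile

from .types import AGE_LEVELS, VOLUME_LEVELS, ForceCurve

log = logging.getLogger(__name__)

FORCE_CURVE_COLUMNS = ("segment", "z_nm", "deflection_nm")


class ParseError(ValueError):
    """A file does not conform to its documented dialect."""


@dataclass
class IntensityImage:
    """Multi-channel pixel data with labels; values in native intensity units."""

    data: np.ndarray                 # (C, H, W)
    bit_depth: int
    channel_labels: tuple[str, ...]
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_3d(self.data)
        if self.data.ndim != 3:
            raise ValueError("image data must be (C, H, W)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_labels.index(label)]


# ---------------------------------------------------------------------------
# Force-curve tables
# ---------------------------------------------------------------------------

def write_force_curve_table(curve: ForceCurve, path: str | os.PathLike) -> None:
    curve.validate()
    with open(path, "w") as fh:
        fh.write(f"# curve_id: {curve.curve_id}\n")
        fh.write(f"# k_N_per_m: {curve.k!r}\n")
        fh.write(f"# R_um: {curve.R_um!r}\n")
        for key, val in curve.metadata.items():
            fh.write(f"# meta.{key}: {val}\n")
        fh.write("\t".join(FORCE_CURVE_COLUMNS) + "\n")
        for seg, z, d in (("approach", curve.z_app_nm, curve.defl_app_nm),
                          ("withdrawal", curve.z_ret_nm, curve.defl_ret_nm)):
            for zi, di in zip(z, d):
                fh.write(f"{seg}\t{zi:.17g}\t{di:.17g}\n")


def read_force_curve_table(path: str | os.PathLike) -> ForceCurve:
    """Parse one force-curve table; fails loudly naming the offending line."""
    header: dict[str, str] = {}
    segments: dict[str, list[tuple[float, float]]] = {"approach": [], "withdrawal": []}
    col_line_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                header[key.strip()] = val.strip()
                continue
            parts = line.split("\t")
            if not col_line_seen:
                if tuple(p.strip() for p in parts) != FORCE_CURVE_COLUMNS:
                    raise ParseError(
                        f"{path}:{lineno}: expected columns {FORCE_CURVE_COLUMNS}, got {parts}")
                col_line_seen = True
                continue
            if len(parts) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            seg = parts[0].strip()
            if seg not in segments:
                raise ParseError(f"{path}:{lineno}: unknown segment {seg!r}")
            try:
                z, d = float(parts[1]), float(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
            segments[seg].append((z, d))

    for key in ("k_N_per_m", "R_um"):
        if key not in header:
            raise ParseError(f"{path}: missing required header '# {key}: ...'")
    try:
        k = float(header["k_N_per_m"])
        R_um = float(header["R_um"])
    except ValueError:
        raise ParseError(f"{path}: non-numeric k/R header value") from None
    for seg in ("approach", "withdrawal"):
        if not segments[seg]:
            raise ParseError(f"{path}: missing {seg} segment")

    z_app, d_app = (np.array(v) for v in zip(*segments["approach"]))
    z_ret, d_ret = (np.array(v) for v in zip(*segments["withdrawal"]))
    # normalize withdrawal to acquisition order (z decreasing)
    if z_ret.size > 1 and z_ret[0] < z_ret[-1]:
        z_ret, d_ret = z_ret[::-1], d_ret[::-1]
    metadata = {key[5:]: val for key, val in header.items() if key.startswith("meta.")}
    curve = ForceCurve(
        curve_id=header.get("curve_id", os.path.basename(os.fspath(path))),
        z_app_nm=z_app, defl_app_nm=d_app, z_ret_nm=z_ret, defl_ret_nm=d_ret,
        k=k, R_um=R_um, metadata=metadata)
    curve.validate()
    return curve


# ---------------------------------------------------------------------------
# TIFF images
# ---------------------------------------------------------------------------

def write_multichannel_tiff(path: str | os.PathLike, data: np.ndarray) -> None:
    data = np.asarray(data)
    if data.dtype not in (np.uint8, np.uint16):
        raise ValueError(f"only 8/16-bit images are written, got dtype {data.dtype}")
    if data.ndim == 2:
        data = data[None]
    tifffile.imwrite(path, data, photometric="minisblack")


def read_multichannel_tiff(path: str | os.PathLike,
                           channel_labels: tuple[str, ...] | None = None,
                           pixel_size_um: float | None = None) -> IntensityImage:
    """Read a 1-4 channel, 8- or 16-bit TIFF; intensities are left untouched."""
    data = tifffile.imread(path)
    if data.dtype == np.uint8:
        bit_depth = 8
    elif data.dtype == np.uint16:
        bit_depth = 16
    else:
        raise ValueError(f"{path}: unsupported bit depth (dtype {data.dtype}; expected uint8/uint16)")
    if data.ndim == 2:
        data = data[None]
    elif data.ndim == 3:
        if data.shape[-1] in (3, 4) and data.shape[0] not in (1, 2, 3, 4):
            log.warning("%s: interpreting a (H, W, %d) plane as interleaved channels",
                        path, data.shape[-1])
            data = np.moveaxis(data, -1, 0)
    else:
        raise ValueError(f"{path}: unsupported TIFF layout with shape {data.shape}")
    if data.shape[0] > 4:
        raise ValueError(f"{path}: unsupported channel count {data.shape[0]} (expected 1-4)")
    if channel_labels is None:
        channel_labels = tuple(f"ch{i}" for i in range(data.shape[0]))
    if len(channel_labels) != data.shape[0]:
        raise ValueError(f"{path}: {data.shape[0]} channels found but "
                         f"{len(channel_labels)} labels configured")
    return IntensityImage(data=data, bit_depth=bit_depth,
                          channel_labels=tuple(channel_labels),
                          pixel_size_um=pixel_size_um)


# ---------------------------------------------------------------------------
# Group design
# ---------------------------------------------------------------------------

@dataclass
class GroupDesign:
    """Sample -> (age, volume, data path) assignment table."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __iter__(self):
        return iter(self.table.itertuples(index=False))

    def __len__(self) -> int:
        return len(self.table)


def read_group_design(path: str | os.PathLike, check_paths: bool = True) -> GroupDesign:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "age", "volume", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing design columns {sorted(missing)}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise ParseError(f"{path}: duplicate sample_id {dup.iloc[0]!r}")
    for idx, row in df.iterrows():
        if row["age"] not in AGE_LEVELS:
            raise ParseError(f"{path} row {idx}: age {row['age']!r} not in {AGE_LEVELS}")
        if row["volume"] not in VOLUME_LEVELS:
            raise ParseError(f"{path} row {idx}: volume {row['volume']!r} not in {VOLUME_LEVELS}")
    if check_paths:
        base = os.path.dirname(os.path.abspath(os.fspath(path)))
        for idx, row in df.iterrows():
            target = row["path"]
            if not os.path.isabs(target):
                target = os.path.join(base, target)
            if not os.path.exists(target):
                raise ParseError(f"{path} row {idx}: referenced path does not exist: {row['path']}")
    return GroupDesign(table=df)


def write_group_design(design: pd.DataFrame, path: str | os.PathLike) -> None:
    design.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

def write_results_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_json(obj: dict, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
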