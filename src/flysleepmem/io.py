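"""Readers and writers for the field's file formats.

- activity: TriKinetics DAM monitor files (tab-delimited, 42 columns, the
  last 32 being per-channel beam-break counts) and a minimal two-column
  ``time_min,count`` CSV; the dialect is auto-detected from the column
  count and logged;
- sleep outputs: per-fly bout CSV and 30-min profile CSV;
- calcium: multi-page grayscale TIFF movies (time-major pages) with a JSON
  metadata sidecar carrying the volume shape and rate; voxel masks as JSON
  voxel lists or label TIFFs;
- generic JSON reports with a schema version field.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from flysleepmem.calcium import CalciumMovie, R2Volume
from flysleepmem.exceptions import ValidationError
from flysleepmem.sleep import ActivityTrace, SleepBout, SleepProfile

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

DAM_N_COLUMNS = 42
DAM_N_CHANNELS = 32


# ---------------------------------------------------------------------------
# Activity traces


def read_activity(path, t0_min: int = 0) -> list[ActivityTrace]:
    """Read activity counts; returns one trace per occupied DAM channel, or a
    single trace for the minimal CSV dialect."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    n_tabs = first.count("\t")
    if n_tabs >= DAM_N_COLUMNS - 1:
        logger.info("reading %s as TriKinetics DAM monitor text", path.name)
        return _read_dam_monitor(path, t0_min)
    logger.info("reading %s as minimal time,count CSV", path.name)
    return [_read_minimal_csv(path, t0_min)]


def _read_dam_monitor(path: Path, t0_min: int) -> list[ActivityTrace]:
    df = pd.read_csv(path, sep="\t", header=None)
    if df.shape[1] != DAM_N_COLUMNS:
        raise ValidationError(
            f"{path.name}: expected {DAM_N_COLUMNS} tab-separated columns, "
            f"got {df.shape[1]}"
        )
    counts = df.iloc[:, -DAM_N_CHANNELS:].to_numpy()
    traces = []
    stem = path.stem
    for ch in range(DAM_N_CHANNELS):
        col = counts[:, ch]
        traces.append(ActivityTrace(
            fly_id=f"{stem}_ch{ch + 1:02d}", t0_min=t0_min,
            counts=np.asarray(col, dtype=np.int64),
        ))
    return traces


def _read_minimal_csv(path: Path, t0_min: int) -> ActivityTrace:
    df = pd.read_csv(path)
    if df.shape[1] != 2:
        raise ValidationError(f"{path.name}: minimal dialect needs 2 columns")
    counts = df.iloc[:, 1].to_numpy()
    t = df.iloc[:, 0].to_numpy()
    start = int(t[0]) if np.issubdtype(np.asarray(t).dtype, np.number) else t0_min
    return ActivityTrace(fly_id=path.stem, t0_min=start,
                         counts=np.asarray(counts, dtype=np.int64))


def write_activity_csv(trace: ActivityTrace, path) -> None:
    """Minimal dialect: columns time_min (from training onset) and count."""
    t = trace.t0_min + np.arange(trace.duration_min)
    pd.DataFrame({"time_min": t, "count": trace.counts}).to_csv(path, index=False)


def write_dam_monitor(traces: list[ActivityTrace], path) -> None:
    """Write up to 32 equal-length traces as a DAM monitor text file."""
    if not traces or len(traces) > DAM_N_CHANNELS:
        raise ValidationError(f"need 1..{DAM_N_CHANNELS} traces")
    n = traces[0].duration_min
    if any(tr.duration_min != n for tr in traces):
        raise ValidationError("all traces must have equal length")
    counts = np.zeros((n, DAM_N_CHANNELS), dtype=np.int64)
    for ch, tr in enumerate(traces):
        counts[:, ch] = tr.counts
    with open(path, "w") as fh:
        for i in range(n):
            minute = traces[0].t0_min + i
            hh, mm = divmod(minute % 1440, 60)
            meta = [str(i + 1), "1 Jan 26", f"{hh:02d}:{mm:02d}:00", "1"] + ["0"] * 6
            fh.write("\t".join(meta + [str(c) for c in counts[i]]) + "\n")


# ---------------------------------------------------------------------------
# Sleep outputs


def write_bouts_csv(bouts_by_fly: dict[str, list[SleepBout]], path) -> None:
    rows = [
        (fly, b.start_min, b.end_min, int(b.censored))
        for fly, bouts in bouts_by_fly.items()
        for b in bouts
    ]
    pd.DataFrame(rows, columns=["fly_id", "start_min", "end_min", "censored"]).to_csv(
        path, index=False
    )


def read_bouts_csv(path) -> dict[str, list[SleepBout]]:
    df = pd.read_csv(path, dtype={"fly_id": str})
    out: dict[str, list[SleepBout]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.fly_id, []).append(
            SleepBout(int(row.start_min), int(row.end_min), bool(row.censored))
        )
    return out


def write_profile_csv(profiles_by_fly: dict[str, SleepProfile], path) -> None:
    rows = []
    for fly, prof in profiles_by_fly.items():
        for lo, hi, m in zip(prof.bin_edges_min[:-1], prof.bin_edges_min[1:],
                             prof.minutes_asleep):
            rows.append((fly, lo, hi, m))
    pd.DataFrame(
        rows, columns=["fly_id", "bin_start_min", "bin_end_min", "minutes_asleep"]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Calcium movies, masks, maps


def write_movie_tiff(movie: CalciumMovie, tiff_path, sidecar_path=None) -> None:
    """Time-major multi-page TIFF (pages = time * z) plus a JSON sidecar with
    the volume shape and acquisition metadata."""
    tiff_path = Path(tiff_path)
    t, z, y, x = movie.data.shape
    tifffile.imwrite(tiff_path, movie.data.reshape(t * z, y, x).astype(np.float32),
                     photometric="minisblack")
    sidecar = Path(sidecar_path) if sidecar_path else tiff_path.with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "schema_version": SCHEMA_VERSION,
                "n_volumes": t,
                "volume_shape": [z, y, x],
                "volume_rate_hz": movie.volume_rate_hz,
                "meta": movie.meta,
            },
            fh, indent=2,
        )


def read_movie_tiff(tiff_path, sidecar_path=None) -> CalciumMovie:
    tiff_path = Path(tiff_path)
    sidecar = Path(sidecar_path) if sidecar_path else tiff_path.with_suffix(".json")
    if not sidecar.exists():
        raise ValidationError(f"missing metadata sidecar {sidecar}")
    with open(sidecar) as fh:
        meta = json.load(fh)
    pages = tifffile.imread(tiff_path)
    t = int(meta["n_volumes"])
    z, y, x = (int(v) for v in meta["volume_shape"])
    if pages.shape != (t * z, y, x):
        raise ValidationError(
            f"TIFF pages {pages.shape} inconsistent with sidecar ({t}*{z}, {y}, {x})"
        )
    return CalciumMovie(
        data=pages.reshape(t, z, y, x).astype(float),
        volume_rate_hz=float(meta["volume_rate_hz"]),
        meta=meta.get("meta", {}),
    )


def write_mask_json(mask: np.ndarray, path, label: str = "roi") -> None:
    """Voxel-list mask: shape plus (z, y, x) indices of True voxels."""
    mask = np.asarray(mask, dtype=bool)
    voxels = np.argwhere(mask)
    with open(path, "w") as fh:
        json.dump(
            {
                "schema_version": SCHEMA_VERSION,
                "label": label,
                "shape": list(mask.shape),
                "voxels": voxels.tolist(),
            },
            fh,
        )


def read_mask_json(path) -> tuple[np.ndarray, str]:
    with open(path) as fh:
        d = json.load(fh)
    mask = np.zeros(tuple(d["shape"]), dtype=bool)
    vox = np.asarray(d["voxels"], dtype=np.intp)
    if vox.size:
        if vox.min() < 0 or np.any(vox.max(axis=0) >= mask.shape):
            raise ValidationError("mask voxels outside the stated shape")
        mask[tuple(vox.T)] = True
    return mask, d.get("label", "roi")


def read_mask_tiff(path, label_value: int | None = None) -> np.ndarray:
    """Label TIFF: nonzero (or a specific label value) marks ROI voxels."""
    arr = tifffile.imread(path)
    if arr.ndim != 3:
        raise ValidationError("label TIFF must be a 3-D stack")
    return arr == label_value if label_value is not None else arr != 0


def write_r2_tiffs(r2: R2Volume, float_path, uint16_path) -> None:
    """Write the R2 map as 32-bit float and as the 16-bit linear projection."""
    from flysleepmem.calcium import r2_to_uint16_stack

    tifffile.imwrite(float_path, r2.r2.astype(np.float32), photometric="minisblack")
    tifffile.imwrite(uint16_path, r2_to_uint16_stack(r2), photometric="minisblack")


def read_uint16_stack(path) -> np.ndarray:
    return tifffile.imread(path)


# ---------------------------------------------------------------------------
# Generic reports


def write_report_json(payload: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump({"schema_version": SCHEMA_VERSION, **payload}, fh, indent=2,
                  default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
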