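"""File formats: TIFF images/volumes with JSON sidecars, CSV traces.

Volumes are stored as multi-page TIFF (intensity pages first, then the
optional DOPU pages) plus a JSON sidecar carrying pixel pitch, region
label, channel list and seed.  Gaze traces, trajectory logs, layer
surfaces and point-pair sets travel as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .layers import LayerSurfaces
from .registration import PointPair, RegionTransform
from .synthetic import GazeTrace, OCTVolume


def write_image(path: str | Path, image: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))


def read_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path))


def write_volume(path: str | Path, volume: OCTVolume) -> None:
    path = Path(path)
    channels = ["intensity"] + (["dopu"] if volume.dopu is not None else [])
    pages = [volume.intensity.astype(np.float32)]
    if volume.dopu is not None:
        pages.append(volume.dopu.astype(np.float32))
    tifffile.imwrite(str(path), np.concatenate(pages, axis=0))
    sidecar = {
        "pixel_pitch_um": list(volume.pitch_um),
        "region": volume.region,
        "channels": channels,
        "seed": volume.seed,
        "n_bscans": volume.n_bscans,
        "meta": {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in volume.meta.items()},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_volume(path: str | Path) -> OCTVolume:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    stack = tifffile.imread(str(path))
    nb = sidecar["n_bscans"]
    intensity = stack[:nb]
    dopu = stack[nb:2 * nb] if "dopu" in sidecar["channels"] else None
    return OCTVolume(intensity=intensity, dopu=dopu,
                     pitch_um=tuple(sidecar["pixel_pitch_um"]),
                     region=sidecar["region"], seed=sidecar["seed"],
                     meta=sidecar.get("meta", {}))


def write_gaze(path: str | Path, trace: GazeTrace) -> None:
    n = len(trace)
    blink = np.zeros(n, dtype=int)
    for a, b in trace.blink_intervals:
        blink[a:b] = 1
    pd.DataFrame({
        "frame": np.arange(n),
        "dx_um": trace.offsets_um[:, 0],
        "dy_um": trace.offsets_um[:, 1],
        "blink_flag": blink,
    }).to_csv(path, index=False)


def read_gaze(path: str | Path, frame_rate: float = 60.0) -> GazeTrace:
    df = pd.read_csv(path)
    offsets = df[["dx_um", "dy_um"]].to_numpy(dtype=float)
    blink = df["blink_flag"].to_numpy(dtype=int)
    intervals: list[tuple[int, int]] = []
    in_blink = False
    start = 0
    for i, b in enumerate(blink):
        if b and not in_blink:
            start, in_blink = i, True
        elif not b and in_blink:
            intervals.append((start, i))
            in_blink = False
    if in_blink:
        intervals.append((start, len(blink)))
    return GazeTrace(offsets_um=offsets, frame_rate=frame_rate,
                     blink_intervals=intervals)


def write_trajectory(path: str | Path, log: list[dict]) -> None:
    pd.DataFrame(log, columns=["frame", "bscan_index", "dx", "dy", "peak",
                               "valid", "event"]).to_csv(path, index=False)


def write_surfaces(path: str | Path, surfaces: LayerSurfaces) -> None:
    nb, nx = surfaces.ilm.shape
    b, a = np.meshgrid(np.arange(nb), np.arange(nx), indexing="ij")
    pd.DataFrame({
        "bscan": b.ravel(), "ascan": a.ravel(),
        "ilm": surfaces.ilm.ravel(), "isos": surfaces.isos.ravel(),
        "rpe": surfaces.rpe.ravel(),
    }).to_csv(path, index=False)


def read_surfaces(path: str | Path) -> LayerSurfaces:
    df = pd.read_csv(path)
    nb = int(df["bscan"].max()) + 1
    nx = int(df["ascan"].max()) + 1
    out = {}
    for name in ("ilm", "isos", "rpe"):
        arr = np.full((nb, nx), np.nan)
        arr[df["bscan"], df["ascan"]] = df[name]
        out[name] = arr
    return LayerSurfaces(**out)


def write_pointpairs(path: str | Path, pairs: list[PointPair]) -> None:
    pd.DataFrame([{
        "src_x": p.source[0], "src_y": p.source[1],
        "dst_x": p.target[0], "dst_y": p.target[1],
        "peak": p.peak_height, "level": p.level,
    } for p in pairs]).to_csv(path, index=False)


def write_transform(path: str | Path, transform: RegionTransform) -> None:
    Path(path).write_text(json.dumps(transform.to_dict(), indent=1))


def read_transform(path: str | Path,
                   shape: tuple[int, int] | None = None) -> RegionTransform:
    return RegionTransform.from_dict(json.loads(Path(path).read_text()),
                                     shape=shape)
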