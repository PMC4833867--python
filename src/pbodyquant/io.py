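"""File formats: multi-page TIFF micrographs, ground-truth JSON, CSV tables."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import tifffile

from pbodyquant.synthdata import AmplificationCurve, GroundTruth, MultiChannelImage

__all__ = [
    "write_micrograph",
    "read_micrograph",
    "write_ground_truth",
    "read_ground_truth",
    "write_table",
    "read_table",
    "write_curves",
    "read_curves",
]


def write_micrograph(path: str | Path, img: MultiChannelImage) -> None:
    """One TIFF page per channel (float32); channel names in the description."""
    meta = {"channel_names": list(img.channel_names), "pixel_size": img.pixel_size}
    tifffile.imwrite(
        str(path),
        img.data.astype(np.float32),
        photometric="minisblack",
        description=json.dumps(meta),
    )


def read_micrograph(
    path: str | Path, channel_names: Optional[Iterable[str]] = None
) -> MultiChannelImage:
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    if data.ndim == 2:
        data = data[None]
    names: Optional[list[str]] = list(channel_names) if channel_names else None
    pixel_size = 1.0
    if names is None and desc:
        try:
            meta = json.loads(desc)
            names = list(meta.get("channel_names", []))
            pixel_size = float(meta.get("pixel_size", 1.0))
        except (json.JSONDecodeError, TypeError):
            names = None
    if not names or len(names) != data.shape[0]:
        names = [f"ch{i}" for i in range(data.shape[0])]
    return MultiChannelImage(data.astype(float), tuple(names), pixel_size)


def write_ground_truth(path: str | Path, truth: GroundTruth) -> None:
    Path(path).write_text(truth.to_json())


def read_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text())


def write_table(path: str | Path, frame: pd.DataFrame,
                header_comment: Optional[str] = None, index: bool = False) -> None:
    """CSV with header row; optional ``#``-prefixed provenance comment line."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, index=index)


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col=index_col)


def write_curves(path: str | Path, curves: Iterable[AmplificationCurve]) -> None:
    """Long-format CSV: sample, gene, replicate, cycle, fluorescence."""
    rows = []
    for c in curves:
        for cyc, f in zip(c.cycles, c.fluorescence):
            rows.append((c.sample, c.gene, c.replicate, cyc, f))
    frame = pd.DataFrame(
        rows, columns=["sample", "gene", "replicate", "cycle", "fluorescence"]
    )
    write_table(path, frame)


def read_curves(path: str | Path) -> list[AmplificationCurve]:
    frame = read_table(path)
    curves = []
    for (sample, gene, rep), grp in frame.groupby(["sample", "gene", "replicate"]):
        grp = grp.sort_values("cycle")
        curves.append(
            AmplificationCurve(
                cycles=grp["cycle"].to_numpy(float),
                fluorescence=grp["fluorescence"].to_numpy(float),
                sample=str(sample),
                gene=str(gene),
                replicate=int(rep),
            )
        )
    return curves
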