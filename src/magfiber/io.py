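"""TIFF / CSV / manifest I/O shared by the command-line interface.

Images travel as multi-page TIFF with channels as pages (channel order:
nuclei, actin[, fiber]); pixel size is carried in the TIFF resolution tags
and may be overridden by configuration (configuration wins, with a
warning). All CSV output is UTF-8, comma-separated, with '#'-prefixed
header comments carrying the config hash and seed so any stochastic output
can be reproduced bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

__all__ = ["write_stack", "read_stack", "write_table", "read_table",
           "write_manifest", "config_hash"]


def write_stack(path, channels, pixel_size_um: float,
                channel_names=None) -> None:
    """Write channels (sequence of 2D arrays) as a multi-page TIFF."""
    path = Path(path)
    arr = np.stack([np.asarray(c, dtype=np.float32) for c in channels])
    res = 1.0 / pixel_size_um     # pixels per micron
    tifffile.imwrite(path, arr, photometric="minisblack",
                     resolution=(res, res), resolutionunit="MICROMETER",
                     metadata={"axes": "CYX",
                               "channel_names": list(channel_names or [])})


def read_stack(path, pixel_size_um: float = None):
    """Read a 1-3 channel TIFF; returns (stack (C, Y, X), pixel_size_um).

    Pixel size comes from the TIFF resolution tags when present, else from
    the argument; when both exist and disagree the argument wins with a
    warning. Raises for unsupported bit depths and missing files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input image not found: {path}")
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        page = tif.pages[0]
        if page.dtype not in (np.dtype(np.uint8), np.dtype(np.uint16),
                              np.dtype(np.float32), np.dtype(np.float64)):
            raise ValueError(f"unsupported TIFF bit depth: {page.dtype}")
        meta_px = None
        xres = page.tags.get("XResolution")
        if xres is not None:
            num, den = xres.value
            if num:
                meta_px = den / num
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3 or arr.shape[0] > 4:
        raise ValueError(f"expected 1-3 channel 2D TIFF, got shape {arr.shape}")
    px = pixel_size_um
    if px is None:
        px = meta_px
    elif meta_px is not None and not np.isclose(meta_px, px, rtol=1e-3):
        logger.warning("pixel size %.4g um from metadata overridden by "
                       "configured %.4g um", meta_px, px)
    if px is None:
        raise ValueError("pixel size not in TIFF metadata; pass it explicitly")
    return arr.astype(np.float32), float(px)


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(path, table: pd.DataFrame, config: dict = None,
                seed: int = None) -> None:
    """CSV with a '#' comment header carrying config hash and seed."""
    with open(path, "w", encoding="utf-8") as fh:
        if config is not None:
            fh.write(f"# config_hash: {config_hash(config)}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        table.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_manifest(out_dir, config: dict, seed: int, timings: dict = None
                   ) -> Path:
    """Run manifest (config echo, seed, versions, timings) beside outputs."""
    import magfiber
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config,
        "config_hash": config_hash(config),
        "seed": seed,
        "versions": {
            "magfiber": magfiber.__version__,
            "numpy": np.__version__,
        },
        "timings_s": timings or {},
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
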