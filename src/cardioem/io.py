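"""Atomic result writing and run manifests.

Every run directory gets the result tables (CSV + JSON), the effective
configuration echo, and a manifest with the config hash and library
versions, so any run is reconstructible from its output directory alone.
Files are written to a temporary name and renamed into place, so a partial
failure never leaves a half-written table.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

__all__ = ["atomic_write", "write_outputs", "write_manifest"]


def atomic_write(path, text: str) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    return path


def write_manifest(out_dir, config) -> Path:
    import numpy
    import scipy
    from . import __version__
    manifest = {
        "package": "cardioem",
        "version": __version__,
        "config_hash": config.hash(),
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
    }
    return atomic_write(Path(out_dir) / "manifest.json",
                        json.dumps(manifest, indent=2) + "\n")


def write_outputs(result, out_dir, config=None) -> dict:
    """Write a SweepResult (or any to_frame/to_dict object) atomically.

    Returns the mapping of artifact name to path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {}
    if hasattr(result, "to_frame"):
        df = result.to_frame()
        files["csv"] = atomic_write(out / "sweep.csv",
                                    df.to_csv(index=False))
    if hasattr(result, "to_dict"):
        files["json"] = atomic_write(
            out / "sweep.json", json.dumps(result.to_dict(), indent=2,
                                           default=float) + "\n")
    if config is not None:
        files["config"] = config.echo(out)
        files["manifest"] = write_manifest(out, config)
    return files
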