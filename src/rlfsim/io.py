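"""Plain-text artifact formats: XYZ snapshots/trajectories, tidy CSV tables,
and JSON run metadata."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np


def write_xyz(path, frames, elements, comments=None):
    """Write one or more frames as (multi-frame) XYZ, coordinates in Angstrom."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    n = frames.shape[1]
    if len(elements) != n:
        raise ValueError("elements length must match atom count")
    if comments is None:
        comments = [f"frame {i}" for i in range(frames.shape[0])]
    elif isinstance(comments, str):
        comments = [comments] * frames.shape[0]
    with open(path, "w") as fh:
        for f, comment in zip(frames, comments):
            fh.write(f"{n}\n{comment}\n")
            for el, (x, y, z) in zip(elements, f):
                fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path):
    """Read a (multi-frame) XYZ file; returns (frames, elements, comments)."""
    frames, comments = [], []
    elements = None
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        comments.append(lines[i + 1])
        block = lines[i + 2: i + 2 + n]
        els, xyz = [], []
        for ln in block:
            parts = ln.split()
            els.append(parts[0])
            xyz.append([float(v) for v in parts[1:4]])
        if elements is None:
            elements = els
        frames.append(xyz)
        i += 2 + n
    return np.asarray(frames, dtype=float), elements, comments


def system_elements(system) -> list[str]:
    """Element symbols of a ParticleSystem in packed order (ion first)."""
    return [system.ion_atom().element] + [a.element for a in system.atoms]


def write_run_metadata(path, **meta):
    """JSON sidecar with seeds, temperature, timestep, lambda, etc."""
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    Path(path).write_text(json.dumps(meta, indent=2, default=_default) + "\n")
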