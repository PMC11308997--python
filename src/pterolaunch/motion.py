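"""Tab-delimited motion-file I/O (.sto/.mot style).

Header: ``name``, ``nRows``, ``nColumns``, ``inDegrees`` flag, then
``endheader`` and a tab-separated table whose first column is time (s).
Angles are written in degrees when ``in_degrees`` (the default, matching
the format's convention) and converted back to radians on read.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import List, Tuple

import numpy as np

from .kinematics import KinematicSequence


def write_motion(
    sequence: KinematicSequence,
    path: str | Path,
    n_frames: int = 101,
    in_degrees: bool = True,
) -> Path:
    """Sample a sequence on a uniform grid and write a motion file."""
    path = Path(path)
    coords = sequence.coordinates()
    times = np.linspace(0.0, 1.0, n_frames)
    scale = 180.0 / math.pi if in_degrees else 1.0
    lines = [
        f"{sequence.style}",
        f"nRows={n_frames}",
        f"nColumns={len(coords) + 1}",
        f"inDegrees={'yes' if in_degrees else 'no'}",
        "endheader",
        "\t".join(["time"] + coords),
    ]
    for t in times:
        pose = sequence.pose_at(float(t))
        row = [f"{t:.17g}"] + [f"{pose[c] * scale:.17g}" for c in coords]
        lines.append("\t".join(row))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_motion(path: str | Path) -> Tuple[List[str], np.ndarray, np.ndarray]:
    """Read a motion file: (coordinate names, times s, angles rad).

    Returns angles as an (n_frames, n_coordinates) array in radians
    regardless of the file's unit flag.
    """
    text = Path(path).read_text().splitlines()
    in_degrees = True
    i = 0
    for i, line in enumerate(text):
        low = line.strip().lower()
        if low.startswith("indegrees"):
            in_degrees = low.split("=", 1)[1].strip() in ("yes", "true", "1")
        if low == "endheader":
            break
    else:
        raise ValueError(f"{path}: no 'endheader' marker found")
    header = text[i + 1].split("\t")
    if not header or header[0].strip().lower() != "time":
        raise ValueError(f"{path}: first column must be 'time'")
    coords = [h.strip() for h in header[1:]]
    data = np.array(
        [[float(x) for x in line.split("\t")] for line in text[i + 2:] if line.strip()]
    )
    times = data[:, 0]
    angles = data[:, 1:]
    if in_degrees:
        angles = angles * math.pi / 180.0
    return coords, times, angles
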