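"""Frame input: numbered-PNG directories or video containers.

A directory of numbered PNG frames is the fully supported, dependency-light
path; video containers work wherever imageio has a matching plugin
(e.g. imageio-ffmpeg for MP4/AVI).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator

import numpy as np

from .config import ConfigError


def iter_frames(path: str | Path) -> Iterator[np.ndarray]:
    """Yield RGB uint8 frames from a PNG directory or a video file."""
    import imageio.v3 as iio

    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".png", ".jpg", ".jpeg"))
        if not files:
            raise ConfigError(f"no image frames found in {path}")
        for p in files:
            yield np.asarray(iio.imread(p))[..., :3]
    elif path.is_file():
        for frame in iio.imiter(path):
            yield np.asarray(frame)[..., :3]
    else:
        raise ConfigError(f"input {path} does not exist")
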