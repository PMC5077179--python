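"""Reading and writing the pipeline's on-disk artifacts.

Video stacks are multi-page TIFF (16-bit for simulated camera data, 32-bit
float for derived grids), ground truth and tracks are CSV, configs are YAML,
calibrations JSON and paths JSON control-point lists.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import tifffile

from .config import SimConfig
from .render import FrameStack
from .simulate import trajectories_to_frame


def write_stack(path, stack: FrameStack) -> None:
    data = np.clip(np.round(stack.data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)


def read_stack(path, config: SimConfig) -> FrameStack:
    data = tifffile.imread(path).astype(float)
    if data.ndim == 2:
        data = data[None]
    return FrameStack(data, config)


def write_grid(path, grid: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(grid, dtype=np.float32))


def write_truth(path, trajectories) -> None:
    trajectories_to_frame(trajectories).to_csv(path, index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_path_json(path, control_points_um) -> None:
    with open(path, "w") as fh:
        json.dump({"control_points_um": np.asarray(control_points_um).tolist()}, fh)


def read_path_json(path):
    with open(path) as fh:
        return np.asarray(json.load(fh)["control_points_um"], dtype=float)


def write_png(path, rgb: np.ndarray) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    plt.imsave(path, np.clip(rgb, 0, 1))
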