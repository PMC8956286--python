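"""File I/O: HDF5 movies and traces, YAML parameter sets, CSV trajectories."""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .cones import ConeParams
from .stimuli import StimulusMovie, Trajectory

__all__ = [
    "save_movie", "load_movie", "save_trace", "load_trace",
    "save_cone_params", "load_cone_params",
    "save_trajectory", "load_trajectory", "load_image",
]


def save_movie(path, movie: StimulusMovie, name: str = "stimulus") -> None:
    import h5py

    with h5py.File(path, "a") as fh:
        if name in fh:
            del fh[name]
        g = fh.create_group(name)
        d = g.create_dataset("frames", data=movie.frames)
        d.attrs["dt_frame"] = movie.dt_frame
        d.attrs["pixel_pitch"] = movie.pixel_pitch
        d.attrs["background"] = movie.background


def load_movie(path, name: str = "stimulus") -> StimulusMovie:
    import h5py

    with h5py.File(path, "r") as fh:
        d = fh[name]["frames"]
        return StimulusMovie(d[()], dt_frame=float(d.attrs["dt_frame"]),
                             pixel_pitch=float(d.attrs["pixel_pitch"]),
                             background=float(d.attrs["background"]))


def save_trace(path, trace: np.ndarray, dt: float, name: str, background: float | None = None) -> None:
    import h5py

    with h5py.File(path, "a") as fh:
        if name in fh:
            del fh[name]
        d = fh.create_dataset(name, data=np.asarray(trace))
        d.attrs["dt"] = dt
        if background is not None:
            d.attrs["background"] = background


def load_trace(path, name: str) -> tuple:
    import h5py

    with h5py.File(path, "r") as fh:
        d = fh[name]
        return d[()], float(d.attrs["dt"])


def save_cone_params(path, params: ConeParams) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh)


def load_cone_params(path) -> ConeParams:
    with open(path) as fh:
        return ConeParams.from_dict(yaml.safe_load(fh))


def save_trajectory(path, traj: Trajectory) -> None:
    pd.DataFrame({
        "time_s": traj.times, "x_cones": traj.x, "y_cones": traj.y,
        "is_saccade": traj.saccade_flags.astype(int),
    }).to_csv(path, index=False)


def load_trajectory(path) -> Trajectory:
    df = pd.read_csv(path)
    return Trajectory(times=df.time_s.to_numpy(), x=df.x_cones.to_numpy(),
                      y=df.y_cones.to_numpy(),
                      saccade_flags=df.is_saccade.to_numpy().astype(bool))


def load_image(path) -> np.ndarray:
    """Grayscale image (PNG/TIFF) as a float array; RGB is averaged."""
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path), dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    return img
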