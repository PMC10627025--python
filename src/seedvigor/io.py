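"""HDF5 persistence for hypercubes and CSV persistence for spectra and splits."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import Hypercube, SpectraMatrix, SplitBundle, WavelengthGrid

__all__ = ["save_hypercube", "load_hypercube", "spectra_to_csv",
           "spectra_from_csv", "split_to_csv", "split_from_csv"]


def save_hypercube(path: str | Path, cube: Hypercube,
                   white: np.ndarray | None = None,
                   dark: np.ndarray | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=cube.values, compression="gzip")
        if white is not None:
            f.create_dataset("white", data=white, compression="gzip")
        if dark is not None:
            f.create_dataset("dark", data=dark, compression="gzip")
        f.attrs["calibrated"] = cube.calibrated
        f.attrs["all_nm"] = cube.grid.all_nm
        f.attrs["retained_index_window"] = cube.grid.retained_index_window
        f.attrs["retained_nm"] = cube.grid.retained_nm


def load_hypercube(path: str | Path
                   ) -> tuple[Hypercube, np.ndarray | None, np.ndarray | None]:
    with h5py.File(path, "r") as f:
        grid = WavelengthGrid(
            all_nm=np.asarray(f.attrs["all_nm"]),
            retained_index_window=tuple(int(v) for v in f.attrs["retained_index_window"]),
            retained_nm=np.asarray(f.attrs["retained_nm"]))
        cube = Hypercube(values=f["values"][()], grid=grid,
                         calibrated=bool(f.attrs["calibrated"]))
        white = f["white"][()] if "white" in f else None
        dark = f["dark"][()] if "dark" in f else None
    return cube, white, dark


def spectra_to_csv(path: str | Path, data: SpectraMatrix,
                   wavelengths_nm: np.ndarray | None = None) -> None:
    """One row per seed: variety, label, then the per-band reflectances."""
    if wavelengths_nm is not None:
        cols = [f"r{nm:.1f}" for nm in wavelengths_nm]
    else:
        cols = [f"band{i}" for i in range(data.n_bands)]
    df = pd.DataFrame(data.spectra, columns=cols)
    df.insert(0, "variety", data.domain)
    df.insert(1, "label", data.labels if data.labels is not None else -1)
    df.to_csv(path, index=False, float_format="%.6f")


def spectra_from_csv(path: str | Path) -> SpectraMatrix:
    df = pd.read_csv(path)
    labels = df["label"].to_numpy()
    domain = str(df["variety"].iloc[0]) if len(df) else ""
    spectra = df.drop(columns=["variety", "label"]).to_numpy(dtype=np.float64)
    return SpectraMatrix(spectra=spectra,
                         labels=None if (labels < 0).all() else labels,
                         domain=domain)


def split_to_csv(path: str | Path, split: SplitBundle) -> None:
    rows = ([("train", i) for i in split.train]
            + [("val", i) for i in split.val]
            + [("test", i) for i in split.test])
    df = pd.DataFrame(rows, columns=["subset", "index"])
    df["seed"] = split.seed if split.seed is not None else -1
    df.to_csv(path, index=False)


def split_from_csv(path: str | Path) -> SplitBundle:
    df = pd.read_csv(path)
    seed = int(df["seed"].iloc[0]) if len(df) else None
    def pick(name):
        return df.loc[df["subset"] == name, "index"].to_numpy(dtype=np.int64)
    return SplitBundle(train=pick("train"), val=pick("val"), test=pick("test"),
                       seed=None if seed == -1 else seed)
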