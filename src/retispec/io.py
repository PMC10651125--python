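"""Delimited-text readers and writers for spectral data.

Dialects:

* ``csv-matrix`` — first column ``wavenumber``, one column per spectrum
  (column names become spectrum ids).
* ``long`` — long-format rows, instrument-export style: either
  ``x, y, wavenumber, intensity`` (map with stage positions) or
  ``wavenumber, intensity`` (single spectrum); comma/tab/whitespace
  delimited, header optional.
* ``two-column`` — a single ``wavenumber, intensity`` spectrum.

All floats are written at 17 significant digits so a write/read round trip
reproduces values exactly.  Wavenumber axes are ascending internally; files
in descending order are sorted on read with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .spectra import SpectralMap

__all__ = [
    "ParseError",
    "DatasetManifest",
    "read_spectra",
    "write_spectra",
    "write_table",
    "write_dataset",
    "read_dataset",
]

_FLOAT_FMT = "%.17g"


class ParseError(ValueError):
    def __init__(self, message: str, line: int | None = None):
        self.line = line
        suffix = f" (line {line})" if line is not None else ""
        super().__init__(message + suffix)


@dataclass
class DatasetManifest:
    spectra_file: str
    labels_file: str
    dialect: str
    ground_truth_file: str | None = None


def _numeric_frame(df: pd.DataFrame, path) -> pd.DataFrame:
    try:
        return df.astype(float)
    except (ValueError, TypeError):
        for i, row in enumerate(df.itertuples(index=False)):
            for v in row:
                try:
                    float(v)
                except (ValueError, TypeError):
                    raise ParseError(f"non-numeric cell {v!r} in {path}",
                                     line=i + 2) from None
        raise ParseError(f"could not parse {path} as numeric")


def _sorted_axis(axis: np.ndarray, values: np.ndarray, path):
    if np.unique(axis).size != axis.size:
        raise ParseError(f"duplicate wavenumbers in {path}")
    if np.all(np.diff(axis) > 0):
        return axis, values
    warnings.warn(f"{path}: wavenumber axis not ascending; sorting", UserWarning)
    order = np.argsort(axis)
    return axis[order], values[..., order]


def read_spectra(path, dialect: str = "csv-matrix") -> SpectralMap:
    path = Path(path)
    if dialect == "csv-matrix":
        try:
            df = pd.read_csv(path, float_precision="round_trip")
        except pd.errors.ParserError as e:
            raise ParseError(f"ragged or malformed CSV {path}: {e}") from None
        if df.shape[1] < 2:
            raise ParseError(f"{path} has no spectrum columns")
        df = _numeric_frame(df, path)
        axis = df.iloc[:, 0].to_numpy()
        inten = df.iloc[:, 1:].to_numpy().T
        axis, inten = _sorted_axis(axis, inten, path)
        meta = pd.DataFrame({"spectrum_id": list(df.columns[1:])})
        return SpectralMap(axis, inten, meta)
    if dialect in ("long", "two-column"):
        try:
            df = pd.read_csv(path, sep=None, engine="python", header=None,
                             comment="#")
        except pd.errors.ParserError as e:
            raise ParseError(f"ragged or malformed file {path}: {e}") from None
        # drop a header row if the first row is not numeric
        try:
            df.iloc[0].astype(float)
        except (ValueError, TypeError):
            df = df.iloc[1:].reset_index(drop=True)
        df = _numeric_frame(df, path)
        if dialect == "two-column" or df.shape[1] == 2:
            if df.shape[1] != 2:
                raise ParseError(f"{path}: expected 2 columns, got {df.shape[1]}")
            axis = df.iloc[:, 0].to_numpy()
            inten = df.iloc[:, 1].to_numpy()[None, :]
            axis, inten = _sorted_axis(axis, inten, path)
            return SpectralMap(axis, inten, pd.DataFrame({"spectrum_id": ["s0"]}))
        if df.shape[1] != 4:
            raise ParseError(f"{path}: long dialect expects 2 or 4 columns, "
                             f"got {df.shape[1]}")
        df.columns = ["x", "y", "wavenumber", "intensity"]
        spectra, meta_rows, axis_ref = [], [], None
        for (x, y), grp in df.groupby(["x", "y"], sort=True):
            axis = grp["wavenumber"].to_numpy()
            vals = grp["intensity"].to_numpy()
            axis, vals = _sorted_axis(axis, vals, path)
            if axis_ref is None:
                axis_ref = axis
            elif not np.array_equal(axis, axis_ref):
                raise ParseError(f"{path}: map positions have differing axes")
            spectra.append(vals)
            meta_rows.append({"x": x, "y": y})
        return SpectralMap(axis_ref, np.stack(spectra), pd.DataFrame(meta_rows))
    raise ValueError(f"unknown dialect {dialect!r}")


def write_spectra(smap: SpectralMap, path, dialect: str = "csv-matrix") -> None:
    path = Path(path)
    if len(smap) == 0:
        raise ValueError("refusing to write an empty map")
    if dialect == "csv-matrix":
        if "spectrum_id" in smap.meta.columns:
            names = [str(s) for s in smap.meta["spectrum_id"]]
        else:
            names = [f"s{i:04d}" for i in range(len(smap))]
        df = pd.DataFrame({"wavenumber": smap.axis})
        for name, row in zip(names, smap.intensities):
            df[name] = row
        df.to_csv(path, index=False, float_format=_FLOAT_FMT)
        return
    if dialect == "long":
        pos = smap.positions
        if pos is None:
            pos = np.stack([np.arange(len(smap)), np.zeros(len(smap))], axis=1)
        rows = []
        for (x, y), vals in zip(pos, smap.intensities):
            rows.append(pd.DataFrame({"x": x, "y": y, "wavenumber": smap.axis,
                                      "intensity": vals}))
        pd.concat(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)
        return
    raise ValueError(f"unknown dialect {dialect!r}")


def write_table(df: pd.DataFrame, path) -> None:
    pd.DataFrame(df).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_dataset(dataset_or_map, outdir, true_ratios: pd.DataFrame | None = None
                  ) -> DatasetManifest:
    """Write a labeled dataset: spectra matrix + label sidecar + optional
    ground truth + a YAML manifest tying them together.

    Accepts either a GeneratedDataset or a bare labeled SpectralMap.
    """
    smap = getattr(dataset_or_map, "map", dataset_or_map)
    if true_ratios is None:
        true_ratios = getattr(dataset_or_map, "true_ratios", None)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_spectra(smap, outdir / "spectra.csv")
    labels = smap.meta[["sample_id", "label"]].copy()
    labels.insert(0, "spectrum_index", np.arange(len(smap)))
    write_table(labels, outdir / "labels.csv")
    truth_file = None
    if true_ratios is not None and len(true_ratios):
        write_table(true_ratios, outdir / "ground_truth.csv")
        truth_file = "ground_truth.csv"
    manifest = DatasetManifest("spectra.csv", "labels.csv", "csv-matrix",
                               truth_file)
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(vars(manifest), fh)
    return manifest


def read_dataset(directory) -> tuple[SpectralMap, pd.DataFrame]:
    """Load spectra + labels written by :func:`write_dataset`; returns the
    labeled map and the ground-truth table (empty frame if absent)."""
    directory = Path(directory)
    with open(directory / "manifest.yaml") as fh:
        manifest = DatasetManifest(**yaml.safe_load(fh))
    for name in (manifest.spectra_file, manifest.labels_file):
        if not (directory / name).exists():
            raise FileNotFoundError(f"manifest references missing file {name}")
    smap = read_spectra(directory / manifest.spectra_file, manifest.dialect)
    labels = pd.read_csv(directory / manifest.labels_file)
    if len(labels) != len(smap):
        raise ParseError("label table does not cover every spectrum")
    smap = SpectralMap(smap.axis, smap.intensities,
                       labels[["sample_id", "label"]].copy())
    truth = pd.DataFrame()
    if manifest.ground_truth_file and (directory / manifest.ground_truth_file).exists():
        truth = pd.read_csv(directory / manifest.ground_truth_file)
    return smap, truth
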