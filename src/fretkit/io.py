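"""Readers and writers for the formats the pipeline touches.

Photon files use a Photon-HDF5-style layout; the mandatory subset is:

* ``/photon_data/timestamps`` (int64) with
  ``/photon_data/timestamps_specs/timestamps_unit`` (seconds per tick)
* ``/photon_data/nanotimes`` (int32) with
  ``/photon_data/nanotimes_specs/tcspc_unit`` and ``tcspc_num_bins``
* ``/photon_data/detectors`` (uint8; donor = 0, acceptor = 1 unless the
  measurement_specs detector mapping says otherwise)
* ``/photon_data/measurement_specs/alex_excitation_period1`` / ``..._period2``
  (Dex / Aex nanotime windows, half-open, in TCSPC bins)

Unknown groups are ignored with a logged warning (vendor files vary);
missing mandatory fields and non-monotone timestamps are hard errors.

All tabular output is TSV (tab-separated, '.' decimal, one header row);
the active RunConfig is serialised into each file as ``# key: json``
comment lines so that any result is reproducible from the file alone.
"""

from __future__ import annotations

import io as _io
import json
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .photons import PIEScheme, PhotonStream, StreamError

__all__ = [
    "write_photon_hdf5", "read_photon_hdf5",
    "write_table", "read_table",
    "read_peak_table", "write_peak_table",
    "read_titration", "PEAK_COLUMNS",
]

log = logging.getLogger("fretkit")

_KNOWN_ROOT = {"photon_data", "setup", "acquisition_duration", "description",
               "identity"}

PEAK_COLUMNS = ["residue", "residue_type", "wH_ppm", "wC_ppm", "intensity",
                "noise_floor", "domain", "flags"]


# ---------------------------------------------------------------------------
# Photon-HDF5-style container
# ---------------------------------------------------------------------------

def write_photon_hdf5(stream: PhotonStream, path, truth: dict | None = None,
                      comment: str = "") -> None:
    """Write a stream (and optional ground-truth JSON sidecar at
    ``<path>.truth.json``)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f["description"] = comment or stream.meta.get("comment", "")
        f["acquisition_duration"] = float(stream.duration)
        pd_grp = f.create_group("photon_data")
        pd_grp.create_dataset("timestamps", data=stream.timestamps)
        pd_grp.create_dataset("nanotimes", data=stream.nanotimes)
        pd_grp.create_dataset("detectors", data=stream.detectors)
        pd_grp["timestamps_specs/timestamps_unit"] = 1.0 / stream.clock_rate
        pd_grp["nanotimes_specs/tcspc_unit"] = stream.tcspc_unit
        pd_grp["nanotimes_specs/tcspc_num_bins"] = stream.pie.n_bins
        ms = pd_grp.create_group("measurement_specs")
        ms["measurement_type"] = "smFRET-nsALEX"
        ms["alex_excitation_period1"] = np.asarray(stream.pie.dex_window)
        ms["alex_excitation_period2"] = np.asarray(stream.pie.aex_window)
        ms["detectors_specs/spectral_ch1"] = 0   # donor
        ms["detectors_specs/spectral_ch2"] = 1   # acceptor
    if truth is not None:
        sidecar = path.with_suffix(path.suffix + ".truth.json")
        sidecar.write_text(json.dumps(_jsonable(truth), indent=1))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if hasattr(obj, "__dataclass_fields__"):
        import dataclasses
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, frozenset):
        return sorted(obj)
    return obj


def read_photon_hdf5(path) -> PhotonStream:
    """Read a Photon-HDF5-style file into a validated PhotonStream."""
    path = Path(path)
    with h5py.File(path, "r") as f:
        for name in f:
            if name not in _KNOWN_ROOT:
                log.warning("ignoring unknown root group %r in %s", name, path)
        if "photon_data" not in f:
            raise StreamError(f"{path}: missing mandatory group 'photon_data'")
        g = f["photon_data"]
        for req in ("timestamps", "nanotimes", "detectors",
                    "timestamps_specs/timestamps_unit",
                    "nanotimes_specs/tcspc_unit",
                    "measurement_specs/alex_excitation_period1",
                    "measurement_specs/alex_excitation_period2"):
            if req not in g:
                raise StreamError(f"{path}: missing mandatory field "
                                  f"'photon_data/{req}'")
        ts_unit = float(g["timestamps_specs/timestamps_unit"][()])
        tcspc_unit = float(g["nanotimes_specs/tcspc_unit"][()])
        dex = tuple(int(v) for v in g["measurement_specs/alex_excitation_period1"][()])
        aex = tuple(int(v) for v in g["measurement_specs/alex_excitation_period2"][()])
        n_bins = int(g["nanotimes_specs/tcspc_num_bins"][()]) \
            if "nanotimes_specs/tcspc_num_bins" in g else max(dex[1], aex[1])
        meta = {}
        if "acquisition_duration" in f:
            meta["duration_s"] = float(f["acquisition_duration"][()])
        if "description" in f:
            raw = f["description"][()]
            meta["comment"] = raw.decode() if isinstance(raw, bytes) else str(raw)
        stream = PhotonStream(
            timestamps=g["timestamps"][()],
            nanotimes=g["nanotimes"][()],
            detectors=g["detectors"][()],
            clock_rate=1.0 / ts_unit,
            tcspc_unit=tcspc_unit,
            pie=PIEScheme(dex_window=dex, aex_window=aex, n_bins=n_bins),
            meta=meta,
        )
    return stream.validate()


# ---------------------------------------------------------------------------
# TSV tables with '#'-comment config headers
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path, header: dict | None = None) -> None:
    """Write a TSV table; ``header`` entries become ``# key: <json>`` lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in (header or {}).items():
            fh.write(f"# {key}: {json.dumps(_jsonable(value), sort_keys=True)}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> tuple[pd.DataFrame, dict]:
    """Read a TSV table written by :func:`write_table`; returns (df, header)."""
    path = Path(path)
    header = {}
    lines = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                body = line[1:].strip()
                if ": " in body:
                    key, _, val = body.partition(": ")
                    try:
                        header[key] = json.loads(val)
                    except json.JSONDecodeError:
                        header[key] = val
            else:
                lines.append(line)
    df = pd.read_csv(_io.StringIO("".join(lines)), sep="\t")
    return df, header


def write_peak_table(df: pd.DataFrame, path, header: dict | None = None) -> None:
    write_table(df[PEAK_COLUMNS], path, header)


def read_peak_table(path) -> pd.DataFrame:
    """Read and validate an NMR peak table (TSV)."""
    df, _ = read_table(path)
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing peak-table columns {missing}")
    dup = df["residue"][df["residue"].duplicated()]
    if not dup.empty:
        raise ValueError(
            f"{path}: duplicate residue id(s): {sorted(set(dup.tolist()))}")
    if (df["intensity"] < 0).any():
        bad = df.loc[df["intensity"] < 0, "residue"].tolist()
        raise ValueError(f"{path}: negative intensity for residue(s) {bad}")
    if (df["noise_floor"] <= 0).any():
        raise ValueError(f"{path}: noise_floor must be positive")
    df["flags"] = df["flags"].fillna("").astype(str)
    return df


def read_titration(path) -> pd.DataFrame:
    """Read a titration TSV with columns concentration_uM, signal."""
    df, _ = read_table(path)
    for col in ("concentration_uM", "signal"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return df
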