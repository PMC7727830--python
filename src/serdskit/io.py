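"""Frame, cube and configuration I/O.

Detector frames travel as FITS images (primary HDU counts + an IMAGE
extension with the saturation mask) with the acquisition geometry in header
keys (TRACEPIT, SHUFOFF, BLOCKSZ, ...).  The FITS layer here is a small
self-contained reader/writer for simple image HDUs — 2880-byte header blocks
of 80-character cards and big-endian binary data — which covers everything
this package produces.  Cubes additionally export to a long-format CSV
(spaxel_row, spaxel_col, axis value, intensity).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ccd import DetectorFrame, TraceLayout
from .forward import ExcitationPair, SpectralAxis, make_schedule

__all__ = [
    "write_fits",
    "read_fits",
    "write_frame",
    "read_frame",
    "cube_to_csv",
    "cube_from_csv",
    "load_config",
]

BLOCK = 2880

_BITPIX_DTYPE = {
    8: ">u1",
    16: ">i2",
    32: ">i4",
    -32: ">f4",
    -64: ">f8",
}


def _card(key: str, value, comment: str = "") -> bytes:
    key = key[:8].ljust(8)
    if isinstance(value, bool):
        val = ("T" if value else "F").rjust(20)
    elif isinstance(value, (int, np.integer)):
        val = str(int(value)).rjust(20)
    elif isinstance(value, (float, np.floating)):
        val = np.format_float_scientific(value, precision=14).upper().rjust(20)
    elif isinstance(value, str):
        val = f"'{value[:67]}'"
    else:
        raise TypeError(f"unsupported header value type for {key}: {type(value)}")
    card = f"{key}= {val}"
    if comment:
        card += f" / {comment}"
    return card[:80].ljust(80).encode("ascii")


def _header_bytes(cards: list[bytes]) -> bytes:
    raw = b"".join(cards) + b"END".ljust(80)
    pad = (-len(raw)) % BLOCK
    return raw + b" " * pad


def _data_bytes(data: np.ndarray, bitpix: int) -> bytes:
    raw = np.ascontiguousarray(data, dtype=_BITPIX_DTYPE[bitpix]).tobytes()
    pad = (-len(raw)) % BLOCK
    return raw + b"\x00" * pad


def write_fits(path, hdus: list[tuple[np.ndarray, dict]]) -> None:
    """Write image HDUs to a FITS file.

    ``hdus`` is a list of (2-D array, header dict); the first becomes the
    primary HDU, the rest IMAGE extensions.  float64 data is stored as
    BITPIX -64, (unsigned) integer masks as BITPIX 8.
    """
    out = b""
    for n, (data, header) in enumerate(hdus):
        data = np.asarray(data)
        bitpix = 8 if data.dtype.kind in "bu" and data.dtype.itemsize == 1 else -64
        cards = []
        if n == 0:
            cards.append(_card("SIMPLE", True, "conforms to FITS"))
        else:
            cards.append(_card("XTENSION", "IMAGE", "image extension"))
        cards.append(_card("BITPIX", bitpix))
        cards.append(_card("NAXIS", data.ndim))
        for ax in range(data.ndim):
            # FITS axis order is Fortran-style: NAXIS1 is the fastest axis
            cards.append(_card(f"NAXIS{ax + 1}", data.shape[data.ndim - 1 - ax]))
        if n > 0:
            cards.append(_card("PCOUNT", 0))
            cards.append(_card("GCOUNT", 1))
        for key, val in header.items():
            cards.append(_card(key, val))
        out += _header_bytes(cards) + _data_bytes(data, bitpix)
    Path(path).write_bytes(out)


def _parse_value(text: str):
    text = text.strip()
    if text.startswith("'"):
        return text[1 : text.rindex("'")].rstrip()
    if text == "T":
        return True
    if text == "F":
        return False
    try:
        return int(text)
    except ValueError:
        pass
    try:
        return float(text)
    except ValueError as err:
        raise ValueError(f"cannot parse FITS header value {text!r}") from err


def read_fits(path) -> list[tuple[np.ndarray, dict]]:
    """Read all image HDUs of a FITS file written by :func:`write_fits`."""
    raw = Path(path).read_bytes()
    if len(raw) % BLOCK or not raw[:6] in (b"SIMPLE",):
        raise ValueError(f"{path}: not a valid FITS file")
    hdus = []
    pos = 0
    while pos < len(raw):
        header: dict = {}
        end = False
        while not end:
            block = raw[pos : pos + BLOCK]
            if len(block) < BLOCK:
                raise ValueError(f"{path}: truncated FITS header")
            pos += BLOCK
            for c in range(0, BLOCK, 80):
                card = block[c : c + 80].decode("ascii", errors="replace")
                key = card[:8].strip()
                if key == "END":
                    end = True
                    break
                if not key or card[8:10] != "= ":
                    continue
                body = card[10:].split(" / ")[0]
                header[key] = _parse_value(body)
        bitpix = header["BITPIX"]
        shape = tuple(
            header[f"NAXIS{header['NAXIS'] - ax}"] for ax in range(header["NAXIS"])
        )
        count = int(np.prod(shape)) if shape else 0
        dtype = np.dtype(_BITPIX_DTYPE[bitpix])
        nbytes = count * dtype.itemsize
        data = np.frombuffer(raw[pos : pos + nbytes], dtype=dtype).reshape(shape)
        pos += nbytes + ((-nbytes) % BLOCK)
        hdus.append((data.astype(dtype.newbyteorder("=")), header))
    return hdus


# ---------------------------------------------------------------------------
# frames
# ---------------------------------------------------------------------------

def write_frame(path, frame: DetectorFrame) -> None:
    """Write a detector frame with its layout/schedule metadata and mask plane."""
    lay = frame.layout
    header = {
        "TRACEPIT": lay.trace_pitch,
        "SHUFOFF": lay.shuffle_offset,
        "BLOCKSZ": lay.block_size,
        "NBLOCKS": lay.n_blocks,
        "CROSSSIG": lay.cross_profile_sigma,
        "ROWORIG": lay.row_origin,
        "LAMBDA1": frame.pair.lambda1,
        "LAMBDA2": frame.pair.lambda2,
        "SCHEDMOD": frame.schedule.mode,
        "NCYCLES": frame.schedule.n_cycles,
        "TEXP": frame.schedule.t_exp,
        "RONSIGMA": frame.readout_noise_sigma,
        "SATLEVEL": frame.saturation,
        "READOUT": frame.read_out,
    }
    if frame.rng_seed is not None:
        header["SEED"] = int(frame.rng_seed)
    for d, c in enumerate(lay.dispersion):
        header[f"DISP{d}"] = float(c)
    write_fits(
        path,
        [
            (frame.counts, header),
            (frame.saturated.astype(np.uint8), {"EXTNAME": "SATMASK"}),
        ],
    )


def read_frame(path) -> DetectorFrame:
    """Reconstruct a :class:`DetectorFrame` from disk."""
    hdus = read_fits(path)
    counts, header = hdus[0]
    for key in ("TRACEPIT", "SHUFOFF", "BLOCKSZ", "NBLOCKS", "LAMBDA1", "SCHEDMOD"):
        if key not in header:
            raise KeyError(f"{path}: missing required header key {key}")
    dispersion = []
    d = 0
    while f"DISP{d}" in header:
        dispersion.append(float(header[f"DISP{d}"]))
        d += 1
    layout = TraceLayout(
        frame_shape=counts.shape,
        trace_pitch=header["TRACEPIT"],
        shuffle_offset=header["SHUFOFF"],
        block_size=header["BLOCKSZ"],
        n_blocks=header["NBLOCKS"],
        cross_profile_sigma=float(header.get("CROSSSIG", 0.7)),
        dispersion=tuple(dispersion) or (0.0, 1.0),
        row_origin=int(header.get("ROWORIG", 2)),
    )
    schedule = make_schedule(header["SCHEDMOD"], header["NCYCLES"], float(header["TEXP"]))
    frame = DetectorFrame(
        counts=np.array(counts, dtype=float),
        layout=layout,
        schedule=schedule,
        pair=ExcitationPair(float(header["LAMBDA1"]), float(header["LAMBDA2"])),
        rng_seed=header.get("SEED"),
        readout_noise_sigma=float(header.get("RONSIGMA", 0.0)),
        saturation=float(header.get("SATLEVEL", np.inf)),
        read_out=bool(header.get("READOUT", False)),
    )
    if len(hdus) > 1:
        frame.saturated = hdus[1][0].astype(bool)
    return frame


# ---------------------------------------------------------------------------
# cubes
# ---------------------------------------------------------------------------

_AXIS_COLUMN = {
    "wavelength-nm": "wavelength_nm",
    "relative-wavenumber-cm-1": "relative_wavenumber_cm1",
    "detector-channel": "channel",
}


def cube_to_csv(cube, path) -> None:
    """Long-format CSV export: one row per (spaxel, channel) of unmasked spaxels."""
    rows, cols = cube.grid_shape
    axis_col = _AXIS_COLUMN[cube.axis.kind]
    recs = []
    for i in range(rows):
        for j in range(cols):
            if not cube.mask[i, j]:
                continue
            recs.append(
                pd.DataFrame(
                    {
                        "spaxel_row": i,
                        "spaxel_col": j,
                        axis_col: cube.axis.values,
                        "intensity": cube.data[i, j],
                    }
                )
            )
    pd.concat(recs, ignore_index=True).to_csv(path, index=False)


def cube_from_csv(path):
    """Round-trip reader for :func:`cube_to_csv` output (returns a DataCube)."""
    from .reduction import DataCube

    df = pd.read_csv(path)
    axis_col = [c for c in df.columns if c in _AXIS_COLUMN.values()][0]
    kind = {v: k for k, v in _AXIS_COLUMN.items()}[axis_col]
    axis_vals = np.sort(df[axis_col].unique())
    rows = int(df["spaxel_row"].max()) + 1
    cols = int(df["spaxel_col"].max()) + 1
    data = np.zeros((rows, cols, axis_vals.size))
    mask = np.zeros((rows, cols), dtype=bool)
    for (i, j), grp in df.groupby(["spaxel_row", "spaxel_col"]):
        grp = grp.sort_values(axis_col)
        data[int(i), int(j)] = grp["intensity"].to_numpy()
        mask[int(i), int(j)] = True
    return DataCube(SpectralAxis(kind, axis_vals), data, mask)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_SCHEMA = {
    "scene": str,
    "schedule": dict,
    "seed": int,
    "layout": dict,
    "noise": dict,
    "output": str,
    "clusters": int,
    "normalize": bool,
    "snip_half_width": int,
}

_SCHEDULE_KEYS = {"mode": str, "n_cycles": int, "t_exp": (int, float)}


def load_config(path) -> dict:
    """Load and validate a YAML run configuration.

    Unknown keys and wrong types raise with the offending key named, so a
    run is fully determined by (config file, seed).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    for key, val in cfg.items():
        if key not in _SCHEMA:
            raise ValueError(f"{path}: unknown configuration key {key!r}")
        if not isinstance(val, _SCHEMA[key]):
            raise ValueError(f"{path}: key {key!r} must be of type {_SCHEMA[key]}")
    sched = cfg.get("schedule", {})
    for key, val in sched.items():
        if key not in _SCHEDULE_KEYS:
            raise ValueError(f"{path}: unknown schedule key {key!r}")
        if not isinstance(val, _SCHEDULE_KEYS[key]):
            raise ValueError(f"{path}: schedule key {key!r} has the wrong type")
    return cfg
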