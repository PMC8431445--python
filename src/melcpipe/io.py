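"""Readers and writers for the pipeline's on-disk artifacts.

Images are grayscale TIFF (float32 for corrected intensities, uint16 for
label masks and raw acquisitions); tables are CSV; configuration is YAML.
A minimal FCS 3.0 writer is included so normalized feature tables can be
loaded into cytometry tools.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale TIFF as a float64 array."""
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D grayscale image, got shape {arr.shape}")
    return arr.astype(np.float64)


def write_image(path: str | Path, image: np.ndarray, dtype=np.float32) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), np.asarray(image, dtype=dtype))


def read_label_mask(path: str | Path) -> np.ndarray:
    """Read an integer label mask (16-bit TIFF; 0 = background)."""
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D label mask, got shape {arr.shape}")
    return arr.astype(np.int64)


def write_label_mask(path: str | Path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.min() < 0:
        raise ValueError("label masks are nonnegative")
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("label id exceeds 16-bit range")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), labels.astype(np.uint16))


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_yaml(path: str | Path, obj: dict) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def write_fcs(path: str | Path, table: pd.DataFrame) -> None:
    """Write a numeric table as an FCS 3.0 list-mode file (float32 data).

    Each column becomes one parameter ($PnN = column name).  Non-numeric
    columns are dropped.  The file carries a single dataset and no analysis
    segment, which is what downstream cytometry viewers expect of an export.
    """
    num = table.select_dtypes(include=[np.number])
    if num.shape[1] == 0:
        raise ValueError("no numeric columns to export")
    data = np.ascontiguousarray(num.to_numpy(dtype="<f4"))
    n_events, n_par = data.shape

    text = {
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$TOT": str(n_events),
        "$PAR": str(n_par),
    }
    for i, name in enumerate(num.columns, start=1):
        text[f"$P{i}N"] = str(name).replace("/", "_")
        text[f"$P{i}B"] = "32"
        text[f"$P{i}E"] = "0,0"
        rng = float(np.nanmax(data[:, i - 1])) if n_events else 1.0
        text[f"$P{i}R"] = str(int(max(rng, 1.0)) + 1)

    delim = "/"
    header_len = 58  # "FCS3.0" + 4 space-padded 8-char offsets fields (6 numbers)

    def text_bytes(begin_data: int, end_data: int) -> bytes:
        items = dict(text)
        items["$BEGINDATA"] = str(begin_data)
        items["$ENDDATA"] = str(end_data)
        items["$BEGINANALYSIS"] = "0"
        items["$ENDANALYSIS"] = "0"
        items["$BEGINSTEXT"] = "0"
        items["$ENDSTEXT"] = "0"
        s = delim + delim.join(f"{k}{delim}{v}" for k, v in sorted(items.items())) + delim
        return s.encode("ascii")

    # data offset depends on text length which depends on the offset digits;
    # iterate to a fixed point (converges in <=3 rounds)
    begin_data = header_len + 1
    for _ in range(5):
        tb = text_bytes(begin_data, begin_data + data.nbytes - 1)
        new_begin = header_len + len(tb)
        if new_begin == begin_data:
            break
        begin_data = new_begin
    tb = text_bytes(begin_data, begin_data + data.nbytes - 1)
    end_data = begin_data + data.nbytes - 1

    begin_text = header_len
    end_text = begin_text + len(tb) - 1
    header = b"FCS3.0    " + (
        f"{begin_text:>8d}{end_text:>8d}"
        f"{begin_data if begin_data <= 99999999 else 0:>8d}"
        f"{end_data if end_data <= 99999999 else 0:>8d}"
        f"{0:>8d}{0:>8d}"
    ).encode("ascii")
    assert len(header) == header_len

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(tb)
        fh.write(data.tobytes())


def read_fcs(path: str | Path) -> pd.DataFrame:
    """Read back an FCS 3.0 file written by :func:`write_fcs` (round-trip aid)."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if not raw.startswith(b"FCS3.0"):
        raise ValueError("not an FCS 3.0 file")
    begin_text = int(raw[10:18])
    end_text = int(raw[18:26])
    text = raw[begin_text : end_text + 1].decode("ascii")
    delim = text[0]
    parts = text.strip(delim).split(delim)
    kv = dict(zip(parts[::2], parts[1::2]))
    n_par = int(kv["$PAR"])
    n_tot = int(kv["$TOT"])
    begin_data = int(kv["$BEGINDATA"])
    names = [kv[f"$P{i}N"] for i in range(1, n_par + 1)]
    data = np.frombuffer(raw, dtype="<f4", count=n_par * n_tot, offset=begin_data)
    return pd.DataFrame(data.reshape(n_tot, n_par), columns=names)
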