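"""Minimal FITS image I/O (32-bit float, multi-HDU).

Implements just the subset of the FITS standard the pipeline outputs need:
primary image HDUs and IMAGE extensions, BITPIX -32 (float32) or 8 (uint8
masks), with scalar metadata as header cards. Keeps outputs at 32-bit
floating-point precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BLOCK = 2880
CARD = 80

_BITPIX_DTYPE = {-32: ">f4", -64: ">f8", 8: ">u1", 16: ">i2", 32: ">i4"}


def _fmt_value(v) -> str:
    if isinstance(v, bool):
        return "T" if v else "F"
    if isinstance(v, (int, np.integer)):
        return f"{int(v):>20d}"
    if isinstance(v, (float, np.floating)):
        return f"{float(v):>20.13E}"
    s = str(v).replace("'", "''")
    return f"'{s:<8s}'"


def _card(key: str, value=None, comment: str = "") -> bytes:
    if value is None:
        text = f"{key:<8s}"
    else:
        text = f"{key:<8s}= {_fmt_value(value)}"
        if comment:
            text += f" / {comment}"
    return text[:CARD].ljust(CARD).encode("ascii")


def _pad(buf: bytes, fill: bytes = b" ") -> bytes:
    n = (-len(buf)) % BLOCK
    return buf + fill * n


@dataclass
class ImageHDU:
    """One image HDU: a 2-D/3-D array plus scalar header entries."""

    data: np.ndarray | None
    name: str = ""
    header: dict = field(default_factory=dict)


def _serialize_hdu(hdu: ImageHDU, primary: bool) -> bytes:
    cards = []
    if primary:
        cards.append(_card("SIMPLE", True, "conforms to FITS standard"))
    else:
        cards.append(_card("XTENSION", "IMAGE", "image extension"))
    if hdu.data is None:
        data = np.zeros((0,), dtype=">f4")
        bitpix, shape = -32, ()
    else:
        data = np.asarray(hdu.data)
        if data.dtype == np.uint8:
            bitpix = 8
            data = data.astype(">u1")
        else:
            bitpix = -32
            data = data.astype(">f4")
        shape = data.shape
    cards.append(_card("BITPIX", bitpix))
    cards.append(_card("NAXIS", len(shape)))
    # FITS axis order is reversed relative to the C row-major array shape
    for i, n in enumerate(reversed(shape)):
        cards.append(_card(f"NAXIS{i + 1}", n))
    if not primary:
        cards.append(_card("PCOUNT", 0))
        cards.append(_card("GCOUNT", 1))
    if hdu.name:
        cards.append(_card("EXTNAME", hdu.name))
    for k, v in hdu.header.items():
        cards.append(_card(k[:8].upper(), v))
    cards.append(_card("END"))
    header = _pad(b"".join(cards))
    payload = _pad(data.tobytes(), b"\x00") if data.size else b""
    return header + payload


def write_fits(path, data=None, header=None, extensions=()):
    """Write a FITS file with a primary image and optional IMAGE extensions.

    Parameters
    ----------
    data : ndarray or None
        Primary HDU image (written as float32, or uint8 for uint8 input).
    header : dict, optional
        Scalar key/value cards for the primary header.
    extensions : iterable of ImageHDU
        Additional image extensions.
    """
    buf = _serialize_hdu(ImageHDU(data, header=dict(header or {})), primary=True)
    for ext in extensions:
        buf += _serialize_hdu(ext, primary=False)
    with open(path, "wb") as fh:
        fh.write(buf)


def _parse_value(raw: str):
    raw = raw.strip()
    if raw.startswith("'"):
        return raw[1:].rsplit("'", 1)[0].rstrip().replace("''", "'")
    if raw in ("T", "F"):
        return raw == "T"
    try:
        return int(raw)
    except ValueError:
        pass
    try:
        return float(raw.replace("D", "E"))
    except ValueError:
        return raw


def _read_hdu(fh):
    cards = {}
    first = fh.read(BLOCK)
    if not first:
        return None
    block = first
    done = False
    while True:
        for i in range(0, len(block), CARD):
            card = block[i : i + CARD].decode("ascii", errors="replace")
            key = card[:8].strip()
            if key == "END":
                done = True
                break
            if "= " in card[8:10] or card[8] == "=":
                body = card[10:]
                if " / " in body:
                    body = body.split(" / ", 1)[0]
                cards[key] = _parse_value(body)
        if done:
            break
        block = fh.read(BLOCK)
        if not block:
            raise OSError("truncated FITS header")
    bitpix = cards["BITPIX"]
    naxis = cards["NAXIS"]
    shape = tuple(cards[f"NAXIS{i}"] for i in range(naxis, 0, -1))
    n = int(np.prod(shape)) if shape else 0
    data = None
    if n:
        nbytes = n * abs(bitpix) // 8
        raw = fh.read(nbytes)
        if len(raw) < nbytes:
            raise OSError("truncated FITS data")
        fh.read((-nbytes) % BLOCK)
        data = np.frombuffer(raw, dtype=_BITPIX_DTYPE[bitpix]).reshape(shape)
        data = data.astype(data.dtype.newbyteorder("="))
    name = cards.get("EXTNAME", "")
    meta = {
        k: v
        for k, v in cards.items()
        if k not in ("SIMPLE", "XTENSION", "BITPIX", "NAXIS", "PCOUNT", "GCOUNT", "EXTNAME")
        and not k.startswith("NAXIS")
    }
    return ImageHDU(data, name=name, header=meta)


def read_fits(path) -> list[ImageHDU]:
    """Read all image HDUs from a FITS file."""
    hdus = []
    with open(path, "rb") as fh:
        while True:
            hdu = _read_hdu(fh)
            if hdu is None:
                break
            hdus.append(hdu)
    if not hdus:
        raise OSError(f"no HDUs in {path}")
    return hdus
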