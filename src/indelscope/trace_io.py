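"""Reading, writing and normalizing capillary sequencing traces.

A capillary (Sanger) trace is represented by :class:`Chromatogram`: the
called base string plus a per-position matrix of four peak heights, one
per fluorescence channel, in fixed column order A, C, G, T.  Downstream
analysis never uses raw heights directly; it operates on per-position
signal *fractions* (:class:`SignalMatrix`), which are invariant to the
overall trace intensity and to any per-position scaling applied by the
base-calling software.

Supported on-disk formats:

* ABIF (``.ab1``) — read through Biopython's ABI parser.  Peak heights
  are taken from the four analyzed-data channels (``DATA9``–``DATA12``,
  channel-to-base mapping from ``FWO_1``) sampled at the per-base peak
  locations recorded by the base caller (``PLOC2``, falling back to
  ``PLOC1``); called bases come from ``PBAS2`` (falling back ``PBAS1``).
* SCF v3 (``.scf``) — parsed directly (header, delta-delta-encoded
  sample arrays, per-base peak indices).
* A plain-text fixture dialect — tab-separated with header
  ``pos base A C G T``, 1-based positions — for diffable, hand-editable
  test inputs.

Writing supports the fixture dialect (bit-exact round trip) and a
minimal ABIF containing exactly the tag set the reader consumes
(integer-exact round trip of peak heights).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_VALID_CALLS = set("ACGTN")


class TraceFormatError(ValueError):
    """The file is not a parseable trace in the declared/detected format."""


class TraceIntegrityError(ValueError):
    """The file parsed but its records are mutually inconsistent."""


@dataclass
class Chromatogram:
    """Called bases plus an aligned N x 4 peak-height matrix (A,C,G,T).

    Ambiguity codes other than N in the called sequence are replaced by
    N on construction; calls are used only for alignment and display, so
    the peak fractions are unaffected.
    """

    bases: str
    peaks: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.bases = "".join(
            b if b in _VALID_CALLS else "N" for b in self.bases.upper()
        )
        self.peaks = np.asarray(self.peaks, dtype=float)
        if len(self.bases) < 1:
            raise ValueError("chromatogram must contain at least one called base")
        if self.peaks.shape != (len(self.bases), 4):
            raise TraceIntegrityError(
                f"peak matrix shape {self.peaks.shape} does not match "
                f"{len(self.bases)} called bases"
            )
        if np.any(self.peaks < 0):
            raise ValueError("peak heights must be non-negative")

    def __len__(self) -> int:
        return len(self.bases)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Chromatogram):
            return NotImplemented
        return self.bases == other.bases and np.array_equal(self.peaks, other.peaks)


@dataclass
class SignalMatrix:
    """Per-position signal fractions; every unmasked row sums to 1.

    ``mask`` marks positions whose raw channel sum was zero (late-read
    dropout); those rows are filled with 0.25 per channel so that shifted
    model columns built from them stay well defined, and the mask lets
    the decomposition drop them from the fit.
    """

    fractions: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.mask is None:
            self.mask = np.zeros(self.fractions.shape[0], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)

    def __len__(self) -> int:
        return self.fractions.shape[0]


def normalize(c: Chromatogram) -> SignalMatrix:
    """Convert raw peak heights to per-position signal fractions.

    Each row is divided by its four-channel sum.  Rows whose sum is zero
    carry no signal: they are masked and filled with a uniform 0.25.
    """
    sums = c.peaks.sum(axis=1)
    mask = sums <= 0
    safe = np.where(mask, 1.0, sums)
    fractions = c.peaks / safe[:, None]
    fractions[mask] = 0.25
    return SignalMatrix(fractions=fractions, mask=mask)


# ---------------------------------------------------------------------------
# fixture dialect (TSV)
# ---------------------------------------------------------------------------

_FIXTURE_HEADER = "pos\tbase\tA\tC\tG\tT"


def _read_fixture(path: Path) -> Chromatogram:
    lines = path.read_text().splitlines()
    if not lines or lines[0].rstrip() != _FIXTURE_HEADER:
        raise TraceFormatError(
            f"{path}: fixture trace must start with header '{_FIXTURE_HEADER}'"
        )
    bases = []
    rows = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 6:
            raise TraceFormatError(f"{path}:{ln}: expected 6 tab-separated fields")
        try:
            pos = int(parts[0])
            heights = [float(v) for v in parts[2:]]
        except ValueError as exc:
            raise TraceFormatError(f"{path}:{ln}: {exc}") from exc
        if pos != len(bases) + 1:
            raise TraceIntegrityError(
                f"{path}:{ln}: position {pos} out of order (expected {len(bases) + 1})"
            )
        bases.append(parts[1])
        rows.append(heights)
    if not bases:
        raise TraceFormatError(f"{path}: fixture trace contains no records")
    return Chromatogram("".join(bases), np.array(rows), source_id=path.name)


def _write_fixture(c: Chromatogram, path: Path) -> None:
    out = [_FIXTURE_HEADER]
    for i, b in enumerate(c.bases):
        heights = "\t".join(repr(float(v)) for v in c.peaks[i])
        out.append(f"{i + 1}\t{b}\t{heights}")
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# ABIF
# ---------------------------------------------------------------------------

# Directory entry: name, number, element type, element size, element count,
# data size, data offset (or inline data when size <= 4), handle.
_ABIF_DIRFMT = ">4sI2H4I"
_ABIF_HEADFMT = ">H4sI2H3I"  # after the 4-byte "ABIF" magic


def _abif_tag(raw: dict, name: str, fallback: str | None = None):
    if name in raw:
        return raw[name]
    if fallback is not None and fallback in raw:
        return raw[fallback]
    raise TraceFormatError(
        f"ABIF file lacks required tag {name}"
        + (f" (and fallback {fallback})" if fallback else "")
    )


def _read_abif(path: Path) -> Chromatogram:
    from Bio import SeqIO

    try:
        record = SeqIO.read(str(path), "abi")
    except (ValueError, struct.error, AssertionError) as exc:
        raise TraceFormatError(f"{path}: not a readable ABIF file ({exc})") from exc

    raw = record.annotations.get("abif_raw", {})
    bases_raw = _abif_tag(raw, "PBAS2", "PBAS1")
    bases = bases_raw.decode() if isinstance(bases_raw, bytes) else str(bases_raw)
    ploc = _abif_tag(raw, "PLOC2", "PLOC1")
    if isinstance(ploc, int):
        ploc = (ploc,)
    ploc = np.asarray(ploc, dtype=int)
    fwo = _abif_tag(raw, "FWO_1")
    order = fwo.decode() if isinstance(fwo, bytes) else str(fwo)
    if sorted(order) != ["A", "C", "G", "T"]:
        raise TraceFormatError(f"{path}: FWO_1 channel order {order!r} is not a permutation of ACGT")

    if len(bases) != len(ploc):
        raise TraceIntegrityError(
            f"{path}: {len(bases)} called bases but {len(ploc)} peak locations"
        )

    channels = []
    for i in range(4):
        data = _abif_tag(raw, f"DATA{9 + i}")
        if isinstance(data, int):
            data = (data,)
        channels.append(np.asarray(data, dtype=float))
    n_samples = min(len(ch) for ch in channels)
    if len(ploc) and (ploc.min() < 0 or ploc.max() >= n_samples):
        raise TraceIntegrityError(
            f"{path}: peak location {ploc.max()} outside analyzed data "
            f"({n_samples} samples)"
        )

    peaks = np.zeros((len(bases), 4))
    for ch_idx, base in enumerate(order):
        peaks[:, BASE_INDEX[base]] = channels[ch_idx][ploc]
    return Chromatogram(bases, peaks, source_id=path.name)


def _write_abif(c: Chromatogram, path: Path) -> None:
    """Emit a minimal ABIF file with the tag set the reader consumes.

    Peak heights are rounded to the nearest integer (ABIF stores analyzed
    channels as 16-bit integers) and one data sample is written per called
    base, with PLOC2[i] = i.  Channel file order follows the conventional
    GATC filter-wheel order.
    """
    peaks = np.rint(c.peaks).astype(int)
    if peaks.max(initial=0) > 32767:
        raise ValueError("ABIF analyzed channels are 16-bit; peak height > 32767")
    n = len(c.bases)
    order = "GATC"

    tags: list[tuple[bytes, int, int, int, int, bytes]] = []

    def add(name: bytes, number: int, etype: int, esize: int, data: bytes, enum: int):
        tags.append((name, number, etype, esize, enum, data))

    for ch_idx, base in enumerate(order):
        col = peaks[:, BASE_INDEX[base]]
        add(b"DATA", 9 + ch_idx, 4, 2, struct.pack(f">{n}h", *col), n)
    add(b"FWO_", 1, 2, 1, order.encode(), 4)
    add(b"PBAS", 2, 2, 1, c.bases.encode(), n)
    add(b"PLOC", 2, 4, 2, struct.pack(f">{n}H", *range(n)), n)

    blobs = bytearray()
    blob_base = 128
    entries = []
    for name, number, etype, esize, enum, data in tags:
        dsize = len(data)
        if dsize <= 4:
            inline = data.ljust(4, b"\0")
            entry = (
                struct.pack(">4sI2H2I", name, number, etype, esize, enum, dsize)
                + inline
                + struct.pack(">I", 0)
            )
        else:
            offset = blob_base + len(blobs)
            blobs.extend(data)
            entry = struct.pack(
                _ABIF_DIRFMT, name, number, etype, esize, enum, dsize, offset, 0
            )
        entries.append(entry)

    dir_offset = blob_base + len(blobs)
    header = b"ABIF" + struct.pack(
        _ABIF_HEADFMT, 101, b"tdir", 1, 1023, 28, len(entries), 28 * len(entries), dir_offset
    )
    header = header.ljust(128, b"\0")
    path.write_bytes(header + bytes(blobs) + b"".join(entries))


# ---------------------------------------------------------------------------
# SCF v3
# ---------------------------------------------------------------------------

_SCF_HEADER = ">4s8I4s4I18I"


def _scf_undelta(arr: np.ndarray) -> np.ndarray:
    # SCF v3 stores sample arrays twice delta-encoded with wraparound
    # arithmetic in the native unsigned width.
    out = np.cumsum(arr, dtype=arr.dtype)
    return np.cumsum(out, dtype=arr.dtype)


def _read_scf(path: Path) -> Chromatogram:
    data = path.read_bytes()
    if len(data) < 128:
        raise TraceFormatError(f"{path}: SCF file shorter than its 128-byte header")
    fields = struct.unpack(_SCF_HEADER, data[:128])
    magic = fields[0]
    if magic != b".scf":
        raise TraceFormatError(f"{path}: bad SCF magic {magic!r}")
    (n_samples, samples_offset, n_bases, _lclip, _rclip, bases_offset,
     _csize, _coffset) = fields[1:9]
    version = fields[9]
    sample_size = fields[10]
    try:
        major = float(version.decode())
    except (UnicodeDecodeError, ValueError):
        raise TraceFormatError(f"{path}: unreadable SCF version {version!r}") from None
    if major < 3:
        raise TraceFormatError(
            f"{path}: SCF version {version.decode()} not supported (need >= 3.00)"
        )
    if sample_size not in (1, 2):
        raise TraceFormatError(f"{path}: invalid SCF sample size {sample_size}")
    dtype = np.dtype(">u2") if sample_size == 2 else np.dtype("u1")

    samples_end = samples_offset + 4 * n_samples * sample_size
    bases_end = bases_offset + 12 * n_bases
    if samples_end > len(data) or bases_end > len(data):
        raise TraceIntegrityError(f"{path}: SCF sections extend past end of file")

    block = np.frombuffer(data[samples_offset:samples_end], dtype=dtype)
    channels = [
        _scf_undelta(block[i * n_samples:(i + 1) * n_samples].copy()).astype(float)
        for i in range(4)
    ]

    # v3 bases section: peak indices, then 4 probability arrays, bases, spare.
    off = bases_offset
    peak_idx = np.frombuffer(data[off:off + 4 * n_bases], dtype=">u4").astype(int)
    off += 4 * n_bases + 4 * n_bases  # skip probabilities
    bases = data[off:off + n_bases].decode("ascii", errors="replace")
    if n_bases == 0:
        raise TraceFormatError(f"{path}: SCF file contains no called bases")
    if peak_idx.max(initial=0) >= n_samples:
        raise TraceIntegrityError(f"{path}: SCF peak index outside sample array")

    peaks = np.zeros((n_bases, 4))
    for ch, base in enumerate(BASES):  # SCF channel order is A,C,G,T
        peaks[:, ch] = channels[ch][peak_idx]
    return Chromatogram(bases, peaks, source_id=path.name)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def _detect_format(path: Path) -> str:
    with open(path, "rb") as fh:
        head = fh.read(4)
    if head == b"ABIF":
        return "abif"
    if head == b".scf":
        return "scf"
    return "fixture"


def read_trace(path, format: str = "auto") -> Chromatogram:
    """Read a trace file into a :class:`Chromatogram`.

    Parameters
    ----------
    path
        File in ABIF, SCF v3, or fixture-TSV format.
    format
        One of ``abif``, ``scf``, ``fixture`` or ``auto`` (sniff the
        magic bytes).
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    if format == "auto":
        format = _detect_format(path)
    if format == "abif":
        return _read_abif(path)
    if format == "scf":
        return _read_scf(path)
    if format == "fixture":
        return _read_fixture(path)
    raise ValueError(f"unknown trace format {format!r}")


def write_fixture(c: Chromatogram, path, format: str = "fixture") -> None:
    """Write a chromatogram to disk in the fixture dialect or minimal ABIF."""
    path = Path(path)
    if format == "fixture":
        _write_fixture(c, path)
    elif format == "abif":
        _write_abif(c, path)
    else:
        raise ValueError(f"unknown output format {format!r}")
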