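"""Shared fixtures and helpers for the test suite.

All test data is generated programmatically: synthetic chromatograms
come from the ``synth`` module, and binary trace files (ABIF, SCF) are
built in memory at test time.
"""

from __future__ import annotations

import struct

import numpy as np
import pytest

import indelscope as ix


def build_scf_v3(bases: str, peaks: np.ndarray, version: bytes = b"3.00") -> bytes:
    """Serialize a chromatogram as a minimal SCF v3 byte blob.

    One sample per called base; channel order A,C,G,T; sample arrays
    twice delta-encoded in 16-bit wraparound arithmetic as the v3 format
    requires.
    """
    n = len(bases)
    peaks = np.asarray(peaks)
    encoded = []
    for c in range(4):
        ch = peaks[:, c].astype(np.uint16)
        d1 = np.diff(ch, prepend=np.uint16(0)).astype(np.uint16)
        d2 = np.diff(d1, prepend=np.uint16(0)).astype(np.uint16)
        encoded.append(d2)
    samples = b"".join(e.astype(">u2").tobytes() for e in encoded)
    samples_offset = 128
    bases_offset = samples_offset + len(samples)
    bases_section = (
        np.arange(n, dtype=">u4").tobytes()  # peak indices
        + bytes(4 * n)  # four probability arrays
        + bases.encode()
        + bytes(3 * n)  # spare
    )
    header = struct.pack(
        ">4s8I4s4I18I",
        b".scf",
        n,
        samples_offset,
        n,
        0,
        0,
        bases_offset,
        0,
        bases_offset + len(bases_section),
        version,
        2,
        0,
        0,
        0,
        *([0] * 18),
    )
    return header + samples + bases_section


@pytest.fixture
def amplicon():
    """800-nt random amplicon with a guide whose cut falls at index 197."""
    rng = np.random.default_rng(20140936)
    seq = ix.random_sequence(800, rng)
    guide = seq[180:200]
    return seq, guide, 197


@pytest.fixture
def noiseless_params():
    return ix.TraceParams(noise_cv=0.0, crosstalk=0.0, seed=0)


def run_mixture(
    seq: str,
    guide: str,
    cut: int,
    spectrum: list[tuple[int, float] | tuple[int, float, str]],
    control_params: ix.TraceParams,
    sample_params: ix.TraceParams,
    max_indel: int = 10,
) -> ix.Report:
    """Render a control trace and an indel-mixture sample, then run the
    full analysis.  Spectrum entries are (size, weight) or
    (size, weight, inserted_bases)."""
    control = ix.render_trace(seq, control_params)
    specs = []
    for entry in spectrum:
        size, weight = entry[0], entry[1]
        bases = entry[2] if len(entry) > 2 else ("A" * max(size, 0))
        specs.append((ix.IndelSpec(size, cut, bases if size > 0 else ""), weight))
    sample = ix.indel_pool(seq, specs, sample_params)
    return ix.analyze(control, sample, guide, max_indel=max_indel)
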