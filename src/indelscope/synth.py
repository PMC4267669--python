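"""Synthetic chromatogram generation.

The decomposition pipeline assumes a specific statistical structure in
its input: an edited cell pool yields a PCR product whose Sanger trace
is, downstream of the nuclease cut, a *linear mixture* of the wild-type
trace and copies of it shifted by each indel present in the pool.  This
module generates traces with exactly that structure — a called base
sequence, four per-position peak heights with exponential signal decay
along the read, optional inter-channel crosstalk, multiplicative
lognormal peak noise, and weighted mixtures of sequence variants sharing
a common 5' prefix — so the whole pipeline is testable without
sequencing hardware.

It does not attempt physical realism (peak shapes, mobility shifts, dye
blobs): one peak-height sample per called base is the level of detail
the decomposition consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trace_io import BASES, BASE_INDEX, Chromatogram


@dataclass
class TraceParams:
    """Parameters of the trace renderer.

    base_amplitude
        Peak height of the first position, arbitrary fluorescence units.
    decay_rate
        Exponential signal decay per position; typical clean runs lose
        most of their signal over ~1000 bases.
    noise_cv
        Coefficient of variation of the multiplicative lognormal noise
        applied per channel per position.
    crosstalk
        Fraction of each peak's height leaked uniformly into the other
        three channels (total leak; each receives a third).
    seed
        Seed of the noise generator; identical inputs and seed give a
        bit-identical trace.
    """

    base_amplitude: float = 1000.0
    decay_rate: float = 0.0015
    noise_cv: float = 0.05
    crosstalk: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_amplitude <= 0:
            raise ValueError("base_amplitude must be positive")
        if self.decay_rate < 0:
            raise ValueError("decay_rate must be >= 0")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not 0 <= self.crosstalk <= 0.3:
            raise ValueError("crosstalk must lie in [0, 0.3]")


@dataclass
class IndelSpec:
    """One indel: signed size, insertion bases, and the cut coordinate.

    Negative sizes are deletions of the |size| bases immediately 3' of
    the cut; positive sizes insert ``inserted_bases`` immediately 3' of
    the cut; size 0 is the unmodified wild type.
    """

    size: int
    position: int
    inserted_bases: str = ""

    def __post_init__(self) -> None:
        self.inserted_bases = self.inserted_bases.upper()
        if self.size > 0 and len(self.inserted_bases) != self.size:
            raise ValueError(
                f"insertion of size +{self.size} needs {self.size} inserted bases, "
                f"got {self.inserted_bases!r}"
            )
        if self.size <= 0 and self.inserted_bases:
            raise ValueError("inserted_bases only apply to insertions")
        if any(b not in BASES for b in self.inserted_bases):
            raise ValueError("inserted_bases must be over ACGT")


def apply_indel(sequence: str, indel: IndelSpec) -> str:
    """Apply a single indel to a sequence at its cut coordinate."""
    pos = indel.position
    if not 0 <= pos <= len(sequence):
        raise ValueError(f"cut position {pos} outside sequence of length {len(sequence)}")
    if indel.size == 0:
        return sequence
    if indel.size < 0:
        end = pos - indel.size
        if end > len(sequence):
            raise ValueError(
                f"deletion of {-indel.size} at {pos} runs off the sequence end"
            )
        return sequence[:pos] + sequence[end:]
    return sequence[:pos] + indel.inserted_bases + sequence[pos:]


def random_sequence(length: int, rng: np.random.Generator) -> str:
    """Uniform random sequence over ACGT."""
    return "".join(rng.choice(list(BASES), size=length))


def _noiseless_matrix(sequence: str, params: TraceParams) -> np.ndarray:
    """Peak matrix before noise: decayed amplitude in the called channel,
    crosstalk leak split evenly over the other three channels."""
    n = len(sequence)
    heights = params.base_amplitude * np.exp(-params.decay_rate * np.arange(n))
    mat = np.full((n, 4), 0.0)
    idx = np.fromiter((BASE_INDEX[b] for b in sequence), dtype=int, count=n)
    leak = params.crosstalk
    mat[:] = (heights * (leak / 3.0))[:, None]
    mat[np.arange(n), idx] = heights * (1.0 - leak)
    return mat


def _apply_noise(mat: np.ndarray, params: TraceParams, rng: np.random.Generator) -> np.ndarray:
    if params.noise_cv == 0:
        return mat
    sigma = np.sqrt(np.log1p(params.noise_cv**2))
    factors = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=mat.shape)
    return mat * factors


def render_trace(sequence: str, params: TraceParams) -> Chromatogram:
    """Render one sequence into a synthetic chromatogram."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    if any(b not in BASES for b in sequence.upper()):
        raise ValueError("sequence must be over ACGT")
    sequence = sequence.upper()
    rng = np.random.default_rng(params.seed)
    mat = _apply_noise(_noiseless_matrix(sequence, params), params, rng)
    return Chromatogram(sequence, mat, source_id=f"synth:seed={params.seed}")


def mix_traces(
    components: list[tuple[str, float]], params: TraceParams
) -> Chromatogram:
    """Mix sequence variants into one composite chromatogram.

    Each component's noiseless peak matrix is weighted and summed
    position-wise (components are aligned at their shared 5' prefix, as
    PCR amplicons sharing a primer are); noise is applied once, after
    mixing, because the fluorescence detector sees the summed signal.
    Components shorter than the longest contribute nothing past their
    own end.  Called bases of the composite are the per-position
    channel argmax.
    """
    if not components:
        raise ValueError("need at least one component")
    weights = np.array([w for _, w in components], dtype=float)
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"weights must sum to 1 (got {weights.sum()!r})")

    seqs = [s.upper() for s, _ in components]
    length = max(len(s) for s in seqs)
    mat = np.zeros((length, 4))
    for seq, w in zip(seqs, weights):
        if w == 0:
            continue
        mat[: len(seq)] += w * _noiseless_matrix(seq, params)

    rng = np.random.default_rng(params.seed)
    mat = _apply_noise(mat, params, rng)
    called = "".join(BASES[i] for i in mat.argmax(axis=1))
    return Chromatogram(called, mat, source_id=f"synth-mix:seed={params.seed}")


def indel_pool(
    sequence: str,
    spectrum: list[tuple[IndelSpec, float]],
    params: TraceParams,
) -> Chromatogram:
    """Convenience: mix the variants produced by a spectrum of indels.

    ``spectrum`` pairs each :class:`IndelSpec` with its pool frequency;
    frequencies must sum to 1.
    """
    components = [(apply_indel(sequence, spec), w) for spec, w in spectrum]
    return mix_traces(components, params)
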