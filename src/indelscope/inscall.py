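"""Base composition of single-base (+1) insertions.

At the first position 3' of the cut, every allele except the insertions
shows a predictable base: the wild type and every deletion of size d
show the control base from ``cut + d`` positions in, while insertions of
two or more bases show an unknown inserted base (approximated as an
uninformative uniform channel row — their fitted frequencies are
typically small, so the approximation is second order).  Subtracting
that aggregate expected signal, weighted by the fitted coefficients,
from the observed sample signal at the position leaves a residual
carried by the +1 alleles alone: the residual's channel distribution is
the base composition of the single inserted nucleotide.

Insertions longer than +1 are not base-called; only the composition of
the single-base insertion, the most frequent insertion class, is
inferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decomp import DecompositionResult
from .locate import BreakSite, OffsetAlignment
from .trace_io import BASES, SignalMatrix

#: minimum +1 percentage for the composition to be considered supported
SUPPORT_THRESHOLD_PCT = 1.0


@dataclass
class InsertionComposition:
    """Relative frequency of each base as the +1 inserted nucleotide."""

    fractions: np.ndarray  # length 4, order A,C,G,T; NaN when unsupported
    supported: bool
    note: str = ""

    def as_dict(self) -> dict[str, float]:
        return {b: float(f) for b, f in zip(BASES, self.fractions)}

    @property
    def called_base(self) -> str | None:
        if not self.supported:
            return None
        return BASES[int(np.nanargmax(self.fractions))]


def plus_one_composition(
    sample_signal: SignalMatrix,
    control_signal: SignalMatrix,
    result: DecompositionResult,
    site: BreakSite,
    offset: OffsetAlignment,
) -> InsertionComposition:
    """Infer the base composition of +1 insertions from the residual
    signal at the first post-cut position."""
    cut = site.cut_index
    sample_pos = cut + offset.offset
    if not 0 <= sample_pos < len(sample_signal):
        raise ValueError("first post-cut position not readable in the sample trace")

    plus_one_pct = result.percentage(+1)
    if plus_one_pct < SUPPORT_THRESHOLD_PCT:
        return InsertionComposition(
            fractions=np.full(4, np.nan),
            supported=False,
            note=f"+1 frequency {plus_one_pct:.2f}% below "
            f"{SUPPORT_THRESHOLD_PCT}% support threshold",
        )

    expected = np.zeros(4)
    uniform = np.full(4, 0.25)
    for label, coef in zip(result.indel_labels, result.coefficients):
        if label == +1:
            continue  # the +1 alleles are the signal we want to isolate
        if label <= 0:
            src = cut + (-label)  # deletion of d shows control base cut+d; wt shows cut
            if src < len(control_signal):
                expected += coef * control_signal.fractions[src]
            else:
                expected += coef * uniform
        else:
            expected += coef * uniform  # first base of a >= +2 insertion is unknown

    residual = sample_signal.fractions[sample_pos] - expected
    residual = np.clip(residual, 0.0, None)
    total = residual.sum()
    if total <= 0:
        return InsertionComposition(
            fractions=np.full(4, np.nan),
            supported=False,
            note=f"+1 frequency is {plus_one_pct:.2f}% but the post-cut residual "
            "is non-positive; modeled signal already exceeds the observation",
        )
    return InsertionComposition(fractions=residual / total, supported=True)
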