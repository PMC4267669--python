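"""Cut-site location and control/sample offset estimation.

The expected SpCas9 break site is found by local (Smith–Waterman)
alignment of the 20-nt guide — and its reverse complement — against the
control trace's called bases.  SpCas9 cuts bluntly 3 bp 5' of the PAM,
i.e. between protospacer positions 17 and 18; the cut coordinate is
mapped through the alignment and, for reverse-strand hits, through the
reverse-complement coordinate flip.

A second local alignment of the control region immediately upstream of
the cut against the sample trace gives the coordinate offset between
the two reads (they may start at different positions in the amplicon).
Because the probe lies entirely 5' of the cut, it is indel-free in
every allele of the pool, so the offset is well defined even for
heavily edited samples.

All coordinates are 0-based, half-open; the cut index names the gap
*before* that index.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Align import PairwiseAligner
from Bio.Seq import reverse_complement

from .trace_io import Chromatogram

GUIDE_LENGTH = 20
#: blunt cut 3 bp 5' of the PAM = between protospacer positions 17|18
CUT_OFFSET_IN_GUIDE = 17
MIN_IDENTITY = 0.9

# match +2 / mismatch -1 / gap open -5 / extend -2: a perfect 20-mer hit
# scores 40 and gapped guide matches are strongly discouraged.
_SCORING = dict(
    match_score=2.0,
    mismatch_score=-1.0,
    open_gap_score=-5.0,
    extend_gap_score=-2.0,
)


class GuideNotFoundError(ValueError):
    """No acceptable guide match in the control trace."""


class SampleMismatchError(ValueError):
    """The sample read does not contain the control's upstream region."""


@dataclass
class BreakSite:
    """Expected cut coordinate on the control trace."""

    cut_index: int
    strand: str  # "forward" | "reverse"
    guide_start: int
    alignment_score: float


@dataclass
class OffsetAlignment:
    """Signed shift mapping control coordinates to sample coordinates
    (``sample_index = control_index + offset``)."""

    offset: int
    alignment_score: float


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    for key, val in _SCORING.items():
        setattr(aligner, key, val)
    return aligner


def _best_local(query: str, target: str):
    """Best local alignment of query in target.

    Returns (score, query_anchor_start_in_target, identities, n_distinct_starts)
    where the anchor start is the target coordinate query position 0 maps
    to (extrapolated through the first aligned block), and
    n_distinct_starts counts optimal alignments at distinct target
    positions (> 1 signals a repetitive target).
    """
    aligner = _make_aligner()
    alignments = aligner.align(target, query)
    try:
        best = alignments[0]
    except IndexError:
        return float("-inf"), -1, 0, 0
    score = best.score
    starts = set()
    for i, aln in enumerate(alignments):
        if i >= 8:  # enough to detect a repeat; avoids enumerating blowups
            break
        if aln.score < score:
            break
        tblk, qblk = aln.aligned
        starts.add(int(tblk[0][0]) - int(qblk[0][0]))
    tblk, qblk = best.aligned
    anchor = int(tblk[0][0]) - int(qblk[0][0])
    identities = sum(
        1
        for (ts, te), (qs, qe) in zip(tblk, qblk)
        for k in range(te - ts)
        if target[ts + k] == query[qs + k]
    )
    return score, anchor, identities, len(starts)


def locate_guide(control: Chromatogram, guide: str) -> BreakSite:
    """Locate the guide (either strand) on the control trace and derive
    the expected cut coordinate.

    Raises :class:`GuideNotFoundError` when the best hit has < 90%
    identity, when forward and reverse strands tie, or when equally good
    hits occur at several positions (repetitive target).
    """
    guide = guide.upper()
    if len(guide) != GUIDE_LENGTH:
        raise ValueError(f"guide must be {GUIDE_LENGTH} nt, got {len(guide)}")
    if any(b not in "ACGT" for b in guide):
        raise ValueError("guide must be over ACGT")

    target = control.bases
    fwd_score, fwd_anchor, fwd_ident, fwd_ties = _best_local(guide, target)
    rc = reverse_complement(guide)
    rev_score, rev_anchor, rev_ident, rev_ties = _best_local(rc, target)

    if fwd_score == rev_score:
        raise GuideNotFoundError(
            f"guide matches both strands equally (forward score {fwd_score}, "
            f"reverse score {rev_score}); cannot orient the cut site"
        )
    if fwd_score > rev_score:
        strand, score, anchor, ident, ties = "forward", fwd_score, fwd_anchor, fwd_ident, fwd_ties
    else:
        strand, score, anchor, ident, ties = "reverse", rev_score, rev_anchor, rev_ident, rev_ties

    if ident < MIN_IDENTITY * GUIDE_LENGTH:
        raise GuideNotFoundError(
            f"best guide match has identity {ident}/{GUIDE_LENGTH} < 90% "
            f"(forward score {fwd_score}, reverse score {rev_score})"
        )
    if ties > 1:
        raise GuideNotFoundError(
            f"guide matches {ties} positions equally well; "
            "repetitive target sequence"
        )

    if strand == "forward":
        cut = anchor + CUT_OFFSET_IN_GUIDE
    else:
        # reverse-complement coordinates: protospacer 17|18 maps to the
        # gap 3 bases into the reverse-complement match
        cut = anchor + (GUIDE_LENGTH - CUT_OFFSET_IN_GUIDE)
    if not 0 < cut < len(control):
        raise GuideNotFoundError(
            f"derived cut index {cut} lies outside the control read"
        )
    return BreakSite(cut_index=cut, strand=strand, guide_start=anchor, alignment_score=score)


def align_offset(
    control: Chromatogram,
    sample: Chromatogram,
    site: BreakSite,
    probe_len: int = 100,
) -> OffsetAlignment:
    """Estimate the control→sample coordinate shift.

    The probe is the control region ``[max(0, cut - probe_len), cut)``;
    its best local-alignment position in the sample gives the offset.
    Identity below 90% means the sample does not contain the control's
    upstream sequence — a mixed-up sample pair.
    """
    if probe_len < 1:
        raise ValueError("probe_len must be positive")
    probe_start = max(0, site.cut_index - probe_len)
    probe = control.bases[probe_start: site.cut_index]
    if not probe:
        raise ValueError("no control sequence upstream of the cut to anchor on")

    score, anchor, ident, _ = _best_local(probe, sample.bases)
    if ident < MIN_IDENTITY * len(probe):
        raise SampleMismatchError(
            f"sample does not match control upstream of the break "
            f"(identity {ident}/{len(probe)} < 90%)"
        )
    return OffsetAlignment(offset=anchor - probe_start, alignment_score=score)
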