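"""Indel-spectrum decomposition of a composite sequence trace.

Downstream of a nuclease cut, the trace of an edited cell pool is a
linear superposition of the wild-type trace and copies of it shifted
left or right by each deletion or insertion present in the pool.  The
decomposition therefore:

1. builds one model vector per indel size in {-n..+n} by shifting the
   control trace's signal fractions by the appropriate number of
   positions (a deletion of d shows, at window position i, the control
   base from position i + d; an insertion of k shows the one from
   i - k), restricted to a decomposition window and concatenated over
   the four channels into a single length-4W column;
2. fits the sample's windowed signal vector as a non-negative linear
   combination of those columns (NNLS);
3. reports goodness of fit (R^2), a per-coefficient standard error and
   two-tailed t-test p-value from the unconstrained least-squares
   variance–covariance matrix evaluated at the NNLS solution, and the
   coefficients rescaled by a single constant so that they sum to R^2
   (absorbing systematic intensity differences between the two runs),
   expressed as percentages.

The default window starts s+5 positions past the cut (for any insertion
of size <= s, every window position of its shifted model is then
determined by known control sequence — the unknown inserted bases stay
left of the window) and stops s+5 positions before the end of the
shortest read.

The aberrant-signal profile — the fraction of signal at each position
not attributable to the control-called base — is the quality-control
view: it should be near zero before the cut in both traces and rise at
the cut in the edited sample.  Because a fully independent base matches
the reference by chance 1 time in 4, a 100% edited trace saturates at
~75% aberrant signal.
"""

from __future__ import annotations

import warnings as _pywarnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import nnls

from .locate import BreakSite, OffsetAlignment
from .trace_io import BASE_INDEX, SignalMatrix


class WindowError(ValueError):
    """The decomposition window is empty or too short for the model."""


@dataclass
class DecompositionWindow:
    """Half-open interval [left, right) in control-frame coordinates."""

    left: int
    right: int

    def __post_init__(self) -> None:
        if self.right <= self.left:
            raise WindowError(f"empty decomposition window [{self.left}, {self.right})")

    @property
    def width(self) -> int:
        return self.right - self.left


@dataclass
class IndelModelSet:
    """Design matrix of shifted control traces.

    ``matrix`` has shape (4W, 2n+1): per indel, the control signal
    fractions over the window, shifted by the indel size, with the four
    per-base vectors concatenated in A,C,G,T block order.
    ``source_mask`` marks window positions whose *unshifted* control row
    was masked (signal dropout).
    """

    n: int
    window: DecompositionWindow
    matrix: np.ndarray
    indel_labels: np.ndarray
    source_mask: np.ndarray = field(default=None)  # type: ignore[assignment]


@dataclass
class AberrantProfile:
    """Per-position aberrant signal for both traces, in the control frame."""

    control: np.ndarray
    sample: np.ndarray
    cut_index: int


@dataclass
class DecompositionResult:
    indel_labels: np.ndarray
    coefficients: np.ndarray
    percentages: np.ndarray
    se: np.ndarray
    p: np.ndarray
    r_squared: float
    window: DecompositionWindow
    warnings: list[str] = field(default_factory=list)

    @property
    def total_efficiency(self) -> float:
        """Summed percentage of all non-wild-type indels."""
        return float(self.percentages[self.indel_labels != 0].sum())

    def percentage(self, indel: int) -> float:
        (idx,) = np.nonzero(self.indel_labels == indel)
        if idx.size == 0:
            raise KeyError(f"indel {indel:+d} outside modeled range")
        return float(self.percentages[idx[0]])

    def p_value(self, indel: int) -> float:
        (idx,) = np.nonzero(self.indel_labels == indel)
        if idx.size == 0:
            raise KeyError(f"indel {indel:+d} outside modeled range")
        return float(self.p[idx[0]])


def aberrant_signal(signal: SignalMatrix, reference_bases: str) -> np.ndarray:
    """Fraction of signal per position not from the reference base.

    Positions whose reference call is N, and masked (dropout) positions,
    yield NaN.
    """
    if len(signal) != len(reference_bases):
        raise ValueError(
            f"signal has {len(signal)} positions but reference has "
            f"{len(reference_bases)}"
        )
    out = np.full(len(signal), np.nan)
    for i, base in enumerate(reference_bases):
        if base in BASE_INDEX and not signal.mask[i]:
            out[i] = 1.0 - signal.fractions[i, BASE_INDEX[base]]
    return out


def aberrant_profile(
    control_signal: SignalMatrix,
    control_bases: str,
    sample_signal: SignalMatrix,
    offset: OffsetAlignment,
    cut_index: int,
) -> AberrantProfile:
    """Quality-control profile: both traces' aberrant signal relative to
    the control-called bases, with the sample shifted into the control
    frame."""
    ctrl = aberrant_signal(control_signal, control_bases)
    n = len(control_bases)
    sample_ctrl_frame = np.full(n, np.nan)
    for i in range(n):
        j = i + offset.offset
        if 0 <= j < len(sample_signal):
            base = control_bases[i]
            if base in BASE_INDEX and not sample_signal.mask[j]:
                sample_ctrl_frame[i] = 1.0 - sample_signal.fractions[j, BASE_INDEX[base]]
    return AberrantProfile(control=ctrl, sample=sample_ctrl_frame, cut_index=cut_index)


def default_window(
    site: BreakSite,
    offset: OffsetAlignment,
    control_len: int,
    sample_len: int,
    n: int,
) -> DecompositionWindow:
    """Default decomposition window: [cut + n + 5, shortest-read-end − (n + 5)).

    The shortest usable read end is taken in control-frame coordinates
    (the sample's end maps to ``sample_len - offset``).
    """
    left = site.cut_index + n + 5
    usable_end = min(control_len, sample_len - offset.offset)
    right = usable_end - (n + 5)
    if right <= left or (right - left) < 10 * (2 * n + 1) / 4:
        raise WindowError(
            f"reads too short for requested indel range: window "
            f"[{left}, {right}) from cut {site.cut_index}, n={n}"
        )
    return DecompositionWindow(left=left, right=right)


def build_models(
    control_signal: SignalMatrix, window: DecompositionWindow, n: int
) -> IndelModelSet:
    """Construct the shifted-trace design matrix for indels in {-n..+n}."""
    if n < 1:
        raise ValueError("maximum indel size must be >= 1")
    if len(control_signal) < window.right + n:
        raise ValueError(
            f"control trace ({len(control_signal)} positions) too short for "
            f"window right edge {window.right} plus shift {n}"
        )
    if window.left - n < 0:
        raise ValueError("window left edge leaves no room for insertion shifts")

    idx = np.arange(window.left, window.right)
    labels = np.arange(-n, n + 1)
    cols = []
    for k in labels:
        # indel of signed size k shows control position i - k at window position i
        src = idx - k
        cols.append(control_signal.fractions[src].T.ravel())
    matrix = np.column_stack(cols)
    return IndelModelSet(
        n=n,
        window=window,
        matrix=matrix,
        indel_labels=labels,
        source_mask=control_signal.mask[idx].copy(),
    )


def _window_vector(signal: SignalMatrix, idx: np.ndarray) -> np.ndarray:
    return signal.fractions[idx].T.ravel()


def decompose(
    sample_signal: SignalMatrix,
    models: IndelModelSet,
    offset: OffsetAlignment,
) -> DecompositionResult:
    """Fit the sample's windowed signal as a non-negative combination of
    the indel models and attach fit statistics."""
    window = models.window
    idx = np.arange(window.left, window.right)
    sample_idx = idx + offset.offset
    if sample_idx[0] < 0 or sample_idx[-1] >= len(sample_signal):
        raise ValueError(
            "sample trace does not cover the decomposition window after "
            f"offset shift ({offset.offset:+d})"
        )

    keep = ~models.source_mask & ~sample_signal.mask[sample_idx]
    if not np.any(keep):
        raise WindowError("every window position is masked in one of the traces")
    w = window.width
    k_models = models.matrix.shape[1]
    m = models.matrix.reshape(4, w, k_models)[:, keep, :].reshape(-1, k_models)
    y = sample_signal.fractions[sample_idx][keep].T.ravel()

    coef, rnorm = nnls(m, y)
    rss = float(rnorm**2)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    r2 = float(min(max(r2, 0.0), 1.0))

    run_warnings: list[str] = []
    dof = m.shape[0] - k_models
    mtm = m.T @ m
    sigma2 = rss / dof if dof > 0 else np.nan
    bad = np.zeros(k_models, dtype=bool)
    cond = np.linalg.cond(mtm)
    if cond > 1e10:
        # near-duplicate model columns (repetitive control sequence) make
        # the covariance of the affected coefficients meaningless
        run_warnings.append(
            f"model matrix is near-singular (condition number {cond:.2e}); "
            "repetitive control sequence — p-values suppressed for duplicated indels"
        )
        norms = np.linalg.norm(m, axis=0)
        for i in range(k_models):
            for j in range(i + 1, k_models):
                if np.linalg.norm(m[:, i] - m[:, j]) <= 1e-9 * max(norms[i], norms[j], 1.0):
                    bad[i] = bad[j] = True
        cov_unscaled = np.linalg.pinv(mtm)
    else:
        cov_unscaled = np.linalg.inv(mtm)

    with _pywarnings.catch_warnings():
        _pywarnings.simplefilter("ignore", RuntimeWarning)
        se = np.sqrt(np.clip(np.diag(cov_unscaled), 0, None) * sigma2)
        tvals = np.divide(coef, se, out=np.zeros_like(coef), where=se > 0)
    p = 2.0 * stats.t.sf(np.abs(tvals), dof)
    p[coef <= 0] = 1.0  # boundary coefficients: no evidence of presence
    p[se <= 0] = 1.0
    p[bad] = np.nan

    total = coef.sum()
    if total > 0:
        percentages = coef * (100.0 * r2 / total)
    else:
        percentages = np.zeros_like(coef)

    return DecompositionResult(
        indel_labels=models.indel_labels.copy(),
        coefficients=coef,
        percentages=percentages,
        se=se,
        p=p,
        r_squared=r2,
        window=window,
        warnings=run_warnings,
    )


#: quality rules of thumb
PRE_BREAK_BACKGROUND_MAX = 0.10
R_SQUARED_MIN = 0.9
_RISE_MIN = 0.02
_EFFICIENCY_FLOOR = 5.0


def quality_check(profile: AberrantProfile, result: DecompositionResult) -> list[str]:
    """Apply the quality-control rules of thumb; returns warning strings.

    Checks: pre-break aberrant background below 10% in both traces,
    R^2 above 0.9, and — when substantial editing is reported — that the
    aberrant signal actually rises at the expected cut site (a flat
    profile with high reported efficiency suggests a misplaced cut or a
    wrong alignment).
    """
    warnings: list[str] = []
    cut = profile.cut_index

    for name, series in (("control", profile.control), ("sample", profile.sample)):
        pre = series[:cut]
        pre = pre[~np.isnan(pre)]
        if pre.size and pre.mean() >= PRE_BREAK_BACKGROUND_MAX:
            warnings.append(
                f"high pre-break aberrant background in {name} trace "
                f"({100 * pre.mean():.1f}% >= {100 * PRE_BREAK_BACKGROUND_MAX:.0f}%)"
            )

    if result.r_squared <= R_SQUARED_MIN:
        warnings.append(
            f"low goodness of fit (R^2 = {result.r_squared:.3f} <= {R_SQUARED_MIN})"
        )

    pre = profile.sample[:cut]
    post = profile.sample[cut:]
    pre = pre[~np.isnan(pre)]
    post = post[~np.isnan(post)]
    if (
        pre.size
        and post.size
        and result.total_efficiency > _EFFICIENCY_FLOOR
        and (post.mean() - pre.mean()) < _RISE_MIN
    ):
        warnings.append(
            "aberrant signal does not rise at the expected cut site despite "
            f"{result.total_efficiency:.1f}% reported editing; check guide and alignment"
        )
    return warnings
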