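"""Pipeline orchestration, machine-readable reports, and the CLI.

``run`` wires the full analysis — guide location, offset alignment,
window selection, model construction, non-negative decomposition,
quality checks, and +1 base-composition inference — and optionally
writes four artifacts into an output directory:

* ``spectrum.tsv``   — indel, percentage, se, p, significant
* ``profile.tsv``    — per-position aberrant signal of both traces
* ``composition.tsv``— +1 inserted-base fractions
* ``report.json``    — everything above plus provenance (input hashes,
  parameters, tool version)

Coordinates in all user-facing output are 1-based; internally
everything is 0-based half-open.

The CLI exposes two subcommands: ``decompose`` (the analysis) and
``synth`` (synthetic trace generation).  Exit codes: 0 success,
2 success with quality warnings, 1 error.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd

from . import __version__
from .decomp import (
    AberrantProfile,
    DecompositionResult,
    DecompositionWindow,
    aberrant_profile,
    build_models,
    decompose,
    default_window,
    quality_check,
)
from .inscall import InsertionComposition, plus_one_composition
from .locate import BreakSite, OffsetAlignment, align_offset, locate_guide
from .synth import IndelSpec, TraceParams, apply_indel, mix_traces, random_sequence
from .trace_io import normalize, read_trace, write_fixture

logger = logging.getLogger("indelscope")


@dataclass
class RunConfig:
    control_path: str
    sample_path: str
    guide: str
    max_indel: int = 10
    window_override: tuple[int, int] | None = None
    alpha: float = 0.001
    probe_len: int = 100
    output_dir: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.max_indel < 1:
            raise ValueError("max_indel must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class Report:
    site: BreakSite
    offset: OffsetAlignment
    profile: AberrantProfile
    result: DecompositionResult
    composition: InsertionComposition
    warnings: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def spectrum_frame(self, alpha: float) -> pd.DataFrame:
        r = self.result
        return pd.DataFrame(
            {
                "indel": r.indel_labels,
                "percentage": r.percentages,
                "se": r.se,
                "p": r.p,
                "significant": (r.p < alpha) & (r.percentages > 0),
            }
        )

    def profile_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pos": np.arange(1, len(self.profile.control) + 1),  # 1-based
                "control_aberrant": self.profile.control,
                "sample_aberrant": self.profile.sample,
            }
        )

    def composition_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "base": list("ACGT"),
                "fraction": self.composition.fractions,
            }
        )

    def to_json_dict(self, alpha: float) -> dict:
        r = self.result

        def _clean(x):
            return None if (isinstance(x, float) and np.isnan(x)) else x

        return {
            "tool": {"name": "indelscope", "version": __version__},
            "provenance": self.provenance,
            "break_site": {
                "cut_index": self.site.cut_index + 1,  # 1-based in output
                "strand": self.site.strand,
                "guide_start": self.site.guide_start + 1,
                "alignment_score": self.site.alignment_score,
            },
            "offset": {
                "offset": self.offset.offset,
                "alignment_score": self.offset.alignment_score,
            },
            "window": {"left": r.window.left + 1, "right": r.window.right},
            "r_squared": r.r_squared,
            "total_efficiency": r.total_efficiency,
            "spectrum": [
                {
                    "indel": int(l),
                    "percentage": float(pct),
                    "se": _clean(float(se)),
                    "p": _clean(float(p)),
                    "significant": bool(p < alpha and pct > 0),
                }
                for l, pct, se, p in zip(r.indel_labels, r.percentages, r.se, r.p)
            ],
            "plus_one_composition": {
                "supported": self.composition.supported,
                "fractions": {
                    b: _clean(v) for b, v in self.composition.as_dict().items()
                },
                "note": self.composition.note,
            },
            "profile": {
                "control_aberrant": [
                    _clean(float(v)) for v in self.profile.control
                ],
                "sample_aberrant": [_clean(float(v)) for v in self.profile.sample],
            },
            "quality_warnings": list(self.warnings),
        }


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def analyze(
    control,
    sample,
    guide: str,
    max_indel: int = 10,
    window_override: tuple[int, int] | None = None,
    probe_len: int = 100,
) -> Report:
    """Run the full pipeline on in-memory chromatograms.

    Steps: guide location, upstream-offset alignment, window selection,
    shifted-model construction, non-negative decomposition, quality
    checks, +1 base-composition inference.
    """
    control_signal = normalize(control)
    sample_signal = normalize(sample)

    site = locate_guide(control, guide)
    logger.info("cut site at control index %d (%s strand)", site.cut_index, site.strand)
    offset = align_offset(control, sample, site, probe_len=probe_len)
    logger.info("sample offset %+d", offset.offset)

    if window_override is not None:
        window = DecompositionWindow(*window_override)
    else:
        window = default_window(site, offset, len(control), len(sample), max_indel)

    models = build_models(control_signal, window, max_indel)
    result = decompose(sample_signal, models, offset)
    profile = aberrant_profile(
        control_signal, control.bases, sample_signal, offset, site.cut_index
    )
    warnings = result.warnings + quality_check(profile, result)
    composition = plus_one_composition(
        sample_signal, control_signal, result, site, offset
    )
    return Report(
        site=site,
        offset=offset,
        profile=profile,
        result=result,
        composition=composition,
        warnings=warnings,
    )


def run(config: RunConfig) -> Report:
    """Execute the pipeline for one control/sample trace file pair."""
    logger.info("reading control %s and sample %s", config.control_path, config.sample_path)
    control = read_trace(config.control_path)
    sample = read_trace(config.sample_path)
    report = analyze(
        control,
        sample,
        config.guide,
        max_indel=config.max_indel,
        window_override=config.window_override,
        probe_len=config.probe_len,
    )
    report.provenance = {
        "control": {"path": str(config.control_path), "sha256": _sha256(config.control_path)},
        "sample": {"path": str(config.sample_path), "sha256": _sha256(config.sample_path)},
        "guide": config.guide.upper(),
        "parameters": {
            "max_indel": config.max_indel,
            "alpha": config.alpha,
            "probe_len": config.probe_len,
            "window_override": list(config.window_override)
            if config.window_override
            else None,
        },
    }
    if config.output_dir is not None:
        write_report(report, config)
    return report


def write_report(report: Report, config: RunConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.spectrum_frame(config.alpha).to_csv(out / "spectrum.tsv", sep="\t", index=False)
    report.profile_frame().to_csv(out / "profile.tsv", sep="\t", index=False)
    report.composition_frame().to_csv(out / "composition.tsv", sep="\t", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(report.to_json_dict(config.alpha), fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def _parse_indel_list(text: str) -> list[tuple[IndelSpec, float]]:
    """Parse ``SIZE[:BASES]@POS,WEIGHT;...`` into specs and weights."""
    spectrum = []
    for part in text.split(";"):
        part = part.strip()
        if not part:
            continue
        try:
            head, weight_s = part.rsplit(",", 1)
            size_s, pos_s = head.split("@")
            if ":" in size_s:
                size_s, bases = size_s.split(":")
            else:
                bases = ""
            spec = IndelSpec(size=int(size_s), position=int(pos_s), inserted_bases=bases)
            spectrum.append((spec, float(weight_s)))
        except ValueError as exc:
            raise click.BadParameter(
                f"cannot parse indel component {part!r} "
                "(expected SIZE[:BASES]@POS,WEIGHT)"
            ) from exc
    if not spectrum:
        raise click.BadParameter("empty indel list")
    return spectrum


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Log progress to stderr.")
def main(verbose: bool) -> None:
    """Quantify nuclease-induced indel spectra from paired Sanger traces."""
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(levelname)s %(name)s: %(message)s",
    )


@main.command("decompose")
@click.option("--control", "control_path", required=True, type=click.Path(exists=True))
@click.option("--sample", "sample_path", required=True, type=click.Path(exists=True))
@click.option("--guide", required=True, help="20-nt guide sequence.")
@click.option("--max-indel", default=10, show_default=True, type=int)
@click.option(
    "--window",
    default=None,
    help="Override decomposition window as 'LEFT,RIGHT' (1-based, inclusive left).",
)
@click.option("--alpha", default=0.001, show_default=True, type=float)
@click.option("--probe-len", default=100, show_default=True, type=int)
@click.option("--out", "output_dir", required=True, type=click.Path())
def decompose_cmd(
    control_path, sample_path, guide, max_indel, window, alpha, probe_len, output_dir
):
    """Decompose an edited sample trace against its control."""
    override = None
    if window is not None:
        try:
            left_s, right_s = window.split(",")
            override = (int(left_s) - 1, int(right_s))  # user input is 1-based
        except ValueError:
            raise click.BadParameter("--window must be 'LEFT,RIGHT'")
    config = RunConfig(
        control_path=control_path,
        sample_path=sample_path,
        guide=guide,
        max_indel=max_indel,
        window_override=override,
        alpha=alpha,
        probe_len=probe_len,
        output_dir=output_dir,
    )
    try:
        report = run(config)
    except Exception as exc:  # noqa: BLE001 - CLI boundary
        logger.error("%s: %s", type(exc).__name__, exc)
        click.echo(f"error: {exc}", err=True)
        sys.exit(1)
    eff = report.result.total_efficiency
    click.echo(
        f"R^2 = {report.result.r_squared:.4f}; total editing {eff:.1f}%; "
        f"wild type {report.result.percentage(0):.1f}%"
    )
    for w in report.warnings:
        click.echo(f"warning: {w}", err=True)
    sys.exit(2 if report.warnings else 0)


@main.command("synth")
@click.option("--sequence", default=None, help="Explicit amplicon sequence (ACGT).")
@click.option("--length", default=800, show_default=True, type=int)
@click.option("--seed", default=0, show_default=True, type=int)
@click.option(
    "--indels",
    default=None,
    help="Mixture as 'SIZE[:BASES]@POS,WEIGHT;...'; omit for a pure trace.",
)
@click.option("--amplitude", default=1000.0, show_default=True, type=float)
@click.option("--decay-rate", default=0.0015, show_default=True, type=float)
@click.option("--noise-cv", default=0.05, show_default=True, type=float)
@click.option("--crosstalk", default=0.02, show_default=True, type=float)
@click.option("--out", "out_path", required=True, type=click.Path())
@click.option(
    "--format",
    "out_format",
    default="fixture",
    show_default=True,
    type=click.Choice(["fixture", "abif"]),
)
def synth_cmd(
    sequence, length, seed, indels, amplitude, decay_rate, noise_cv, crosstalk,
    out_path, out_format,
):
    """Generate a synthetic chromatogram (pure trace or indel mixture)."""
    params = TraceParams(
        base_amplitude=amplitude,
        decay_rate=decay_rate,
        noise_cv=noise_cv,
        crosstalk=crosstalk,
        seed=seed,
    )
    if sequence is None:
        sequence = random_sequence(length, np.random.default_rng(seed))
    try:
        if indels is None:
            components = [(sequence, 1.0)]
        else:
            components = [
                (apply_indel(sequence, spec), w)
                for spec, w in _parse_indel_list(indels)
            ]
        trace = mix_traces(components, params)
        write_fixture(trace, out_path, format=out_format)
    except (ValueError, OSError) as exc:
        click.echo(f"error: {exc}", err=True)
        sys.exit(1)
    click.echo(f"wrote {len(trace)}-position trace to {out_path}")
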