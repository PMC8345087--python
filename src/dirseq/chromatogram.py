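"""Under-peak allele quantification in Sanger chromatograms.

At a heterozygous position a trace shows two superimposed peaks, one per
allele, and the integrated intensity under each peak is proportional to the
allele's abundance in the template.  Comparing the allele ratio between a
genomic-DNA trace and a cDNA trace of the same site turns this into an
allele-specific-expression readout: the odds ratio of the cDNA ratio over the
gDNA ratio is the allelic expression fold, 1 meaning both alleles are
expressed in proportion to their genomic dosage.

Traces are consumed in a simple columnar text format (position plus A/C/G/T
intensities, with a JSON sidecar of called positions); conversion from vendor
binary traces is left to existing converters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, ValidationError

CHANNELS = ("A", "C", "G", "T")


@dataclass
class Chromatogram:
    """Four intensity channels over trace samples plus the base calls."""

    channels: dict[str, np.ndarray]
    called_positions: np.ndarray
    called_sequence: str

    def __post_init__(self) -> None:
        lengths = {len(self.channels[b]) for b in CHANNELS}
        if len(lengths) != 1:
            raise ValidationError("channels must have equal length")
        self.called_positions = np.asarray(self.called_positions, dtype=int)
        if len(self.called_positions) != len(self.called_sequence):
            raise ValidationError("one called position per called base required")
        if np.any(np.diff(self.called_positions) <= 0):
            raise ValidationError("called positions must be strictly increasing")
        if self.called_positions.size and (
            self.called_positions[0] < 0 or self.called_positions[-1] >= self.n_samples
        ):
            raise ValidationError("called positions outside trace")

    @property
    def n_samples(self) -> int:
        return len(self.channels["A"])

    def write(self, trace_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        df = pd.DataFrame({"position": np.arange(self.n_samples)})
        for b in CHANNELS:
            df[b] = self.channels[b]
        df.to_csv(trace_path, sep="\t", index=False, float_format="%.6g")
        sidecar = sidecar_path or Path(trace_path).with_suffix(".calls.json")
        with open(sidecar, "w") as fh:
            json.dump(
                {
                    "called_positions": self.called_positions.tolist(),
                    "called_sequence": self.called_sequence,
                },
                fh,
            )

    @classmethod
    def read(cls, trace_path: str | Path, sidecar_path: str | Path | None = None) -> "Chromatogram":
        df = pd.read_csv(trace_path, sep="\t")
        sidecar = sidecar_path or Path(trace_path).with_suffix(".calls.json")
        with open(sidecar) as fh:
            calls = json.load(fh)
        return cls(
            channels={b: df[b].to_numpy(float) for b in CHANNELS},
            called_positions=np.asarray(calls["called_positions"]),
            called_sequence=calls["called_sequence"],
        )

    def locate(self, context: str) -> int:
        """Find a unique occurrence of ``context`` (with one N at the site of
        interest) in the called sequence and return the N's call index."""
        context = context.upper()
        if context.count("N") != 1:
            raise ValidationError("context must mark the site with exactly one N")
        pattern = context.replace("N", ".")
        import re

        hits = [m.start() for m in re.finditer(f"(?={pattern})", self.called_sequence)]
        if len(hits) != 1:
            raise InputError(f"context matches {len(hits)} times in the called sequence")
        return hits[0] + context.index("N")


@dataclass
class AlleleQuant:
    """Under-peak areas and normalized ratios of two alleles at one position."""

    position: int
    allele_areas: dict[str, float]
    ratios: dict[str, float]


def _local_spacing(trace: Chromatogram, call_index: int) -> float:
    pos = trace.called_positions
    if len(pos) < 2:
        raise InputError("need at least two called positions to estimate peak spacing")
    gaps = []
    if call_index > 0:
        gaps.append(pos[call_index] - pos[call_index - 1])
    if call_index < len(pos) - 1:
        gaps.append(pos[call_index + 1] - pos[call_index])
    return float(np.mean(gaps))


def peak_area(
    trace: Chromatogram,
    call_index: int,
    channel: str,
    window_frac: float = 0.5,
    mode: str = "area",
) -> float:
    """Baseline-subtracted intensity under one channel's peak at a base call.

    The integration window extends ``window_frac`` of the local inter-peak
    spacing on each side of the called position.  The baseline is the
    channel's 10th-percentile intensity over a neighborhood five times the
    window (floored at zero — trace intensities are nonnegative); it is
    subtracted before the trapezoidal integral.  Negative results clip to 0.
    ``mode="height"`` returns the baseline-subtracted maximum instead of the
    integral, as a sensitivity check.
    """
    if channel not in CHANNELS:
        raise ValidationError(f"unknown channel {channel!r}")
    if not 0 < window_frac <= 1:
        raise ValidationError("window_frac must lie in (0, 1]")
    if not 0 <= call_index < len(trace.called_positions):
        raise InputError(f"call_index {call_index} out of range")
    center = int(trace.called_positions[call_index])
    w = int(round(window_frac * _local_spacing(trace, call_index)))
    lo, hi = center - w, center + w
    if lo < 0 or hi >= trace.n_samples:
        raise InputError("integration window falls off the trace edge")
    y = trace.channels[channel]
    half = 5 * w
    n_lo, n_hi = max(0, center - half), min(trace.n_samples, center + half + 1)
    baseline = max(0.0, float(np.percentile(y[n_lo:n_hi], 10)))
    segment = y[lo : hi + 1] - baseline
    if mode == "height":
        return max(0.0, float(segment.max()))
    if mode != "area":
        raise ValidationError(f"unknown mode {mode!r}")
    return max(0.0, float(np.trapezoid(segment)))


def allele_ratio(
    trace: Chromatogram,
    call_index: int,
    alleles: tuple[str, str],
    window_frac: float = 0.5,
) -> AlleleQuant:
    """Normalized under-peak areas of two candidate alleles at one base call."""
    a, b = alleles
    if a == b:
        raise ValidationError("alleles must be distinct")
    areas = {x: peak_area(trace, call_index, x, window_frac=window_frac) for x in (a, b)}
    total = areas[a] + areas[b]
    if total == 0:
        raise InputError(f"both allele areas are zero at call {call_index}")
    ratios = {a: areas[a] / total, b: areas[b] / total}
    return AlleleQuant(position=call_index, allele_areas=areas, ratios=ratios)


def ase_imbalance(gdna: AlleleQuant, cdna: AlleleQuant, allele: str) -> float:
    """Allelic expression fold: odds(cDNA, allele) / odds(gDNA, allele).

    A fold of 1 means the allele is expressed in proportion to its genomic
    dosage; >1 means allele-specific over-expression.
    """
    if set(gdna.ratios) != set(cdna.ratios):
        raise InputError("gDNA and cDNA quantifications cover different allele pairs")
    if allele not in gdna.ratios:
        raise ValidationError(f"allele {allele!r} not quantified")
    g = gdna.ratios[allele]
    if g in (0.0, 1.0):
        raise InputError("gDNA allele ratio is degenerate (0 or 1); cannot normalize")
    c = cdna.ratios[allele]
    odds_g = g / (1.0 - g)
    odds_c = np.inf if c == 1.0 else c / (1.0 - c)
    return float(odds_c / odds_g)
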