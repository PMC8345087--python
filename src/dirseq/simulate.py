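"""Synthetic data generators for every input the pipeline consumes.

A declared ground truth (per-construct activity multipliers, noise levels,
seeds) drives the generation of plasmid/cDNA count tables, paired-end FASTQ
reads, qPCR Ct tables, genotype–expression tables and four-channel Sanger
traces, so every downstream stage can be tested against known parameters.

The count model follows the assay's structure: the plasmid pool is equimolar
with mild lognormal jitter (pipetting/cloning variation), and each cDNA
replicate draws negative-binomial counts whose mean is the plasmid proportion
times the construct's activity multiplier times the sequencing depth.  The
negative-binomial dispersion is a knob with Poisson as its zero limit;
reporter-assay replicates are overdispersed relative to Poisson.

All randomness flows from a single integer seed through named per-artifact
streams, so any stage's inputs can be regenerated independently and
bit-identically.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import Construct, NEGATIVE_CONTROL_ID
from .errors import ValidationError
from .quant import AnchorConfig, CountTable

#: Default lognormal sigma (log scale) of the plasmid pool's departure from equimolarity.
PLASMID_JITTER_SD = 0.05


def stream(seed: int, name: str) -> np.random.Generator:
    """Named child generator: one master seed, independent per-artifact streams."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(name.encode())]))


@dataclass
class SimulationTruth:
    """Ground truth for the reporter-assay count and read simulators.

    ``activity_multiplier`` maps construct_id -> relative transcription rate
    (the negative control is pinned at 1); unlisted constructs default to 1.
    """

    activity_multiplier: Mapping[str, float] = field(default_factory=dict)
    replicates: int = 3
    depth: int = 100_000
    dispersion: float = 0.002
    read_error_rate: float = 0.0
    plasmid_jitter_sd: float = PLASMID_JITTER_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.activity_multiplier.values()):
            raise ValidationError("activity multipliers must be positive")
        if self.replicates < 2:
            raise ValidationError("need at least 2 replicates")
        if self.depth < 0:
            raise ValidationError("depth must be nonnegative")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be nonnegative")
        if not 0 <= self.read_error_rate < 0.1:
            raise ValidationError("read_error_rate must be in [0, 0.1)")

    def multiplier(self, construct: Construct) -> float:
        if construct.allele_role == "control":
            return 1.0
        return float(self.activity_multiplier.get(construct.construct_id, 1.0))


@dataclass
class TraceTruth:
    """Ground truth for a simulated chromatogram with one heterozygous site."""

    allele_fraction: float = 0.5  # fraction of allele 1; allele 2 gets the complement
    peak_spacing: int = 12  # trace samples per called base
    peak_width: float = 2.0  # Gaussian sigma of a peak, in trace samples
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.allele_fraction <= 1.0:
            raise ValidationError("allele_fraction must lie in [0, 1]")
        if self.peak_spacing < 4 or self.peak_width <= 0:
            raise ValidationError("peak geometry out of range")


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def simulate_counts(
    constructs: Sequence[Construct],
    truth: SimulationTruth,
    cell_lines: Sequence[str] = ("MCF7", "T47D", "MDA-MB-453"),
) -> CountTable:
    """Draw a plasmid-input column and per-cell-line cDNA replicate columns."""
    ids = [c.construct_id for c in constructs]
    n = len(ids)
    rng = stream(truth.seed, "counts")

    jitter = np.exp(rng.normal(0.0, truth.plasmid_jitter_sd, size=n))
    plasmid_prop = jitter / jitter.sum()
    plasmid = rng.poisson(plasmid_prop * truth.depth)

    mult = np.array([truth.multiplier(c) for c in constructs])
    cdna_prop = plasmid_prop * mult
    cdna_prop = cdna_prop / cdna_prop.sum()

    columns = {"plasmid": plasmid}
    meta = [{"sample": "plasmid", "cell_line": "", "replicate": 0, "material": "plasmid"}]
    if truth.depth == 0:
        warnings.warn("depth 0: all cDNA columns will be zero", stacklevel=2)
    for line in cell_lines:
        for rep in range(1, truth.replicates + 1):
            mean = cdna_prop * truth.depth
            if truth.dispersion > 0:
                size = 1.0 / truth.dispersion
                col = rng.negative_binomial(size, size / (size + np.maximum(mean, 1e-12)))
            else:
                col = rng.poisson(mean)
            name = f"{line}_rep{rep}"
            columns[name] = col
            meta.append({"sample": name, "cell_line": line, "replicate": rep, "material": "cdna"})
    counts = pd.DataFrame(columns, index=pd.Index(ids, name="construct_id"))
    return CountTable(counts=counts, samples=pd.DataFrame(meta))


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT_LUT = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMPLEMENT_LUT[_a] = _b


def _mutate(reads: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Apply per-base substitution errors to an (n, L) uint8 read matrix."""
    if rate <= 0:
        return reads
    mask = rng.random(reads.shape) < rate
    # substitute with one of the three other bases, uniformly
    shift = rng.integers(1, 4, size=reads.shape)
    idx = np.searchsorted(_BASES, reads)
    reads = reads.copy()
    reads[mask] = _BASES[(idx[mask] + shift[mask]) % 4]
    return reads


def fragment_sequence(construct: Construct, anchors: AnchorConfig | None = None) -> str:
    anchors = anchors or AnchorConfig()
    return anchors.upstream + construct.sublib_tag + construct.barcode + anchors.downstream


def render_fastq(
    counts: pd.Series,
    constructs: Sequence[Construct],
    truth: SimulationTruth,
    r1_path: str | Path,
    r2_path: str | Path,
    sample: str = "sample",
    anchors: AnchorConfig | None = None,
) -> int:
    """Write one sample's count column as overlapping paired-end FASTQ reads.

    Each construct is emitted exactly ``counts[construct_id]`` times; mate 1 is
    the fragment, mate 2 its reverse complement, each with independent
    substitution errors at ``truth.read_error_rate``.  Returns the number of
    read pairs written.
    """
    anchors = anchors or AnchorConfig()
    by_id = {c.construct_id: c for c in constructs}
    frags: list[str] = []
    names: list[str] = []
    for cid, n in counts.items():
        n = int(n)
        if n < 0:
            raise ValidationError(f"negative count for {cid}")
        if n:
            frags.extend([fragment_sequence(by_id[cid], anchors)] * n)
            names.extend(f"{sample}:{cid}:{i}" for i in range(n))
    rng = stream(truth.seed, f"reads:{sample}")
    if frags:
        mat = np.frombuffer("".join(frags).encode(), dtype=np.uint8).reshape(len(frags), -1)
        r1 = _mutate(mat, truth.read_error_rate, rng)
        r2 = _mutate(_COMPLEMENT_LUT[mat][:, ::-1], truth.read_error_rate, rng)
    else:
        r1 = r2 = np.empty((0, 0), dtype=np.uint8)
    qual = "I" * anchors.fragment_length
    for path, mat, mate in ((r1_path, r1, 1), (r2_path, r2, 2)):
        with open(path, "w") as fh:
            for name, row in zip(names, mat):
                fh.write(f"@{name}/{mate}\n{row.tobytes().decode()}\n+\n{qual}\n")
    return len(frags)


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------


def simulate_ct_table(
    assays: Sequence[Mapping],
    noise_sd: float = 0.0,
    seed: int = 0,
    baseline_ct: float = 20.0,
    replicates: int = 3,
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Ct records for a set of assay wells with known template quantities.

    Each assay is a mapping with keys ``sample``, ``amplicon``, ``role`` and
    ``quantity`` (relative template amount, > 0).  The mean Ct follows the
    amplification model Ct = baseline - log_e(quantity) for efficiency e, and
    technical replicates add Gaussian noise of ``noise_sd`` cycles.
    """
    rng = stream(seed, "ct")
    log_e = np.log(efficiency)
    rows = []
    for assay in assays:
        quantity = float(assay["quantity"])
        if quantity <= 0:
            raise ValidationError(f"quantity must be positive in assay {assay}")
        mean_ct = baseline_ct - np.log(quantity) / log_e
        for rep in range(1, replicates + 1):
            rows.append(
                {
                    "sample": assay["sample"],
                    "amplicon": assay["amplicon"],
                    "role": assay.get("role", "target"),
                    "ct": mean_ct + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0),
                    "replicate": rep,
                }
            )
    return pd.DataFrame(rows)


def simulate_genotype_expression(
    group_means: Mapping[str, float],
    n_per_group: int = 20,
    sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Genotype-class expression table for eQTL-style association tests."""
    rng = stream(seed, "eqtl")
    rows = []
    for genotype, mean in group_means.items():
        for value in rng.normal(mean, sd, size=n_per_group):
            rows.append({"genotype": genotype, "expression": value})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# chromatogram traces
# ---------------------------------------------------------------------------


def simulate_trace(
    truth: TraceTruth,
    sequence: str,
    het_position: int,
    alleles: tuple[str, str],
):
    """Four-channel Sanger-like trace with one two-allele position.

    Every called base contributes a Gaussian peak of unit amplitude in its
    channel at regular spacing; at ``het_position`` the two allele channels
    instead carry peaks with amplitudes equal to the allele fractions, so the
    under-peak areas are proportional to allele abundance.  Channel noise is
    i.i.d. Gaussian, and intensities are floored at zero (a physical trace is
    nonnegative).
    """
    from .chromatogram import Chromatogram

    sequence = sequence.upper()
    if not 0 <= het_position < len(sequence):
        raise ValidationError("het_position outside sequence")
    if alleles[0] == alleles[1]:
        raise ValidationError("alleles must differ")
    rng = stream(truth.seed, "trace")
    spacing, sigma = truth.peak_spacing, truth.peak_width
    margin = 3 * spacing
    length = 2 * margin + spacing * (len(sequence) - 1) + 1
    positions = margin + spacing * np.arange(len(sequence))
    t = np.arange(length, dtype=float)
    channels = {b: np.zeros(length) for b in "ACGT"}

    def add_peak(base: str, center: float, amplitude: float) -> None:
        channels[base] += amplitude * np.exp(-0.5 * ((t - center) / sigma) ** 2)

    for i, base in enumerate(sequence):
        if i == het_position:
            add_peak(alleles[0], positions[i], truth.allele_fraction)
            add_peak(alleles[1], positions[i], 1.0 - truth.allele_fraction)
        else:
            add_peak(base, positions[i], 1.0)
    if truth.noise_sd > 0:
        for b in "ACGT":
            channels[b] = np.maximum(channels[b] + rng.normal(0, truth.noise_sd, length), 0.0)
    called = sequence[:het_position] + "N" + sequence[het_position + 1 :]
    return Chromatogram(
        channels={b: channels[b] for b in "ACGT"},
        called_positions=positions,
        called_sequence=called,
    )
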