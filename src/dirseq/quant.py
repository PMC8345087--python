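"""From raw paired reads to normalized reporter activity.

The read structure is fixed by the library design: a constant upstream anchor,
the 6-nt sub-library tag, the 2-nt dinucleotide barcode, and a constant
downstream anchor (the reverse complement of the BarP6 RT primer).  Mates fully
overlap, so merging reduces to finding the best reverse-complement alignment
offset.  Counting is exact on the (tag, barcode) pair — a dinucleotide barcode
is too short to tolerate mismatches — while the anchors absorb a configurable
number of substitutions.

Activity is the standard MPRA normalization: per-sample counts-per-million,
divided by the plasmid-input cpm, scaled so the insert-free negative control is
exactly 1 in every sample.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .design import Construct, identity_map
from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

#: Constant flank placed upstream of the sub-library tag in every read.
UPSTREAM_ANCHOR = "TCTAGAGGATCCAAGGCGCG"

#: BarP6, the reverse-transcription primer that terminates the read.
BARP6 = "CACGATCTGTCCGCACTGCTTGG"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


#: Constant flank downstream of the barcode (reverse complement of BarP6).
DOWNSTREAM_ANCHOR = revcomp(BARP6)


@dataclass
class AnchorConfig:
    """Where the (tag, barcode) identity sits inside a merged read."""

    upstream: str = UPSTREAM_ANCHOR
    downstream: str = DOWNSTREAM_ANCHOR
    tag_length: int = 6
    barcode_length: int = 2

    @property
    def fragment_length(self) -> int:
        return len(self.upstream) + self.tag_length + self.barcode_length + len(self.downstream)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CountTable:
    """Constructs x samples integer counts plus per-sample metadata.

    ``samples`` has one row per column of ``counts`` with columns
    sample, cell_line, replicate and material (plasmid or cdna).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.samples["sample"]):
            raise InputError("count columns and sample sheet rows disagree")
        if (self.counts.to_numpy() < 0).any():
            raise InputError("negative counts")
        if (self.samples["material"] == "plasmid").sum() != 1:
            raise InputError("expected exactly one plasmid input column")

    @property
    def plasmid_column(self) -> str:
        return self.samples.loc[self.samples["material"] == "plasmid", "sample"].iloc[0]

    @property
    def cdna_columns(self) -> list[str]:
        return self.samples.loc[self.samples["material"] == "cdna", "sample"].tolist()

    def cell_line_of(self, sample: str) -> str:
        return self.samples.set_index("sample").loc[sample, "cell_line"]

    def write(self, counts_path: str | Path, samples_path: str | Path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="construct_id")
        self.samples.to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def read(cls, counts_path: str | Path, samples_path: str | Path) -> "CountTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col="construct_id")
        samples = pd.read_csv(samples_path, sep="\t", dtype={"replicate": "Int64"})
        return cls(counts=counts, samples=samples)


@dataclass
class ActivityTable:
    """Per-construct, per-cDNA-sample normalized reporter activity.

    ``flags`` marks each construct ``ok`` or ``low_input``; low-input
    constructs carry NaN activities.
    """

    activity: pd.DataFrame
    flags: pd.Series
    samples: pd.DataFrame

    def write(self, path: str | Path) -> None:
        out = self.activity.copy()
        out["flag"] = self.flags
        out.to_csv(path, sep="\t", index_label="construct_id")

    @classmethod
    def read(cls, path: str | Path, samples: pd.DataFrame | None = None) -> "ActivityTable":
        df = pd.read_csv(path, sep="\t", index_col="construct_id")
        flags = df.pop("flag")
        if samples is None:
            samples = pd.DataFrame({"sample": df.columns})
        return cls(activity=df, flags=flags, samples=samples)


# ---------------------------------------------------------------------------
# pair merging
# ---------------------------------------------------------------------------


@dataclass
class MergeReport:
    total: int = 0
    merged: int = 0
    discarded_low_overlap: int = 0
    discarded_mismatch: int = 0
    discarded_ambiguous: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _read_fastq(path: str | Path) -> list[str]:
    with open(path) as handle:
        return [seq.upper() for _, seq, _ in FastqGeneralIterator(handle)]


def _encode(seqs: list[str]) -> np.ndarray:
    """Uniform-length sequences -> (n, L) uint8 matrix."""
    return np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), -1)


def merge_pairs(
    r1: str | Path | list[str],
    r2: str | Path | list[str],
    min_overlap: int = 20,
    max_mismatch: int = 2,
) -> tuple[list[str], MergeReport]:
    """Merge mate pairs by aligning mate 2's reverse complement to mate 1.

    Every alignment offset giving at least ``min_overlap`` overlapping bases is
    scored by its substitution count; the pair merges at the unique
    best-scoring offset if that score is <= ``max_mismatch``.  A tie between
    two equally good offsets discards the pair rather than guessing.  Within
    the overlap the mate-1 base is kept (reads carry no usable quality signal
    in this design).

    Returns the merged sequences and a tally report.
    """
    seqs1 = _read_fastq(r1) if isinstance(r1, (str, Path)) else [s.upper() for s in r1]
    seqs2 = _read_fastq(r2) if isinstance(r2, (str, Path)) else [s.upper() for s in r2]
    if len(seqs1) != len(seqs2):
        raise InputError(f"mate count mismatch: {len(seqs1)} vs {len(seqs2)}")
    report = MergeReport(total=len(seqs1))
    if not seqs1:
        return [], report

    rc2 = [revcomp(s) for s in seqs2]
    merged: list[str] = []

    # Group pairs by (len1, len2) so each group is a rectangular array and all
    # offsets can be scored vectorized across the group.
    by_shape: dict[tuple[int, int], list[int]] = {}
    for i, (a, b) in enumerate(zip(seqs1, rc2)):
        by_shape.setdefault((len(a), len(b)), []).append(i)

    keep: dict[int, str] = {}
    for (l1, l2), idx in by_shape.items():
        a = _encode([seqs1[i] for i in idx])
        b = _encode([rc2[i] for i in idx])
        offsets = [o for o in range(-(l2 - min_overlap), l1 - min_overlap + 1)]
        if not offsets:
            report.discarded_low_overlap += len(idx)
            continue
        scores = np.empty((len(idx), len(offsets)), dtype=np.int32)
        for j, o in enumerate(offsets):
            a_lo, a_hi = max(0, o), min(l1, o + l2)
            b_lo = a_lo - o
            scores[:, j] = (a[:, a_lo:a_hi] != b[:, b_lo : b_lo + (a_hi - a_lo)]).sum(axis=1)
        best_j = scores.argmin(axis=1)
        best = scores[np.arange(len(idx)), best_j]
        ties = (scores == best[:, None]).sum(axis=1) > 1
        for row, i in enumerate(idx):
            if ties[row]:
                report.discarded_ambiguous += 1
            elif best[row] > max_mismatch:
                report.discarded_mismatch += 1
            else:
                o = offsets[best_j[row]]
                left = rc2[i][: -o] if o < 0 else ""
                right = rc2[i][l1 - o :] if o + l2 > l1 else ""
                keep[i] = left + seqs1[i] + right
    for i in sorted(keep):
        merged.append(keep[i])
    report.merged = len(merged)
    return merged, report


# ---------------------------------------------------------------------------
# demultiplexing
# ---------------------------------------------------------------------------


def demultiplex_count(
    reads: list[str],
    constructs: list[Construct],
    anchors: AnchorConfig | None = None,
    max_anchor_mismatch: int = 1,
) -> tuple[pd.Series, int]:
    """Assign merged reads to constructs by (sub-library tag, barcode).

    The upstream anchor is located allowing up to ``max_anchor_mismatch``
    substitutions at the unique best-scoring position (a positional tie makes
    the read ambiguous); the 8 nt that follow are split into tag and barcode
    and must match a construct identity exactly.  Returns a per-construct count
    column plus the unassigned tally; assigned + unassigned == len(reads).
    """
    if not constructs:
        raise ConfigurationError("empty construct table")
    anchors = anchors or AnchorConfig()
    ident = identity_map(constructs)
    counts = pd.Series(0, index=[c.construct_id for c in constructs], dtype=np.int64)
    unassigned = 0

    anchor = np.frombuffer(anchors.upstream.encode(), dtype=np.uint8)
    alen = len(anchor)
    idlen = anchors.tag_length + anchors.barcode_length

    by_len: dict[int, list[str]] = {}
    for r in reads:
        by_len.setdefault(len(r), []).append(r.upper())
    for length, group in by_len.items():
        n_pos = length - alen - idlen + 1
        if n_pos <= 0:
            unassigned += len(group)
            continue
        arr = _encode(group)
        scores = np.empty((len(group), n_pos), dtype=np.int32)
        for p in range(n_pos):
            scores[:, p] = (arr[:, p : p + alen] != anchor).sum(axis=1)
        best_p = scores.argmin(axis=1)
        best = scores[np.arange(len(group)), best_p]
        ties = (scores == best[:, None]).sum(axis=1) > 1
        for row, read in enumerate(group):
            if best[row] > max_anchor_mismatch or ties[row]:
                unassigned += 1
                continue
            start = best_p[row] + alen
            tag = read[start : start + anchors.tag_length]
            barcode = read[start + anchors.tag_length : start + idlen]
            cid = ident.get((tag, barcode))
            if cid is None:
                unassigned += 1
            else:
                counts[cid] += 1
    return counts, unassigned


def count_sample(
    r1: str | Path,
    r2: str | Path,
    constructs: list[Construct],
    anchors: AnchorConfig | None = None,
    min_overlap: int = 20,
    max_mismatch: int = 2,
    max_anchor_mismatch: int = 1,
) -> tuple[pd.Series, dict]:
    """Merge one sample's FASTQ pair and demultiplex it into a count column."""
    merged, report = merge_pairs(r1, r2, min_overlap=min_overlap, max_mismatch=max_mismatch)
    counts, unassigned = demultiplex_count(
        merged, constructs, anchors=anchors, max_anchor_mismatch=max_anchor_mismatch
    )
    info = report.as_dict()
    info.update(assigned=int(counts.sum()), unassigned=int(unassigned))
    assert info["assigned"] + info["unassigned"] == report.merged
    return counts, info


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def normalize_activity(
    counts: CountTable,
    control_id: str,
    pseudocount: float = 0.0,
    min_input_count: int = 10,
) -> ActivityTable:
    """Plasmid-normalized, control-scaled reporter activity.

    Per sample, counts are converted to counts-per-million; each construct's
    cDNA cpm is divided by its plasmid cpm, and the resulting ratios are scaled
    by the negative control's ratio so the control is exactly 1 in every
    column.  Constructs whose raw plasmid count falls below
    ``min_input_count`` are flagged ``low_input`` and carry no activity.
    """
    if control_id not in counts.counts.index:
        raise InputError(f"control construct {control_id!r} absent from count table")
    plasmid = counts.counts[counts.plasmid_column].astype(float)
    if plasmid[control_id] <= 0:
        raise InputError(f"control construct {control_id!r} has zero plasmid input")

    low_input = counts.counts[counts.plasmid_column] < min_input_count
    if low_input[control_id]:
        raise InputError(
            f"control construct {control_id!r} plasmid count below min_input_count"
        )
    flags = pd.Series(np.where(low_input, "low_input", "ok"), index=counts.counts.index)

    shifted = counts.counts.astype(float) + pseudocount
    cpm = shifted / shifted.sum(axis=0) * 1e6
    cdna_cols = counts.cdna_columns
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = cpm[cdna_cols].div(cpm[counts.plasmid_column], axis=0)
        activity = raw / raw.loc[control_id]
    activity[low_input] = np.nan
    # pin the control at exactly 1, immune to floating division round-off
    activity.loc[control_id] = 1.0
    n_low = int(low_input.sum())
    if n_low:
        logger.info("%d constructs flagged low_input (plasmid < %d)", n_low, min_input_count)
    return ActivityTable(
        activity=activity,
        flags=flags,
        samples=counts.samples[counts.samples["material"] == "cdna"].reset_index(drop=True),
    )


def write_run_report(path: str | Path, stats: dict) -> None:
    stats = dict(stats)
    stats.setdefault("depth_normalization", "counts-per-million before plasmid ratio")
    with open(path, "w") as fh:
        json.dump(stats, fh, indent=2, sort_keys=True)
        fh.write("\n")
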