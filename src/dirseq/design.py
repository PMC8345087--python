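"""Reporter library design: SNP-centered allele oligos and barcoded constructs.

Each cancer-risk SNP contributes two 55-bp inserts (risk and protective allele,
SNP at the central position) cloned upstream of an SV40 promoter in a DiR
reporter vector.  Every construct — including a promoter-only negative control —
is identified by a 6-nt sub-library tag plus a 2-nt dinucleotide barcode in the
transcribed region; the (tag, barcode) pair is the construct's sequencing
identity and is assigned deterministically so a manifest always yields the same
library.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

OLIGO_LENGTH = 55
SNP_CENTER = OLIGO_LENGTH // 2  # 27: a 55-mer has a unique central base
FLANK = SNP_CENTER  # nucleotides required on each side of the SNP

NUCLEOTIDES = ("A", "C", "G", "T")

#: The 16 dinucleotide barcodes in the fixed assignment order AA, AC, ..., TT.
DINUCLEOTIDES = tuple("".join(p) for p in itertools.product(NUCLEOTIDES, repeat=2))

#: Fixed 6-nt sub-library tags, opened in order as each fills its 16 barcodes.
#: The tag sits immediately upstream of the dinucleotide barcode in the read.
SUBLIB_TAGS = (
    "AAGCTA",
    "CCATGC",
    "GGTACG",
    "TTCGAT",
    "ACTGGA",
    "CAGATT",
    "GTCCAA",
    "TGAGCC",
)

#: Identifier used for the insert-free negative-control construct.
NEGATIVE_CONTROL_ID = "negctrl"

MANIFEST_COLUMNS = ("rsid", "risk_allele", "protective_allele", "context", "snp_offset", "source")


@dataclass(frozen=True)
class SnpDesignRecord:
    """One risk SNP with its two alleles and genomic flanking context."""

    rsid: str
    risk_allele: str
    protective_allele: str
    context: str
    snp_offset: int
    source: str = ""

    def __post_init__(self) -> None:
        for name in ("risk_allele", "protective_allele"):
            allele = getattr(self, name)
            if allele not in NUCLEOTIDES:
                raise ValidationError(f"{self.rsid}: {name} {allele!r} is not a single nucleotide")
        if self.risk_allele == self.protective_allele:
            raise ValidationError(f"{self.rsid}: risk and protective alleles are identical")
        if not (0 <= self.snp_offset < len(self.context)):
            raise ValidationError(f"{self.rsid}: snp_offset {self.snp_offset} outside context")
        bad = set(self.context.upper()) - set(NUCLEOTIDES)
        if bad:
            raise ValidationError(f"{self.rsid}: context contains non-ACGT characters {sorted(bad)}")
        if self.snp_offset < FLANK or len(self.context) - self.snp_offset - 1 < FLANK:
            raise ValidationError(
                f"{self.rsid}: context needs >= {FLANK} nt on each side of the SNP"
            )

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.risk_allele, self.protective_allele)


@dataclass(frozen=True)
class Construct:
    """A barcoded reporter insert: one SNP allele, or the negative control."""

    construct_id: str
    rsid_or_control: str
    allele_role: str  # one of {risk, protective, control}
    insert_seq: str  # 55 nt, empty for the control
    sublib_tag: str
    barcode: str

    def __post_init__(self) -> None:
        if self.allele_role not in ("risk", "protective", "control"):
            raise ValidationError(f"bad allele_role {self.allele_role!r}")
        if self.allele_role == "control":
            if self.insert_seq:
                raise ValidationError("negative control must not carry an insert")
        elif len(self.insert_seq) != OLIGO_LENGTH:
            raise ValidationError(
                f"{self.construct_id}: insert is {len(self.insert_seq)} nt, expected {OLIGO_LENGTH}"
            )
        if len(self.sublib_tag) != 6:
            raise ValidationError(f"{self.construct_id}: sub-library tag must be 6 nt")
        if self.barcode not in DINUCLEOTIDES:
            raise ValidationError(f"{self.construct_id}: barcode {self.barcode!r} not a dinucleotide")


def load_snp_manifest(path: str | Path) -> list[SnpDesignRecord]:
    """Read a tab-separated SNP design manifest into validated records.

    The manifest must carry the columns rsid, risk_allele, protective_allele,
    context, snp_offset and source.  Alleles are upper-cased; duplicate rsIDs
    are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"manifest {path} is missing columns {missing}")
    if df.empty:
        logger.warning("manifest %s has no data rows", path)
        return []
    dupes = df["rsid"][df["rsid"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"duplicate rsIDs in manifest: {sorted(set(dupes))}")
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                SnpDesignRecord(
                    rsid=row["rsid"],
                    risk_allele=row["risk_allele"].strip().upper(),
                    protective_allele=row["protective_allele"].strip().upper(),
                    context=row["context"].strip().upper(),
                    snp_offset=int(row["snp_offset"]),
                    source=row["source"],
                )
            )
        except ValidationError as err:
            raise ValidationError(f"manifest row {i + 2} ({row['rsid']}): {err}") from err
    return records


def design_oligo(record: SnpDesignRecord, allele: str) -> str:
    """Return the 55-nt SNP-centered insert for one allele of a record.

    The allele occupies the central position (0-based index 27); the flanks are
    copied verbatim from the record's genomic context.
    """
    if allele not in record.alleles:
        raise ValidationError(f"{record.rsid}: allele {allele!r} is not one of {record.alleles}")
    ctx, pos = record.context, record.snp_offset
    oligo = ctx[pos - FLANK : pos] + allele + ctx[pos + 1 : pos + FLANK + 1]
    assert len(oligo) == OLIGO_LENGTH
    return oligo


def build_constructs(records: list[SnpDesignRecord]) -> list[Construct]:
    """Assemble the barcoded construct library for a set of design records.

    Produces 2N allele constructs plus one negative control.  The control takes
    the first identity slot (it anchors the activity scale); allele constructs
    follow in sorted (rsid, allele_role) order.  Identities fill each
    sub-library's 16 dinucleotide barcodes alphabetically before the next
    sub-library tag is opened, so the library is reproducible without seeds.
    """
    if not records:
        logger.warning("no SNP records: building a control-only library")
    seen = set()
    for rec in records:
        if rec.rsid in seen:
            raise ValidationError(f"duplicate rsID {rec.rsid}")
        seen.add(rec.rsid)

    n_slots = 2 * len(records) + 1
    if n_slots > len(SUBLIB_TAGS) * len(DINUCLEOTIDES):
        raise ConfigurationError(
            f"{n_slots} constructs exceed the {len(SUBLIB_TAGS) * 16} available identities"
        )

    def identity(slot: int) -> tuple[str, str]:
        return SUBLIB_TAGS[slot // 16], DINUCLEOTIDES[slot % 16]

    tag, barcode = identity(0)
    constructs = [
        Construct(
            construct_id=NEGATIVE_CONTROL_ID,
            rsid_or_control=NEGATIVE_CONTROL_ID,
            allele_role="control",
            insert_seq="",
            sublib_tag=tag,
            barcode=barcode,
        )
    ]
    slot = 1
    for rec in sorted(records, key=lambda r: r.rsid):
        for role in ("protective", "risk"):  # alphabetical within an rsID
            allele = rec.protective_allele if role == "protective" else rec.risk_allele
            tag, barcode = identity(slot)
            constructs.append(
                Construct(
                    construct_id=f"{rec.rsid}_{role}",
                    rsid_or_control=rec.rsid,
                    allele_role=role,
                    insert_seq=design_oligo(rec, allele),
                    sublib_tag=tag,
                    barcode=barcode,
                )
            )
            slot += 1
    return constructs


def constructs_to_frame(constructs: list[Construct]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "construct_id": c.construct_id,
                "rsid_or_control": c.rsid_or_control,
                "allele_role": c.allele_role,
                "insert_seq": c.insert_seq,
                "sublib_tag": c.sublib_tag,
                "barcode": c.barcode,
            }
            for c in constructs
        ]
    )


def write_constructs(constructs: list[Construct], path: str | Path) -> None:
    constructs_to_frame(constructs).to_csv(path, sep="\t", index=False)


def read_constructs(path: str | Path) -> list[Construct]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    return [Construct(**row) for row in df.to_dict("records")]


def write_inserts_fasta(constructs: list[Construct], path: str | Path) -> None:
    """Export the non-control insert sequences as FASTA."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    fasta = [
        SeqRecord(Seq(c.insert_seq), id=c.construct_id, description=f"{c.sublib_tag}-{c.barcode}")
        for c in constructs
        if c.allele_role != "control"
    ]
    seqio_write(fasta, str(path), "fasta")


def identity_map(constructs: list[Construct]) -> dict[tuple[str, str], str]:
    """Invertible (sublib_tag, barcode) -> construct_id lookup for demultiplexing."""
    mapping: dict[tuple[str, str], str] = {}
    for c in constructs:
        key = (c.sublib_tag, c.barcode)
        if key in mapping:
            raise ValidationError(f"duplicate identity {key} in construct table")
        mapping[key] = c.construct_id
    return mapping
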