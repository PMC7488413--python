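"""Readers and writers for the pipeline's plain-text interchange formats.

TSV (tab-separated, UTF-8, header row, ``.`` for missing) is the interchange
dialect; FASTA/FASTQ go through Biopython; gzip is auto-detected by suffix.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import asdict, dataclass

from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .classify import AmpliconRef
from .design import HdrTemplate, TranscriptModel, VariantSpec
from .exceptions import SchemaError
from .qc import SampleCounts

MANIFEST_COLUMNS = [
    "variant_id",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "class",
    "gdna_amplicon_fasta_id",
    "cdna_amplicon_fasta_id",
    "cut_offset_gdna",
    "cut_offset_cdna",
    "variant_offset_gdna",
    "variant_offset_cdna",
]

TALLY_COLUMNS = ["variant_id", "material", "replicate", "n_ref", "n_alt", "n_nhej"]


def _check_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} missing column(s): {', '.join(missing)}")


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["."])
    _check_columns(df, MANIFEST_COLUMNS, "variant manifest")
    return df


def write_manifest(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=".")


def amplicon_refs_from_manifest(
    manifest: pd.DataFrame, sequences: dict[str, str], edit_window: int = 20
) -> dict[tuple[str, str], AmpliconRef]:
    """Build AmpliconRef objects for each (variant, material) in a manifest.

    ``sequences`` maps FASTA record ids to amplicon sequences.
    """
    refs: dict[tuple[str, str], AmpliconRef] = {}
    for row in manifest.itertuples():
        for material, fid, cut, voff in (
            ("gDNA", row.gdna_amplicon_fasta_id, row.cut_offset_gdna, row.variant_offset_gdna),
            ("cDNA", row.cdna_amplicon_fasta_id, row.cut_offset_cdna, row.variant_offset_cdna),
        ):
            if fid not in sequences:
                raise SchemaError(
                    f"manifest row {row.variant_id}: amplicon {fid!r} not in FASTA"
                )
            refs[(row.variant_id, material)] = AmpliconRef(
                amplicon_id=str(fid),
                material=material,
                sequence=sequences[fid],
                variant_offset=int(voff),
                ref_allele=str(row.ref),
                alt_allele=str(row.alt),
                cut_offset=int(cut),
                edit_window=edit_window,
            )
    return refs


def read_fasta(path) -> dict[str, str]:
    opener = gzip.open(str(path), "rt") if str(path).endswith(".gz") else open(path)
    with opener as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(records: dict[str, str] | Iterable[tuple[str, str]], path) -> None:
    items = records.items() if isinstance(records, dict) else records
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    SeqIO.write(seqs, str(path), "fasta")


def write_templates_fasta(templates: Iterable[HdrTemplate], path) -> None:
    write_fasta(
        [(t.variant_id or f"template_{i}", t.sequence) for i, t in enumerate(templates)],
        path,
    )


def read_tally(path) -> list[SampleCounts]:
    df = pd.read_csv(path, sep="\t", na_values=["."])
    _check_columns(df, TALLY_COLUMNS, "tally table")
    return [
        SampleCounts(
            str(r.variant_id),
            str(r.material),
            int(r.replicate),
            int(r.n_ref),
            int(r.n_alt),
            int(r.n_nhej),
        )
        for r in df.itertuples()
    ]


def write_tally(samples: Iterable[SampleCounts], path, extra: pd.DataFrame | None = None) -> None:
    rows = [
        {
            "variant_id": s.variant_id,
            "material": s.material,
            "replicate": s.replicate,
            "n_ref": s.n_ref,
            "n_alt": s.n_alt,
            "n_nhej": s.n_nhej,
        }
        for s in samples
    ]
    pd.DataFrame(rows, columns=TALLY_COLUMNS).to_csv(path, sep="\t", index=False, na_rep=".")


def read_transcripts(path) -> dict[str, TranscriptModel]:
    """Read transcript models from TSV.

    Columns: ``transcript_id, strand, exon_starts, exon_ends, cds_start,
    cds_end[, chrom]`` with comma-separated exon lists in transcription
    order.
    """
    df = pd.read_csv(path, sep="\t", na_values=["."])
    _check_columns(
        df, ["transcript_id", "strand", "exon_starts", "exon_ends", "cds_start", "cds_end"],
        "transcript table",
    )
    out = {}
    for r in df.itertuples():
        starts = [int(x) for x in str(r.exon_starts).split(",") if x]
        ends = [int(x) for x in str(r.exon_ends).split(",") if x]
        if len(starts) != len(ends):
            raise SchemaError(f"{r.transcript_id}: exon_starts/exon_ends length mismatch")
        out[str(r.transcript_id)] = TranscriptModel(
            transcript_id=str(r.transcript_id),
            strand=str(r.strand),
            exons=tuple(zip(starts, ends)),
            cds_start=int(r.cds_start),
            cds_end=int(r.cds_end),
            chrom=str(getattr(r, "chrom", ".")),
        )
    return out


def write_variants(variants: Iterable[VariantSpec], path) -> None:
    rows = [
        {
            "variant_id": v.variant_id,
            "gene": v.gene,
            "chrom": v.chrom,
            "pos": v.pos,
            "ref": v.ref_allele,
            "alt": v.alt_allele,
            "class": v.variant_class,
            "expected_direction": v.expected_direction,
        }
        for v in variants
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep=".")


@dataclass
class RunConfig:
    """End-to-end run configuration with the assay's standard thresholds."""

    manifest_path: str = ""
    fastq_dir: str = ""
    output_dir: str = "."
    min_reads: int = 1000
    max_nhej: float = 0.80
    max_het_hdr: float = 0.30
    min_hdr: float = 0.004
    alpha: float = 0.05
    nmd_threshold: int = 55
    control_class: str = "control_non_eqtl"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("max_nhej", "max_het_hdr", "min_hdr", "alpha"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
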