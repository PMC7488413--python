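"""Assay design: HDR templates, synthetic-control alleles, NMD annotation and
candidate-selection filters.

The editing assay introduces a single variant into its native genomic context
with an HDR (homology-directed repair) template: the reference sequence
flanking the variant with the alternative allele substituted.  For premature
stop-gained variants, the expected transcript-level consequence is
nonsense-mediated decay (NMD) when the stop lies at least ~55 bp upstream of
the last exon-exon junction, and NMD escape otherwise.  This module builds
templates and matched synthetic-control alleles, tiles novel stop codons
around the NMD boundary of a transcript, and applies the population-data
filters used to pick stop-gained, eQTL and negative-control candidates.

Coordinates are 1-based inclusive in all public I/O (VCF/GFF convention) and
0-based half-open internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .exceptions import (
    CoordinateError,
    DesignInfeasibleError,
    FlankBoundsError,
    NoJunctionError,
    ReferenceMismatchError,
    SchemaError,
)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
BASES = "ACGT"

VARIANT_CLASSES = (
    "stop_gained_gtex",
    "eqtl",
    "stop_gained_disease",
    "control_non_eqtl",
    "control_synthetic",
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class VariantSpec:
    """A single candidate variant chosen for editing."""

    variant_id: str
    gene: str
    chrom: str
    pos: int  # 1-based genomic
    ref_allele: str
    alt_allele: str
    variant_class: str
    expected_direction: str = "unknown"  # negative | positive | none | unknown

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise CoordinateError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.variant_id}: ref and alt alleles are identical")
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant class {self.variant_class!r}")


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure of one transcript.

    ``exons`` are 1-based inclusive genomic intervals in *transcription*
    order (for minus-strand transcripts the first exon has the largest
    coordinates).  ``cds_start``/``cds_end`` are the genomic positions of the
    first and last coding base in transcription order.
    """

    transcript_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int = 0
    cds_end: int = 0
    chrom: str = "."

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.exons) < 1:
            raise ValueError("transcript needs at least one exon")
        object.__setattr__(self, "exons", tuple((int(a), int(b)) for a, b in self.exons))
        for a, b in self.exons:
            if a > b:
                raise ValueError(f"exon start {a} > end {b}")
        spans = sorted(self.exons)
        for (_, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("exons overlap")

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def length(self) -> int:
        return sum(b - a + 1 for a, b in self.exons)

    def genomic_to_transcript(self, pos: int) -> int:
        """Map a 1-based genomic position to a 1-based transcript position."""
        offset = 0
        for a, b in self.exons:
            if a <= pos <= b:
                return offset + (pos - a + 1 if self.strand == "+" else b - pos + 1)
            offset += b - a + 1
        raise CoordinateError(
            f"position {pos} is not exonic in {self.transcript_id}"
        )

    def transcript_to_genomic(self, tpos: int) -> int:
        """Map a 1-based transcript position back to genomic coordinates."""
        if tpos < 1 or tpos > self.length:
            raise CoordinateError(f"transcript position {tpos} out of range")
        offset = 0
        for a, b in self.exons:
            n = b - a + 1
            if tpos <= offset + n:
                k = tpos - offset - 1
                return a + k if self.strand == "+" else b - k
            offset += n
        raise AssertionError("unreachable")

    @property
    def last_junction_tpos(self) -> int:
        """Transcript position of the last base before the final exon-exon junction."""
        if self.n_exons < 2:
            raise NoJunctionError(
                f"{self.transcript_id} is single-exon: no exon-exon junction"
            )
        return sum(b - a + 1 for a, b in self.exons[:-1])

    def spliced_sequence(self, genome: str) -> str:
        """Spliced transcript sequence from a plus-strand genome string.

        ``genome`` is indexed so that genomic position 1 is ``genome[0]``.
        """
        parts = []
        for a, b in self.exons:
            chunk = genome[a - 1 : b]
            parts.append(chunk if self.strand == "+" else reverse_complement(chunk))
        return "".join(parts)


@dataclass(frozen=True)
class HdrTemplate:
    """Homology-directed repair template: alt allele with flanking homology arms."""

    variant_id: str
    sequence: str
    variant_offset: int  # 0-based offset of the alt allele within sequence


def build_hdr_template(
    genomic_context: str,
    variant_offset_in_context: int,
    ref_allele: str,
    alt_allele: str,
    flank: int = 50,
    variant_id: str = "",
) -> HdrTemplate:
    """Extract ``flank`` bp either side of the variant and substitute the alt allele.

    For a SNV at the default flank the template is 101 bp with the variant at
    offset 50.
    """
    ctx = genomic_context.upper()
    ref = ref_allele.upper()
    alt = alt_allele.upper()
    i = variant_offset_in_context
    if i < 0 or i + len(ref) > len(ctx):
        raise FlankBoundsError("variant offset outside the supplied context")
    if ctx[i : i + len(ref)] != ref:
        raise ReferenceMismatchError(
            f"context has {ctx[i : i + len(ref)]!r} at offset {i}, expected {ref!r}"
        )
    if i < flank or len(ctx) - (i + len(ref)) < flank:
        raise FlankBoundsError(
            f"need {flank} bp of context on both sides of the variant"
        )
    seq = ctx[i - flank : i] + alt + ctx[i + len(ref) : i + len(ref) + flank]
    return HdrTemplate(variant_id=variant_id, sequence=seq, variant_offset=flank)


def pick_synthetic_control_allele(
    codon_context: str,
    frame_offset: int,
    ref_allele: str,
    stop_alt_allele: str,
) -> str:
    """Pick a third allele at a stop-gained locus that creates no stop codon.

    Synthetic controls carry a nucleotide differing from both the reference
    allele and the stop-creating alternative allele, chosen so the resulting
    codon is not TAA/TAG/TGA.  Ties are broken by the first qualifying base
    in A<C<G<T order.
    """
    codon = codon_context.upper()
    if len(codon) != 3:
        raise ValueError("codon_context must be the 3-bp codon containing the variant")
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    ref = ref_allele.upper()
    stop_alt = stop_alt_allele.upper()
    if len(ref) != 1 or len(stop_alt) != 1:
        raise ValueError("single-nucleotide variants only")
    if codon[frame_offset] != ref:
        raise ReferenceMismatchError(
            f"codon {codon} has {codon[frame_offset]} at frame offset "
            f"{frame_offset}, expected {ref}"
        )
    for base in BASES:
        if base in (ref, stop_alt):
            continue
        mutated = codon[:frame_offset] + base + codon[frame_offset + 1 :]
        if mutated not in STOP_CODONS:
            return base
    raise DesignInfeasibleError(
        f"every third allele at {codon}[{frame_offset}] creates a stop codon"
    )


def nmd_distance(transcript: TranscriptModel, stop_pos_genomic: int) -> int:
    """Distance d from a stop codon to the last exon-exon junction.

    Measured in spliced-transcript bases from the *first* base of the stop
    codon.  Positive d means the stop is upstream of the junction; zero or
    negative means at/after it (any stop in the last exon gives d <= 0).
    """
    tpos = transcript.genomic_to_transcript(stop_pos_genomic)
    return transcript.last_junction_tpos - tpos + 1


def predict_nmd(d: int, threshold: int = 55) -> str:
    """Predict ``"trigger"`` when d >= threshold bp upstream of the last junction."""
    return "trigger" if d >= threshold else "escape"


@dataclass
class StopTiling:
    """Output of :func:`tile_stop_codons`: the variants plus unfillable slots."""

    variants: list[VariantSpec] = field(default_factory=list)
    unfillable: list[int] = field(default_factory=list)  # target d of empty slots
    distances: dict[str, int] = field(default_factory=dict)  # variant_id -> d


def _stop_snvs_in_codon(codon: str) -> list[tuple[int, str]]:
    """All (offset_in_codon, alt_base) SNVs turning a non-stop codon into a stop."""
    out = []
    if codon in STOP_CODONS:
        return out
    for j in range(3):
        for base in BASES:
            if base == codon[j]:
                continue
            if codon[:j] + base + codon[j + 1 :] in STOP_CODONS:
                out.append((j, base))
    return out


def tile_stop_codons(
    transcript: TranscriptModel,
    coding_sequence: str,
    n_each_side: int,
    spacing: int = 20,
    nmd_threshold: int = 55,
    gene: str = "",
) -> StopTiling:
    """Design stop-gained SNVs spaced around the NMD boundary of a transcript.

    Target slots sit at NMD distances d = threshold + k*spacing on the
    NMD-trigger side and d = threshold - (k+1)*spacing on the escape side,
    k = 0..n_each_side-1, so the boundary slot itself is included once.  For
    each slot the nearest codon (within spacing/2 of the target, measured at
    the codon's first base) that can be turned into TAA/TAG/TGA by a single
    substitution is chosen; slots with no such codon are reported as
    unfillable.  Alleles are reported on the genomic plus strand.

    ``coding_sequence`` is the in-frame spliced CDS of the transcript
    (transcription-order, coding strand).
    """
    cds = coding_sequence.upper()
    if len(cds) % 3:
        raise ValueError("coding_sequence length must be a multiple of 3")
    junction = transcript.last_junction_tpos  # needs >= 2 exons
    cds_tstart = transcript.genomic_to_transcript(transcript.cds_start)
    gene = gene or transcript.transcript_id

    # transcript position of the first base of codon i
    def codon_tpos(i: int) -> int:
        return cds_tstart + 3 * i

    boundary_tpos = junction - nmd_threshold + 1  # stop starting here has d = threshold
    targets: list[int] = []  # target d values, trigger side first
    for k in range(n_each_side):
        targets.append(nmd_threshold + k * spacing)
    for k in range(n_each_side):
        targets.append(nmd_threshold - (k + 1) * spacing)

    n_codons = len(cds) // 3
    result = StopTiling()
    used_codons: set[int] = set()
    for target_d in targets:
        target_tpos = boundary_tpos + (nmd_threshold - target_d)
        best: tuple[int, int, int, str] | None = None  # (|gap|, codon_i, j, alt)
        for i in range(n_codons):
            if i in used_codons:
                continue
            tp = codon_tpos(i)
            gap = abs(tp - target_tpos)
            if gap > spacing / 2:
                continue
            snvs = _stop_snvs_in_codon(cds[3 * i : 3 * i + 3])
            if not snvs:
                continue
            j, alt = snvs[0]  # deterministic: first offset, alphabetical alt
            if best is None or (gap, tp) < (best[0], codon_tpos(best[1])):
                best = (gap, i, j, alt)
        if best is None:
            result.unfillable.append(target_d)
            continue
        _, i, j, alt = best
        used_codons.add(i)
        tp = codon_tpos(i)
        d = junction - tp + 1
        var_tpos = tp + j
        gpos = transcript.transcript_to_genomic(var_tpos)
        ref_coding = cds[3 * i + j]
        if transcript.strand == "+":
            ref_g, alt_g = ref_coding, alt
        else:
            ref_g, alt_g = reverse_complement(ref_coding), reverse_complement(alt)
        vid = f"{gene}:stop_d{d:+d}"
        result.variants.append(
            VariantSpec(
                variant_id=vid,
                gene=gene,
                chrom=transcript.chrom,
                pos=gpos,
                ref_allele=ref_g,
                alt_allele=alt_g,
                variant_class="stop_gained_disease",
                expected_direction=(
                    "negative" if predict_nmd(d, nmd_threshold) == "trigger" else "none"
                ),
            )
        )
        result.distances[vid] = d
    return result


def _require_columns(rows: pd.DataFrame, cols: Iterable[str]) -> None:
    missing = [c for c in cols if c not in rows.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")


def filter_stop_gained_candidates(rows: pd.DataFrame) -> pd.DataFrame:
    """Select stop-gained candidates showing consistent NMD in population data.

    Keeps rows with RNA-seq coverage >= 20 reads, reference ratio
    Ref/(Ref+Alt) > 0.7, gene expression > 0.5 RPKM, ASE observed in >= 5
    tissues with a first-quartile ASE > 0.7, and > 30 bp from the exon end.
    """
    _require_columns(
        rows,
        ["coverage", "ref_ratio", "rpkm", "n_tissues_with_ase", "ase_q1", "dist_to_exon_end"],
    )
    mask = (
        (rows["coverage"] >= 20)
        & (rows["ref_ratio"] > 0.7)
        & (rows["rpkm"] > 0.5)
        & (rows["n_tissues_with_ase"] >= 5)
        & (rows["ase_q1"] > 0.7)
        & (rows["dist_to_exon_end"] > 30)
    )
    return rows[mask]


def filter_eqtl_candidates(rows: pd.DataFrame) -> pd.DataFrame:
    """Select fine-mapped eQTL candidates.

    Keeps variants in a protein-coding transcript with CAVIAR posterior
    probability > 0.8, eGene expression > 1 RPKM and |aFC| in the top
    quartile of associations (> 0.30 log2 units).
    """
    _require_columns(
        rows, ["in_protein_coding_transcript", "caviar_pp", "egene_rpkm", "abs_afc"]
    )
    mask = (
        rows["in_protein_coding_transcript"].astype(bool)
        & (rows["caviar_pp"] > 0.8)
        & (rows["egene_rpkm"] > 1)
        & (rows["abs_afc"] > 0.30)
    )
    return rows[mask]


def filter_non_eqtl_controls(rows: pd.DataFrame) -> pd.DataFrame:
    """Select negative-control variants: common synonymous sites with eQTL p > 0.1."""
    _require_columns(rows, ["is_synonymous", "is_common", "eqtl_p"])
    mask = (
        rows["is_synonymous"].astype(bool)
        & rows["is_common"].astype(bool)
        & (rows["eqtl_p"] > 0.1)
    )
    return rows[mask]
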