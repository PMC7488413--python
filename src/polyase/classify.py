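"""Classify targeted amplicon-sequencing reads as HDR, no-edit or NHEJ.

Each read from an edited polyclonal population is aligned to the amplicon
reference (gDNA or cDNA) for its target.  Reads carrying an insertion or
deletion near the predicted Cas9 cut site are NHEJ products; indel-free reads
are called HDR or NO_EDIT by the base(s) they carry at the variant position;
everything else (poor alignments, third alleles, ambiguous bases,
mate-discordant pairs) is discarded.  Because reads with both the alt allele
and a cut-site indel cannot be used for allelic quantification, the indel
check takes precedence over the variant allele.

Alignment is unit-cost infix alignment (the read is located as a substring of
the amplicon, free end gaps on the reference) via edlib, with exact-match
fast paths for unedited and clean-HDR reads; reads whose unit-cost alignment
contains indels are re-aligned with affine gap penalties so that clustered
substitutions are never mistaken for NHEJ indels.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import IO, Iterator

import edlib
from Bio import SeqIO
from Bio.Align import PairwiseAligner

from .exceptions import FastqParseError
from .design import reverse_complement

LABELS = ("HDR", "NO_EDIT", "NHEJ", "DISCARD")


@dataclass(frozen=True)
class AmpliconRef:
    """Amplicon reference for one target and material.

    ``variant_offset`` and ``cut_offset`` are 0-based offsets into
    ``sequence``; ``edit_window`` is the number of bases either side of the
    cut site scanned for NHEJ indels.
    """

    amplicon_id: str
    material: str  # gDNA | cDNA
    sequence: str
    variant_offset: int
    ref_allele: str
    alt_allele: str
    cut_offset: int
    edit_window: int = 20

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        object.__setattr__(self, "ref_allele", self.ref_allele.upper())
        object.__setattr__(self, "alt_allele", self.alt_allele.upper())
        if self.material not in ("gDNA", "cDNA"):
            raise ValueError(f"material must be gDNA or cDNA, got {self.material!r}")
        n = len(self.sequence)
        if not (0 <= self.variant_offset < n):
            raise ValueError("variant_offset outside the amplicon")
        if not (0 <= self.cut_offset < n):
            raise ValueError("cut_offset outside the amplicon")
        at = self.sequence[self.variant_offset : self.variant_offset + len(self.ref_allele)]
        if at != self.ref_allele:
            raise ValueError(
                f"amplicon {self.amplicon_id} has {at!r} at variant_offset, "
                f"expected ref allele {self.ref_allele!r}"
            )
        if len(self.ref_allele) != len(self.alt_allele):
            raise ValueError("only equal-length ref/alt alleles are supported")

    @property
    def hdr_sequence(self) -> str:
        """The amplicon with the alternative allele substituted."""
        i = self.variant_offset
        return self.sequence[:i] + self.alt_allele + self.sequence[i + len(self.ref_allele) :]

    def reverse_complement(self) -> "AmpliconRef":
        n = len(self.sequence)
        L = len(self.ref_allele)
        return AmpliconRef(
            amplicon_id=self.amplicon_id,
            material=self.material,
            sequence=reverse_complement(self.sequence),
            variant_offset=n - self.variant_offset - L,
            ref_allele=reverse_complement(self.ref_allele),
            alt_allele=reverse_complement(self.alt_allele),
            cut_offset=n - 1 - self.cut_offset,
            edit_window=self.edit_window,
        )


@dataclass(frozen=True)
class ReadCall:
    """Classification outcome for one read (or concordant read pair)."""

    read_id: str
    label: str
    allele_at_variant: str | None = None
    n_indels_in_window: int = 0
    alignment_score: float = 0.0
    discard_reason: str | None = None


def _affine_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    # free end gaps: the read is an infix of the amplicon
    try:
        aligner.end_insertion_score = 0
        aligner.end_deletion_score = 0
    except AttributeError:  # older attribute names
        aligner.target_end_gap_score = 0
        aligner.query_end_gap_score = 0
    return aligner


_AFFINE = _affine_aligner()


def _affine_ops(read: str, ref_seq: str) -> tuple[list[tuple[int, str]], int]:
    """Affine-gap alignment as cigar-style ops [(n, op)] plus the ref start.

    Used when the unit-cost pass reports indels: with affine scoring,
    substitutions are strictly preferred over spurious insertion/deletion
    pairs, so only genuine indels survive.
    """
    aln = _AFFINE.align(ref_seq, read)[0]
    t_blocks, q_blocks = aln.aligned
    ops: list[tuple[int, str]] = []
    if len(t_blocks) == 0:
        return ops, 0
    start = int(t_blocks[0][0])
    prev_t, prev_q = None, None
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if prev_t is not None:
            if ts > prev_t:
                ops.append((ts - prev_t, "D"))
            if qs > prev_q:
                ops.append((qs - prev_q, "I"))
        i = 0
        while i < te - ts:  # emit '='/'X' runs within the block
            same = ref_seq[ts + i] == read[qs + i]
            j = i
            while j < te - ts and (ref_seq[ts + j] == read[qs + j]) == same:
                j += 1
            ops.append((j - i, "=" if same else "X"))
            i = j
        prev_t, prev_q = te, qe
    return ops, start


def _cigar_ops(cigar: str) -> list[tuple[int, str]]:
    ops = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((int(num), ch))
            num = ""
    return ops


def _align_calls(
    read: str,
    ref: AmpliconRef,
    max_mismatch_frac: float,
    min_aligned_frac: float,
) -> tuple[str, str | None, int, float, str | None]:
    """Align one oriented read; return (label, allele, n_indels, score, reason)."""
    res = edlib.align(read, ref.sequence, mode="HW", task="path")
    ops = _cigar_ops(res["cigar"])
    start = res["locations"][0][0]
    score = float(len(read) - res["editDistance"])
    if any(op in "ID" for _, op in ops):
        # unit-cost ties can fake indels out of clustered substitutions;
        # re-align with affine gap penalties before calling NHEJ
        ops, start = _affine_ops(read, ref.sequence)

    n_match = n_mismatch = 0
    indels: list[tuple[int, int]] = []  # ref-coordinate half-open spans
    var_lo = ref.variant_offset
    var_hi = var_lo + len(ref.ref_allele)
    allele_chars: dict[int, str] = {}

    rpos, qpos = start, 0
    for n, ch in ops:
        if ch in "=X":
            if ch == "=":
                n_match += n
            else:
                # the variant base is signal, not error: mismatches within the
                # variant span do not count toward the quality threshold
                in_var = max(0, min(rpos + n, var_hi) - max(rpos, var_lo))
                n_mismatch += n - in_var
                n_match += in_var
            lo = max(rpos, var_lo)
            hi = min(rpos + n, var_hi)
            for p in range(lo, hi):
                allele_chars[p] = read[qpos + (p - rpos)]
            rpos += n
            qpos += n
        elif ch == "I":  # bases in the read absent from the reference
            indels.append((rpos, rpos))
            qpos += n
        elif ch == "D":  # reference bases absent from the read
            indels.append((rpos, rpos + n))
            rpos += n

    aligned_frac = (n_match + n_mismatch) / len(read)
    mismatch_frac = n_mismatch / len(read)
    if aligned_frac < min_aligned_frac:
        return "DISCARD", None, 0, score, "poor alignment"
    if mismatch_frac > max_mismatch_frac:
        return "DISCARD", None, 0, score, "low quality"

    w_lo = ref.cut_offset - ref.edit_window
    w_hi = ref.cut_offset + ref.edit_window
    n_in_window = 0
    for s, e in indels:
        if s == e:  # insertion point
            if w_lo <= s <= w_hi:
                n_in_window += 1
        elif s <= w_hi and e - 1 >= w_lo:
            n_in_window += 1
    if n_in_window:
        return "NHEJ", None, n_in_window, score, None

    if len(allele_chars) < var_hi - var_lo:
        covered = any(var_lo <= s < var_hi or (s < var_hi and e > var_lo) for s, e in indels)
        reason = "variant position deleted" if covered else "variant not covered"
        return "DISCARD", None, 0, score, reason
    allele = "".join(allele_chars[p] for p in range(var_lo, var_hi))
    if "N" in allele:
        return "DISCARD", allele, 0, score, "ambiguous base at variant"
    if allele == ref.alt_allele:
        return "HDR", allele, 0, score, None
    if allele == ref.ref_allele:
        return "NO_EDIT", allele, 0, score, None
    return "DISCARD", allele, 0, score, "third allele"


def classify_read(
    read_sequence: str,
    ref: AmpliconRef,
    max_mismatch_frac: float = 0.1,
    min_aligned_frac: float = 0.5,
    read_id: str = "",
    try_reverse_complement: bool = True,
) -> ReadCall:
    """Classify a single read against its amplicon reference.

    If the forward orientation fails the alignment-quality thresholds the
    reverse complement is tried (reverse-strand mates need no special
    handling by the caller).
    """
    read = read_sequence.upper()
    if not read:
        return ReadCall(read_id, "DISCARD", discard_reason="empty read")

    # exact-match fast paths: unedited and clean HDR reads covering the variant
    var_hi = ref.variant_offset + len(ref.ref_allele)
    i = ref.sequence.find(read)
    if i >= 0 and i <= ref.variant_offset and i + len(read) >= var_hi:
        return ReadCall(read_id, "NO_EDIT", ref.ref_allele, 0, float(len(read)))
    i = ref.hdr_sequence.find(read)
    if i >= 0 and i <= ref.variant_offset and i + len(read) >= var_hi:
        return ReadCall(read_id, "HDR", ref.alt_allele, 0, float(len(read)))

    label, allele, n_indels, score, reason = _align_calls(
        read, ref, max_mismatch_frac, min_aligned_frac
    )
    if (
        try_reverse_complement
        and label == "DISCARD"
        and reason in ("poor alignment", "low quality")
    ):
        rc_label, rc_allele, rc_n, rc_score, rc_reason = _align_calls(
            reverse_complement(read), ref, max_mismatch_frac, min_aligned_frac
        )
        if rc_reason not in ("poor alignment", "low quality"):
            label, allele, n_indels, score, reason = (
                rc_label,
                rc_allele,
                rc_n,
                rc_score,
                rc_reason,
            )
    return ReadCall(read_id, label, allele, n_indels, score, reason)


@dataclass
class ClassifyTally:
    """Per-sample classification summary."""

    counts: Counter = field(default_factory=Counter)
    discard_reasons: Counter = field(default_factory=Counter)

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())

    def add(self, call: ReadCall) -> None:
        self.counts[call.label] += 1
        if call.label == "DISCARD" and call.discard_reason:
            self.discard_reasons[call.discard_reason] += 1

    def as_dict(self) -> dict[str, int]:
        return {label: self.counts.get(label, 0) for label in LABELS}


def _open_maybe_gzip(path) -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _parse_fastq(path) -> Iterator:
    try:
        with _open_maybe_gzip(path) as fh:
            index = 0
            for rec in SeqIO.parse(fh, "fastq"):
                yield rec
                index += 1
    except ValueError as exc:
        raise FastqParseError(f"{path}: record {index}: {exc}") from exc


def _strip_mate_suffix(read_id: str) -> str:
    return read_id[:-2] if read_id.endswith(("/1", "/2")) else read_id


def classify_fastq(
    fastq1,
    ref: AmpliconRef,
    fastq2=None,
    max_mismatch_frac: float = 0.1,
    min_aligned_frac: float = 0.5,
) -> tuple[list[ReadCall], ClassifyTally]:
    """Classify a FASTQ file (or read-pair files) against one amplicon.

    Paired mates are classified independently and must agree; a discordant
    pair is discarded with reason ``"mate conflict"``.  Each pair contributes
    a single call to the tally.
    """

    def _one(rec) -> ReadCall:
        return classify_read(
            str(rec.seq),
            ref,
            max_mismatch_frac=max_mismatch_frac,
            min_aligned_frac=min_aligned_frac,
            read_id=_strip_mate_suffix(rec.id),
        )

    calls: list[ReadCall] = []
    tally = ClassifyTally()
    if fastq2 is None:
        for rec in _parse_fastq(fastq1):
            call = _one(rec)
            calls.append(call)
            tally.add(call)
    else:
        for rec1, rec2 in zip(_parse_fastq(fastq1), _parse_fastq(fastq2), strict=True):
            id1, id2 = _strip_mate_suffix(rec1.id), _strip_mate_suffix(rec2.id)
            if id1 != id2:
                raise FastqParseError(
                    f"mate id mismatch: {rec1.id!r} vs {rec2.id!r}"
                )
            c1, c2 = _one(rec1), _one(rec2)
            if c1.label == c2.label:
                call = replace(
                    c1, n_indels_in_window=max(c1.n_indels_in_window, c2.n_indels_in_window)
                )
            else:
                call = ReadCall(id1, "DISCARD", discard_reason="mate conflict")
            calls.append(call)
            tally.add(call)
    return calls, tally
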