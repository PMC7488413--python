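"""Per-sample allele counts and the QC cascade.

A sample is one (variant, material, replicate) sequencing library.  Its locus
coverage is the number of classified reads (no-edit + HDR + NHEJ); discarded
reads do not count.  Samples are dropped when coverage is below 1000 reads or
the NHEJ fraction exceeds 80% (an alignment-artifact signature).  Variants
are dropped when the gDNA HDR rate — the alternative-allele frequency in the
edited population's genomic DNA — exceeds 30% (the line is likely
heterozygous rather than edited) or falls below 0.4% (too few HDR molecules
for a stable allelic ratio).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .exceptions import UndefinedRateError

QC_MIN_READS = 1000
QC_MAX_NHEJ = 0.80
QC_MAX_HET_HDR = 0.30
QC_MIN_HDR = 0.004


@dataclass(frozen=True)
class SampleCounts:
    """Classified read counts for one (variant, material, replicate) sample."""

    variant_id: str
    material: str  # gDNA | cDNA
    replicate: int
    n_ref: int
    n_alt: int
    n_nhej: int

    def __post_init__(self) -> None:
        if min(self.n_ref, self.n_alt, self.n_nhej) < 0:
            raise ValueError("counts must be non-negative")
        if self.material not in ("gDNA", "cDNA"):
            raise ValueError(f"material must be gDNA or cDNA, got {self.material!r}")

    @property
    def coverage(self) -> int:
        return self.n_ref + self.n_alt + self.n_nhej


def hdr_rate(counts: SampleCounts) -> float:
    """HDR rate: alternative-allele frequency among classified reads."""
    cov = counts.coverage
    if cov == 0:
        raise UndefinedRateError(f"{counts.variant_id}: zero coverage")
    return counts.n_alt / cov


def nhej_rate(counts: SampleCounts) -> float:
    cov = counts.coverage
    if cov == 0:
        raise UndefinedRateError(f"{counts.variant_id}: zero coverage")
    return counts.n_nhej / cov


@dataclass(frozen=True)
class SampleQc:
    passed: bool
    reasons: tuple[str, ...]


def apply_sample_qc(
    counts: SampleCounts,
    min_reads: int = QC_MIN_READS,
    max_nhej: float = QC_MAX_NHEJ,
) -> SampleQc:
    """Sample-level QC: coverage floor and outlier NHEJ rate."""
    reasons: list[str] = []
    if counts.coverage < min_reads:
        reasons.append("low_reads")
    if counts.coverage > 0 and nhej_rate(counts) > max_nhej:
        reasons.append("high_nhej")
    return SampleQc(passed=not reasons, reasons=tuple(reasons))


@dataclass(frozen=True)
class QcStatus:
    """Variant-level QC verdict, evaluated on the gDNA sample."""

    variant_id: str
    passed: bool
    reasons: tuple[str, ...]
    hdr_rate_gdna: float
    nhej_rate: float


def apply_variant_qc(
    gdna: SampleCounts,
    max_het_hdr: float = QC_MAX_HET_HDR,
    min_hdr: float = QC_MIN_HDR,
) -> QcStatus:
    """Variant-level QC on gDNA: heterozygosity and minimum-HDR filters."""
    h = hdr_rate(gdna)
    reasons: list[str] = []
    if h > max_het_hdr:
        reasons.append("het_gdna")
    if h < min_hdr:
        reasons.append("low_hdr")
    return QcStatus(
        variant_id=gdna.variant_id,
        passed=not reasons,
        reasons=tuple(reasons),
        hdr_rate_gdna=h,
        nhej_rate=nhej_rate(gdna),
    )


@dataclass
class QcReport:
    """Outcome of the full cascade over a batch of samples."""

    table: pd.DataFrame  # one row per sample with rates, pass flag and reasons
    surviving_pairs: set[tuple[str, int]]  # (variant_id, replicate)
    surviving_variants: set[str]


def apply_qc_cascade(
    samples: Iterable[SampleCounts],
    min_reads: int = QC_MIN_READS,
    max_nhej: float = QC_MAX_NHEJ,
    max_het_hdr: float = QC_MAX_HET_HDR,
    min_hdr: float = QC_MIN_HDR,
) -> QcReport:
    """Run sample- then variant-level QC over a batch.

    A (variant, replicate) pair survives when both its gDNA and cDNA samples
    pass sample QC and the gDNA sample passes variant QC.  A variant survives
    when at least one replicate survives.  The outcome is order-independent:
    filters are pure predicates on each sample.
    """
    samples = list(samples)
    by_pair: dict[tuple[str, int], dict[str, SampleCounts]] = {}
    rows = []
    for s in samples:
        by_pair.setdefault((s.variant_id, s.replicate), {})[s.material] = s

    surviving: set[tuple[str, int]] = set()
    for (vid, rep), mats in sorted(by_pair.items()):
        pair_ok = set(mats) == {"gDNA", "cDNA"}
        for material in ("gDNA", "cDNA"):
            s = mats.get(material)
            if s is None:
                pair_ok = False
                continue
            sqc = apply_sample_qc(s, min_reads=min_reads, max_nhej=max_nhej)
            reasons = list(sqc.reasons)
            h = hdr_rate(s) if s.coverage else float("nan")
            q = nhej_rate(s) if s.coverage else float("nan")
            if material == "gDNA" and sqc.passed:
                vqc = apply_variant_qc(s, max_het_hdr=max_het_hdr, min_hdr=min_hdr)
                reasons += list(vqc.reasons)
            passed = not reasons
            pair_ok &= passed
            rows.append(
                {
                    "variant_id": vid,
                    "replicate": rep,
                    "material": material,
                    "coverage": s.coverage,
                    "hdr_rate": h,
                    "nhej_rate": q,
                    "pass": passed,
                    "reasons": ",".join(reasons) if reasons else ".",
                }
            )
        if pair_ok:
            surviving.add((vid, rep))

    table = pd.DataFrame(
        rows,
        columns=[
            "variant_id",
            "replicate",
            "material",
            "coverage",
            "hdr_rate",
            "nhej_rate",
            "pass",
            "reasons",
        ],
    )
    return QcReport(
        table=table,
        surviving_pairs=surviving,
        surviving_variants={vid for vid, _ in surviving},
    )
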