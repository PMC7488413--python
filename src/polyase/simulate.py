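"""Ground-truth-known simulation of polyclonal editing experiments.

After transfection, a polyclonal culture is a mixture of unedited cells,
HDR-edited cells carrying the alternative allele, and NHEJ cells carrying
cut-site indels.  The gDNA sample draws alleles directly from these class
fractions; the cDNA sample re-weights them by relative expression: the HDR
allele by 2^aFC (the variant's true regulatory effect), NHEJ alleles by a
depletion factor (frameshift products are usually degraded), plus an
optional carryover fraction of pre-editing mRNA that is entirely unedited
(the reason harvests are taken ~9 days post-transfection).  Sequencing error
flips ref<->alt at the variant base at rate error/3.  Counts are multinomial
at the requested depth and fully reproducible from the seed.

``simulate_fastq``/``simulate_reads`` are the read-level twin, producing
paired 150-bp reads whose classification recovers the class fractions.
``simulate_study`` assembles a study-scale batch (negative controls, eQTL
variants, stop-gained variants and ClinVar-style disease stops) with
per-replicate technical noise matched to the replicate variability the assay
exhibits in practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import AmpliconRef
from .exceptions import ParameterError
from .qc import SampleCounts

BASES = "ACGT"

# ClinVar-style disease stop-gained truths used by the bundled study emulation:
# a strong NMD-triggering stop, a moderate one, and an NMD-escaping stop.
CLINVAR_TRUE_AFC = (-1.39, -1.02, -0.17)

# Per-replicate technical noise (log2 units) of the study emulation, set so the
# combined (2-replicate) negative-control aFC variance matches the control
# variance the assay shows in practice (~0.038, sd ~0.195): 0.195*sqrt(2).
STUDY_TECHNICAL_NOISE_SD = 0.28


@dataclass(frozen=True)
class SimScenario:
    """Ground-truth parameters for one simulated variant."""

    variant_id: str
    true_afc: float
    hdr_rate: float
    nhej_rate: float
    depth_gdna: int = 85_000
    depth_cdna: int = 85_000
    seq_error: float = 0.001
    carryover: float = 0.0
    nhej_expression: float = 0.3
    extra_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.hdr_rate <= 1 and 0 <= self.nhej_rate <= 1):
            raise ParameterError("hdr_rate and nhej_rate must lie in [0, 1]")
        if self.hdr_rate + self.nhej_rate > 1:
            raise ParameterError("hdr_rate + nhej_rate must be <= 1")
        if not 0 <= self.carryover <= 1:
            raise ParameterError("carryover must lie in [0, 1]")
        if not 0 <= self.seq_error < 1:
            raise ParameterError("seq_error must lie in [0, 1)")
        if self.depth_gdna <= 0 or self.depth_cdna <= 0:
            raise ParameterError("depths must be positive")
        if self.nhej_expression < 0 or self.extra_noise_sd < 0:
            raise ParameterError("nhej_expression and extra_noise_sd must be >= 0")


def _seq_error_mix(fracs: np.ndarray, eps: float) -> np.ndarray:
    """Flip ref<->alt at the variant base with probability eps/3 each way."""
    ref, alt, nhej = fracs
    e = eps / 3.0
    return np.array([ref * (1 - e) + alt * e, alt * (1 - e) + ref * e, nhej])


def class_fractions(
    s: SimScenario, material: str, afc_noise: float = 0.0
) -> np.ndarray:
    """Expected (ref, alt, nhej) read fractions for one material.

    ``afc_noise`` is an additive log2 perturbation of the allelic ratio used
    to model per-sample technical variability; it applies to cDNA only.
    """
    h, q = s.hdr_rate, s.nhej_rate
    u = 1.0 - h - q
    if material == "gDNA":
        fracs = np.array([u, h, q])
    elif material == "cDNA":
        w = np.array([u, h * 2.0 ** (s.true_afc + afc_noise), q * s.nhej_expression])
        tot = w.sum()
        if tot == 0:
            raise ParameterError("cDNA expression weights are all zero")
        w = w / tot
        c = s.carryover
        fracs = (1 - c) * w + c * np.array([1.0, 0.0, 0.0])
    else:
        raise ValueError(f"material must be gDNA or cDNA, got {material!r}")
    return _seq_error_mix(fracs, s.seq_error)


def simulate_counts(
    s: SimScenario,
    replicate: int = 1,
    rng: np.random.Generator | None = None,
) -> tuple[SampleCounts, SampleCounts]:
    """Draw (gDNA, cDNA) allele counts for one scenario.

    Deterministic given the scenario seed (or a caller-supplied generator).
    """
    if rng is None:
        rng = np.random.default_rng(s.seed)
    noise = rng.normal(0.0, s.extra_noise_sd) if s.extra_noise_sd > 0 else 0.0
    g = rng.multinomial(s.depth_gdna, class_fractions(s, "gDNA"))
    c = rng.multinomial(s.depth_cdna, class_fractions(s, "cDNA", afc_noise=noise))
    gdna = SampleCounts(s.variant_id, "gDNA", replicate, int(g[0]), int(g[1]), int(g[2]))
    cdna = SampleCounts(s.variant_id, "cDNA", replicate, int(c[0]), int(c[1]), int(c[2]))
    return gdna, cdna


def expected_afc(s: SimScenario) -> float:
    """Closed-form aFC that the multinomial model converges to.

    Carryover inflates the cDNA reference share, so with carryover c > 0 the
    observed aFC underestimates the true one even at infinite depth; this is
    the quantity the timecourse experiment tracks back to zero.
    """
    g = class_fractions(s, "gDNA")
    c = class_fractions(s, "cDNA")
    return math.log2((c[1] / c[0]) / (g[1] / g[0]))


@dataclass(frozen=True)
class SimRead:
    read_id: str
    label: str  # generating class: NO_EDIT | HDR | NHEJ
    r1: str
    r2: str


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    if hits.size == 0:
        return seq
    lut = {ord(b): [ord(x) for x in BASES if x != b] for b in BASES}
    for i in hits:
        alts = lut.get(int(arr[i]))
        if alts:
            arr[i] = alts[rng.integers(3)]
    return arr.tobytes().decode()


def simulate_reads(
    s: SimScenario,
    ref: AmpliconRef,
    n_reads: int,
    read_len: int = 150,
    indel_size_geom_p: float = 0.4,
    rng: np.random.Generator | None = None,
) -> list[SimRead]:
    """Simulate paired reads for one sample of the given material.

    Molecules are drawn from the class fractions of :func:`simulate_counts`;
    NHEJ molecules carry a deletion or insertion (equal odds, geometric size)
    at the cut site; per-base substitution errors are applied at
    ``seq_error``.  R1 is the amplicon 5' end, R2 the reverse complement of
    the 3' end, both truncated to ``read_len``.
    """
    if not 0 < indel_size_geom_p <= 1:
        raise ParameterError("indel_size_geom_p must lie in (0, 1]")
    if rng is None:
        rng = np.random.default_rng(s.seed)
    from .design import reverse_complement  # local import avoids a cycle

    labels = ("NO_EDIT", "HDR", "NHEJ")
    # molecule fractions without the analytic ref<->alt error mixing:
    # the read-level twin applies sequencing error per base below instead
    h, q = s.hdr_rate, s.nhej_rate
    if ref.material == "gDNA":
        mol_fracs = np.array([1 - h - q, h, q])
    else:
        w = np.array([1 - h - q, h * 2.0**s.true_afc, q * s.nhej_expression])
        w = w / w.sum()
        c = s.carryover
        mol_fracs = (1 - c) * w + c * np.array([1.0, 0.0, 0.0])
    choice = rng.choice(3, size=n_reads, p=mol_fracs)

    reads: list[SimRead] = []
    for i, k in enumerate(choice):
        label = labels[k]
        if label == "NO_EDIT":
            mol = ref.sequence
        elif label == "HDR":
            mol = ref.hdr_sequence
        else:
            size = int(rng.geometric(indel_size_geom_p))
            cut = ref.cut_offset
            if rng.random() < 0.5:
                mol = ref.sequence[:cut] + ref.sequence[cut + size :]
            else:
                ins = "".join(BASES[j] for j in rng.integers(0, 4, size))
                mol = ref.sequence[:cut] + ins + ref.sequence[cut:]
        mol = _mutate(mol, rng, s.seq_error)
        r1 = mol[:read_len]
        r2 = reverse_complement(mol)[:read_len]
        reads.append(SimRead(f"{s.variant_id}:{ref.material}:{i}", label, r1, r2))
    return reads


def write_fastq_pair(reads: Sequence[SimRead], path1, path2, quality: int = 35) -> None:
    """Write simulated read pairs as two FASTQ files (constant quality)."""
    import gzip

    def _open(p):
        return gzip.open(p, "wt") if str(p).endswith(".gz") else open(p, "wt")

    with _open(path1) as f1, _open(path2) as f2:
        for r in reads:
            qual1 = chr(quality + 33) * len(r.r1)
            qual2 = chr(quality + 33) * len(r.r2)
            f1.write(f"@{r.read_id}/1\n{r.r1}\n+\n{qual1}\n")
            f2.write(f"@{r.read_id}/2\n{r.r2}\n+\n{qual2}\n")


def simulate_fastq(
    s: SimScenario,
    ref: AmpliconRef,
    path1,
    path2,
    n_reads: int | None = None,
    read_len: int = 150,
    indel_size_geom_p: float = 0.4,
) -> list[SimRead]:
    """Simulate a sample and write paired FASTQ; returns the truth records."""
    if n_reads is None:
        n_reads = s.depth_gdna if ref.material == "gDNA" else s.depth_cdna
    reads = simulate_reads(
        s, ref, n_reads, read_len=read_len, indel_size_geom_p=indel_size_geom_p
    )
    write_fastq_pair(reads, path1, path2)
    return reads


def simulate_timecourse(
    s: SimScenario, carryover_by_day: Mapping[int, float]
) -> list[tuple[int, SampleCounts, SampleCounts]]:
    """One (gDNA, cDNA) draw per harvest day at the given carryover levels.

    Carryover must be non-increasing in day (old mRNA decays).  With a true
    aFC of 0, the estimated aFC is negative while carryover is high and
    returns to ~0 as carryover vanishes.
    """
    days = sorted(carryover_by_day)
    values = [carryover_by_day[d] for d in days]
    if any(b > a for a, b in zip(values, values[1:])):
        raise ParameterError("carryover must be non-increasing in day")
    out = []
    for day in days:
        s_day = replace(s, carryover=carryover_by_day[day])
        rng = np.random.default_rng(np.random.SeedSequence([s.seed, day]))
        g, c = simulate_counts(s_day, rng=rng)
        out.append((day, g, c))
    return out


def _spawn_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def simulate_study(
    seed: int = 0,
    n_controls: int = 30,
    n_eqtl: int = 33,
    n_stop_gtex: int = 6,
    clinvar_afcs: Sequence[float] = CLINVAR_TRUE_AFC,
    n_replicates: int = 2,
    depth: int = 85_000,
    clinvar_hdr: float = 0.05,
    hdr_range: tuple[float, float] = (0.001, 0.30),
    nhej_range: tuple[float, float] = (0.05, 0.60),
    technical_noise_sd: float = STUDY_TECHNICAL_NOISE_SD,
    seq_error: float = 0.001,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a full study-scale editing batch at counts level.

    The batch mirrors the assay's published design: 30 non-eQTL negative
    controls (true aFC 0), 33 fine-mapped eQTL variants (|aFC| 0.3-1.5,
    random sign), 6 stop-gained variants expected to trigger NMD (aFC -2.5
    to -0.5) and three ClinVar-style disease stops at the bundled truths
    (-1.39, -1.02, -0.17).  HDR rates are drawn log-uniformly over the range
    the assay observes (0.1-30%), so a realistic fraction of variants is
    later lost to the 0.4% HDR floor; the ClinVar variants use a fixed 5%
    HDR.
    Each variant gets ``n_replicates`` independent draws at median depth
    85,000 with per-replicate technical noise on the allelic ratio.

    Returns (counts, truth) DataFrames; ``counts`` has one row per
    (variant, material, replicate) in the tally schema, ``truth`` one row
    per variant with its generating parameters.
    """
    master = np.random.default_rng(seed)
    roster: list[tuple[str, str, float]] = []  # (variant_id, class, true_afc)
    for i in range(n_controls):
        roster.append((f"ctrl_{i:02d}", "control_non_eqtl", 0.0))
    for i in range(n_eqtl):
        mag = master.uniform(0.3, 1.5)
        sign = 1.0 if master.random() < 0.35 else -1.0
        roster.append((f"eqtl_{i:02d}", "eqtl", sign * mag))
    for i in range(n_stop_gtex):
        roster.append((f"stop_{i:02d}", "stop_gained_gtex", master.uniform(-2.5, -0.5)))
    for i, a in enumerate(clinvar_afcs):
        roster.append((f"clinvar_{i}", "stop_gained_disease", float(a)))

    lo, hi = hdr_range
    counts_rows = []
    truth_rows = []
    for vid, cls, true_afc in roster:
        if cls == "stop_gained_disease":
            h = clinvar_hdr
        else:
            h = float(np.exp(master.uniform(np.log(lo), np.log(hi))))
        q = float(master.uniform(*nhej_range))
        q = min(q, 0.99 - h)
        s = SimScenario(
            variant_id=vid,
            true_afc=true_afc,
            hdr_rate=h,
            nhej_rate=q,
            depth_gdna=depth,
            depth_cdna=depth,
            seq_error=seq_error,
            extra_noise_sd=technical_noise_sd,
            seed=_spawn_seed(master),
        )
        truth_rows.append(
            {
                "variant_id": vid,
                "class": cls,
                "true_afc": true_afc,
                "hdr_rate": h,
                "nhej_rate": q,
                "expected_afc": expected_afc(s),
            }
        )
        for rep in range(1, n_replicates + 1):
            rng = np.random.default_rng(np.random.SeedSequence([s.seed, rep]))
            g, c = simulate_counts(s, replicate=rep, rng=rng)
            for sc in (g, c):
                counts_rows.append(
                    {
                        "variant_id": sc.variant_id,
                        "class": cls,
                        "material": sc.material,
                        "replicate": sc.replicate,
                        "n_ref": sc.n_ref,
                        "n_alt": sc.n_alt,
                        "n_nhej": sc.n_nhej,
                    }
                )
    return pd.DataFrame(counts_rows), pd.DataFrame(truth_rows)
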