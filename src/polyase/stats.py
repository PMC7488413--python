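"""Allelic fold change and significance against an empirical control null.

The effect size of an edited variant is the allelic fold change

    aFC = log2( (Alt/Ref in cDNA) / (Alt/Ref in gDNA) )

zero meaning the variant leaves transcript abundance unchanged.  Because the
assay has no analytic error model, significance is assessed against an
empirical null built from negative-control variants (common synonymous
non-eQTL sites): a z-score from the control mean and standard deviation,
two-sided normal p-value, Bonferroni-corrected over the non-control variants
tested.  Group-level contrasts use a two-sided Wilcoxon rank-sum test
(location) and a variance-ratio F test, both implemented here with exact
small-sample enumeration where feasible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as _sps

from .exceptions import DegenerateNullError, UndefinedAfcError
from .qc import SampleCounts


def afc(cdna: SampleCounts, gdna: SampleCounts, pseudocount: float = 0) -> float:
    """Allelic fold change from one cDNA/gDNA sample pair.

    With the default ``pseudocount=0`` every allele count must be positive;
    QC (HDR rate >= 0.4% of >= 1000 reads) makes genuine zeros rare, so a
    zero raises instead of silently returning an infinity.
    """
    if cdna.variant_id != gdna.variant_id:
        raise ValueError(
            f"sample pair mismatch: {cdna.variant_id!r} vs {gdna.variant_id!r}"
        )
    counts = (cdna.n_alt, cdna.n_ref, gdna.n_alt, gdna.n_ref)
    if pseudocount == 0 and min(counts) == 0:
        raise UndefinedAfcError(
            f"{cdna.variant_id}: zero allele count; use a pseudocount (e.g. 0.5)"
        )
    pc = pseudocount
    return math.log2(
        ((cdna.n_alt + pc) / (cdna.n_ref + pc)) / ((gdna.n_alt + pc) / (gdna.n_ref + pc))
    )


def pooled_afc(
    cdna: Sequence[SampleCounts], gdna: Sequence[SampleCounts], pseudocount: float = 0
) -> float:
    """aFC from replicate counts pooled before forming the ratio (option)."""
    tot = lambda ss, f: sum(getattr(s, f) for s in ss)
    merged_c = SampleCounts(
        cdna[0].variant_id, "cDNA", 0, tot(cdna, "n_ref"), tot(cdna, "n_alt"), 0
    )
    merged_g = SampleCounts(
        gdna[0].variant_id, "gDNA", 0, tot(gdna, "n_ref"), tot(gdna, "n_alt"), 0
    )
    return afc(merged_c, merged_g, pseudocount=pseudocount)


def combine_replicates(afcs: Sequence[float]) -> tuple[float, float | None]:
    """Combine per-replicate aFCs: unweighted mean, plus sd when n >= 2."""
    vals = [float(v) for v in afcs]
    if not vals:
        raise ValueError("no replicate aFC values to combine")
    if not all(math.isfinite(v) for v in vals):
        raise ValueError("non-finite aFC value in replicates")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if len(vals) >= 2 else None
    return mean, sd


@dataclass(frozen=True)
class ControlNull:
    """Empirical null distribution of aFC over negative-control variants."""

    mean: float
    sd: float
    n: int
    variant_ids: tuple[str, ...]


def fit_control_null(
    control_effects: Sequence[tuple[str, float]],
    check_normality: bool = True,
) -> ControlNull:
    """Fit the control null: sample mean and sd (n-1) over control variants.

    Controls should be the non-eQTL synonymous class; synthetic third-allele
    controls are not suitable (a subset has reproducible large effects).
    A Shapiro-Wilk sanity check warns (advisory only) when the control aFCs
    look grossly non-normal, since the downstream z-test assumes normality.
    """
    ids = tuple(v for v, _ in control_effects)
    vals = np.asarray([a for _, a in control_effects], dtype=float)
    if vals.size < 2:
        raise DegenerateNullError("need at least 2 control variants for the null")
    sd = float(vals.std(ddof=1))
    if sd == 0:
        raise DegenerateNullError("control aFCs have zero spread")
    if check_normality and vals.size >= 3:
        p_norm = _sps.shapiro(vals).pvalue
        if p_norm < 0.01:
            warnings.warn(
                f"control aFCs deviate from normality (Shapiro p={p_norm:.2g}); "
                "z-test p-values are approximate",
                stacklevel=2,
            )
    return ControlNull(mean=float(vals.mean()), sd=sd, n=int(vals.size), variant_ids=ids)


@dataclass(frozen=True)
class ZTestResult:
    z: float
    p: float
    p_adj: float
    significant: bool


def variant_z_test(
    afc_value: float,
    null: ControlNull,
    m: int,
    alpha: float = 0.05,
    tail: str = "normal",
) -> ZTestResult:
    """Per-variant significance against the control null.

    z = (aFC - null.mean)/null.sd; two-sided p; Bonferroni over the m
    non-control variants tested.  ``tail="normal"`` is the assay's standard
    procedure (the null treated as known); ``tail="t"`` applies a
    finite-control-sample predictive correction (Student t with n-1 df and a
    sqrt(1 + 1/n) scale), which is better calibrated when the control set is
    small but is not the default.
    """
    if null.sd <= 0:
        raise DegenerateNullError("null sd must be positive")
    if m < 1:
        raise ValueError("m must be >= 1")
    z = (afc_value - null.mean) / null.sd
    if tail == "normal":
        p = 2.0 * _sps.norm.sf(abs(z))
    elif tail == "t":
        t = z / math.sqrt(1.0 + 1.0 / null.n)
        p = 2.0 * _sps.t.sf(abs(t), df=null.n - 1)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    p_adj = min(1.0, m * p)
    return ZTestResult(z=z, p=p, p_adj=p_adj, significant=bool(p_adj < alpha))


def wilcoxon_rank_sum(
    group_a: Sequence[float],
    group_b: Sequence[float],
    exact_max_n: int = 12,
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test with midranks for ties.

    Exact enumeration of all rank assignments when n_a + n_b <= exact_max_n;
    otherwise a normal approximation with tie correction and continuity
    correction.  Returns (rank-sum statistic of group_a, two-sided p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    na, nb = a.size, b.size
    n = na + nb
    pooled = np.concatenate([a, b])
    ranks = _sps.rankdata(pooled)  # midranks
    w = float(ranks[:na].sum())
    mu = na * (n + 1) / 2.0

    if n <= exact_max_n:
        obs = abs(w - mu)
        count = total = 0
        for idx in combinations(range(n), na):
            wp = ranks[list(idx)].sum()
            total += 1
            if abs(wp - mu) >= obs - 1e-9:
                count += 1
        return w, count / total

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
    var = na * nb / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return w, 1.0
    d = w - mu
    d -= 0.5 * np.sign(d)  # continuity correction toward the mean
    z = d / math.sqrt(var)
    return w, float(2.0 * _sps.norm.sf(abs(z)))


def variance_f_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided F test for a difference in variance between two groups."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 observations")
    va = float(a.var(ddof=1))
    vb = float(b.var(ddof=1))
    if vb == 0:
        raise ZeroDivisionError("zero variance in denominator group")
    f = va / vb
    dist = _sps.f(a.size - 1, b.size - 1)
    p = 2.0 * min(dist.cdf(f), dist.sf(f))
    return f, float(min(1.0, p))


def afc_heterozygote(
    ase_counts: Sequence[tuple[int, int]], min_reads: int = 50
) -> list[float]:
    """Per-individual aFC from allele-specific expression counts.

    Each element of ``ase_counts`` aggregates (ref, alt) read counts over
    heterozygous gene-body sites for one individual; individuals with
    ``min_reads`` or fewer total reads are dropped (strict: a total of
    exactly ``min_reads`` is excluded).
    """
    out: list[float] = []
    for ref_n, alt_n in ase_counts:
        if ref_n + alt_n <= min_reads:
            continue
        with np.errstate(divide="ignore"):
            out.append(float(np.log2(alt_n / ref_n)) if ref_n else float("inf"))
    if not out:
        warnings.warn("all individuals filtered by the read-depth threshold", stacklevel=2)
    return out
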