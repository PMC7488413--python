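"""Model/Results interface for a polyclonal allelic-expression experiment.

:class:`PolyclonalAssay` is built from a tidy table of per-sample allele
counts plus variant class labels; :meth:`PolyclonalAssay.fit` runs the full
analysis — QC cascade, per-replicate allelic fold change, replicate
combination, empirical control null, per-variant z-tests with Bonferroni
correction, and the group-level Wilcoxon and variance-F contrasts — and
returns an :class:`AssayResults` carrying the estimates, their
uncertainties, diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import qc as _qc
from . import stats as _stats
from .exceptions import DegenerateNullError, SchemaError, UndefinedAfcError
from .qc import SampleCounts

COUNT_COLUMNS = ["variant_id", "material", "replicate", "n_ref", "n_alt", "n_nhej"]
CONTROL_CLASSES = {"control_non_eqtl", "control_synthetic"}


class PolyclonalAssay:
    """Polyclonal editing assay model over a batch of variants.

    Parameters
    ----------
    counts
        Tidy DataFrame with columns ``variant_id, material, replicate,
        n_ref, n_alt, n_nhej`` (one row per sequenced sample) and either a
        ``class`` column or a separate ``variant_classes`` mapping.
    variant_classes
        Mapping variant_id -> variant class (``control_non_eqtl``,
        ``control_synthetic``, ``eqtl``, ``stop_gained_gtex``,
        ``stop_gained_disease``).  Non-eQTL controls form the empirical
        null; all non-control variants form the Bonferroni family.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        variant_classes: Mapping[str, str] | pd.Series | None = None,
        control_class: str = "control_non_eqtl",
        min_reads: int = _qc.QC_MIN_READS,
        max_nhej: float = _qc.QC_MAX_NHEJ,
        max_het_hdr: float = _qc.QC_MAX_HET_HDR,
        min_hdr: float = _qc.QC_MIN_HDR,
        alpha: float = 0.05,
    ) -> None:
        counts = pd.DataFrame(counts).copy()
        missing = [c for c in COUNT_COLUMNS if c not in counts.columns]
        if missing:
            raise SchemaError(f"counts table missing column(s): {', '.join(missing)}")
        if variant_classes is None:
            if "class" not in counts.columns:
                raise SchemaError("provide a 'class' column or variant_classes mapping")
            classes = counts.drop_duplicates("variant_id").set_index("variant_id")["class"]
        else:
            classes = pd.Series(dict(variant_classes))
        unknown = set(counts["variant_id"]) - set(classes.index)
        if unknown:
            raise SchemaError(f"no class label for variant(s): {sorted(unknown)[:5]}")
        self.counts = counts
        self.classes = classes.astype(str)
        self.control_class = control_class
        self.min_reads = min_reads
        self.max_nhej = max_nhej
        self.max_het_hdr = max_het_hdr
        self.min_hdr = min_hdr
        self.alpha = alpha

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_samples(
        cls, samples: Sequence[SampleCounts], variant_classes: Mapping[str, str], **kw
    ) -> "PolyclonalAssay":
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
        return cls(pd.DataFrame(rows), variant_classes, **kw)

    @classmethod
    def from_tsv(cls, path, **kw) -> "PolyclonalAssay":
        return cls(pd.read_csv(path, sep="\t"), **kw)

    # -- fitting ----------------------------------------------------------
    def _samples(self) -> list[SampleCounts]:
        return [
            SampleCounts(
                r.variant_id,
                r.material,
                int(r.replicate),
                int(r.n_ref),
                int(r.n_alt),
                int(r.n_nhej),
            )
            for r in self.counts.itertuples()
        ]

    def fit(
        self,
        pseudocount: float = 0,
        combine: str = "mean",
        tail: str = "normal",
    ) -> "AssayResults":
        """Run QC, effect estimation and significance testing.

        ``combine="mean"`` averages per-replicate aFCs (the default
        treatment of replicates as paired observations); ``"pool"`` sums
        counts across replicates before forming the ratio.
        """
        if combine not in ("mean", "pool"):
            raise ValueError("combine must be 'mean' or 'pool'")
        samples = self._samples()
        report = _qc.apply_qc_cascade(
            samples,
            min_reads=self.min_reads,
            max_nhej=self.max_nhej,
            max_het_hdr=self.max_het_hdr,
            min_hdr=self.min_hdr,
        )
        by_key = {(s.variant_id, s.material, s.replicate): s for s in samples}

        rows = []
        per_replicate: dict[str, list[float]] = {}
        for vid in sorted(report.surviving_variants):
            reps = sorted(r for v, r in report.surviving_pairs if v == vid)
            cdnas = [by_key[(vid, "cDNA", r)] for r in reps]
            gdnas = [by_key[(vid, "gDNA", r)] for r in reps]
            afcs = []
            for c, g in zip(cdnas, gdnas):
                try:
                    afcs.append(_stats.afc(c, g, pseudocount=pseudocount))
                except UndefinedAfcError:
                    if pseudocount == 0:
                        raise
            per_replicate[vid] = afcs
            if combine == "mean":
                mean, sd = _stats.combine_replicates(afcs)
            else:
                mean = _stats.pooled_afc(cdnas, gdnas, pseudocount=pseudocount)
                sd = _stats.combine_replicates(afcs)[1] if len(afcs) > 1 else None
            hdr = float(np.mean([_qc.hdr_rate(g) for g in gdnas]))
            rows.append(
                {
                    "variant_id": vid,
                    "variant_class": self.classes[vid],
                    "afc": mean,
                    "afc_sd": np.nan if sd is None else sd,
                    "n_replicates": len(reps),
                    "hdr_rate_gdna": hdr,
                }
            )
        effects = pd.DataFrame(
            rows,
            columns=[
                "variant_id",
                "variant_class",
                "afc",
                "afc_sd",
                "n_replicates",
                "hdr_rate_gdna",
            ],
        )

        ctrl = effects[effects["variant_class"] == self.control_class]
        if len(ctrl) < 2:
            raise DegenerateNullError(
                f"need >= 2 passing {self.control_class} variants to fit the null, "
                f"got {len(ctrl)}"
            )
        null = _stats.fit_control_null(list(zip(ctrl["variant_id"], ctrl["afc"])))

        is_control = effects["variant_class"].isin(CONTROL_CLASSES)
        m = int((~is_control).sum())
        zs, ps, padjs, sigs = [], [], [], []
        for _, row in effects.iterrows():
            res = _stats.variant_z_test(
                row["afc"], null, m=max(m, 1), alpha=self.alpha, tail=tail
            )
            zs.append(res.z)
            ps.append(res.p)
            if row["variant_class"] in CONTROL_CLASSES:
                padjs.append(np.nan)
                sigs.append(False)
            else:
                padjs.append(res.p_adj)
                sigs.append(res.significant)
        effects["z"] = zs
        effects["p"] = ps
        effects["p_adj"] = padjs
        effects["significant"] = sigs

        group_tests = self._group_tests(effects)
        return AssayResults(
            model=self,
            effects=effects,
            null=null,
            m=m,
            qc_report=report,
            group_tests=group_tests,
            per_replicate=per_replicate,
        )

    def _group_tests(self, effects: pd.DataFrame) -> dict[str, dict]:
        """Wilcoxon location contrasts vs controls and the variance F tests."""
        out: dict[str, dict] = {}
        ctrl_vals = effects.loc[
            effects["variant_class"] == self.control_class, "afc"
        ].to_list()
        for cls in sorted(set(effects["variant_class"]) - {self.control_class}):
            vals = effects.loc[effects["variant_class"] == cls, "afc"].to_list()
            if not vals or not ctrl_vals:
                continue
            w, p = _stats.wilcoxon_rank_sum(vals, ctrl_vals)
            entry = {"n": len(vals), "wilcoxon_w": w, "wilcoxon_p": p}
            if len(vals) >= 2 and len(ctrl_vals) >= 2:
                f, fp = _stats.variance_f_test(vals, ctrl_vals)
                entry["f"] = f
                entry["f_p"] = fp
                entry["var"] = float(np.var(vals, ddof=1))
                entry["var_control"] = float(np.var(ctrl_vals, ddof=1))
            out[f"{cls}_vs_{self.control_class}"] = entry
        return out


@dataclass
class AssayResults:
    """Fitted results of a :class:`PolyclonalAssay`."""

    model: PolyclonalAssay
    effects: pd.DataFrame
    null: _stats.ControlNull
    m: int
    qc_report: _qc.QcReport
    group_tests: dict[str, dict]
    per_replicate: dict[str, list[float]] = field(default_factory=dict)

    @property
    def significant_variants(self) -> list[str]:
        return self.effects.loc[self.effects["significant"], "variant_id"].to_list()

    def direction_match(self, reference_afc: Mapping[str, float]) -> pd.Series:
        """Whether each variant's aFC sign matches an external estimate."""
        ref = pd.Series(dict(reference_afc))
        joined = self.effects.set_index("variant_id")["afc"]
        common = joined.index.intersection(ref.index)
        return np.sign(joined[common]) == np.sign(ref[common])

    def summary(self) -> str:
        """Human-readable summary table of the fit."""
        e = self.effects
        lines = [
            "Polyclonal allelic-expression assay results",
            "=" * 60,
            f"variants passing QC: {len(e)}   "
            f"(of {self.model.counts['variant_id'].nunique()} assayed)",
            f"control null ({self.model.control_class}, n={self.null.n}): "
            f"mean={self.null.mean:+.3f}  sd={self.null.sd:.3f}",
            f"Bonferroni family size m={self.m}; alpha={self.model.alpha}",
            f"significant variants: {len(self.significant_variants)}",
            "",
            "Group tests vs control:",
        ]
        for name, t in self.group_tests.items():
            bits = [f"  {name}: W={t['wilcoxon_w']:.1f} p={t['wilcoxon_p']:.3g}"]
            if "f" in t:
                bits.append(f"F={t['f']:.3g} p={t['f_p']:.3g}")
            lines.append(" ".join(bits))
        lines += ["", "Per-variant effects (top |z|):"]
        show = e.reindex(e["z"].abs().sort_values(ascending=False).index).head(15)
        lines.append(
            show.to_string(
                index=False,
                float_format=lambda v: f"{v:.3g}",
                columns=[
                    "variant_id",
                    "variant_class",
                    "afc",
                    "n_replicates",
                    "z",
                    "p_adj",
                    "significant",
                ],
            )
        )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.effects.to_csv(path, sep="\t", index=False, na_rep=".")

    def plot_effects(self, ax=None):
        """Strip chart of aFC by variant class; significant variants marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        classes = sorted(self.effects["variant_class"].unique())
        rng = np.random.default_rng(0)
        for i, cls in enumerate(classes):
            sub = self.effects[self.effects["variant_class"] == cls]
            x = i + rng.uniform(-0.15, 0.15, len(sub))
            sig = sub["significant"].to_numpy(dtype=bool)
            ax.scatter(x[~sig], sub["afc"][~sig], s=18, alpha=0.7)
            ax.scatter(x[sig], sub["afc"][sig], s=30, marker="^", color="crimson")
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_xticks(range(len(classes)), classes, rotation=30, ha="right")
        ax.set_ylabel("aFC (log2)")
        return ax
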