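"""Efficiency-corrected qPCR relative expression.

Two complementary quantities are computed from ct tables with per-primer
amplification efficiencies E (fold per cycle, estimated from a dilution
standard curve as E = 10^(-1/slope)):

* fold change of a gene between treatment groups by the delta-delta-ct
  method normalized to a reference gene (ef1alpha in the source study) --
  by default the Pfaffl-style ratio E_gene^-(dct_gene) / E_ref^-(dct_ref),
  which reduces to the classic 2^-ddct when both efficiencies are 2;
* within-sample relative transcript abundance against an anchor gene,
  abundance_n = E_anchor^(ct_anchor) / E_n^(ct_n), so that a 6-cycle
  separation at E = 2 corresponds to a 64-fold difference.

Undetectable transcripts are represented as missing (NaN ct) and excluded
from statistics, never imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CtTable",
    "ExpressionResult",
    "efficiency_from_standard_curve",
    "ddct_fold_change",
    "relative_abundance",
    "read_ct_csv",
]

_REQUIRED_COLUMNS = ("sample_id", "treatment", "gene", "ct", "efficiency")


@dataclass
class CtTable:
    """Tidy gene x sample ct values with per-primer efficiencies.

    ``data`` columns: sample_id, treatment, gene, ct, efficiency.
    Undetectable genes carry NaN ct.  ``ref_gene`` names the internal
    control (reference) gene.
    """

    data: pd.DataFrame
    ref_gene: str

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"ct table missing columns: {missing}")
        if self.ref_gene not in set(self.data["gene"]):
            raise ValueError(f"reference gene {self.ref_gene!r} absent from table")
        eff = self.data["efficiency"]
        if ((eff <= 1.0) | (eff > 2.0)).any():
            raise ValueError("efficiencies must lie in (1, 2]")
        ct = self.data["ct"]
        if (ct[ct.notna()] <= 0).any():
            raise ValueError("detected ct values must be > 0")
        # every sample needs a reference-gene ct
        ref = self.data[self.data["gene"] == self.ref_gene]
        for sid in self.data["sample_id"].unique():
            row = ref[ref["sample_id"] == sid]
            if row.empty or row["ct"].isna().all():
                raise ValueError(f"sample {sid!r} lacks a reference-gene ct")

    def genes(self) -> list[str]:
        return sorted(set(self.data["gene"]))

    def undetected(self) -> pd.DataFrame:
        """Rows flagged undetectable (NaN ct)."""
        return self.data[self.data["ct"].isna()]


@dataclass
class ExpressionResult:
    """Per-sample values plus a group mean +/- SEM summary."""

    per_sample: pd.DataFrame
    summary: pd.DataFrame
    method: str
    excluded_samples: list[str] = field(default_factory=list)


def efficiency_from_standard_curve(dilution_log10, ct) -> tuple[float, float]:
    """Amplification efficiency from a cDNA dilution standard curve.

    Returns ``(E, percent_efficiency)`` where E = 10^(-1/m) with m the OLS
    slope of ct on log10(input), and percent efficiency = (E - 1) * 100.
    A perfect doubling assay has m = -3.3219 and E = 2 (100%).
    """
    x = np.asarray(dilution_log10, dtype=float)
    y = np.asarray(ct, dtype=float)
    if len(x) < 3:
        raise ValueError("standard curve needs >= 3 dilution points")
    if len(np.unique(x)) < 2:
        raise ValueError("standard curve needs >= 2 distinct dilutions")
    xbar = x.mean()
    m = float(np.sum((x - xbar) * (y - y.mean())) / np.sum((x - xbar) ** 2))
    if m >= 0:
        raise ValueError("ct must decrease with template input (slope must be < 0)")
    e = 10.0 ** (-1.0 / m)
    return e, (e - 1.0) * 100.0


def _gene_frame(table: CtTable, gene: str) -> pd.DataFrame:
    g = table.data[table.data["gene"] == gene]
    if g.empty:
        raise ValueError(f"gene {gene!r} absent from table")
    return g


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.std(x, ddof=1) / math.sqrt(len(x))) if len(x) > 1 else math.nan


def ddct_fold_change(
    table: CtTable,
    gene: str,
    control_group: str,
    treated_group: str,
    method: str = "pfaffl",
) -> ExpressionResult:
    """Fold change of ``gene`` in ``treated_group`` vs ``control_group``.

    method="pfaffl" (default): per sample,
        fold = E_gene^-(ct_gene - mean ct_gene,control)
               / E_ref^-(ct_ref - mean ct_ref,control),
    which corrects target and reference with their own efficiencies and is
    invariant to per-sample loading offsets.
    method="target_only": fold = E_gene^-(dct - mean dct_control) with
    dct = ct_gene - ct_ref (single-efficiency form).
    method="classic": the E=2 special case 2^-ddct.

    Samples missing the gene or reference ct are excluded with a log
    entry in ``excluded_samples``.  Control-group per-sample folds are
    reported too (their mean is 1 by construction only on the log scale).
    """
    if method not in ("pfaffl", "target_only", "classic"):
        raise ValueError(f"unknown method {method!r}")
    g = _gene_frame(table, gene)
    r = _gene_frame(table, table.ref_gene)
    e_gene = float(g["efficiency"].iloc[0])
    e_ref = float(r["efficiency"].iloc[0])
    if method == "classic":
        e_gene = e_ref = 2.0

    merged = pd.merge(
        g[["sample_id", "treatment", "ct"]],
        r[["sample_id", "ct"]],
        on="sample_id",
        suffixes=("_gene", "_ref"),
    )
    excluded = sorted(merged.loc[merged[["ct_gene", "ct_ref"]].isna().any(axis=1), "sample_id"])
    merged = merged.dropna(subset=["ct_gene", "ct_ref"])
    ctrl = merged[merged["treatment"] == control_group]
    trt = merged[merged["treatment"] == treated_group]
    if ctrl.empty or trt.empty:
        raise ValueError("both control and treated groups must have detected samples")

    if method == "pfaffl":
        dct_g = merged["ct_gene"] - ctrl["ct_gene"].mean()
        dct_r = merged["ct_ref"] - ctrl["ct_ref"].mean()
        fold = e_gene ** (-dct_g) / e_ref ** (-dct_r)
    else:
        dct = merged["ct_gene"] - merged["ct_ref"]
        ddct = dct - (ctrl["ct_gene"] - ctrl["ct_ref"]).mean()
        fold = e_gene ** (-ddct)

    per_sample = merged[["sample_id", "treatment"]].copy()
    per_sample["gene"] = gene
    per_sample["fold_change"] = fold.to_numpy()
    rows = []
    for grp, sub in per_sample.groupby("treatment"):
        vals = sub["fold_change"].to_numpy()
        rows.append(
            {"gene": gene, "treatment": grp, "mean": float(vals.mean()),
             "sem": _sem(vals), "n": len(vals)}
        )
    return ExpressionResult(
        per_sample=per_sample,
        summary=pd.DataFrame(rows),
        method=f"ddct-{method}",
        excluded_samples=excluded,
    )


def relative_abundance(table: CtTable, anchor_gene: str) -> ExpressionResult:
    """Within-sample abundance of every gene relative to ``anchor_gene``.

    Per sample, abundance_n = E_anchor^(ct_anchor) / E_n^(ct_n); the
    anchor's own value is 1 in every sample.  Group means +/- SEM are
    reported per gene and treatment; samples lacking an anchor ct are
    excluded.
    """
    a = _gene_frame(table, anchor_gene)
    e_anchor = float(a["efficiency"].iloc[0])
    anchor_ct = a.set_index("sample_id")["ct"]
    excluded = sorted(anchor_ct[anchor_ct.isna()].index)
    rows = []
    for gene in table.genes():
        g = _gene_frame(table, gene)
        e_n = float(g["efficiency"].iloc[0])
        for _, row in g.iterrows():
            sid = row["sample_id"]
            if sid in excluded or sid not in anchor_ct.index:
                continue
            if math.isnan(row["ct"]):
                continue
            ab = e_anchor ** float(anchor_ct.loc[sid]) / e_n ** float(row["ct"])
            rows.append(
                {"sample_id": sid, "treatment": row["treatment"], "gene": gene,
                 "relative_abundance": ab}
            )
    per_sample = pd.DataFrame(rows)
    summary_rows = []
    for (gene, grp), sub in per_sample.groupby(["gene", "treatment"]):
        vals = sub["relative_abundance"].to_numpy()
        summary_rows.append(
            {"gene": gene, "treatment": grp, "mean": float(vals.mean()),
             "sem": _sem(vals), "n": len(vals)}
        )
    return ExpressionResult(
        per_sample=per_sample,
        summary=pd.DataFrame(summary_rows),
        method=f"anchored-abundance[{anchor_gene}]",
        excluded_samples=[str(s) for s in excluded],
    )


def read_ct_csv(path, ref_gene: str) -> CtTable:
    """Read a ct CSV with columns sample_id, treatment, gene, ct, efficiency."""
    return CtTable(data=pd.read_csv(path), ref_gene=ref_gene)
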