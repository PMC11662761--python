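"""Relative gene-expression analysis: triplicate collapse, geNorm M, ddCq.

Quantification cycles (Cq) from technical replicates are averaged per
(sample, gene); candidate reference genes are ranked by the geNorm stability
value M (mean standard deviation of pairwise log2 expression ratios against
the other candidates; lower is more stable; conventional acceptance cutoffs
are 1.0 for tissue and 0.5 for cell culture); and relative expression is
computed by the ddCq method with one or more reference genes, assuming an
amplification efficiency of 2 (perfect doubling per cycle):

    dCq  = Cq_target - mean(Cq_references)          per sample
    ddCq = dCq - mean(dCq over control-group samples)
    fold = 2 ** (-ddCq)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CqTable",
    "GeNormResult",
    "DdcqResult",
    "read_cq_table",
    "collapse_triplicates",
    "genorm_m",
    "relative_expression_ddcq",
]

GENORM_THRESHOLD_TISSUE = 1.0
GENORM_THRESHOLD_CULTURE = 0.5

_REQUIRED_COLS = ["sample_id", "group", "gene", "replicate", "cq"]


@dataclass
class CqTable:
    """Long-format table of raw technical-replicate Cq values.

    ``data`` has columns sample_id, group, gene, replicate, cq.  Every
    (sample, gene) pair must carry at least one finite positive Cq.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED_COLS if c not in self.data.columns]
        if missing:
            raise ValueError(f"CqTable missing columns: {missing}")
        cq = self.data["cq"].to_numpy(dtype=float)
        if not np.all(np.isfinite(cq)) or np.any(cq <= 0):
            raise ValueError("all Cq values must be positive and finite")
        dup = self.data.duplicated(subset=["sample_id", "gene", "replicate"])
        if dup.any():
            rows = self.data.loc[dup, ["sample_id", "gene", "replicate"]]
            raise ValueError(
                f"duplicate (sample, gene, replicate) rows:\n{rows.to_string(index=False)}"
            )


@dataclass
class GeNormResult:
    """Per-gene geNorm stability values and threshold flags."""

    m_values: pd.Series  # index: gene, value: M
    threshold: float

    @property
    def stable(self) -> pd.Series:
        """Genes with M below the acceptance threshold."""
        return self.m_values < self.threshold

    def failing_genes(self) -> list[str]:
        return sorted(self.m_values.index[~self.stable])


@dataclass
class DdcqResult:
    """Per-(sample, target) dCq / ddCq / fold change and group summaries."""

    per_sample: pd.DataFrame  # sample_id, group, gene, dcq, ddcq, fold
    group_summary: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.group_summary is None:
            g = (
                self.per_sample.groupby(["gene", "group"], sort=True)
                .agg(
                    mean_fold=("fold", "mean"),
                    geomean_fold=("fold", lambda f: float(np.exp(np.mean(np.log(f))))),
                    n=("fold", "size"),
                )
                .reset_index()
            )
            self.group_summary = g


def read_cq_table(path) -> CqTable:
    """Read a raw Cq CSV (sample_id, group, gene, replicate, cq)."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    return CqTable(df)


def collapse_triplicates(
    table: CqTable,
    *,
    reject_outliers: bool = False,
    outlier_cycles: float = 0.5,
) -> pd.DataFrame:
    """Mean Cq per (sample, gene) across technical replicates.

    Plain arithmetic averaging of the available replicates; pairs with fewer
    than three replicates are tolerated with a warning.  With
    ``reject_outliers`` a replicate more than ``outlier_cycles`` from the
    replicate median is dropped first (off by default).

    Returns
    -------
    DataFrame with columns sample_id, group, gene, cq_mean, n_replicates.
    """
    df = table.data.copy()
    if reject_outliers:
        med = df.groupby(["sample_id", "gene"])["cq"].transform("median")
        keep = (df["cq"] - med).abs() <= outlier_cycles
        df = df[keep]
        if df.groupby(["sample_id", "gene"]).size().min() < 1:
            raise ValueError("outlier rejection removed all replicates for a pair")
    out = (
        df.groupby(["sample_id", "group", "gene"], sort=True)["cq"]
        .agg(cq_mean="mean", n_replicates="size")
        .reset_index()
    )
    short = out[out["n_replicates"] < 3]
    if len(short):
        warnings.warn(
            f"{len(short)} (sample, gene) pairs have fewer than 3 replicates",
            stacklevel=2,
        )
    return out


def _cq_matrix(collapsed: pd.DataFrame) -> pd.DataFrame:
    """Pivot collapsed Cq to a samples x genes matrix."""
    return collapsed.pivot(index="sample_id", columns="gene", values="cq_mean")


def genorm_m(
    collapsed: pd.DataFrame,
    candidates: Sequence[str],
    *,
    threshold: float = GENORM_THRESHOLD_TISSUE,
) -> GeNormResult:
    """geNorm stability value M for each candidate reference gene.

    For genes j, k the per-sample log2 expression ratio is Cq_k - Cq_j
    (with efficiency 2, expression = 2**(-Cq)); V_jk is its standard
    deviation over samples (ddof=1) and M_j the mean of V_jk over all
    k != j.  Lower M means more stable expression across samples.

    Parameters
    ----------
    collapsed : DataFrame
        Output of :func:`collapse_triplicates` (or any frame with
        sample_id / gene / cq_mean columns).
    candidates : sequence of str
        Candidate reference genes (at least two), each measured in every
        sample considered.
    threshold : float
        Acceptance cutoff recorded on the result (1.0 tissue, 0.5 culture).
    """
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ValueError("geNorm requires at least two candidate genes")
    mat = _cq_matrix(collapsed)
    missing = [g for g in candidates if g not in mat.columns]
    if missing:
        raise ValueError(f"candidate genes not in table: {missing}")
    sub = mat[candidates].dropna()
    if len(sub) < 2:
        raise ValueError("geNorm requires at least two samples with all candidates")
    m = {}
    for j in candidates:
        sds = [
            float(np.std(sub[k] - sub[j], ddof=1)) for k in candidates if k != j
        ]
        m[j] = float(np.mean(sds))
    return GeNormResult(m_values=pd.Series(m, name="M"), threshold=threshold)


def relative_expression_ddcq(
    collapsed: pd.DataFrame,
    targets: Sequence[str],
    references: Sequence[str],
    control_group: str,
    *,
    calibrator_sample: str | None = None,
) -> DdcqResult:
    """Relative expression of target genes by the ddCq method.

    Per sample, dCq = Cq_target - mean(Cq over reference genes) (arithmetic
    mean of reference Cq, equivalent to geometric-mean expression
    normalization).  ddCq centres dCq on the control group's mean dCq —
    so the control group's geometric-mean fold is exactly 1 — unless a
    single ``calibrator_sample`` is named, in which case that sample's dCq
    is the reference point.  Fold change = 2**(-ddCq).

    Samples missing a target or reference measurement are dropped with a
    warning; a gene listed both as target and reference is an error.
    """
    targets = list(targets)
    references = list(references)
    if not references:
        raise ValueError("at least one reference gene is required")
    overlap = sorted(set(targets) & set(references))
    if overlap:
        raise ValueError(f"genes listed as both target and reference: {overlap}")
    mat = _cq_matrix(collapsed)
    groups = collapsed.drop_duplicates("sample_id").set_index("sample_id")["group"]
    missing_ref = [g for g in references if g not in mat.columns]
    if missing_ref:
        raise ValueError(f"reference genes not measured: {missing_ref}")

    ref_mean = mat[references].mean(axis=1)
    rows = []
    for gene in targets:
        if gene not in mat.columns:
            raise ValueError(f"target gene not measured: {gene}")
        dcq = mat[gene] - ref_mean
        ok = dcq.notna()
        dropped = sorted(dcq.index[~ok])
        if dropped:
            warnings.warn(
                f"gene {gene!r}: samples dropped (missing measurements): {dropped}",
                stacklevel=2,
            )
        dcq = dcq[ok]
        grp = groups.reindex(dcq.index)
        if calibrator_sample is not None:
            if calibrator_sample not in dcq.index:
                raise ValueError(f"calibrator sample {calibrator_sample!r} missing for {gene!r}")
            anchor = float(dcq.loc[calibrator_sample])
        else:
            ctrl = dcq[grp == control_group]
            if ctrl.empty:
                raise ValueError(f"control group {control_group!r} has no samples for {gene!r}")
            anchor = float(ctrl.mean())
        ddcq = dcq - anchor
        for sid in dcq.index:
            rows.append(
                {
                    "sample_id": sid,
                    "group": grp.loc[sid],
                    "gene": gene,
                    "dcq": float(dcq.loc[sid]),
                    "ddcq": float(ddcq.loc[sid]),
                    "fold": float(2.0 ** (-ddcq.loc[sid])),
                }
            )
    return DdcqResult(per_sample=pd.DataFrame(rows))
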