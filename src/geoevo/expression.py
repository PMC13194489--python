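"""Relative gene expression from qRT-PCR threshold cycles (2^-ddCT method).

Expression of each target gene is normalized to a housekeeping gene within
each sample (dCT = CT_target - CT_housekeeping) and then to a reference
strain within each gene x condition group (ddCT = dCT - mean reference
dCT), giving fold change = 2^-ddCT.  Amplification efficiency is fixed at
2 per cycle (no efficiency correction).  Replicates are aggregated on the
log2 scale, so the reported fold is a geometric mean and the reference
strain's own mean fold is exactly 1 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["strain", "condition", "gene", "replicate", "ct"]


@dataclass
class ExpressionResult:
    """Per (strain, condition, gene) fold changes with replicate dispersion.

    ``summary`` has one row per group: fold (geometric mean), log2_sd, n.
    ``replicates`` keeps per-replicate folds for downstream contrasts.
    """

    summary: pd.DataFrame
    replicates: pd.DataFrame
    housekeeping_gene: str
    reference_strain: str

    def fold(self, strain: str, gene: str, condition=None) -> float:
        df = self.summary
        m = (df.strain == strain) & (df.gene == gene)
        if condition is not None:
            m &= df.condition == condition
        sel = df[m]
        if len(sel) != 1:
            raise KeyError(f"{strain}/{gene}/{condition}: {len(sel)} rows matched")
        return float(sel.fold.iloc[0])


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"CT table missing columns {sorted(missing)}")
    return df


def delta_delta_ct(table: pd.DataFrame, housekeeping_gene: str,
                   reference_strain: str) -> ExpressionResult:
    """Relative expression by the 2^-ddCT method.

    ``table`` needs columns strain, condition, gene, replicate, ct.  Every
    (strain, condition, replicate) sample must include the housekeeping
    gene; the reference strain must be present for every gene x condition.
    """
    df = table.copy()
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"CT table missing columns {sorted(missing)}")
    if not np.isfinite(df.ct).all():
        raise ValueError("CT values must be finite")

    hk = df[df.gene == housekeeping_gene].rename(columns={"ct": "ct_hk"})
    if hk.empty:
        raise ValueError(f"housekeeping gene {housekeeping_gene!r} absent from table")
    targets = df[df.gene != housekeeping_gene]
    merged = targets.merge(
        hk[["strain", "condition", "replicate", "ct_hk"]],
        on=["strain", "condition", "replicate"], how="left")
    if merged.ct_hk.isna().any():
        bad = merged[merged.ct_hk.isna()][["strain", "condition", "replicate"]]
        raise ValueError(
            f"samples missing the housekeeping gene:\n{bad.drop_duplicates()}")
    merged["dct"] = merged.ct - merged.ct_hk

    ref = merged[merged.strain == reference_strain]
    if ref.empty:
        raise ValueError(f"reference strain {reference_strain!r} absent from table")
    ref_mean = (ref.groupby(["condition", "gene"], as_index=False)
                .dct.mean().rename(columns={"dct": "ref_dct"}))
    merged = merged.merge(ref_mean, on=["condition", "gene"], how="left")
    if merged.ref_dct.isna().any():
        bad = merged[merged.ref_dct.isna()][["condition", "gene"]].drop_duplicates()
        raise ValueError(f"reference strain missing for groups:\n{bad}")
    merged["ddct"] = merged.dct - merged.ref_dct
    merged["fold"] = 2.0 ** (-merged.ddct)

    summary = (
        merged.groupby(["strain", "condition", "gene"], as_index=False)
        .agg(n=("fold", "size"),
             log2_mean=("ddct", lambda x: -x.mean()),
             log2_sd=("ddct", "std"))
    )
    summary["fold"] = 2.0 ** summary.log2_mean
    summary = summary[["strain", "condition", "gene", "fold", "log2_sd", "n"]]
    reps = merged[["strain", "condition", "gene", "replicate", "dct", "ddct", "fold"]]
    return ExpressionResult(summary, reps, housekeeping_gene, reference_strain)


def expression_contrast(result: ExpressionResult, gene: str,
                        group_a: list[str], group_b: list[str],
                        condition=None) -> tuple[float, float, float]:
    """Contrast per-replicate fold changes between two strain groups.

    Independent t-test on log2 folds (symmetric under fold inversion).
    Returns (geometric mean fold of group a, of group b, p).  With a single
    replicate in either group no test is possible and p is nan (point
    estimates are still returned).
    """
    df = result.replicates
    m = df.gene == gene
    if condition is not None:
        m &= df.condition == condition
    df = df[m]
    xa = np.log2(df[df.strain.isin(group_a)].fold.to_numpy())
    xb = np.log2(df[df.strain.isin(group_b)].fold.to_numpy())
    if len(xa) == 0 or len(xb) == 0:
        raise ValueError("empty strain group in contrast")
    fa, fb = float(2 ** xa.mean()), float(2 ** xb.mean())
    if len(xa) < 2 or len(xb) < 2:
        return fa, fb, float("nan")
    return fa, fb, float(stats.ttest_ind(xa, xb).pvalue)


def write_expression_csv(result: ExpressionResult, path: str | Path) -> None:
    result.summary.rename(columns={"log2_sd": "sd"}).to_csv(path, index=False)
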