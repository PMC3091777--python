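"""Relative qPCR quantification (2^-ddCt) and array-vs-qPCR rank concordance.

Quantitative PCR reports a threshold cycle Ct per well; one extra cycle means
half the starting template, so with amplification efficiency exactly 2 the
relative expression of a target gene between exercised and control muscle,
normalized to a reference gene measured in the same samples, is

    dCt      = Ct_target - Ct_reference          (per condition)
    ddCt     = dCt_exercised - dCt_control
    fold     = 2 ** (-ddCt)

Technical replicates (duplicate wells) are averaged on the Ct scale before
differencing.  Cross-platform validation compares per-gene fold changes from
the array (2**b for the representative probe's contrast) with qPCR folds via
Spearman rank correlation, which is invariant to monotone calibration
differences between the platforms.

A Ct panel is a long-format table with columns
``gene, comparison, subject, arm, well_role, ct`` where ``arm`` is
``exercised``/``control`` and ``well_role`` is ``target``/``reference``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConcordanceResult",
    "ddct_fold",
    "ddct_table",
    "spearman_concordance",
    "array_fold_table",
    "platform_concordance",
    "PANEL_COLUMNS",
]

PANEL_COLUMNS = ("gene", "comparison", "subject", "arm", "well_role", "ct")


@dataclass(frozen=True)
class ConcordanceResult:
    rho: float
    p: float
    n: int


def _mean_ct(panel: pd.DataFrame, arm: str, role: str) -> float:
    sel = panel[(panel["arm"] == arm) & (panel["well_role"] == role)]
    if len(sel) == 0:
        raise ValueError(f"missing {role} well(s) for arm {arm!r}")
    ct = sel["ct"].to_numpy(dtype=float)
    if (ct <= 0).any():
        raise ValueError("Ct values must be positive")
    return float(ct.mean())


def ddct_fold(panel_entry: pd.DataFrame) -> float:
    """2^-ddCt fold change for one gene in one subject.

    ``panel_entry`` holds that subject's wells: target and reference rows for
    both arms, replicates as extra rows (averaged per well group).
    """
    dct_ex = _mean_ct(panel_entry, "exercised", "target") - _mean_ct(
        panel_entry, "exercised", "reference"
    )
    dct_ctl = _mean_ct(panel_entry, "control", "target") - _mean_ct(
        panel_entry, "control", "reference"
    )
    return float(2.0 ** (-(dct_ex - dct_ctl)))


def ddct_table(panel: pd.DataFrame) -> pd.DataFrame:
    """Per (gene, comparison, subject) fold changes for a whole Ct panel."""
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"Ct panel missing column(s) {missing}")
    rows = []
    for (gene, comp, subject), grp in panel.groupby(
        ["gene", "comparison", "subject"], sort=True
    ):
        rows.append((gene, comp, subject, ddct_fold(grp)))
    return pd.DataFrame(rows, columns=["gene", "comparison", "subject", "fold"])


def spearman_concordance(x, y, exact: bool = False) -> ConcordanceResult:
    """Spearman rank correlation with average-rank ties.

    The p-value uses the t-approximation with n-2 degrees of freedom; with
    ``exact=True`` (n <= 9) it is the two-sided exact permutation tail of
    |rho| instead.  Constant input yields rho = nan (flagged, no p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need >= 3 pairs for a correlation p-value")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return ConcordanceResult(rho=float("nan"), p=float("nan"), n=n)
    if exact:
        if n > 9:
            raise ValueError("exact permutation p-value supported only for n <= 9")
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        obs = np.corrcoef(rx, ry)[0, 1]
        count = 0
        total = 0
        for perm in permutations(ry):
            r = np.corrcoef(rx, np.asarray(perm))[0, 1]
            count += abs(r) >= abs(obs) - 1e-12
            total += 1
        return ConcordanceResult(rho=float(obs), p=count / total, n=n)
    rho, p = stats.spearmanr(x, y)
    return ConcordanceResult(rho=float(rho), p=float(p), n=n)


def array_fold_table(
    gene_stats_by_comparison: dict[str, pd.DataFrame],
    gene_map: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene array fold changes (2**b) using the representative probe.

    For genes measured by several probes the probe with the highest mean
    signal intensity ``a`` in that comparison is used.  ``b`` is the mean
    contrast across subjects, so 2**b is the (log-scale averaged) fold.
    """
    rows = []
    for comp, gstats in gene_stats_by_comparison.items():
        df = gstats[["b", "a"]].copy()
        df["probe"] = df.index
        genes = gene_map.loc[df.index] if gene_map is not None else pd.Series(
            df.index, index=df.index
        )
        df = df.assign(gene=genes.to_numpy())
        rep = (
            df.sort_values(["gene", "a", "probe"], kind="stable")
            .groupby("gene", sort=True)
            .tail(1)
        )
        for _, r in rep.iterrows():
            rows.append((r["gene"], comp, float(2.0 ** r["b"])))
    return pd.DataFrame(rows, columns=["gene", "comparison", "fold_array"])


def platform_concordance(
    gene_stats_by_comparison: dict[str, pd.DataFrame],
    qpcr_panel: pd.DataFrame,
    gene_map: pd.Series | None = None,
) -> tuple[ConcordanceResult, pd.DataFrame]:
    """Spearman concordance between array and qPCR fold changes.

    qPCR folds are averaged over subjects on the log2 scale (then
    exponentiated) per gene x comparison; array folds come from
    :func:`array_fold_table`.  Returns the concordance result plus the
    paired fold table (gene, comparison, fold_array, fold_qpcr).
    """
    folds = ddct_table(qpcr_panel)
    folds["log2_fold"] = np.log2(folds["fold"])
    qpcr = (
        folds.groupby(["gene", "comparison"], sort=True)["log2_fold"]
        .mean()
        .pipe(lambda s: 2.0 ** s)
        .rename("fold_qpcr")
        .reset_index()
    )
    array = array_fold_table(gene_stats_by_comparison, gene_map)
    pairs = array.merge(qpcr, on=["gene", "comparison"], how="inner")
    if len(pairs) < 3:
        raise ValueError(
            f"need >= 3 overlapping gene x comparison pairs, found {len(pairs)}"
        )
    res = spearman_concordance(pairs["fold_array"].to_numpy(), pairs["fold_qpcr"].to_numpy())
    return res, pairs[["gene", "comparison", "fold_array", "fold_qpcr"]]
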