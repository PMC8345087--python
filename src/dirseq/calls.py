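"""Regulatory-SNP calling and allele-association statistics.

A SNP is called regulatory in a cell line when the risk/protective activity
fold change passes a two-sided gate (< 0.8 or > 1.2) *and* the replicate
activities differ significantly (two-tailed two-sample t-test, p < 0.05).
The default test pools variances (Student); the Welch unequal-variance
variant is used for genotype–expression (eQTL) comparisons and is available
for the reporter call as a robustness option.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, InsufficientDataError, ValidationError


@dataclass
class CallConfig:
    """Thresholds of the regulatory-SNP definition."""

    fc_low: float = 0.8
    fc_high: float = 1.2
    alpha: float = 0.05
    test: str = "student"  # or "welch"

    def __post_init__(self) -> None:
        if not 0 < self.fc_low < 1 < self.fc_high:
            raise ValidationError("need 0 < fc_low < 1 < fc_high")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.test not in ("student", "welch"):
            raise ValidationError(f"unknown test {self.test!r}")


@dataclass
class RegulatoryCall:
    """Per SNP, per cell line: fold change, significance, and the call."""

    rsid: str
    cell_line: str
    fc: float
    log2fc: float
    p_value: float
    call: str  # one of {down, up, none}
    n_risk: int
    n_prot: int


def _ttest(risk: np.ndarray, prot: np.ndarray, kind: str) -> tuple[float, float]:
    """Two-tailed two-sample t-test; degenerate zero-variance cases resolved
    by exact separation (p=0 if the constant groups differ, else p=1)."""
    if np.var(risk) == 0 and np.var(prot) == 0:
        same = np.isclose(risk.mean(), prot.mean())
        return (0.0, 1.0) if same else (np.inf, 0.0)
    t, p = stats.ttest_ind(risk, prot, equal_var=(kind == "student"))
    return float(t), float(p)


def call_regulatory(
    risk_acts: Sequence[float],
    prot_acts: Sequence[float],
    cfg: CallConfig | None = None,
    rsid: str = "",
    cell_line: str = "",
) -> RegulatoryCall:
    """Compare replicate activities of the two alleles and apply the call rule.

    fc = mean(risk) / mean(protective) on the linear activity scale;
    call = "down" if fc < fc_low and p < alpha, "up" if fc > fc_high and
    p < alpha, otherwise "none".
    """
    cfg = cfg or CallConfig()
    risk = np.asarray(risk_acts, dtype=float)
    prot = np.asarray(prot_acts, dtype=float)
    risk = risk[~np.isnan(risk)]
    prot = prot[~np.isnan(prot)]
    if len(risk) < 2 or len(prot) < 2:
        raise InsufficientDataError(
            f"{rsid or 'SNP'}/{cell_line or 'cell line'}: need >= 2 replicates per allele"
        )
    if (risk <= 0).any() or (prot <= 0).any():
        raise ValidationError("activities must be positive")
    fc = float(risk.mean() / prot.mean())
    _, p = _ttest(risk, prot, cfg.test)
    if fc < cfg.fc_low and p < cfg.alpha:
        call = "down"
    elif fc > cfg.fc_high and p < cfg.alpha:
        call = "up"
    else:
        call = "none"
    return RegulatoryCall(
        rsid=rsid,
        cell_line=cell_line,
        fc=fc,
        log2fc=float(np.log2(fc)),
        p_value=p,
        call=call,
        n_risk=len(risk),
        n_prot=len(prot),
    )


def calls_to_frame(calls: Sequence[RegulatoryCall]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in calls])


def fc_matrix(calls: Sequence[RegulatoryCall]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SNP x cell-line matrix of log2(risk/protective) plus a significance mask.

    Cells absent from ``calls`` are NaN in the matrix and False in the mask;
    a duplicated (rsid, cell_line) pair is an error.
    """
    df = calls_to_frame(list(calls))
    if df.empty:
        return pd.DataFrame(), pd.DataFrame()
    if df.duplicated(["rsid", "cell_line"]).any():
        dupes = df[df.duplicated(["rsid", "cell_line"])][["rsid", "cell_line"]]
        raise InputError(f"duplicate calls for {dupes.to_records(index=False).tolist()}")
    matrix = df.pivot(index="rsid", columns="cell_line", values="log2fc")
    mask = (
        df.assign(sig=df["call"] != "none")
        .pivot(index="rsid", columns="cell_line", values="sig")
        .isin([True])
    )
    return matrix, mask


def plot_fc_heatmap(matrix: pd.DataFrame, mask: pd.DataFrame, path: str) -> None:
    """Render the log2 fold-change matrix as an annotated heatmap PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1 + 0.6 * matrix.shape[1], 1 + 0.3 * matrix.shape[0]))
    vmax = np.nanmax(np.abs(matrix.to_numpy())) or 1.0
    im = ax.imshow(matrix.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=45, ha="right")
    ax.set_yticks(range(matrix.shape[0]), matrix.index)
    for i in range(matrix.shape[0]):
        for j in range(matrix.shape[1]):
            val = matrix.iat[i, j]
            if np.isfinite(val):
                star = "*" if mask.iat[i, j] else ""
                ax.text(j, i, f"{val:.2f}{star}", ha="center", va="center", fontsize=7)
    fig.colorbar(im, ax=ax, label="log2(risk/protective)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def welch_association(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Welch two-tailed t-tests between genotype-class expression groups.

    For two groups a single test; for three genotype classes all three
    pairwise tests.  Returns a table with columns group1, group2, t, p,
    df (Welch–Satterthwaite degrees of freedom).
    """
    if len(groups) < 2:
        raise InsufficientDataError("need at least two genotype groups")
    arrays = {}
    for name, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if len(arr) < 2:
            raise InsufficientDataError(f"group {name!r} has fewer than 2 observations")
        arrays[name] = arr
    rows = []
    for (n1, g1), (n2, g2) in combinations(arrays.items(), 2):
        t, p = _ttest(g1, g2, "welch")
        v1, v2 = g1.var(ddof=1), g2.var(ddof=1)
        se1, se2 = v1 / len(g1), v2 / len(g2)
        if se1 + se2 > 0:
            df = (se1 + se2) ** 2 / (se1**2 / (len(g1) - 1) + se2**2 / (len(g2) - 1))
        else:
            df = float(len(g1) + len(g2) - 2)
        rows.append({"group1": n1, "group2": n2, "t": t, "p": p, "df": float(df)})
    return pd.DataFrame(rows)
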