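"""Supporting statistics for a recessive-mutant study.

Three small tools: the 3:1 Mendelian segregation chi-square test used to
establish recessive single-locus inheritance; a fold-change + Wilcoxon
rank-sum screen for differentially accumulated metabolites (up if the
mutant/wild mean ratio is >= 2, down if <= 0.5); and a log2 FPKM-ratio
ranking of a gene family's expression difference between mutant and wild
type.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SegregationResult",
    "ScreenRecord",
    "segregation_chisq",
    "chisq_critical",
    "rank_sum_test",
    "metabolite_screen",
    "expression_log2_ratio",
]

#: Largest per-group size for which the rank-sum null is fully enumerated.
EXACT_ENUMERATION_MAX = 10


@dataclass(frozen=True)
class SegregationResult:
    n_wild: int
    n_mutant: int
    expected_ratio: tuple[float, float]
    chi2: float
    df: int
    critical_value: float
    consistent: bool


@dataclass(frozen=True)
class ScreenRecord:
    analyte_id: str
    mean_mut: float
    mean_wt: float
    fold_change: float  # NaN when the wild mean is zero
    p_value: float
    status: str  # up | down | ns


def segregation_chisq(
    n_wild: int,
    n_mutant: int,
    ratio: tuple[float, float] = (3.0, 1.0),
    critical: float = 3.84,
) -> SegregationResult:
    """Goodness-of-fit of observed phenotype counts to a Mendelian ratio.

    chi2 = sum (obs - exp)^2 / exp with one degree of freedom; the counts are
    consistent with the ratio when chi2 < critical (default 3.84, the 5%
    point of chi-square with df = 1).
    """
    if n_wild < 0 or n_mutant < 0:
        raise ValueError("counts must be >= 0")
    total = n_wild + n_mutant
    if total == 0:
        raise ValueError("at least one individual is required")
    w = ratio[0] / (ratio[0] + ratio[1])
    expected = [total * w, total * (1 - w)]
    chi2 = float(
        stats.chisquare(f_obs=[n_wild, n_mutant], f_exp=expected).statistic
    )
    return SegregationResult(
        n_wild=n_wild,
        n_mutant=n_mutant,
        expected_ratio=ratio,
        chi2=chi2,
        df=1,
        critical_value=critical,
        consistent=chi2 < critical,
    )


def chisq_critical(alpha: float = 0.05, df: int = 1) -> float:
    """Upper-alpha quantile of the chi-square distribution."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(stats.chi2.ppf(1.0 - alpha, df))


def _exact_rank_sum_p(x_ranks_sum: float, pooled_ranks: np.ndarray, n1: int) -> float:
    """Two-sided exact p for the rank-sum statistic by full enumeration.

    Enumerates all C(n, n1) assignments of the pooled (mid)ranks to the first
    group; p = min(1, 2 * min(P(W <= w), P(W >= w))).  Ties are handled
    naturally because the enumeration redistributes the observed midranks.
    """
    n_le = n_ge = total = 0
    eps = 1e-9
    for combo in itertools.combinations(range(len(pooled_ranks)), n1):
        w = pooled_ranks[list(combo)].sum()
        total += 1
        if w <= x_ranks_sum + eps:
            n_le += 1
        if w >= x_ranks_sum - eps:
            n_ge += 1
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact by full enumeration when both groups have <= 10 observations
    (covering triplicate designs with room to spare); the normal
    approximation without continuity correction above that.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups need at least one observation")
    if max(len(x), len(y)) <= EXACT_ENUMERATION_MAX:
        ranks = stats.rankdata(np.concatenate([x, y]))
        return _exact_rank_sum_p(ranks[: len(x)].sum(), ranks, len(x))
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    return float(res.pvalue)


def metabolite_screen(
    table: pd.DataFrame,
    mut_samples: Sequence[str],
    wt_samples: Sequence[str],
    up: float = 2.0,
    down: float = 0.5,
    p_gate: float | None = None,
) -> pd.DataFrame:
    """Differential-accumulation screen over an analyte x sample table.

    Fold change is mean(mutant)/mean(wild); an analyte is 'up' when the fold
    change is >= ``up`` and 'down' when <= ``down``.  The Wilcoxon rank-sum
    p-value is reported alongside; by default it does not gate the call
    (pass ``p_gate`` to additionally require p < p_gate).  A zero wild-type
    mean with a nonzero mutant mean is 'up' with missing fold change — the
    direction is unambiguous even though the ratio is not finite.
    """
    for col in list(mut_samples) + list(wt_samples):
        if col not in table.columns:
            raise KeyError(f"sample column {col!r} not in table")
    values = table[list(mut_samples) + list(wt_samples)].to_numpy(dtype=float)
    if (values < 0).any() or not np.isfinite(values).all():
        raise ValueError("abundances must be finite and >= 0")
    records = []
    for _, row in table.iterrows():
        xv = row[list(mut_samples)].to_numpy(dtype=float)
        yv = row[list(wt_samples)].to_numpy(dtype=float)
        mean_mut, mean_wt = float(xv.mean()), float(yv.mean())
        p = rank_sum_test(xv, yv)
        if mean_wt == 0.0:
            fc = math.nan
            status = "up" if mean_mut > 0 else "ns"
        else:
            fc = mean_mut / mean_wt
            status = "up" if fc >= up else ("down" if fc <= down else "ns")
        if p_gate is not None and status != "ns" and not p < p_gate:
            status = "ns"
        records.append(
            ScreenRecord(
                analyte_id=str(row.iloc[0]) if "analyte_id" not in table.columns
                else str(row["analyte_id"]),
                mean_mut=mean_mut, mean_wt=mean_wt,
                fold_change=fc, p_value=p, status=status,
            )
        )
    return pd.DataFrame([vars(r) for r in records])


def expression_log2_ratio(
    table: pd.DataFrame, pseudocount: float = 0.01
) -> pd.DataFrame:
    """Per-gene log2((FPKM_mut + c)/(FPKM_wt + c)), sorted ascending.

    The shared pseudocount ``c`` keeps zero-FPKM genes finite; with the
    default 0.01 a gene silenced from moderate expression reports a large
    negative ratio.  A pseudocount of 0 is allowed but lets zero-FPKM genes
    go to +/-inf.  Ties in the ratio are ordered by gene_id.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    for col in ("gene_id", "fpkm_mut", "fpkm_wt"):
        if col not in table.columns:
            raise KeyError(f"column {col!r} required")
    fm = table["fpkm_mut"].to_numpy(dtype=float)
    fw = table["fpkm_wt"].to_numpy(dtype=float)
    if (fm < 0).any() or (fw < 0).any():
        raise ValueError("FPKM values must be >= 0")
    out = table[["gene_id", "fpkm_mut", "fpkm_wt"]].copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        out["log2_ratio"] = np.log2((fm + pseudocount) / (fw + pseudocount))
    out["pseudocount"] = pseudocount
    return out.sort_values(
        ["log2_ratio", "gene_id"], kind="stable"
    ).reset_index(drop=True)
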