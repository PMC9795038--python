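"""Cell QC filters, ΔΔCt qPCR analysis, and the group-comparison battery.

Statistical conventions:

* two groups — Welch's t test (unequal variances, Welch–Satterthwaite df);
* three or more groups — Bartlett's test gates at alpha=0.05 between
  one-way ANOVA + Tukey HSD (homoscedastic route) and Welch's ANOVA +
  Dunnett's T3 (heteroscedastic route);
* nonparametric — Kruskal–Wallis (tie-corrected) with Dunn's post hoc z
  tests, Benjamini–Hochberg adjusted across all pairs.

Welch t, ANOVA, Tukey, Bartlett, Kruskal–Wallis and the BH adjustment are
delegated to scipy/statsmodels.  Dunn's test and Dunnett's T3 (studentized
maximum modulus p-values) are implemented here.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats

__all__ = [
    "QCError",
    "QCThresholds",
    "QPCRMeasurement",
    "StatResult",
    "filter_cells",
    "ddct_knockdown",
    "compare_two",
    "compare_many",
    "kruskal_dunn",
]


class QCError(ValueError):
    pass


# ---------------------------------------------------------------------------
# cell / gene quality filters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QCThresholds:
    """Quality thresholds for the cell x gene count table.

    Defaults follow common full-length single-cell practice: genes kept if
    detected in >=3 cells; cells kept if they express >=3000 such genes with
    a mitochondrial read fraction <=7%.
    """

    min_genes_per_cell: int = 3000
    max_mito_fraction: float = 0.07
    min_cells_per_gene: int = 3

    def __post_init__(self) -> None:
        if self.min_genes_per_cell <= 0 or self.min_cells_per_gene <= 0:
            raise QCError("count thresholds must be positive")
        if not (0 < self.max_mito_fraction <= 1):
            raise QCError("max_mito_fraction must be in (0, 1]")


def filter_cells(
    counts: pd.DataFrame,
    thresholds: QCThresholds | None = None,
    mito_prefix: str = "mt-",
) -> tuple[pd.DataFrame, dict]:
    """Apply gene and cell quality filters to a cells x genes count table.

    The gene filter (detected in >= ``min_cells_per_gene`` cells) is applied
    first; the per-cell expressed-gene tally then counts only surviving
    genes.  The mitochondrial fraction is read-based and computed on the
    unfiltered table (genes whose id starts with ``mito_prefix``,
    case-insensitive).  Returns the filtered table and a report of dropped
    ids with reasons.  The operation is idempotent.
    """
    thresholds = thresholds or QCThresholds()
    if counts.empty:
        raise QCError("empty count table")
    if (counts.to_numpy() < 0).any():
        raise QCError("counts must be nonnegative")

    mito_cols = [g for g in counts.columns if str(g).lower().startswith(mito_prefix.lower())]
    total = counts.sum(axis=1)
    mito_frac = (
        counts[mito_cols].sum(axis=1) / total.replace(0, np.nan)
    ).fillna(0.0) if mito_cols else pd.Series(0.0, index=counts.index)

    cells_per_gene = (counts > 0).sum(axis=0)
    kept_genes = counts.columns[cells_per_gene >= thresholds.min_cells_per_gene]
    dropped_genes = [g for g in counts.columns if g not in set(kept_genes)]

    genes_per_cell = (counts[kept_genes] > 0).sum(axis=1)
    low_genes = genes_per_cell < thresholds.min_genes_per_cell
    high_mito = mito_frac > thresholds.max_mito_fraction
    keep_cell = ~(low_genes | high_mito)

    report = {
        "dropped_genes": [
            {"gene": str(g), "reason": f"present in <{thresholds.min_cells_per_gene} cells"}
            for g in dropped_genes
        ],
        "dropped_cells": [
            {
                "cell": str(c),
                "reason": "; ".join(
                    (["too few genes expressed"] if low_genes[c] else [])
                    + (["mitochondrial fraction too high"] if high_mito[c] else [])
                ),
                "n_genes": int(genes_per_cell[c]),
                "mito_fraction": float(mito_frac[c]),
            }
            for c in counts.index[~keep_cell]
        ],
        "n_genes_kept": int(len(kept_genes)),
        "n_cells_kept": int(keep_cell.sum()),
    }
    return counts.loc[keep_cell, kept_genes], report


# ---------------------------------------------------------------------------
# ΔΔCt qPCR knockdown
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QPCRMeasurement:
    """Ct triplicates for a target gene and a reference gene in one sample."""

    sample: str
    target_ct: tuple[float, ...]
    reference_ct: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "target_ct", tuple(float(x) for x in self.target_ct))
        object.__setattr__(self, "reference_ct", tuple(float(x) for x in self.reference_ct))
        if not self.target_ct or not self.reference_ct:
            raise QCError("Ct replicate lists must be non-empty")
        if any(x <= 0 for x in self.target_ct + self.reference_ct):
            raise QCError("Ct values must be positive")

    @property
    def delta_ct(self) -> float:
        """mean(target Ct) - mean(reference Ct)."""
        return float(np.mean(self.target_ct) - np.mean(self.reference_ct))


def ddct_knockdown(test: QPCRMeasurement, control: QPCRMeasurement) -> dict:
    """Relative expression and knockdown by the ΔΔCt method.

    ΔΔCt = ΔCt(test) − ΔCt(control); relative expression = 2^(−ΔΔCt);
    knockdown% = 100 × (1 − 2^(−ΔΔCt)).  Also reports the per-replicate
    spread of test-sample ΔCt values against the control mean ΔCt.
    """
    ddct = test.delta_ct - control.delta_ct
    rel = 2.0 ** (-ddct)
    per_rep = [
        100.0 * (1.0 - 2.0 ** (-(t - float(np.mean(test.reference_ct)) - control.delta_ct)))
        for t in test.target_ct
    ]
    return {
        "delta_ct_test": test.delta_ct,
        "delta_ct_control": control.delta_ct,
        "delta_delta_ct": ddct,
        "relative_expression": rel,
        "knockdown_pct": 100.0 * (1.0 - rel),
        "knockdown_pct_per_replicate": per_rep,
    }


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

@dataclass
class StatResult:
    method: str
    statistic: float
    p_value: float
    route: str = ""
    alpha: float = 0.05
    pairwise: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "route": self.route,
            "alpha": self.alpha,
        }
        if self.pairwise is not None:
            d["pairwise"] = self.pairwise.to_dict(orient="records")
        return d


def _as_arrays(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    return [np.asarray(g, dtype=float) for g in groups]


def compare_two(a: Sequence[float], b: Sequence[float]) -> StatResult:
    """Two-sided Welch's t test (Welch–Satterthwaite degrees of freedom)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise QCError("each group needs n >= 2")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return StatResult("welch_t", 0.0, 1.0)
        return StatResult("welch_t", math.inf, 0.0)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return StatResult("welch_t", float(t), float(p))


def _smm_sf(m: float, k: int, df: float) -> float:
    """Survival function of the studentized maximum modulus, SMM(k, df).

    P(max_i |t_i| > m) for k independent two-sided t-type contrasts sharing
    df; computed by integrating [2Φ(m s) − 1]^k over the chi(df)/sqrt(df)
    scale density.  For k=1 this reduces to the two-sided t tail.
    """
    if m <= 0:
        return 1.0
    if not np.isfinite(m):
        return 0.0

    def integrand(s: float) -> float:
        log_fs = (
            math.log(2.0)
            + (df / 2.0) * math.log(df / 2.0)
            - math.lgamma(df / 2.0)
            + (df - 1.0) * math.log(s)
            - df * s * s / 2.0
        )
        inner = 2.0 * stats.norm.cdf(m * s) - 1.0
        return math.exp(log_fs) * inner**k

    cdf, _ = integrate.quad(integrand, 0, np.inf, limit=200)
    return float(min(max(1.0 - cdf, 0.0), 1.0))


def _welch_pair(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch t statistic and Welch–Satterthwaite df for one pair."""
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    denom = math.sqrt(va + vb)
    if denom == 0:
        return (0.0 if a.mean() == b.mean() else math.inf), 1.0
    t = (a.mean() - b.mean()) / denom
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return t, df


def _dunnett_t3(groups: list[np.ndarray], names: list[str]) -> pd.DataFrame:
    pairs = list(itertools.combinations(range(len(groups)), 2))
    rows = []
    for i, j in pairs:
        t, df = _welch_pair(groups[i], groups[j])
        p = _smm_sf(abs(t), len(pairs), df)
        rows.append(
            {
                "group_a": names[i],
                "group_b": names[j],
                "statistic": t,
                "df": df,
                "p_adj": p,
                "adjustment": "dunnett_t3_smm",
            }
        )
    return pd.DataFrame(rows)


def compare_many(
    groups: Sequence[Sequence[float]],
    names: Sequence[str] | None = None,
    bartlett_alpha: float = 0.05,
) -> StatResult:
    """Omnibus comparison of >=3 groups with variance-gated routing.

    Bartlett's test at ``bartlett_alpha`` decides the route: equal variances
    go to one-way ANOVA with Tukey HSD; unequal variances (or any
    zero-variance group, where Bartlett is undefined) go to Welch's ANOVA
    with Dunnett's T3.  All-identical data short-circuit to p = 1.
    """
    arrays = _as_arrays(groups)
    if len(arrays) < 3:
        raise QCError("compare_many needs >=3 groups (use compare_two)")
    if any(len(g) < 2 for g in arrays):
        raise QCError("each group needs n >= 2")
    names = list(names) if names is not None else [f"g{i}" for i in range(len(arrays))]

    flat = np.concatenate(arrays)
    if np.all(flat == flat[0]):
        pw = pd.DataFrame(
            {
                "group_a": [names[i] for i, _ in itertools.combinations(range(len(arrays)), 2)],
                "group_b": [names[j] for _, j in itertools.combinations(range(len(arrays)), 2)],
                "statistic": 0.0,
                "p_adj": 1.0,
                "adjustment": "none",
            }
        )
        return StatResult("anova", 0.0, 1.0, route="degenerate_constant", pairwise=pw)

    zero_var = any(g.var(ddof=1) == 0 for g in arrays)
    if zero_var:
        warnings.warn("constant group; Bartlett undefined, routing to Welch/Dunnett-T3")
        bartlett_p = 0.0
    else:
        _, bartlett_p = stats.bartlett(*arrays)

    if bartlett_p < bartlett_alpha:
        from statsmodels.stats.oneway import anova_oneway

        res = anova_oneway(arrays, use_var="unequal", welch_correction=True)
        pw = _dunnett_t3(arrays, names)
        return StatResult(
            "welch_anova",
            float(res.statistic),
            float(res.pvalue),
            route=f"bartlett_p={bartlett_p:.4g} -> welch_anova+dunnett_t3",
            alpha=bartlett_alpha,
            pairwise=pw,
        )

    f, p = stats.f_oneway(*arrays)
    tk = stats.tukey_hsd(*arrays)
    rows = [
        {
            "group_a": names[i],
            "group_b": names[j],
            "statistic": float(tk.statistic[i, j]),
            "p_adj": float(tk.pvalue[i, j]),
            "adjustment": "tukey_hsd",
        }
        for i, j in itertools.combinations(range(len(arrays)), 2)
    ]
    return StatResult(
        "anova",
        float(f),
        float(p),
        route=f"bartlett_p={bartlett_p:.4g} -> anova+tukey",
        alpha=bartlett_alpha,
        pairwise=pd.DataFrame(rows),
    )


def kruskal_dunn(
    groups: Sequence[Sequence[float]], names: Sequence[str] | None = None
) -> StatResult:
    """Kruskal–Wallis omnibus with Dunn's post hoc z tests, BH-adjusted.

    The H statistic is tie-corrected; Dunn's z for a pair (i, j) is
    (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T)(1/n_i + 1/n_j)) with tie term
    T = Σ(t³ − t) / (12(N − 1)); two-sided normal p-values are adjusted by
    Benjamini–Hochberg across all pairs.
    """
    arrays = _as_arrays(groups)
    if len(arrays) < 2:
        raise QCError("kruskal_dunn needs >=2 groups")
    names = list(names) if names is not None else [f"g{i}" for i in range(len(arrays))]

    flat = np.concatenate(arrays)
    if np.all(flat == flat[0]):
        return StatResult("kruskal_wallis", 0.0, 1.0, route="degenerate_constant")

    h, p = stats.kruskal(*arrays)

    ranks = stats.rankdata(flat)
    n_total = len(flat)
    sizes = [len(g) for g in arrays]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(arrays))]
    _, tie_counts = np.unique(flat, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        se = math.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        rows.append(
            {
                "group_a": names[i],
                "group_b": names[j],
                "statistic": z,
                "p_raw": 2.0 * stats.norm.sf(abs(z)),
            }
        )
    pw = pd.DataFrame(rows)
    pw["p_adj"] = stats.false_discovery_control(pw["p_raw"], method="bh")
    pw["adjustment"] = "benjamini_hochberg"
    return StatResult(
        "kruskal_wallis", float(h), float(p), route="kruskal+dunn_bh", pairwise=pw
    )
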