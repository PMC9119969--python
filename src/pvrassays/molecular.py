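"""Comparative-CT qPCR fold changes, gene-set overlap and statistical tests.

The comparative-CT (ΔΔCt) method expresses a target gene's abundance
relative to a housekeeping reference gene (here conventionally Gapdh) and
a control condition:

    ΔCt   = Ct_target − Ct_reference          (per condition)
    ΔΔCt  = ΔCt_condition − ΔCt_control
    fold change = 2^(−ΔΔCt)

Technical replicates are averaged on the Ct scale before the subtraction,
following standard practice.  Statistical reporting mirrors the bench
conventions of the assays: one-way ANOVA with Tukey's HSD for >2 groups,
Student's unpaired t-test for two, and two-tailed Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .frames import InputError

__all__ = [
    "StatReport",
    "ddct_fold_change",
    "gene_set_overlap",
    "anova_tukey",
    "t_test_unpaired",
    "pearson_correlation",
]


@dataclass
class StatReport:
    """Uniform result container for the supported tests."""

    test: str
    statistic: float
    p_value: float
    group_stats: pd.DataFrame | None = None
    pairwise: pd.DataFrame | None = None
    flags: list = field(default_factory=list)

    def __repr__(self) -> str:  # compact, log-friendly
        s = f"StatReport({self.test}: statistic={self.statistic:.4g}, p={self.p_value:.4g}"
        if self.flags:
            s += f", flags={self.flags}"
        return s + ")"


def ddct_fold_change(
    table: pd.DataFrame,
    reference_gene: str | None = None,
    control_condition: str | None = None,
) -> pd.DataFrame:
    """Comparative-CT fold changes from a long-form Ct table.

    ``table`` needs columns (gene, condition, replicate, ct); the reference
    gene and control condition default to the table's ``attrs`` when set by
    the generator or reader.  Returns one row per (gene, condition) with
    delta_ct, delta_delta_ct, fold_change (2^−ΔΔCt) and log2_fold_change.
    The control condition's fold change is exactly 1 for every gene.
    """
    reference_gene = reference_gene or table.attrs.get("reference_gene")
    control_condition = control_condition or table.attrs.get("control_condition")
    if reference_gene is None or control_condition is None:
        raise InputError("reference_gene and control_condition must be given")
    required = {"gene", "condition", "ct"}
    if not required <= set(table.columns):
        raise InputError(f"Ct table must have columns {sorted(required)}")
    if not np.isfinite(table["ct"]).all():
        raise InputError("Ct values must be finite")

    # technical replicates: mean on the Ct scale
    mean_ct = table.groupby(["gene", "condition"], sort=False)["ct"].mean().unstack()
    if reference_gene not in mean_ct.index:
        raise InputError(f"reference gene {reference_gene!r} absent from table")
    if control_condition not in mean_ct.columns:
        raise InputError(f"control condition {control_condition!r} absent from table")
    ref_ct = mean_ct.loc[reference_gene]
    gaps = [
        (g, c)
        for g in mean_ct.index
        for c in mean_ct.columns
        if pd.isna(mean_ct.loc[g, c]) or pd.isna(ref_ct[c])
    ]
    if gaps:
        raise InputError(f"missing Ct measurements for: {gaps}")

    rows = []
    targets = [g for g in mean_ct.index if g != reference_gene]
    for g in targets:
        delta_control = mean_ct.loc[g, control_condition] - ref_ct[control_condition]
        for cond in mean_ct.columns:
            delta = mean_ct.loc[g, cond] - ref_ct[cond]
            ddct = delta - delta_control
            rows.append(
                {
                    "gene": g,
                    "condition": cond,
                    "delta_ct": float(delta),
                    "delta_delta_ct": float(ddct),
                    "fold_change": float(2.0 ** (-ddct)),
                    "log2_fold_change": float(-ddct),
                }
            )
    return pd.DataFrame(rows)


def gene_set_overlap(query, reference) -> dict:
    """Overlap of two gene-identifier sets, as a percentage of the query.

    Identifiers are case-normalised before intersection.  The percentage is
    reported both rounded to the nearest integer and at full precision; an
    empty query yields a missing (NaN) percentage, never 0.
    """
    q = {str(g).strip().upper() for g in query}
    r = {str(g).strip().upper() for g in reference}
    q.discard("")
    r.discard("")
    inter = len(q & r)
    pct = 100.0 * inter / len(q) if q else float("nan")
    return {
        "query_set_size": len(q),
        "reference_set_size": len(r),
        "intersection_size": inter,
        "overlap_pct": pct,
        "overlap_pct_rounded": int(round(pct)) if q else None,
    }


def anova_tukey(groups: dict[str, list | np.ndarray], alpha: float = 0.05) -> StatReport:
    """One-way ANOVA followed by all-pairs Tukey HSD.

    ``groups`` maps group label to its replicate values; each group needs
    n >= 2.  The pairwise table carries Tukey-adjusted p-values at family
    level ``alpha``.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if len(groups) < 2:
        raise InputError("need at least 2 groups")
    for label, vals in groups.items():
        if len(vals) < 2:
            raise InputError(f"group {label!r} has n < 2")
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    flags = []
    if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        # all observations identical: no variance anywhere
        f_stat, p = 0.0, 1.0
        flags.append("zero-variance-everywhere")
        pairwise = None
    else:
        f_stat, p = stats.f_oneway(*arrays)
        values = np.concatenate(arrays)
        group_labels = np.concatenate(
            [[k] * len(a) for k, a in zip(labels, arrays)]
        )
        tk = pairwise_tukeyhsd(values, group_labels, alpha=alpha)
        pairwise = pd.DataFrame(
            tk.summary().data[1:], columns=tk.summary().data[0]
        )
    descr = pd.DataFrame(
        {
            "group": labels,
            "mean": [float(a.mean()) for a in arrays],
            "sd": [float(a.std(ddof=1)) for a in arrays],
            "n": [len(a) for a in arrays],
        }
    )
    return StatReport(
        test="anova_tukey",
        statistic=float(f_stat),
        p_value=float(p),
        group_stats=descr,
        pairwise=pairwise,
        flags=flags,
    )


def t_test_unpaired(a, b) -> StatReport:
    """Two-tailed Student's unpaired (pooled-variance) t-test."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InputError("both samples need n >= 2")
    flags = []
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        flags.append("degenerate-zero-variance")
        if a[0] == b[0]:
            return StatReport("t_test", 0.0, 1.0, flags=flags)
        return StatReport("t_test", float("inf"), 0.0, flags=flags)
    t_stat, p = stats.ttest_ind(a, b, equal_var=True)
    descr = pd.DataFrame(
        {
            "group": ["a", "b"],
            "mean": [a.mean(), b.mean()],
            "sd": [a.std(ddof=1), b.std(ddof=1)],
            "n": [len(a), len(b)],
        }
    )
    return StatReport("t_test", float(t_stat), float(p), group_stats=descr, flags=flags)


def pearson_correlation(x, y) -> StatReport:
    """Two-tailed Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise InputError("need equal-length samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InputError("values must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InputError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return StatReport("pearson", float(r), float(p))
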