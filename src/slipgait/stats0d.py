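"""Scalar statistics: normality gating, condition/age comparisons with
Bonferroni alpha ladders, and the three-part correlation plan.

Pearson is used only when both variables pass the Shapiro-Wilk gate;
otherwise Spearman.  Participants whose recovery was capped (n_steps = 16)
are excluded from any correlation involving n_steps, with the excluded
count reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

__all__ = [
    "TestResult",
    "CorrelationResult",
    "normality_gate",
    "compare_conditions",
    "correlate",
    "correlation_plan",
    "family_alpha",
]

# printed Bonferroni ladder: family size -> adjusted alpha
_ALPHA_LADDER = {5: 0.01, 7: 0.007, 8: 0.0063, 9: 0.0056, 10: 0.005, 45: 0.0011}


@dataclass
class TestResult:
    test: str
    contrast: str
    statistic: float
    p_value: float
    alpha_adjusted: float

    @property
    def significant(self) -> bool:
        return self.p_value <= self.alpha_adjusted


@dataclass
class CorrelationResult:
    pair: str
    method: str  # "pearson" | "spearman"
    coefficient: float
    p_value: float
    n: int
    excluded_capped: int = 0


def family_alpha(family_size: int, base: float = 0.05) -> float:
    """Bonferroni-adjusted alpha, truncated to the documented ladder when the
    family size matches one of the reported families."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    if family_size in _ALPHA_LADDER:
        return _ALPHA_LADDER[family_size]
    return base / family_size


def normality_gate(values, alpha: float = 0.05) -> bool:
    """True iff the sample is parametric-eligible (Shapiro-Wilk p > alpha).

    Constant input cannot be tested and is flagged as not eligible.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 3:
        raise ValueError("need at least 3 values")
    if np.ptp(vals) == 0:
        return False
    return bool(sps.shapiro(vals).pvalue > alpha)


def compare_conditions(
    table: pd.DataFrame,
    design: str,
    family_size: int | None = None,
    between: str | None = None,
) -> list[TestResult]:
    """Omnibus test over conditions plus post-hoc pairwise tests.

    ``table`` is wide: one row per participant, one column per condition;
    ``between`` optionally names a column holding the group factor (for the
    mixed ANOVA and for ``mann_whitney``).  Post-hoc Wilcoxon tests run only
    when the omnibus is significant, at the Bonferroni-adjusted alpha for
    ``family_size`` (default: the number of pairs).
    """
    cond_cols = [c for c in table.columns if c != between]
    data = table[cond_cols]
    if data.isna().any().any():
        raise ValueError("repeated-measures designs require a complete table")
    results: list[TestResult] = []

    if design == "mann_whitney":
        if between is None:
            raise ValueError("mann_whitney requires a 'between' column")
        groups = table[between].unique()
        if len(groups) != 2:
            raise ValueError("mann_whitney requires exactly two groups")
        fam = family_size or len(cond_cols)
        for col in cond_cols:
            a = table.loc[table[between] == groups[0], col]
            b = table.loc[table[between] == groups[1], col]
            stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
            results.append(TestResult("mann_whitney", f"{col}:{groups[0]}~{groups[1]}",
                                      float(stat), float(p), family_alpha(fam)))
        return results

    if design == "friedman":
        if np.all(data.nunique(axis=1) == 1):
            # every participant identical across conditions: nothing to test
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.friedmanchisquare(*[data[c] for c in cond_cols])
        omnibus = TestResult("friedman", "|".join(cond_cols), float(stat),
                             float(p), 0.05)
        results.append(omnibus)
        if omnibus.significant:
            pairs = list(combinations(cond_cols, 2))
            fam = family_size or len(pairs)
            alpha = family_alpha(fam)
            for ca, cb in pairs:
                diff = data[ca] - data[cb]
                if np.all(diff == 0):
                    results.append(TestResult("wilcoxon", f"{ca}~{cb}", 0.0,
                                              1.0, alpha))
                    continue
                stat, p = sps.wilcoxon(data[ca], data[cb], zero_method="wilcox")
                results.append(TestResult("wilcoxon", f"{ca}~{cb}", float(stat),
                                          float(p), alpha))
        return results

    if design == "mixed_anova":
        if between is None:
            raise ValueError("mixed_anova requires a 'between' column")
        long = table.reset_index(names="subject").melt(
            id_vars=["subject", between], value_vars=cond_cols,
            var_name="condition", value_name="value",
        )
        aov = pg.mixed_anova(data=long, dv="value", within="condition",
                             subject="subject", between=between)
        for _, row in aov.iterrows():
            results.append(TestResult("mixed_anova", str(row["Source"]),
                                      float(row["F"]), float(row["p_unc"]),
                                      0.05))
        cond_row = aov[aov["Source"] == "condition"]
        if len(cond_row) and float(cond_row["p_unc"].iloc[0]) <= 0.05:
            pairs = list(combinations(cond_cols, 2))
            fam = family_size or len(pairs)
            alpha = family_alpha(fam)
            for ca, cb in pairs:
                stat, p = sps.ttest_rel(data[ca], data[cb])
                results.append(TestResult("paired_t", f"{ca}~{cb}", float(stat),
                                          float(p), alpha))
        return results

    if design == "wilcoxon_posthoc":
        pairs = list(combinations(cond_cols, 2))
        fam = family_size or len(pairs)
        alpha = family_alpha(fam)
        for ca, cb in pairs:
            diff = data[ca] - data[cb]
            if np.all(diff == 0):
                results.append(TestResult("wilcoxon", f"{ca}~{cb}", 0.0, 1.0,
                                          alpha))
                continue
            stat, p = sps.wilcoxon(data[ca], data[cb], zero_method="wilcox")
            results.append(TestResult("wilcoxon", f"{ca}~{cb}", float(stat),
                                      float(p), alpha))
        return results

    raise ValueError(f"unknown design: {design}")


def correlate(
    x,
    y,
    pair: str = "",
    exclude_capped: bool = False,
    capped_mask=None,
    normality_alpha: float = 0.05,
) -> CorrelationResult:
    """Bivariate correlation: Pearson when both variables pass the normality
    gate, Spearman otherwise.

    When ``exclude_capped`` is set, entries flagged in ``capped_mask``
    (participants who never regained stable gait) are dropped first.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    excluded = 0
    if exclude_capped:
        if capped_mask is None:
            raise ValueError("exclude_capped requires capped_mask")
        keep = ~np.asarray(capped_mask, dtype=bool)
        excluded = int(np.sum(~keep))
        x, y = x[keep], y[keep]
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 pairs after exclusions")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant variable")
    parametric = (
        normality_gate(x, normality_alpha) and normality_gate(y, normality_alpha)
    )
    if parametric:
        r, p = sps.pearsonr(x, y)
        method = "pearson"
    else:
        r, p = sps.spearmanr(x, y)
        method = "spearman"
    return CorrelationResult(pair=pair, method=method, coefficient=float(r),
                             p_value=float(p), n=int(x.size),
                             excluded_capped=excluded)


def correlation_plan(
    mos: pd.DataFrame,
    outcomes: pd.DataFrame,
    roi: pd.DataFrame | None = None,
    scalar_sources: list[tuple[str, int, str, pd.Series]] | None = None,
    normality_alpha: float = 0.05,
) -> list[CorrelationResult]:
    """Execute the enumerated correlation analyses.

    (1) pre-slip balance vs first-recovery balance, for the first and last
        slips; (2) first-slip vs last-slip balance (Rec1, Rec2 MoS and
        n_steps); (3) every significant region-of-interest average (and
        significant scalar deviation) vs the MoS of the following steps and
        vs n_steps of that slip.

    ``mos`` columns: participant, slip, step_label, mos_cm.
    ``outcomes`` columns: participant, slip, n_steps, capped.
    ``roi`` columns: participant, channel, contrast, slip, step_label,
    start_pct, end_pct, value.
    ``scalar_sources``: (name, slip, step_label, values-by-participant) for
    0D variables that differed from Normal (e.g. step lengths); they enter
    part (3) exactly like ROI averages.
    """
    results: list[CorrelationResult] = []

    def mos_of(slip: int, label: str) -> pd.Series:
        sel = mos[(mos["slip"] == slip) & (mos["step_label"] == label)]
        return sel.set_index("participant")["mos_cm"]

    def nsteps_of(slip: int) -> pd.DataFrame:
        return outcomes[outcomes["slip"] == slip].set_index("participant")

    first = int(mos[mos["slip"] > 0]["slip"].min())
    last = int(mos["slip"].max())

    # (1) anticipatory balance vs reactive balance
    for slip in (first, last):
        for pre in ("Pre2", "Pre1"):
            a, b = mos_of(slip, pre), mos_of(slip, "Rec1")
            idx = a.index.intersection(b.index)
            results.append(
                correlate(a[idx], b[idx],
                          pair=f"Slip{slip:02d}_{pre}~Slip{slip:02d}_Rec1",
                          normality_alpha=normality_alpha)
            )

    # (2) first slip vs last slip
    for label in ("Rec1", "Rec2"):
        a, b = mos_of(first, label), mos_of(last, label)
        idx = a.index.intersection(b.index)
        results.append(
            correlate(a[idx], b[idx],
                      pair=f"Slip{first:02d}_{label}~Slip{last:02d}_{label}",
                      normality_alpha=normality_alpha)
        )
    na, nb = nsteps_of(first), nsteps_of(last)
    idx = na.index.intersection(nb.index)
    capped = na.loc[idx, "capped"].to_numpy() | nb.loc[idx, "capped"].to_numpy()
    if np.sum(~capped) >= 3:
        results.append(
            correlate(na.loc[idx, "n_steps"], nb.loc[idx, "n_steps"],
                      pair=f"Slip{first:02d}_nsteps~Slip{last:02d}_nsteps",
                      exclude_capped=True, capped_mask=capped,
                      normality_alpha=normality_alpha)
        )

    # (3) significant mechanical deviations vs subsequent balance
    next_steps = {"Pert": ["Rec1", "Rec2"], "Rec1": ["Rec2", "Rec3"]}
    sources: list[tuple[str, int, str, pd.Series]] = []
    if roi is not None and len(roi):
        for (channel, contrast, slip, label, s_pct, e_pct), grp in roi.groupby(
            ["channel", "contrast", "slip", "step_label", "start_pct", "end_pct"]
        ):
            name = f"{channel}[{contrast}:{int(s_pct)}-{int(e_pct)}%]"
            sources.append((name, int(slip), str(label),
                            grp.set_index("participant")["value"]))
    if scalar_sources:
        sources.extend(scalar_sources)
    for name, slip, label, values in sources:
        for nxt in next_steps.get(label, []):
            target = mos_of(slip, nxt)
            idx = values.index.intersection(target.index)
            results.append(
                correlate(values[idx], target[idx],
                          pair=f"{name}~Slip{slip:02d}_{nxt}_MoS",
                          normality_alpha=normality_alpha)
            )
        ns = nsteps_of(slip)
        idx = values.index.intersection(ns.index)
        capped = ns.loc[idx, "capped"].to_numpy()
        if np.sum(~capped) >= 3:
            results.append(
                correlate(values[idx], ns.loc[idx, "n_steps"],
                          pair=f"{name}~Slip{slip:02d}_nsteps",
                          exclude_capped=True, capped_mask=capped,
                          normality_alpha=normality_alpha)
            )
    return results
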