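"""Ensemble-level statistics of the catalytic salt-bridge mechanism.

Distance distributions per variant are summarized against crystal-structure
anchors (3.2 Å inactive-like, 7.2 Å active-like), compared variant-vs-WT by
Mann-Whitney U, and discretized into intact (< 4 Å) / disrupted (> 6 Å)
categories for a chi-square contingency test. Boundary values fall into an
explicit intermediate category excluded from the 2x2 test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "INACTIVE_REF_ANGSTROM",
    "ACTIVE_REF_ANGSTROM",
    "DistanceSummary",
    "mann_whitney_u",
    "classify_intact_disrupted",
    "chi_square_test",
    "distance_summary",
    "variant_vs_wt_tests",
]

INACTIVE_REF_ANGSTROM = 3.2  # intact salt bridge, inactive-like crystal anchor
ACTIVE_REF_ANGSTROM = 7.2    # disrupted salt bridge, active-like crystal anchor


def mann_whitney_u(sample_a: np.ndarray, sample_b: np.ndarray,
                   alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U of sample_a vs sample_b with tie correction.

    Exact null enumeration for small samples (both n <= 20, no ties),
    normal approximation otherwise — scipy's default policy.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative=alternative, method="auto")
    return float(res.statistic), float(res.pvalue)


def classify_intact_disrupted(distances: np.ndarray, lo: float = 4.0,
                              hi: float = 6.0) -> dict[str, int]:
    """Strict-inequality counts: intact < lo, disrupted > hi, the rest
    intermediate (boundary values are intermediate)."""
    if lo >= hi:
        raise ValueError("lo threshold must be < hi threshold")
    d = np.asarray(distances, dtype=float)
    intact = int(np.sum(d < lo))
    disrupted = int(np.sum(d > hi))
    return {"intact": intact, "disrupted": disrupted,
            "intermediate": len(d) - intact - disrupted}


def chi_square_test(table: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 intact/disrupted table, df = 1, no
    continuity correction."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    chi2, p, dof, expected = stats.chi2_contingency(obs, correction=False)
    if np.any(expected <= 0):
        raise ValueError("zero expected count in contingency table")
    assert dof == 1
    return float(chi2), float(p)


@dataclass
class DistanceSummary:
    variant: str
    n: int
    median: float
    q1: float
    q3: float
    frac_intact: float
    frac_disrupted: float


def distance_summary(fm_data: pd.DataFrame, lo: float = 4.0, hi: float = 6.0
                     ) -> pd.DataFrame:
    """Per-variant distance summary table from a feature matrix frame."""
    rows = []
    for v, grp in fm_data.groupby("variant", sort=True):
        d = grp["salt_bridge_dist"].to_numpy()
        cats = classify_intact_disrupted(d, lo=lo, hi=hi)
        q1, med, q3 = np.percentile(d, [25, 50, 75])
        rows.append({"variant": v, "n": len(d), "median": med, "q1": q1, "q3": q3,
                     "frac_intact": cats["intact"] / len(d),
                     "frac_disrupted": cats["disrupted"] / len(d)})
    return pd.DataFrame(rows)


def variant_vs_wt_tests(fm_data: pd.DataFrame, wt_variant: str,
                        lo: float = 4.0, hi: float = 6.0,
                        alternative: str = "two-sided",
                        bonferroni: bool = False) -> pd.DataFrame:
    """WT-vs-each-variant Mann-Whitney tests plus the intact/disrupted
    chi-square where both expected counts are positive.

    Multiple-testing correction is off by default; ``bonferroni=True``
    multiplies the p-values by the number of comparisons.
    """
    wt = fm_data.loc[fm_data["variant"] == wt_variant, "salt_bridge_dist"].to_numpy()
    if len(wt) == 0:
        raise ValueError(f"no frames for reference variant {wt_variant!r}")
    wt_cats = classify_intact_disrupted(wt, lo=lo, hi=hi)
    others = [v for v in sorted(fm_data["variant"].unique()) if v != wt_variant]
    rows = []
    for v in others:
        d = fm_data.loc[fm_data["variant"] == v, "salt_bridge_dist"].to_numpy()
        u, p = mann_whitney_u(wt, d, alternative=alternative)
        cats = classify_intact_disrupted(d, lo=lo, hi=hi)
        table = np.array([[wt_cats["intact"], wt_cats["disrupted"]],
                          [cats["intact"], cats["disrupted"]]], dtype=float)
        if np.all(table.sum(axis=0) > 0) and np.all(table.sum(axis=1) > 0):
            chi2, chi_p = chi_square_test(table)
        else:
            chi2, chi_p = float("nan"), float("nan")
        rows.append({"variant": v, "n": len(d), "mw_u": u, "mw_p": p,
                     "chi2": chi2, "chi2_p": chi_p})
    out = pd.DataFrame(rows)
    if bonferroni and len(out):
        out["mw_p"] = np.minimum(out["mw_p"] * len(out), 1.0)
        out["chi2_p"] = np.minimum(out["chi2_p"] * len(out), 1.0)
    return out
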