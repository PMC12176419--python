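"""Frequentist testing scaffold: t-tests, BH-FDR, the per-region 12-test
ledger, and sector aggregation.

Each region's decoding analyses form a fixed family of 12 tests (category
decoding per task and overall, task decoding, category-vs-task contrast,
both cross-decoding analyses with their drop tests, the cross-decoding
ratio, and pattern difference decoding), corrected together with the
Benjamini-Hochberg step-up procedure at q = .05.  Geometry-change tests form
a separate family.  Sector statistics are unweighted means of the final
per-region, per-participant values, so every region contributes equally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets import SectorMap

CHANCE = 0.5

STARS = ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.1, "†"))


class LedgerError(ValueError):
    """Raised when a test ledger cannot be assembled."""


def one_sample_t(values, mu0: float, tail: str = "two-sided") -> tuple[float, float]:
    """One-sample t-test; ``tail`` in {"two-sided", "greater", "less"}."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise LedgerError("need n >= 2")
    if values.std(ddof=1) == 0:
        raise LedgerError("zero variance")
    res = stats.ttest_1samp(values, popmean=mu0, alternative=tail)
    return float(res.statistic), float(res.pvalue)


def paired_t(a, b, tail: str = "two-sided") -> tuple[float, float]:
    """Paired (within-subjects) t-test of a vs b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise LedgerError("paired samples must have equal length")
    if a.size < 2:
        raise LedgerError("need n >= 2")
    diff = a - b
    if np.all(diff == 0):
        return 0.0, 1.0 if tail == "two-sided" else 0.5
    if diff.std(ddof=1) == 0:
        raise LedgerError("zero variance of paired differences")
    res = stats.ttest_rel(a, b, alternative=tail)
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at FDR level q."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise LedgerError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


# ----------------------------------------------------------------------
# The per-region 12-test ledger
# ----------------------------------------------------------------------
#: (name, tail, short description); order fixed.
LEDGER_TESTS = [
    ("category_decoding_task1_vs_chance", "greater",
     "category decoding vs chance, first task"),
    ("category_decoding_task2_vs_chance", "greater",
     "category decoding vs chance, second task"),
    ("category_decoding_task1_vs_task2", "two-sided",
     "category decoding compared between tasks"),
    ("category_decoding_overall_vs_chance", "greater",
     "task-averaged category decoding vs chance"),
    ("task_decoding_vs_chance", "greater", "task decoding vs chance"),
    ("category_vs_task_decoding", "two-sided",
     "category decoding compared with task decoding"),
    ("category_cross_decoding_vs_chance", "greater",
     "category cross-decoding vs chance"),
    ("category_within_vs_cross", "greater",
     "within-task category decoding vs category cross-decoding"),
    ("category_cross_ratio_vs_one", "less",
     "category cross-decoding ratio vs 1"),
    ("task_cross_decoding_vs_chance", "greater",
     "task cross-decoding vs chance"),
    ("task_within_vs_cross", "greater",
     "within-category task decoding vs task cross-decoding"),
    ("pattern_difference_vs_chance", "greater",
     "pattern difference decoding vs chance"),
]

#: per-participant input arrays required to build a full ledger
LEDGER_INPUTS = (
    "category_acc_task1",
    "category_acc_task2",
    "task_acc",
    "category_cross_acc",
    "task_cross_acc",
    "category_cross_ratio",
    "pattern_difference_acc",
)


@dataclass
class TestLedger:
    """Ordered record of one region's 12 corrected decoding tests."""

    scope: str
    entries: list[dict] = field(default_factory=list)
    fdr_q: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries)

    def stars(self, p: float) -> str:
        for cut, mark in STARS:
            if p < cut:
                return mark
        return ""

    def report(self) -> str:
        lines = [f"Ledger for {self.scope} (BH-FDR q = {self.fdr_q})"]
        for e in self.entries:
            flag = "SIG" if e["corrected_significance"] else "   "
            lines.append(
                f"  {flag} {e['name']:<40s} t = {e['statistic']:+7.3f}  "
                f"p = {e['p']:.4f} {self.stars(e['p'])} ({e['tail']})"
            )
        return "\n".join(lines)


def build_region_ledger(inputs: dict, scope: str = "region",
                        fdr_q: float = 0.05) -> TestLedger:
    """Assemble and BH-correct the fixed 12-test family for one region.

    ``inputs`` maps the names in :data:`LEDGER_INPUTS` to per-participant
    arrays.  Ratios may contain NaN for flagged (within <= chance)
    participants; those are dropped from the ratio test only.
    """
    missing = [k for k in LEDGER_INPUTS if k not in inputs]
    if missing:
        names = {
            "category_cross_acc": "category cross-decoding",
            "task_cross_acc": "task cross-decoding",
            "category_cross_ratio": "category cross-decoding ratio",
            "pattern_difference_acc": "pattern difference decoding",
        }
        labels = [names.get(m, m) for m in missing]
        raise LedgerError(f"ledger inputs missing: {', '.join(labels)}")
    arr = {k: np.asarray(inputs[k], dtype=float) for k in LEDGER_INPUTS}
    cat1, cat2 = arr["category_acc_task1"], arr["category_acc_task2"]
    overall = 0.5 * (cat1 + cat2)
    ratio = arr["category_cross_ratio"]
    ratio_ok = ratio[~np.isnan(ratio)]

    computations = [
        lambda: one_sample_t(cat1, CHANCE, "greater"),
        lambda: one_sample_t(cat2, CHANCE, "greater"),
        lambda: paired_t(cat1, cat2, "two-sided"),
        lambda: one_sample_t(overall, CHANCE, "greater"),
        lambda: one_sample_t(arr["task_acc"], CHANCE, "greater"),
        lambda: paired_t(overall, arr["task_acc"], "two-sided"),
        lambda: one_sample_t(arr["category_cross_acc"], CHANCE, "greater"),
        lambda: paired_t(overall, arr["category_cross_acc"], "greater"),
        lambda: one_sample_t(ratio_ok, 1.0, "less"),
        lambda: one_sample_t(arr["task_cross_acc"], CHANCE, "greater"),
        lambda: paired_t(arr["task_acc"], arr["task_cross_acc"], "greater"),
        lambda: one_sample_t(arr["pattern_difference_acc"], CHANCE, "greater"),
    ]
    entries = []
    for (name, tail, description), compute in zip(LEDGER_TESTS, computations):
        t, p = compute()
        entries.append(dict(name=name, description=description, tail=tail,
                            statistic=t, p=p))
    rejected = bh_fdr([e["p"] for e in entries], q=fdr_q)
    for e, r in zip(entries, rejected):
        e["corrected_significance"] = bool(r)
    return TestLedger(scope=scope, entries=entries, fdr_q=fdr_q)


def sector_aggregate(per_region_values: pd.DataFrame,
                     sector_map: SectorMap) -> pd.DataFrame:
    """Average final per-region, per-participant values into sectors.

    ``per_region_values`` is participants x regions.  Averaging happens at
    the final stage of each analysis (means of finished per-region values,
    e.g. of ratios rather than of the accuracies entering a ratio), so each
    region contributes equally to its sector.
    """
    out = {}
    for sector, regions in sector_map.items():
        missing = [r for r in regions if r not in per_region_values.columns]
        if missing:
            raise LedgerError(
                f"sector {sector!r} missing region(s) {missing}"
            )
        out[sector] = per_region_values[list(regions)].mean(axis=1)
    return pd.DataFrame(out, index=per_region_values.index)
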