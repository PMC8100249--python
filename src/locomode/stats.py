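"""Paradigm x window-length statistical comparison of accuracy tables.

The experiment harness follows the study's analysis plan: Shapiro-Wilk on
the model residuals as the normality check, a two-way fixed-factor ANOVA
with accuracy as the response and training paradigm and window length as
factors, and — for factors significant at alpha = 0.01 — all-pairs post-hoc
comparison with Bonferroni correction.  These are standard published tests
(scipy / statsmodels); the harness adds balance validation and reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

ALPHA = 0.01

REQUIRED_COLUMNS = ("subject", "task", "paradigm", "window_ms", "accuracy")


@dataclass
class StatsReport:
    """Normality check, ANOVA table and post-hoc pairs for one accuracy table."""

    shapiro_stat: float
    shapiro_p: float
    anova: pd.DataFrame
    #: factor name -> p-value of the main effect (and "interaction")
    effects: dict[str, float]
    #: rows: factor, level_a, level_b, p_raw, p_bonferroni, significant
    posthoc: pd.DataFrame
    alpha: float = ALPHA

    def significant(self, effect: str) -> bool:
        p = self.effects.get(effect)
        return p is not None and np.isfinite(p) and p < self.alpha


def _check_balanced(table: pd.DataFrame) -> None:
    counts = table.groupby(["paradigm", "window_ms"]).size()
    n_para = table["paradigm"].nunique()
    n_win = table["window_ms"].nunique()
    if len(counts) != n_para * n_win:
        missing = n_para * n_win - len(counts)
        raise ValueError(
            f"accuracy table is missing {missing} (paradigm, window) cell(s); "
            "the two-way ANOVA requires every combination to be observed"
        )
    if counts.nunique() != 1:
        raise ValueError(
            "accuracy table is unbalanced: cell sizes range "
            f"{counts.min()}-{counts.max()}; provide equal replicates per "
            "(paradigm, window) cell"
        )


def compare_conditions(table: pd.DataFrame, alpha: float = ALPHA) -> StatsReport:
    """Two-way ANOVA of accuracy over (paradigm, window length).

    ``table`` needs columns subject, task, paradigm, window_ms, accuracy,
    one row per replicate cell observation.  Post-hoc pairwise comparisons
    (Bonferroni-adjusted two-sample t-tests pooled over the other factor)
    are run only for factors whose main effect is significant at ``alpha``.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"accuracy table is missing column(s) {missing}")
    _check_balanced(table)
    df = table.copy()
    df["paradigm"] = df["paradigm"].astype(str)
    df["window_ms"] = df["window_ms"].astype(float)

    acc = df["accuracy"].to_numpy(dtype=float)
    if np.allclose(acc, acc[0]):
        # constant response: F statistics are 0/0, no effect can exist
        return StatsReport(
            shapiro_stat=float("nan"),
            shapiro_p=float("nan"),
            anova=pd.DataFrame(),
            effects={"paradigm": float("nan"), "window_ms": float("nan"),
                     "interaction": float("nan")},
            posthoc=pd.DataFrame(
                columns=["factor", "level_a", "level_b", "mean_a", "mean_b",
                         "p_raw", "p_bonferroni", "significant"]
            ),
            alpha=alpha,
        )

    model = smf.ols("accuracy ~ C(paradigm) * C(window_ms)", data=df).fit()
    resid = np.asarray(model.resid, dtype=float)
    if np.allclose(resid, 0.0):
        # degenerate: a perfect fit (e.g. constant response) — Shapiro is
        # undefined on a constant vector
        shapiro_stat, shapiro_p = float("nan"), float("nan")
    else:
        shapiro_stat, shapiro_p = sps.shapiro(resid)
    anova = sm.stats.anova_lm(model, typ=2)

    def _p(term: str) -> float:
        try:
            return float(anova.loc[term, "PR(>F)"])
        except KeyError:
            return float("nan")

    effects = {
        "paradigm": _p("C(paradigm)"),
        "window_ms": _p("C(window_ms)"),
        "interaction": _p("C(paradigm):C(window_ms)"),
    }

    rows = []
    for factor in ("paradigm", "window_ms"):
        p_main = effects[factor]
        if not (np.isfinite(p_main) and p_main < alpha):
            continue
        levels = sorted(df[factor].unique())
        pairs = list(combinations(levels, 2))
        m = len(pairs)
        for a, b in pairs:
            xa = df.loc[df[factor] == a, "accuracy"]
            xb = df.loc[df[factor] == b, "accuracy"]
            t, p_raw = sps.ttest_ind(xa, xb)
            p_adj = min(1.0, m * float(p_raw))
            rows.append(
                {
                    "factor": factor,
                    "level_a": a,
                    "level_b": b,
                    "mean_a": float(xa.mean()),
                    "mean_b": float(xb.mean()),
                    "p_raw": float(p_raw),
                    "p_bonferroni": p_adj,
                    "significant": p_adj < alpha,
                }
            )
    posthoc = pd.DataFrame(
        rows,
        columns=[
            "factor", "level_a", "level_b", "mean_a", "mean_b",
            "p_raw", "p_bonferroni", "significant",
        ],
    )
    return StatsReport(
        shapiro_stat=float(shapiro_stat),
        shapiro_p=float(shapiro_p),
        anova=anova,
        effects=effects,
        posthoc=posthoc,
        alpha=alpha,
    )


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: ``min(1, m * p)`` per test."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    return np.minimum(1.0, m * p)
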