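"""Method-agreement statistics.

The battery used to compare two infarct scorings or volume series: pooled
2x2 contingency tables and Cohen's kappa for binary segment scores,
sensitivity/specificity/PPV/NPV against a gold standard, Bland-Altman bias
and 95% limits of agreement, two-way random-effects absolute-agreement
single-measure ICC (Shrout-Fleiss ICC(2,1)), Pearson R², and the Wilcoxon
signed-rank test with an optional Bonferroni-corrected significance level
(0.05 / 11 comparisons ≈ 0.0045 for the segment-location battery).

Conventions: segment scores are pooled across subjects (all segments, not
per-segment); paired differences are method A − method B; undefined
diagnostic metrics (zero marginal) are reported as NaN, never as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

__all__ = [
    "AgreementReport",
    "BONFERRONI_SEGMENT_ALPHA",
    "Contingency2x2",
    "WilcoxonResult",
    "bland_altman",
    "bonferroni_alpha",
    "cohens_kappa",
    "contingency",
    "diagnostic_metrics",
    "icc",
    "pearson_r2",
    "percent_agreement",
    "wilcoxon_signed_rank",
]


def bonferroni_alpha(alpha: float = 0.05, n_comparisons: int = 11) -> float:
    """Per-test level alpha / m for m comparisons (0.05/11 ≈ 0.0045)."""
    if n_comparisons < 1:
        raise ValueError("need at least one comparison")
    return alpha / n_comparisons


BONFERRONI_SEGMENT_ALPHA = bonferroni_alpha()


@dataclass
class Contingency2x2:
    """Counts a (test+/gold+), b (test+/gold-), c (test-/gold+), d (test-/gold-)."""

    a: int
    b: int
    c: int
    d: int
    test_label: str = "test"
    gold_label: str = "gold"

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.total == 0:
            raise ValueError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def transposed(self) -> "Contingency2x2":
        return Contingency2x2(self.a, self.c, self.b, self.d, self.gold_label, self.test_label)


def _flatten_scores(scores) -> np.ndarray:
    arrs = [np.asarray(s.values if hasattr(s, "values") else s, dtype=int) for s in scores]
    flat = np.concatenate(arrs)
    if not np.isin(flat, (0, 1)).all():
        raise ValueError("segment scores must be binary")
    return flat


def contingency(test, gold, test_label: str = "test", gold_label: str = "gold") -> Contingency2x2:
    """Pool binary segment scores across subjects and cross-tabulate."""
    t = _flatten_scores(test)
    g = _flatten_scores(gold)
    if t.shape != g.shape:
        raise ValueError("test and gold score lists have different lengths")
    return Contingency2x2(
        a=int(np.sum((t == 1) & (g == 1))),
        b=int(np.sum((t == 1) & (g == 0))),
        c=int(np.sum((t == 0) & (g == 1))),
        d=int(np.sum((t == 0) & (g == 0))),
        test_label=test_label,
        gold_label=gold_label,
    )


def percent_agreement(t: Contingency2x2) -> float:
    return (t.a + t.d) / t.total


def cohens_kappa(t: Contingency2x2) -> float:
    """Chance-corrected agreement κ = (p_o − p_e) / (1 − p_e)."""
    n = t.total
    p_o = (t.a + t.d) / n
    p_e = ((t.a + t.b) * (t.a + t.c) + (t.c + t.d) * (t.b + t.d)) / (n * n)
    if p_e == 1.0:
        if p_o == 1.0:
            return 1.0
        raise ValueError("kappa undefined: degenerate marginals with imperfect agreement")
    return (p_o - p_e) / (1.0 - p_e)


def diagnostic_metrics(t: Contingency2x2) -> dict:
    """Standard sensitivity, specificity, PPV, NPV with the gold standard on columns.

    A metric whose marginal is zero is undefined and reported as NaN.
    """

    def _ratio(num: int, den: int) -> float:
        return num / den if den > 0 else math.nan

    return {
        "sensitivity": _ratio(t.a, t.a + t.c),
        "specificity": _ratio(t.d, t.b + t.d),
        "ppv": _ratio(t.a, t.a + t.b),
        "npv": _ratio(t.d, t.c + t.d),
    }


def bland_altman(x, y) -> tuple[float, tuple[float, float]]:
    """Bias and 95% limits of agreement of paired differences x − y.

    Returns ``(bias, (lower, upper))`` with limits at bias ± 1.96 SD.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("need two equally sized series of length >= 2")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, (bias - 1.96 * sd, bias + 1.96 * sd)


def icc(x, y) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measures."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need paired series of length >= 3")
    if np.allclose(x, x[0]) and np.allclose(y, y[0]):
        raise ValueError("ICC undefined: zero total variance")
    n = len(x)
    df = pd.DataFrame(
        {
            "subject": np.tile(np.arange(n), 2),
            "rater": np.repeat(["A", "B"], n),
            "value": np.concatenate([x, y]),
        }
    )
    import warnings as _warnings

    with _warnings.catch_warnings(), np.errstate(divide="ignore", invalid="ignore"):
        _warnings.simplefilter("ignore", RuntimeWarning)
        table = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="value")
    table = table.set_index("Type")
    # pingouin labels ICC(2,1) either "ICC2" or "ICC(A,1)" depending on version
    for label in ("ICC2", "ICC(A,1)"):
        if label in table.index:
            return float(table.loc[label, "ICC"])
    raise RuntimeError("ICC(2,1) row not found in pingouin output")


def pearson_r2(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


@dataclass
class WilcoxonResult:
    statistic: float   # W+ = sum of ranks of positive differences
    p_value: float
    significant: bool
    n: int             # non-zero differences used
    method: str        # "exact" | "approx"


def _exact_signed_rank_p(w_plus: float, ranks: np.ndarray) -> float:
    """Two-sided exact p over all 2^n sign assignments (midrank ties allowed).

    Uses the generating polynomial of doubled ranks (integers), i.e. a
    convolution over achievable rank sums.
    """
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(round(2.0 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(x, y, alpha: float = 0.05) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test, two-sided.

    Zero differences are dropped (Wilcoxon's convention); the p-value is
    from the exact sign-assignment distribution for n <= 25 non-zero pairs
    (valid under midrank ties) and the tie-corrected normal approximation
    above that.  ``significant`` compares p to ``alpha``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("need equally sized paired series")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero: no test is possible")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= 25:
        p = _exact_signed_rank_p(w_plus, ranks)
        method = "exact"
    else:
        p = float(stats.wilcoxon(x, y, zero_method="wilcox", method="approx").pvalue)
        method = "approx"
    return WilcoxonResult(w_plus, p, bool(p < alpha), n, method)


@dataclass
class AgreementReport:
    """Bundle of the agreement battery for one method pair."""

    kappa: float | None = None
    percent_agreement: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    ppv: float | None = None
    npv: float | None = None
    icc: float | None = None
    r_squared: float | None = None
    bias: float | None = None
    loa: tuple | None = None
    wilcoxon_p: float | None = None
    significant: bool | None = None
    meta: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            if k == "meta" or v is None:
                continue
            out[k] = list(v) if isinstance(v, tuple) else v
        return out
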