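"""Nested likelihood-ratio tests, per-site evidence ratios, and
model-preference categories.

The five models form a (mostly) nested ladder; each comparison is assessed
with a chi-squared likelihood ratio test.  Degrees of freedom follow
parameter counting: 1 for 2H:1H, 3HSI:2H and 3H+:3HSI; 2 for 3H+:2H; 3 for
3H+:1H; and 2 for 3H:1H (delta plus the tied 3H rate).  Null rates sit on
the boundary of the parameter space, which makes the plain chi-squared
reference distribution conservative; this is deliberate and no
boundary-corrected mixture distribution is used.

Evidence ratios (ER) compare per-site likelihoods between two fitted
models: ER_s = L(s | alt) / L(s | null).  Their product over sites equals
the overall likelihood ratio, so large-ER sites are exactly the sites
driving model preference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .fit import FitResult

# comparison name -> (alt model, null model, degrees of freedom)
COMPARISONS: dict[str, tuple[str, str, int]] = {
    "2H:1H": ("2H", "1H", 1),
    "3HSI:2H": ("3HSI", "2H", 1),
    "3H+:3HSI": ("3H+", "3HSI", 1),
    "3H+:2H": ("3H+", "2H", 2),
    "3H+:1H": ("3H+", "1H", 3),
    "3H:1H": ("3H", "1H", 2),
}

# the four comparisons used for rate-preference categorization
CATEGORY_TESTS = ("2H:1H", "3HSI:2H", "3H+:3HSI", "3H+:2H")

_STAT_TOL = -2e-6  # numerical slack for warm-started nested fits


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    p_value: float


def lrt(lnL_alt: float, lnL_null: float, df: int) -> LRTResult:
    """Likelihood ratio test of a nested pair.

    The statistic 2(lnL_alt - lnL_null) is clipped at zero (boundary
    maxima), and the p-value is the upper chi-squared tail with ``df``
    degrees of freedom.
    """
    if df not in (1, 2, 3):
        raise ValueError(f"unsupported degrees of freedom: {df}")
    stat = 2.0 * (lnL_alt - lnL_null)
    if stat < _STAT_TOL:
        raise ValueError(
            f"alternative lnL {lnL_alt} below null {lnL_null}: fits are "
            "inconsistent with nesting"
        )
    stat = max(stat, 0.0)
    return LRTResult(statistic=stat, df=df, p_value=float(chi2.sf(stat, df)))


def evidence_ratios(
    site_lnL_alt: np.ndarray, site_lnL_null: np.ndarray
) -> np.ndarray:
    """Per-site evidence ratios exp(lnL_alt - lnL_null)."""
    a = np.asarray(site_lnL_alt, dtype=float)
    b = np.asarray(site_lnL_null, dtype=float)
    if a.shape != b.shape:
        raise ValueError("site log-likelihood vectors differ in length")
    return np.exp(a - b)


@dataclass
class TestReport:
    """All test results for one alignment."""

    __test__ = False  # not a pytest collectible

    comparisons: dict[str, LRTResult]
    evidence: dict[str, np.ndarray] = field(default_factory=dict)
    alpha: float = 0.01
    bonferroni: int = 1

    def significant(self, name: str, alpha: float | None = None) -> bool:
        a = (alpha if alpha is not None else self.alpha) / self.bonferroni
        return self.comparisons[name].p_value <= a

    def er_count(self, name: str, threshold: float = 5.0) -> int:
        return int((self.evidence[name] > threshold).sum())

    def to_dict(self) -> dict:
        return {
            "test results": {
                name: {
                    "LRT": r.statistic,
                    "df": r.df,
                    "p-value": r.p_value,
                }
                for name, r in self.comparisons.items()
            },
            "evidence ratios": {
                name: er.tolist() for name, er in self.evidence.items()
            },
            "alpha": self.alpha,
            "bonferroni": self.bonferroni,
            "preference category": preference_category(self, self.alpha),
        }


def run_tests(
    fits: dict[str, FitResult],
    alpha: float = 0.01,
    bonferroni: int = 1,
) -> TestReport:
    """Compute every LRT and ER vector available from the fitted models."""
    comps: dict[str, LRTResult] = {}
    evid: dict[str, np.ndarray] = {}
    for name, (alt, null, df) in COMPARISONS.items():
        if alt in fits and null in fits:
            comps[name] = lrt(fits[alt].lnL, fits[null].lnL, df)
            evid[name] = evidence_ratios(
                fits[alt].site_lnL, fits[null].site_lnL
            )
    return TestReport(
        comparisons=comps, evidence=evid, alpha=alpha, bonferroni=bonferroni
    )


def preference_category(report: TestReport, alpha: float = 0.01) -> str:
    """Canonical label for the subset of significant categorization tests.

    Labels: ``"1H"`` (nothing significant), ``"2H-only"`` (only 2H:1H),
    ``"island-constrained"`` (3HSI:2H significant but 3H+:3HSI not —
    triple hits confined to synonymous islands), otherwise the sorted
    ``+``-joined list of significant test names.
    """
    sig = {
        name
        for name in CATEGORY_TESTS
        if name in report.comparisons
        and report.comparisons[name].p_value <= alpha
    }
    if not sig:
        return "1H"
    if sig == {"2H:1H"}:
        return "2H-only"
    if "3HSI:2H" in sig and "3H+:3HSI" not in sig:
        return "island-constrained"
    return "+".join(sorted(sig))
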