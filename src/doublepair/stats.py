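"""Per-stratum relative risk and variance estimation.

The double pair comparison cancels the control occupant's own fatality
risk: with aggregate counts A_orig (female subjects killed), B_orig
(controls killed alongside a female subject), C_orig and D_orig (the
male analogues),

    r1 = A_orig / B_orig,   r2 = C_orig / D_orig,   R = r1 / r2.

The stratified counts a..g (see :mod:`doublepair.pairs`) refine this:
because A_orig = a + b, B_orig = a + c, C_orig = e + f, D_orig = e + g,
the risk ratio can equivalently be written directly on stratified
counts, and — unlike the aggregate form — they support a count-based
variance for ln R:

    var(ln R) = [ (a(a+b+c) + bc)(f+g) + (e(e+f+g) + fg)(b+c) ]
                / [ (a+b)(a+c)(e+f)(e+g) ]

which is symmetric under swapping the female and male triples.  The
older intrinsic-uncertainty error (a standard error on R itself,
R * sqrt(sigma_mu^2 + 1/A + 1/B + 1/C + 1/D)) is provided as a legacy
comparator only and never used in default pooling.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .pairs import PairCounts

__all__ = [
    "RiskEstimate",
    "UndefinedRatioError",
    "simple_ratios",
    "risk_ratio",
    "log_rr_variance",
    "evans_error",
    "estimate_stratum",
]


class UndefinedRatioError(ZeroDivisionError):
    """A ratio or variance is undefined because a denominator count is zero.

    ``which`` names the failing denominator(s).
    """

    def __init__(self, which):
        self.which = tuple(which)
        super().__init__(f"zero denominator count(s): {', '.join(self.which)}")


@dataclasses.dataclass(frozen=True)
class RiskEstimate:
    """Relative-risk estimate for a single stratum."""

    stratum_label: str
    r1: float
    r2: float
    R: float
    var_logR: float
    counts: Optional[PairCounts] = None
    n_fatalities: int = 0

    def as_dict(self) -> dict:
        d = {
            "stratum_label": self.stratum_label,
            "r1": self.r1,
            "r2": self.r2,
            "R": self.R,
            "var_logR": self.var_logR,
            "n_fatalities": self.n_fatalities,
        }
        if self.counts is not None:
            c = self.counts
            d.update(
                a_both=c.a_both, b_subj_only=c.b_subj_only,
                c_ctrl_only=c.c_ctrl_only, e_both=c.e_both,
                f_subj_only=c.f_subj_only, g_ctrl_only=c.g_ctrl_only,
                A_orig=c.A_orig, B_orig=c.B_orig,
                C_orig=c.C_orig, D_orig=c.D_orig,
            )
        return d


def simple_ratios(counts: PairCounts) -> tuple[float, float]:
    """Subject-vs-control fatality ratios (r1 female, r2 male)."""
    bad = [name for name, v in (("B_orig", counts.B_orig),
                                ("D_orig", counts.D_orig)) if v == 0]
    if bad:
        raise UndefinedRatioError(bad)
    return counts.A_orig / counts.B_orig, counts.C_orig / counts.D_orig


def risk_ratio(counts: PairCounts) -> float:
    """Female-vs-male relative risk ratio R on stratified counts.

    Algebraically identical to r1/r2 through the aggregation
    identities; requires B_orig, C_orig and D_orig positive.
    """
    bad = [name for name, v in (("B_orig", counts.B_orig),
                                ("C_orig", counts.C_orig),
                                ("D_orig", counts.D_orig)) if v == 0]
    if bad:
        raise UndefinedRatioError(bad)
    r1 = counts.A_orig / counts.B_orig
    r2 = counts.C_orig / counts.D_orig
    return r1 / r2


def log_rr_variance(counts: PairCounts) -> float:
    """Count-based variance of ln R from the stratified counts."""
    a, b, c = counts.a_both, counts.b_subj_only, counts.c_ctrl_only
    e, f, g = counts.e_both, counts.f_subj_only, counts.g_ctrl_only
    den = (a + b) * (a + c) * (e + f) * (e + g)
    if den == 0:
        bad = [name for name, v in (("A_orig", a + b), ("B_orig", a + c),
                                    ("C_orig", e + f), ("D_orig", e + g))
               if v == 0]
        raise UndefinedRatioError(bad)
    num = (a * (a + b + c) + b * c) * (f + g) + (e * (e + f + g) + f * g) * (b + c)
    return num / den


def evans_error(R: float, counts: PairCounts, sigma_mu: float = 0.0) -> float:
    """Legacy intrinsic-uncertainty standard error of R.

    ``Delta R = R * sqrt(sigma_mu^2 + 1/A + 1/B + 1/C + 1/D)`` on the
    aggregate counts, with sigma_mu conventionally 0.05 or 0.1.  The
    constant term inflates all errors toward a common floor, which
    biases inverse-variance pooling; kept only for comparison with
    historical analyses.
    """
    orig = {"A_orig": counts.A_orig, "B_orig": counts.B_orig,
            "C_orig": counts.C_orig, "D_orig": counts.D_orig}
    bad = [name for name, v in orig.items() if v == 0]
    if bad:
        raise UndefinedRatioError(bad)
    return R * np.sqrt(sigma_mu**2 + sum(1.0 / v for v in orig.values()))


def estimate_stratum(counts: PairCounts, stratum_label: str = "") -> RiskEstimate:
    """Full per-stratum estimate (r1, r2, R, var ln R).

    Raises :class:`UndefinedRatioError` when any required denominator is
    zero; pooling callers catch this and drop the stratum.
    """
    r1, r2 = simple_ratios(counts)
    R = risk_ratio(counts)
    var = log_rr_variance(counts)
    return RiskEstimate(
        stratum_label=stratum_label, r1=r1, r2=r2, R=R, var_logR=var,
        counts=counts, n_fatalities=counts.n_fatalities,
    )
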