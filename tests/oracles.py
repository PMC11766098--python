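"""Independent reference implementations used to check the package.

These deliberately avoid the code paths they validate: exact rational
arithmetic and Decimal continued fractions for the t-test, an explicit
sums-of-squares partition for the repeated-measures ANOVA, per-base
bitmaps for coverage unions, and exhaustive subset search for the
minimal interval cover.
"""

from __future__ import annotations

import itertools
import math
from decimal import Decimal, getcontext
from fractions import Fraction

import numpy as np

getcontext().prec = 60


# ---------------------------------------------------------------------------
# arbitrary-precision one-sample t


def exact_t_statistic(values, reference) -> Decimal:
    """t = (mean - ref) / (sd / sqrt(n)) in exact rational arithmetic,
    with a 60-digit Decimal square root at the end."""
    vals = [Fraction(v) for v in values]
    ref = Fraction(reference)
    n = len(vals)
    mean = sum(vals) / n
    var = sum((x - mean) ** 2 for x in vals) / (n - 1)
    if var == 0:
        raise ZeroDivisionError("zero variance")
    t_sq = n * (mean - ref) ** 2 / var
    t_abs = (Decimal(t_sq.numerator) / Decimal(t_sq.denominator)).sqrt()
    return t_abs if mean >= ref else -t_abs


def _beta_half(df: int) -> Decimal:
    """B(df/2, 1/2) exactly, via Gamma at integers and half-integers."""
    pi = _machin_pi()

    def gamma_half_int(twice: int) -> Decimal:
        # Gamma(twice/2) for positive integer `twice`
        if twice % 2 == 0:
            return Decimal(math.factorial(twice // 2 - 1))
        # Gamma(k + 1/2) = (2k)! sqrt(pi) / (4^k k!)
        k = (twice - 1) // 2
        return (
            Decimal(math.factorial(2 * k)) * pi.sqrt()
            / (Decimal(4) ** k * Decimal(math.factorial(k)))
        )

    return gamma_half_int(df) * gamma_half_int(1) / gamma_half_int(df + 1)


def _machin_pi() -> Decimal:
    """pi to working precision via Machin's arctan formula."""

    def arctan_inv(x: int) -> Decimal:
        total = Decimal(0)
        term = Decimal(1) / x
        xsq = Decimal(x) * x
        n = 0
        while term != 0:
            total += term / (2 * n + 1) * (-1 if n % 2 else 1)
            term /= xsq
            n += 1
        return total

    return 16 * arctan_inv(5) - 4 * arctan_inv(239)


def _betacf(a: Decimal, b: Decimal, x: Decimal, max_iter: int = 500) -> Decimal:
    """Continued fraction for the incomplete beta (Lentz's method)."""
    tiny = Decimal(10) ** -50
    qab, qap, qam = a + b, a + 1, a - 1
    c = Decimal(1)
    d = 1 - qab * x / qap
    if abs(d) < tiny:
        d = tiny
    d = 1 / d
    h = d
    for m in range(1, max_iter):
        m2 = 2 * m
        aa = m * (b - m) * x / ((qam + m2) * (a + m2))
        d = 1 + aa * d
        if abs(d) < tiny:
            d = tiny
        c = 1 + aa / c
        if abs(c) < tiny:
            c = tiny
        d = 1 / d
        h *= d * c
        aa = -(a + m) * (qab + m) * x / ((a + m2) * (qap + m2))
        d = 1 + aa * d
        if abs(d) < tiny:
            d = tiny
        c = 1 + aa / c
        if abs(c) < tiny:
            c = tiny
        d = 1 / d
        delta = d * c
        h *= delta
        if abs(delta - 1) < Decimal(10) ** -55:
            break
    return h


def _reg_inc_beta(a: Decimal, b: Decimal, x: Decimal, beta_ab: Decimal) -> Decimal:
    if x <= 0:
        return Decimal(0)
    if x >= 1:
        return Decimal(1)
    ln_front = a * x.ln() + b * (1 - x).ln()
    front = ln_front.exp() / beta_ab
    if x < (a + 1) / (a + b + 2):
        return front * _betacf(a, b, x) / a
    # symmetry: I_x(a,b) = 1 - I_{1-x}(b,a); B(a,b) symmetric
    ln_front2 = b * (1 - x).ln() + a * x.ln()
    return 1 - ln_front2.exp() / beta_ab * _betacf(b, a, 1 - x) / b


def exact_t_p_two_sided(t: Decimal | float, df: int) -> Decimal:
    """Two-sided p from the t distribution: I_{df/(df+t^2)}(df/2, 1/2)."""
    t = Decimal(t) if not isinstance(t, Decimal) else t
    x = Decimal(df) / (Decimal(df) + t * t)
    a = Decimal(df) / 2
    b = Decimal(1) / 2
    return _reg_inc_beta(a, b, x, _beta_half(df))


# ---------------------------------------------------------------------------
# repeated-measures ANOVA sums-of-squares partition


def rm_anova_ss_partition(values: np.ndarray) -> dict[str, tuple[float, int, int]]:
    """Explicit SS decomposition of a (subjects, a-levels, b-levels)
    array; returns F, df_num, df_den per effect."""
    values = np.asarray(values, dtype=float)
    s, a, b = values.shape
    grand = values.mean()
    A = values.mean(axis=(0, 2))
    B = values.mean(axis=(0, 1))
    S = values.mean(axis=(1, 2))
    AB = values.mean(axis=0)
    AS = values.mean(axis=2)
    BS = values.mean(axis=1)

    ss_a = s * b * ((A - grand) ** 2).sum()
    ss_b = s * a * ((B - grand) ** 2).sum()
    ss_ab = s * ((AB - A[:, None] - B[None, :] + grand) ** 2).sum()
    ss_as = b * ((AS - A[None, :] - S[:, None] + grand) ** 2).sum()
    ss_bs = a * ((BS - B[None, :] - S[:, None] + grand) ** 2).sum()
    resid = (
        values
        - AB[None, :, :]
        - AS[:, :, None]
        - BS[:, None, :]
        + A[None, :, None]
        + B[None, None, :]
        + S[:, None, None]
        - grand
    )
    ss_abs = (resid ** 2).sum()

    df_a, df_b, df_ab = a - 1, b - 1, (a - 1) * (b - 1)
    df_as, df_bs, df_abs = (a - 1) * (s - 1), (b - 1) * (s - 1), (a - 1) * (b - 1) * (s - 1)
    return {
        "factor_a": ((ss_a / df_a) / (ss_as / df_as), df_a, df_as),
        "factor_b": ((ss_b / df_b) / (ss_bs / df_bs), df_b, df_bs),
        "interaction": ((ss_ab / df_ab) / (ss_abs / df_abs), df_ab, df_abs),
    }


# ---------------------------------------------------------------------------
# coverage bitmaps and interval covers


def bitmap_covered_fraction(intervals, qlen: int) -> float:
    """Union of 1-based inclusive intervals via a per-base bitmap."""
    mask = bytearray(qlen)
    for start, end in intervals:
        for i in range(start - 1, end):
            mask[i] = 1
    return sum(mask) / qlen


def bitmap_span_coverage_pct(spans, ref_length: int) -> float:
    """Union of 0-based half-open spans via a per-base bitmap."""
    mask = bytearray(ref_length)
    for start, end in spans:
        for i in range(start, end):
            mask[i] = 1
    return 100.0 * sum(mask) / ref_length


def brute_force_min_cover(intervals: dict[str, tuple[int, int]]) -> int | None:
    """Smallest number of intervals covering every rank covered by any
    interval; exhaustive subset search (feasible for <= ~15 intervals)."""
    names = sorted(intervals)
    target = set()
    for first, last in intervals.values():
        target.update(range(first, last + 1))
    for size in range(1, len(names) + 1):
        for combo in itertools.combinations(names, size):
            covered = set()
            for name in combo:
                first, last = intervals[name]
                covered.update(range(first, last + 1))
            if covered >= target:
                return size
    return None
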