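"""Small shared statistical helpers."""

from __future__ import annotations

import math

from scipy import stats


def round_percent(numerator: float, denominator: float) -> int:
    """100*num/den rounded to the nearest integer percent (half away from zero)."""
    if denominator == 0:
        raise ZeroDivisionError("percentage undefined for zero denominator")
    x = 100.0 * numerator / denominator
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def fisher_2x2(a: int, b: int, c: int, d: int, alternative: str = "two-sided") -> float:
    """Fisher's exact p for the 2x2 table [[a, b], [c, d]].

    Two-sided p follows the "probability at most observed" rule (the
    convention scipy implements); one-sided alternatives are the exact
    hypergeometric tails.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError(f"table entries must be non-negative, got {(a, b, c, d)}")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative=alternative)[1])


def binomial_tail_p(n_success: int, n_trials: int, p: float = 0.5) -> float:
    """One-sided exact binomial tail P(X >= n_success)."""
    if not 0 <= n_success <= n_trials:
        raise ValueError("n_success must be in [0, n_trials]")
    return float(stats.binom.sf(n_success - 1, n_trials, p))
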