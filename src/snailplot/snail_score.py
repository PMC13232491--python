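"""The snail score: adjusted relative auN, with expected-size corrections.

Relative auN is auN divided by the longest scaffold length, a unitless value
in (0, 1] that equals 1 only for single-scaffold (or all-equal-length)
assemblies. The snail score is the same ratio computed from the N-adjusted
auN, so joining contigs with long N runs cannot inflate the score.

Corrections guard against over-filtering, incomplete assembly, and
over-scaffolding when an expected genome size and/or expected longest
scaffold length (typically from a T2T reference assembly) is available:

* G  : base * min(1, span / expected_span)
* GS : G * min(1, longest / expected_longest)
* aG : base * r_G if r_G <= 1 else base / r_G        (r_G = span ratio)
* aGS: G * r_S if r_S <= 1 else G / r_S              (r_S = longest ratio)

The absolute (a-) variants take the inverse of the ratio instead of clamping
when it exceeds one, penalizing spans or longest scaffolds that overshoot
the expectation. aGS chains from the clamped G score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import ConfigError, InputError
from .summary_stats import AssemblySummary


@dataclass
class ScoreSet:
    """Snail score plus corrected variants and the expectations that fed them.

    Corrected variants are ``None`` when the expectation they require is
    absent (g/ag need ``expected_span``; gs/ags additionally need
    ``expected_longest``).
    """

    relative_aun: float
    base: float
    g: Optional[float] = None
    gs: Optional[float] = None
    ag: Optional[float] = None
    ags: Optional[float] = None
    expected_span: Optional[float] = None
    expected_longest: Optional[float] = None

    def as_dict(self) -> dict:
        return {
            "relative_aun": self.relative_aun,
            "base": self.base,
            "g": self.g,
            "gs": self.gs,
            "ag": self.ag,
            "ags": self.ags,
            "expected_span": self.expected_span,
            "expected_longest": self.expected_longest,
        }

    def get(self, score_type: str) -> Optional[float]:
        if score_type not in ("base", "g", "gs", "ag", "ags"):
            raise ConfigError(f"unknown score type {score_type!r}; expected base, g, gs, ag or ags")
        return getattr(self, score_type)


def relative_aun(aun: float, longest: float) -> float:
    """auN / longest scaffold length, in (0, 1]."""
    if longest <= 0:
        raise InputError("longest scaffold length must be positive")
    if aun <= 0 or aun > longest:
        raise InputError(f"auN must be in (0, longest]; got auN={aun}, longest={longest}")
    return aun / longest


def snail_score(adjusted_aun: float, longest: float) -> float:
    """Adjusted auN / longest scaffold length (including Ns), in (0, 1].

    Equals :func:`relative_aun` for assemblies with no Ns.
    """
    return relative_aun(adjusted_aun, longest)


def _clamped(ratio: float) -> float:
    return min(1.0, ratio)


def _absolute(ratio: float) -> float:
    return ratio if ratio <= 1.0 else 1.0 / ratio


def correct_scores(
    base: float,
    span: float,
    longest: float,
    expected_span: Optional[float] = None,
    expected_longest: Optional[float] = None,
    relative: Optional[float] = None,
) -> ScoreSet:
    """Apply the expected-size corrections to a base snail score.

    ``relative`` optionally records the unadjusted relative auN alongside the
    base score; it defaults to ``base`` (exact for N-free assemblies).
    """
    if not 0 < base <= 1:
        raise InputError(f"base snail score must be in (0, 1], got {base}")
    if expected_span is not None and expected_span <= 0:
        raise ConfigError(f"expected span must be positive, got {expected_span}")
    if expected_longest is not None and expected_longest <= 0:
        raise ConfigError(f"expected longest scaffold must be positive, got {expected_longest}")
    scores = ScoreSet(
        relative_aun=relative if relative is not None else base,
        base=base,
        expected_span=expected_span,
        expected_longest=expected_longest,
    )
    if expected_span is not None:
        r_g = span / expected_span
        scores.g = base * _clamped(r_g)
        scores.ag = base * _absolute(r_g)
        if expected_longest is not None:
            r_s = longest / expected_longest
            scores.gs = scores.g * _clamped(r_s)
            scores.ags = scores.g * _absolute(r_s)
    return scores


def score_assembly(
    summary: AssemblySummary,
    reference: Optional[AssemblySummary] = None,
    expected_span: Optional[float] = None,
    expected_longest: Optional[float] = None,
) -> ScoreSet:
    """Build the full score set for an assembly summary.

    A reference assembly supplies ``expected_span`` (its span) and
    ``expected_longest`` (its longest scaffold); explicit values override the
    reference-derived ones.
    """
    if expected_span is None and reference is not None:
        expected_span = reference.span
    if expected_longest is None and reference is not None:
        expected_longest = reference.longest
    base = snail_score(summary.adjusted_aun, summary.longest)
    rel = relative_aun(summary.aun, summary.longest)
    return correct_scores(
        base,
        span=summary.span,
        longest=summary.longest,
        expected_span=expected_span,
        expected_longest=expected_longest,
        relative=rel,
    )
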