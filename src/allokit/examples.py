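"""Worked-example target patterns for the flexibility construction.

Three four-site target patterns (labelled by the colours used in their
original presentation) with different mixtures of positive and negative
effective cooperativities, together with the accuracy controls (delta,
eps) at which the construction realizes each of them to a maximum relative
error below 0.01.
"""

from __future__ import annotations

from typing import Dict, Tuple

from .flexibility import TargetPattern

__all__ = ["four_site_patterns"]


def _pattern(beta, alpha) -> TargetPattern:
    return TargetPattern(
        n=4,
        beta=dict(enumerate(beta, start=1)),
        alpha={(i, frozenset(S)): v for (i, *S), v in alpha.items()},
    )


def four_site_patterns() -> Dict[str, Tuple[TargetPattern, float, float]]:
    """name -> (targets, delta, eps) for the three worked examples."""
    maroon = _pattern(
        (1.5777, 24.013, 89.958, 0.015685),
        {
            (1, 2): 0.084815,
            (1, 3): 3.7432,
            (1, 4): 0.044245,
            (2, 3): 30.240,
            (2, 4): 0.074064,
            (3, 4): 9.2687,
            (1, 2, 3): 4.0933,
            (1, 2, 4): 15.687,
            (1, 3, 4): 0.013335,
            (2, 3, 4): 0.082851,
            (1, 2, 3, 4): 6.5843,
        },
    )
    orange = _pattern(
        (0.031353, 0.011104, 13.195, 52.437),
        {
            (1, 2): 1.0801,
            (1, 3): 34.768,
            (1, 4): 0.032668,
            (2, 3): 4.0683,
            (2, 4): 1.5098,
            (3, 4): 0.025183,
            (1, 2, 3): 0.31238,
            (1, 2, 4): 0.70016,
            (1, 3, 4): 0.13042,
            (2, 3, 4): 2.5235,
            (1, 2, 3, 4): 0.017404,
        },
    )
    red = _pattern(
        (0.21257, 0.84301, 9.8514, 27.000),
        {
            (1, 2): 50.455,
            (1, 3): 0.016359,
            (1, 4): 0.60018,
            (2, 3): 7.2944,
            (2, 4): 0.010809,
            (3, 4): 0.012613,
            (1, 2, 3): 57.783,
            (1, 2, 4): 0.025618,
            (1, 3, 4): 4.4450,
            (2, 3, 4): 0.13584,
            (1, 2, 3, 4): 0.063587,
        },
    )
    return {
        "maroon": (maroon, 1e-7, 1e-12),
        "orange": (orange, 1e-7, 1e-14),
        "red": (red, 1e-7, 1e-16),
    }
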