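"""Backcasting little auk abundance under pre-whaling bowhead numbers.

The competitive share ``Za`` measures the little auks' realised hold on
their niche once current whale consumption is netted out:

    Za = Ca21 / (Qa - Cb21 * Y)

The whaling-era predation release ``Cb17 - Cb21`` is assumed accessible to
auks only in proportion to the niche-overlap degree ``Y``, of which they
capture the share ``Za`` (competition with unmodelled zooplanktivores takes
the rest).  The backcast abundance is then a cross-multiplication:

    Na17 = Na21 * (Ca21 - (Cb17 - Cb21) * Y * Za) / Ca21

All quantities must be in one consistent biomass unit (internally the
package uses grams); the functions are unit-agnostic ratios otherwise.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .errors import InputError


@dataclass(frozen=True)
class BackcastInputs:
    """Present-day state feeding the backcast (consistent biomass units)."""

    na21_pairs: float
    ca21: float
    cb17: float
    cb21: float
    qa: float
    y: float

    def __post_init__(self) -> None:
        if min(self.na21_pairs, self.ca21, self.cb17, self.cb21, self.qa) < 0:
            raise InputError("backcast inputs must be non-negative")
        if self.ca21 > self.qa * (1 + 1e-12):
            raise InputError("consumption Ca21 cannot exceed accessible biomass Qa")
        if not 0 <= self.y <= 1:
            raise InputError("overlap degree Y must lie in [0, 1]")


@dataclass(frozen=True)
class BackcastResult:
    """Backcast outputs; ``valid`` is False for arithmetic pathologies
    (Za outside [0, 1] or a negative abundance)."""

    za: float
    release: float
    release_in_auk_niche: float
    auk_consumed_release: float
    na17_pairs: float
    valid: bool


def competitive_share(ca21: float, qa: float, cb21: float, y: float) -> float:
    """Za: fraction of auk-accessible, whale-unconsumed biomass that auks consume.

    Returns ``nan`` when the denominator ``Qa - Cb21*Y`` is non-positive;
    callers treat that (and Za outside [0, 1]) as an invalid scenario.
    """
    if min(ca21, qa, cb21) < 0:
        raise InputError("biomass quantities must be non-negative")
    if not 0 <= y <= 1:
        raise InputError("overlap degree Y must lie in [0, 1]")
    denom = qa - cb21 * y
    if denom <= 0:
        return float("nan")
    return ca21 / denom


def predation_release(cb17: float, cb21: float) -> float:
    """Biomass no longer consumed by whales after their collapse, Cb17 - Cb21."""
    if cb17 < 0 or cb21 < 0:
        raise InputError("consumptions must be non-negative")
    if cb17 < cb21:
        warnings.warn(
            "Cb17 < Cb21: computing a negative release (whale recovery scenario)",
            stacklevel=2,
        )
    return cb17 - cb21


def backcast_na17(inputs: BackcastInputs, za: float) -> BackcastResult:
    """Little auk abundance with pre-whaling bowhead numbers.

    ``Na17 = Na21 * (Ca21 - release * Y * Za) / Ca21`` with
    ``release = Cb17 - Cb21``.  When whale consumption is unchanged
    (``Cb17 = Cb21``) or the niches are disjoint (``Y = 0``) this reduces to
    ``Na17 = Na21`` exactly.
    """
    if inputs.ca21 <= 0:
        raise InputError("Ca21 must be positive to backcast")
    release = inputs.cb17 - inputs.cb21
    release_in_niche = release * inputs.y
    consumed_release = release_in_niche * za
    na17 = inputs.na21_pairs * (inputs.ca21 - consumed_release) / inputs.ca21
    valid = math.isfinite(za) and 0 <= za <= 1 and math.isfinite(na17) and na17 >= 0
    return BackcastResult(
        za=za,
        release=release,
        release_in_auk_niche=release_in_niche,
        auk_consumed_release=consumed_release,
        na17_pairs=na17,
        valid=valid,
    )
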