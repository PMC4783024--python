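"""Expression-to-colour mapping for the three interpretation modes.

*Absolute* mode paints each tissue on a yellow-to-red ramp: yellow is no
expression, full red is the view's maximal tissue mean (or a user cap).
*Relative* mode colours the log2 ratio of each tissue's mean to a control
level, defined as the median of the non-missing tissue means in the
view: yellow-to-red above the control, yellow-to-blue below, exact
yellow at the control.  *Compare* mode applies the Relative colour rule
to the per-tissue log2 ratio of a primary gene over a secondary gene.

Ratios are log2-transformed before colouring so a k-fold increase and a
k-fold decrease sit symmetrically on the two ramps.  Tissues whose mean
is zero (or whose control/denominator is zero) have an undefined log
ratio and are masked grey rather than coloured; tissues without data get
a lighter "missing" grey.  Ramp saturation defaults to "auto": the
largest |log2 ratio| among unmasked tissues maps to the ramp endpoint.

Channel interpolation rounds half-up, so colour assignments are
bit-exact and testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .errors import AnatogramError
from .expression import TissueSummary

RGB = tuple[int, int, int]

YELLOW: RGB = (255, 255, 0)
RED: RGB = (255, 0, 0)
BLUE: RGB = (0, 0, 255)
MISSING_GREY: RGB = (221, 221, 221)
MASKED_GREY: RGB = (160, 160, 160)


@dataclass(frozen=True)
class ColourSpec:
    """The five sentinel colours of the scheme; overridable but distinct.

    zero_colour anchors both ramps (no expression / at control level);
    high_colour and low_colour are the ramp endpoints above and below;
    missing_colour marks tissues without data; masked_colour marks
    tissues whose ratio is undefined (zero numerator/denominator).
    """

    zero_colour: RGB = YELLOW
    high_colour: RGB = RED
    low_colour: RGB = BLUE
    missing_colour: RGB = MISSING_GREY
    masked_colour: RGB = MASKED_GREY

    def __post_init__(self) -> None:
        colours = (
            self.zero_colour,
            self.high_colour,
            self.low_colour,
            self.missing_colour,
            self.masked_colour,
        )
        if len(set(colours)) != 5:
            raise AnatogramError("the five scheme colours must be distinct")
        for c in colours:
            if len(c) != 3 or any(not (0 <= v <= 255) for v in c):
                raise AnatogramError(f"invalid RGB triple {c}")


@dataclass(frozen=True)
class ModeResult:
    """Per-tissue numeric result and assigned colour for one query.

    ``value`` is the absolute tissue mean (Absolute mode) or the signed
    log2 ratio (Relative/Compare); ``fold_change`` is 2^|value| with the
    direction carried by the sign of ``value``; ``control`` is the
    median control level (Relative mode only).  ``mean`` always carries
    the tissue's mean expression for tables and tooltips.
    """

    tissue_name: str
    value: float
    colour: RGB
    mean: float = math.nan
    control: Optional[float] = None
    fold_change: Optional[float] = None
    sd: Optional[float] = None
    masked: bool = False
    missing: bool = False


def interpolate_colour(fraction: float, from_colour: RGB, to_colour: RGB) -> RGB:
    """Per-channel linear interpolation with round-half-up to integers."""
    if not (0.0 <= fraction <= 1.0):
        raise AnatogramError(f"interpolation fraction {fraction} outside [0, 1]")
    return tuple(
        int(math.floor(f + (t - f) * fraction + 0.5))
        for f, t in zip(from_colour, to_colour)
    )  # type: ignore[return-value]


def _require_data(summaries: Sequence[TissueSummary]) -> None:
    if not any(not s.missing for s in summaries):
        raise AnatogramError("all tissues are missing; nothing to colour")


def absolute_mode(
    summaries: Sequence[TissueSummary],
    cap: Optional[float] = None,
    spec: ColourSpec = ColourSpec(),
) -> list[ModeResult]:
    """Yellow-to-red colouring of tissue means against the view maximum.

    The ramp endpoint M is ``cap`` when given, else the largest
    non-missing tissue mean; means above the cap clamp to full red.
    M = 0 (a gene silent everywhere) leaves every tissue at the zero
    colour.
    """
    _require_data(summaries)
    if cap is not None and cap <= 0:
        raise AnatogramError(f"cap must be positive, got {cap}")
    m = cap if cap is not None else max(s.mean for s in summaries if not s.missing)
    out: list[ModeResult] = []
    for s in summaries:
        if s.missing:
            out.append(
                ModeResult(s.tissue_name, math.nan, spec.missing_colour, missing=True)
            )
            continue
        fraction = 0.0 if m == 0 else min(s.mean / m, 1.0)
        colour = interpolate_colour(fraction, spec.zero_colour, spec.high_colour)
        out.append(
            ModeResult(s.tissue_name, s.mean, colour, mean=s.mean, sd=s.sd)
        )
    return out


def _ratio_colour(value: float, saturation: float, spec: ColourSpec) -> RGB:
    if value == 0 or saturation == 0:
        return spec.zero_colour
    fraction = min(abs(value) / saturation, 1.0)
    target = spec.high_colour if value > 0 else spec.low_colour
    return interpolate_colour(fraction, spec.zero_colour, target)


def _saturation(
    values: Sequence[float], cap_log2: Union[float, str]
) -> float:
    if cap_log2 != "auto":
        cap = float(cap_log2)  # type: ignore[arg-type]
        if cap <= 0:
            raise AnatogramError(f"cap_log2 must be positive, got {cap_log2}")
        return cap
    return max((abs(v) for v in values), default=0.0)


def relative_mode(
    summaries: Sequence[TissueSummary],
    cap_log2: Union[float, str] = "auto",
    spec: ColourSpec = ColourSpec(),
) -> list[ModeResult]:
    """Colour each tissue by log2(mean / control).

    The control is the median of the non-missing tissue means (even
    count: mean of the two central values).  Zero means — and every
    tissue when the control itself is zero — are masked.  Saturation S
    is ``cap_log2`` when numeric, else the max |log2 ratio| over
    unmasked tissues; S = 0 (all tissues at control) gives all yellow.
    """
    _require_data(summaries)
    means = sorted(s.mean for s in summaries if not s.missing)
    mid = len(means) // 2
    control = (
        means[mid] if len(means) % 2 else (means[mid - 1] + means[mid]) / 2.0
    )
    values: dict[str, float] = {}
    for s in summaries:
        if s.missing or s.mean == 0 or control == 0:
            continue
        values[s.tissue_name] = math.log2(s.mean / control)
    saturation = _saturation(list(values.values()), cap_log2)
    out: list[ModeResult] = []
    for s in summaries:
        if s.missing:
            out.append(
                ModeResult(
                    s.tissue_name, math.nan, spec.missing_colour,
                    control=control, missing=True,
                )
            )
        elif s.tissue_name not in values:
            out.append(
                ModeResult(
                    s.tissue_name, math.nan, spec.masked_colour,
                    mean=s.mean, control=control, sd=s.sd, masked=True,
                )
            )
        else:
            v = values[s.tissue_name]
            out.append(
                ModeResult(
                    s.tissue_name,
                    v,
                    _ratio_colour(v, saturation, spec),
                    mean=s.mean,
                    control=control,
                    fold_change=2.0 ** abs(v),
                    sd=s.sd,
                )
            )
    return out


def compare_mode(
    primary: Sequence[TissueSummary],
    secondary: Sequence[TissueSummary],
    cap_log2: Union[float, str] = "auto",
    spec: ColourSpec = ColourSpec(),
) -> list[ModeResult]:
    """Colour each tissue by log2(primary mean / secondary mean).

    Both summary lists must cover the same tissues in the same order.
    A tissue is masked when either gene's mean is zero or missing.
    Saturation follows the Relative-mode rule.
    """
    if [s.tissue_name for s in primary] != [s.tissue_name for s in secondary]:
        raise AnatogramError("primary and secondary tissue lists differ")
    values: dict[str, float] = {}
    for p, s in zip(primary, secondary):
        if p.missing or s.missing or p.mean == 0 or s.mean == 0:
            continue
        values[p.tissue_name] = math.log2(p.mean / s.mean)
    saturation = _saturation(list(values.values()), cap_log2)
    out: list[ModeResult] = []
    for p, s in zip(primary, secondary):
        if p.missing and s.missing:
            out.append(
                ModeResult(p.tissue_name, math.nan, spec.missing_colour, missing=True)
            )
        elif p.tissue_name not in values:
            out.append(
                ModeResult(
                    p.tissue_name, math.nan, spec.masked_colour,
                    mean=p.mean, sd=p.sd, masked=True,
                )
            )
        else:
            v = values[p.tissue_name]
            out.append(
                ModeResult(
                    p.tissue_name,
                    v,
                    _ratio_colour(v, saturation, spec),
                    mean=p.mean,
                    fold_change=2.0 ** abs(v),
                    sd=p.sd,
                )
            )
    return out
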