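"""Per-array trimmed-mean scaling to a common target intensity.

Microarray compendia are only comparable across arrays after each array's
overall signal level has been equalized.  The convention implemented here
is the scaling step of the MAS 5 pipeline: compute the two-sided trimmed
mean of each array (column), default trim fraction 2% per tail with the
per-tail trim count ``floor(n * trim_fraction)``, and multiply the column
by ``target / trimmed_mean`` so every array's trimmed mean equals the
target (default 100 signal units).

This operates on already-summarized probe-set signals; probe-level
processing (background correction, mismatch handling, Tukey-biweight
summarization) happens upstream and is out of scope here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import NormalizationError
from .expression import ExpressionMatrix


@dataclass(frozen=True)
class ScalingConfig:
    """Target intensity and two-sided trim fraction for array scaling.

    ``target`` is the common post-scaling trimmed mean (signal units,
    default 100); ``trim_fraction`` is the fraction trimmed from *each*
    tail before averaging (default 0.02).
    """

    target: float = 100.0
    trim_fraction: float = 0.02

    def __post_init__(self) -> None:
        if not self.target > 0:
            raise NormalizationError(f"target must be > 0, got {self.target}")
        if not (0 <= self.trim_fraction < 0.5):
            raise NormalizationError(
                f"trim_fraction must be in [0, 0.5), got {self.trim_fraction}"
            )


def trimmed_mean(values: Sequence[float], trim_fraction: float = 0.02) -> float:
    """Two-sided trimmed mean: drop ``floor(n*trim_fraction)`` values from
    each end of the sorted vector, average the rest.

    Missing entries (NaN) are removed first; an empty vector (after
    removal) is a hard error.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise NormalizationError("trimmed_mean of empty vector")
    if not (0 <= trim_fraction < 0.5):
        raise NormalizationError(
            f"trim_fraction must be in [0, 0.5), got {trim_fraction}"
        )
    k = math.floor(arr.size * trim_fraction)
    arr.sort()
    kept = arr[k : arr.size - k] if k else arr
    return float(kept.mean())


def scale_array(
    column: Sequence[float], config: ScalingConfig = ScalingConfig()
) -> tuple[np.ndarray, float]:
    """Scale one array (column) so its trimmed mean equals the target.

    Returns ``(scaled_values, scale_factor)`` where
    ``scale_factor = target / trimmed_mean(column)``.  Missing entries
    stay missing.  A non-positive trimmed mean is a hard error.
    """
    arr = np.asarray(column, dtype=float)
    tm = trimmed_mean(arr, config.trim_fraction)
    if tm <= 0:
        raise NormalizationError(f"non-positive trimmed mean ({tm}); cannot scale")
    factor = config.target / tm
    return arr * factor, factor


def scale_matrix(
    matrix: ExpressionMatrix, config: ScalingConfig = ScalingConfig()
) -> tuple[ExpressionMatrix, dict[str, float]]:
    """Apply :func:`scale_array` independently to every column.

    Returns the scaled matrix (platform tag preserved, missing cells
    preserved) and the per-sample scale factors.
    """
    scaled = {}
    factors: dict[str, float] = {}
    for sample in matrix.sample_ids:
        col = matrix.values[sample].to_numpy()
        try:
            scaled_col, factor = scale_array(col, config)
        except NormalizationError as exc:
            raise NormalizationError(f"sample {sample!r}: {exc}") from exc
        scaled[sample] = scaled_col
        factors[sample] = factor
    out = pd.DataFrame(scaled, index=matrix.values.index, columns=matrix.sample_ids)
    return ExpressionMatrix(out, matrix.platform_tag), factors
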