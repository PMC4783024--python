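"""Independent brute-force oracles for cross-checking the colour engine.

Deliberately a separate code path from the package: numpy-based
arithmetic, manual sorting/median, explicit loops.  Used to verify the
mode functions bit-exactly on random inputs.
"""

from __future__ import annotations

import numpy as np

YELLOW = (255, 255, 0)
RED = (255, 0, 0)
BLUE = (0, 0, 255)
MISSING = (221, 221, 221)
MASKED = (160, 160, 160)


def oracle_interpolate(fraction, frm, to):
    frm = np.asarray(frm, dtype=float)
    to = np.asarray(to, dtype=float)
    mixed = frm + (to - frm) * fraction
    return tuple(int(v) for v in np.floor(mixed + 0.5))


def oracle_median(values):
    vals = sorted(values)
    n = len(vals)
    if n % 2 == 1:
        return vals[n // 2]
    return (vals[n // 2 - 1] + vals[n // 2]) / 2.0


def oracle_absolute(means, missing_flags, cap=None):
    """Expected colours for absolute mode; means aligned with missing flags."""
    present = [m for m, miss in zip(means, missing_flags) if not miss]
    top = cap if cap is not None else max(present)
    colours = []
    for m, miss in zip(means, missing_flags):
        if miss:
            colours.append(MISSING)
        elif top == 0:
            colours.append(YELLOW)
        else:
            colours.append(oracle_interpolate(min(m / top, 1.0), YELLOW, RED))
    return colours


def _oracle_ratio_colours(values, masked_flags, missing_flags, cap_log2):
    if cap_log2 == "auto":
        unmasked = [
            v for v, mk, ms in zip(values, masked_flags, missing_flags)
            if not mk and not ms
        ]
        sat = max((abs(v) for v in unmasked), default=0.0)
    else:
        sat = float(cap_log2)
    colours = []
    for v, mk, ms in zip(values, masked_flags, missing_flags):
        if ms:
            colours.append(MISSING)
        elif mk:
            colours.append(MASKED)
        elif v == 0 or sat == 0:
            colours.append(YELLOW)
        else:
            frac = min(abs(v) / sat, 1.0)
            target = RED if v > 0 else BLUE
            colours.append(oracle_interpolate(frac, YELLOW, target))
    return colours


def oracle_relative(means, missing_flags, cap_log2="auto"):
    """Expected (values, colours) for relative mode."""
    present = [m for m, miss in zip(means, missing_flags) if not miss]
    control = oracle_median(present)
    values, masked = [], []
    for m, miss in zip(means, missing_flags):
        if miss:
            values.append(np.nan)
            masked.append(False)
        elif m == 0 or control == 0:
            values.append(np.nan)
            masked.append(True)
        else:
            values.append(float(np.log2(m / control)))
            masked.append(False)
    colours = _oracle_ratio_colours(values, masked, missing_flags, cap_log2)
    return control, values, colours


def oracle_compare(p_means, p_missing, s_means, s_missing, cap_log2="auto"):
    """Expected (values, colours) for compare mode."""
    values, masked, missing = [], [], []
    for pm, pmiss, sm, smiss in zip(p_means, p_missing, s_means, s_missing):
        if pmiss and smiss:
            values.append(np.nan)
            masked.append(False)
            missing.append(True)
        elif pmiss or smiss or pm == 0 or sm == 0:
            values.append(np.nan)
            masked.append(True)
            missing.append(False)
        else:
            values.append(float(np.log2(pm / sm)))
            masked.append(False)
            missing.append(False)
    colours = _oracle_ratio_colours(values, masked, missing, cap_log2)
    return values, colours
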