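"""Chemical-shift comparisons between two protein states.

The weighted combined amide perturbation uses the conventional weighting of
the 15N dimension by the shift-dispersion ratio 0.154, so that 1H and 15N
changes contribute on a common ppm scale.
"""

from __future__ import annotations

import logging
import math
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "W_H",
    "W_N",
    "csp",
    "csp_map",
    "classify_significant",
    "compare_secondary_shifts",
]

#: Weight of the 1H shift difference in the combined perturbation.
W_H = 1.0
#: Weight of the 15N shift difference in the combined perturbation.
W_N = 0.154


def csp(dH_a: float, dH_b: float, dN_a: float, dN_b: float) -> float:
    """Weighted combined 1H/15N perturbation between states a and b (ppm).

    sqrt((ddH*W_H)^2 + (ddN*W_N)^2) with W_H = 1 and W_N = 0.154.
    """
    ddH = dH_b - dH_a
    ddN = dN_b - dN_a
    if not (math.isfinite(ddH) and math.isfinite(ddN)):
        raise ValueError("shift differences must be finite")
    return math.hypot(ddH * W_H, ddN * W_N)


def csp_map(table_a: dict, table_b: dict) -> dict:
    """Per-residue combined perturbations from two {residue: (dH, dN)} tables.

    Residues missing from either state are skipped with a logged notice,
    never imputed.
    """
    out = {}
    for res, (h_a, n_a) in table_a.items():
        if res not in table_b:
            logger.info("residue %s missing in second state; skipped", res)
            continue
        h_b, n_b = table_b[res]
        out[res] = csp(h_a, h_b, n_a, n_b)
    return out


def classify_significant(csp_by_residue: dict, threshold_ppm: float = 0.3) -> list:
    """Residues with perturbation strictly above ``threshold_ppm``, ordered."""
    if threshold_ppm <= 0:
        raise ValueError("threshold must be positive")
    return [res for res, v in csp_by_residue.items() if v > threshold_ppm]


class SecondaryShiftFit(NamedTuple):
    slope: float
    intercept: float
    r: float
    n: int


def compare_secondary_shifts(
    ca_a: dict, ca_b: dict, random_coil: dict
) -> SecondaryShiftFit:
    """Linear comparison of secondary Calpha shifts between two states.

    The secondary shift of each residue is its observed Calpha shift minus
    the residue's random-coil reference; the paired values from states a and
    b are regressed (b on the x-axis) and the Pearson correlation returned.
    A slope and r near 1 indicate an unchanged backbone conformation.
    """
    shared = [r for r in ca_a if r in ca_b and r in random_coil]
    if len(shared) < 3:
        raise ValueError("need at least 3 residues with Calpha and coil values")
    sec_a = np.array([ca_a[r] - random_coil[r] for r in shared])
    sec_b = np.array([ca_b[r] - random_coil[r] for r in shared])
    res = stats.linregress(sec_b, sec_a)
    return SecondaryShiftFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        n=len(shared),
    )
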