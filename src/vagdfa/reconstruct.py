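"""Criterion-gated signal reconstruction from selected IMFs.

Only IMFs whose dual-scaling DFA fit shows persistent temporal correlations
(alpha > 0.5) with a trustworthy log-log regression (R^2 > 0.9) are summed.
Applying the gate to the short-scale exponent yields the "local" (x_alpha1)
reconstruction; applying it to the long-scale exponent yields the "global"
(x_alpha2) reconstruction.  Both thresholds are strict inequalities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dfa import DualScalingFit
from .emd import ImfDecomposition

__all__ = ["ReconstructedPair", "select_components", "reconstruct_signal", "reconstruct_pair"]

ALPHA_MIN = 0.5
R2_MIN = 0.9


@dataclass(frozen=True)
class ReconstructedPair:
    x_alpha1: np.ndarray
    x_alpha2: np.ndarray
    included_local: frozenset[int]
    included_global: frozenset[int]
    empty_local: bool
    empty_global: bool


def select_components(
    fits: list[DualScalingFit | None],
    scale: str,
    alpha_min: float = ALPHA_MIN,
    r2_min: float = R2_MIN,
) -> frozenset[int]:
    """1-based indices of IMFs passing the persistence + fit-quality gate.

    ``scale='local'`` tests (alpha1, r2_1); ``scale='global'`` tests
    (alpha2, r2_2).  Missing fits are excluded.
    """
    if scale not in ("local", "global"):
        raise ValueError("scale must be 'local' or 'global'")
    out = set()
    for i, fit in enumerate(fits, start=1):
        if fit is None:
            continue
        alpha, r2 = (fit.alpha1, fit.r2_1) if scale == "local" else (fit.alpha2, fit.r2_2)
        if alpha > alpha_min and r2 > r2_min:
            out.add(i)
    return frozenset(out)


def reconstruct_signal(decomp: ImfDecomposition, idx) -> np.ndarray:
    """Element-wise sum of the selected IMFs (zero signal for an empty set)."""
    n = decomp.residue.size
    out = np.zeros(n)
    for i in idx:
        if not 1 <= i <= len(decomp.imfs):
            raise IndexError(f"IMF index {i} out of range 1..{len(decomp.imfs)}")
        out += decomp.imfs[i - 1]
    return out


def reconstruct_pair(
    decomp: ImfDecomposition,
    fits: list[DualScalingFit | None],
    alpha_min: float = ALPHA_MIN,
    r2_min: float = R2_MIN,
) -> ReconstructedPair:
    """Local (alpha1) and global (alpha2) reconstructions of one recording.

    Recordings where no IMF passes a gate keep a zero signal and a flag so
    cohort sizes stay balanced downstream.
    """
    local = select_components(fits, "local", alpha_min, r2_min)
    global_ = select_components(fits, "global", alpha_min, r2_min)
    return ReconstructedPair(
        x_alpha1=reconstruct_signal(decomp, sorted(local)),
        x_alpha2=reconstruct_signal(decomp, sorted(global_)),
        included_local=local,
        included_global=global_,
        empty_local=not local,
        empty_global=not global_,
    )
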