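"""Position-specific compositional bias between two fragment sets.

The comparison mirrors a two-sample sequence logo: for every flanking
window position and every residue, the occurrence frequencies in set A and
set B are contrasted with a two-sided two-proportion test, and the
(position, residue) pairs significant at ``alpha`` are reported as
enriched (over-represented in A) or depleted (over-represented in B).
Counts too sparse for the normal approximation (any expected cell below 5)
fall back to Fisher's exact test.  No multiple-testing correction is
applied by default, so the report is a raw per-cell significance table; a
Bonferroni flag is available for conservative use.

Also provided: per-position mean solvent-accessibility profiles, used to
contrast the structural exposure of modified versus unmodified cysteines.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import ASATable
from .seq_data import AA_ORDER, PAD, SiteFragment, window_offsets


@dataclass(frozen=True)
class PositionBias:
    """A significant compositional difference at one (position, residue) cell."""

    position: int
    residue: str
    direction: Literal["enriched", "depleted"]
    p_value: float
    freq_a: float
    freq_b: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        expected = "enriched" if self.freq_a > self.freq_b else "depleted"
        if self.direction != expected:
            raise ValueError("direction inconsistent with frequency difference")


def _two_proportion_p(c_a: int, n_a: int, c_b: int, n_b: int) -> float:
    """Two-sided p-value for H0: equal occurrence proportions.

    Uses the pooled two-proportion z-test, switching to Fisher's exact test
    whenever any expected count under H0 drops below 5.
    """
    table = np.array([[c_a, n_a - c_a], [c_b, n_b - c_b]], dtype=float)
    total = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
    if (expected < 5).any():
        return float(stats.fisher_exact(table.astype(int), alternative="two-sided")[1])
    p_pool = (c_a + c_b) / (n_a + n_b)
    se = np.sqrt(p_pool * (1 - p_pool) * (1 / n_a + 1 / n_b))
    if se == 0:
        return 1.0
    z = (c_a / n_a - c_b / n_b) / se
    return float(2.0 * stats.norm.sf(abs(z)))


def two_sample_logo(
    set_a: Sequence[SiteFragment],
    set_b: Sequence[SiteFragment],
    alpha: float = 0.01,
    bonferroni: bool = False,
) -> list[PositionBias]:
    """Significant per-(position, residue) composition differences between two sets.

    Window pads ('X') are excluded from both numerator and denominator at
    their position.  Results are ordered by position then residue order.
    """
    if not set_a or not set_b:
        raise ValueError("both fragment sets must be non-empty")
    n = set_a[0].n
    if any(f.n != n for f in list(set_a) + list(set_b)):
        raise ValueError("fragment sets must share one window size")
    offsets = window_offsets(n)
    n_tests = len(offsets) * 20
    cutoff = alpha / n_tests if bonferroni else alpha
    out: list[PositionBias] = []
    for off in offsets:
        col_a = [f.residue_at(off) for f in set_a]
        col_b = [f.residue_at(off) for f in set_b]
        n_a = sum(c != PAD for c in col_a)
        n_b = sum(c != PAD for c in col_b)
        if n_a == 0 or n_b == 0:
            continue
        for aa in AA_ORDER:
            c_a = col_a.count(aa)
            c_b = col_b.count(aa)
            if c_a == 0 and c_b == 0:
                continue
            freq_a, freq_b = c_a / n_a, c_b / n_b
            if freq_a == freq_b:
                continue
            p = _two_proportion_p(c_a, n_a, c_b, n_b)
            if p < cutoff:
                out.append(PositionBias(
                    position=off, residue=aa,
                    direction="enriched" if freq_a > freq_b else "depleted",
                    p_value=p, freq_a=freq_a, freq_b=freq_b,
                ))
    return out


def bias_frame(biases: Sequence[PositionBias]) -> pd.DataFrame:
    rows = [
        {"position": b.position, "residue": b.residue, "direction": b.direction,
         "freq_a": round(b.freq_a, 6), "freq_b": round(b.freq_b, 6),
         "p_value": f"{b.p_value:.3e}"}
        for b in biases
    ]
    return pd.DataFrame(
        rows, columns=["position", "residue", "direction", "freq_a", "freq_b", "p_value"]
    )


def write_bias_table(biases: Sequence[PositionBias], path: str | Path) -> None:
    bias_frame(biases).to_csv(path, sep="\t", index=False)


def mean_asa_profile(
    fragments: Sequence[SiteFragment], asa: ASATable
) -> np.ndarray:
    """Per-window-position arithmetic mean accessibility percentage.

    Positions covered only by 'X' pads across all fragments are reported as
    NaN (missing), never as 0.
    """
    if not fragments:
        raise ValueError("empty fragment set")
    n = fragments[0].n
    w = 2 * n + 1
    sums = np.zeros(w)
    counts = np.zeros(w)
    for frag in fragments:
        if frag.accession not in asa:
            raise KeyError(f"no ASA values for {frag.accession}")
        values = asa[frag.accession]
        center = frag.position - 1
        for i, off in enumerate(range(-n, n + 1)):
            if frag.residue_at(off) == PAD:
                continue
            sums[i] += values[center + off]
            counts[i] += 1
    with np.errstate(invalid="ignore"):
        profile = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return profile
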