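"""Position-specific composition and structure summaries around Gla sites.

These are the data products behind sequence-logo style analyses: a
per-position residue frequency matrix, a two-sample position-specific
enrichment/depletion test (two-proportion z-test, the classic two-sample
logo statistic; no multiple-testing correction by default), mean-ASA curves
per window offset, and the helix/sheet/coil fractions at the central Glu.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .sequence_data import AMINO_ACIDS, PAD, SiteFragment, UNKNOWN, WindowConfig
from .structure import ResidueProfile, profile_window

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class PositionCompositionDiff:
    """A significant per-(position, residue) composition difference."""

    position: int  # offset -n..+n
    residue: str
    direction: Literal["enriched", "depleted"]
    p_value: float


def position_counts(
    fragments: Sequence[SiteFragment],
) -> tuple[np.ndarray, np.ndarray]:
    """Residue counts per window position, and non-pad totals per position.

    Returns ``(counts, totals)`` with counts shaped (2n+1, 20); pad and 'X'
    are excluded from both counts and totals.
    """
    if not fragments:
        raise ValueError("no fragments supplied")
    length = len(fragments[0].window)
    counts = np.zeros((length, 20))
    totals = np.zeros(length)
    for frag in fragments:
        if len(frag.window) != length:
            raise ValueError("fragments have mixed window lengths")
        for p, sym in enumerate(frag.window):
            if sym in (PAD, UNKNOWN):
                continue
            counts[p, _AA_INDEX[sym]] += 1
            totals[p] += 1
    return counts, totals


def frequency_matrix(fragments: Sequence[SiteFragment]) -> pd.DataFrame:
    """Relative frequency of the 20 amino acids at each window offset.

    Rows are offsets -n..+n and sum to 1 over the non-pad symbols (each
    position renormalized by its own non-pad total).
    """
    counts, totals = position_counts(fragments)
    n = (counts.shape[0] - 1) // 2
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(totals[:, None] > 0, counts / totals[:, None], 0.0)
    return pd.DataFrame(
        freq, index=range(-n, n + 1), columns=list(AMINO_ACIDS)
    )


def two_proportion_pvalues(
    pos_counts: np.ndarray,
    pos_totals: np.ndarray,
    neg_counts: np.ndarray,
    neg_totals: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized pooled two-proportion z-test per (position, residue).

    Returns ``(p_values, diff)`` where diff = positive freq - negative freq.
    Cells with a degenerate pooled variance get p-value 1.
    """
    n1 = pos_totals[:, None]
    n2 = neg_totals[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(n1 > 0, pos_counts / n1, 0.0)
        p2 = np.where(n2 > 0, neg_counts / n2, 0.0)
        pooled = np.where(n1 + n2 > 0, (pos_counts + neg_counts) / (n1 + n2), 0.0)
        var = pooled * (1 - pooled) * (1 / np.maximum(n1, 1) + 1 / np.maximum(n2, 1))
        z = np.where(var > 0, (p1 - p2) / np.sqrt(np.where(var > 0, var, 1.0)), 0.0)
    pvals = 2 * norm.sf(np.abs(z))
    pvals = np.where((var > 0) & (n1 > 0) & (n2 > 0), pvals, 1.0)
    return pvals, p1 - p2


def two_sample_diff(
    pos_fragments: Sequence[SiteFragment],
    neg_fragments: Sequence[SiteFragment],
    alpha: float = 0.05,
) -> list[PositionCompositionDiff]:
    """Significant per-position residue differences between two fragment sets.

    Swapping the two sets flips every reported direction (antisymmetry).
    The central position is skipped: both sets are Glu there by construction.
    """
    if not pos_fragments or not neg_fragments:
        raise ValueError("both fragment sets must be non-empty")
    pc, pt = position_counts(pos_fragments)
    nc, nt = position_counts(neg_fragments)
    if pc.shape != nc.shape:
        raise ValueError("fragment sets have different window lengths")
    pvals, diff = two_proportion_pvalues(pc, pt, nc, nt)
    n = (pc.shape[0] - 1) // 2
    out: list[PositionCompositionDiff] = []
    for p in range(pc.shape[0]):
        offset = p - n
        if offset == 0:
            continue
        for a, residue in enumerate(AMINO_ACIDS):
            if pvals[p, a] < alpha and diff[p, a] != 0:
                out.append(
                    PositionCompositionDiff(
                        offset,
                        residue,
                        "enriched" if diff[p, a] > 0 else "depleted",
                        float(pvals[p, a]),
                    )
                )
    return out


def mean_asa_curve(
    fragments: Sequence[SiteFragment],
    profiles: Mapping[str, ResidueProfile],
    cfg: WindowConfig | None = None,
) -> pd.Series:
    """Arithmetic mean ASA percent per window offset; padding excluded."""
    if not fragments:
        raise ValueError("no fragments supplied")
    if cfg is None:
        cfg = WindowConfig(fragments[0].n)
    sums = np.zeros(cfg.window_length)
    counts = np.zeros(cfg.window_length)
    for frag in fragments:
        if frag.protein_id not in profiles:
            raise ValueError(f"missing structure profile for {frag.protein_id}")
        profile = profiles[frag.protein_id]
        for j, pos in enumerate(range(frag.center - cfg.n, frag.center + cfg.n + 1)):
            if 1 <= pos <= len(profile):
                sums[j] += profile.asa_percent[pos - 1]
                counts[j] += 1
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.Series(means, index=list(cfg.offsets), name="mean_asa_percent")


def ss_fractions(
    fragments: Sequence[SiteFragment],
    profiles: Mapping[str, ResidueProfile],
) -> dict[str, float]:
    """Fractions of helix/sheet/coil at the central Glu; they sum to 1."""
    if not fragments:
        raise ValueError("no fragments supplied")
    counts = {"H": 0, "E": 0, "C": 0}
    for frag in fragments:
        if frag.protein_id not in profiles:
            raise ValueError(f"missing structure profile for {frag.protein_id}")
        counts[profiles[frag.protein_id].ss[frag.center - 1]] += 1
    total = sum(counts.values())
    return {state: c / total for state, c in counts.items()}


def diffs_to_frame(diffs: Sequence[PositionCompositionDiff]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "position": d.position,
                "residue": d.residue,
                "direction": d.direction,
                "p_value": d.p_value,
            }
            for d in diffs
        ],
        columns=["position", "residue", "direction", "p_value"],
    )
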