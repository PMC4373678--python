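"""Sequence aggregation-propensity profiling (AGGRESCAN-style).

Each residue carries an intrinsic aggregation-propensity value (a3v); the
profile value a4v at a position is the centred moving average of a3v over a
window whose width grows with sequence length.  An aggregation *hot spot*
is a maximal run of at least five consecutive residues whose a4v exceeds
the hot-spot threshold (HST) with no proline in the run (proline is a
strong beta-breaker and vetoes the run).  The per-residue normalized
profile sum (Na4vSS) summarizes the whole-sequence propensity.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = ["A3V", "HST_DEFAULT", "AggregationProfile", "aggrescan_profile", "window_for_length"]


def _load_a3v() -> dict[str, float]:
    ref = resources.files("mpsscore.data") / "aggrescan_a3v.tsv"
    table: dict[str, float] = {}
    for line in ref.read_text().splitlines():
        if line.startswith("#") or line.startswith("aa") or not line.strip():
            continue
        aa, v = line.split("\t")
        table[aa] = float(v)
    return table


#: intrinsic per-amino-acid aggregation propensities
A3V = _load_a3v()

#: hot-spot threshold on a4v (frequency-weighted average intrinsic propensity)
HST_DEFAULT = -0.02

#: minimal hot-spot length (residues)
MIN_HOT_SPOT = 5


def window_for_length(n: int) -> int:
    """Sliding-window width by sequence-length class: 5/7/9/11 residues."""
    if n <= 75:
        return 5
    if n <= 175:
        return 7
    if n <= 300:
        return 9
    return 11


@dataclass(frozen=True)
class AggregationProfile:
    sequence: str
    window: int
    hst: float
    a3v: np.ndarray
    a4v: np.ndarray
    hot_spots: tuple[tuple[int, int], ...]  # 1-based inclusive (start, end)
    na4vss: float

    def hot_spots_overlapping(self, position: int) -> list[tuple[int, int]]:
        return [(s, e) for s, e in self.hot_spots if s <= position <= e]


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average; the window shrinks symmetrically at the termini."""
    half = window // 2
    n = len(values)
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out[i] = values[lo:hi].mean()
    return out


def find_hot_spots(a4v: np.ndarray, sequence: str, hst: float) -> tuple[tuple[int, int], ...]:
    """Maximal proline-free runs of >= 5 residues with a4v above threshold."""
    n = len(sequence)
    ok = [(a4v[i] > hst) and sequence[i] != "P" for i in range(n)]
    spots = []
    i = 0
    while i < n:
        if ok[i]:
            j = i
            while j + 1 < n and ok[j + 1]:
                j += 1
            if j - i + 1 >= MIN_HOT_SPOT:
                spots.append((i + 1, j + 1))
            i = j + 1
        else:
            i += 1
    return tuple(spots)


def aggrescan_profile(
    sequence: str,
    hst: float = HST_DEFAULT,
    window: int | None = None,
) -> AggregationProfile:
    """Compute the a4v profile, hot spots and Na4vSS of a protein sequence."""
    sequence = sequence.upper()
    if window is None:
        window = window_for_length(len(sequence))
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if len(sequence) < window:
        raise ValueError(f"sequence length {len(sequence)} < window {window}")
    try:
        a3v = np.array([A3V[aa] for aa in sequence])
    except KeyError as exc:
        raise ValueError(f"non-canonical residue {exc.args[0]!r}") from None
    a4v = _moving_average(a3v, window)
    hot_spots = find_hot_spots(a4v, sequence, hst)
    na4vss = float(a4v.sum() / len(sequence) * 100.0)
    return AggregationProfile(
        sequence=sequence,
        window=window,
        hst=hst,
        a3v=a3v,
        a4v=a4v,
        hot_spots=hot_spots,
        na4vss=na4vss,
    )
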