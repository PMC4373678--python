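"""Score aggregation: totals, severity bands and genotype-level scores.

Each missense mutation receives ten integer parameter scores (the stability
parameter ranges 0-2, every other parameter 0-1), so a mutation total lies
in [0, 11].  Patient genotypes combine two allele totals either additively
or multiplicatively; the multiplicative rule is the default because it is
the better ordinal predictor of clinical severity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ParameterScores",
    "GenotypeScore",
    "total_score",
    "band",
    "compound_score",
]

#: number of evidence parameters
N_PARAMETERS = 10

#: index (1-based) of the protein-stability parameter, the only one scored 0-2
STABILITY_PARAMETER = 3


@dataclass(frozen=True)
class ParameterScores:
    """The ten per-parameter integer scores of one mutation plus their total.

    Parameters (in order): translation rate, aggregation propensity,
    cellular stability, secondary structure, catalytic-site proximity,
    glycosylation, conformational flexibility, surface polarity/charge,
    evolutionary conservation, physiological function (dimer / Ca2+).
    """

    values: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.values) != N_PARAMETERS:
            raise ValueError(
                f"expected {N_PARAMETERS} parameter scores, got {len(self.values)}"
            )
        for i, v in enumerate(self.values, start=1):
            hi = 2 if i == STABILITY_PARAMETER else 1
            if not isinstance(v, int) or not 0 <= v <= hi:
                raise ValueError(f"parameter {i} score {v!r} outside 0..{hi}")

    @property
    def total(self) -> int:
        return sum(self.values)

    def __getitem__(self, parameter: int) -> int:
        """Score of 1-based ``parameter``."""
        if not 1 <= parameter <= N_PARAMETERS:
            raise IndexError(f"parameter index {parameter} outside 1..{N_PARAMETERS}")
        return self.values[parameter - 1]


def total_score(scores: ParameterScores) -> int:
    """Sum of the ten parameter scores (0..11)."""
    return scores.total


def band(score: float, mean: float, sd: float) -> str:
    """Classify a total into ``low`` / ``moderate`` / ``high`` by mean +/- 1 SD.

    ``high`` iff score > mean + sd, ``low`` iff score < mean - sd, otherwise
    ``moderate``.  With the bundled catalogue's own mean and SD the three
    bands contain 10, 70 and 6 of the 86 mutations.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    if score > mean + sd:
        return "high"
    if score < mean - sd:
        return "low"
    return "moderate"


@dataclass(frozen=True)
class GenotypeScore:
    """A combined two-allele score.

    ``degenerate`` is set when the product rule meets a zero-score allele:
    the product is then 0 regardless of the partner allele and carries no
    ordinal information, so such genotypes are excluded from correlation
    analyses by default.
    """

    mode: str
    value: float
    degenerate: bool = field(default=False)


def compound_score(score_a: float, score_b: float, mode: str = "product") -> GenotypeScore:
    """Combine two allele totals under ``mode`` in {'sum', 'product'}."""
    for s in (score_a, score_b):
        if not 0 <= s <= 11:
            raise ValueError(f"allele score {s} outside [0, 11]")
    if mode == "sum":
        return GenotypeScore(mode="sum", value=score_a + score_b)
    if mode == "product":
        degenerate = score_a == 0 or score_b == 0
        return GenotypeScore(mode="product", value=score_a * score_b, degenerate=degenerate)
    raise ValueError(f"unknown mode {mode!r} (expected 'sum' or 'product')")
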