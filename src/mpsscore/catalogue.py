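"""Mutation labels and the scored-mutation catalogue.

Mutations are written in the three-letter convention used throughout the
clinical literature (``Arg245His``: arginine 245 to histidine, 1-based
full-protein numbering).  A catalogue is an ordered collection of scored
mutations; the package bundles the 86-mutation SGSH reference catalogue
used by all statistics downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.SeqUtils import seq1, seq3

from .scoring import N_PARAMETERS, STABILITY_PARAMETER, ParameterScores

__all__ = [
    "MutationRecord",
    "ScoredMutation",
    "Catalogue",
    "CatalogueError",
    "parse_mutation_label",
    "read_catalogue",
    "write_catalogue",
    "preselect_missense",
    "unique_positions",
]

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: raw-mutation-list class vocabulary
MUTATION_CLASSES = frozenset({"missense", "nonsense", "frameshift", "splice", "other"})

CATALOGUE_COLUMNS = ["mutation"] + [f"p{i}" for i in range(1, 11)] + ["total"]

_LABEL_RE = re.compile(r"^([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})$")


class CatalogueError(ValueError):
    """Malformed mutation label or catalogue file."""


def _aa1(code3: str) -> str:
    aa = seq1(code3)
    if aa not in CANONICAL_AA:
        raise CatalogueError(f"unknown amino-acid code {code3!r}")
    return aa


@dataclass(frozen=True)
class MutationRecord:
    """One amino-acid substitution, with optional wild-type/mutant codons."""

    position: int
    wt_aa: str
    mut_aa: str
    wt_codon: str | None = None
    mut_codon: str | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise CatalogueError(f"position must be >= 1, got {self.position}")
        for aa in (self.wt_aa, self.mut_aa):
            if aa not in CANONICAL_AA:
                raise CatalogueError(f"non-canonical amino acid {aa!r}")
        if self.wt_aa == self.mut_aa:
            raise CatalogueError(
                f"identity substitution {self.wt_aa}{self.position}{self.mut_aa}"
            )
        for codon, aa in ((self.wt_codon, self.wt_aa), (self.mut_codon, self.mut_aa)):
            if codon is not None:
                translated = standard_dna_table.forward_table.get(codon.upper())
                if translated != aa:
                    raise CatalogueError(
                        f"codon {codon} does not encode {aa} (encodes {translated})"
                    )

    @property
    def label(self) -> str:
        """Three-letter label as printed, e.g. ``Arg245His``."""
        return f"{seq3(self.wt_aa)}{self.position}{seq3(self.mut_aa)}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def parse_mutation_label(text: str) -> MutationRecord:
    """Parse ``Arg245His``-style labels into a :class:`MutationRecord`."""
    m = _LABEL_RE.match(text.strip())
    if m is None:
        raise CatalogueError(f"malformed mutation label {text!r}")
    wt3, pos, mut3 = m.groups()
    return MutationRecord(position=int(pos), wt_aa=_aa1(wt3), mut_aa=_aa1(mut3))


@dataclass(frozen=True)
class ScoredMutation:
    mutation: MutationRecord
    scores: ParameterScores

    @property
    def total(self) -> int:
        return self.scores.total


@dataclass
class Catalogue:
    """Ordered, label-unique collection of scored mutations."""

    entries: list[ScoredMutation]
    provenance: str = ""

    def __post_init__(self) -> None:
        labels = [e.mutation.label for e in self.entries]
        seen: set[str] = set()
        for lab in labels:
            if lab in seen:
                raise CatalogueError(f"duplicate mutation label {lab}")
            seen.add(lab)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Catalogue):
            return NotImplemented
        return self.entries == other.entries

    def labels(self) -> list[str]:
        return [e.mutation.label for e in self.entries]

    def totals(self) -> list[int]:
        return [e.total for e in self.entries]

    def get(self, label: str) -> ScoredMutation:
        for e in self.entries:
            if e.mutation.label == label:
                return e
        raise KeyError(label)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            [e.mutation.label, *e.scores.values, e.total] for e in self.entries
        ]
        return pd.DataFrame(rows, columns=CATALOGUE_COLUMNS)


def read_catalogue(path: str | Path, provenance: str | None = None) -> Catalogue:
    """Read a scored catalogue TSV (columns ``mutation p1..p10 total``).

    Every row is validated: parameter ranges (p3 in {0,1,2}, others in
    {0,1}) and the printed total against the recomputed parameter sum.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"mutation": str}, comment="#")
    if list(df.columns) != CATALOGUE_COLUMNS:
        raise CatalogueError(
            f"bad header {list(df.columns)}; expected {CATALOGUE_COLUMNS}"
        )
    if df.empty:
        raise CatalogueError(f"{path}: no records")
    entries = []
    for row in df.itertuples(index=False):
        label = row.mutation
        mutation = parse_mutation_label(label)
        values = tuple(int(getattr(row, f"p{i}")) for i in range(1, N_PARAMETERS + 1))
        try:
            scores = ParameterScores(values)
        except ValueError as exc:
            raise CatalogueError(f"{label}: {exc}") from exc
        if scores.total != int(row.total):
            raise CatalogueError(
                f"{label}: stated total {row.total} != parameter sum {scores.total}"
            )
        entries.append(ScoredMutation(mutation=mutation, scores=scores))
    return Catalogue(entries=entries, provenance=provenance or str(path))


def write_catalogue(catalogue: Catalogue, path: str | Path) -> None:
    """Write the catalogue in the canonical TSV dialect (tab, LF, UTF-8)."""
    path = Path(path)
    df = catalogue.to_frame()
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


@dataclass(frozen=True)
class PreselectionResult:
    kept: list[str]
    dropped_by_class: dict[str, int]
    dropped_excluded: list[str]


def preselect_missense(
    raw_records: list[tuple[str, str]],
    exclusion_labels: set[str] | frozenset[str] = frozenset(),
) -> PreselectionResult:
    """Keep missense records not on the exclusion list.

    ``raw_records`` are ``(label, class)`` pairs with class one of
    missense / nonsense / frameshift / splice / other.  Mirrors the curation
    step that reduces a raw clinical mutation list to the scoreable
    missense set (e.g. 87 candidates minus one unverifiable record = 86).
    """
    kept: list[str] = []
    dropped: dict[str, int] = {}
    excluded: list[str] = []
    for label, klass in raw_records:
        if klass not in MUTATION_CLASSES:
            raise CatalogueError(f"unknown mutation class {klass!r} for {label}")
        if klass != "missense":
            dropped[klass] = dropped.get(klass, 0) + 1
        elif label in exclusion_labels:
            excluded.append(label)
        else:
            kept.append(label)
    return PreselectionResult(kept=kept, dropped_by_class=dropped, dropped_excluded=excluded)


def unique_positions(catalogue: Catalogue) -> int:
    """Number of distinct mutated residue positions in the catalogue."""
    return len({e.mutation.position for e in catalogue.entries})
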