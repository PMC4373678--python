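"""Evidence inputs consumed by the ten parameter scorers.

A de-novo scoring run needs, per protein: the amino-acid sequence, its
coding DNA, a codon -> relative tRNA-abundance table, structure coordinates,
per-residue secondary-structure / solvent-accessibility annotations, a
multiple alignment with homologous sulfatases, a curated site configuration
(catalytic residues, glycosylated asparagines, Ca2+ ligands, dimer
interface) and external per-mutation stability calls.  This module reads
and validates each of these and bundles them coherently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import NamedTuple

import gemmi
import pandas as pd
import yaml
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq

__all__ = [
    "Atom",
    "ResidueAnnotation",
    "CodonUsageTable",
    "SiteConfig",
    "StabilityCalls",
    "Alignment",
    "EvidenceBundle",
    "EvidenceError",
    "read_fasta",
    "read_structure",
    "read_msa",
    "read_annotations",
    "read_codon_table",
    "read_site_config",
    "read_stability",
    "load_default_codon_table",
    "validate_bundle",
    "rsa_from_structure",
]

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
DNA_ALPHABET = set("ACGT")

#: Theoretical maximum accessible surface areas (A^2) per residue,
#: Tien et al. (2013); used to normalize absolute ASA to relative RSA.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "E": 223.0, "Q": 225.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}


class EvidenceError(ValueError):
    """Malformed or inconsistent evidence input."""


class Atom(NamedTuple):
    chain: str
    resnum: int
    resname: str
    name: str
    x: float
    y: float
    z: float


@dataclass(frozen=True)
class ResidueAnnotation:
    """Secondary-structure state (H/E/C) and relative accessibility of a residue."""

    position: int
    ss: str
    rsa: float

    def __post_init__(self) -> None:
        if self.ss not in {"H", "E", "C"}:
            raise EvidenceError(f"ss must be H/E/C, got {self.ss!r}")
        if not 0.0 <= self.rsa <= 1.0:
            raise EvidenceError(f"rsa {self.rsa} outside [0, 1]")


@dataclass
class CodonUsageTable:
    """Relative tRNA abundance (or codon-usage frequency) per sense codon."""

    abundance: dict[str, float]
    amino_acid: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.abundance) > 61:
            raise EvidenceError("more than 61 sense codons")
        for codon, v in self.abundance.items():
            if v < 0:
                raise EvidenceError(f"negative abundance for {codon}")

    def __getitem__(self, codon: str) -> float:
        codon = codon.upper().replace("U", "T")
        if codon not in self.abundance:
            raise EvidenceError(f"codon {codon} not in abundance table")
        return self.abundance[codon]

    def codons_for(self, aa: str) -> list[str]:
        return [c for c, a in self.amino_acid.items() if a == aa]


@dataclass
class SiteConfig:
    """Curated functional-site positions plus the proximity cutoff (Angstrom)."""

    catalytic_residues: list[int] = field(default_factory=list)
    glycosylated_asn: list[int] = field(default_factory=list)
    ca_ligands: list[int] = field(default_factory=list)
    dimer_interface: list[int] = field(default_factory=list)
    proximity_cutoff: float = 8.0

    def __post_init__(self) -> None:
        for name in ("catalytic_residues", "glycosylated_asn", "ca_ligands", "dimer_interface"):
            if any(p < 1 for p in getattr(self, name)):
                raise EvidenceError(f"{name} contains a non-positive position")
        if self.proximity_cutoff <= 0:
            raise EvidenceError("proximity_cutoff must be > 0")


@dataclass
class StabilityCalls:
    """External stability-predictor output per mutation label.

    Either a direct class in {0, 1, 2} or a raw predictor margin that the
    stability scorer maps through configurable thresholds.
    """

    classes: dict[str, int] = field(default_factory=dict)
    raw_values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, c in self.classes.items():
            if c not in (0, 1, 2):
                raise EvidenceError(f"stability class for {label} must be 0/1/2, got {c}")

    def __contains__(self, label: str) -> bool:
        return label in self.classes or label in self.raw_values


@dataclass
class Alignment:
    """Equal-length aligned sequences with gap-aware target-position mapping."""

    sequences: dict[str, str]
    target_id: str

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise EvidenceError("ragged alignment")
        if self.target_id not in self.sequences:
            raise EvidenceError(f"target id {self.target_id!r} absent from alignment")
        target = self.sequences[self.target_id]
        # map 1-based target residue position -> 0-based alignment column
        self._pos2col = [i for i, c in enumerate(target) if c != "-"]

    @property
    def target_ungapped(self) -> str:
        return self.sequences[self.target_id].replace("-", "")

    def column_for_position(self, position: int) -> int:
        """0-based alignment column of 1-based target position."""
        if not 1 <= position <= len(self._pos2col):
            raise EvidenceError(f"target position {position} outside alignment")
        return self._pos2col[position - 1]

    def column(self, position: int, include_target: bool = False) -> list[str]:
        """Residues of the homologs (optionally the target) at a target position."""
        col = self.column_for_position(position)
        return [
            seq[col]
            for sid, seq in self.sequences.items()
            if include_target or sid != self.target_id
        ]


@dataclass
class EvidenceBundle:
    """Everything a full ten-parameter scoring run consumes."""

    protein_seq: str
    cds: str
    codon_table: CodonUsageTable
    structure: list[Atom]
    annotations: dict[int, ResidueAnnotation]
    msa: Alignment
    sites: SiteConfig
    stability: StabilityCalls

    def annotation(self, position: int) -> ResidueAnnotation:
        try:
            return self.annotations[position]
        except KeyError:
            raise EvidenceError(f"no annotation at position {position}") from None

    def residue_atoms(self, position: int) -> list[Atom]:
        return [a for a in self.structure if a.resnum == position]


# ---------------------------------------------------------------------------
# readers


def read_fasta(path: str | Path, molecule: str = "protein") -> dict[str, str]:
    """Ordered id -> uppercase sequence map; validates the declared alphabet."""
    alphabet = PROTEIN_ALPHABET if molecule == "protein" else DNA_ALPHABET
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - alphabet
        if bad:
            raise EvidenceError(
                f"{rec.id}: illegal {molecule} symbol(s) {sorted(bad)}"
            )
        records[rec.id] = seq
    if not records:
        raise EvidenceError(f"{path}: empty FASTA")
    return records


def read_structure(path: str | Path) -> list[Atom]:
    """Heavy-atom records of the first model of a PDB file.

    Alternate locations collapse to one atom each: highest occupancy wins,
    ties broken alphabetically by altloc id.  Waters and other heteroatoms
    are dropped.
    """
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise EvidenceError(f"{path}: no models")
    atoms: list[Atom] = []
    model = st[0]
    for chain in model:
        for residue in chain:
            if residue.het_flag != "A":  # ATOM records only
                continue
            best: dict[str, gemmi.Atom] = {}
            for atom in residue:
                if atom.element.is_hydrogen:
                    continue
                prev = best.get(atom.name)
                if prev is None or (atom.occ, -ord(atom.altloc or "~")) > (
                    prev.occ,
                    -ord(prev.altloc or "~"),
                ):
                    best[atom.name] = atom
            for name, atom in best.items():
                atoms.append(
                    Atom(
                        chain=chain.name,
                        resnum=residue.seqid.num,
                        resname=residue.name,
                        name=name,
                        x=atom.pos.x,
                        y=atom.pos.y,
                        z=atom.pos.z,
                    )
                )
    if not atoms:
        raise EvidenceError(f"{path}: no ATOM records")
    return atoms


def read_msa(path: str | Path, target_id: str, fmt: str = "fasta") -> Alignment:
    """Read an aligned FASTA or Clustal file into an :class:`Alignment`."""
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise EvidenceError(f"{path}: {exc}") from exc
    sequences = {rec.id: str(rec.seq).upper() for rec in aln}
    return Alignment(sequences=sequences, target_id=target_id)


def read_annotations(path: str | Path) -> dict[int, ResidueAnnotation]:
    """Per-residue annotation TSV with columns ``position ss rsa``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if list(df.columns) != ["position", "ss", "rsa"]:
        raise EvidenceError(f"bad annotation header {list(df.columns)}")
    out = {}
    for row in df.itertuples(index=False):
        ann = ResidueAnnotation(position=int(row.position), ss=str(row.ss), rsa=float(row.rsa))
        out[ann.position] = ann
    return out


def read_codon_table(path: str | Path) -> CodonUsageTable:
    """Codon table TSV with columns ``codon aa abundance``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if list(df.columns) != ["codon", "aa", "abundance"]:
        raise EvidenceError(f"bad codon-table header {list(df.columns)}")
    abundance, amino = {}, {}
    for row in df.itertuples(index=False):
        codon = str(row.codon).upper()
        if codon in abundance:
            raise EvidenceError(f"duplicate codon {codon}")
        abundance[codon] = float(row.abundance)
        amino[codon] = str(row.aa).upper()
    return CodonUsageTable(abundance=abundance, amino_acid=amino)


def load_default_codon_table() -> CodonUsageTable:
    """The packaged human codon-usage frequency table."""
    ref = resources.files("mpsscore.data") / "codon_usage_human.tsv"
    with resources.as_file(ref) as path:
        return read_codon_table(path)


def read_site_config(path: str | Path) -> SiteConfig:
    """Site configuration YAML (keys as the :class:`SiteConfig` fields)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    allowed = {"catalytic_residues", "glycosylated_asn", "ca_ligands", "dimer_interface", "proximity_cutoff"}
    unknown = set(raw) - allowed
    if unknown:
        raise EvidenceError(f"unknown site-config keys {sorted(unknown)}")
    return SiteConfig(**raw)


def read_stability(path: str | Path) -> StabilityCalls:
    """Stability TSV: ``mutation value`` (raw margin) or ``mutation class``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = list(df.columns)
    if cols == ["mutation", "class"]:
        return StabilityCalls(classes={str(r.mutation): int(getattr(r, "_1", r[1])) for r in df.itertuples(index=False)})
    if cols == ["mutation", "value"]:
        return StabilityCalls(raw_values={str(r.mutation): float(r.value) for r in df.itertuples(index=False)})
    raise EvidenceError(f"bad stability header {cols}")


# ---------------------------------------------------------------------------
# validation


def validate_bundle(bundle: EvidenceBundle) -> list[str]:
    """Check every bundle invariant; returns the list of violations (empty = pass)."""
    problems: list[str] = []
    n = len(bundle.protein_seq)
    cds = bundle.cds.upper()
    if len(cds) not in (3 * n, 3 * n + 3):
        problems.append(f"cds length {len(cds)} incompatible with protein length {n}")
    else:
        translated = str(Seq(cds[: 3 * n]).translate())
        for i, (a, b) in enumerate(zip(translated, bundle.protein_seq), start=1):
            if a != b:
                problems.append(f"translation mismatch at {i}: cds gives {a}, protein has {b}")
        if len(cds) == 3 * n + 3 and str(Seq(cds[3 * n:]).translate()) != "*":
            problems.append("trailing codon is not a stop")
    bad_ann = [p for p in bundle.annotations if not 1 <= p <= n]
    if bad_ann:
        problems.append(f"annotation positions outside 1..{n}: {sorted(bad_ann)}")
    target = bundle.msa.sequences.get(bundle.msa.target_id, "")
    if bundle.msa.target_ungapped != bundle.protein_seq:
        problems.append("msa target sequence (ungapped) differs from protein sequence")
    bad_res = sorted({a.resnum for a in bundle.structure if not 1 <= a.resnum <= n})
    if bad_res:
        problems.append(f"structure residue ids outside 1..{n}: {bad_res}")
    return problems


# ---------------------------------------------------------------------------
# optional geometry helper


def rsa_from_structure(path: str | Path, n_points: int = 960, probe_radius: float = 1.4) -> dict[int, float]:
    """Relative solvent accessibility per residue from coordinates.

    Shrake-Rupley sphere sampling (default 960 points, 1.4 A probe) on the
    first model, normalized by the Tien et al. theoretical maximum ASA per
    residue type.  Intended for pipelines lacking precomputed annotations.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.SASA import ShrakeRupley
    from Bio.SeqUtils import seq1

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    model = next(structure.get_models())
    ShrakeRupley(probe_radius=probe_radius, n_points=n_points).compute(model, level="R")
    out: dict[int, float] = {}
    for chain in model:
        for residue in chain:
            if residue.id[0] != " ":
                continue
            aa = seq1(residue.get_resname().capitalize())
            max_asa = MAX_ASA.get(aa)
            if max_asa:
                out[residue.id[1]] = min(residue.sasa / max_asa, 1.0)
    return out
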