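"""Packaged reference data and synthetic test inputs.

Two kinds of fixtures live here: the bundled 86-mutation SGSH reference
catalogue (checksummed package data), and a small synthetic "toy" protein
whose evidence bundle plants one feature per scorer — a helix, a strand, a
glycosylation sequon, a residue beside the catalytic site, a Ca2+ ligand,
buried and exposed residues, and a 5-homolog alignment with one fully
conserved column — together with a ground-truth map stating which
parameter each planted mutation fires.  The toy protein is synthetic, not
SGSH, so structure-dependent scorers are testable without any real
crystallographic entry.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .catalogue import Catalogue, read_catalogue, write_catalogue
from .evidence import (
    Alignment,
    Atom,
    CodonUsageTable,
    EvidenceBundle,
    ResidueAnnotation,
    SiteConfig,
    StabilityCalls,
    load_default_codon_table,
)

__all__ = [
    "ToyBundleSpec",
    "table1_dataset",
    "make_toy_bundle",
    "synthetic_sgsh_like_sequence",
    "write_fixture_files",
    "TABLE1_SHA256",
]

#: pinned checksum of the packaged reference catalogue
TABLE1_SHA256 = "901ed19d241fdd4d91d4d1564b6369d33240a3405aa55b727dcb42997f2c3b94"


def table1_dataset() -> Catalogue:
    """The packaged 86-row SGSH reference catalogue (checksum verified)."""
    ref = resources.files("mpsscore.data") / "table1_scores.tsv"
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != TABLE1_SHA256:
        raise RuntimeError(
            f"packaged catalogue is corrupted (sha256 {digest[:12]}... != pinned)"
        )
    with resources.as_file(ref) as path:
        return read_catalogue(path, provenance="bundled SGSH reference catalogue")


# ---------------------------------------------------------------------------
# toy evidence bundle

# 60-residue synthetic protein.  Layout (1-based):
#   10-18 helix, 25-31 strand (30 buried), 20 catalytic, 40-42 N-A-S sequon,
#   50 Ca2+ ligand, 22/55 dimer interface, 33 conserved column, elsewhere coil.
TOY_SEQUENCE = (
    "MAEFSHEWK"      # 1-9
    "AELKLLEAL"      # 10-18 helix
    "KDKAT"          # 19-23 (20 catalytic, 22 interface)
    "S"              # 24
    "VITVTLV"        # 25-31 strand (30 buried)
    "KRESTKEA"       # 32-39 (33 conserved)
    "NAS"            # 40-42 sequon
    "TEKHEAKD"       # 43-50 (50 Ca ligand)
    "KEAHWEKAEK"     # 51-60 (55 interface)
)
assert len(TOY_SEQUENCE) == 60

#: residue substituted into each homolog where the column is not conserved
_HOMOLOG_SUBS = {"A": "V", "E": "D", "F": "Y", "S": "T", "H": "Q", "W": "F",
                 "K": "R", "L": "I", "D": "E", "T": "S", "V": "I", "I": "L",
                 "M": "L", "R": "K", "N": "Q", "G": "A", "P": "A", "C": "S",
                 "Q": "N", "Y": "F"}

#: which parameter(s) each planted mutation is engineered to fire;
#: ``total`` is asserted only for the fully engineered score_all cases.
TOY_TRUTH = {
    "Leu12Pro": {"params": {4: 1}},            # helix + proline breaker
    "Ile26Gly": {"params": {4: 1}},            # strand + glycine breaker
    "Val28Asp": {"params": {4: 1}},            # strand, propensity below breaker threshold
    "Lys21Met": {"params": {5: 1}},            # 3.8 A from the catalytic residue
    "Ser42Ala": {"params": {6: 1}},            # destroys the N40 sequon
    "Ala39Val": {"params": {6: 1}},            # within +/-2 of glycosylated Asn40
    "Leu30Arg": {"params": {8: 1}},            # buried hydrophobic -> charged
    "Arg33His": {"params": {9: 1}},            # fully conserved column
    "Glu34Lys": {"params": {9: 0}},            # fully divergent column
    "Asp50Glu": {"params": {10: 1}},           # listed Ca2+ ligand
    "Ala22Pro": {"params": {5: 1, 7: 1, 10: 1}, "total": 3},
    "Thr43Ser": {"params": {}, "total": 0},    # engineered fully neutral
    "Thr36Ser": {"params": {3: 2}, "total": 2},  # stability class 2, all else neutral
}

_TOY_STABILITY_CLASSES = {"Ala22Pro": 0, "Thr43Ser": 0, "Thr36Ser": 2}


@dataclass(frozen=True)
class ToyBundleSpec:
    """Configuration of the synthetic toy protein bundle."""

    seed: int = 0
    helix: tuple[int, int] = (10, 18)
    strand: tuple[int, int] = (25, 31)
    sequon_asn: int = 40
    catalytic: int = 20
    ca_ligand: int = 50
    dimer_interface: tuple[int, ...] = (22, 55)
    buried: tuple[int, ...] = (30,)
    conserved_column: int = 33
    n_homologs: int = 5
    spacing: float = 3.8  # inter-residue CA spacing (A) of the linear chain
    proximity_cutoff: float = 8.0


def _toy_cds(sequence: str, table: CodonUsageTable) -> str:
    """Reverse-translate with the most abundant codon per residue, plus a stop."""
    codons = []
    for aa in sequence:
        best = max(table.codons_for(aa), key=lambda c: table.abundance[c])
        codons.append(best)
    return "".join(codons) + "TAA"


def make_toy_bundle(spec: ToyBundleSpec | None = None) -> tuple[EvidenceBundle, dict]:
    """Deterministic toy evidence bundle plus its ground-truth feature map."""
    spec = spec or ToyBundleSpec()
    seq = TOY_SEQUENCE
    n = len(seq)
    table = load_default_codon_table()

    annotations = {}
    for pos in range(1, n + 1):
        if spec.helix[0] <= pos <= spec.helix[1]:
            ss = "H"
        elif spec.strand[0] <= pos <= spec.strand[1]:
            ss = "E"
        else:
            ss = "C"
        rsa = 0.05 if pos in spec.buried else 0.5
        annotations[pos] = ResidueAnnotation(position=pos, ss=ss, rsa=rsa)

    # linear CA trace: residues i, j are |i-j| * spacing apart
    from Bio.SeqUtils import seq3
    structure = [
        Atom(chain="A", resnum=i, resname=seq3(seq[i - 1]).upper(), name="CA",
             x=spec.spacing * (i - 1), y=0.0, z=0.0)
        for i in range(1, n + 1)
    ]

    homologs = {}
    for h in range(1, spec.n_homologs + 1):
        homologs[f"homolog{h}"] = "".join(
            seq[i] if (i + 1) == spec.conserved_column else _HOMOLOG_SUBS[seq[i]]
            for i in range(n)
        )
    msa = Alignment(sequences={"toy": seq, **homologs}, target_id="toy")

    sites = SiteConfig(
        catalytic_residues=[spec.catalytic],
        glycosylated_asn=[spec.sequon_asn],
        ca_ligands=[spec.ca_ligand],
        dimer_interface=list(spec.dimer_interface),
        proximity_cutoff=spec.proximity_cutoff,
    )
    bundle = EvidenceBundle(
        protein_seq=seq,
        cds=_toy_cds(seq, table),
        codon_table=table,
        structure=structure,
        annotations=annotations,
        msa=msa,
        sites=sites,
        stability=StabilityCalls(classes=dict(_TOY_STABILITY_CLASSES)),
    )
    return bundle, dict(TOY_TRUTH)


def synthetic_sgsh_like_sequence(length: int = 502, seed: int = 7) -> str:
    """A synthetic stand-in sequence of SGSH-like length and composition.

    Not the real SGSH sequence: residues are drawn from a typical globular
    amino-acid composition with a serine planted at position 66 inside a
    moderately hydrophobic stretch, so that the Ser66Trp substitution
    raises the aggregation propensity there.  Used only for the
    aggregation-scorer regression.
    """
    rng = np.random.default_rng(seed)
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    freqs = np.array([
        8.3, 1.4, 5.4, 6.7, 3.9, 7.1, 2.3, 5.9, 5.8, 9.7,
        2.4, 4.1, 4.7, 3.9, 5.5, 6.6, 5.4, 6.9, 1.1, 2.9,
    ])
    freqs = freqs / freqs.sum()
    seq = list(rng.choice(aas, size=length, p=freqs))
    seq[60:72] = list("ATVLASAVLTAV")  # mildly hydrophobic context
    seq[65] = "S"  # position 66
    return "".join(seq)


# ---------------------------------------------------------------------------
# file emission


def _pdb_line(serial: int, atom: Atom) -> str:
    return (
        f"ATOM  {serial:5d}  {atom.name:<3s} {atom.resname:>3s} {atom.chain:1s}"
        f"{atom.resnum:4d}    {atom.x:8.3f}{atom.y:8.3f}{atom.z:8.3f}"
        f"{1.0:6.2f}{0.0:6.2f}          {'C':>2s}"
    )


def write_fixture_files(out_dir: str | Path, seed: int = 0, n_patients: int = 60) -> dict[str, Path]:
    """Write every fixture (toy bundle files, catalogue, synthetic cohort)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = ToyBundleSpec(seed=seed)
    bundle, _ = make_toy_bundle(spec)
    paths: dict[str, Path] = {}

    def _write(name: str, text: str) -> None:
        p = out / name
        p.write_text(text)
        paths[name.split(".")[0]] = p

    _write("protein.fasta", f">toy\n{bundle.protein_seq}\n")
    _write("cds.fasta", f">toy\n{bundle.cds}\n")
    _write(
        "msa.fasta",
        "".join(f">{sid}\n{s}\n" for sid, s in bundle.msa.sequences.items()),
    )
    _write(
        "structure.pdb",
        "\n".join(_pdb_line(i + 1, a) for i, a in enumerate(bundle.structure)) + "\nEND\n",
    )
    _write(
        "annotations.tsv",
        "position\tss\trsa\n"
        + "".join(f"{a.position}\t{a.ss}\t{a.rsa}\n" for a in bundle.annotations.values()),
    )
    _write(
        "stability.tsv",
        "mutation\tclass\n"
        + "".join(f"{m}\t{c}\n" for m, c in bundle.stability.classes.items()),
    )
    _write(
        "sites.yaml",
        yaml.safe_dump(
            {
                "catalytic_residues": bundle.sites.catalytic_residues,
                "glycosylated_asn": bundle.sites.glycosylated_asn,
                "ca_ligands": bundle.sites.ca_ligands,
                "dimer_interface": bundle.sites.dimer_interface,
                "proximity_cutoff": bundle.sites.proximity_cutoff,
            },
            sort_keys=False,
        ),
    )

    catalogue = table1_dataset()
    write_catalogue(catalogue, out / "catalogue.tsv")
    paths["catalogue"] = out / "catalogue.tsv"

    from .cohort import synth_cohort, write_patients

    patients = synth_cohort(catalogue, n_patients=n_patients, seed=seed)
    write_patients(patients, out / "patients.tsv")
    paths["patients"] = out / "patients.tsv"
    return paths
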