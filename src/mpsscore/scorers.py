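"""The ten per-mutation evidence scorers.

Each scorer inspects one axis of protein biogenesis and returns an integer
score (0/1, or 0-2 for stability — the stability parameter is deliberately
weighted higher) plus a structured rationale recording the facts the
decision used.  A score of 1 (or 2) flags a predicted negative effect of
the substitution on SGSH biogenesis.

Parameters:

1.  translation rate — mutant codon decoded by a rarer tRNA than wild type
2.  aggregation propensity — mutation creates/extends a hot spot or raises
    the whole-sequence propensity
3.  cellular stability — pass-through of an external sequence/structure
    stability predictor (class 0/1/2, or a raw margin mapped by thresholds)
4.  secondary structure — mutation breaks the helix/strand element hosting
    the residue
5.  catalytic-site proximity — residue within cutoff of a catalytic residue
6.  glycosylation — sequon destroyed/created or residue adjacent to a
    glycosylated asparagine
7.  conformational flexibility — proline/glycine/cysteine gained or lost
8.  surface polarity & charge — hydrophobicity class swap in the core,
    polar->nonpolar swap at the surface, or formal-charge change
9.  evolutionary conservation — wild-type residue conserved across the
    homologous sulfatase alignment
10. physiological function — residue at (or near) the Ca2+ site or the
    homodimer interface
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .aggrescan import aggrescan_profile
from .catalogue import MutationRecord
from .evidence import Alignment, Atom, CodonUsageTable, EvidenceBundle, EvidenceError, SiteConfig, StabilityCalls
from .scoring import ParameterScores

__all__ = [
    "ScorerResult",
    "ScorerConfig",
    "ScoringOutcome",
    "score_p1_translation",
    "score_p2_aggregation",
    "score_p3_stability",
    "score_p4_secondary_structure",
    "score_p5_catalytic_proximity",
    "score_p6_glycosylation",
    "score_p7_flexibility",
    "score_p8_surface",
    "score_p9_conservation",
    "score_p10_physiology",
    "score_all",
]

#: Chou-Fasman secondary-structure propensities (helix P_alpha, strand P_beta)
CHOU_FASMAN = {
    "A": (1.42, 0.83), "R": (0.98, 0.93), "N": (0.67, 0.89), "D": (1.01, 0.54),
    "C": (0.70, 1.19), "Q": (1.11, 1.10), "E": (1.51, 0.37), "G": (0.57, 0.75),
    "H": (1.00, 0.87), "I": (1.08, 1.60), "L": (1.21, 1.30), "K": (1.16, 0.74),
    "M": (1.45, 1.05), "F": (1.13, 1.38), "P": (0.57, 0.55), "S": (0.77, 0.75),
    "T": (0.83, 1.19), "W": (1.08, 1.37), "Y": (0.69, 1.47), "V": (1.06, 1.70),
}

NONPOLAR = set("AVLIMFWPGC")

_CHARGE = {**{aa: -1 for aa in "DE"}, **{aa: +1 for aa in "KRH"}}


def charge_class(aa: str) -> int:
    """Formal side-chain charge class at pH 7: D/E = -1, K/R/H = +1, else 0."""
    return _CHARGE.get(aa, 0)


@dataclass(frozen=True)
class ScorerResult:
    parameter: int
    score: int
    rationale: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        hi = 2 if self.parameter == 3 else 1
        if not 0 <= self.score <= hi:
            raise ValueError(f"parameter {self.parameter} score {self.score} outside 0..{hi}")


@dataclass(frozen=True)
class ScorerConfig:
    """Tunable thresholds of the ten scorers (defaults are conventional values)."""

    ratio_threshold: float = 0.5        # p1: mutant/wild-type tRNA-abundance ratio
    delta_threshold: float = 0.0        # p2: minimal Na4vSS increase that scores
    hst: float = -0.02                  # p2: hot-spot threshold on a4v
    stability_t_severe: float = -1.0    # p3: raw margin below which class = 2
    stability_t_mild: float = -0.5      # p3: raw margin below which class = 1
    cf_breaker_threshold: float = 0.75  # p4: Chou-Fasman propensity marking a breaker
    sequon_window: int = 2              # p6: +/- residues around a glycosylated Asn
    rsa_buried_cutoff: float = 0.20     # p8: RSA below which a residue counts as buried
    identity_threshold: float = 0.60    # p9: conserved-column identity fraction


@dataclass(frozen=True)
class ScoringOutcome:
    scores: ParameterScores
    rationales: tuple[ScorerResult, ...]


# ---------------------------------------------------------------------------
# parameter 1: translation rate


def _single_nt_neighbours(codon: str) -> list[str]:
    out = []
    for i, base in enumerate(codon):
        for b in "ACGT":
            if b != base:
                out.append(codon[:i] + b + codon[i + 1:])
    return out


def derive_codons(
    mutation: MutationRecord, cds: str, codon_table: CodonUsageTable
) -> tuple[str, str]:
    """Wild-type codon from the CDS; mutant codon from the mutation or inferred.

    When the mutant codon is not given it is taken among single-nucleotide
    neighbours of the wild-type codon that encode the mutant residue,
    choosing the most abundant (conservative toward scoring 0); if no
    single-nucleotide neighbour encodes it, the most abundant codon of the
    mutant residue is used.
    """
    pos = mutation.position
    if mutation.wt_codon is not None:
        wt_codon = mutation.wt_codon.upper()
    else:
        if 3 * pos > len(cds):
            raise EvidenceError(f"position {pos} beyond the CDS")
        wt_codon = cds[3 * (pos - 1): 3 * pos].upper()
    if codon_table.amino_acid.get(wt_codon) != mutation.wt_aa:
        raise EvidenceError(
            f"{mutation.label}: CDS codon {wt_codon} does not encode {mutation.wt_aa}"
        )
    if mutation.mut_codon is not None:
        return wt_codon, mutation.mut_codon.upper()
    candidates = [
        c for c in _single_nt_neighbours(wt_codon)
        if codon_table.amino_acid.get(c) == mutation.mut_aa
    ] or codon_table.codons_for(mutation.mut_aa)
    if not candidates:
        raise EvidenceError(f"no codon found for residue {mutation.mut_aa}")
    return wt_codon, max(candidates, key=lambda c: codon_table[c])


def score_p1_translation(
    mutation: MutationRecord,
    cds: str,
    codon_table: CodonUsageTable,
    ratio_threshold: float = 0.5,
) -> ScorerResult:
    """Score 1 iff the mutant codon's tRNA abundance is below
    ``ratio_threshold`` times the wild-type codon's (strict inequality)."""
    wt_codon, mut_codon = derive_codons(mutation, cds, codon_table)
    wt_ab, mut_ab = codon_table[wt_codon], codon_table[mut_codon]
    score = 1 if mut_ab < ratio_threshold * wt_ab else 0
    return ScorerResult(1, score, {
        "wt_codon": wt_codon, "mut_codon": mut_codon,
        "wt_abundance": wt_ab, "mut_abundance": mut_ab,
        "ratio_threshold": ratio_threshold,
    })


# ---------------------------------------------------------------------------
# parameter 2: aggregation propensity


def score_p2_aggregation(
    mutation: MutationRecord,
    protein_seq: str,
    delta_threshold: float = 0.0,
    hst: float = -0.02,
) -> ScorerResult:
    """Score 1 iff the substitution creates a hot spot overlapping the site,
    extends/intensifies an existing one there, or raises Na4vSS by more than
    ``delta_threshold``."""
    pos = mutation.position
    if not 1 <= pos <= len(protein_seq):
        raise EvidenceError(f"position {pos} outside sequence of length {len(protein_seq)}")
    if protein_seq[pos - 1] != mutation.wt_aa:
        raise EvidenceError(
            f"{mutation.label}: sequence has {protein_seq[pos - 1]} at {pos}"
        )
    mutant_seq = protein_seq[: pos - 1] + mutation.mut_aa + protein_seq[pos:]
    wt = aggrescan_profile(protein_seq, hst=hst)
    mut = aggrescan_profile(mutant_seq, hst=hst)
    wt_here = wt.hot_spots_overlapping(pos)
    mut_here = mut.hot_spots_overlapping(pos)

    def area(profile, spots):
        return sum(profile.a4v[s - 1: e].sum() for s, e in spots)

    new_spot = bool(mut_here) and not wt_here
    grown = (
        bool(mut_here)
        and bool(wt_here)
        and (
            sum(e - s + 1 for s, e in mut_here) > sum(e - s + 1 for s, e in wt_here)
            or area(mut, mut_here) > area(wt, wt_here)
        )
    )
    delta = mut.na4vss - wt.na4vss
    score = 1 if (new_spot or grown or delta > delta_threshold) else 0
    return ScorerResult(2, score, {
        "wt_hot_spots": list(wt.hot_spots), "mut_hot_spots": list(mut.hot_spots),
        "new_hot_spot": new_spot, "extended_or_intensified": grown,
        "delta_na4vss": delta, "delta_threshold": delta_threshold,
    })


# ---------------------------------------------------------------------------
# parameter 3: stability (external predictor pass-through)


def score_p3_stability(
    mutation: MutationRecord,
    stability_calls: StabilityCalls,
    thresholds: tuple[float, float] = (-1.0, -0.5),
) -> ScorerResult:
    """Pass a direct 0/1/2 class through, or map a raw predictor margin:
    v < t_severe -> 2, t_severe <= v < t_mild -> 1, else 0."""
    label = mutation.label
    t_severe, t_mild = thresholds
    if t_severe > t_mild:
        raise ValueError("thresholds must satisfy t_severe <= t_mild")
    if label in stability_calls.classes:
        c = stability_calls.classes[label]
        return ScorerResult(3, c, {"source": "class", "class": c})
    if label in stability_calls.raw_values:
        v = stability_calls.raw_values[label]
        c = 2 if v < t_severe else (1 if v < t_mild else 0)
        return ScorerResult(3, c, {"source": "raw", "value": v, "thresholds": thresholds})
    raise EvidenceError(f"no stability call for {label}")


# ---------------------------------------------------------------------------
# parameter 4: secondary structure


def score_p4_secondary_structure(
    mutation: MutationRecord,
    annotations,
    cf_breaker_threshold: float = 0.75,
) -> ScorerResult:
    """Inside a helix/strand, score 1 iff the mutant residue is a recognized
    breaker of the element (Pro or Gly) or drops below the Chou-Fasman
    breaker threshold while the wild type does not.  Coil residues score 0."""
    ann = annotations.get(mutation.position) if hasattr(annotations, "get") else None
    if ann is None:
        raise EvidenceError(f"no annotation at position {mutation.position}")
    if ann.ss == "C":
        return ScorerResult(4, 0, {"element": "C"})
    idx = 0 if ann.ss == "H" else 1
    wt_p = CHOU_FASMAN[mutation.wt_aa][idx]
    mut_p = CHOU_FASMAN[mutation.mut_aa][idx]
    breaker = mutation.mut_aa in {"P", "G"} or (
        mut_p <= cf_breaker_threshold and wt_p > cf_breaker_threshold
    )
    return ScorerResult(4, 1 if breaker else 0, {
        "element": ann.ss, "wt_propensity": wt_p, "mut_propensity": mut_p,
        "breaker_threshold": cf_breaker_threshold,
    })


# ---------------------------------------------------------------------------
# structure distance helpers


def _min_distance(atoms_a: list[Atom], atoms_b: list[Atom]) -> float:
    best = math.inf
    for a in atoms_a:
        for b in atoms_b:
            d = math.dist((a.x, a.y, a.z), (b.x, b.y, b.z))
            best = min(best, d)
    return best


def _min_distance_to_positions(structure: list[Atom], position: int, targets: list[int]) -> float:
    res_atoms = [a for a in structure if a.resnum == position]
    if not res_atoms:
        raise EvidenceError(f"residue {position} absent from structure")
    target_atoms = [a for a in structure if a.resnum in set(targets) and a.resnum != position]
    if not target_atoms:
        raise EvidenceError(f"none of the residues {targets} resolved in structure")
    return _min_distance(res_atoms, target_atoms)


# parameter 5: catalytic-site proximity


def score_p5_catalytic_proximity(
    mutation: MutationRecord, structure: list[Atom], sites: SiteConfig
) -> ScorerResult:
    """Score 1 iff the minimal heavy-atom distance to any catalytic residue
    is within the proximity cutoff (boundary inclusive)."""
    if not sites.catalytic_residues:
        raise EvidenceError("no catalytic residues configured")
    if mutation.position in sites.catalytic_residues:
        return ScorerResult(5, 1, {"catalytic_residue_itself": True, "distance": 0.0})
    d = _min_distance_to_positions(structure, mutation.position, sites.catalytic_residues)
    return ScorerResult(5, 1 if d <= sites.proximity_cutoff else 0, {
        "distance": d, "cutoff": sites.proximity_cutoff,
    })


# ---------------------------------------------------------------------------
# parameter 6: glycosylation


def find_sequons(sequence: str) -> list[int]:
    """1-based positions of the Asn of each N-X-[S/T] sequon (X != P)."""
    out = []
    for i in range(len(sequence) - 2):
        if sequence[i] == "N" and sequence[i + 1] != "P" and sequence[i + 2] in "ST":
            out.append(i + 1)
    return out


def score_p6_glycosylation(
    mutation: MutationRecord,
    protein_seq: str,
    sites: SiteConfig,
    sequon_window: int = 2,
) -> ScorerResult:
    """Score 1 iff the mutation destroys or creates an N-glycosylation
    sequon, or lies within ``sequon_window`` of a configured glycosylated
    asparagine."""
    pos = mutation.position
    if not 1 <= pos <= len(protein_seq):
        raise EvidenceError(f"position {pos} outside sequence")
    mutant_seq = protein_seq[: pos - 1] + mutation.mut_aa + protein_seq[pos:]
    wt_sequons = set(find_sequons(protein_seq))
    mut_sequons = set(find_sequons(mutant_seq))
    destroyed = sorted(wt_sequons - mut_sequons)
    created = sorted(mut_sequons - wt_sequons)
    near = [
        asn for asn in sites.glycosylated_asn if abs(asn - pos) <= sequon_window
    ]
    score = 1 if (destroyed or created or near) else 0
    return ScorerResult(6, score, {
        "sequons_destroyed": destroyed, "sequons_created": created,
        "near_glycosylated_asn": near, "window": sequon_window,
    })


# ---------------------------------------------------------------------------
# parameter 7: conformational flexibility / disulfides


def score_p7_flexibility(mutation: MutationRecord) -> ScorerResult:
    """Score 1 iff the substitution gains or loses proline, glycine or
    cysteine — the residues governing backbone flexibility and disulfides."""
    involved = sorted({mutation.wt_aa, mutation.mut_aa} & {"P", "G", "C"})
    return ScorerResult(7, 1 if involved else 0, {"residues_involved": involved})


# ---------------------------------------------------------------------------
# parameter 8: surface polarity and charge


def score_p8_surface(
    mutation: MutationRecord, annotations, rsa_buried_cutoff: float = 0.20
) -> ScorerResult:
    """Score 1 iff (a) a buried residue swaps hydrophobicity class,
    (b) an exposed polar/charged residue turns nonpolar, or (c) the formal
    charge class changes."""
    ann = annotations.get(mutation.position) if hasattr(annotations, "get") else None
    if ann is None:
        raise EvidenceError(f"no annotation at position {mutation.position}")
    wt_np = mutation.wt_aa in NONPOLAR
    mut_np = mutation.mut_aa in NONPOLAR
    buried = ann.rsa < rsa_buried_cutoff
    clause_a = buried and wt_np != mut_np
    clause_b = (not buried) and (not wt_np) and mut_np
    clause_c = charge_class(mutation.wt_aa) != charge_class(mutation.mut_aa)
    score = 1 if (clause_a or clause_b or clause_c) else 0
    return ScorerResult(8, score, {
        "rsa": ann.rsa, "buried": buried,
        "buried_class_swap": clause_a, "exposed_polar_to_nonpolar": clause_b,
        "charge_change": clause_c,
        "wt_charge": charge_class(mutation.wt_aa), "mut_charge": charge_class(mutation.mut_aa),
    })


# ---------------------------------------------------------------------------
# parameter 9: evolutionary conservation


def score_p9_conservation(
    mutation: MutationRecord, msa: Alignment, identity_threshold: float = 0.60
) -> ScorerResult:
    """Score 1 iff the wild-type residue is conserved (identity fraction
    over non-gap homolog residues >= threshold) at the aligned column."""
    col = msa.column(mutation.position)
    target_res = msa.target_ungapped[mutation.position - 1]
    if target_res != mutation.wt_aa:
        raise EvidenceError(
            f"{mutation.label}: alignment target has {target_res} at {mutation.position}"
        )
    residues = [c for c in col if c != "-"]
    matches = sum(1 for c in residues if c == mutation.wt_aa)
    fraction = matches / len(residues) if residues else 0.0
    return ScorerResult(9, 1 if fraction >= identity_threshold else 0, {
        "identity_fraction": fraction, "n_homologs": len(residues),
        "threshold": identity_threshold,
    })


# ---------------------------------------------------------------------------
# parameter 10: physiological requirements (dimer interface, Ca2+)


def score_p10_physiology(
    mutation: MutationRecord, structure: list[Atom] | None, sites: SiteConfig
) -> ScorerResult:
    """Score 1 iff the residue is a listed Ca2+ ligand / interface residue,
    or lies within the proximity cutoff of one (when a structure is given)."""
    listed = sorted(set(sites.ca_ligands) | set(sites.dimer_interface))
    if not listed:
        raise EvidenceError("both physiological site lists are empty")
    if mutation.position in listed:
        return ScorerResult(10, 1, {"listed_site": mutation.position})
    if structure:
        d = _min_distance_to_positions(structure, mutation.position, listed)
        return ScorerResult(10, 1 if d <= sites.proximity_cutoff else 0, {
            "distance": d, "cutoff": sites.proximity_cutoff,
        })
    return ScorerResult(10, 0, {"listed_site": None})


# ---------------------------------------------------------------------------
# all ten


def score_all(
    mutation: MutationRecord,
    bundle: EvidenceBundle,
    config: ScorerConfig | None = None,
) -> ScoringOutcome:
    """Run the ten scorers against a validated evidence bundle."""
    cfg = config or ScorerConfig()
    sites = bundle.sites
    steps = [
        lambda: score_p1_translation(mutation, bundle.cds, bundle.codon_table, cfg.ratio_threshold),
        lambda: score_p2_aggregation(mutation, bundle.protein_seq, cfg.delta_threshold, cfg.hst),
        lambda: score_p3_stability(mutation, bundle.stability, (cfg.stability_t_severe, cfg.stability_t_mild)),
        lambda: score_p4_secondary_structure(mutation, bundle.annotations, cfg.cf_breaker_threshold),
        lambda: score_p5_catalytic_proximity(mutation, bundle.structure, sites),
        lambda: score_p6_glycosylation(mutation, bundle.protein_seq, sites, cfg.sequon_window),
        lambda: score_p7_flexibility(mutation),
        lambda: score_p8_surface(mutation, bundle.annotations, cfg.rsa_buried_cutoff),
        lambda: score_p9_conservation(mutation, bundle.msa, cfg.identity_threshold),
        lambda: score_p10_physiology(mutation, bundle.structure, sites),
    ]
    results = []
    for i, step in enumerate(steps, start=1):
        try:
            results.append(step())
        except Exception as exc:
            raise EvidenceError(f"parameter {i} failed for {mutation.label}: {exc}") from exc
    scores = ParameterScores(tuple(r.score for r in results))
    return ScoringOutcome(scores=scores, rationales=tuple(results))
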