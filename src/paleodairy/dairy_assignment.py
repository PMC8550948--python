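"""Milk-peptide taxonomic assignment and per-individual dairy calls.

A milk-protein reference set (β-lactoglobulin and its equid variants
BLG-I/BLG-II, the caseins, α-lactalbumin) is digested in silico with
trypsin, building an index from every theoretical peptide to the set of
(taxon, protein family) pairs that could have produced it.  An observed
dairy peptide is then assigned the most specific taxonomic level consistent
with all of its possible sources — the lowest common ancestor (LCA) of the
taxon set — so a peptide shared by cattle, water buffalo and bison resolves
to the subfamily Bovinae, while one unique to horse BLG-I resolves to the
genus Equus.

Per-individual evidence is summarized as a three-way call: negative (no
milk peptides), equivocal (casein families only — caseins preserve poorly
and are rarely authentic on their own), or positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import parser as _pyt_parser

from .psm_validation import AMINO_ACIDS, PeptideSpectralMatch
from .taxonomy import Taxonomy

__all__ = [
    "MILK_FAMILIES",
    "CASEIN_FAMILIES",
    "MilkProteinRecord",
    "DairyEvidence",
    "tryptic_digest",
    "build_peptide_index",
    "assign_taxon",
    "count_deamidation_sites",
    "call_dairy_status",
    "read_milk_fasta",
    "write_milk_fasta",
    "read_exclusion_list",
]

MILK_FAMILIES = frozenset(
    {
        "BLG",
        "BLG-I",
        "BLG-II",
        "alpha-S1-casein",
        "alpha-S2-casein",
        "alpha-lactalbumin",
        "other-milk",
    }
)

#: Families whose unaccompanied presence yields an equivocal (not positive)
#: dairy call.
CASEIN_FAMILIES = frozenset({"alpha-S1-casein", "alpha-S2-casein"})

#: Cleave after K or R except when followed by proline.
TRYPSIN_RULE = r"[KR](?!P)"


@dataclass(frozen=True)
class MilkProteinRecord:
    accession: str
    protein_family: str
    taxon: str
    sequence: str

    def __post_init__(self) -> None:
        if self.protein_family not in MILK_FAMILIES:
            raise ValueError(f"unknown milk protein family: {self.protein_family!r}")
        if not self.sequence or not set(self.sequence) <= AMINO_ACIDS:
            raise ValueError(f"invalid sequence in record {self.accession!r}")


@dataclass
class DairyEvidence:
    """Milk-peptide evidence for one individual.

    ``assignments`` holds (peptide, protein_family, assigned_taxon,
    n_possible_deamidation_sites) tuples; ``call`` is negative when empty,
    equivocal when only equivocal families (caseins by default) are present,
    positive otherwise.
    """

    individual_id: str
    assignments: list[tuple[str, str, str, int]] = field(default_factory=list)
    families_present: set[str] = field(default_factory=set)
    call: str = "negative"


def tryptic_digest(
    sequence: str, missed_cleavages: int = 2, min_length: int = 6
) -> set[str]:
    """Theoretical tryptic peptides of a protein sequence.

    Cleaves after K/R except before P, allowing up to ``missed_cleavages``
    missed sites; peptides shorter than ``min_length`` are discarded.  The
    C-terminal peptide may end in any residue.
    """
    if not sequence or not set(sequence) <= AMINO_ACIDS:
        bad = sorted(set(sequence) - AMINO_ACIDS) if sequence else []
        raise ValueError(f"invalid residues {bad} in sequence")
    if missed_cleavages < 0 or min_length < 1:
        raise ValueError("missed_cleavages >= 0 and min_length >= 1 required")
    return set(
        _pyt_parser.cleave(
            sequence, TRYPSIN_RULE, missed_cleavages=missed_cleavages, min_length=min_length
        )
    )


def build_peptide_index(
    records: Sequence[MilkProteinRecord],
    tree: Taxonomy,
    exclusion: Iterable[str] = (),
    missed_cleavages: int = 2,
    min_length: int = 6,
    collapse_il: bool = False,
) -> dict[str, set[tuple[str, str]]]:
    """Map every digested reference peptide to its {(taxon, family)} sources.

    Records whose accession is on the contaminant exclusion list (e.g. the
    bacterial entries whose deposited sequences are near-identical to
    ruminant casein) contribute nothing.  With ``collapse_il`` the isobaric
    leucine/isoleucine pair is merged before indexing; off by default since
    taxonomic specificity can hinge on an I/L difference.
    """
    excluded = set(exclusion)
    index: dict[str, set[tuple[str, str]]] = {}
    for record in records:
        if record.accession in excluded:
            continue
        if record.taxon not in tree:
            raise ValueError(
                f"record {record.accession!r}: taxon {record.taxon!r} not in taxonomy"
            )
        for peptide in tryptic_digest(record.sequence, missed_cleavages, min_length):
            key = peptide.replace("I", "L") if collapse_il else peptide
            index.setdefault(key, set()).add((record.taxon, record.protein_family))
    return index


def assign_taxon(
    peptide: str, index: Mapping[str, set[tuple[str, str]]], tree: Taxonomy
) -> str:
    """Most specific taxonomic node consistent with a peptide's sources."""
    if peptide not in index:
        raise KeyError(f"peptide not in reference index: {peptide!r}")
    taxa = {taxon for taxon, _family in index[peptide]}
    return tree.lca(taxa)


def count_deamidation_sites(peptide: str) -> int:
    """Number of possible deamidation sites (N and Q residues).

    Counts chemistry-capable positions, not observed modifications; a
    peptide with a single N/Q offers little support for authenticating
    antiquity via deamidation.
    """
    if not peptide or not set(peptide) <= AMINO_ACIDS:
        raise ValueError(f"invalid peptide: {peptide!r}")
    return peptide.count("N") + peptide.count("Q")


def call_dairy_status(
    individual_id: str,
    psms: Sequence[PeptideSpectralMatch],
    index: Mapping[str, set[tuple[str, str]]],
    tree: Taxonomy,
    equivocal_families: frozenset[str] = CASEIN_FAMILIES,
) -> DairyEvidence:
    """Assign taxa to an individual's validated milk PSMs and call status.

    Only PSMs whose peptide occurs in the reference index count as dairy
    evidence.  The per-PSM family is the PSM's reported family when the
    index agrees, otherwise the index's (alphabetically first) family.
    """
    evidence = DairyEvidence(individual_id=individual_id)
    for psm in psms:
        if psm.is_decoy or psm.peptide not in index:
            continue
        sources = index[psm.peptide]
        families = {family for _taxon, family in sources}
        family = psm.protein_family if psm.protein_family in families else min(families)
        node = assign_taxon(psm.peptide, index, tree)
        evidence.assignments.append(
            (psm.peptide, family, node, count_deamidation_sites(psm.peptide))
        )
        evidence.families_present.add(family)

    if not evidence.assignments:
        evidence.call = "negative"
    elif evidence.families_present <= equivocal_families:
        evidence.call = "equivocal"
    else:
        evidence.call = "positive"
    return evidence


# ---- reference-set I/O -------------------------------------------------

def read_milk_fasta(path) -> list[MilkProteinRecord]:
    """Read a milk reference FASTA with ``>acc|family=BLG|taxon=Bos`` headers."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.description.split("|")
        fields = dict(p.split("=", 1) for p in parts[1:] if "=" in p)
        if "family" not in fields or "taxon" not in fields:
            raise ValueError(f"FASTA header missing family=/taxon= tags: {rec.description!r}")
        records.append(
            MilkProteinRecord(
                accession=parts[0],
                protein_family=fields["family"],
                taxon=fields["taxon"],
                sequence=str(rec.seq),
            )
        )
    return records


def write_milk_fasta(records: Iterable[MilkProteinRecord], path) -> None:
    seq_records = [
        SeqRecord(
            Seq(r.sequence),
            id=f"{r.accession}|family={r.protein_family}|taxon={r.taxon}",
            description="",
        )
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_exclusion_list(path) -> set[str]:
    """One accession per line; blank lines and '#' comments ignored."""
    out = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out
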