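"""Parsing of protein-DNA complex structures from PDB-format text.

The parser produces a typed :class:`ComplexStructure` whose residues are
partitioned into protein chains, DNA chains and everything else.  Record
reading is delegated to :mod:`gemmi`; this module owns the partition rules
(which residue names count as amino acids or deoxynucleotides), altloc
resolution, chimera rejection and a minimal PDB writer used for round-trip
checks.

Conventions:

* only MODEL 1 of multi-model (NMR) files is kept;
* alternate locations are resolved per atom name to the highest-occupancy
  copy (ties broken by file order);
* author residue numbering is preserved because HELIX/SHEET header records
  reference it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "ResidueKind",
    "Chain",
    "SegmentAnnotation",
    "SegmentKind",
    "ComplexStructure",
    "PdbParseError",
    "NotProteinDnaComplexError",
    "ChimericChainError",
    "UnsupportedNucleotideError",
    "parse_pdb",
    "to_pdb_string",
    "protein_sequence",
    "dna_sequence",
]


class PdbParseError(ValueError):
    """A PDB record could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class NotProteinDnaComplexError(ValueError):
    """Structure lacks a protein chain or a DNA chain."""


class ChimericChainError(ValueError):
    """A single chain mixes amino-acid and nucleotide residues."""


class UnsupportedNucleotideError(ValueError):
    """A nucleotide other than A, C, G, T (e.g. DU) was encountered."""


AMINO3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

# Two-letter (current PDB) and bare one-letter (legacy) deoxynucleotide names.
DEOXY_TO_BASE = {"DA": "A", "DC": "C", "DG": "G", "DT": "T"}
LEGACY_BASES = {"A", "C", "G", "T"}
# Recognized as nucleotides so they stay in DNA chains, but unsupported as
# sequence letters (the feature set covers A, C, G, T only).
UNSUPPORTED_NUCLEOTIDES = {"DU", "DI", "U", "I"}


class ResidueKind(Enum):
    AMINO_ACID = "AMINO_ACID"
    NUCLEOTIDE = "NUCLEOTIDE"
    OTHER = "OTHER"


class SegmentKind(Enum):
    HELIX = "HELIX"
    SHEET = "SHEET"


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coords: np.ndarray  # (3,) Å
    occupancy: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: non-finite coordinates")
        if not self.element:
            raise ValueError(f"atom {self.name}: empty element symbol")


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    insertion_code: str
    res_name: str
    atoms: list[Atom]
    kind: ResidueKind

    @property
    def id(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_number, self.insertion_code)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def base(self) -> str | None:
        """One-letter DNA base, or None for non/unsupported nucleotides."""
        if self.res_name in DEOXY_TO_BASE:
            return DEOXY_TO_BASE[self.res_name]
        if self.res_name in LEGACY_BASES:
            return self.res_name
        return None


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SegmentAnnotation:
    kind: SegmentKind
    chain_id: str
    start_seq: int
    end_seq: int

    def __post_init__(self):
        if self.start_seq > self.end_seq:
            raise ValueError(
                f"{self.kind.value} segment {self.chain_id} "
                f"{self.start_seq}-{self.end_seq}: start > end"
            )


@dataclass
class ComplexStructure:
    complex_id: str
    protein_chains: list[Chain]
    dna_chains: list[Chain]
    helix_segments: list[SegmentAnnotation] = field(default_factory=list)
    sheet_segments: list[SegmentAnnotation] = field(default_factory=list)

    def protein_residues(self) -> Iterator[Residue]:
        for ch in self.protein_chains:
            yield from ch

    def dna_residues(self) -> Iterator[Residue]:
        for ch in self.dna_chains:
            yield from ch

    def protein_atom_coords(self) -> np.ndarray:
        return _stack_coords(self.protein_residues())

    def dna_atom_coords(self) -> np.ndarray:
        return _stack_coords(self.dna_residues())


def _stack_coords(residues) -> np.ndarray:
    coords = [a.coords for r in residues for a in r.atoms]
    if not coords:
        return np.empty((0, 3))
    return np.vstack(coords)


def _classify_res_name(res_name: str, atom_names: set[str]) -> ResidueKind:
    if res_name in AMINO3_TO_1:
        return ResidueKind.AMINO_ACID
    if res_name in DEOXY_TO_BASE or res_name in UNSUPPORTED_NUCLEOTIDES:
        return ResidueKind.NUCLEOTIDE
    # Legacy one-letter nucleotide names only count when the residue carries
    # a nucleic sugar atom.
    if res_name in LEGACY_BASES and "C1'" in atom_names:
        return ResidueKind.NUCLEOTIDE
    return ResidueKind.OTHER


def _validate_atom_records(text: str) -> None:
    """Cheap fixed-column sanity check so errors carry line numbers."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec not in ("ATOM", "HETATM"):
            continue
        if len(line) < 54:
            raise PdbParseError(
                f"{rec} record shorter than the coordinate columns", lineno
            )
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            fieldtxt = line[lo:hi].strip()
            try:
                float(fieldtxt)
            except ValueError:
                raise PdbParseError(
                    f"unparsable {what} coordinate {fieldtxt!r}", lineno
                ) from None


def _resolve_altlocs(res: gemmi.Residue) -> list[Atom]:
    """Keep one copy per atom name: highest occupancy, ties -> first seen."""
    best: dict[str, tuple[float, int]] = {}
    picked: dict[str, gemmi.Atom] = {}
    for order, atom in enumerate(res):
        key = atom.name
        if key not in best or atom.occ > best[key][0]:
            best[key] = (atom.occ, order)
            picked[key] = atom
    out = []
    for name, atom in picked.items():
        element = atom.element.name or "X"
        out.append(
            Atom(
                name=name,
                element=element,
                coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                occupancy=atom.occ,
            )
        )
    return out


def parse_pdb(text: str, complex_id: str = "complex") -> ComplexStructure:
    """Parse PDB-format text into a :class:`ComplexStructure`.

    Only MODEL 1 is used.  Every ATOM/HETATM record with a standard
    amino-acid or deoxynucleotide residue name is assigned to a protein or
    DNA chain; waters and ligands are dropped (peptide-like nonstandard
    residues inside protein chains are kept and later rendered as ``X``).

    Raises
    ------
    PdbParseError
        On malformed fixed-column records (with the line number).
    NotProteinDnaComplexError
        If no protein chain or no DNA chain remains after partitioning.
    ChimericChainError
        If one chain mixes amino acids and nucleotides.
    """
    if not any(line[:6].strip() in ("ATOM", "HETATM") for line in text.splitlines()):
        raise PdbParseError("no ATOM or HETATM records found")
    _validate_atom_records(text)
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:  # gemmi reports its own line info
        raise PdbParseError(str(exc)) from exc
    if len(st) == 0:
        raise PdbParseError("no models in structure")
    if len(st) > 1:
        logger.warning("%s: %d models present, keeping MODEL 1", complex_id, len(st))
    model = st[0]

    protein_chains: list[Chain] = []
    dna_chains: list[Chain] = []
    for gchain in model:
        residues: list[Residue] = []
        kinds_present: set[ResidueKind] = set()
        for gres in gchain:
            atoms = _resolve_altlocs(gres)
            atom_names = {a.name for a in atoms}
            kind = _classify_res_name(gres.name, atom_names)
            res = Residue(
                chain_id=gchain.name,
                seq_number=gres.seqid.num,
                insertion_code=(gres.seqid.icode or " ").strip() or "",
                res_name=gres.name,
                atoms=atoms,
                kind=kind,
            )
            residues.append(res)
            if kind is not ResidueKind.OTHER:
                kinds_present.add(kind)
        if not kinds_present:
            continue  # chain of waters/ligands only
        if kinds_present == {ResidueKind.AMINO_ACID, ResidueKind.NUCLEOTIDE}:
            raise ChimericChainError(
                f"chain {gchain.name} mixes amino-acid and nucleotide residues"
            )
        if ResidueKind.AMINO_ACID in kinds_present:
            # Keep peptide-like OTHER residues (e.g. MSE: has N and CA);
            # drop waters and ligands.
            kept = [
                r
                for r in residues
                if r.kind is ResidueKind.AMINO_ACID
                or (
                    r.kind is ResidueKind.OTHER
                    and r.atom("N") is not None
                    and r.atom("CA") is not None
                )
            ]
            protein_chains.append(Chain(gchain.name, kept))
        else:
            kept = [r for r in residues if r.kind is ResidueKind.NUCLEOTIDE]
            dna_chains.append(Chain(gchain.name, kept))

    if not protein_chains or not dna_chains:
        raise NotProteinDnaComplexError(
            f"{complex_id}: not a protein-DNA complex "
            f"({len(protein_chains)} protein, {len(dna_chains)} DNA chains)"
        )

    known_chains = {c.chain_id for c in protein_chains} | {
        c.chain_id for c in dna_chains
    }
    helix_segments = []
    for h in st.helices:
        if h.start.chain_name in known_chains:
            helix_segments.append(
                SegmentAnnotation(
                    SegmentKind.HELIX,
                    h.start.chain_name,
                    h.start.res_id.seqid.num,
                    h.end.res_id.seqid.num,
                )
            )
    sheet_segments = []
    for sheet in st.sheets:
        for strand in sheet.strands:
            if strand.start.chain_name in known_chains:
                sheet_segments.append(
                    SegmentAnnotation(
                        SegmentKind.SHEET,
                        strand.start.chain_name,
                        strand.start.res_id.seqid.num,
                        strand.end.res_id.seqid.num,
                    )
                )

    return ComplexStructure(
        complex_id=complex_id,
        protein_chains=protein_chains,
        dna_chains=dna_chains,
        helix_segments=helix_segments,
        sheet_segments=sheet_segments,
    )


def protein_sequence(cs: ComplexStructure) -> list[str]:
    """One-letter sequence per protein chain; nonstandard residues -> X."""
    return [
        "".join(AMINO3_TO_1.get(r.res_name, "X") for r in chain)
        for chain in cs.protein_chains
    ]


def dna_sequence(cs: ComplexStructure) -> list[str]:
    """Base string per DNA chain, 5'->3' in file order (DA/DC/DG/DT -> ACGT)."""
    out = []
    for chain in cs.dna_chains:
        letters = []
        for r in chain:
            base = r.base
            if base is None:
                raise UnsupportedNucleotideError(
                    f"unsupported nucleotide {r.res_name} at "
                    f"{r.chain_id}{r.seq_number}"
                )
            letters.append(base)
        out.append("".join(letters))
    return out


def _residue_name_at(cs: ComplexStructure, chain_id: str, seq: int) -> str:
    for chain in list(cs.protein_chains) + list(cs.dna_chains):
        if chain.chain_id != chain_id:
            continue
        for r in chain:
            if r.seq_number == seq:
                return r.res_name
    return "ALA"


def to_pdb_string(cs: ComplexStructure) -> str:
    """Serialize back to fixed-column PDB text (ATOM/HELIX/SHEET/TER/END)."""
    lines: list[str] = []
    for i, seg in enumerate(cs.helix_segments, start=1):
        lines.append(
            "HELIX  %3d %3d %3s %1s %4d  %3s %1s %4d  1 %30s%6d"
            % (
                i,
                i,
                _residue_name_at(cs, seg.chain_id, seg.start_seq)[:3],
                seg.chain_id,
                seg.start_seq,
                _residue_name_at(cs, seg.chain_id, seg.end_seq)[:3],
                seg.chain_id,
                seg.end_seq,
                "",
                seg.end_seq - seg.start_seq + 1,
            )
        )
    for i, seg in enumerate(cs.sheet_segments, start=1):
        lines.append(
            "SHEET  %3d %3s%2d %3s %1s%4d  %3s %1s%4d  0"
            % (
                i,
                "S%d" % i,
                1,
                _residue_name_at(cs, seg.chain_id, seg.start_seq)[:3],
                seg.chain_id,
                seg.start_seq,
                _residue_name_at(cs, seg.chain_id, seg.end_seq)[:3],
                seg.chain_id,
                seg.end_seq,
            )
        )
    serial = 1
    for chain in list(cs.protein_chains) + list(cs.dna_chains):
        for res in chain:
            for atom in res.atoms:
                name = atom.name
                # PDB atom-name justification: 1-letter elements start col 14
                padded = f" {name:<3s}" if len(name) < 4 else name
                lines.append(
                    "ATOM  %5d %4s %3s %1s%4d%1s   %8.3f%8.3f%8.3f%6.2f%6.2f          %2s"
                    % (
                        serial,
                        padded,
                        res.res_name[:3],
                        res.chain_id[:1],
                        res.seq_number,
                        res.insertion_code or " ",
                        atom.coords[0],
                        atom.coords[1],
                        atom.coords[2],
                        atom.occupancy,
                        0.0,
                        atom.element[:2],
                    )
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"
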