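"""Reading RNA structures and sequences.

Each nucleotide is reduced to a three-atom coarse-grained frame: C4', C1' and
the glycosidic nitrogen (N9 for the purines A/G, N1 for the pyrimidines C/U).
A chain becomes a :class:`CoarseBackbone` — an (N, 3, 3) coordinate array in
Angstroms plus the sequence.  Nucleotides missing any of the three atoms are
dropped with a warning; modified or non-RNA residues keep their coordinates
(when complete) but read as the unknown letter ``N`` and such chains are by
default excluded from training data.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

ATOM_ORDER = ("C4'", "C1'", "N")  # third atom is N9 (A/G) or N1 (C/U)
UNKNOWN = "N"
PURINES = {"A", "G"}
PYRIMIDINES = {"C", "U"}
_RESNAME_TO_LETTER = {"A": "A", "U": "U", "C": "C", "G": "G"}


class ParseError(ValueError):
    """Malformed structure or sequence text."""


class NoRNAChainError(ParseError):
    """The structure contains no chain with nucleotide residues."""


@dataclass
class CoarseBackbone:
    """Three-atom coarse-grained RNA backbone for one chain.

    ``coords[i]`` holds the (C4', C1', N1/N9) coordinates of nucleotide ``i``
    in Angstroms, rows in that fixed order.
    """

    coords: np.ndarray          # (N, 3, 3)
    sequence: str               # over {A,U,C,G} plus UNKNOWN
    chain_id: str = "A"
    residue_ids: list[int] = field(default_factory=list)
    name: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (3, 3) or self.coords.shape[0] < 1:
            raise ValueError(f"coords must be (N, 3, 3) with N >= 1, got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("backbone coordinates contain non-finite values")
        if len(self.sequence) != self.coords.shape[0]:
            raise ValueError("sequence length does not match coordinate count")
        if not self.residue_ids:
            self.residue_ids = list(range(1, len(self.sequence) + 1))
        if len(self.residue_ids) != len(self.sequence):
            raise ValueError("residue_ids length mismatch")

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def is_canonical(self) -> bool:
        """True when every position reads one of the four RNA letters."""
        return UNKNOWN not in self.sequence

    @property
    def c1(self) -> np.ndarray:
        return self.coords[:, 1, :]

    @property
    def c4(self) -> np.ndarray:
        return self.coords[:, 0, :]

    @property
    def n_glyc(self) -> np.ndarray:
        return self.coords[:, 2, :]


@dataclass
class SequenceRecord:
    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ParseError(f"record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - set("ACGU")
        if bad:
            raise ParseError(f"record {self.id!r} has non-ACGU letters after sanitization: {sorted(bad)}")


# ---------------------------------------------------------------------------
# PDB parsing
# ---------------------------------------------------------------------------

def _pick_atom(residue: gemmi.Residue, name: str) -> gemmi.Atom | None:
    """Select one conformer of atom ``name``: blank altloc wins, then altloc
    order with occupancy as tie-break (deterministic single conformer)."""
    candidates = [a for a in residue if a.name == name]
    if not candidates:
        return None
    blanks = [a for a in candidates if a.altloc in ("", "\0")]
    if blanks:
        return blanks[0]
    return sorted(candidates, key=lambda a: (-a.occ, a.altloc))[0]


def _residue_letter(residue: gemmi.Residue) -> str:
    return _RESNAME_TO_LETTER.get(residue.name.strip(), UNKNOWN)


def _glycosidic_name(letter: str, residue: gemmi.Residue) -> str | None:
    if letter in PURINES:
        return "N9"
    if letter in PYRIMIDINES:
        return "N1"
    # unknown/modified residue: prefer N9 if present, else N1
    if any(a.name == "N9" for a in residue):
        return "N9"
    if any(a.name == "N1" for a in residue):
        return "N1"
    return None


def parse_backbone(structure_text: str, chain: str | None = None,
                   name: str = "") -> list[CoarseBackbone]:
    """Extract coarse-grained backbones from PDB-format text.

    Uses model 1 only.  Returns one :class:`CoarseBackbone` per chain that
    contains at least one complete nucleotide; raises
    :class:`NoRNAChainError` when none does (or the requested chain has no
    usable nucleotide).
    """
    try:
        structure = gemmi.read_pdb_string(structure_text)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse PDB text: {exc}") from exc
    if len(structure) == 0:
        raise NoRNAChainError("structure contains no models")
    model = structure[0]

    backbones: list[CoarseBackbone] = []
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        coords, letters, resids = [], [], []
        for residue in ch:
            # nucleotide-like residues are recognized by the ribose C1' atom
            if _pick_atom(residue, "C1'") is None:
                continue
            letter = _residue_letter(residue)
            n_name = _glycosidic_name(letter, residue)
            atoms = [_pick_atom(residue, "C4'"), _pick_atom(residue, "C1'"),
                     _pick_atom(residue, n_name) if n_name else None]
            if any(a is None for a in atoms):
                logger.warning("dropping %s %s%d: missing backbone atom",
                               residue.name, ch.name, residue.seqid.num)
                continue
            coords.append([[a.pos.x, a.pos.y, a.pos.z] for a in atoms])
            letters.append(letter)
            resids.append(residue.seqid.num)
        if coords:
            backbones.append(CoarseBackbone(
                coords=np.asarray(coords), sequence="".join(letters),
                chain_id=ch.name, residue_ids=resids, name=name or structure.name))
    if not backbones:
        where = f"chain {chain!r}" if chain else "structure"
        raise NoRNAChainError(f"no RNA nucleotides found in {where}")
    return backbones


def filter_by_length(records: list[CoarseBackbone], min_len: int = 20,
                     max_len: int = 280) -> list[CoarseBackbone]:
    """Keep backbones with min_len <= N <= max_len (inclusive), order preserved.

    The defaults are the dataset filter used for the benchmark corpus.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    return [r for r in records if min_len <= len(r) <= max_len]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(text: str) -> list[SequenceRecord]:
    """Parse FASTA text; lowercase is uppercased and T becomes U."""
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = str(rec.seq).upper().replace("T", "U")
        if not seq:
            raise ParseError(f"FASTA record {rec.id!r} has an empty sequence")
        records.append(SequenceRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(records: list[SequenceRecord]) -> str:
    out = io.StringIO()
    SeqIO.write([SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records],
                out, "fasta")
    return out.getvalue()
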