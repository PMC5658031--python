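"""Backbone structure container, PDB I/O and the flat feature representation.

A conformation of an L-residue protein is either a :class:`BackboneStructure`
(per-residue N/CA/C/O coordinates in Angstrom plus the one-letter sequence) or
a flat feature vector of length ``L * 13``: twelve normalized coordinates per
residue in the fixed order N.x N.y N.z CA.x .. O.z, followed by one
residue-type channel in [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .geometry import NormalizationScale, denormalize, normalize

logger = logging.getLogger(__name__)

__all__ = [
    "BackboneStructure",
    "BACKBONE_ATOMS",
    "AA_THREE_TO_ONE",
    "AA_ONE_TO_THREE",
    "read_pdb",
    "write_pdb",
    "read_fasta",
    "encode_residue_types",
    "structure_to_features",
    "features_to_structure",
    "pad_or_trim_template",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")
N_CHANNELS = 13  # 4 atoms * 3 coordinates + 1 residue-type channel

_STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"  # alphabetical one-letter order

AA_THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
AA_ONE_TO_THREE = {v: k for k, v in AA_THREE_TO_ONE.items()}


@dataclass
class BackboneStructure:
    """Backbone of one conformation: sequence plus (L, 4, 3) coordinates.

    Atom order within each residue is fixed: N, CA, C, O.  ``vacant`` flags
    alignment gaps whose coordinates are zero-filled placeholders; geometry
    routines exclude those residues from superposition and loss sums.
    """

    sequence: str
    coords: np.ndarray
    id: str = "structure"
    vacant: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.sequence), 4, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match "
                f"sequence length {len(self.sequence)}"
            )
        if len(self.sequence) < 2:
            raise ValueError("a backbone needs at least 2 residues")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.vacant is None:
            self.vacant = np.zeros(len(self.sequence), dtype=bool)
        else:
            self.vacant = np.asarray(self.vacant, dtype=bool)
            if self.vacant.shape != (len(self.sequence),):
                raise ValueError("vacant mask length does not match sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def ca(self) -> np.ndarray:
        """(L, 3) CA coordinates."""
        return self.coords[:, 1, :]

    @property
    def flat_coords(self) -> np.ndarray:
        """(L*12,) residue-major coordinate vector (no residue-type channel)."""
        return self.coords.reshape(-1)

    def copy(self) -> "BackboneStructure":
        return BackboneStructure(
            sequence=self.sequence,
            coords=self.coords.copy(),
            id=self.id,
            vacant=self.vacant.copy(),
        )


def read_pdb(path, chain: str | None = None, strict: bool = True) -> BackboneStructure:
    """Read the N/CA/C/O backbone of one chain from a PDB file.

    Only the first model is used; alternate locations resolve to the first
    occurrence.  In strict mode a residue missing any backbone atom is an
    error; in lenient mode it is dropped with a log message.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models in file")
    model = st[0]
    if chain is not None:
        ch = model.find_chain(chain)
        if ch is None:
            raise ValueError(f"{path}: chain {chain!r} not found")
        chains = [ch]
    else:
        chains = list(model)

    seq: list[str] = []
    coords: list[np.ndarray] = []
    for ch in chains:
        for res in ch:
            if res.het_flag == "H":
                continue
            atoms = {}
            for atom in res:
                name = atom.name.strip()
                if name in BACKBONE_ATOMS and name not in atoms:
                    atoms[name] = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
            if not atoms:
                continue
            if len(atoms) < 4:
                if strict:
                    raise ValueError(
                        f"{path}: residue {ch.name}/{res.seqid.num} {res.name} "
                        f"missing backbone atoms {set(BACKBONE_ATOMS) - set(atoms)}"
                    )
                logger.warning(
                    "dropping residue %s/%s %s with incomplete backbone",
                    ch.name, res.seqid.num, res.name,
                )
                continue
            seq.append(AA_THREE_TO_ONE.get(res.name, "X"))
            coords.append(np.stack([atoms[a] for a in BACKBONE_ATOMS]))
        if coords and chain is None:
            break  # default: first chain carrying backbone residues
    if len(coords) < 2:
        raise ValueError(f"{path}: no parsable residues")
    return BackboneStructure(
        sequence="".join(seq), coords=np.stack(coords), id=path.stem
    )


def write_pdb(structure: BackboneStructure, path) -> None:
    """Write a backbone as standard fixed-column ATOM records.

    Serial numbers start at 1, chain id is A, occupancy 1.00, B-factor 0.00,
    element column filled; the chain is closed with TER and END.
    """
    if np.any(np.abs(structure.coords) >= 10000.0):
        raise ValueError("coordinate magnitude >= 10000 overflows PDB columns")
    lines: list[str] = []
    serial = 0
    for i, aa in enumerate(structure.sequence):
        resname = AA_ONE_TO_THREE.get(aa, "UNK")
        for j, atom in enumerate(BACKBONE_ATOMS):
            serial += 1
            x, y, z = structure.coords[i, j]
            # fixed columns: name 13-16 (element right-justified at 13-14),
            # resName 18-20, chain 22, resSeq 23-26, xyz 31-54, element 77-78
            lines.append(
                f"ATOM  {serial:5d} {(' ' + atom).ljust(4)} {resname:>3s} A"
                f"{i + 1:4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                f"          {atom[0]:>2s}"
            )
    resname = AA_ONE_TO_THREE.get(structure.sequence[-1], "UNK")
    lines.append(f"TER   {serial + 1:5d}      {resname:>3s} A{len(structure):4d}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fasta(path) -> str:
    """Read the first sequence from a FASTA file (or a plain-sequence file)."""
    seq: list[str] = []
    started = False
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if started:
                break
            started = True
            continue
        seq.append(line)
    if not seq:
        raise ValueError(f"{path}: no sequence found")
    return "".join(seq).upper()


def encode_residue_types(sequence: str) -> np.ndarray:
    """Numeric residue-type channel: 1-based alphabetical index / 20.

    A -> 0.05 ... Y -> 1.0; any nonstandard or unknown code maps to 0.
    """
    if len(sequence) == 0:
        raise ValueError("empty sequence")
    return np.array(
        [(_STANDARD_AA.index(a) + 1) / 20.0 if a in _STANDARD_AA else 0.0
         for a in sequence.upper()]
    )


def structure_to_features(
    structure: BackboneStructure, scale: NormalizationScale
) -> np.ndarray:
    """Flatten a structure into the L*13 feature vector under ``scale``.

    Residue-major layout: 12 normalized coordinates then the residue-type
    channel.  Inverse of :func:`features_to_structure`.
    """
    L = len(structure)
    out = np.empty(L * N_CHANNELS)
    norm = normalize(structure.coords, scale).reshape(L, 12)
    aa = encode_residue_types(structure.sequence)
    out.reshape(L, N_CHANNELS)[:, :12] = norm
    out.reshape(L, N_CHANNELS)[:, 12] = aa
    return out


def features_to_structure(
    features: np.ndarray,
    scale: NormalizationScale,
    sequence: str,
    structure_id: str = "reconstructed",
    vacant: np.ndarray | None = None,
) -> BackboneStructure:
    """Rebuild a structure from a feature vector (inverse of the forward map).

    The residue-type channel in ``features`` is discarded in favor of the
    supplied sequence.
    """
    features = np.asarray(features, dtype=float)
    L = len(sequence)
    if features.shape != (L * N_CHANNELS,):
        raise ValueError(
            f"feature length {features.shape} does not match 13 * {L} residues"
        )
    coords = denormalize(
        features.reshape(L, N_CHANNELS)[:, :12], scale
    ).reshape(L, 4, 3)
    return BackboneStructure(
        sequence=sequence, coords=coords, id=structure_id, vacant=vacant
    )


def pad_or_trim_template(
    template: BackboneStructure, alignment
) -> BackboneStructure:
    """Map a template onto the target length using a residue alignment.

    ``alignment`` is a sequence of length L_target whose entry t is either the
    0-based template residue index aligned to target position t, or None for a
    gap.  Gap positions get all-zero coordinates and are flagged vacant;
    template residues outside the alignment are discarded.
    """
    L_target = len(alignment)
    if L_target < 2:
        raise ValueError("target length must be at least 2")
    coords = np.zeros((L_target, 4, 3))
    vacant = np.ones(L_target, dtype=bool)
    seq = []
    for t, ti in enumerate(alignment):
        if ti is None:
            seq.append("X")
            continue
        if not (0 <= ti < len(template)):
            raise IndexError(
                f"alignment maps target {t} to template {ti}, outside "
                f"0..{len(template) - 1}"
            )
        coords[t] = template.coords[ti]
        seq.append(template.sequence[ti])
        vacant[t] = False
    return BackboneStructure(
        sequence="".join(seq),
        coords=coords,
        id=f"{template.id}_aligned",
        vacant=vacant,
    )
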