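"""Decoy ensembles, synthetic natives and input corruption.

The decoy generator stands in for an external decoy program: it produces
diverse, well-spread alternative conformations of a template backbone whose
CA RMSD to the native is controlled to lie in a requested band (the training
regime uses 3-13 Angstrom).  Decoys are made by rotating the chain about
randomly chosen phi/psi bond axes (which preserves all covalent geometry
exactly) with the kick magnitude rescaled iteratively until the conformation
lands at a stratified target RMSD, so the ensemble covers the band
approximately uniformly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import (
    build_chain_from_torsions,
    kabsch_superpose,
    rmsd,
)
from .structure_io import BackboneStructure, read_pdb, write_pdb

logger = logging.getLogger(__name__)

__all__ = [
    "DecoySet",
    "generate_synthetic_native",
    "generate_decoys",
    "perturb_torsions",
    "corrupt_input",
    "import_external_decoys",
]

RETRY_FACTOR = 50  # total rejection budget is RETRY_FACTOR * n decoys

# ideal secondary-structure torsions (phi, psi), degrees
_MOTIF_TORSIONS = {"helix": (-57.0, -47.0), "strand": (-135.0, 135.0)}

# Ramachandran basins sampled for turn/loop residues (phi, psi), degrees:
# alpha-R, alpha-L, and two bend-like regions.  Including left-handed
# conformations lets the chain reverse direction the way real turns do.
_TURN_BASINS = ((-60.0, -30.0), (60.0, 40.0), (-90.0, 0.0), (80.0, 0.0))


@dataclass
class DecoySet:
    """Perturbed conformations of one template with RMSD-to-native labels."""

    template_id: str
    decoys: list
    rmsd_to_native: np.ndarray  # CA RMSD after superposition, Angstrom
    seed: int

    def __post_init__(self) -> None:
        self.rmsd_to_native = np.asarray(self.rmsd_to_native, dtype=float)
        if len(self.decoys) != len(self.rmsd_to_native):
            raise ValueError("decoy list and RMSD annotations differ in length")

    def __len__(self) -> int:
        return len(self.decoys)

    def save(self, directory) -> None:
        """Write decoys as numbered PDB files plus a tab-separated manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = ["decoy_id\trmsd_to_native\tseed"]
        for i, (decoy, r) in enumerate(zip(self.decoys, self.rmsd_to_native)):
            name = f"decoy_{i:04d}.pdb"
            write_pdb(decoy, directory / name)
            rows.append(f"{name}\t{r:.6f}\t{self.seed}")
        (directory / "manifest.tsv").write_text("\n".join(rows) + "\n")


def _ca_rmsd_superposed(decoy: BackboneStructure, native: BackboneStructure) -> float:
    sup = kabsch_superpose(decoy.ca, native.ca)
    return sup.rmsd_after


def _has_ca_clash(coords: np.ndarray, min_dist: float = 3.0) -> bool:
    ca = coords[:, 1, :]
    d = np.linalg.norm(ca[:, None, :] - ca[None, :, :], axis=-1)
    iu = np.triu_indices(len(ca), k=2)  # skip self and sequence neighbours
    return bool(np.any(d[iu] < min_dist))


def generate_synthetic_native(
    length: int, motif: str = "mixed", seed: int = 0
) -> BackboneStructure:
    """Deterministic native-like backbone for fixtures and simulations.

    Built from ideal secondary-structure torsions (helix -57/-47, strand
    -135/+135 degrees) with small Gaussian torsion jitter.  ``mixed`` chains
    alternate helix and strand segments joined by 2-4 residue turns whose
    torsions are drawn from real turn basins (including left-handed ones, so
    the chain can reverse direction); among the clash-free candidates drawn,
    the most compact (smallest CA radius of gyration) is kept, emulating the
    globularity of folded proteins.  Every result is clash-free at the CA
    level (no non-neighbour CA pair closer than 3 A) and deterministic for a
    given seed.
    """
    if length < 8:
        raise ValueError("synthetic natives need at least 8 residues")
    if motif not in ("helix", "strand", "mixed"):
        raise ValueError(f"unknown motif {motif!r}")
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))

    n_draws = 150 if motif == "mixed" else 50
    best: tuple[float, BackboneStructure] | None = None
    for _ in range(n_draws):
        phi = np.empty(length)
        psi = np.empty(length)
        if motif in ("helix", "strand"):
            phi[:], psi[:] = _MOTIF_TORSIONS[motif]
        else:
            i = 0
            kind = "helix" if rng.random() < 0.5 else "strand"
            while i < length:
                seg = int(rng.integers(6, 13))
                p, s = _MOTIF_TORSIONS[kind]
                phi[i : i + seg] = p
                psi[i : i + seg] = s
                i += seg
                turn = min(int(rng.integers(2, 5)), length - i)
                for t in range(turn):
                    bp, bs = _TURN_BASINS[rng.integers(0, len(_TURN_BASINS))]
                    phi[i + t] = bp + rng.normal(0.0, 15.0)
                    psi[i + t] = bs + rng.normal(0.0, 15.0)
                i += turn
                kind = "strand" if kind == "helix" else "helix"
        phi += rng.normal(0.0, 4.0, length)
        psi += rng.normal(0.0, 4.0, length)
        omega = 180.0 + rng.normal(0.0, 1.5, length)
        st = build_chain_from_torsions(
            seq, phi, psi, omega, structure_id=f"native_{motif}_{seed}"
        )
        if _has_ca_clash(st.coords):
            continue
        ca = st.ca
        rg = float(np.sqrt(((ca - ca.mean(axis=0)) ** 2).sum(axis=1).mean()))
        if best is None or rg < best[0]:
            best = (rg, st)
        if motif in ("helix", "strand"):
            break  # ideal-torsion chains need no compactness selection
    if best is None:
        raise RuntimeError("could not build a clash-free synthetic native")
    return best[1]


def _downstream_rotation(
    coords: np.ndarray, residue: int, torsion: str, delta_deg: float
) -> np.ndarray:
    """Rotate everything downstream of one phi/psi bond by delta degrees.

    Rotating about the actual bond axis changes exactly that torsion while
    preserving all bond lengths and angles of the chain.
    """
    out = coords.copy()
    if torsion == "phi":
        p0, p1 = coords[residue, 0], coords[residue, 1]  # N-CA axis
        # moves: C and O of this residue, all later residues
        mask = np.zeros(coords.shape[:2], dtype=bool)
        mask[residue, 2:] = True
        mask[residue + 1 :, :] = True
    elif torsion == "psi":
        p0, p1 = coords[residue, 1], coords[residue, 2]  # CA-C axis
        # moves: carbonyl O of this residue and all later residues
        mask = np.zeros(coords.shape[:2], dtype=bool)
        mask[residue, 3] = True
        mask[residue + 1 :, :] = True
    else:
        raise ValueError(f"unknown torsion {torsion!r}")
    axis = p1 - p0
    axis = axis / np.linalg.norm(axis)
    th = np.radians(delta_deg)
    k = axis
    pts = out[mask] - p1
    # Rodrigues rotation
    rot = (
        pts * np.cos(th)
        + np.cross(k, pts) * np.sin(th)
        + k * (pts @ k)[:, None] * (1 - np.cos(th))
    )
    out[mask] = rot + p1
    return out


def perturb_torsions(
    structure: BackboneStructure, moves: list[tuple[int, str, float]]
) -> BackboneStructure:
    """Apply a list of (residue, 'phi'|'psi', delta degrees) bond rotations."""
    coords = structure.coords
    for residue, torsion, delta in moves:
        coords = _downstream_rotation(coords, residue, torsion, delta)
    return BackboneStructure(
        sequence=structure.sequence,
        coords=coords,
        id=f"{structure.id}_perturbed",
        vacant=structure.vacant.copy(),
    )


def generate_decoys(
    native: BackboneStructure,
    n: int,
    rmsd_band: tuple[float, float] = (3.0, 13.0),
    seed: int = 0,
    cartesian_jitter: float = 0.0,
) -> DecoySet:
    """Generate ``n`` torsion-perturbation decoys with banded CA RMSD.

    Target RMSDs are stratified uniformly across ``rmsd_band`` so every part
    of the band is populated.  For each decoy, 1-3 pivot residues get random
    phi/psi kicks whose common magnitude is rescaled (up to a rejection
    budget of ``RETRY_FACTOR * n`` fresh attempts overall) until the CA RMSD
    after superposition lands within the band near its target.  Optional
    isotropic Cartesian jitter is added before the final RMSD is recorded.
    """
    low, high = rmsd_band
    if n < 1:
        raise ValueError("need at least one decoy")
    if not (0 < low < high):
        raise ValueError("rmsd band must satisfy 0 < low < high")
    rng = np.random.default_rng(seed)
    L = len(native)
    # stratified targets, shuffled so decoy order is not rank order
    targets = low + (high - low) * (np.arange(n) + rng.uniform(0, 1, n)) / n
    rng.shuffle(targets)
    tol = max(0.05, (high - low) / 20.0)

    budget = RETRY_FACTOR * n
    decoys: list[BackboneStructure] = []
    rmsds: list[float] = []
    for target in targets:
        accepted = None
        while accepted is None:
            if budget <= 0:
                raise RuntimeError(
                    f"rmsd band {rmsd_band} unreachable within the retry budget"
                )
            budget -= 1
            k = int(rng.integers(1, 4))
            pivots = rng.choice(np.arange(1, L - 1), size=k, replace=False)
            kinds = rng.choice(["phi", "psi"], size=k)
            base = rng.normal(0.0, 1.0, k)
            scale = 10.0 * target / max(k, 1)  # rough linear guess, degrees
            for _ in range(12):
                moves = [
                    (int(p), str(t), float(b * scale))
                    for p, t, b in zip(pivots, kinds, base)
                ]
                cand = perturb_torsions(native, moves)
                if cartesian_jitter > 0:
                    cand.coords += rng.normal(0, cartesian_jitter, cand.coords.shape)
                r = _ca_rmsd_superposed(cand, native)
                if abs(r - target) <= tol and low <= r <= high:
                    accepted = (cand, r)
                    break
                if r < 1e-6:
                    break
                scale = float(np.clip(scale * target / r, 1e-3, 2000.0))
        cand, r = accepted
        cand.id = f"{native.id}_decoy_{len(decoys):04d}"
        decoys.append(cand)
        rmsds.append(r)
    return DecoySet(
        template_id=native.id,
        decoys=decoys,
        rmsd_to_native=np.array(rmsds),
        seed=seed,
    )


def corrupt_input(
    features: np.ndarray, mask_fraction: float, seed: int = 0
) -> np.ndarray:
    """Denoising corruption: zero coordinate channels independently with
    probability ``mask_fraction``; residue-type channels are never touched.

    Masking to zero mirrors the zero-fill convention for vacant alignment
    positions, so the model sees the same kind of missingness at train time.
    """
    if not 0.0 <= mask_fraction <= 1.0:
        raise ValueError("mask fraction must be in [0, 1]")
    features = np.asarray(features, dtype=float)
    out = features.copy()
    rng = np.random.default_rng(seed)
    flat = out.reshape(-1, 13)
    drop = rng.random(flat[:, :12].shape) < mask_fraction
    flat[:, :12] = np.where(drop, 0.0, flat[:, :12])
    return out


def import_external_decoys(
    directory, native: BackboneStructure, strict: bool = True
) -> DecoySet:
    """Build a DecoySet from a directory of externally generated decoy PDBs.

    RMSD annotations are recomputed against ``native``.  Length-mismatched
    files raise in strict mode and are skipped with a log message otherwise.
    """
    directory = Path(directory)
    paths = sorted(directory.glob("*.pdb"))
    if not paths:
        raise ValueError(f"{directory}: no PDB files found")
    decoys: list[BackboneStructure] = []
    rmsds: list[float] = []
    for p in paths:
        st = read_pdb(p)
        if len(st) != len(native):
            if strict:
                raise ValueError(
                    f"{p}: decoy length {len(st)} differs from native {len(native)}"
                )
            logger.warning("skipping %s: length mismatch", p)
            continue
        decoys.append(st)
        rmsds.append(_ca_rmsd_superposed(st, native))
    if not decoys:
        raise ValueError(f"{directory}: no usable decoys")
    return DecoySet(
        template_id=native.id,
        decoys=decoys,
        rmsd_to_native=np.array(rmsds),
        seed=-1,
    )
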