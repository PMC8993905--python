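"""Residue-contact analysis of multi-frame coordinates.

Contacts are defined on minimum inter-residue heavy-atom distances: 5 A
for direct contacts observed along a trajectory, and a looser 7 A when
checking co-evolution predictions against simulation frames (the standard
allowance for the coarse nature of coupling-derived contacts).  Frames
come from multi-model PDB files (each MODEL is one frame), a directory of
single-frame PDBs, or programmatic construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CoordinateFrames",
    "ContactSeries",
    "min_heavy_distance",
    "contact_series",
    "dca_md_agreement",
]


@dataclass
class CoordinateFrames:
    """Heavy-atom coordinates of a (possibly multi-chain) assembly.

    ``coords`` has shape (n_frames, n_atoms, 3) in A; per-atom chain ids,
    residue numbers, atom names and element symbols are parallel arrays.
    Hydrogens are excluded by element at construction.
    """

    coords: np.ndarray
    chains: np.ndarray
    resids: np.ndarray
    names: np.ndarray
    elements: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None]
        self.chains = np.asarray(self.chains)
        self.resids = np.asarray(self.resids, int)
        self.names = np.asarray(self.names)
        self.elements = np.asarray([str(e).upper() for e in self.elements])
        heavy = self.elements != "H"
        if not np.all(heavy):
            self.coords = self.coords[:, heavy]
            self.chains = self.chains[heavy]
            self.resids = self.resids[heavy]
            self.names = self.names[heavy]
            self.elements = self.elements[heavy]
        n_atoms = self.coords.shape[1]
        if not (self.chains.size == self.resids.size == self.names.size
                == self.elements.size == n_atoms):
            raise ValueError("inconsistent atom annotation lengths")
        self._index = {}
        for k, (c, r) in enumerate(zip(self.chains, self.resids)):
            self._index.setdefault((str(c), int(r)), []).append(k)
        self._index = {k: np.asarray(v) for k, v in self._index.items()}

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def residues(self) -> list:
        """Sorted (chain, resid) identifiers."""
        return sorted(self._index)

    def atom_indices(self, residue) -> np.ndarray:
        chain, resid = residue
        key = (str(chain), int(resid))
        if key not in self._index:
            raise KeyError(f"residue {key} not present")
        return self._index[key]

    @classmethod
    def from_pdb(cls, path) -> "CoordinateFrames":
        """Read frames from a multi-model PDB or a directory of PDB files."""
        import biotite.structure.io.pdb as pdbio

        path = Path(path)
        stacks = []
        files = sorted(path.glob("*.pdb")) if path.is_dir() else [path]
        if not files:
            raise ValueError(f"no PDB files under {path}")
        annot = None
        for f in files:
            st = pdbio.PDBFile.read(str(f)).get_structure()
            coords = np.atleast_3d(st.coord)
            if coords.ndim == 2:
                coords = coords[None]
            stacks.append(st.coord if st.coord.ndim == 3 else st.coord[None])
            annot = st
        coords = np.concatenate(stacks, axis=0)
        return cls(coords, annot.chain_id, annot.res_id, annot.atom_name,
                   annot.element)

    def to_pdb(self, path) -> None:
        """Write frames as a multi-model PDB (one MODEL per frame)."""
        import biotite.structure as struc
        import biotite.structure.io.pdb as pdbio

        n_atoms = self.coords.shape[1]
        arr = struc.AtomArrayStack(self.n_frames, n_atoms)
        arr.coord = self.coords
        arr.chain_id = self.chains.astype("U4")
        arr.res_id = self.resids
        arr.atom_name = self.names.astype("U6")
        arr.element = self.elements.astype("U2")
        arr.res_name = np.full(n_atoms, "ALA", dtype="U5")
        f = pdbio.PDBFile()
        f.set_structure(arr)
        f.write(str(path))


@dataclass
class ContactSeries:
    """Per-frame minimum distances and contact booleans for residue pairs."""

    pairs: list                 # [((chain, res), (chain, res)), ...]
    distances: np.ndarray       # (n_pairs, n_frames), A
    cutoff: float

    def __post_init__(self):
        self.distances = np.asarray(self.distances, float)
        if self.distances.shape[0] != len(self.pairs):
            raise ValueError("one distance row per pair required")
        self._lookup = {}
        for k, (a, b) in enumerate(self.pairs):
            self._lookup[(a, b)] = k
            self._lookup[(b, a)] = k

    @property
    def contacts(self) -> np.ndarray:
        return self.distances < self.cutoff

    def contact_fraction(self, pair=None):
        """Fraction of frames in contact, per pair or for one pair."""
        frac = self.contacts.mean(axis=1)
        if pair is None:
            return {p: float(f) for p, f in zip(self.pairs, frac)}
        return float(frac[self._lookup[tuple(pair)]])

    def at_cutoff(self, cutoff: float) -> "ContactSeries":
        return ContactSeries(self.pairs, self.distances, cutoff)

    def transient_pairs(self, min_fraction: float = 0.0) -> list:
        """Pairs in contact in more than ``min_fraction`` of frames
        (default: at least one frame)."""
        frac = self.contacts.mean(axis=1)
        return [p for p, f in zip(self.pairs, frac) if f > min_fraction]


def min_heavy_distance(frames: CoordinateFrames, res_a, res_b,
                       frame: int = 0) -> float:
    """Minimum heavy-atom distance (A) between two residues in one frame."""
    ia = frames.atom_indices(res_a)
    ib = frames.atom_indices(res_b)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("residues must have >= 1 heavy atom")
    a = frames.coords[frame, ia]
    b = frames.coords[frame, ib]
    d2 = np.sum((a[:, None, :] - b[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.min()))


def _min_dist_series(frames, res_a, res_b, frame_slice):
    ia = frames.atom_indices(res_a)
    ib = frames.atom_indices(res_b)
    a = frames.coords[frame_slice][:, ia]
    b = frames.coords[frame_slice][:, ib]
    d2 = np.sum((a[:, :, None, :] - b[:, None, :, :]) ** 2, axis=-1)
    return np.sqrt(d2.reshape(d2.shape[0], -1).min(axis=1))


def contact_series(frames: CoordinateFrames, pair_selection,
                   cutoff: float = 5.0, stride: int = 1) -> ContactSeries:
    """Per-frame contact booleans for the selected residue pairs.

    ``pair_selection`` is an iterable of ((chain, res), (chain, res))
    pairs; ``stride`` subsamples frames (the analysis-stride knob).
    """
    pairs = [(tuple(a), tuple(b)) for a, b in pair_selection]
    if not pairs:
        raise ValueError("empty pair selection")
    if frames.n_frames < 1:
        raise ValueError("need >= 1 frame")
    sl = slice(None, None, stride)
    dists = np.stack([_min_dist_series(frames, a, b, sl) for a, b in pairs])
    return ContactSeries(pairs, dists, cutoff)


def residue_pairs(frames: CoordinateFrames, selection_a, selection_b=None,
                  min_same_chain_separation: int = 1) -> list:
    """Enumerate residue pairs between two selections across all chains.

    Selections are residue numbers; chain combinations are enumerated
    exhaustively (inter-subunit contacts count).  Same-chain pairs require
    a residue-number separation of at least ``min_same_chain_separation``.
    """
    sel_a = set(selection_a)
    sel_b = set(selection_b) if selection_b is not None else None
    residues = frames.residues
    out = []
    for k, (ca, ra) in enumerate(residues):
        if ra not in sel_a:
            continue
        for cb, rb in residues:
            if sel_b is not None and rb not in sel_b:
                continue
            if sel_b is None and (cb, rb) <= (ca, ra):
                continue
            if ca == cb and abs(ra - rb) < min_same_chain_separation:
                continue
            pair = ((ca, ra), (cb, rb))
            if (pair[1], pair[0]) not in {(a, b) for a, b in out}:
                out.append(pair)
    return out


def dca_md_agreement(series: ContactSeries, pairs,
                     loose_cutoff: float = 7.0,
                     formed_min_fraction: float = 0.0) -> pd.DataFrame:
    """Check predicted residue pairs against trajectory contacts.

    For each predicted (i, j) pair, the per-frame minimum distance over all
    chain-pair realizations of those residue numbers is compared to the
    loose cutoff; the pair is 'formed' when the contact fraction exceeds
    ``formed_min_fraction`` (default: formed in at least one frame).
    Raises if a predicted residue number is absent from the series.
    """
    from .coevolution_eval import RankedPairs

    if isinstance(pairs, RankedPairs):
        pairs = [(i, j) for i, j, _ in pairs.pairs]
    by_resnum: dict = {}
    for k, ((ca, ra), (cb, rb)) in enumerate(series.pairs):
        key = (min(ra, rb), max(ra, rb))
        by_resnum.setdefault(key, []).append(k)
    rows = []
    for i, j in pairs:
        key = (min(i, j), max(i, j))
        if key not in by_resnum:
            raise ValueError(
                f"predicted pair {key} has no realization in the contact "
                "series (residue numbering mismatch)")
        d = series.distances[by_resnum[key]].min(axis=0)
        frac = float(np.mean(d < loose_cutoff))
        rows.append((key[0], key[1], frac, frac > formed_min_fraction))
    return pd.DataFrame(rows, columns=["i", "j", "fraction_formed", "formed"])
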