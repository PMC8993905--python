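"""Co-evolution contact-prediction evaluation.

Alignment processing follows standard direct-coupling-analysis (DCA)
practice: sequences with more than 25% gaps are discarded (fragment
removal), the remainder are reweighted so that each cluster of sequences
sharing more than 90% identity carries unit total weight, and the sum of
weights is the effective sequence number B_eff.  Ranked coupling scores
(from any external DCA inference) are evaluated against structural
contacts: pairs separated by more than four residues along the chain, an
8 A heavy-atom contact definition, and the positive predictive value (PPV)
of the top-k predictions.  A weighted mutual-information scorer with
average-product correction (APC) is included so the pipeline runs
end-to-end without external coupling scores; it is plumbing, not a DCA
replacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import AlignIO

__all__ = [
    "WeightedAlignment",
    "RankedPairs",
    "ContactReference",
    "read_alignment",
    "filter_coverage",
    "reweight",
    "evaluate_predictions",
    "mi_apc_scores",
]

GAP_CHARS = frozenset("-.")
_ALPHABET = "ACDEFGHIKLMNPQRSTVWY-"
_CHAR_TO_INT = {c: i for i, c in enumerate(_ALPHABET)}


def _encode(sequences) -> np.ndarray:
    """Integer-encode aligned sequences; gaps become the 21st symbol."""
    rows = []
    for s in sequences:
        rows.append([_CHAR_TO_INT.get(c if c not in GAP_CHARS else "-",
                                      _CHAR_TO_INT["-"])
                     for c in s.upper()])
    arr = np.asarray(rows, dtype=np.int8)
    if arr.ndim != 2:
        raise ValueError("sequences must all have the same aligned length")
    return arr


@dataclass
class WeightedAlignment:
    """MSA with per-sequence identity weights and B_eff = sum of weights."""

    sequences: list
    weights: np.ndarray
    identity_threshold: float

    def __post_init__(self):
        self.weights = np.asarray(self.weights, float)
        if len(self.sequences) != self.weights.size:
            raise ValueError("one weight per sequence required")
        if self.sequences and (np.any(self.weights <= 0)
                               or np.any(self.weights > 1)):
            raise ValueError("weights must lie in (0, 1]")

    @property
    def n_positions(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def b_eff(self) -> float:
        return float(np.sum(self.weights))


@dataclass
class RankedPairs:
    """Position pairs (1-based, i < j) ordered by descending score."""

    pairs: list  # list of (i, j, score)

    def __post_init__(self):
        for i, j, _ in self.pairs:
            if not i < j:
                raise ValueError(f"pairs must satisfy i < j, got ({i}, {j})")
        self.pairs = sorted(self.pairs, key=lambda p: (-p[2], p[0], p[1]))

    @classmethod
    def from_tsv(cls, path) -> "RankedPairs":
        df = pd.read_csv(path, sep="\t", names=["i", "j", "score"],
                         header=None, comment="#")
        return cls([(int(r.i), int(r.j), float(r.score))
                    for r in df.itertuples()])

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.pairs, columns=["i", "j", "score"]).to_csv(
            path, sep="\t", index=False, header=False)


@dataclass
class ContactReference:
    """Minimum heavy-atom distances between residue positions.

    ``distances`` maps (i, j) with i < j to the minimum distance in A over
    all chain-pair realizations (a DCA prediction cannot distinguish intra-
    from inter-molecular contacts); ``defined_positions`` are positions
    resolved in the structure.
    """

    distances: dict
    defined_positions: set

    def __post_init__(self):
        for (i, j), d in self.distances.items():
            if not i < j:
                raise ValueError("distance keys must have i < j")
            if d <= 0:
                raise ValueError("distances must be > 0")

    def distance(self, i: int, j: int) -> float:
        return self.distances.get((min(i, j), max(i, j)), np.inf)

    @classmethod
    def from_frames(cls, frames, frame_index: int = 0) -> "ContactReference":
        """Build from a :class:`~masdyn.contact_analysis.CoordinateFrames`.

        Positions are residue numbers; the distance stored for (i, j) is
        the minimum over every chain-pair combination carrying those
        residue numbers, so intra- and inter-chain contacts both satisfy a
        prediction.
        """
        from .contact_analysis import min_heavy_distance
        residues = frames.residues
        defined = {res for _, res in residues}
        dist: dict = {}
        for a_idx, (ca, ra) in enumerate(residues):
            for cb, rb in residues[a_idx:]:
                i, j = min(ra, rb), max(ra, rb)
                if i == j and ca == cb:
                    continue
                d = min_heavy_distance(frames, (ca, ra), (cb, rb),
                                       frame_index)
                key = (i, j) if i < j else (j, i)
                if i == j:
                    continue
                if d < dist.get(key, np.inf):
                    dist[key] = d
        return cls(dist, defined)


def read_alignment(path, fmt: str = "fasta") -> list:
    """Aligned sequences from a FASTA or Stockholm file."""
    aln = AlignIO.read(str(path), fmt)
    return [str(rec.seq) for rec in aln]


def filter_coverage(sequences, max_gap_fraction: float = 0.25) -> list:
    """Drop fragment sequences with a gap fraction above the threshold.

    'No more than 25% gapped positions' is inclusive: a sequence exactly at
    the boundary is kept.
    """
    arr = _encode(sequences)
    gap_frac = np.mean(arr == _CHAR_TO_INT["-"], axis=1)
    kept = [s for s, f in zip(sequences, gap_frac) if f <= max_gap_fraction]
    if not kept:
        warnings.warn("coverage filter removed every sequence", stacklevel=2)
    return kept


def reweight(sequences, identity_threshold: float = 0.9, *,
             include_gaps: bool = True) -> WeightedAlignment:
    """Identity-based sequence reweighting.

    weight_i = 1 / |{j : identity(i, j) > threshold}| with self included,
    identity being the fraction of identical symbols over all columns.  By
    default the gap counts as a 21st symbol and the denominator is the full
    alignment length; ``include_gaps=False`` ignores columns gapped in
    either sequence.
    """
    if not len(sequences):
        raise ValueError("need >= 1 sequence")
    arr = _encode(sequences)
    n, L = arr.shape
    gap = _CHAR_TO_INT["-"]
    counts = np.zeros(n)
    for i in range(n):
        eq = arr == arr[i]
        if include_gaps:
            ident = eq.mean(axis=1)
        else:
            valid = (arr != gap) & (arr[i] != gap)
            nv = valid.sum(axis=1)
            with np.errstate(invalid="ignore"):
                ident = np.where(nv > 0, (eq & valid).sum(axis=1) / np.maximum(nv, 1), 0.0)
        counts[i] = np.sum(ident > identity_threshold)
    return WeightedAlignment(list(sequences), 1.0 / counts, identity_threshold)


def evaluate_predictions(pairs: RankedPairs, reference: ContactReference,
                         top_k: int, min_separation: int = 4,
                         cutoff: float = 8.0):
    """PPV of the top-k ranked pairs against structural contacts.

    Pairs with |i - j| <= ``min_separation`` are discarded before ranking
    truncation; a surviving pair is a true positive when its reference
    distance (minimum over chain-pair variants) is below ``cutoff``.
    Returns ``(ppv, ppv_defined, labels)`` where ``ppv_defined`` restricts
    the denominator to pairs whose both positions are structurally defined
    and ``labels`` is a DataFrame with one row per evaluated pair.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    eligible = [(i, j, s) for i, j, s in pairs.pairs
                if abs(i - j) > min_separation]
    if top_k > len(eligible):
        warnings.warn(
            f"top_k = {top_k} exceeds the {len(eligible)} eligible pairs; "
            "evaluating on all of them", stacklevel=2)
    taken = eligible[:top_k]
    rows = []
    for i, j, s in taken:
        d = reference.distance(i, j)
        defined = (i in reference.defined_positions
                   and j in reference.defined_positions)
        rows.append((i, j, s, d, bool(d < cutoff), defined))
    labels = pd.DataFrame(rows, columns=["i", "j", "score", "distance",
                                         "contact", "defined"])
    ppv = float(labels["contact"].mean()) if len(labels) else 0.0
    sub = labels[labels["defined"]]
    ppv_defined = float(sub["contact"].mean()) if len(sub) else 0.0
    return ppv, ppv_defined, labels


def mi_apc_scores(alignment: WeightedAlignment,
                  pseudocount: float = 0.5) -> RankedPairs:
    """Weighted mutual information per column pair, APC-corrected.

    Frequencies use the sequence weights with a symmetric pseudocount mixed
    in as f = (1 - lam) f_data + lam / q (lam = pseudocount / (pseudocount
    + B_eff), q = 21 symbols); the average-product correction
    APC_ij = MI_i. * MI_.j / MI_.. removes phylogenetic/entropic background.
    This is fallback plumbing for running the evaluation pipeline without
    external coupling scores.
    """
    arr = _encode(alignment.sequences)
    n, L = arr.shape
    if L < 2:
        raise ValueError("need >= 2 alignment columns")
    q = len(_ALPHABET)
    w = alignment.weights / alignment.b_eff
    lam = pseudocount / (pseudocount + alignment.b_eff)

    # single-site frequencies (L, q)
    f1 = np.zeros((L, q))
    for a in range(q):
        f1[:, a] = np.sum(w[:, None] * (arr == a), axis=0)
    f1 = (1 - lam) * f1 + lam / q

    onehot = np.zeros((n, L, q))
    onehot[np.arange(n)[:, None], np.arange(L)[None, :], arr] = 1.0
    wh = onehot * w[:, None, None]

    mi = np.zeros((L, L))
    for i in range(L):
        # joint frequencies of column i with all columns: (L, q, q)
        fij = np.einsum("n a, n l b -> l a b", wh[:, i, :], onehot)
        fij = (1 - lam) * fij + lam / q**2
        denom = f1[i][None, :, None] * f1[:, None, :]
        mi[i] = np.sum(fij * np.log(fij / denom), axis=(1, 2))
    mi = (mi + mi.T) / 2.0
    np.fill_diagonal(mi, 0.0)

    col_mean = mi.sum(axis=0) / (L - 1)
    total_mean = mi.sum() / (L * (L - 1))
    apc = np.outer(col_mean, col_mean) / total_mean
    score = mi - apc
    pairs = [(i + 1, j + 1, float(score[i, j]))
             for i in range(L) for j in range(i + 1, L)]
    return RankedPairs(pairs)
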