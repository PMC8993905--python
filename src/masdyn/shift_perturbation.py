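"""Combined chemical-shift-perturbation (CSP) mapping between two states.

Per residue, the 1H, 15N and 13CA shift differences between two assigned
states are combined as

    CSP = sqrt(d_H^2 + alpha_N * d_N^2 + alpha_CA * d_CA^2)

with alpha_N = 0.1 and alpha_CA = 0.3, and residues whose CSP exceeds a
multiple (default 3) of the standard deviation over all residues are
flagged as significantly perturbed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PeakList", "CspWeights", "CspResult", "combined_csp", "csp_map"]

_ATOMS = ("H", "N", "CA")


@dataclass
class PeakList:
    """Residue-indexed backbone shifts (ppm) for one state.

    ``entries`` maps residue number -> dict with any of the keys
    'H', 'N', 'CA'.
    """

    entries: dict
    state_label: str = ""

    def __post_init__(self):
        for res, shifts in self.entries.items():
            for atom, v in shifts.items():
                if atom not in _ATOMS:
                    raise ValueError(f"unknown atom {atom!r} for residue {res}")
                if not np.isfinite(v):
                    raise ValueError(f"non-finite shift for residue {res}/{atom}")

    @classmethod
    def from_csv(cls, path, state_label: str = "") -> "PeakList":
        """Read a long-format CSV with columns residue, atom, shift_ppm."""
        df = pd.read_csv(path)
        entries: dict = {}
        for _, row in df.iterrows():
            entries.setdefault(int(row["residue"]), {})[str(row["atom"])] = \
                float(row["shift_ppm"])
        return cls(entries, state_label)

    def to_csv(self, path) -> None:
        rows = [(res, atom, v) for res, shifts in sorted(self.entries.items())
                for atom, v in shifts.items()]
        pd.DataFrame(rows, columns=["residue", "atom", "shift_ppm"]).to_csv(
            path, index=False)

    @property
    def residues(self) -> set:
        return set(self.entries)


@dataclass(frozen=True)
class CspWeights:
    """Nucleus weights of the combined CSP."""

    alpha_n: float = 0.1
    alpha_ca: float = 0.3

    def __post_init__(self):
        if self.alpha_n <= 0 or self.alpha_ca <= 0:
            raise ValueError("CSP weights must be > 0")


@dataclass
class CspResult:
    """Per-residue combined CSPs with the significance threshold."""

    csp: dict                  # residue -> ppm
    threshold: float           # ppm
    significant: set           # residues with csp > threshold
    partial: set = field(default_factory=set)  # residues missing >= 1 atom


def combined_csp(delta_h: float, delta_n: float, delta_ca: float,
                 weights: CspWeights = CspWeights()) -> float:
    """Weighted Euclidean combination of per-nucleus shift differences."""
    return float(np.sqrt(delta_h**2 + weights.alpha_n * delta_n**2
                         + weights.alpha_ca * delta_ca**2))


def csp_map(state_a: PeakList, state_b: PeakList,
            weights: CspWeights = CspWeights(),
            sd_multiplier: float = 3.0, *, trim_outliers: bool = False,
            trim_fraction: float = 0.1) -> CspResult:
    """Residue-wise combined CSP between two states with a 3-SD line.

    Only residues assigned in both states enter.  A missing atom in either
    state contributes zero to that residue's CSP and marks it partial.  The
    significance threshold is ``sd_multiplier`` times the standard deviation
    of all computed CSPs (optionally with symmetric trimming of the most
    extreme values before taking the SD; off by default).
    """
    common = sorted(state_a.residues & state_b.residues)
    if len(common) < 2:
        raise ValueError("need >= 2 residues assigned in both states")
    csp: dict = {}
    partial: set = set()
    for res in common:
        sa, sb = state_a.entries[res], state_b.entries[res]
        deltas = {}
        for atom in _ATOMS:
            if atom in sa and atom in sb:
                deltas[atom] = sa[atom] - sb[atom]
            else:
                deltas[atom] = 0.0
                partial.add(res)
        csp[res] = combined_csp(deltas["H"], deltas["N"], deltas["CA"], weights)
    values = np.array(list(csp.values()))
    if trim_outliers and values.size > 4:
        k = int(np.floor(values.size * trim_fraction / 2))
        values_for_sd = np.sort(values)[k:values.size - k if k else None]
    else:
        values_for_sd = values
    sd = float(np.std(values_for_sd, ddof=1)) if values_for_sd.size > 1 else 0.0
    threshold = sd_multiplier * sd
    significant = {res for res, v in csp.items() if v > threshold}
    return CspResult(csp, threshold, significant, partial)
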