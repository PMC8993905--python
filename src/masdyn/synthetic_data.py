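"""Seeded synthetic datasets with the statistical structure of each stage.

Every generator is bit-reproducible under a fixed seed and produces valid
input for its target analysis module, together with a machine-readable
truth record, so the whole pipeline can be exercised closed-loop without
any experimental download.  Default truth values follow the study
conditions the analyses were designed around: a highly flexible methyl
site with S^2 = 0.15 among rigid sites in the 0.7-1 band, the printed
R1 delay grid, a 0.1-6.4 mM substrate series measured in duplicate, and a
5-of-100-residue chemical-shift perturbation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import lambertw
from scipy.stats import truncnorm

from .kinetics import AbsorbanceModel, KineticTrace
from .relaxation import R1_DELAYS, RelaxationDecay
from .shift_perturbation import PeakList
from .spin_sim import (DipolarTensor, PowderScheme, PulseTiming, RedorCurve,
                       methyl_rigid_limit, simulate_redor)

__all__ = [
    "ScenarioConfig",
    "make_redor_dataset",
    "make_relaxation_dataset",
    "make_csp_dataset",
    "make_kinetics_dataset",
    "make_msa",
    "make_toy_assembly",
    "default_scenario",
    "REDOR_NOISE_SIGMA",
    "DEFAULT_SUBSTRATE_CONCS_MM",
]

#: spectral noise level (dS/S0 units) calibrated so the Monte Carlo SD of
#: S^2 at the flexible-site truth (S^2 = 0.15) is ~0.02
REDOR_NOISE_SIGMA = 0.105

#: duplicate-measured substrate series, mM
DEFAULT_SUBSTRATE_CONCS_MM = (0.1, 0.2, 0.4, 0.8, 1.6, 3.2, 6.4)


def _s2_to_anisotropy(s2: float) -> float:
    return float(np.sqrt(s2) * methyl_rigid_limit())


@dataclass
class ScenarioConfig:
    """Parameter block for the default end-to-end scenario."""

    seed: int = 0
    # REDOR: (label, S^2 truth, eta truth)
    redor_sites: tuple = (("V120", 0.15, 0.3), ("I139", 0.18, 0.2),
                          ("V-rigid-1", 0.85, 0.1), ("V-rigid-2", 0.95, 0.0),
                          ("V-rigid-3", 0.70, 0.15))
    redor_noise_sigma: float = REDOR_NOISE_SIGMA
    # relaxation: site -> R1rho rates per spin-lock field (flat + rising)
    nerrd_fields_hz: tuple = (2000.0, 5000.0, 10000.0, 20000.0, 35000.0)
    mas_frequency: float = 46000.0
    relax_sigma: float = 2.0
    # CSP
    n_residues: int = 100
    perturbed_residues: tuple = (120, 121, 122, 123, 124)
    n15_offset_ppm: float = 0.5
    csp_noise_ppm: float = 0.01
    # kinetics
    km_mM: float = 1.0
    kcat_per_s: float = 50.0
    substrate_concs_mM: tuple = DEFAULT_SUBSTRATE_CONCS_MM
    kinetics_noise_fraction: float = 0.03
    # MSA
    msa_sequences: int = 400
    msa_positions: int = 40
    covarying_pairs: tuple = ((5, 25), (10, 30))
    coupling_strength: float = 0.9
    gap_rate: float = 0.05


def make_redor_dataset(truths, timing: PulseTiming | None = None,
                       noise_sigma: float = REDOR_NOISE_SIGMA,
                       seed: int | None = None,
                       powder: PowderScheme | None = None) -> dict:
    """Noisy REDOR curves for labelled tensor truths.

    ``truths`` is a mapping label -> DipolarTensor (or (anisotropy, eta)
    tuple).  Noise is truncated-normal at +-3 sigma, matching the Monte
    Carlo convention of the fitting stage.  Returns
    {label: (RedorCurve, DipolarTensor)}.
    """
    timing = timing or PulseTiming.shifted()
    rng = np.random.default_rng(seed)
    rigid = methyl_rigid_limit()
    out = {}
    for label, tensor in truths.items():
        if not isinstance(tensor, DipolarTensor):
            tensor = DipolarTensor(*tensor)
        if tensor.anisotropy > rigid * (1 + 1e-12):
            raise ValueError(
                f"truth anisotropy {tensor.anisotropy} Hz for {label!r} "
                f"exceeds the methyl rigid limit {rigid:.0f} Hz")
        clean = simulate_redor(tensor, timing, powder)
        if noise_sigma > 0:
            noise = truncnorm.rvs(-3, 3, scale=noise_sigma,
                                  size=clean.dephasing.size, random_state=rng)
        else:
            noise = 0.0
        out[label] = (RedorCurve(clean.dephasing_times,
                                 clean.dephasing + noise, noise_sigma),
                      tensor)
    return out


def make_relaxation_dataset(rates, fields=None, delays=R1_DELAYS,
                            sigma: float = 0.0, seed: int | None = None,
                            amplitude: float = 100.0,
                            mas_frequency: float = 46000.0) -> dict:
    """Monoexponential decays per site and spin-lock field.

    ``rates`` maps site -> rate (s^-1, used at every field) or
    site -> {field: rate}.  ``fields`` (Hz) defaults to a single R1-style
    measurement (field 0).  Returns {site: [RelaxationDecay, ...]}.
    """
    rng = np.random.default_rng(seed)
    delays = np.asarray(delays, float)
    fields = list(fields) if fields is not None else [0.0]
    out = {}
    for site, r in rates.items():
        per_field = r if isinstance(r, dict) else {f: r for f in fields}
        decays = []
        for f, rate in sorted(per_field.items()):
            if rate <= 0:
                raise ValueError("rates must be > 0")
            y = amplitude * np.exp(-rate * delays)
            if sigma > 0:
                y = y + rng.normal(0.0, sigma, delays.size)
            decays.append(RelaxationDecay(delays, y, sigma, f, mas_frequency))
        out[site] = decays
    return out


def make_csp_dataset(n_residues: int = 100, perturbed_set=(120, 121, 122, 123, 124),
                     offsets=None, sigma: float = 0.01,
                     seed: int | None = None) -> tuple:
    """Two peak lists differing by localized 15N offsets plus noise.

    State B equals state A plus per-atom offsets on the perturbed residues
    and normal noise of SD ``sigma`` ppm on every shift.  ``offsets`` maps
    atom -> ppm (default: 0.5 ppm on 15N only).  Residue numbers start at
    101 by default so the loop-like range 120-124 exists.
    """
    rng = np.random.default_rng(seed)
    offsets = offsets if offsets is not None else {"N": 0.5}
    residues = range(101, 101 + n_residues)
    perturbed = set(perturbed_set)
    if not perturbed <= set(residues):
        raise ValueError("perturbed_set must be within the residue range")
    a_entries, b_entries = {}, {}
    for res in residues:
        base = {"H": rng.uniform(7.0, 9.5), "N": rng.uniform(105.0, 130.0),
                "CA": rng.uniform(50.0, 65.0)}
        a_entries[res] = {k: v + rng.normal(0.0, sigma) for k, v in base.items()}
        b = {k: v + rng.normal(0.0, sigma) for k, v in base.items()}
        if res in perturbed:
            for atom, off in offsets.items():
                b[atom] += off
        b_entries[res] = b
    return (PeakList(a_entries, "state_a"), PeakList(b_entries, "state_b"))


def make_kinetics_dataset(km: float = 1.0e-3, kcat: float = 50.0,
                          enzyme_site_conc: float | None = None,
                          substrate_concs=None, noise_fraction: float = 0.03,
                          seed: int | None = None, duration: float = 60.0,
                          n_points: int = 121,
                          model: AbsorbanceModel = AbsorbanceModel()) -> dict:
    """Integrated Michaelis-Menten progress curves as absorbance traces.

    Product formation follows the closed-form integrated rate law (Lambert
    W); concentrations convert to absorbance through the Beer-Lambert
    model.  Each substrate concentration is measured in duplicate, plus a
    blank (no enzyme).  ``noise_fraction`` scales multiplicative normal
    noise on the absorbance increments.  km in M, kcat in s^-1.
    Returns {"traces": [KineticTrace...], "blanks": [...], "truth": dict}.
    """
    if km <= 0 or kcat <= 0:
        raise ValueError("km and kcat must be > 0")
    if enzyme_site_conc is None:
        from .kinetics import site_concentration
        enzyme_site_conc = site_concentration()
    substrate_concs = substrate_concs or tuple(
        c * 1e-3 for c in DEFAULT_SUBSTRATE_CONCS_MM)
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, duration, n_points)
    vmax = kcat * enzyme_site_conc
    traces, blanks = [], []
    for s0 in substrate_concs:
        # S(t) = KM * W((S0/KM) exp((S0 - Vmax t)/KM)); P = S0 - S(t)
        arg = (s0 / km) * np.exp((s0 - vmax * t) / km)
        s_t = km * np.real(lambertw(arg))
        p_t = s0 - s_t
        a_clean = p_t * model.epsilon * model.path_length
        for _ in range(2):  # duplicate wells
            a = a_clean.copy()
            if noise_fraction > 0:
                scale = np.maximum(np.abs(a_clean), np.max(a_clean) * 0.02)
                a = a + rng.normal(0.0, noise_fraction, a.size) * scale
                a[0] = a_clean[0]
            traces.append(KineticTrace(t, a, s0, False))
        blanks.append(KineticTrace(t, np.zeros_like(t), s0, True))
    truth = {"km": km, "kcat": kcat, "vmax": vmax,
             "enzyme_site_conc": enzyme_site_conc}
    return {"traces": traces, "blanks": blanks, "truth": truth}


_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def make_msa(n_sequences: int = 400, n_positions: int = 40,
             covarying_pairs=((5, 25),), coupling_strength: float = 0.9,
             gap_rate: float = 0.0, seed: int | None = None) -> dict:
    """Alignment with independent columns except imposed pair couplings.

    Coupled pairs (1-based positions) draw, with probability
    ``coupling_strength``, a jointly chosen symbol pair (a random bijection
    links the two columns' alphabets) and an independent background draw
    otherwise, so covariation is detectable by mutual information.  Gaps
    are inserted per-site at ``gap_rate``.  Returns {"sequences": [...],
    "coupled_pairs": [...]} with positions 1-based.
    """
    rng = np.random.default_rng(seed)
    pairs = [tuple(p) for p in covarying_pairs]
    flat = [p for pair in pairs for p in pair]
    if len(set(flat)) != len(flat):
        raise ValueError("coupled pairs must not overlap")
    for i, j in pairs:
        if not (1 <= i <= n_positions and 1 <= j <= n_positions and i != j):
            raise ValueError(f"pair ({i}, {j}) outside positions 1..{n_positions}")

    # background column profiles: Dirichlet over a 6-letter sub-alphabet
    profiles = []
    for _ in range(n_positions):
        letters = rng.choice(list(_AA20), size=6, replace=False)
        probs = rng.dirichlet(np.ones(6))
        profiles.append((letters, probs))
    bijections = {pair: rng.permutation(len(_AA20)) for pair in pairs}

    seqs = []
    for _ in range(n_sequences):
        chars = [rng.choice(p[0], p=p[1]) for p in profiles]
        for (i, j) in pairs:
            if rng.random() < coupling_strength:
                a = rng.integers(len(_AA20))
                chars[i - 1] = _AA20[a]
                chars[j - 1] = _AA20[bijections[(i, j)][a]]
        if gap_rate > 0:
            mask = rng.random(n_positions) < gap_rate
            chars = ["-" if m else c for c, m in zip(chars, mask)]
        seqs.append("".join(chars))
    return {"sequences": seqs, "coupled_pairs": pairs}


def make_toy_assembly(n_frames: int = 50, loop_excursion_amplitude: float = 6.0,
                      approach_fraction: float = 0.4,
                      seed: int | None = None):
    """Two-chain toy assembly with a mobile loop approaching an active site.

    Chain A carries a rigid scaffold (residues 101-115) and a mobile loop
    (residues 120-126); chain B carries the partner scaffold with a
    designated active-site residue 150.  In a designed fraction of frames
    the loop tip (residue 123) sits 4.0 A from the active-site residue;
    in the rest it is displaced outward by ``loop_excursion_amplitude`` A.
    Amplitude 0 keeps the tip permanently engaged (constant contact map).
    Returns (CoordinateFrames, truth dict).
    """
    from .contact_analysis import CoordinateFrames

    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)

    chains, resids, names, elements, base = [], [], [], [], []

    def add_residue(chain, resid, centre):
        # CA + CB heavy-atom pair per residue
        for name, off in (("CA", (0.0, 0.0, 0.0)), ("CB", (0.0, 0.0, 1.5))):
            chains.append(chain)
            resids.append(resid)
            names.append(name)
            elements.append("C")
            base.append(np.asarray(centre, float) + off)

    for k, resid in enumerate(range(101, 116)):       # chain A scaffold
        add_residue("A", resid, (3.8 * k, 0.0, 0.0))
    for k, resid in enumerate(range(120, 127)):       # chain A loop
        add_residue("A", resid, (10.0 + 3.8 * k, 12.0, 0.0))
    for k, resid in enumerate(range(140, 161)):       # chain B scaffold
        add_residue("B", resid, (3.8 * k, 30.0, 0.0))

    base = np.asarray(base)
    atoms_per_res = 2
    tip_mask = (np.asarray(chains) == "A") & (np.asarray(resids) == 123)
    site_mask = (np.asarray(chains) == "B") & (np.asarray(resids) == 150)
    site_centre = base[site_mask].mean(axis=0)

    n_in = int(round(approach_fraction * n_frames))
    engaged = np.zeros(n_frames, bool)
    engaged[:n_in] = True
    rng.shuffle(engaged)

    coords = np.repeat(base[None], n_frames, axis=0)
    direction = np.array([0.0, 1.0, 0.0])
    for f in range(n_frames):
        tip_target = site_centre - direction * 4.0
        if not engaged[f] and loop_excursion_amplitude > 0:
            tip_target = tip_target - direction * loop_excursion_amplitude
        shift = tip_target - base[tip_mask][0]
        coords[f, tip_mask] = base[tip_mask] + shift
    frames = CoordinateFrames(coords, chains, resids, names, elements)
    truth = {"tip": ("A", 123), "site": ("B", 150),
             "approach_fraction": n_in / n_frames,
             "engaged_frames": engaged.tolist()}
    return frames, truth


# --------------------------------------------------------------------------
# end-to-end scenario emission
# --------------------------------------------------------------------------

def default_scenario(seed: int = 0, outdir=None,
                     config: ScenarioConfig | None = None) -> dict:
    """Generate every stage's input under one seed; optionally write files.

    Returns a dict of in-memory objects plus the truth record; when
    ``outdir`` is given, CSV/FASTA/PDB files and ``truths.json`` are
    written there.
    """
    cfg = config or ScenarioConfig(seed=seed)
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=6)

    timing = PulseTiming.shifted()
    redor = make_redor_dataset(
        {label: (_s2_to_anisotropy(s2), eta)
         for label, s2, eta in cfg.redor_sites},
        timing, cfg.redor_noise_sigma, int(sub_seeds[0]))

    nerrd_rates = {
        "flat-site": {f: 8.0 for f in cfg.nerrd_fields_hz},
        "loop-site": {f: 8.0 + 30.0 * (f / cfg.mas_frequency) ** 2
                      for f in cfg.nerrd_fields_hz},
    }
    # spin-lock decays sample the same relative grid as the R1 template,
    # compressed into the rotating-frame decay window (rates of tens s^-1)
    decays = make_relaxation_dataset(nerrd_rates, cfg.nerrd_fields_hz,
                                     np.asarray(R1_DELAYS) / 20.0,
                                     cfg.relax_sigma, int(sub_seeds[1]),
                                     mas_frequency=cfg.mas_frequency)

    peaks_a, peaks_b = make_csp_dataset(cfg.n_residues,
                                        cfg.perturbed_residues,
                                        {"N": cfg.n15_offset_ppm},
                                        cfg.csp_noise_ppm, int(sub_seeds[2]))

    kin = make_kinetics_dataset(cfg.km_mM * 1e-3, cfg.kcat_per_s,
                                substrate_concs=tuple(
                                    c * 1e-3 for c in cfg.substrate_concs_mM),
                                noise_fraction=cfg.kinetics_noise_fraction,
                                seed=int(sub_seeds[3]))

    msa = make_msa(cfg.msa_sequences, cfg.msa_positions, cfg.covarying_pairs,
                   cfg.coupling_strength, cfg.gap_rate, int(sub_seeds[4]))

    frames, assembly_truth = make_toy_assembly(seed=int(sub_seeds[5]))

    truth = {
        "seed": seed,
        "redor": {label: {"anisotropy": t.anisotropy, "asymmetry": t.asymmetry,
                          "s_squared": (t.anisotropy / methyl_rigid_limit())**2}
                  for label, (_, t) in redor.items()},
        "nerrd": nerrd_rates,
        "csp": {"perturbed": list(cfg.perturbed_residues),
                "offset_ppm": cfg.n15_offset_ppm},
        "kinetics": kin["truth"],
        "msa": {"coupled_pairs": [list(p) for p in msa["coupled_pairs"]]},
        "assembly": {k: v for k, v in assembly_truth.items()
                     if k != "engaged_frames"},
    }
    out = {"redor": redor, "timing": timing, "decays": decays,
           "peaks": (peaks_a, peaks_b), "kinetics": kin, "msa": msa,
           "frames": frames, "truth": truth}

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = [(label, t, d, cfg.redor_noise_sigma)
                for label, (curve, _) in redor.items()
                for t, d in zip(curve.dephasing_times, curve.dephasing)]
        pd.DataFrame(rows, columns=["site", "time_s", "dephasing", "sigma"]) \
            .to_csv(outdir / "redor_curves.csv", index=False)
        rows = [(site, d.spin_lock_rf, t, i, d.intensity_sigma)
                for site, ds in decays.items() for d in ds
                for t, i in zip(d.delays, d.intensities)]
        pd.DataFrame(rows, columns=["site", "spin_lock_rf", "delay_s",
                                    "intensity", "sigma"]) \
            .to_csv(outdir / "decays.csv", index=False)
        peaks_a.to_csv(outdir / "peaks_a.csv")
        peaks_b.to_csv(outdir / "peaks_b.csv")
        rows = [(f"S{t.substrate_conc*1e3:g}_{k}", t.substrate_conc * 1e3,
                 tt, aa, t.is_blank)
                for k, t in enumerate(kin["traces"] + kin["blanks"])
                for tt, aa in zip(t.times, t.absorbance)]
        pd.DataFrame(rows, columns=["well", "substrate_mM", "time_s",
                                    "absorbance", "is_blank"]) \
            .to_csv(outdir / "traces.csv", index=False)
        with open(outdir / "msa.fasta", "w") as fh:
            for k, s in enumerate(msa["sequences"]):
                fh.write(f">seq{k}\n{s}\n")
        frames.to_pdb(outdir / "assembly.pdb")
        with open(outdir / "truths.json", "w") as fh:
            json.dump(truth, fh, indent=2)
    return out
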