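"""Seeded generators for every input the analysis pipeline consumes.

Each generator draws from a fresh, explicitly seeded NumPy Generator (no
global state), adds i.i.d. Gaussian noise on the measured signal, and is
byte-deterministic for a given (seed, parameters).  Defaults encode the
experimental conditions of the study system: a ~60-residue acidic SH3
domain with water stability ~4.4 kJ/mol rising to ~20 kJ/mol at 800 mM
NaCl, slow unfolding (k_u ~ 0.09 1/s), a compact transition state
(beta_urea ~ 0.91), rigid-backbone amide dynamics (S^2 ~ 0.85,
tau_c = 5.76 ns at 600 MHz), an ion atmosphere of sodium around 15 acidic
side chains with rare chloride-lysine contacts, and an ortholog family of
262 sequences with mean net charge -10 and one covarying column pair.

Toy trajectories use geometric placement, not physics: occupancy of the
4 A contact shell is the only property the downstream statistics depend
on, so each tagged ion (or salt-bridge partner) is simply placed inside
(<4 A) or outside (>6 A) its target group by a seeded Bernoulli draw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import rt_kj
from .equilibrium import (
    DEFAULT_TEMPERATURE,
    DenaturationCurve,
    StabilitySeries,
    two_state_signal,
)
from .kinetics import KineticTrace
from .relaxation import (
    ModelFreeParams,
    RelaxationRecord,
    SpectrometerConfig,
    r1rho_from_r1_r2,
    predict_relaxation_rates,
)
from .sequence import Alignment, SequenceRecord
from .trajectory import RunEnsemble, Trajectory

__all__ = [
    "GeneratorSpec",
    "GroundTruth",
    "ToyTrajectoryLayout",
    "DEFAULT_UREA_GRID",
    "DEFAULT_IONIC_STRENGTH_GRID",
    "gen_equilibrium_curve",
    "gen_unfolding_trace",
    "gen_salt_series",
    "gen_relaxation_set",
    "gen_toy_trajectory",
    "gen_alignment",
]

#: Default urea grid, M: a buffer-only well plus a serial-dilution series
#: from 10.5 M down (the assay starts concentrated and dilutes), which
#: samples the low-urea transition region of a marginally stable domain
#: densely instead of evenly.
DEFAULT_UREA_GRID = np.concatenate(
    [[0.0], (10.5 * 0.82 ** np.arange(25))[::-1]])

#: Default ionic-strength grid, M: five log-spaced points from 5 to 800 mM.
#: The top matches the highest salt condition studied; the dilute end is
#: where the sqrt(I), I and ln(I) stability models separate most.
DEFAULT_IONIC_STRENGTH_GRID = np.geomspace(0.005, 0.8, 5)


@dataclass
class GeneratorSpec:
    """Reproducibility contract for one generator call."""

    seed: int
    noise_sd: float = 0.0  # signal units, i.i.d. Gaussian
    replicate_count: int = 1

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """Generative parameters for the synthetic experiments.

    Thermodynamics in kJ/mol (dG0 > 0 = folded favoured), rates in 1/s,
    correlation times in s.
    """

    # equilibrium (no-salt condition)
    dG0: float = 4.4  # kJ/mol
    m_eq: float = 5.0  # kJ/mol/M
    baseline_native: tuple[float, float] = (1.0, -0.01)
    baseline_denatured: tuple[float, float] = (0.2, 0.005)
    temperature: float = DEFAULT_TEMPERATURE
    # salt dependence (Debye-Hueckel form)
    m_salt: float = 17.0  # kJ/mol/M^0.5
    # kinetics (no-salt condition)
    ku0: float = 0.088  # 1/s
    m_ku: float = 0.177  # 1/M
    # relaxation
    S2: float = 0.85
    tau_e: float = 50e-12  # s
    tau_c: float = 5.76e-9  # s

    def __post_init__(self) -> None:
        if not 0.0 <= self.S2 <= 1.0:
            raise ValueError("S2 must lie in [0, 1]")
        if self.ku0 <= 0 or self.tau_e <= 0 or self.tau_c <= 0:
            raise ValueError("all rates and times must be positive")

    @property
    def kf0(self) -> float:
        """Folding rate implied by detailed balance, 1/s."""
        return self.ku0 * math.exp(self.dG0 / rt_kj(self.temperature))


def gen_equilibrium_curve(truth: GroundTruth, urea_grid=None,
                          spec: GeneratorSpec | None = None,
                          salt_label: str = "", ionic_strength: float = 0.0
                          ) -> DenaturationCurve:
    """Two-state denaturation curve with linear baselines and Gaussian noise."""
    spec = spec or GeneratorSpec(seed=0)
    u = np.asarray(DEFAULT_UREA_GRID if urea_grid is None else urea_grid,
                   dtype=float)
    if u.size == 0:
        raise ValueError("urea grid must be non-empty")
    if np.any(u < 0):
        raise ValueError("urea concentrations must be non-negative")
    if np.any(u > 10.5):
        raise ValueError("urea concentrations above 10.5 M are not supported")
    signal = two_state_signal(
        u, truth.dG0, truth.m_eq,
        truth.baseline_native[0], truth.baseline_native[1],
        truth.baseline_denatured[0], truth.baseline_denatured[1],
        temperature=truth.temperature,
    )
    noise = spec.rng().normal(0.0, spec.noise_sd, size=u.shape) \
        if spec.noise_sd > 0 else 0.0
    return DenaturationCurve(
        urea=u, signal=signal + noise, temperature=truth.temperature,
        salt_label=salt_label, ionic_strength=ionic_strength,
    )


def gen_unfolding_trace(k_u: float, amplitude: float, offset: float,
                        time_grid=None, spec: GeneratorSpec | None = None,
                        urea: float = 9.0, ionic_strength: float = 0.0,
                        temperature: float = DEFAULT_TEMPERATURE
                        ) -> KineticTrace:
    """Single-exponential unfolding trace signal = offset + A*exp(-k_u*t)."""
    if k_u <= 0:
        raise ValueError("k_u must be positive")
    spec = spec or GeneratorSpec(seed=0)
    # one-minute read at 10 Hz unless a grid is given
    t = np.arange(0.0, 60.05, 0.1) if time_grid is None \
        else np.asarray(time_grid, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    signal = offset + amplitude * np.exp(-k_u * t)
    noise = spec.rng().normal(0.0, spec.noise_sd, size=t.shape) \
        if spec.noise_sd > 0 else 0.0
    return KineticTrace(time=t, signal=signal + noise, urea=urea,
                        ionic_strength=ionic_strength, temperature=temperature)


def gen_salt_series(dG0: float, m_salt: float, I_grid=None,
                    spec: GeneratorSpec | None = None,
                    salt_type: str = "NaCl") -> StabilitySeries:
    """Stability vs ionic strength following dG(I) = dG0 + m_salt*sqrt(I)."""
    spec = spec or GeneratorSpec(seed=0)
    I = np.asarray(DEFAULT_IONIC_STRENGTH_GRID if I_grid is None else I_grid,
                   dtype=float)
    if np.any(I < 0):
        raise ValueError("ionic strength must be non-negative")
    dG = dG0 + m_salt * np.sqrt(I)
    noise = spec.rng().normal(0.0, spec.noise_sd, size=I.shape) \
        if spec.noise_sd > 0 else 0.0
    errors = np.full(I.shape, spec.noise_sd) if spec.noise_sd > 0 else None
    return StabilitySeries(ionic_strength=I, dG=dG + noise,
                           dG_errors=errors, salt_type=salt_type)


def gen_relaxation_set(params_per_residue, config: SpectrometerConfig | None = None,
                       spec: GeneratorSpec | None = None,
                       nu_SL: float = 2000.0) -> list[RelaxationRecord]:
    """Per-residue (R1, R1rho, R2, NOE) records from model-free parameters.

    Rates are forward-calculated, Gaussian noise (``noise_sd``, absolute,
    per rate for R1/R2, divided by 10 for the dimensionless NOE) is added,
    and R1rho is then back-composed from the noisy R1/R2 at the spin-lock
    strength and a seeded per-residue carrier offset, so the
    R1rho -> R2 conversion is exactly consistent with the stored rates.
    """
    spec = spec or GeneratorSpec(seed=0)
    config = config or SpectrometerConfig()
    params = list(params_per_residue)
    for p in params:
        if not 0.0 <= p.S2 <= 1.0:
            raise ValueError("S2 out of range")
        if not p.tau_e < p.tau_c:
            raise ValueError("require tau_e < tau_c")
    rng = spec.rng()
    offsets = rng.uniform(-1500.0, 1500.0, size=len(params))  # Hz
    records = []
    for i, p in enumerate(params):
        R1, R2, NOE = predict_relaxation_rates(p, config)
        if spec.noise_sd > 0:
            R1 += rng.normal(0.0, spec.noise_sd)
            R2 += rng.normal(0.0, spec.noise_sd)
            NOE += rng.normal(0.0, spec.noise_sd / 10.0)
        R1rho = r1rho_from_r1_r2(R1, R2, nu_SL, offsets[i])
        records.append(RelaxationRecord(
            residue=i + 1, R1=R1, R1rho=R1rho, NOE=NOE,
            nu_SL=nu_SL, Omega=float(offsets[i]), R2=R2,
            R1_err=spec.noise_sd or float("nan"),
            R2_err=spec.noise_sd or float("nan"),
            NOE_err=(spec.noise_sd / 10.0) or float("nan"),
        ))
    return records


# ---------------------------------------------------------------------------
# toy trajectories

@dataclass
class ToyTrajectoryLayout:
    """Occupancy targets for a toy ion/salt-bridge trajectory.

    ``ion_sites``: (resname, resid, occupancy) — an oppositely charged
    monovalent ion is within 4 A of that residue's charged group in the
    stated fraction of frames (Na+ for Asp/Glu sites, Cl- for Lys sites).
    ``bridges``: (lys_resid, acidic_resname, acidic_resid, occupancy).
    """

    ion_sites: list[tuple[str, int, float]] = field(default_factory=lambda: [
        # 15 acidic residues with the study's asymmetry: frequent cation
        # contacts near the binding surface, rare anion contacts at the
        # three lysines.
        *[("ASP", rid, occ) for rid, occ in
          [(9, 0.45), (12, 0.40), (16, 0.35), (24, 0.20), (33, 0.30),
           (35, 0.30), (38, 0.25), (44, 0.15)]],
        *[("GLU", rid, occ) for rid, occ in
          [(5, 0.35), (11, 0.30), (20, 0.25), (30, 0.20), (40, 0.10),
           (42, 0.10), (55, 0.25)]],
        *[("LYS", rid, occ) for rid, occ in
          [(25, 0.02), (43, 0.02), (47, 0.03)]],
    ])
    bridges: list[tuple[int, str, int, float]] = field(default_factory=lambda: [
        (125, "GLU", 142, 0.55),  # mimics K25-E42
        (143, "ASP", 124, 0.45),  # K43-D24
        (243, "ASP", 144, 0.35),  # K43-D44
        (147, "GLU", 140, 0.50),  # K47-E40
    ])

    def validate(self) -> None:
        for _, _, occ in self.ion_sites:
            if not 0.0 <= occ <= 1.0:
                raise ValueError(f"ion occupancy {occ} outside [0, 1]")
        for _, _, _, occ in self.bridges:
            if not 0.0 <= occ <= 1.0:
                raise ValueError(f"bridge occupancy {occ} outside [0, 1]")


_SIDECHAIN = {
    "LYS": ["NZ"],
    "ASP": ["CG", "OD1", "OD2"],
    "GLU": ["CD", "OE1", "OE2"],
}
_GROUP_OFFSETS = {
    "NZ": (0.0, 0.0, 0.0),
    "CG": (0.0, 0.0, 0.0), "OD1": (1.1, 0.0, 0.0), "OD2": (-0.6, 1.0, 0.0),
    "CD": (0.0, 0.0, 0.0), "OE1": (1.1, 0.0, 0.0), "OE2": (-0.6, 1.0, 0.0),
}
_BACKBONE_OFFSETS = {
    "N": (-1.5, -3.0, 0.0), "H": (-1.5, -4.0, 0.0), "CA": (0.0, -3.0, 0.0),
    "C": (1.4, -3.0, 0.5), "O": (2.3, -3.0, -0.2),
}

_IN_DIST = 3.0  # A, inside the 4 A contact shell
_OUT_DIST = 9.0  # A, outside the 6 A exclusion shell
_JITTER_SD = 0.02  # A, cosmetic thermal jitter, << contact margins


def _build_residue(resname, resid, center, atoms, coords):
    for name, off in _BACKBONE_OFFSETS.items():
        atoms.append((name, resname, resid, "A", name[0]))
        coords.append(np.asarray(center) + off)
    for name in _SIDECHAIN[resname]:
        atoms.append((name, resname, resid, "A", name[0]))
        coords.append(np.asarray(center) + _GROUP_OFFSETS[name])


def gen_toy_trajectory(layout: ToyTrajectoryLayout | None = None,
                       n_frames: int = 2000, n_runs: int = 3,
                       spec: GeneratorSpec | None = None) -> RunEnsemble:
    """Geometric toy ensemble with prescribed contact occupancies.

    Residues sit on a wide grid (25 A apart) so sites are independent; each
    tagged ion is placed 3 A from its residue's charged group when the
    seeded Bernoulli draw says "in contact" and 9 A away otherwise, and
    each salt-bridge acidic group is likewise placed relative to the lysine
    NZ.  All frames get a small (0.02 A) positional jitter.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    layout = layout or ToyTrajectoryLayout()
    layout.validate()
    spec = spec or GeneratorSpec(seed=0)
    child_seeds = np.random.SeedSequence(spec.seed).spawn(n_runs)

    # ---- static topology (shared by all runs)
    atoms: list[tuple] = []
    base: list[np.ndarray] = []
    spacing = 25.0
    site_info = []  # (kind, payload, base-atom indices...)
    idx = 0

    def _grid(i):
        return np.array([(i % 6) * spacing, ((i // 6) % 6) * spacing,
                         (i // 36) * spacing])

    slot = 0
    for resname, resid, occ in layout.ion_sites:
        center = _grid(slot); slot += 1
        start = len(atoms)
        _build_residue(resname, resid, center, atoms, base)
        group0 = start + len(_BACKBONE_OFFSETS)  # first side-chain atom
        ion_res = "CL" if resname == "LYS" else "NA"
        atoms.append((ion_res, ion_res, 9000 + resid, "A",
                      "CL" if ion_res == "CL" else "NA"))
        base.append(center + np.array([_OUT_DIST, 0.0, 0.0]))
        site_info.append(("ion", occ, group0, len(atoms) - 1, center))
    for lys_resid, ac_name, ac_resid, occ in layout.bridges:
        center = _grid(slot); slot += 1
        start = len(atoms)
        _build_residue("LYS", lys_resid, center, atoms, base)
        nz = start + len(_BACKBONE_OFFSETS)
        ac_center = center + np.array([8.0, 0.0, 0.0])
        ac_start = len(atoms)
        _build_residue(ac_name, ac_resid, ac_center, atoms, base)
        ac_group = list(range(ac_start + len(_BACKBONE_OFFSETS), len(atoms)))
        site_info.append(("bridge", occ, nz, ac_group, center))

    atom_df = pd.DataFrame(atoms,
                           columns=["name", "resname", "resid", "chain",
                                    "element"])
    base_xyz = np.asarray(base)

    runs = []
    for seed_seq in child_seeds:
        rng = np.random.default_rng(seed_seq)
        coords = np.tile(base_xyz, (n_frames, 1, 1))
        for info in site_info:
            kind = info[0]
            occ = info[1]
            contact = (np.ones(n_frames, bool) if occ >= 1.0
                       else np.zeros(n_frames, bool) if occ <= 0.0
                       else rng.random(n_frames) < occ)
            if kind == "ion":
                _, _, group0, ion_idx, center = info
                anchor = base_xyz[group0]
                coords[:, ion_idx, :] = np.where(
                    contact[:, None],
                    anchor + np.array([_IN_DIST, 0.0, 0.0]),
                    anchor + np.array([_OUT_DIST, 0.0, 0.0]),
                )
            else:
                _, _, nz, ac_group, center = info
                anchor = base_xyz[nz]
                near = anchor + np.array([3.5, 0.0, 0.0])
                far = anchor + np.array([8.0, 0.0, 0.0])
                # move the whole acidic charged group rigidly
                for k, ai in enumerate(ac_group):
                    off = base_xyz[ai] - base_xyz[ac_group[0]]
                    coords[:, ai, :] = np.where(
                        contact[:, None], near + off, far + off,
                    )
        coords += rng.normal(0.0, _JITTER_SD, size=coords.shape)
        runs.append(Trajectory(atoms=atom_df.copy(), coords=coords))
    return RunEnsemble(runs=runs, condition="toy")


# ---------------------------------------------------------------------------
# alignments

_NEUTRAL = "ACFGHILMNPQSTVWY"


def gen_alignment(n_seqs: int = 262, length: int = 60,
                  charge_target: int = -10,
                  covarying_pair: tuple[int, int] = (40, 47),
                  spec: GeneratorSpec | None = None,
                  n_variable_charge_cols: int = 4,
                  conservation: float = 0.7) -> Alignment:
    """Ortholog-like alignment with a planted covarying column pair.

    The covarying pair takes two complementary two-letter joint states
    (("N","S") or ("S","N")), drawn 50/50 per row, giving 1 bit of mutual
    information; constant acidic/basic columns plus ``n_variable_charge_cols``
    half-occupied acidic columns set the mean net charge exactly to
    ``charge_target``; every remaining column is independent with a
    ``conservation`` fraction of a column-specific consensus letter.
    """
    if length < 2:
        raise ValueError("length must be >= 2")
    i, j = covarying_pair
    if i == j or not (0 <= i < length and 0 <= j < length):
        raise ValueError("covarying pair positions must be distinct and < length")
    spec = spec or GeneratorSpec(seed=0)
    rng = spec.rng()

    nv = n_variable_charge_cols
    if nv % 2:
        raise ValueError("n_variable_charge_cols must be even")
    constant_net = charge_target + nv // 2  # E[variable part] = -nv/2
    if constant_net <= 0:
        n_pos = 2
        n_neg = n_pos - constant_net
    else:
        n_neg = 2
        n_pos = n_neg + constant_net
    needed = 2 + nv + n_pos + n_neg
    if needed > length:
        raise ValueError(
            f"impossible charge target {charge_target} for length {length}: "
            f"needs {needed} dedicated columns"
        )

    cols = np.empty((length, n_seqs), dtype="<U1")
    free = [c for c in range(length) if c not in (i, j)]
    acid_cols = free[:n_neg]
    basic_cols = free[n_neg:n_neg + n_pos]
    var_cols = free[n_neg + n_pos:n_neg + n_pos + nv]
    other_cols = free[n_neg + n_pos + nv:]

    state = rng.random(n_seqs) < 0.5
    cols[i] = np.where(state, "N", "S")
    cols[j] = np.where(state, "S", "N")
    for k, c in enumerate(acid_cols):
        cols[c] = "D" if k % 2 == 0 else "E"
    for c in basic_cols:
        cols[c] = "K"
    for c in var_cols:
        cols[c] = np.where(rng.random(n_seqs) < 0.5, "D", "N")
    # background columns: a consensus letter plus a few alternates, the
    # column diversity actually seen in ortholog alignments (a flat 16-letter
    # column would carry ~0.6 bits of pure finite-sample MI bias at n~260)
    neutral = np.array(list(_NEUTRAL))
    for c in other_cols:
        letters = neutral[rng.permutation(len(neutral))[:4]]
        draw = letters[1:][rng.integers(3, size=n_seqs)]
        cols[c] = np.where(rng.random(n_seqs) < conservation, letters[0], draw)

    rows = ["".join(cols[:, s]) for s in range(n_seqs)]
    return Alignment(rows=[
        SequenceRecord(id=f"ortholog_{s:04d}", sequence=rows[s])
        for s in range(n_seqs)
    ])
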