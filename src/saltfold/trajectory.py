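"""Ion-atmosphere and structural statistics on MD trajectory ensembles.

Works on lightweight in-memory trajectories (an atom table plus a
frames x atoms x 3 coordinate array) read from or written to multi-model
PDB through MDAnalysis.  The statistics implemented are the ones used to
characterise territorial ion binding around a highly acidic domain:

* per-residue ion-contact fractions — an oppositely charged monovalent ion
  within a distance cutoff (default 4 A) of any side-chain charged-group
  heavy atom;
* mean numbers of distinct cations/anions in contact per frame;
* salt-bridge occupancies — lysine NZ to the most distal side-chain carbon
  of Asp (CG) or Glu (CD) within the same cutoff;
* backbone atomic fluctuations (RMSF) after least-squares superposition on
  an iterated mean structure;
* intramolecular hydrogen-bond counts under a distance + angle criterion.

Each statistic is computed per independent run, and the cross-run mean and
standard deviation are reported, mirroring how replicate simulations are
summarised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "Trajectory",
    "RunEnsemble",
    "ContactStats",
    "SaltBridgeResult",
    "charged_group_atoms",
    "ion_contact_stats",
    "salt_bridge_fractions",
    "backbone_rmsf",
    "count_hbonds",
    "write_pdb",
    "load_trajectory",
    "CATION_RESNAMES",
    "ANION_RESNAMES",
]

#: Residue names recognised as monovalent cations / anions (PDB dialects).
CATION_RESNAMES = {"NA", "NA+", "SOD", "K", "K+", "POT"}
ANION_RESNAMES = {"CL", "CL-", "CLA"}

#: Side-chain charged-group heavy atoms (ion-contact criterion uses any of
#: them; the salt-bridge criterion uses only NZ and the distal carbon).
CHARGED_GROUPS = {
    "LYS": {"NZ"},
    "ASP": {"CG", "OD1", "OD2"},
    "GLU": {"CD", "OE1", "OE2"},
}

#: Most distal side-chain carbon, the salt-bridge reference atom.
BRIDGE_ATOM = {"LYS": "NZ", "ASP": "CG", "GLU": "CD"}

POSITIVE_RESNAMES = {"LYS"}
NEGATIVE_RESNAMES = {"ASP", "GLU"}


@dataclass
class Trajectory:
    """Labelled coordinate frames: an atom table plus coordinates in A.

    ``atoms`` columns: name, resname, resid, chain, element.
    ``coords`` shape: (n_frames, n_atoms, 3).
    """

    atoms: pd.DataFrame
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError("atom table and coordinate array disagree on atom count")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def ion_mask(self, kind: str) -> np.ndarray:
        names = CATION_RESNAMES if kind == "cation" else ANION_RESNAMES
        return self.atoms["resname"].str.upper().isin(names).to_numpy()

    @property
    def protein_mask(self) -> np.ndarray:
        ions = CATION_RESNAMES | ANION_RESNAMES
        return ~self.atoms["resname"].str.upper().isin(ions).to_numpy()


@dataclass
class RunEnsemble:
    """Independent simulation replicates of one condition."""

    runs: list[Trajectory]
    condition: str = ""

    def __post_init__(self) -> None:
        if not self.runs:
            raise ValueError("ensemble needs at least one run")
        ref = self.runs[0].atoms
        for run in self.runs[1:]:
            if len(run.atoms) != len(ref) or not (
                run.atoms[["name", "resname", "resid"]]
                .reset_index(drop=True)
                .equals(ref[["name", "resname", "resid"]].reset_index(drop=True))
            ):
                raise ValueError("all runs must share one topology")


@dataclass
class ContactStats:
    """Ion-contact summary: per-residue fractions and global ion counts."""

    per_residue: pd.DataFrame  # resid, resname, fraction_mean, fraction_sd
    cations_per_frame: float  # mean distinct cations contacting acidic groups
    cations_per_frame_sd: float
    anions_per_frame: float  # mean distinct anions contacting basic groups
    anions_per_frame_sd: float


@dataclass
class SaltBridgeResult:
    """Occupancy of one salt bridge across runs."""

    pair: str  # e.g. "K25-E42"
    fractions: list[float]  # one per run
    mean: float
    sd: float


def charged_group_atoms(atoms: pd.DataFrame) -> dict[int, set[str]]:
    """Map resid -> side-chain charged-group atom names for charged residues.

    Only Lys/Asp/Glu carry charged groups here (the domain under study has
    no Arg or protonation-ambiguous His in its charge model).
    """
    mapping: dict[int, set[str]] = {}
    for (resid, resname), _ in atoms.groupby(["resid", "resname"], sort=True):
        rn = str(resname).upper()
        if rn in CHARGED_GROUPS:
            mapping[int(resid)] = set(CHARGED_GROUPS[rn])
        elif rn not in CATION_RESNAMES | ANION_RESNAMES and rn not in {
            "ALA", "ARG", "ASN", "CYS", "GLN", "GLY", "HIS", "ILE", "LEU",
            "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
            "HOH", "WAT", "TIP", "TIP3", "SOL",
        }:
            raise ValueError(f"unknown residue name {resname!r}")
    return mapping


def _per_run_sd(values: list[float]) -> float:
    return float(np.std(values, ddof=1)) if len(values) > 1 else 0.0


def ion_contact_stats(ensemble: RunEnsemble, cutoff: float = 4.0) -> ContactStats:
    """Per-residue ion-contact fractions and distinct-ion counts per frame.

    A residue is in contact in a frame iff any oppositely charged ion lies
    within ``cutoff`` A of any atom of its side-chain charged group.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    rows: dict[tuple[int, str], list[float]] = {}
    cat_counts, an_counts = [], []
    for run in ensemble.runs:
        atoms = run.atoms
        groups = charged_group_atoms(atoms)
        cat_idx = np.nonzero(run.ion_mask("cation"))[0]
        an_idx = np.nonzero(run.ion_mask("anion"))[0]
        resname_by_id = {
            int(r): str(n).upper()
            for r, n in zip(atoms["resid"], atoms["resname"])
        }
        # distinct-ion contact masks accumulated per frame
        cat_contact = np.zeros((run.n_frames, len(cat_idx)), dtype=bool)
        an_contact = np.zeros((run.n_frames, len(an_idx)), dtype=bool)
        for resid, names in sorted(groups.items()):
            rn = resname_by_id[resid]
            sel = (
                (atoms["resid"].to_numpy() == resid)
                & atoms["name"].isin(names).to_numpy()
            )
            gxyz = run.coords[:, sel, :]  # (F, G, 3)
            ion_idx = cat_idx if rn in NEGATIVE_RESNAMES else an_idx
            key = (resid, rn)
            if len(ion_idx) == 0:
                rows.setdefault(key, []).append(0.0)
                continue
            ixyz = run.coords[:, ion_idx, :]  # (F, M, 3)
            # (F, G, M) pairwise distances, small systems so broadcast is fine
            d = np.linalg.norm(gxyz[:, :, None, :] - ixyz[:, None, :, :], axis=-1)
            near = d <= cutoff  # contact is inclusive of the cutoff
            frame_contact = near.any(axis=(1, 2))
            rows.setdefault(key, []).append(float(frame_contact.mean()))
            ion_near = near.any(axis=1)  # (F, M)
            if rn in NEGATIVE_RESNAMES:
                cat_contact |= ion_near
            else:
                an_contact |= ion_near
        cat_counts.append(float(cat_contact.sum(axis=1).mean()) if len(cat_idx) else 0.0)
        an_counts.append(float(an_contact.sum(axis=1).mean()) if len(an_idx) else 0.0)

    table = pd.DataFrame(
        [
            {
                "resid": resid,
                "resname": rn,
                "fraction_mean": float(np.mean(fr)),
                "fraction_sd": _per_run_sd(fr),
            }
            for (resid, rn), fr in sorted(rows.items())
        ]
    )
    return ContactStats(
        per_residue=table,
        cations_per_frame=float(np.mean(cat_counts)),
        cations_per_frame_sd=_per_run_sd(cat_counts),
        anions_per_frame=float(np.mean(an_counts)),
        anions_per_frame_sd=_per_run_sd(an_counts),
    )


def _bridge_atom_index(atoms: pd.DataFrame, resid: int) -> int:
    sel = atoms.index[atoms["resid"] == resid]
    if len(sel) == 0:
        raise ValueError(f"residue {resid} not found in topology")
    resname = str(atoms.loc[sel[0], "resname"]).upper()
    if resname not in BRIDGE_ATOM:
        raise ValueError(f"residue {resid} ({resname}) carries no bridge atom")
    name = BRIDGE_ATOM[resname]
    hit = atoms.index[(atoms["resid"] == resid) & (atoms["name"] == name)]
    if len(hit) == 0:
        raise ValueError(f"atom {name} missing on residue {resid}")
    return int(hit[0])


def salt_bridge_fractions(ensemble: RunEnsemble, pairs,
                          cutoff: float = 4.0) -> list[SaltBridgeResult]:
    """Occupancy of Lys-NZ to Asp-CG / Glu-CD salt bridges.

    ``pairs`` is an iterable of ``(resid_basic, resid_acidic)`` tuples; a
    bridge is formed in a frame iff the two reference atoms are within
    ``cutoff`` A (inclusive).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    results = []
    one_letter = {"LYS": "K", "ASP": "D", "GLU": "E"}
    for ra, rb in pairs:
        fracs = []
        label = None
        for run in ensemble.runs:
            atoms = run.atoms.reset_index(drop=True)
            ia = _bridge_atom_index(atoms, int(ra))
            ib = _bridge_atom_index(atoms, int(rb))
            if label is None:
                na = one_letter[str(atoms.loc[ia, "resname"]).upper()]
                nb = one_letter[str(atoms.loc[ib, "resname"]).upper()]
                label = f"{na}{int(ra)}-{nb}{int(rb)}"
            d = np.linalg.norm(run.coords[:, ia, :] - run.coords[:, ib, :], axis=-1)
            fracs.append(float((d <= cutoff).mean()))
        results.append(
            SaltBridgeResult(
                pair=label, fractions=fracs,
                mean=float(np.mean(fracs)), sd=_per_run_sd(fracs),
            )
        )
    return results


def _kabsch_superpose(frames: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Superpose each frame onto ref (optimal rotation + translation)."""
    out = np.empty_like(frames)
    ref_c = ref - ref.mean(axis=0)
    for i, fr in enumerate(frames):
        mu = fr.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_c, fr - mu)
        out[i] = rot.apply(fr - mu) + ref.mean(axis=0)
    return out


def backbone_rmsf(ensemble: RunEnsemble,
                  selection: set[str] = frozenset({"N", "CA", "C", "O"})):
    """Per-residue backbone RMSF (A) after superposition, mean +- SD over runs.

    Each run's frames are least-squares superposed onto the run's iterated
    mean structure (two passes), then RMSF_i = sqrt(<|r_i - <r_i>|^2>) per
    atom, averaged over the selected backbone atoms of each residue.
    Returns a DataFrame with columns resid, rmsf_mean, rmsf_sd.
    """
    per_run: dict[int, list[float]] = {}
    for run in ensemble.runs:
        if run.n_frames < 2:
            raise ValueError("RMSF needs at least 2 frames")
        atoms = run.atoms.reset_index(drop=True)
        sel = atoms["name"].isin(selection).to_numpy() & run.protein_mask
        xyz = run.coords[:, sel, :]
        resids = atoms.loc[sel, "resid"].to_numpy()
        aligned = xyz
        ref = xyz[0]
        for _ in range(2):  # two-pass iterated mean
            aligned = _kabsch_superpose(xyz, ref)
            ref = aligned.mean(axis=0)
        mean = aligned.mean(axis=0)
        msf = ((aligned - mean) ** 2).sum(axis=-1).mean(axis=0)
        rmsf_atom = np.sqrt(msf)
        for resid in np.unique(resids):
            val = float(rmsf_atom[resids == resid].mean())
            per_run.setdefault(int(resid), []).append(val)
    return pd.DataFrame(
        [
            {"resid": resid, "rmsf_mean": float(np.mean(v)),
             "rmsf_sd": _per_run_sd(v)}
            for resid, v in sorted(per_run.items())
        ]
    )


def count_hbonds(ensemble: RunEnsemble, d_cut: float = 3.0,
                 angle_cut: float = 135.0):
    """Average intramolecular hydrogen bonds per frame, mean +- SD over runs.

    A bond is counted when a protein donor heavy atom (N or O with a
    covalently attached hydrogen, inferred by a <= 1.25 A N/O-H distance in
    the first frame) is within ``d_cut`` A of a protein acceptor (O or N not
    acting as that donor) and the donor-H-acceptor angle is >= ``angle_cut``
    degrees.  Ion records are ignored.
    """
    means = []
    for run in ensemble.runs:
        atoms = run.atoms.reset_index(drop=True)
        prot = run.protein_mask
        names = atoms["name"].to_numpy()
        elements = atoms["element"].astype(str).str.upper().to_numpy()
        heavy_don = np.nonzero(prot & np.isin(elements, ["N", "O"]))[0]
        hydro = np.nonzero(prot & (elements == "H"))[0]
        if len(hydro) == 0:
            raise ValueError("no hydrogens present; cannot identify donors")
        # donor-H pairs from first-frame covalent geometry
        pairs = []
        xyz0 = run.coords[0]
        for h in hydro:
            d = np.linalg.norm(xyz0[heavy_don] - xyz0[h], axis=-1)
            j = np.argmin(d)
            if d[j] <= 1.25:
                pairs.append((int(heavy_don[j]), int(h)))
        if not pairs:
            raise ValueError("no identifiable donor-H pairs")
        acceptors = np.nonzero(prot & (elements == "O"))[0]
        count = np.zeros(run.n_frames)
        for don, h in pairs:
            acc = acceptors[acceptors != don]
            if len(acc) == 0:
                continue
            dxyz = run.coords[:, don, :]
            hxyz = run.coords[:, h, :]
            axyz = run.coords[:, acc, :]
            dist = np.linalg.norm(axyz - dxyz[:, None, :], axis=-1)
            v1 = dxyz[:, None, :] - hxyz[:, None, :]
            v2 = axyz - hxyz[:, None, :]
            cosang = (v1 * v2).sum(-1) / (
                np.linalg.norm(v1, axis=-1) * np.linalg.norm(v2, axis=-1)
            )
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            count += ((dist <= d_cut) & (ang >= angle_cut)).sum(axis=1)
        means.append(float(count.mean()))
    return float(np.mean(means)), _per_run_sd(means)


# ---------------------------------------------------------------------------
# multi-model PDB I/O (via MDAnalysis, behind one loading interface)

def write_pdb(traj: Trajectory, path) -> None:
    """Write a trajectory as a multi-model PDB (MODEL/ENDMDL records)."""
    import warnings as _w

    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    atoms = traj.atoms.reset_index(drop=True)
    n = len(atoms)
    resids_seq = atoms["resid"].to_numpy()
    # residue blocks in order of first appearance
    block_ids = np.unique(resids_seq, return_index=True)[1]
    order = np.argsort(block_ids)
    uniq = resids_seq[np.sort(block_ids)]
    res_index = {rid: i for i, rid in enumerate(uniq)}
    u = mda.Universe.empty(
        n, n_residues=len(uniq),
        atom_resindex=[res_index[r] for r in resids_seq],
        trajectory=True,
    )
    u.add_TopologyAttr("names", atoms["name"].tolist())
    u.add_TopologyAttr("elements", atoms["element"].tolist())
    resnames, chains = [], []
    seen = set()
    for rid, rn, ch in zip(resids_seq, atoms["resname"], atoms["chain"]):
        if rid not in seen:
            seen.add(rid)
            resnames.append(rn)
            chains.append(ch if ch else "A")
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", list(uniq))
    u.add_TopologyAttr("segids", ["SYS"])
    u.load_new(traj.coords.astype(np.float32), format=MemoryReader)
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        with mda.Writer(str(path), n, multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


def load_trajectory(path, topology=None) -> Trajectory:
    """Load a trajectory (multi-model PDB, or DCD/XTC plus a topology).

    One interface over the MDAnalysis readers; returns the in-memory
    :class:`Trajectory` used by every analysis here.
    """
    import warnings as _w

    import MDAnalysis as mda

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        u = mda.Universe(str(topology), str(path)) if topology else mda.Universe(str(path))
        ag = u.atoms
        try:
            elements = [str(e).upper() for e in ag.elements]
        except Exception:
            elements = [
                mda.topology.guessers.guess_atom_element(nm) for nm in ag.names
            ]
        atoms = pd.DataFrame(
            {
                "name": ag.names,
                "resname": ag.resnames,
                "resid": ag.resids,
                "chain": getattr(ag, "chainIDs", ["A"] * len(ag)),
                "element": elements,
            }
        )
        coords = np.stack([ag.positions.copy() for _ in u.trajectory]).astype(float)
    return Trajectory(atoms=atoms, coords=coords)
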