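import numpy as np
import pandas as pd
import pytest

from saltfold import GeneratorSpec, GroundTruth, Trajectory

# Printed his-tagged construct of the S. cerevisiae Abp1p SH3 domain.
ABP_SC_CONSTRUCT = (
    "MAPKENPWATAEYDYDAAEDNELTFVENDKIINIEFVDDDWWLGELEKDGSKGLFPSNYVSLGNLE"
    "HHHHHH"
)


@pytest.fixture
def abp_construct() -> str:
    return ABP_SC_CONSTRUCT


@pytest.fixture
def truth() -> GroundTruth:
    return GroundTruth()


@pytest.fixture
def zero_noise_spec() -> GeneratorSpec:
    return GeneratorSpec(seed=0, noise_sd=0.0)


def make_trajectory(atom_rows, frames) -> Trajectory:
    """Hand-built trajectory: atom_rows = (name, resname, resid), frames =
    list of per-atom coordinate lists."""
    atoms = pd.DataFrame(
        [
            {"name": n, "resname": rn, "resid": rid, "chain": "A",
             "element": n[0]}
            for n, rn, rid in atom_rows
        ]
    )
    return Trajectory(atoms=atoms, coords=np.asarray(frames, dtype=float))
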