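import numpy as np
import pytest

from incellfold import molecule as mol
from incellfold import synthetic_fixtures as sf


@pytest.fixture(scope="session")
def hairpin_scenario():
    """Noiseless hairpin scenario shared across tests (read-only)."""
    return sf.make_scenario("hairpin12", seed=11, noise_sigma=0.0)


@pytest.fixture(scope="session")
def hairpin_restraints(hairpin_scenario):
    """Inter-residue truth restraints (intra-residue distances are fixed by
    covalent geometry and carry no conformational information)."""
    return [r for r in hairpin_scenario.truth_restraints
            if r.options[0][0][0] != r.options[0][1][0]]


@pytest.fixture(scope="session")
def hairpin_backbone(hairpin_scenario):
    tpl = hairpin_scenario.structure.template
    idx = [tpl.atom_index(r, n) for r in range(1, 13)
           for n in ("N", "CA", "C")]
    return np.array(idx, dtype=int)


def backbone_rmsd(conf, ref_coords, bb_idx):
    """Minimal Kabsch RMSD of a conformer's backbone to reference coords."""
    from incellfold.ensemble_analysis import kabsch_superpose

    co = mol.build_coordinates(conf).coords
    return kabsch_superpose(co, ref_coords, bb_idx)[2]
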