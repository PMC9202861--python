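"""Shared fixtures: hand-written PDB text, synthetic helices, small cohorts."""

from __future__ import annotations

from pathlib import Path

import pytest

import helixprime as hp
from helixprime.structure_io import extract_backbone

WINDOW = list(range(60, 75))

# two residues (GLY, ALA) with full backbones; ALA adds CB -> 9 heavy atoms
TWO_RESIDUE_PDB = """\
ATOM      1  N   GLY A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  GLY A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   GLY A   1      10.729   6.745  -4.124  1.00  0.00           C
ATOM      4  O   GLY A   1       9.704   7.329  -4.477  1.00  0.00           O
ATOM      5  N   ALA A   2      11.107   6.683  -2.851  1.00  0.00           N
ATOM      6  CA  ALA A   2      10.316   7.289  -1.780  1.00  0.00           C
ATOM      7  C   ALA A   2      10.948   8.610  -1.347  1.00  0.00           C
ATOM      8  O   ALA A   2      12.139   8.856  -1.537  1.00  0.00           O
ATOM      9  CB  ALA A   2      10.225   6.328  -0.597  1.00  0.00           C
END
"""


@pytest.fixture
def two_residue_pdb(tmp_path: Path) -> Path:
    path = tmp_path / "dipeptide.pdb"
    path.write_text(TWO_RESIDUE_PDB)
    return path


@pytest.fixture
def ideal_helix() -> hp.Structure:
    return hp.build_backbone(hp.ideal_helix_profile(15), structure_id="ideal")


@pytest.fixture
def kinked_helix() -> hp.Structure:
    return hp.build_backbone(hp.kinked_helix_profile(15), structure_id="kinked")


@pytest.fixture
def ideal_segment(ideal_helix):
    return extract_backbone(ideal_helix, WINDOW, reference_positions=WINDOW)


@pytest.fixture
def kinked_segment(kinked_helix):
    return extract_backbone(kinked_helix, WINDOW, reference_positions=WINDOW)


@pytest.fixture
def identity_map() -> hp.ResidueMap:
    return hp.ResidueMap(
        target_id="ideal",
        window=[(p, p) for p in WINDOW],
        anchors={65: 65, 66: 66, 67: 67},
    )


@pytest.fixture(scope="session")
def small_cohort() -> hp.Cohort:
    return hp.generate_cohort(
        hp.CohortSpec(n_can_form=5, n_cannot_form=5, noise_sd=0.1, seed=11)
    )
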