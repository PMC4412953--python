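import numpy as np
import pytest

from tazstruct import (
    build_bundle,
    build_helix,
    build_pocket_construct,
    compute_sasa,
    packaged_fixtures,
    relative_accessibility,
)
from tazstruct.core_io import AtomRecord, ResidueView, Structure


@pytest.fixture(scope="session")
def fixtures():
    return packaged_fixtures()


@pytest.fixture(scope="session")
def helix():
    return build_helix("LKRAHSGWYV")


@pytest.fixture(scope="session")
def helix_profile(helix):
    return relative_accessibility(helix, compute_sasa(helix))


@pytest.fixture(scope="session")
def bundle():
    return build_bundle()


@pytest.fixture(scope="session")
def pocket_constructs():
    return {kind: build_pocket_construct(kind) for kind in ("cavity", "cup", "tube")}


def single_atom_structure(element="C", coord=(0.0, 0.0, 0.0)):
    return Structure(
        id="one",
        residues=[
            ResidueView("A", 1, "A", [AtomRecord("CA", element, np.array(coord))])
        ],
    )


def atom_pair_structure(separation, element="C"):
    return Structure(
        id="pair",
        residues=[
            ResidueView("A", 1, "A", [AtomRecord("C1", element, np.zeros(3))]),
            ResidueView(
                "A", 2, "A",
                [AtomRecord("C1", element, np.array([separation, 0.0, 0.0]))],
            ),
        ],
    )


def rigid_transform(structure, rotation, translation):
    residues = [
        ResidueView(
            r.chain_id, r.number, r.aa,
            [AtomRecord(a.name, a.element, rotation @ a.coord + translation)
             for a in r.atoms],
            icode=r.icode, name=r.name,
        )
        for r in structure.residues
    ]
    return Structure(id=structure.id + "_moved", residues=residues)
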