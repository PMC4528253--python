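"""Shared test fixtures: tiny hand-checkable families and structures."""

import numpy as np
import pytest

from ptmhotspots.catalog import PTMRecord
from ptmhotspots.msa import FamilyAlignment
from ptmhotspots.structure import Atom, Chain, Residue


@pytest.fixture
def toy_alignment():
    """Four members, 8 columns, one gap each in members c and d.

    Columns (1-based):        12345678
        a  ASKDEFGH
        b  ASKDEYGH
        c  AS-DEFGH
        d  ATKDE-GH
    """
    return FamilyAlignment.from_members(
        [
            ("a", "ASKDEFGH"),
            ("b", "ASKDEYGH"),
            ("c", "AS-DEFGH"),
            ("d", "ATKDE-GH"),
        ],
        family_id="toy",
    )


@pytest.fixture
def toy_records():
    """Three phospho observations mapping to column 2, one ubiquitination to column 3."""
    return [
        PTMRecord("a", 2, "S", "phosphorylation"),
        PTMRecord("b", 2, "S", "phosphorylation", known_function=True),
        PTMRecord("c", 2, "S", "phosphorylation"),
        PTMRecord("a", 3, "K", "ubiquitination"),
    ]


def make_chain(positions, chain_id="A", element="C", resname="ALA", start_seq_id=1):
    """One single-atom residue per coordinate; handy for geometric oracles."""
    residues = [
        Residue(
            resname,
            start_seq_id + i,
            "",
            [Atom("CA", element, np.asarray(pos, float), 1.70)],
        )
        for i, pos in enumerate(positions)
    ]
    return Chain(chain_id, residues)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
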