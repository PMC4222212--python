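"""Shared fixtures: synthetic diverged panels and center points.

Session-scoped so the expensive center-point synthesis runs once.  Panel
conditions mirror the method's study setting: 59 biallelic loci, moderately
diverged wild/farm groups (Balding-Nichols F = 0.3), 100-individual center
points; "strong divergence" suites use F = 0.8.
"""

from __future__ import annotations

import numpy as np
import pytest

import introquant as iq


@pytest.fixture(scope="session")
def panel():
    """Default diverged panel (F=0.3, L=59, 100 wild + 100 farm) + true freqs."""
    matrix, freqs = iq.simulate_reference_populations(
        iq.SyntheticPanelSpec(seed=7)
    )
    return matrix, freqs


@pytest.fixture(scope="session")
def strong_panel():
    """Strongly diverged panel (F=0.8, L=59) + true freqs."""
    matrix, freqs = iq.simulate_reference_populations(
        iq.SyntheticPanelSpec(fst=0.8, seed=21)
    )
    return matrix, freqs


def _centerpoints(matrix):
    wcp = iq.synthesize_centerpoint(
        matrix.select_populations(["wild"]), "wild", 100, seed=1
    )
    fcp = iq.synthesize_centerpoint(
        matrix.select_populations(["farm"]), "farm", 100, seed=2
    )
    return wcp, fcp


@pytest.fixture(scope="session")
def centerpoints(panel):
    return _centerpoints(panel[0])


@pytest.fixture(scope="session")
def strong_centerpoints(strong_panel):
    return _centerpoints(strong_panel[0])


@pytest.fixture(scope="session")
def true_freqs(panel):
    matrix, freqs = panel
    L = matrix.n_loci
    wf = iq.AlleleFrequencies(matrix.locus_ids, freqs["wild"], np.full(L, 200))
    ff = iq.AlleleFrequencies(matrix.locus_ids, freqs["farm"], np.full(L, 200))
    return wf, ff


@pytest.fixture(scope="session")
def strong_true_freqs(strong_panel):
    matrix, freqs = strong_panel
    L = matrix.n_loci
    wf = iq.AlleleFrequencies(matrix.locus_ids, freqs["wild"], np.full(L, 200))
    ff = iq.AlleleFrequencies(matrix.locus_ids, freqs["farm"], np.full(L, 200))
    return wf, ff


@pytest.fixture()
def diagnostic_panel():
    """Fully diagnostic 10-locus pools: wild fixed for A, farm fixed for B."""
    L = 10
    loci = [f"locus_{i + 1}" for i in range(L)]
    wild = iq.GenotypeMatrix(
        [f"w{i}" for i in range(6)], ["wild"] * 6, loci, np.full((6, L), 2)
    )
    farm = iq.GenotypeMatrix(
        [f"f{i}" for i in range(6)], ["farm"] * 6, loci, np.full((6, L), 0)
    )
    return wild, farm
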