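"""Shared fixtures: textbook pedigrees and a small simulated AIL."""

import numpy as np
import pytest

from pedqtl import SimulationSpec, simulate_ail, validate_pedigree


@pytest.fixture
def trio_ped():
    """Two unrelated founders and one offspring."""
    return validate_pedigree([("A", 0, 0, "M"), ("B", 0, 0, "F"), ("C", "A", "B")])


@pytest.fixture
def fullsib_ped():
    """Founder pair with two full-sib offspring."""
    return validate_pedigree(
        [("A", 0, 0, "M"), ("B", 0, 0, "F"), ("C", "A", "B", "M"), ("D", "A", "B", "F")]
    )


@pytest.fixture
def sibmating_ped():
    """Full-sib mating: E is inbred with f = 1/4."""
    return validate_pedigree(
        [("A", 0, 0), ("B", 0, 0), ("C", "A", "B", "M"), ("D", "A", "B", "F"),
         ("E", "C", "D")]
    )


@pytest.fixture
def halfsib_ped():
    """Half-sib mating: E is inbred with f = 1/8."""
    return validate_pedigree(
        [("A", 0, 0, "M"), ("B", 0, 0, "F"), ("X", 0, 0, "F"),
         ("C", "A", "B", "M"), ("D", "A", "X", "F"), ("E", "C", "D")]
    )


@pytest.fixture
def cousin_ped():
    """First cousins C1, C2 and their offspring K (f = 1/16)."""
    return validate_pedigree(
        [("A", 0, 0, "M"), ("B", 0, 0, "F"), ("P", 0, 0, "F"), ("Q", 0, 0, "F"),
         ("S1", "A", "B", "M"), ("S2", "A", "B", "M"),
         ("C1", "S1", "P", "M"), ("C2", "S2", "Q", "F"), ("K", "C1", "C2")]
    )


def random_pedigree(rng, n_founders=None, n_nonfounders=None):
    """Random (possibly inbred) pedigree with sexed parent pools, small
    enough for the 4^m enumeration oracle."""
    nf = int(n_founders if n_founders is not None else rng.integers(2, 5))
    m = int(n_nonfounders if n_nonfounders is not None else rng.integers(2, 7))
    recs = []
    males, females = [], []
    for k in range(nf):
        sex = "M" if k % 2 == 0 else "F"
        recs.append((f"F{k}", 0, 0, sex))
        (males if sex == "M" else females).append(f"F{k}")
    if not males or not females:
        females.append("F_extra")
        recs.append(("F_extra", 0, 0, "F"))
    for k in range(m):
        s = males[rng.integers(len(males))]
        d = females[rng.integers(len(females))]
        sex = "M" if k % 2 == 0 else "F"
        recs.append((f"N{k}", s, d, sex))
        (males if sex == "M" else females).append(f"N{k}")
    return validate_pedigree(recs)


@pytest.fixture(scope="session")
def small_ail():
    """4-generation AIL, 120 per generation, 3 x 20 markers, one QTL."""
    spec = SimulationSpec(
        n_generations=4, n_per_generation=120, chromosomes=3,
        markers_per_chromosome=20, chrom_length_cM=100.0,
        qtl=[("c1m10", 0.8, 0.0)], var_a=1.0, var_d=0.5, var_e=1.0, seed=3,
    )
    ped, gmap, geno = simulate_ail(spec)
    last = [ped.ids[i] for i in range(ped.n) if ped.generation[i] == spec.n_generations - 1]
    return spec, ped, gmap, geno, last


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
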