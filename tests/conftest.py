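import itertools

import numpy as np
import pytest

import disorderkit as dk
from disorderkit.structure_io import frac_to_cart


@pytest.fixture(scope="session")
def propionamide():
    """The disordered propionamide-like fixture (two H-disorder parts)."""
    return dk.make_fixture(dk.FixtureSpec(template="propionamide-P21c",
                                          disorder_mode="two-part", seed=7))


@pytest.fixture(scope="session")
def propionamide_archetypes(propionamide):
    return dk.split_archetypes(propionamide)


@pytest.fixture(scope="session")
def monatomic():
    return dk.make_fixture(dk.FixtureSpec(template="monatomic-P1", seed=0))


def brute_force_cluster_geoms(structure, cutoff, trange=3):
    """Independent oracle: expand every operator x translation in a fixed
    wide range, filter whole molecules by the any-atom rule, and return
    the set of rounded environment-molecule geometries.

    Assumes the ASU molecules are stored contiguously (no periodic
    wrapping), which holds for every generated fixture.
    """
    cell = structure.cell
    frac = structure.frac_coords
    cart = frac_to_cart(cell, frac)
    elements = structure.elements
    graph = dk.perceive_bonds(elements, cart)
    comps = [c.sorted_atoms() for c in dk.molecule_components(graph)]
    geoms = set()
    rng = range(-trange, trange + 1)
    for op_idx, op in enumerate(structure.operations):
        base = op.apply(frac)
        for t in itertools.product(rng, rng, rng):
            if op_idx == 0 and t == (0, 0, 0):
                continue
            img = frac_to_cart(cell, base + np.array(t, dtype=float))
            for idx in comps:
                pts = img[idx]
                d = np.linalg.norm(pts[:, None, :] - cart[None, :, :],
                                   axis=-1)
                if d.min() < 1e-6 or d.min() > cutoff:
                    continue
                geoms.add(tuple(sorted(
                    (elements[i],) + tuple(np.round(p, 4))
                    for i, p in zip(idx, pts))))
    return geoms


def cluster_geoms(cluster):
    """Rounded geometry set of a built cluster, for oracle comparison."""
    return {tuple(sorted((el,) + tuple(np.round(p, 4))
                         for el, p in zip(img.elements, img.positions)))
            for img in cluster.environment}
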