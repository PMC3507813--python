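import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from ramaquery import (
    BackboneSpec,
    ElementSet,
    ResidueConformation,
    StructuralElement,
    build_backbone,
    extract_nmers,
)


def make_element(
    angles,
    sequence=None,
    source="SYN",
    chain="A",
    start="1",
):
    """Element from a list of (phi, psi) or (phi, psi, chi1) tuples; None allowed."""
    confs = []
    for a in angles:
        phi, psi = a[0], a[1]
        chi1 = a[2] if len(a) > 2 else None
        confs.append(ResidueConformation(phi=phi, psi=psi, chi1=chi1))
    seq = sequence or "A" * len(angles)
    return StructuralElement(
        source_id=source, chain_id=chain, start=start, sequence=seq,
        conformations=tuple(confs),
    )


def random_element_set(rng, n=4, count=50, chi_fraction=0.5, undefined_fraction=0.1):
    """Set of random elements with some undefined angles sprinkled in."""
    elements = []
    for i in range(count):
        angles = []
        for _ in range(n):
            phi = float(rng.uniform(-180, 180))
            psi = float(rng.uniform(-180, 180))
            chi1 = float(rng.uniform(-180, 180)) if rng.random() < chi_fraction else None
            if rng.random() < undefined_fraction:
                phi = None
            if rng.random() < undefined_fraction:
                psi = None
            angles.append((phi, psi, chi1))
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))
        elements.append(make_element(angles, sequence=seq, start=str(i + 1)))
    return ElementSet(n=n, elements=elements)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def helical_chain():
    """9-residue all-alanine alpha-helical fixture chain."""
    return build_backbone(BackboneSpec(angles=[(-57.0, -47.0)] * 9))


@pytest.fixture
def small_set(helical_chain):
    return extract_nmers([helical_chain], 4)
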