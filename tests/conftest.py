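import numpy as np
import pytest

from mitolineage import refio

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


@pytest.fixture(scope="session")
def ref():
    return refio.load_reference()


@pytest.fixture(scope="session")
def annotation(ref):
    return refio.load_annotation(ref)


@pytest.fixture(scope="session")
def toy_tree():
    from mitolineage import haplotree
    return haplotree.load_toy_haplotree()


def make_profile(ref, sample_id, labels):
    """Build a VariantProfile from canonical labels."""
    return refio.VariantProfile(
        sample_id=sample_id,
        variants=tuple(refio.parse_variant_label(l, ref) for l in labels))


def random_canonical_variants(ref, rng, n_min=1, n_max=20,
                              allow_indels=True) -> list:
    """Random variant set already in canonical (leftmost-normalized) form.

    Indels are placed only where they cannot shift left, and variant
    positions keep a 4-bp clearance so adjacent-indel ambiguity cannot
    arise; substitutions are unrestricted.
    """
    variants = []
    used: set[int] = set()
    target = int(rng.integers(n_min, n_max + 1))
    attempts = 0
    while len(variants) < target and attempts < 500:
        attempts += 1
        pos = int(rng.integers(2, len(ref) - 1))
        if any(abs(pos - u) < 4 for u in used):
            continue
        base = ref.base(pos)
        r = rng.random()
        if r < 0.6 or not allow_indels:
            if rng.random() < 0.3:
                alts = [b for b in "ACGT"
                        if b != base and b != _TRANSITION[base]]
                v = refio.Variant(position=pos, kind="transversion",
                                  derived_state=alts[int(rng.integers(2))])
            else:
                v = refio.Variant(position=pos, kind="transition",
                                  derived_state=_TRANSITION[base])
        elif r < 0.8:
            if ref.base(pos - 1) == base:
                continue  # left-shiftable deletion
            v = refio.Variant(position=pos, kind="deletion")
        else:
            alts = [b for b in "ACGT" if b != base]
            v = refio.Variant(position=pos, insert_index=1, kind="insertion",
                              derived_state=alts[int(rng.integers(3))])
        used.add(pos)
        variants.append(v)
    return variants
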