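"""Shared fixtures and fragment-building helpers."""

from __future__ import annotations

import numpy as np
import pytest

from linkphase.fragio import AlleleCall, Fragment


def make_fragment(
    calls,
    id="f",
    origin="molecule",
    barcode="BX",
    ordinal=1,
):
    """Build a fragment from (index, allele[, quality]) tuples."""
    acs = tuple(
        AlleleCall(c[0], c[1], c[2] if len(c) > 2 else 30) for c in calls
    )
    if origin == "read":
        return Fragment(id=id, origin="read", calls=acs, barcode=barcode)
    if origin == "barcode":
        return Fragment(id=id, origin="barcode", calls=acs, barcode=barcode)
    return Fragment(
        id=id, origin="molecule", calls=acs, barcode=barcode,
        molecule_ordinal=ordinal,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_fragment(rng, id, n_sites=50, max_calls=8, origin="molecule"):
    n = int(rng.integers(2, max_calls + 1))
    idx = np.sort(rng.choice(np.arange(1, n_sites + 1), size=n, replace=False))
    calls = [
        (int(i), int(rng.integers(0, 2)), int(rng.integers(10, 60)))
        for i in idx
    ]
    return make_fragment(calls, id=id, origin=origin, barcode=f"B{id}")
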