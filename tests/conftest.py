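"""Shared fixtures.

Everything is generated programmatically from the model library; the
heavier record sets are session-scoped so several tests can share one
sweep.
"""

from __future__ import annotations

import pytest

import motif_ident as mi


@pytest.fixture(scope="session")
def m2b7():
    """Basic motif 2, case B7 — the worked flow-augmentation example."""
    return mi.build_model("basic", 2, "B7")


@pytest.fixture(scope="session")
def m3b8():
    """Basic motif 3, case B8 — the worked unidentifiability example."""
    return mi.build_model("basic", 3, "B8")


@pytest.fixture(scope="session")
def m3b7():
    return mi.build_model("basic", 3, "B7")


@pytest.fixture(scope="session")
def toys():
    decay, scaled, chain = mi.toy_models()
    return {"decay": decay, "scaled": scaled, "chain": chain}


@pytest.fixture(scope="session")
def all_models():
    return mi.enumerate_models()


@pytest.fixture(scope="session")
def m3b8_full_records(m3b8):
    """Exact-mode assessment of all 28 measurement combos of motif 3 B8."""
    return mi.run_sweep(families=["basic"], motifs=[3], cases=["B8"],
                        methods=(2,), mode="symbolic", seed=11)


@pytest.fixture(scope="session")
def comparable_case_records():
    """Numeric-mode sweep of the non-always-insufficient combos for the
    basic cases with first-order controller degradation (B2/B5/B8/B11),
    all 8 motifs — 336 instances, 10 draws each."""
    return mi.run_sweep(
        families=["basic"], cases=["B2", "B5", "B8", "B11"],
        categories=["case_and_motif_dependent", "always_sufficient"],
        methods=(2,), mode="numeric", seed=1,
    )
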