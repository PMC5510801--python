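"""Shared fixtures: default parameters, contexts, and cached steady states.

Steady-state solves are cheap (tens of milliseconds) but appear in many
tests, so the wild-type reference and the common mutant bundles are cached
at session scope.  Everything is deterministic; no fixture touches disk.
"""

import pytest

import wntapc as w


@pytest.fixture(scope="session")
def base():
    return w.KineticParameters()


@pytest.fixture(scope="session")
def ctx(base):
    return w.standard_context()


@pytest.fixture(scope="session")
def wt_ref(base, ctx):
    """Untreated wild-type steady state under the standard 5 nM Wnt context."""
    ref = w.wt_reference(base, ctx)
    assert ref.converged
    return ref


@pytest.fixture(scope="session")
def bundle_for(base):
    cache = {}

    def get(genotype: str) -> w.ParameterBundle:
        if genotype not in cache:
            cache[genotype] = w.build_parameters(w.Genotype.from_string(genotype), base)
        return cache[genotype]

    return get


@pytest.fixture(scope="session")
def tcf_of(base, ctx, wt_ref, bundle_for):
    cache = {}

    def get(genotype: str) -> float:
        if genotype not in cache:
            cache[genotype], _ = w.relative_tcf(bundle_for(genotype), ctx, reference=wt_ref)
        return cache[genotype]

    return get
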