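import numpy as np
import pandas as pd
import pytest

import memclinic as mc


@pytest.fixture(scope="session")
def spec():
    return mc.build_published_group_spec()


@pytest.fixture(scope="session")
def risk_cohort(spec):
    """Small labelled risk cohort shared by classifier and pipeline tests."""
    return mc.generate_cohort(spec, {"LOW_RISK": 120, "HIGH_RISK": 120}, seed=7)


@pytest.fixture(scope="session")
def reference_cohort(spec):
    return mc.generate_cohort(spec, {"LOW_RISK": 150}, seed=11)


@pytest.fixture(scope="session")
def norms(reference_cohort):
    return mc.derive_norms_from_reference_cohort(reference_cohort)


def make_deficit_profile(n_cog=0, n_func=0, memory=False, sig_func=None,
                         sig_cog=None, domains=(), language_subtype="logopenic",
                         behavioral=False):
    """Hand-built deficit profile for decision-rule tests."""
    domain_impaired = {d: False for d in mc.norms.COGNITIVE_DOMAINS}
    for d in domains:
        domain_impaired[d] = True
    if memory:
        domain_impaired["memory"] = True
    return mc.DeficitProfile(
        impaired={}, unassessed=(),
        domain_impaired=domain_impaired,
        memory_impaired=domain_impaired["memory"],
        n_cognitive_impairments=n_cog,
        n_functional_impairments=n_func,
        significant_functional_impairment=(n_func >= 3 if sig_func is None else sig_func),
        significant_cognitive_impairment=(n_cog >= 3 if sig_cog is None else sig_cog),
        language_subtype=language_subtype, behavioral=behavioral)


def make_atrophy_profile(medial=False, parieto=False, dominant=False, fronto=False):
    return mc.AtrophyProfile(
        atrophic={}, unassessed=(),
        medial_temporal_atrophy=medial,
        parieto_occipital_atrophy=parieto,
        dominant_hemisphere_focal_atrophy=dominant,
        frontotemporal_atrophy=fronto,
        mri_inconsistent=not (medial or parieto or dominant or fronto))
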