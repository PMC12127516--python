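"""Clinical syndrome profiling, causal hypothesis, and risk-based reclassification.

Subjects with cognitive impairment are mapped to a clinical syndrome by the
first matching rule in a fixed order (typical amnestic AD; posterior cortical
atrophy; the primary-progressive-aphasia variants; behavioral/dysexecutive
frontotemporal presentation; no clear hypothesis).  The syndrome then fixes
the causal hypothesis (suspected AD vs suspected FTLD vs no clear
hypothesis), after which the predicted 24-month conversion risk reclassifies
high-risk bvFTD/fvAD and high-risk unclear cases toward suspected AD — the
published flow only ever moves labels in that direction.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .norms import AtrophyProfile, DeficitProfile
from .schema import AdjudicationError, ProfilingNotApplicable

__all__ = ["Syndrome", "Hypothesis", "HypothesisLabel", "RiskClass",
           "profile_syndrome", "causal_hypothesis", "profile_cohort"]


class Syndrome:
    TYPICAL_AD = "TYPICAL_AD"
    PCA = "PCA"
    LV_PPA = "LV_PPA"
    SV_PPA = "SV_PPA"
    NFV_PPA = "NFV_PPA"
    BVFTD_FVAD = "BVFTD_FVAD"
    NO_CLEAR = "NO_CLEAR"
    ALL = (TYPICAL_AD, PCA, LV_PPA, SV_PPA, NFV_PPA, BVFTD_FVAD, NO_CLEAR)


class Hypothesis:
    SUSPECTED_AD = "SUSPECTED_AD"
    SUSPECTED_FTLD = "SUSPECTED_FTLD"
    NO_CLEAR = "NO_CLEAR"


class RiskClass:
    HR = "HR"
    LR = "LR"


_PPA_BY_SUBTYPE = {"logopenic": Syndrome.LV_PPA, "semantic": Syndrome.SV_PPA,
                   "agrammatic": Syndrome.NFV_PPA, "nonfluent": Syndrome.NFV_PPA}

_BASE_HYPOTHESIS = {
    Syndrome.TYPICAL_AD: Hypothesis.SUSPECTED_AD,
    Syndrome.PCA: Hypothesis.SUSPECTED_AD,
    Syndrome.LV_PPA: Hypothesis.SUSPECTED_AD,
    Syndrome.SV_PPA: Hypothesis.SUSPECTED_FTLD,
    Syndrome.NFV_PPA: Hypothesis.SUSPECTED_FTLD,
    Syndrome.BVFTD_FVAD: Hypothesis.SUSPECTED_FTLD,
    Syndrome.NO_CLEAR: Hypothesis.NO_CLEAR,
}

# syndromes for which the hypothesis depends on the predicted conversion risk
_RISK_DEPENDENT = (Syndrome.BVFTD_FVAD, Syndrome.NO_CLEAR)


@dataclass(frozen=True)
class HypothesisLabel:
    value: str
    reclassified_by_risk: bool


def profile_syndrome(deficits: DeficitProfile, atrophy: AtrophyProfile) -> str:
    """First matching syndrome rule, in the listing order a→g."""
    any_cognitive = deficits.n_cognitive_impairments >= 1 or deficits.memory_impaired
    if not any_cognitive:
        raise ProfilingNotApplicable("no cognitive impairment; profiling not applicable")
    if deficits.memory_impaired and atrophy.medial_temporal_atrophy:
        return Syndrome.TYPICAL_AD
    if deficits.domain_impaired.get("visuoconstructive") and atrophy.parieto_occipital_atrophy:
        return Syndrome.PCA
    if deficits.domain_impaired.get("language") and atrophy.dominant_hemisphere_focal_atrophy:
        try:
            return _PPA_BY_SUBTYPE[deficits.language_subtype]
        except KeyError:
            raise AdjudicationError(
                f"unknown language subtype {deficits.language_subtype!r}") from None
    if (deficits.behavioral or deficits.domain_impaired.get("attention_executive")) \
            and atrophy.frontotemporal_atrophy:
        return Syndrome.BVFTD_FVAD
    # impairment with negative or inconsistent MRI, or matching no rule
    return Syndrome.NO_CLEAR


def causal_hypothesis(syndrome: str, risk: str | None = None) -> HypothesisLabel:
    """Base syndrome→hypothesis map, then high-risk reclassification.

    Risk is required for the bvFTD/fvAD and no-clear-hypothesis syndromes;
    a high conversion risk moves either to suspected AD.
    """
    if syndrome not in _BASE_HYPOTHESIS:
        raise AdjudicationError(f"unknown syndrome {syndrome!r}")
    base = _BASE_HYPOTHESIS[syndrome]
    if syndrome in _RISK_DEPENDENT:
        if risk not in (RiskClass.HR, RiskClass.LR):
            raise AdjudicationError(f"risk class required for syndrome {syndrome}")
        if risk == RiskClass.HR:
            return HypothesisLabel(Hypothesis.SUSPECTED_AD, True)
    return HypothesisLabel(base, False)


def profile_cohort(profiles: list[tuple[str, DeficitProfile, AtrophyProfile]],
                   risk_assignments: dict[str, str] | None = None,
                   ) -> tuple[pd.DataFrame, dict]:
    """Profile a cohort and emit the classification-flow counts.

    ``profiles`` is a list of (subject_id, deficits, atrophy); risk classes
    are looked up per subject where the rules need them.  Per-subject errors
    (profiling not applicable, missing risk) are recorded, not fatal.
    Returns the per-subject table and a flow-count summary: syndrome counts,
    hypothesis counts before and after risk reclassification, and the
    HR/LR splits of the risk-dependent syndromes.
    """
    risk_assignments = risk_assignments or {}
    rows = []
    for subject_id, deficits, atrophy in profiles:
        rec = {"subject_id": subject_id, "syndrome": None, "hypothesis_pre": None,
               "hypothesis": None, "reclassified": False, "error": ""}
        try:
            syndrome = profile_syndrome(deficits, atrophy)
            rec["syndrome"] = syndrome
            rec["hypothesis_pre"] = _BASE_HYPOTHESIS[syndrome]
            label = causal_hypothesis(syndrome, risk_assignments.get(subject_id))
            rec["hypothesis"] = label.value
            rec["reclassified"] = label.reclassified_by_risk
        except (ProfilingNotApplicable, AdjudicationError) as exc:
            rec["error"] = str(exc)
        rows.append(rec)
    table = pd.DataFrame(rows, columns=["subject_id", "syndrome", "hypothesis_pre",
                                        "hypothesis", "reclassified", "error"])
    ok = table[table["error"] == ""]
    flow = {
        "syndrome_counts": ok["syndrome"].value_counts().to_dict(),
        "hypothesis_counts_pre": ok["hypothesis_pre"].value_counts().to_dict(),
        "hypothesis_counts_post": ok["hypothesis"].value_counts().to_dict(),
        "n_reclassified": int(ok["reclassified"].sum()),
        "n_errors": int((table["error"] != "").sum()),
        "risk_splits": {
            s: {r: int(((ok["syndrome"] == s) &
                        (ok["subject_id"].map(risk_assignments) == r)).sum())
                for r in (RiskClass.HR, RiskClass.LR)}
            for s in _RISK_DEPENDENT},
    }
    # flow conservation is structural: every non-error subject appears once
    assert len(ok) == sum(flow["hypothesis_counts_post"].values())
    return table, flow
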