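"""Three-class workflow staging from the deficit profile and MMSE.

The three literal staging rules (moderate-to-severe dementia; MCI/mild
dementia; healthy/subjective-complaint/worried-well) neither partition nor
cover the input space — for example one cognitive impairment with MMSE 25
matches none of them.  The engine therefore evaluates the rules in severity
order and routes uncovered cases through an explicit fallback (any cognitive
impairment → MCI_MD, else HS_SCI_WW), flagging both the matched rule and
whether the fallback fired, so downstream consumers can audit gap cases.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .norms import DeficitProfile
from .schema import StagingError, is_missing

__all__ = ["StageLabel", "stage_subject", "stage_cohort",
           "MSD", "MCI_MD", "HS_SCI_WW"]

MSD = "MSD"
MCI_MD = "MCI_MD"
HS_SCI_WW = "HS_SCI_WW"
STAGES = (MSD, MCI_MD, HS_SCI_WW)


@dataclass(frozen=True)
class StageLabel:
    value: str
    matched_rule: str
    fallback_used: bool


def stage_subject(profile: DeficitProfile, mmse) -> StageLabel:
    """Assign exactly one stage; precedence MSD → MCI_MD → HS_SCI_WW.

    Literal rules: MSD iff (≥3 functional or ≥3 cognitive impairments) and
    MMSE ≤ 26; MCI_MD iff ≥1 cognitive impairment, no significant functional
    impairment and MMSE > 26; HS_SCI_WW iff no memory impairment, no
    significant cognitive or functional impairment and MMSE ≥ 24.
    """
    if is_missing(mmse):
        raise StagingError("stage undefined without MMSE")
    mmse = float(mmse)
    if not 0 <= mmse <= 30:
        raise StagingError(f"MMSE {mmse} outside 0-30")
    if (profile.n_functional_impairments >= 3 or
            profile.n_cognitive_impairments >= 3) and mmse <= 26:
        return StageLabel(MSD, "msd_literal", False)
    if (profile.n_cognitive_impairments >= 1 and
            not profile.significant_functional_impairment and mmse > 26):
        return StageLabel(MCI_MD, "mci_md_literal", False)
    if (not profile.memory_impaired and
            not profile.significant_cognitive_impairment and
            not profile.significant_functional_impairment and mmse >= 24):
        return StageLabel(HS_SCI_WW, "hs_sci_ww_literal", False)
    if profile.n_cognitive_impairments >= 1:
        return StageLabel(MCI_MD, "fallback_cognitive", True)
    return StageLabel(HS_SCI_WW, "fallback_no_cognitive", True)


def stage_cohort(flags: pd.DataFrame, mmse: pd.Series) -> pd.DataFrame:
    """Stage every subject in a flag table (columns as from ``flag_cohort``)."""
    from .norms import DeficitProfile as DP
    rows = []
    for (_, f), m in zip(flags.iterrows(), mmse):
        profile = DP(
            impaired={}, unassessed=(),
            domain_impaired={k.removeprefix("domain_"): bool(f[k])
                             for k in flags.columns if k.startswith("domain_")},
            memory_impaired=bool(f["memory_impaired"]),
            n_cognitive_impairments=int(f["n_cognitive_impairments"]),
            n_functional_impairments=int(f["n_functional_impairments"]),
            significant_functional_impairment=bool(f["significant_functional_impairment"]),
            significant_cognitive_impairment=bool(f["significant_cognitive_impairment"]),
        )
        label = stage_subject(profile, m)
        rows.append({"subject_id": f["subject_id"], "stage": label.value,
                     "matched_rule": label.matched_rule,
                     "fallback_used": label.fallback_used})
    return pd.DataFrame(rows)
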