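"""Normative references and the deficit/atrophy flags the decision rules consume.

Raw scores are compared against per-test cutoffs (direction-aware) and raw
regional volumes against 10th-percentile norms.  The published workflow cites
external normative references without printing the numbers, so the table here
is fully configurable and can be derived empirically from a reference cohort
(cognitive cutoffs at the 5th percentile in the impaired direction, volumetric
norms at the 10th percentile, linear-interpolation quantiles).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .schema import (FAQ_ITEMS, ConfigurationError, ValidationError, is_missing)

__all__ = ["CognitiveNorm", "NormativeTable", "DeficitProfile", "AtrophyProfile",
           "flag_cognitive_deficits", "flag_regional_atrophy",
           "derive_norms_from_reference_cohort", "flag_cohort",
           "DEFAULT_TEST_BATTERY", "COGNITIVE_DOMAINS"]

IMPAIRED_IF_BELOW = "impaired_if_below"
IMPAIRED_IF_ABOVE = "impaired_if_above"

COGNITIVE_DOMAINS = ("memory", "attention_executive", "visuoconstructive",
                     "language", "global")

# test -> (direction, domain); one representative score per instrument
DEFAULT_TEST_BATTERY: dict[str, tuple[str, str]] = {
    "avlt_trial5": (IMPAIRED_IF_BELOW, "memory"),
    "avlt_delayed": (IMPAIRED_IF_BELOW, "memory"),
    "avlt_recognition": (IMPAIRED_IF_BELOW, "memory"),
    "digit_span_fwd": (IMPAIRED_IF_BELOW, "attention_executive"),
    "digit_span_bwd": (IMPAIRED_IF_BELOW, "attention_executive"),
    "tmt_a_time": (IMPAIRED_IF_ABOVE, "attention_executive"),
    "tmt_b_time": (IMPAIRED_IF_ABOVE, "attention_executive"),
    "symbol_digit": (IMPAIRED_IF_BELOW, "attention_executive"),
    "clock_total": (IMPAIRED_IF_BELOW, "visuoconstructive"),
    "fluency_animals": (IMPAIRED_IF_BELOW, "language"),
    "fluency_vegetables": (IMPAIRED_IF_BELOW, "language"),
    "bnt_total": (IMPAIRED_IF_BELOW, "language"),
    "mmse": (IMPAIRED_IF_BELOW, "global"),
}

# regions whose total volumes feed the composite atrophy patterns, plus the
# lateralized language-relevant regions checked per hemisphere
ATROPHY_REGIONS = ("hippocampus", "parahippocampus", "mt_cortex",
                   "po_cortex", "precuneus", "ft_cortex")
LANGUAGE_REGIONS = ("mt_cortex", "ft_cortex")


@dataclass(frozen=True)
class CognitiveNorm:
    cutoff: float
    direction: str
    domain: str

    def __post_init__(self):
        if self.direction not in (IMPAIRED_IF_BELOW, IMPAIRED_IF_ABOVE):
            raise ValidationError(f"unknown direction {self.direction!r}")
        if self.domain not in COGNITIVE_DOMAINS:
            raise ValidationError(f"unknown domain {self.domain!r}")


@dataclass(frozen=True)
class NormativeTable:
    """Cutoffs per cognitive test, FAQ item threshold, volumetric percentiles."""

    cognitive: dict[str, CognitiveNorm]
    volumetric_p10: dict[str, float]  # keys like "hippocampus_total", "mt_cortex_lx"
    faq_item_threshold: int = 2

    def __post_init__(self):
        if not 0 <= self.faq_item_threshold <= 4:
            raise ValidationError("FAQ item threshold must be in 0..4")
        needed = [f"{r}_total" for r in ATROPHY_REGIONS] + \
                 [f"{r}_{h}" for r in LANGUAGE_REGIONS for h in ("rx", "lx")]
        missing = [k for k in needed if k not in self.volumetric_p10]
        if missing:
            raise ConfigurationError(f"volumetric norms missing {missing}")

    def to_yaml(self, path) -> None:
        doc = {
            "cognitive": {t: {"cutoff": float(n.cutoff), "direction": n.direction,
                              "domain": n.domain} for t, n in self.cognitive.items()},
            "volumetric_p10": {k: float(v) for k, v in self.volumetric_p10.items()},
            "faq_item_threshold": int(self.faq_item_threshold),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "NormativeTable":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        cog = {t: CognitiveNorm(**spec) for t, spec in doc["cognitive"].items()}
        return cls(cog, doc["volumetric_p10"], doc.get("faq_item_threshold", 2))


@dataclass(frozen=True)
class DeficitProfile:
    """Boolean deficit flags per test and domain, with impairment counts."""

    impaired: dict[str, bool]
    unassessed: tuple[str, ...]
    domain_impaired: dict[str, bool]
    memory_impaired: bool
    n_cognitive_impairments: int
    n_functional_impairments: int
    significant_functional_impairment: bool
    significant_cognitive_impairment: bool
    language_subtype: str = "logopenic"
    behavioral: bool = False

    def with_annotations(self, language_subtype: str | None = None,
                         behavioral: bool | None = None) -> "DeficitProfile":
        kw = {}
        if language_subtype is not None:
            kw["language_subtype"] = language_subtype
        if behavioral is not None:
            kw["behavioral"] = behavioral
        return replace(self, **kw)


@dataclass(frozen=True)
class AtrophyProfile:
    """Regional atrophy flags and the composite patterns the profiler uses."""

    atrophic: dict[str, bool]
    unassessed: tuple[str, ...]
    medial_temporal_atrophy: bool
    parieto_occipital_atrophy: bool
    dominant_hemisphere_focal_atrophy: bool
    frontotemporal_atrophy: bool
    mri_inconsistent: bool


def flag_cognitive_deficits(scores, norms: NormativeTable,
                            count_unit: str = "domain",
                            sig_cognitive_threshold: int = 3) -> DeficitProfile:
    """Compare scores against normative cutoffs and aggregate per domain.

    A missing score contributes "not impaired" and is recorded unassessed.
    A domain is impaired iff at least one of its tests is impaired.
    ``count_unit`` selects whether the cognitive impairment count tallies
    impaired domains (default) or impaired tests.  Significant functional
    impairment means any FAQ item at the maximum severity (4) or at least
    three items at/above the item threshold.
    """
    if count_unit not in ("domain", "test"):
        raise ValidationError("count_unit must be 'domain' or 'test'")
    for test in DEFAULT_TEST_BATTERY:
        if test not in norms.cognitive and not is_missing(_get(scores, test)):
            raise ConfigurationError(f"no normative cutoff for assessed test {test!r}")
    impaired: dict[str, bool] = {}
    unassessed: list[str] = []
    for test, norm in norms.cognitive.items():
        val = _get(scores, test)
        if is_missing(val):
            impaired[test] = False
            unassessed.append(test)
            continue
        if norm.direction == IMPAIRED_IF_BELOW:
            impaired[test] = val < norm.cutoff
        else:
            impaired[test] = val > norm.cutoff
    domain_impaired = {
        d: any(impaired[t] for t, n in norms.cognitive.items() if n.domain == d)
        for d in COGNITIVE_DOMAINS}
    if count_unit == "domain":
        n_cog = sum(domain_impaired.values())
    else:
        n_cog = sum(impaired.values())
    faq_vals = [_get(scores, item) for item in FAQ_ITEMS]
    n_func = sum(1 for v in faq_vals
                 if not is_missing(v) and v >= norms.faq_item_threshold)
    unassessed += [i for i, v in zip(FAQ_ITEMS, faq_vals) if is_missing(v)]
    sig_func = any(not is_missing(v) and v >= 4 for v in faq_vals) or n_func >= 3
    return DeficitProfile(
        impaired=impaired,
        unassessed=tuple(unassessed),
        domain_impaired=domain_impaired,
        memory_impaired=domain_impaired["memory"],
        n_cognitive_impairments=n_cog,
        n_functional_impairments=n_func,
        significant_functional_impairment=sig_func,
        significant_cognitive_impairment=n_cog >= sig_cognitive_threshold,
    )


def flag_regional_atrophy(volumes, norms: NormativeTable) -> AtrophyProfile:
    """Flag regions strictly below their 10th-percentile norm; derive patterns.

    Composite mapping: medial temporal = hippocampus, parahippocampus or
    medio-temporal cortex; parieto-occipital = parieto-occipital cortex or
    precuneus; frontotemporal = fronto-temporal cortex; dominant-hemisphere
    focal = a left (language-dominant) medio- or fronto-temporal volume
    atrophic with the homologous right volume not atrophic.  A missing volume
    is recorded unassessed and excluded from the composites.
    """
    atrophic: dict[str, bool] = {}
    unassessed: list[str] = []

    def check(key: str) -> bool:
        val = _get(volumes, key)
        if is_missing(val):
            unassessed.append(key)
            atrophic[key] = False
            return False
        flag = val < norms.volumetric_p10[key]  # strict: ties are not atrophic
        atrophic[key] = bool(flag)
        return atrophic[key]

    for region in ATROPHY_REGIONS:
        check(f"{region}_total")
    lateral = {f"{r}_{h}": check(f"{r}_{h}")
               for r in LANGUAGE_REGIONS for h in ("rx", "lx")}
    medial_temporal = any(atrophic[f"{r}_total"] for r in
                          ("hippocampus", "parahippocampus", "mt_cortex"))
    parieto_occipital = atrophic["po_cortex_total"] or atrophic["precuneus_total"]
    frontotemporal = atrophic["ft_cortex_total"]
    dominant_focal = any(lateral[f"{r}_lx"] and not lateral[f"{r}_rx"]
                         for r in LANGUAGE_REGIONS)
    return AtrophyProfile(
        atrophic=atrophic,
        unassessed=tuple(unassessed),
        medial_temporal_atrophy=medial_temporal,
        parieto_occipital_atrophy=parieto_occipital,
        dominant_hemisphere_focal_atrophy=dominant_focal,
        frontotemporal_atrophy=frontotemporal,
        mri_inconsistent=not (medial_temporal or parieto_occipital or
                              frontotemporal or dominant_focal),
    )


def derive_norms_from_reference_cohort(reference: pd.DataFrame,
                                       cognitive_percentile: float = 5.0,
                                       volumetric_percentile: float = 10.0,
                                       faq_item_threshold: int = 2,
                                       battery: dict[str, tuple[str, str]] | None = None,
                                       ) -> NormativeTable:
    """Empirical norms from a (healthy-leaning) reference cohort.

    Cognitive cutoffs sit at the 5th percentile of the reference in the
    impaired direction (95th for time-like scores where higher is worse);
    volumetric norms at the 10th percentile.  Linear-interpolation quantiles;
    deterministic.  Requires at least 50 reference subjects.
    """
    if len(reference) < 50:
        raise ValidationError("need >= 50 reference subjects to derive norms")
    battery = DEFAULT_TEST_BATTERY if battery is None else battery
    cognitive = {}
    for test, (direction, domain) in battery.items():
        vals = reference[test].dropna().to_numpy()
        if len(vals) == 0:
            raise ValidationError(f"reference has no values for {test}")
        q = cognitive_percentile if direction == IMPAIRED_IF_BELOW \
            else 100 - cognitive_percentile
        cognitive[test] = CognitiveNorm(float(np.percentile(vals, q)), direction, domain)
    volumetric = {}
    keys = [f"{r}_total" for r in ATROPHY_REGIONS] + \
           [f"{r}_{h}" for r in LANGUAGE_REGIONS for h in ("rx", "lx")]
    for key in keys:
        vals = reference[key].dropna().to_numpy()
        if len(vals) == 0:
            raise ValidationError(f"reference has no values for {key}")
        volumetric[key] = float(np.percentile(vals, volumetric_percentile))
    return NormativeTable(cognitive, volumetric, faq_item_threshold)


def flag_cohort(cohort: pd.DataFrame, norms: NormativeTable,
                **kwargs) -> pd.DataFrame:
    """Vectorized wrapper: one flag row per subject."""
    rows = []
    for _, subject in cohort.iterrows():
        d = flag_cognitive_deficits(subject, norms, **kwargs)
        a = flag_regional_atrophy(subject, norms)
        rows.append({
            "subject_id": subject["subject_id"],
            "memory_impaired": d.memory_impaired,
            **{f"domain_{k}": v for k, v in d.domain_impaired.items()},
            "n_cognitive_impairments": d.n_cognitive_impairments,
            "n_functional_impairments": d.n_functional_impairments,
            "significant_functional_impairment": d.significant_functional_impairment,
            "significant_cognitive_impairment": d.significant_cognitive_impairment,
            "medial_temporal_atrophy": a.medial_temporal_atrophy,
            "parieto_occipital_atrophy": a.parieto_occipital_atrophy,
            "dominant_hemisphere_focal_atrophy": a.dominant_hemisphere_focal_atrophy,
            "frontotemporal_atrophy": a.frontotemporal_atrophy,
            "mri_inconsistent": a.mri_inconsistent,
        })
    return pd.DataFrame(rows)


def _get(mapping, key):
    if isinstance(mapping, pd.Series):
        return mapping.get(key, float("nan"))
    if hasattr(mapping, "cognitive"):  # SubjectRecord
        if key in mapping.cognitive:
            return mapping.cognitive[key]
        return mapping.volumes.get(key, float("nan"))
    return mapping.get(key, float("nan"))
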