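"""Canonical cohort schema: leaf fields, per-subject typed views, and errors.

A cohort is a :class:`pandas.DataFrame` with one column per leaf field listed
here (plus the metadata columns).  Decision rules consume the light typed
views (:class:`CSFPanel`, :class:`PETStatus`, :class:`SubjectRecord`);
missing values are NaN / ``None`` and always propagate as "not assessable",
never as zero.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

SCHEMA_VERSION = "1"

# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------


class ConfigurationError(ValueError):
    """A rule or generator references something the configuration lacks."""


class ValidationError(ValueError):
    """Malformed or out-of-contract input data."""


class StagingError(ValueError):
    """Stage cannot be assigned (e.g. MMSE missing)."""


class AdjudicationError(ValueError):
    """Biological diagnosis or hypothesis cannot be resolved."""


class ProfilingNotApplicable(Exception):
    """Syndrome profiling requested for a subject with no cognitive impairment."""


# ---------------------------------------------------------------------------
# cognitive leaf fields
# ---------------------------------------------------------------------------

AVLT_TRIALS = [f"avlt_trial{i}" for i in range(1, 7)] + ["avlt_delayed", "avlt_recognition"]
CLOCK_ITEMS = ["clock_contour", "clock_number_order", "clock_numbers_present",
               "clock_hands", "clock_time_signed"]
FAQ_ITEMS = ["faq_finances", "faq_bills", "faq_buying", "faq_social_life",
             "faq_housekeeping", "faq_cooking", "faq_external_events",
             "faq_entertainment", "faq_memory", "faq_transports"]

COGNITIVE_FIELDS: list[str] = (
    ["mmse"]
    + [f for t in AVLT_TRIALS for f in (t, f"{t}_errors")]
    + ["digit_span_fwd", "digit_span_bwd"]
    + ["tmt_a_time", "tmt_a_committed_errors", "tmt_a_omission_errors",
       "tmt_b_time", "tmt_b_committed_errors", "tmt_b_omission_errors"]
    + CLOCK_ITEMS + ["clock_total"]
    + ["symbol_digit"]
    + ["fluency_animals", "fluency_animals_perseveration", "fluency_animals_intrusion",
       "fluency_vegetables", "fluency_vegetables_perseveration", "fluency_vegetables_intrusion"]
    + ["bnt_spontaneous", "bnt_semantic_cues", "bnt_after_semantic",
       "bnt_phonological_cues", "bnt_after_phonological", "bnt_total"]
    + FAQ_ITEMS + ["faq_total"]
)

# ---------------------------------------------------------------------------
# volumetric leaf fields
# ---------------------------------------------------------------------------

# hemispheric compartments carry a percent-over-TIV column besides rx/lx
COMPARTMENTS = ["whole_brain", "gray_matter", "white_matter"]
LATERALIZED_REGIONS = ["cerebellum", "insula", "cingulate_cortex", "hippocampus",
                       "parahippocampus", "amygdala", "ventral_striatum", "thalamus",
                       "precuneus", "ft_cortex", "mt_cortex", "po_cortex"]

VOLUMETRIC_FIELDS: list[str] = []
for _r in COMPARTMENTS:
    VOLUMETRIC_FIELDS += [f"{_r}_total", f"{_r}_perc_tiv", f"{_r}_rx", f"{_r}_lx", f"{_r}_asym"]
VOLUMETRIC_FIELDS += ["csf_volume_total", "csf_volume_perc_tiv", "tiv_total"]
for _r in LATERALIZED_REGIONS:
    VOLUMETRIC_FIELDS += [f"{_r}_total", f"{_r}_rx", f"{_r}_lx", f"{_r}_asym"]

CSF_FIELDS = ["csf_abeta42", "csf_t_tau", "csf_p_tau", "csf_ttau_abeta42_ratio"]

NUMERIC_FIELDS: list[str] = COGNITIVE_FIELDS + VOLUMETRIC_FIELDS + CSF_FIELDS

META_FIELDS = ["subject_id", "group", "clinician_stage_baseline", "diagnosis_24mo",
               "pet_assessed", "pet_positive_for"]

COHORT_COLUMNS: list[str] = META_FIELDS + NUMERIC_FIELDS

PET_PATTERNS = ("AD", "bvFTD", "nfvPPA", "svPPA")
DIAGNOSIS_24MO = ("HS", "ncMCI", "cMCI", "AD")


def is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x)) or (
        isinstance(x, str) and x == "")


# ---------------------------------------------------------------------------
# typed per-subject views
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CSFPanel:
    """First-line CSF panel in pg/mL; the t-tau/Aβ42 ratio is derived."""

    abeta42: float
    t_tau: float
    p_tau: float | None = None

    @property
    def ratio_ttau_abeta42(self) -> float:
        return self.t_tau / self.abeta42

    def __post_init__(self):
        if not (self.abeta42 > 0 and self.t_tau > 0):
            raise ValidationError("CSF concentrations must be positive")


@dataclass(frozen=True)
class PETStatus:
    """FDG-PET read: positivity per syndrome-specific hypometabolic pattern."""

    assessed: bool = False
    positive_for: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.assessed and self.positive_for:
            raise ValidationError("positive_for must be empty when PET not assessed")
        bad = set(self.positive_for) - set(PET_PATTERNS)
        if bad:
            raise ValidationError(f"unknown PET pattern(s): {sorted(bad)}")


@dataclass(frozen=True)
class SubjectRecord:
    """One participant's scores, volumes, CSF panel, PET status and labels."""

    subject_id: str
    cognitive: Mapping[str, float]
    volumes: Mapping[str, float]
    csf: CSFPanel | None
    pet: PETStatus
    clinician_stage_baseline: str | None = None
    diagnosis_24mo: str | None = None

    @classmethod
    def from_row(cls, row: pd.Series) -> "SubjectRecord":
        cog = {f: row.get(f, float("nan")) for f in COGNITIVE_FIELDS}
        vol = {f: row.get(f, float("nan")) for f in VOLUMETRIC_FIELDS}
        csf = None
        if not is_missing(row.get("csf_abeta42")) and not is_missing(row.get("csf_t_tau")):
            ptau = row.get("csf_p_tau")
            csf = CSFPanel(float(row["csf_abeta42"]), float(row["csf_t_tau"]),
                           None if is_missing(ptau) else float(ptau))
        assessed = bool(row.get("pet_assessed", False))
        pos = row.get("pet_positive_for", "")
        patterns = frozenset(p for p in str(pos).split("|") if p) if assessed else frozenset()
        pet = PETStatus(assessed=assessed, positive_for=patterns)
        stage = row.get("clinician_stage_baseline")
        dx = row.get("diagnosis_24mo")
        return cls(str(row["subject_id"]), cog, vol, csf, pet,
                   None if is_missing(stage) else str(stage),
                   None if is_missing(dx) else str(dx))
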