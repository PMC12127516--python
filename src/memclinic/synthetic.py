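"""Synthetic cohort generator parameterized by printed group distributions.

The packaged group-specification table holds, for each subject group
(MCI_MD, MSD, LOW_RISK, HIGH_RISK) and each leaf variable, the published
mean ± SD together with truncation bounds on the variable's valid range.
Subjects are drawn variable-by-variable from truncated Gaussians (marginal
independence within a group), with the structurally derived fields —
lateralized totals, asymmetry indices, percent-over-TIV, the clock and FAQ
sums, and the CSF t-tau/Aβ42 ratio — computed from their components so the
schema invariants hold by construction.  Binary 0/1 subscores are Bernoulli
with the published mean.

The real cohorts behind the published tables are access-restricted; this
generator emulates their group-conditional marginals so every downstream
decision stage is testable without a data download.
"""
from __future__ import annotations

import importlib.resources as ir
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import schema
from .schema import (COGNITIVE_FIELDS, COHORT_COLUMNS, COMPARTMENTS,
                     CLOCK_ITEMS, FAQ_ITEMS, LATERALIZED_REGIONS,
                     NUMERIC_FIELDS, ConfigurationError, ValidationError)
from .stats import group_compare, percent_difference

__all__ = ["GroupSpecTable", "build_published_group_spec", "generate_cohort",
           "summarize_cohort"]

STAGE_GROUPS = ("MCI_MD", "MSD", "HS_SCI_WW")
RISK_GROUPS = ("LOW_RISK", "HIGH_RISK")
_DISTRIBUTIONS = ("gaussian_truncated", "integer_truncated", "bernoulli", "derived")

# fields recomputed from components rather than sampled
DERIVED_FIELDS = frozenset(
    ["clock_total", "faq_total", "csf_ttau_abeta42_ratio"]
    + [f"{r}_total" for r in COMPARTMENTS + LATERALIZED_REGIONS]
    + [f"{r}_asym" for r in COMPARTMENTS + LATERALIZED_REGIONS]
    + [f"{r}_perc_tiv" for r in COMPARTMENTS + ["csf_volume"]]
)


@dataclass(frozen=True)
class GroupSpecTable:
    """Per-(group, variable) parameterization of the generator."""

    table: pd.DataFrame  # columns: group, variable, mean, sd, lower, upper, distribution

    def __post_init__(self):
        t = self.table
        required = {"group", "variable", "mean", "sd", "lower", "upper", "distribution"}
        if not required <= set(t.columns):
            raise ValidationError(f"spec table missing columns {required - set(t.columns)}")
        if (t["sd"] < 0).any():
            raise ValidationError("negative SD in group spec")
        bad = t[(t["lower"] > t["mean"]) | (t["mean"] > t["upper"])]
        if len(bad):
            raise ValidationError(
                f"mean outside truncation bounds for {bad['variable'].tolist()[:5]}")
        unknown = set(t["distribution"]) - set(_DISTRIBUTIONS)
        if unknown:
            raise ValidationError(f"unknown distribution kinds: {unknown}")
        if t.duplicated(["group", "variable"]).any():
            raise ValidationError("duplicate (group, variable) rows")

    @property
    def groups(self) -> list[str]:
        return sorted(self.table["group"].unique())

    def lookup(self, group: str, variable: str) -> tuple[float, float]:
        """Published (mean, sd) for one group and variable."""
        row = self.table[(self.table["group"] == group) &
                         (self.table["variable"] == variable)]
        if len(row) != 1:
            raise ConfigurationError(f"no spec row for ({group}, {variable})")
        return float(row["mean"].iloc[0]), float(row["sd"].iloc[0])

    def rows_for(self, group: str) -> pd.DataFrame:
        rows = self.table[self.table["group"] == group]
        if rows.empty:
            raise ConfigurationError(f"group {group!r} not present in spec")
        return rows

    def sampled_variables(self, group: str) -> pd.DataFrame:
        rows = self.rows_for(group)
        return rows[rows["distribution"] != "derived"].sort_values("variable")


def build_published_group_spec() -> GroupSpecTable:
    """The packaged fixture with every published (group, variable, mean, SD)."""
    with ir.files("memclinic.data").joinpath("group_spec.csv").open() as fh:
        table = pd.read_csv(fh)
    spec = GroupSpecTable(table)
    # every field any decision rule consumes must be parameterized per group
    missing = set(NUMERIC_FIELDS) - set(table["variable"])
    if missing:
        raise ConfigurationError(f"spec fixture missing fields: {sorted(missing)}")
    return spec


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

_REJECTION_CAP = 1000


def _truncated_normal(rng: np.random.Generator, mean, sd, lo, hi, n: int) -> np.ndarray:
    """Rejection sampling from a truncated Gaussian, clipping after a cap."""
    if sd == 0:
        return np.full(n, float(np.clip(mean, lo, hi)))
    x = rng.normal(mean, sd, size=n)
    bad = (x < lo) | (x > hi)
    attempts = 0
    while bad.any() and attempts < _REJECTION_CAP:
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (x < lo) | (x > hi)
        attempts += 1
    return np.clip(x, lo, hi)


def _sample_variable(rng, dist, mean, sd, lo, hi, n):
    if dist == "bernoulli":
        return (rng.random(n) < mean).astype(float)
    x = _truncated_normal(rng, mean, sd, lo, hi, n)
    if dist == "integer_truncated":
        x = np.clip(np.round(x), lo, hi)
    return x


def _derive_fields(df: pd.DataFrame) -> None:
    for r in COMPARTMENTS + LATERALIZED_REGIONS:
        df[f"{r}_total"] = df[f"{r}_rx"] + df[f"{r}_lx"]
        df[f"{r}_asym"] = 100.0 * (df[f"{r}_rx"] - df[f"{r}_lx"]) / (
            df[f"{r}_rx"] + df[f"{r}_lx"])
    for r in COMPARTMENTS + ["csf_volume"]:
        df[f"{r}_perc_tiv"] = 100.0 * df[f"{r}_total"] / df["tiv_total"]
    df["clock_total"] = df[CLOCK_ITEMS].sum(axis=1)
    df["faq_total"] = df[FAQ_ITEMS].sum(axis=1)
    df["csf_ttau_abeta42_ratio"] = df["csf_t_tau"] / df["csf_abeta42"]


def generate_cohort(spec: GroupSpecTable, group_sizes: dict[str, int], seed: int,
                    label_noise: float = 0.15, pet_rate: float = 0.5,
                    missing_rate: float = 0.0) -> pd.DataFrame:
    """Draw a synthetic cohort; deterministic given (spec, sizes, seed).

    ``label_noise`` is the probability that a risk-group subject's 24-month
    conversion label is flipped, so that raw group separation is imperfect,
    as in the published prediction accuracy of about 85%.  ``pet_rate`` is
    the fraction of subjects with an FDG-PET read.  ``missing_rate``
    optionally blanks each cognitive/CSF cell independently (off by default).
    """
    if any(n < 0 for n in group_sizes.values()):
        raise ValidationError("group sizes must be non-negative")
    for g in group_sizes:
        if g not in spec.groups:
            raise ConfigurationError(f"group {g!r} not present in spec")
    rng = np.random.default_rng(seed)
    frames = []
    offset = 0
    for group in sorted(group_sizes):
        n = group_sizes[group]
        if n == 0:
            continue
        data = {}
        for row in spec.sampled_variables(group).itertuples():
            data[row.variable] = _sample_variable(
                rng, row.distribution, row.mean, row.sd, row.lower, row.upper, n)
        df = pd.DataFrame(data)
        _derive_fields(df)
        df["subject_id"] = [f"S{offset + i:05d}" for i in range(n)]
        offset += n
        df["group"] = group
        df["clinician_stage_baseline"] = group if group in STAGE_GROUPS else pd.NA
        if group in RISK_GROUPS:
            base = "cMCI" if group == "HIGH_RISK" else "ncMCI"
            other = "ncMCI" if base == "cMCI" else "cMCI"
            flip = rng.random(n) < label_noise
            df["diagnosis_24mo"] = np.where(flip, other, base)
        else:
            df["diagnosis_24mo"] = pd.NA
        assessed = rng.random(n) < pet_rate
        # PET read is kept loosely concordant with the drawn CSF profile
        p_pos = np.where(df["csf_ttau_abeta42_ratio"] > 0.23, 0.85, 0.15)
        positive = assessed & (rng.random(n) < p_pos)
        df["pet_assessed"] = assessed
        df["pet_positive_for"] = np.where(positive, "AD", "")
        if missing_rate > 0:
            for col in COGNITIVE_FIELDS + list(schema.CSF_FIELDS):
                df.loc[rng.random(n) < missing_rate, col] = np.nan
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=COHORT_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    return out[COHORT_COLUMNS]


def recoverable_variables(spec: GroupSpecTable, group: str,
                          max_truncated_mass: float = 0.05) -> pd.DataFrame:
    """Sampled variables whose printed moments the sampling family can hit.

    Truncating a Gaussian shifts its mean; for boundary-concentrated count
    variables (e.g. a 0–4 item printed as 0.4 ± 1.0) no truncated Gaussian
    attains the printed moments at all.  Mean-recovery checks therefore
    apply to variables whose untruncated Gaussian mass outside the valid
    range is below ``max_truncated_mass``; the rest are documented as
    distribution-distorted.
    """
    from scipy.stats import norm
    rows = spec.sampled_variables(group)
    keep = []
    for row in rows.itertuples():
        if row.distribution == "bernoulli" or row.sd == 0:
            keep.append(True)
            continue
        tail = norm.cdf((row.lower - row.mean) / row.sd) + \
            norm.sf((row.upper - row.mean) / row.sd)
        keep.append(tail < max_truncated_mass)
    return rows[np.asarray(keep)]


# ---------------------------------------------------------------------------
# descriptive summary
# ---------------------------------------------------------------------------


def summarize_cohort(cohort: pd.DataFrame, grouping: str = "group",
                     variables: list[str] | None = None,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Per-variable group means ± SD with percent difference and gated tests.

    Reproduces the layout of the published descriptive tables: for each
    variable, mean and SD per group, the percent difference anchored on the
    first group, a Shapiro–Wilk-gated t-test / Mann–Whitney p-value and its
    Bonferroni adjustment (m = number of variables summarized).  With a
    single group the difference and p-values are omitted.
    """
    if variables is None:
        variables = [c for c in NUMERIC_FIELDS if c in cohort.columns]
    groups = sorted(cohort[grouping].dropna().unique())
    if not groups:
        raise ValidationError("no groups to summarize")
    two = len(groups) >= 2
    m = len(variables)
    rows = []
    for var in variables:
        rec = {"variable": var}
        means = {}
        for g in groups:
            vals = cohort.loc[cohort[grouping] == g, var].dropna()
            rec[f"mean_{g}"] = means[g] = vals.mean()
            rec[f"sd_{g}"] = vals.std(ddof=1)
        if two:
            g0, g1 = groups[0], groups[1]
            sub = cohort[cohort[grouping].isin([g0, g1])][[grouping, var]].dropna()
            try:
                rec["percent_difference"] = percent_difference(means[g0], means[g1])
            except ValidationError:
                rec["percent_difference"] = np.nan
            try:
                test, p, pb = group_compare(sub[var], sub[grouping], alpha, m_tests=m)
            except ValidationError:
                test, p, pb = "unavailable", np.nan, np.nan
            rec["test_used"], rec["test_p"], rec["bonferroni_p"] = test, p, pb
        rows.append(rec)
    return pd.DataFrame(rows)
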