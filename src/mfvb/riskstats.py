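"""Relative-risk stratification statistics for MFVB score categories.

The study's primary endpoint compares the prevalence of elevated
(moderate-or-severe) questionnaire symptom severity inside each MFVB score
category against the prevalence in the full analysis cohort.  The headline
quantity is the Relative Risk Ratio (RR Ratio): the relative risk in the
"Pay Attention" score range (0-69) divided by the relative risk in the
"Excellent" range (80-100).  Confidence intervals are built on the natural
log of the ratio using the standard independent-groups error of a risk
ratio and back-transformed; two-sided p-values come from the normal tail of
the log-scale z statistic.

Note the reference cohort here *contains* each category (category rows are
subsets of the "All" row).  The conventional independent-groups standard
error is applied regardless — that is the convention under which the
published interval endpoints are reproduced exactly — and is documented as
such rather than hidden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .scoring import MFVB_CATEGORIES

# Normal quantile for 95% two-sided intervals.  Kept at full precision; a
# coarser 1.96 changes nothing at two printed decimals but the exact value
# is the honest default.
Z_95 = 1.959964

DOMAINS = ("total", "depression", "anxiety", "ptsd", "bipolar")


@dataclass(frozen=True)
class RiskEstimate:
    """Relative risk of one MFVB category versus a reference group."""

    rr: float
    ci_low: float
    ci_high: float
    n_category: int
    n_reference: int
    degenerate: bool = False

    def __iter__(self):
        yield self.rr
        yield self.ci_low
        yield self.ci_high


@dataclass(frozen=True)
class RatioEstimate:
    """RR Ratio (Pay Attention vs Excellent) with CI and two-sided p."""

    rr_ratio: float
    ci_low: float
    ci_high: float
    p_two_sided: float
    degenerate: bool = False


@dataclass
class CategoryCounts:
    """Elevated/lower counts cross-tabulated by MFVB score category."""

    elevated: dict[str, int] = field(default_factory=dict)
    lower: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cat in MFVB_CATEGORIES:
            self.elevated.setdefault(cat, 0)
            self.lower.setdefault(cat, 0)

    @property
    def total_elevated(self) -> int:
        return sum(self.elevated.values())

    @property
    def total_lower(self) -> int:
        return sum(self.lower.values())

    def n_category(self, category: str) -> int:
        return self.elevated[category] + self.lower[category]

    @property
    def n_total(self) -> int:
        return self.total_elevated + self.total_lower


def build_counts(observations, domain: str) -> CategoryCounts:
    """Cross-tabulate paired observations: MFVB category x elevated/lower.

    ``observations`` is an iterable of :class:`mfvb.study.PairedObservation`;
    unpaired entries (``paired_score is None``) are skipped, mirroring the
    study's exclusion of assessments with no score inside the pairing window.
    """
    from .study import dichotomize  # local import to avoid a cycle

    if domain not in DOMAINS:
        raise ValueError(f"unknown symptom domain {domain!r}; expected one of {DOMAINS}")
    counts = CategoryCounts()
    for obs in observations:
        if obs.paired_score is None:
            continue
        status = dichotomize(obs.assessment.severity[domain])
        if status == "elevated":
            counts.elevated[obs.paired_category] += 1
        else:
            counts.lower[obs.paired_category] += 1
    return counts


def _log_se(a1: int, n1: int, a2: int, n2: int) -> float:
    return math.sqrt(1.0 / a1 - 1.0 / n1 + 1.0 / a2 - 1.0 / n2)


def relative_risk(
    a: int, n: int, a_ref: int, n_ref: int, *, zero_cell_correction: bool = False
) -> RiskEstimate:
    """Relative risk of elevated severity in a category vs a reference.

    rr = (a/n) / (a_ref/n_ref); the 95% CI is exp(ln rr +/- z * SE) with
    SE = sqrt(1/a - 1/n + 1/a_ref - 1/n_ref).

    A zero numerator makes the log-scale SE undefined; by default the
    estimate is returned with NaN interval bounds and ``degenerate=True``.
    With ``zero_cell_correction`` a Haldane-style 0.5 is added to every cell
    of the implied 2x2 table before computing estimate and interval.
    """
    if n < 1 or n_ref < 1:
        raise ValueError("category and reference totals must be >= 1")
    if a_ref < 1:
        raise ValueError("reference must contain at least one elevated case")
    if a == 0:
        if not zero_cell_correction:
            return RiskEstimate(0.0, math.nan, math.nan, n, n_ref, degenerate=True)
        ac, nc = a + 0.5, n + 1.0
        arc, nrc = a_ref + 0.5, n_ref + 1.0
        rr = (ac / nc) / (arc / nrc)
        se = math.sqrt(1.0 / ac - 1.0 / nc + 1.0 / arc - 1.0 / nrc)
        half = Z_95 * se
        return RiskEstimate(
            rr, rr * math.exp(-half), rr * math.exp(half), n, n_ref, degenerate=True
        )
    rr = (a / n) / (a_ref / n_ref)
    se = _log_se(a, n, a_ref, n_ref)
    half = Z_95 * se
    return RiskEstimate(rr, rr * math.exp(-half), rr * math.exp(half), n, n_ref)


def rr_ratio(a1: int, n1: int, a2: int, n2: int) -> RatioEstimate:
    """RR Ratio between two categories sharing a common reference.

    Because the reference prevalence cancels, the ratio of the two category
    RRs equals the plain risk ratio (a1/n1)/(a2/n2).  SE on the log scale is
    sqrt(1/a1 - 1/n1 + 1/a2 - 1/n2); p is the two-sided normal tail of
    z = ln(ratio)/SE.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("group totals must be >= 1")
    if a1 == 0 or a2 == 0:
        ratio = math.nan if a2 == 0 else 0.0
        return RatioEstimate(ratio, math.nan, math.nan, math.nan, degenerate=True)
    ratio = (a1 / n1) / (a2 / n2)
    se = _log_se(a1, n1, a2, n2)
    if se == 0.0:
        # both groups saturated (a == n); no sampling variability on log scale
        return RatioEstimate(ratio, ratio, ratio, 1.0 if ratio == 1.0 else 0.0,
                             degenerate=True)
    log_r = math.log(ratio)
    half = Z_95 * se
    z = log_r / se
    p = 2.0 * _norm_sf(abs(z))
    return RatioEstimate(ratio, ratio * math.exp(-half), ratio * math.exp(half), p)


def _norm_sf(z: float) -> float:
    return 0.5 * math.erfc(z / math.sqrt(2.0))


@dataclass
class DomainReport:
    """Full per-domain record: counts, per-category RRs, Pay/Excellent ratio."""

    domain: str
    counts: CategoryCounts
    risks: dict[str, RiskEstimate]
    ratio: RatioEstimate | None
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        out: dict = {"domain": self.domain, "categories": {}, "flags": self.flags}
        for cat in MFVB_CATEGORIES:
            entry: dict = {
                "elevated": self.counts.elevated[cat],
                "lower": self.counts.lower[cat],
            }
            if cat in self.risks:
                r = self.risks[cat]
                entry.update(rr=r.rr, ci_low=r.ci_low, ci_high=r.ci_high,
                             degenerate=r.degenerate)
            out["categories"][cat] = entry
        out["all"] = {
            "elevated": self.counts.total_elevated,
            "lower": self.counts.total_lower,
        }
        if self.ratio is not None:
            out["rr_ratio"] = {
                "estimate": self.ratio.rr_ratio,
                "ci_low": self.ratio.ci_low,
                "ci_high": self.ratio.ci_high,
                "p_two_sided": self.ratio.p_two_sided,
                "degenerate": self.ratio.degenerate,
            }
        return out


def analyze_counts(counts: CategoryCounts, domain: str = "total") -> DomainReport:
    """Per-category RRs vs the cohort and the Pay/Excellent RR Ratio."""
    flags: list[str] = []
    risks: dict[str, RiskEstimate] = {}
    a_ref, n_ref = counts.total_elevated, counts.n_total
    if n_ref == 0:
        return DomainReport(domain, counts, {}, None, ["empty table"])
    for cat in MFVB_CATEGORIES:
        n_cat = counts.n_category(cat)
        if n_cat == 0:
            flags.append(f"empty category: {cat}")
            continue
        risks[cat] = relative_risk(counts.elevated[cat], n_cat, a_ref, n_ref)
        if risks[cat].degenerate:
            flags.append(f"zero elevated cell: {cat}")
    ratio: RatioEstimate | None = None
    n_pay = counts.n_category("pay_attention")
    n_exc = counts.n_category("excellent")
    if n_pay > 0 and n_exc > 0:
        ratio = rr_ratio(counts.elevated["pay_attention"], n_pay,
                         counts.elevated["excellent"], n_exc)
        if ratio.degenerate:
            flags.append("degenerate RR Ratio (zero cell)")
    else:
        flags.append("RR Ratio unavailable (empty endpoint category)")
    return DomainReport(domain, counts, risks, ratio, flags)


def analyze_domain(observations, domain: str = "total") -> DomainReport:
    """End-to-end Table-style analysis of paired observations for one domain."""
    return analyze_counts(build_counts(observations, domain), domain)


def subgroup_analysis(
    observations, grouping: dict, domain: str = "total"
) -> dict[str, DomainReport]:
    """Run the per-domain analysis inside each level of a participant grouping.

    ``grouping`` maps participant id -> level label.  Each level's reference
    prevalence is recomputed within the level (the level's own "All" row is
    its reference), so the per-level RRs are internally referenced.
    Observations whose participant has no level are ignored.
    """
    by_level: dict[str, list] = {}
    for obs in observations:
        level = grouping.get(obs.assessment.participant_id)
        if level is None:
            continue
        by_level.setdefault(str(level), []).append(obs)
    return {
        level: analyze_domain(group, domain)
        for level, group in sorted(by_level.items())
    }
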