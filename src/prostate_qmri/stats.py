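"""Cohort statistics: exclusions, exact Wilcoxon tests, and persistence calls.

The test battery is fixed at nine paired Wilcoxon signed-rank tests of
pretreatment versus week-5 medians: T2 in {CG, PZ, tumor} for the
hormonal-therapy stratum only (the stratum without hormonal therapy is too
small for T2), and ADC in {CG, PZ, tumor} for both strata.  Significance is
judged at the Bonferroni-corrected level alpha / 9 = 0.00556 (displayed as
0.0056; comparisons always use the unrounded value).

Per-patient persistent change is classified against test-retest
repeatability confidence intervals (11 % for T2, 47 % for ADC): a change is
persistent when some measured week's normalized value leaves the interval
and every later measured week stays outside with the same sign through the
end of treatment.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "bonferroni_threshold",
    "BonferroniThreshold",
    "apply_exclusions",
    "ExclusionReport",
    "PersistenceCall",
    "classify_persistence",
    "summarize_cohort",
    "CohortResult",
    "combined_fraction",
    "CI_T2",
    "CI_ADC",
    "N_TESTS",
]

CI_T2 = 0.11  # test-retest 95% repeatability interval for T2 medians
CI_ADC = 0.47  # QIBA-recommended repeatability interval for ADC medians
N_TESTS = 9


# ---------------------------------------------------------------------------
# Wilcoxon signed rank


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W+ = sum of ranks of positive differences
    p_value: float
    n_informative: int
    method: str  # 'exact' | 'normal'


def _exact_rank_distribution(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Support and counts of W+ over all 2^n equiprobable sign assignments.

    Mid-ranks from ties are half-integers, so everything is doubled to work
    on an integer lattice; the convolution is the polynomial product
    prod_i (1 + z^(2 r_i)).
    """
    doubled = np.rint(2 * ranks).astype(int)
    total = doubled.sum()
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    support = np.arange(total + 1) / 2.0
    return support, counts


def wilcoxon_signed_rank(
    x,
    y=None,
    *,
    zero_method: str = "wilcox",
    exact_max_n: int = 25,
) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test with an exact tie-aware null.

    For ``n`` informative pairs up to ``exact_max_n`` the p-value comes from
    the full sign-assignment distribution of the rank sum (ties mid-ranked);
    larger samples use the normal approximation with tie correction and
    continuity correction.  ``zero_method='wilcox'`` discards zero
    differences before ranking (classical convention); ``'pratt'`` ranks
    them and then drops their ranks.
    """
    x = np.asarray(x, float)
    d = x - np.asarray(y, float) if y is not None else x
    d = d[np.isfinite(d)]
    if zero_method not in ("wilcox", "pratt"):
        raise ValueError(f"unknown zero_method {zero_method!r}")

    if zero_method == "wilcox":
        d = d[d != 0]
        if d.size == 0:
            warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
            return WilcoxonResult(0.0, 1.0, 0, "degenerate")
        ranks = rankdata(np.abs(d))
    else:
        if np.all(d == 0):
            warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
            return WilcoxonResult(0.0, 1.0, 0, "degenerate")
        ranks_all = rankdata(np.abs(d))
        keep = d != 0
        ranks = ranks_all[keep]
        d = d[keep]

    n = d.size
    w_plus = float(ranks[d > 0].sum())

    if n <= exact_max_n:
        support, counts = _exact_rank_distribution(ranks)
        total = counts.sum()
        p_le = counts[support <= w_plus + 1e-9].sum() / total
        p_ge = counts[support >= w_plus - 1e-9].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return WilcoxonResult(w_plus, float(p), n, "exact")

    mean = ranks.sum() / 2.0
    # variance of W+ under the null with mid-ranks: sum r_i^2 / 4
    var = float((ranks**2).sum()) / 4.0
    if var == 0:
        return WilcoxonResult(w_plus, 1.0, n, "degenerate")
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
    p = min(1.0, 2.0 * float(norm.sf(abs(z))))
    return WilcoxonResult(w_plus, p, n, "normal")


# ---------------------------------------------------------------------------
# Multiple testing


@dataclass(frozen=True)
class BonferroniThreshold:
    alpha: float
    n_tests: int
    threshold: float  # unrounded; use this for comparisons
    display: str  # rounded to two significant figures for reporting

    def is_significant(self, p: float) -> bool:
        return p < self.threshold


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = N_TESTS) -> BonferroniThreshold:
    """Per-test significance level alpha / n_tests.

    The displayed value is rounded to two significant figures (0.05/9 shows
    as "0.0056") but all comparisons use the unrounded quotient.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    thr = alpha / n_tests
    exponent = int(np.floor(np.log10(abs(thr))))
    display = f"{round(thr, -exponent + 1):.{max(0, -exponent + 1)}f}"
    return BonferroniThreshold(alpha, n_tests, thr, display)


# ---------------------------------------------------------------------------
# Cohort exclusions


@dataclass
class ExclusionReport:
    adc_patients: list[str]
    t2_patients: list[str]
    excluded: list[tuple[str, str, str]]  # (patient, analysis, reason)

    def reasons(self, patient: str) -> list[str]:
        return [r for p, _, r in self.excluded if p == patient]


def apply_exclusions(manifest: pd.DataFrame, min_exams: int = 3) -> ExclusionReport:
    """Select analyzable patients from an exam-level manifest.

    A patient enters the ADC analysis iff at least ``min_exams`` of the six
    weekly exams exist, a single DWI protocol dialect was used throughout,
    and a week-0 ADC acquisition is present; the T2 analysis additionally
    requires a week-0 T2-mapping acquisition.  Exclusions are returned with
    reasons.
    """
    required = {"patient", "week", "dialect", "has_adc", "has_t2"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    adc_ok: list[str] = []
    t2_ok: list[str] = []
    excluded: list[tuple[str, str, str]] = []
    for patient, g in manifest.groupby("patient", sort=True):
        weeks = set(g["week"].astype(int))
        dialects = set(g["dialect"])
        week0 = g[g["week"] == 0]
        reasons_adc = []
        if len(weeks) < min_exams:
            reasons_adc.append("insufficient exams")
        if len(dialects) > 1:
            reasons_adc.append("multiple DWI protocols")
        if week0.empty or not bool(week0["has_adc"].any()):
            reasons_adc.append("no pretreatment ADC")
        if reasons_adc:
            for r in reasons_adc:
                excluded.append((patient, "ADC", r))
        else:
            adc_ok.append(patient)
        reasons_t2 = list(reasons_adc)
        if week0.empty or not bool(week0["has_t2"].any()):
            reasons_t2.append("no pretreatment T2 map")
        if reasons_t2:
            for r in reasons_t2:
                if (patient, "ADC", r) not in excluded:
                    excluded.append((patient, "T2", r))
        else:
            t2_ok.append(patient)
    return ExclusionReport(adc_ok, t2_ok, excluded)


# ---------------------------------------------------------------------------
# Persistence classification


@dataclass(frozen=True)
class PersistenceCall:
    patient: str
    roi: str
    map_type: str
    ci_threshold: float
    persistent: bool | None  # None = undetermined (too few measured weeks)
    onset_week: int | None
    direction: str | None  # 'increase' | 'decrease'
    imputed_endpoint: bool = False  # endpoint is the last measured week, not week 5


def classify_persistence(
    normalized: dict[int, float],
    ci: float,
    *,
    patient: str = "",
    roi: str = "",
    map_type: str = "",
) -> PersistenceCall:
    """Strict sustained-change call on measured normalized values.

    Persistent iff some measured week w >= 1 has |x_w - 1| > ci and every
    later measured week stays outside the interval with the same sign
    through the endpoint.  The endpoint is week 5 when measured, otherwise
    the last measured week (flagged ``imputed_endpoint``).  Transient
    excursions that return inside the interval do not count.
    """
    weeks = sorted(w for w in normalized if w >= 1 and np.isfinite(normalized[w]))
    if len(weeks) < 2:
        return PersistenceCall(
            patient, roi, map_type, ci, None, None, None, imputed_endpoint=False
        )
    imputed = weeks[-1] != 5
    onset = None
    direction = None
    for w in weeks:
        dev = normalized[w] - 1.0
        if abs(dev) <= ci:
            continue
        sign = np.sign(dev)
        tail = [normalized[v] - 1.0 for v in weeks if v >= w]
        if all(abs(t) > ci and np.sign(t) == sign for t in tail):
            onset = w
            direction = "increase" if sign > 0 else "decrease"
            break
    return PersistenceCall(
        patient,
        roi,
        map_type,
        ci,
        onset is not None,
        onset,
        direction,
        imputed_endpoint=imputed,
    )


def combined_fraction(counts: list[tuple[int, int]]) -> float:
    """Overall percentage from per-stratum (numerator, denominator) counts.

    E.g. persistent-change counts of 14/21 and 2/3 combine to
    100 * 16/24 = 66.7 %.
    """
    num = sum(k for k, _ in counts)
    den = sum(n for _, n in counts)
    if den == 0:
        raise ValueError("empty counts")
    return 100.0 * num / den


# ---------------------------------------------------------------------------
# Cohort summary


@dataclass
class CohortResult:
    tests: list[dict]
    population_medians: pd.DataFrame
    week5_changes: list[dict]
    persistence: list[PersistenceCall]
    persistence_counts: dict
    threshold: BonferroniThreshold
    endpoint_policy: str
    skipped_tests: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "threshold": asdict(self.threshold),
            "endpoint_policy": self.endpoint_policy,
            "tests": self.tests,
            "skipped_tests": self.skipped_tests,
            "week5_changes": self.week5_changes,
            "persistence_counts": self.persistence_counts,
            "persistence_calls": [asdict(c) for c in self.persistence],
            "population_medians": self.population_medians.to_dict(orient="records"),
        }
        text = json.dumps(payload, indent=1, sort_keys=True, default=float)
        if path is not None:
            Path(path).write_text(text)
        return text


TEST_BATTERY = (
    # (map_type, roi, stratum) — 3 T2 tests in the HT stratum + 6 ADC tests
    ("T2", "CG", "HT"),
    ("T2", "PZ", "HT"),
    ("T2", "tumor", "HT"),
    ("ADC", "CG", "HT"),
    ("ADC", "PZ", "HT"),
    ("ADC", "tumor", "HT"),
    ("ADC", "CG", "noHT"),
    ("ADC", "PZ", "noHT"),
    ("ADC", "tumor", "noHT"),
)


def _endpoint_value(g: pd.DataFrame, policy: str) -> tuple[float, float, bool] | None:
    """Per-patient (baseline, endpoint, imputed) pair of measured medians."""
    meas = g[g["measured"]].sort_values("week")
    if meas.empty or 0 not in set(meas["week"]):
        return None
    base = float(meas.loc[meas["week"] == 0, "median_value"].iloc[0])
    if policy == "strict-week5":
        tail = meas[meas["week"] == 5]
        if tail.empty:
            return None
        return base, float(tail["median_value"].iloc[0]), False
    post = meas[meas["week"] >= 1]
    if post.empty:
        return None
    last = post.iloc[-1]
    return base, float(last["median_value"]), int(last["week"]) != 5


def summarize_cohort(
    trajectories: pd.DataFrame,
    exclusions: ExclusionReport | None = None,
    *,
    ci_t2: float = CI_T2,
    ci_adc: float = CI_ADC,
    alpha: float = 0.05,
    n_tests: int = N_TESTS,
    endpoint_policy: str = "last-measured",
    min_pairs: int = 5,
) -> CohortResult:
    """Population trajectories, the nine-test battery, and persistence calls.

    ``trajectories`` is the tidy table produced by
    :func:`prostate_qmri.roi.build_trajectory_table` (interpolated rows
    allowed; they only enter the display medians).  ``endpoint_policy``
    selects the week-5 comparison value for patients missing week 5:
    ``'last-measured'`` substitutes the final measured week (flagged), while
    ``'strict-week5'`` drops those patients from testing.
    """
    if endpoint_policy not in ("last-measured", "strict-week5"):
        raise ValueError(f"unknown endpoint_policy {endpoint_policy!r}")
    thr = bonferroni_threshold(alpha, n_tests)
    df = trajectories.copy()
    df["stratum"] = np.where(df["ht"], "HT", "noHT")
    if exclusions is not None:
        keep_adc = df["patient"].isin(exclusions.adc_patients) & (df["map_type"] == "ADC")
        keep_t2 = df["patient"].isin(exclusions.t2_patients) & (df["map_type"] == "T2")
        df = df[keep_adc | keep_t2]

    # population medians per stratum/roi/map/week (display: interpolated included)
    pop = (
        df.groupby(["stratum", "roi", "map_type", "week"])["normalized_value"]
        .median()
        .reset_index()
        .rename(columns={"normalized_value": "population_median"})
    )

    tests: list[dict] = []
    skipped: list[dict] = []
    week5_changes: list[dict] = []
    for map_type, roi, stratum in TEST_BATTERY:
        sel = df[
            (df["map_type"] == map_type)
            & (df["roi"] == roi)
            & (df["stratum"] == stratum)
        ]
        pairs = []
        endpoints_norm = []
        for patient, g in sel.groupby("patient"):
            pair = _endpoint_value(g, endpoint_policy)
            if pair is None:
                continue
            base, end, imputed = pair
            pairs.append((base, end))
            endpoints_norm.append(end / base)
        entry = {
            "map_type": map_type,
            "roi": roi,
            "stratum": stratum,
            "n_patients": len(pairs),
        }
        if endpoints_norm:
            entry["week5_percent_change"] = 100.0 * (float(np.median(endpoints_norm)) - 1.0)
            week5_changes.append(
                {k: entry[k] for k in ("map_type", "roi", "stratum", "week5_percent_change")}
            )
        if len(pairs) < min_pairs:
            skipped.append({**entry, "reason": "stratum too small for testing"})
            continue
        base_arr = np.array([b for b, _ in pairs])
        end_arr = np.array([e for _, e in pairs])
        res = wilcoxon_signed_rank(end_arr, base_arr)
        entry.update(
            {
                "statistic": res.statistic,
                "p_value": res.p_value,
                "n_informative": res.n_informative,
                "method": res.method,
                "significant": thr.is_significant(res.p_value),
            }
        )
        tests.append(entry)

    # persistence: measured weeks only
    calls: list[PersistenceCall] = []
    meas = df[df["measured"]]
    for (patient, roi, map_type), g in meas.groupby(["patient", "roi", "map_type"]):
        stratum = "HT" if bool(g["ht"].iloc[0]) else "noHT"
        series = dict(zip(g["week"].astype(int), g["normalized_value"].astype(float)))
        ci = ci_t2 if map_type == "T2" else ci_adc
        call = classify_persistence(
            series, ci, patient=patient, roi=roi, map_type=map_type
        )
        calls.append(call)

    counts: dict = {}
    for call in calls:
        if call.persistent is None:
            continue
        pat_row = meas[meas["patient"] == call.patient].iloc[0]
        stratum = "HT" if bool(pat_row["ht"]) else "noHT"
        key = f"{call.map_type}/{stratum}"
        bucket = counts.setdefault(
            key, {"patients": set(), "persistent_patients": set(), "per_roi": {}}
        )
        bucket["patients"].add(call.patient)
        if call.persistent:
            bucket["persistent_patients"].add(call.patient)
            bucket["per_roi"].setdefault(call.roi, set()).add(call.patient)
    persistence_counts = {
        key: {
            "n_patients": len(b["patients"]),
            "n_persistent": len(b["persistent_patients"]),
            "per_roi": {r: len(s) for r, s in sorted(b["per_roi"].items())},
        }
        for key, b in sorted(counts.items())
    }

    return CohortResult(
        tests=tests,
        population_medians=pop,
        week5_changes=week5_changes,
        persistence=calls,
        persistence_counts=persistence_counts,
        threshold=thr,
        endpoint_policy=endpoint_policy,
        skipped_tests=skipped,
    )
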