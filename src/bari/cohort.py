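"""BARI aggregation, growth classification and cohort statistics.

The brachial artery relaxation index (BARI) of a recording is the mean of
the slow diastolic relaxation constant T_R2 over all accepted bi-exponential
fits (all cross-sections, all cycles), in seconds.  A pilot threshold of
1.5 s separates fast from slow aneurysm growth; which side means "fast" is
a mandatory configuration input.  The aneurysm growth rate is
(change in AP diameter / baseline AP diameter) / (days elapsed / 365), as
percent per year.

Cohort-level operations mirror a three-part analysis: a two-group
comparison of BARI between healthy volunteers and aneurysm patients, a
Kruskal-Wallis comparison across aneurysm size groups with rank-based
pairwise follow-ups (Bonferroni-adjusted), and the correlation/regression
of BARI against the yearly growth rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cine_io import ParticipantRecord
from .fitting import FitRecord, RelaxationFit

__all__ = ["BariResult", "CohortStats", "compute_bari", "classify_growth",
           "growth_rate", "run_comparisons"]


@dataclass
class BariResult:
    """The aggregated relaxation index of one recording.

    ``bari`` is None when no relaxation fit was accepted — the index is
    then not derivable for this recording, with the reason recorded.
    ``provenance`` keeps every contributing (x, cycle, T_R2) triple.
    """

    bari: float | None
    n_accepted: int
    provenance: list[tuple[int, int, float]] = field(default_factory=list)
    classification: str | None = None
    reason: str = ""


def compute_bari(fits: list[FitRecord | RelaxationFit],
                 use_fast_constant: bool = False,
                 per_cross_section: bool = False) -> BariResult:
    """Aggregate accepted relaxation fits into BARI.

    Default: the arithmetic mean of T_R2 over all accepted fits, pooling
    every cycle at every cross-section.  ``use_fast_constant`` aggregates
    T_R1 instead (off by default; the slow constant is the index).
    ``per_cross_section`` first averages within each cross-section and
    then across cross-sections — a sensitivity alternative to the pooled
    mean.
    """
    triples: list[tuple[int, int, float]] = []
    for item in fits:
        rec = item if isinstance(item, FitRecord) \
            else FitRecord(x=-1, cycle=-1, fit=item)
        if not rec.fit.accepted:
            continue
        tau = rec.fit.tau1 if use_fast_constant else rec.fit.tau2
        triples.append((rec.x, rec.cycle, float(tau)))
    if not triples:
        return BariResult(bari=None, n_accepted=0,
                          reason="no accepted relaxation fits")
    values = np.array([v for _, _, v in triples])
    if per_cross_section:
        xs = np.array([x for x, _, _ in triples])
        means = [values[xs == x].mean() for x in np.unique(xs)]
        bari = float(np.mean(means))
    else:
        bari = float(values.mean())
    return BariResult(bari=bari, n_accepted=len(triples), provenance=triples)


def classify_growth(bari: float | None, threshold: float = 1.5,
                    fast_side: str | None = None) -> str:
    """Label a BARI value against the pilot threshold (default 1.5 s).

    ``fast_side`` must be ``"above"`` or ``"below"`` and states which side
    of the threshold is called "fast" growth — it is required, never
    defaulted.  A value exactly at the threshold is assigned to the >=
    side (i.e. to the "above" side's label).
    """
    if bari is None or (isinstance(bari, float) and math.isnan(bari)):
        raise ValueError("cannot classify a missing BARI")
    if fast_side not in ("above", "below"):
        raise ValueError('fast_side must be "above" or "below"')
    above = bari >= threshold
    if fast_side == "above":
        return "fast" if above else "slow"
    return "slow" if above else "fast"


def growth_rate(record: ParticipantRecord) -> float | None:
    """Annualised aneurysm growth in percent per year.

    rate = (dAPD / APD_baseline) / (days_elapsed / 365) x 100.
    Returns None when follow-up diameter or elapsed days are missing.
    Exactly homogeneous: scaling both diameters leaves the rate unchanged.
    """
    if record.apd_followup is None or record.days_elapsed is None \
            or record.apd_baseline is None:
        return None
    delta = record.apd_followup - record.apd_baseline
    return (delta / record.apd_baseline) / (record.days_elapsed / 365.0) * 100.0


# --------------------------------------------------------------------------
# Cohort statistics
# --------------------------------------------------------------------------

def _median_iqr(values: np.ndarray) -> dict:
    return {"n": int(values.size),
            "median": float(np.median(values)),
            "iqr": (float(np.percentile(values, 25)),
                    float(np.percentile(values, 75)))}


@dataclass
class CohortStats:
    """Outputs of the three cohort comparisons (missing parts are None)."""

    two_group: dict | None = None       # HV vs aneurysm cohort
    size_groups: dict | None = None     # Kruskal-Wallis across small/mod/large
    growth: dict | None = None          # BARI vs %growth/year
    exclusions: dict = field(default_factory=dict)


def _bari_values(records, group=None):
    vals = [r.bari for r in records
            if r.bari is not None and (group is None or r.group == group)]
    return np.asarray(vals, dtype=float)


def run_comparisons(records: list[ParticipantRecord],
                    min_group_n: int = 2) -> CohortStats:
    """Run the cohort's group comparisons and correlations.

    Rows missing the fields a comparison needs are dropped for that
    comparison only, with counts logged in ``exclusions``.  The two-group
    comparison reports both an unpaired t-test and a Mann-Whitney U
    alongside medians/IQRs (the rank test matches the median/IQR summary;
    both are emitted, clearly labelled).  Groups smaller than
    ``min_group_n`` raise.
    """
    stats_out = CohortStats()
    n_total = len(records)

    hv = _bari_values(records, "HV")
    aaa = np.asarray([r.bari for r in records
                      if r.bari is not None and r.group != "HV"], dtype=float)
    stats_out.exclusions["two_group_missing_bari"] = (
        n_total - hv.size - aaa.size)
    if hv.size >= min_group_n and aaa.size >= min_group_n:
        tt = stats.ttest_ind(hv, aaa, equal_var=True)
        mw = stats.mannwhitneyu(hv, aaa, alternative="two-sided")
        stats_out.two_group = {
            "HV": _median_iqr(hv), "cohort": _median_iqr(aaa),
            "t_test": {"statistic": float(tt.statistic),
                       "p": float(tt.pvalue)},
            "mann_whitney": {"statistic": float(mw.statistic),
                             "p": float(mw.pvalue)},
        }

    groups = {g: _bari_values(records, g)
              for g in ("small", "moderate", "large")}
    present = {g: v for g, v in groups.items() if v.size >= min_group_n}
    if len(present) >= 2:
        kw = stats.kruskal(*present.values())
        pairs = {}
        names = list(present)
        n_pairs = len(names) * (len(names) - 1) // 2
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                mw = stats.mannwhitneyu(present[names[i]], present[names[j]],
                                        alternative="two-sided")
                pairs[f"{names[i]} vs {names[j]}"] = {
                    "p_raw": float(mw.pvalue),
                    "p_bonferroni": float(min(1.0, mw.pvalue * n_pairs)),
                }
        size_pairs = [(r.bari, r.apd_baseline) for r in records
                      if r.bari is not None and r.apd_baseline is not None]
        spearman_size = None
        if len(size_pairs) >= 3:
            b, s = map(np.asarray, zip(*size_pairs))
            rho = stats.spearmanr(s, b)
            spearman_size = {"rho": float(rho.statistic),
                             "p": float(rho.pvalue), "n": len(size_pairs)}
        stats_out.size_groups = {
            "summaries": {g: _median_iqr(v) for g, v in present.items()},
            "kruskal_wallis": {"statistic": float(kw.statistic),
                               "p": float(kw.pvalue)},
            "pairwise": pairs,
            "spearman_bari_vs_size": spearman_size,
        }

    pairs = [(r.bari, growth_rate(r)) for r in records]
    pairs = [(b, g) for b, g in pairs if b is not None and g is not None]
    stats_out.exclusions["growth_missing_fields"] = n_total - len(pairs)
    if len(pairs) >= 3:
        b, g = map(np.asarray, zip(*pairs))
        rho = stats.spearmanr(g, b)
        ols = stats.linregress(g, b)
        stats_out.growth = {
            "n": len(pairs),
            "spearman": {"rho": float(rho.statistic), "p": float(rho.pvalue)},
            "ols": {"slope": float(ols.slope),
                    "intercept": float(ols.intercept),
                    "p": float(ols.pvalue)},
        }
    return stats_out
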