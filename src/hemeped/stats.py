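"""Statistical procedures: prevalence-based co/contravariation, the
Haldane & Smith birth-order test with a Wilcoxon control, and anticipation.

Co/contravariation compares the observed number of affected relatives (OBS)
of a given diagnosis with the number expected (EXP) from that diagnosis'
prevalence within its group (LPD or MPD) applied to the AR pool of the
proband diagnosis.  Covariation means OBS > EXP, contravariation OBS < EXP.

The Haldane & Smith birth-order test compares the sum of birth ranks of
affected sibs against its null distribution under random placement within
each sibship (ranks drawn without replacement): for a sibship of size s with
m affected, the contribution has mean m(s+1)/2 and variance m(s-m)(s+1)/12.
The total over sibships is referred to a normal approximation and reported
as a 95% confidence interval.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .diagnoses import LineageGroup
from .errors import AnalysisError
from .pedigree import Individual, Pedigree, Sex, Sibship
from .rounding import round_half_up

Z_95 = 1.96


# ---------------------------------------------------------------------------
# Prevalence
# ---------------------------------------------------------------------------
class PrevalenceTable:
    """Per-diagnosis person counts and 1-decimal percent within one group."""

    def __init__(self, df: pd.DataFrame, group: LineageGroup):
        self.group = LineageGroup(group)
        self.df = df.copy()
        self.group_total = int(self.df["total"].sum())
        self.df["prevalence_pct"] = [
            round_half_up(100.0 * t / self.group_total, 1) for t in self.df["total"]]

    @classmethod
    def from_counts(cls, counts: dict[str, tuple[int, int, int]],
                    group: Union[LineageGroup, str]) -> "PrevalenceTable":
        """Build from ``{label: (total, male, female)}``."""
        if not counts:
            raise AnalysisError("empty diagnosis group")
        df = pd.DataFrame(
            [(label, t, m, f) for label, (t, m, f) in counts.items()],
            columns=["label", "total", "male", "female"]).set_index("label")
        bad = df[df.total != df.male + df.female]
        if len(bad):
            raise AnalysisError(f"male+female != total for {list(bad.index)}")
        return cls(df, LineageGroup(group))

    def pct(self, label: str) -> float:
        return float(self.df.loc[label, "prevalence_pct"])

    def counts(self, label: str) -> tuple[int, int, int]:
        row = self.df.loc[label]
        return int(row.total), int(row.male), int(row.female)

    @property
    def labels(self) -> list[str]:
        return list(self.df.index)


def compute_prevalence(source, group: Union[LineageGroup, str]) -> PrevalenceTable:
    """Prevalence table of one group from a pedigree or an affected roster.

    ``source`` may be a :class:`Pedigree`, an iterable of affected
    :class:`Individual`, or a ``{label: (total, male, female)}`` dict of
    printed counts.
    """
    group = LineageGroup(group)
    if isinstance(source, dict):
        return PrevalenceTable.from_counts(source, group)
    members = source.affected if isinstance(source, Pedigree) else list(source)
    counts: dict[str, list[int]] = {}
    for ind in members:
        if not ind.affected or ind.diagnosis.lineage_group is not group:
            continue
        c = counts.setdefault(ind.diagnosis.label, [0, 0, 0])
        c[0] += 1
        c[1 if ind.sex is Sex.MALE else 2] += 1
    if not counts:
        raise AnalysisError(f"no affected members in group {group.value}")
    return PrevalenceTable.from_counts(
        {k: tuple(v) for k, v in counts.items()}, group)


# ---------------------------------------------------------------------------
# Expected AR counts and co/contravariation
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class ExpectedCounts:
    total: float
    male: float
    female: float

    def display(self) -> tuple[int, int, int]:
        """Rounded-half-up integers as printed in reports."""
        return (round_half_up(self.total), round_half_up(self.male),
                round_half_up(self.female))


def expected_ar_counts(prev: PrevalenceTable, ar_pool, ar_label: str,
                       exact_prevalence: bool = False) -> ExpectedCounts:
    """Expected AR counts of ``ar_label`` within an AR pool.

    ``ar_pool`` is the total number of ARs of the label's group related to the
    proband diagnosis (an int, or a (total, male, female) triple whose total
    is used).  By default the prevalence enters at its 1-decimal percent, so a
    label at 8.7% with a pool of 121 yields 10.53 rather than the unrounded
    10.497; ``exact_prevalence`` switches to the unrounded fraction.  The sex
    split follows the label's own sex ratio.
    """
    pool_total = int(ar_pool[0]) if isinstance(ar_pool, (tuple, list)) else int(ar_pool)
    if pool_total < 0:
        raise AnalysisError("negative AR pool")
    total, male, female = prev.counts(ar_label)
    if pool_total == 0:
        return ExpectedCounts(0.0, 0.0, 0.0)
    if total == 0:
        raise AnalysisError(f"{ar_label}: zero count, sex split undefined")
    frac = (total / prev.group_total) if exact_prevalence else prev.pct(ar_label) / 100.0
    exp_total = frac * pool_total
    return ExpectedCounts(exp_total, exp_total * male / total, exp_total * female / total)


@dataclass(frozen=True)
class ObsExpRow:
    """Observed vs expected AR counts for one (Pc, AR) diagnosis pairing.

    ``direction`` is the sign-based classification of OBS_total - EXP_total;
    ``call`` additionally requires p < alpha under the package's chi-square.
    """

    obs_total: int
    obs_male: int
    obs_female: int
    exp_total: float
    exp_male: float
    exp_female: float
    chi_square: float
    df: int
    p_value: float
    direction: str  # covariation | contravariation | none
    call: str       # covariation | contravariation | none


def test_cocontravariation(obs, exp, df: int = 2, alpha: float = 0.05) -> ObsExpRow:
    """Pearson chi-square of the (male, female) OBS cells against EXP.

    ``obs`` is (total, male, female); ``exp`` an :class:`ExpectedCounts` or a
    matching triple.  The statistic sums (O-E)^2/E over the two sex cells and
    is referred to chi-square with ``df`` degrees of freedom (default 2, the
    reported convention); no continuity correction.
    """
    ot, om, of_ = (int(x) for x in obs)
    if isinstance(exp, ExpectedCounts):
        et, em, ef = exp.total, exp.male, exp.female
    else:
        et, em, ef = (float(x) for x in exp)
    if em <= 0 or ef <= 0:
        raise AnalysisError(
            "expected cell is zero; pool this diagnosis with a neighbouring one")
    chi2 = (om - em) ** 2 / em + (of_ - ef) ** 2 / ef
    p = float(sps.chi2.sf(chi2, df))
    if ot > et:
        direction = "covariation"
    elif ot < et:
        direction = "contravariation"
    else:
        direction = "none"
    call = direction if p < alpha else "none"
    return ObsExpRow(ot, om, of_, et, em, ef, float(chi2), df, p, direction, call)


def cocontravariation_scan(pairs, prevalence: dict, *, df: int = 2,
                           alpha: float = 0.05,
                           exact_prevalence: bool = False) -> pd.DataFrame:
    """OBS-vs-EXP table over every (Pc diagnosis, AR diagnosis) pairing.

    ``pairs`` is a list of :class:`~hemeped.pairs.PcArPair`; ``prevalence``
    maps a :class:`LineageGroup` to its :class:`PrevalenceTable`.  For each Pc
    label, the AR pool is the set of ARs belonging to the AR label's group;
    pairings whose expected sex cells vanish are skipped (flagged in the
    ``note`` column of a zero-row result would be meaningless - they simply
    do not appear).
    """
    rows = []
    by_pc: dict[str, list] = {}
    for pr in pairs:
        by_pc.setdefault(pr.pc_diagnosis.label, []).append(pr)
    for pc_label, prs in sorted(by_pc.items()):
        ar_groups: dict[LineageGroup, list] = {}
        for pr in prs:
            ar_groups.setdefault(pr.ar_diagnosis.lineage_group, []).append(pr)
        for group, gprs in ar_groups.items():
            if group not in prevalence:
                continue
            prev = prevalence[group]
            pool = (len(gprs),
                    sum(pr.ar_sex is Sex.MALE for pr in gprs),
                    sum(pr.ar_sex is Sex.FEMALE for pr in gprs))
            for ar_label in prev.labels:
                obs_prs = [pr for pr in gprs if pr.ar_diagnosis.label == ar_label]
                obs = (len(obs_prs),
                       sum(pr.ar_sex is Sex.MALE for pr in obs_prs),
                       sum(pr.ar_sex is Sex.FEMALE for pr in obs_prs))
                try:
                    exp = expected_ar_counts(prev, pool, ar_label,
                                             exact_prevalence=exact_prevalence)
                    row = test_cocontravariation(obs, exp, df=df, alpha=alpha)
                except AnalysisError:
                    continue
                rows.append({"pc_dx": pc_label, "ar_dx": ar_label,
                             "ar_group": group.value, **row.__dict__})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Birth order effect
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class BirthOrderResult:
    rank_sum_observed: float
    rank_sum_null_mean: float
    rank_sum_null_variance: float
    ci95: tuple[float, float]
    z: float
    decision: str  # late_excess | early_excess | none
    n_sibships_informative: int


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p_value: float
    n_scores: int
    defined: bool
    mean_score: float = float("nan")  # >0: affected sit late in their sibships


def make_restrict(sex: Optional[Sex] = None, diagnosis: Optional[str] = None,
                  lineage: Optional[str] = None,
                  lineage_map: Optional[dict[str, set]] = None
                  ) -> Callable[[Individual], bool]:
    """Predicate selecting which affected sibs count for the birth-order tests.

    ``lineage`` filtering needs a ``lineage_map`` (individual id -> set of
    lineages), e.g. from :func:`hemeped.pairs.lineage_annotation` or the
    simulator's ground truth.
    """
    def pred(ind: Individual) -> bool:
        if sex is not None and ind.sex is not sex:
            return False
        if diagnosis is not None and (ind.diagnosis is None
                                      or ind.diagnosis.label != diagnosis):
            return False
        if lineage is not None:
            if lineage_map is None:
                raise ValueError("lineage restriction requires a lineage_map")
            if lineage not in lineage_map.get(ind.id, set()):
                return False
        return True
    return pred


def haldane_smith_test(sibships: Sequence[Sibship],
                       restrict: Optional[Callable[[Individual], bool]] = None
                       ) -> BirthOrderResult:
    """Haldane & Smith rank-sum test for a birth-order effect.

    Sums the birth ranks of affected sibs over informative sibships (size >= 2
    with at least one affected and one unaffected under ``restrict``) and
    compares with the null moments of rank sampling without replacement.  The
    decision is ``late_excess`` if the observed sum lies above the 95%
    confidence band, ``early_excess`` below it.
    """
    a_obs = 0.0
    mean = 0.0
    var = 0.0
    n_inf = 0
    for sib in sibships:
        s = sib.size
        ranks = sib.affected_ranks(restrict)
        m = len(ranks)
        if s < 2 or m == 0 or m == s:
            continue  # zero null variance: contributes nothing
        a_obs += sum(ranks)
        mean += m * (s + 1) / 2.0
        var += m * (s - m) * (s + 1) / 12.0
        n_inf += 1
    if n_inf == 0:
        raise AnalysisError("no informative sibship for the birth-order test")
    sd = math.sqrt(var)
    lo, hi = mean - Z_95 * sd, mean + Z_95 * sd
    z = (a_obs - mean) / sd
    decision = "late_excess" if a_obs > hi else "early_excess" if a_obs < lo else "none"
    return BirthOrderResult(a_obs, mean, var, (lo, hi), z, decision, n_inf)


def wilcoxon_boe_control(sibships: Sequence[Sibship],
                         restrict: Optional[Callable[[Individual], bool]] = None
                         ) -> WilcoxonResult:
    """Wilcoxon signed-rank control for the birth-order effect.

    For every affected sib (under ``restrict``) the score is the number of
    older healthy sibs minus the number of younger healthy sibs; the scores
    are tested against a symmetric-about-zero null, dropping zero scores per
    the standard convention.  Sibs not selected by ``restrict`` count as
    healthy.
    """
    pred = restrict if restrict is not None else (lambda ind: True)
    scores = []
    for sib in sibships:
        flags = [m.affected and pred(m) for m in sib.members]
        if not any(flags) or all(flags):
            continue
        for i, is_aff in enumerate(flags):
            if not is_aff:
                continue
            older = sum(1 for j in range(i) if not flags[j])
            younger = sum(1 for j in range(i + 1, sib.size) if not flags[j])
            scores.append(older - younger)
    nonzero = [s for s in scores if s != 0]
    if not nonzero:
        return WilcoxonResult(float("nan"), float("nan"), len(scores), False)
    stat, p = sps.wilcoxon(nonzero)
    mean_score = float(np.mean(scores))
    return WilcoxonResult(float(stat), float(p), len(scores), True, mean_score)


# ---------------------------------------------------------------------------
# Anticipation
# ---------------------------------------------------------------------------
@dataclass
class AnticipationReport:
    """Onset-age trend down the generations plus registry prevalence contrast.

    ``strata`` is ordered oldest -> youngest generation; ``onset_slope`` is
    the least-squares change in onset age per generation (negative =
    anticipation); the trend test is a rank-based (Kendall) two-sided test of
    onset against generation depth.
    """

    strata: pd.DataFrame
    trend_statistic: float
    trend_p: float
    onset_slope: float
    trend_defined: bool
    prevalence_comparison: Optional[pd.DataFrame] = None


def assess_anticipation(p: Pedigree,
                        reference: Optional[PrevalenceTable] = None,
                        alpha: float = 0.05) -> AnticipationReport:
    """Median onset per generation stratum, onset-vs-depth trend, and an
    optional per-diagnosis chi-square against a reference prevalence table.

    Generation strata are founder depths (longest parent-path from a
    founder).  The trend is undefined (NaN, ``trend_defined=False``) with
    fewer than two affected strata.
    """
    recs = [(p.depth(m.id), m.onset_age, m.diagnosis.label,
             m.diagnosis.lineage_group)
            for m in p.affected if m.onset_age is not None]
    if not recs:
        raise AnalysisError("no affected member carries an onset age")
    depths = np.array([r[0] for r in recs], dtype=float)
    onsets = np.array([r[1] for r in recs], dtype=float)
    strata = (pd.DataFrame({"generation": depths.astype(int), "onset": onsets})
              .groupby("generation")["onset"]
              .agg(n_affected="size", median_onset="median")
              .reset_index().sort_values("generation", ignore_index=True))
    if strata.shape[0] < 2:
        tau, tp, slope, defined = float("nan"), float("nan"), float("nan"), False
    elif np.ptp(onsets) == 0 or np.ptp(depths) == 0:
        tau, tp, slope, defined = 0.0, 1.0, 0.0, True
    else:
        tau, tp = sps.kendalltau(depths, onsets)
        slope = float(sps.linregress(depths, onsets).slope)
        tau, tp, defined = float(tau), float(tp), True

    comparison = None
    if reference is not None:
        fam = [r for r in recs if r[3] is reference.group]
        n_fam = len(fam)
        rows = []
        for label in reference.labels:
            k = sum(1 for r in fam if r[2] == label)
            p0 = reference.pct(label) / 100.0
            if n_fam == 0 or p0 <= 0 or p0 >= 1:
                continue
            e1, e0 = n_fam * p0, n_fam * (1 - p0)
            chi2 = (k - e1) ** 2 / e1 + ((n_fam - k) - e0) ** 2 / e0
            rows.append({"label": label, "familial_n": k,
                         "familial_pct": round_half_up(100 * k / n_fam, 1),
                         "reference_pct": reference.pct(label),
                         "chi_square": float(chi2), "df": 1,
                         "p_value": float(sps.chi2.sf(chi2, 1))})
        comparison = pd.DataFrame(rows)
    return AnticipationReport(strata, tau, tp, slope, defined, comparison)
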