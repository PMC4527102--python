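"""Differential statistics for two-group spectral counting.

Implements the statistic set used for label-free case/control comparison
of shotgun-proteomics spectral counts:

* the **spectral index** SpI, a signed score in [-1, 1] combining each
  group's share of the protein's pooled counts with the fraction of that
  group's biological samples in which the protein was detected;
* the **log2 spectral-count ratio** R_SC with pseudocount ``f`` and
  group-total correction (|R_SC| > 1 corresponds to fold change > 2);
* the **G-test of independence** with Yates continuity correction on the
  pooled 2x2 table (target protein vs. all other proteins, by group),
  referred to the chi-square distribution with one degree of freedom;
* **Fisher's exact test** and the **Mann-Whitney U test** as
  distribution-free validation of the G-test calls;
* the joint classification rule (p_G < alpha and |R_SC| > cut) with a
  stricter top tier (p_G < alpha_top and |R_SC| > rsc_top).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .count_data import (
    CountMatrix,
    ProteinGroupSummary,
    ProteinMeta,
    pool_replicates,
    summarize_groups,
)
from .errors import (
    DegenerateTableError,
    InconsistentSummaryError,
    ParameterError,
    UndefinedInputError,
)

logger = logging.getLogger(__name__)

LABEL_CASE = "case_characteristic"
LABEL_CONTROL = "control_characteristic"
LABEL_NS = "not_significant"

#: beyond this combined sample count the Mann-Whitney p switches from the
#: exact permutation distribution to the tie-corrected normal approximation
MW_EXACT_MAX_N = 25


@dataclass(frozen=True)
class Thresholds:
    """Significance thresholds of the joint classification rule.

    ``alpha_g``/``rsc_cut`` define a characteristic protein (G-test
    p < alpha_g and |R_SC| > rsc_cut); ``alpha_top``/``rsc_top`` the
    stricter top tier; ``spi_cut`` the separate spectral-index flag;
    ``f`` the R_SC pseudocount.
    """

    alpha_g: float = 0.05
    rsc_cut: float = 1.0
    spi_cut: float = 0.4
    alpha_top: float = 1e-4
    rsc_top: float = 2.0
    f: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.alpha_top <= self.alpha_g < 1):
            raise ParameterError("require 0 < alpha_top <= alpha_g < 1")
        if not (self.rsc_top >= self.rsc_cut > 0):
            raise ParameterError("require rsc_top >= rsc_cut > 0")
        if not (0 < self.spi_cut < 1):
            raise ParameterError("require 0 < spi_cut < 1")
        if self.f <= 0:
            raise ParameterError("pseudocount f must be > 0")


@dataclass(frozen=True)
class DiffExprRecord:
    """Per-protein differential-expression result.

    Statistical fields are ``None`` for proteins whose 2x2 table is
    degenerate (``skip_reason`` says why); such proteins are always
    labelled not-significant.
    """

    protein: ProteinMeta
    summary: ProteinGroupSummary
    spi: float | None
    rsc: float | None
    g_stat: float | None
    p_g: float | None
    p_fisher: float | None
    p_mw: float | None
    label: str
    top_tier: bool
    spi_flag: bool
    bh_fdr: float | None = None
    skip_reason: str | None = None

    @property
    def entry_name(self) -> str:
        return self.protein.entry_name


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def spectral_index(s: ProteinGroupSummary) -> float:
    """Spectral index SpI in [-1, 1]; positive means case-enriched.

    SpI = (d_B/N_B)(n_B/(n_A+n_B)) - (d_A/N_A)(n_A/(n_A+n_B)), where n are
    pooled group counts, d detection counts and N biological sample sizes.
    Equals +1 iff the protein is seen in every case sample and no control
    sample; antisymmetric under swapping group roles.
    """
    total = s.n_a + s.n_b
    if total == 0:
        raise UndefinedInputError(
            f"{s.entry_name}: SpI undefined when n_A + n_B = 0"
        )
    return (s.d_b / s.cap_n_b) * (s.n_b / total) - (s.d_a / s.cap_n_a) * (
        s.n_a / total
    )


def rsc_log2_ratio(s: ProteinGroupSummary, f: float = 0.5) -> float:
    """Log2 spectral-count ratio (case over control) with pseudocount.

    R_SC = log2((n_B+f)/(n_A+f)) + log2((t_A-n_A+f)/(t_B-n_B+f)); the
    second term corrects for unequal group totals.
    """
    if f <= 0:
        raise ParameterError(f"pseudocount f must be > 0, got {f}")
    if s.t_a < s.n_a or s.t_b < s.n_b:
        raise InconsistentSummaryError(
            f"{s.entry_name}: group total smaller than pooled count"
        )
    return math.log2((s.n_b + f) / (s.n_a + f)) + math.log2(
        (s.t_a - s.n_a + f) / (s.t_b - s.n_b + f)
    )


def _check_table(a: int, b: int, c: int, d: int) -> None:
    if min(a, b, c, d) < 0:
        raise ParameterError("contingency-table cells must be >= 0")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise DegenerateTableError(
            f"table ({a}, {b}; {c}, {d}) has a zero margin"
        )


def g_test_yates(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Yates-corrected G-test of independence on a 2x2 table.

    Rows are (target protein, all other proteins) and columns the two
    groups: ``a = n_A``, ``b = n_B``, ``c = t_A - n_A``, ``d = t_B - n_B``.
    Each observed cell is moved 0.5 toward its expectation (clamped so it
    never crosses it), then G = 2 sum O' ln(O'/E) over cells with O' > 0,
    referred to chi-square with 1 degree of freedom.
    """
    _check_table(a, b, c, d)
    a, b, c, d = int(a), int(b), int(c), int(d)
    total = a + b + c + d
    rows = (a + b, c + d)
    cols = (a + c, b + d)
    terms = []
    for (i, j), o in (((0, 0), a), ((0, 1), b), ((1, 0), c), ((1, 1), d)):
        rc = rows[i] * cols[j]
        diff2 = 2 * (o * total - rc)  # 2N(O - E), exact integer
        if abs(diff2) <= total:  # |O - E| <= 0.5: correction cancels the cell
            continue
        sign = 1 if diff2 > 0 else -1
        o_adj = o - 0.5 * sign
        if o_adj <= 0:
            continue
        # (O' - E)/E with an exact integer numerator avoids cancellation
        delta = (diff2 - sign * total) / (2 * rc)
        terms.append(o_adj * math.log1p(delta))
    g = max(2.0 * math.fsum(terms), 0.0)
    p = float(sps.chi2.sf(g, df=1))
    return g, max(p, np.nextafter(0, 1))


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for a 2x2 table (fixed margins): the sum
    of hypergeometric probabilities of all tables no more probable than
    the observed one."""
    _check_table(a, b, c, d)
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def _u_statistic(case: np.ndarray, control: np.ndarray) -> float:
    diff = case[:, None] - control[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def _exact_mw_p(values: np.ndarray, n_case: int, u_obs: float) -> float:
    """Two-sided p from the exact permutation distribution of U.

    Uses the rank-sum identity U = R_case - n_case(n_case+1)/2 with
    midranks (valid under ties) and enumerates all group-label
    assignments in vectorized chunks.  The two-sided p doubles the
    smaller tail (capped at 1), which stays valid when ties make the
    permutation distribution asymmetric.
    """
    ranks = sps.rankdata(values)
    const = n_case * (n_case + 1) / 2.0
    eps = 1e-9
    lo = hi = total = 0
    combos = itertools.combinations(range(values.size), n_case)
    while True:
        chunk = list(itertools.islice(combos, 100_000))
        if not chunk:
            break
        us = ranks[np.array(chunk)].sum(axis=1) - const
        lo += int((us <= u_obs + eps).sum())
        hi += int((us >= u_obs - eps).sum())
        total += us.size
    return min(1.0, 2.0 * min(lo, hi) / total)


def mann_whitney_groups(
    control_values: Sequence[float], case_values: Sequence[float]
) -> tuple[float, float]:
    """Mann-Whitney U test on per-sample pooled counts of one protein.

    U counts case wins (ties count one half).  The two-sided p comes from
    the exact permutation distribution of U over all group-label
    assignments when the combined sample count is at most 25 (feasible at
    typical study sizes and valid under ties), and otherwise from the
    tie-corrected normal approximation with continuity correction.
    """
    control = np.asarray(control_values, dtype=float)
    case = np.asarray(case_values, dtype=float)
    if control.size == 0 or case.size == 0:
        raise ParameterError("both groups must be non-empty")
    u_obs = _u_statistic(case, control)
    n = control.size + case.size
    if n <= MW_EXACT_MAX_N:
        values = np.concatenate([control, case])
        p = _exact_mw_p(values, case.size, u_obs)
    else:
        p = float(
            sps.mannwhitneyu(
                case, control, alternative="two-sided", method="asymptotic",
                use_continuity=True,
            ).pvalue
        )
    return u_obs, max(p, np.nextafter(0, 1))


# ---------------------------------------------------------------------------
# Classification and orchestration
# ---------------------------------------------------------------------------

def classify_protein(
    spi: float,
    rsc: float,
    p_g: float,
    thresholds: Thresholds = Thresholds(),
) -> tuple[str, bool, bool]:
    """Apply the joint significance rule.

    Returns ``(label, top_tier, spi_flag)``: case-characteristic iff
    p_G < alpha_g and R_SC > rsc_cut, control-characteristic iff
    p_G < alpha_g and R_SC < -rsc_cut; top tier additionally requires
    p_G < alpha_top and |R_SC| > rsc_top.  The spectral-index flag
    (|SpI| > spi_cut) is reported separately and never gates the label.
    """
    t = thresholds
    if p_g < t.alpha_g and rsc > t.rsc_cut:
        label = LABEL_CASE
    elif p_g < t.alpha_g and rsc < -t.rsc_cut:
        label = LABEL_CONTROL
    else:
        label = LABEL_NS
    top = label != LABEL_NS and p_g < t.alpha_top and abs(rsc) > t.rsc_top
    return label, top, abs(spi) > t.spi_cut


def _record_for_summary(
    protein: ProteinMeta,
    s: ProteinGroupSummary,
    control_values: np.ndarray,
    case_values: np.ndarray,
    thresholds: Thresholds,
    validate: bool,
) -> DiffExprRecord:
    if not s.observed:
        return DiffExprRecord(
            protein=protein, summary=s, spi=None, rsc=None,
            g_stat=None, p_g=None, p_fisher=None, p_mw=None,
            label=LABEL_NS, top_tier=False, spi_flag=False,
            skip_reason="never_observed",
        )
    spi = spectral_index(s)
    rsc = rsc_log2_ratio(s, f=thresholds.f)
    try:
        g, p_g = g_test_yates(s.n_a, s.n_b, s.t_a - s.n_a, s.t_b - s.n_b)
    except DegenerateTableError as exc:
        logger.info("G-test skipped for %s: %s", s.entry_name, exc)
        return DiffExprRecord(
            protein=protein, summary=s, spi=spi, rsc=rsc,
            g_stat=None, p_g=None, p_fisher=None, p_mw=None,
            label=LABEL_NS, top_tier=False,
            spi_flag=abs(spi) > thresholds.spi_cut,
            skip_reason="degenerate_table",
        )
    p_fisher = p_mw = None
    if validate:
        p_fisher = fisher_exact_2x2(s.n_a, s.n_b, s.t_a - s.n_a, s.t_b - s.n_b)
        _, p_mw = mann_whitney_groups(control_values, case_values)
    label, top, spi_flag = classify_protein(spi, rsc, p_g, thresholds)
    return DiffExprRecord(
        protein=protein, summary=s, spi=spi, rsc=rsc,
        g_stat=g, p_g=p_g, p_fisher=p_fisher, p_mw=p_mw,
        label=label, top_tier=top, spi_flag=spi_flag,
    )


def run_differential_table(
    matrix: CountMatrix,
    thresholds: Thresholds = Thresholds(),
    detection_threshold: int = 1,
    validate: bool = True,
) -> list[DiffExprRecord]:
    """Full per-protein differential analysis of a count matrix.

    Pools technical replicates, summarizes the two groups, computes SpI,
    R_SC, the Yates-corrected G-test and (when ``validate``) the Fisher
    and Mann-Whitney validation p-values, classifies each protein and
    returns records sorted by descending SpI (entry name breaks ties;
    skipped proteins sort last).  A Benjamini-Hochberg FDR over the
    G-test p-values is attached for information only; it never enters the
    classification.
    """
    pooled = pool_replicates(matrix)
    summaries = summarize_groups(pooled, detection_threshold=detection_threshold)
    design = pooled.design
    mask_a = np.array([c.group == design.control_label for c in design.columns])
    records = [
        _record_for_summary(
            pooled.proteins[i], s, pooled.counts[i, mask_a],
            pooled.counts[i, ~mask_a], thresholds, validate,
        )
        for i, s in enumerate(summaries)
    ]

    tested = [r for r in records if r.p_g is not None]
    if tested:
        fdr = sps.false_discovery_control([r.p_g for r in tested], method="bh")
        by_name = {r.entry_name: q for r, q in zip(tested, fdr)}
        records = [
            DiffExprRecord(**{**r.__dict__, "bh_fdr": by_name.get(r.entry_name)})
            for r in records
        ]

    def key(r: DiffExprRecord):
        return (r.spi is None, -(r.spi if r.spi is not None else 0.0), r.entry_name)

    return sorted(records, key=key)
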