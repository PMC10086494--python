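"""Rare-variant tagging of a founder haplotype.

A founder haplotype is expected to carry rare variants (background
frequency below ~0.5%) that travel with the focal allele; their
over-representation in carriers versus the background population is
direct evidence of shared descent.  This module selects rare sites in a
window around the focal variant and tests each with Fisher's exact test
on the carrier/background 2x2 table.

The exact test is computed from hypergeometric probabilities in log-space
(log-gamma factorials), which stays numerically stable at cohort sizes of
10^5-10^6 where naive factorial ratios overflow.  The two-sided p-value
follows the standard "sum of all tables no more probable than the
observed" rule; the one-sided p is the enrichment upper tail P(A >= a).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .haplotype_io import CarrierSet, HaplotypeMatrix, Site
from .variants import VariantRecord

#: Relative tolerance for "no more probable than observed" ties; tables
#: whose probability exceeds the observed by less than this relative
#: margin still count into the two-sided sum (guards float round-off).
TIE_RTOL = 1e-7


class DegenerateTableError(ValueError):
    """A margin of the 2x2 table is empty, so the test is undefined."""


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: a/b = carriers with/without the variant, c/d = background
    with/without."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class ContingencyResult:
    table: ContingencyTable
    p_two_sided: float
    p_one_sided_enrichment: float
    odds_ratio: float
    #: P(A > a) under the null — with P(A = a) this yields the randomized
    #: p-value  P(A > a) + U * P(A = a),  exactly Uniform(0,1) under the
    #: null despite the discreteness of the exact test.
    p_strictly_greater: float

    def randomized_p(self, u: float) -> float:
        return self.p_strictly_greater + u * (
            self.p_one_sided_enrichment - self.p_strictly_greater
        )


def _log_hypergeom_pmf(support: np.ndarray, r1: int, c1: int, n: int) -> np.ndarray:
    # log C(r1, k) + log C(n - r1, c1 - k) - log C(n, c1)
    def log_comb(m: int | np.ndarray, k: np.ndarray) -> np.ndarray:
        return gammaln(m + 1) - gammaln(k + 1) - gammaln(m - k + 1)

    return (
        log_comb(r1, support)
        + log_comb(n - r1, c1 - support)
        - float(log_comb(np.array(n), np.array(c1)))
    )


def fisher_exact_class(
    r1: int, c1: int, n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Exact-test p-values for every table sharing the margins (r1, c1, n).

    Returns ``(support, p_two_sided, p_one_sided, p_strictly_greater)``,
    one entry per feasible count a in the hypergeometric support.  All
    tables with the same margins share one pmf evaluation, so callers
    sweeping a whole margin class (power scans, enumeration checks) pay
    the log-gamma cost once.
    """
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    logp = _log_hypergeom_pmf(support, r1, c1, n)
    # Two-sided "no more probable than observed": sort the pmf, prefix-sum
    # in log space, and look each table's threshold up by rank.
    order = np.argsort(logp, kind="stable")
    sorted_logp = logp[order]
    cum = np.logaddexp.accumulate(sorted_logp)
    ranks = np.searchsorted(sorted_logp, logp + math.log1p(TIE_RTOL), side="right")
    p_two = np.exp(cum[ranks - 1])
    # Upper tails: accumulate from the right.
    tail = np.logaddexp.accumulate(logp[::-1])[::-1]
    p_one = np.exp(tail)
    p_strict = np.empty_like(p_one)
    p_strict[:-1] = p_one[1:]
    p_strict[-1] = 0.0
    return support, np.minimum(p_two, 1.0), np.minimum(p_one, 1.0), p_strict


def fisher_exact_2x2(table: ContingencyTable) -> ContingencyResult:
    """Fisher's exact test on a 2x2 table, log-space hypergeometric.

    Raises :class:`DegenerateTableError` when a row margin is empty (no
    carriers or no background), in which case no table probability is
    defined.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, c1, n = a + b, a + c, table.total
    if r1 == 0 or c + d == 0:
        raise DegenerateTableError(f"empty row margin in table {table}")
    if n == 0:
        raise DegenerateTableError("empty table")
    support, p_two, p_one, p_strict = fisher_exact_class(r1, c1, n)
    i = a - int(support[0])
    odds = math.inf if b * c == 0 else (a * d) / (b * c)
    return ContingencyResult(
        table=table,
        p_two_sided=float(p_two[i]),
        p_one_sided_enrichment=float(p_one[i]),
        odds_ratio=odds,
        p_strictly_greater=float(min(p_strict[i], 1.0)),
    )


def select_rare_window(
    sites: list[Site],
    focal: VariantRecord,
    window_bp: int = 1_000_000,
    freq_max: float = 0.005,
) -> list[Site]:
    """Rare sites within ``window_bp`` (total width, centred on the focal
    position) whose alt frequency is strictly below ``freq_max``, excluding
    the focal site itself.

    Sites must come from an unfiltered load (frequency filter disabled),
    otherwise rare variants were already discarded.
    """
    half = window_bp / 2
    out = []
    for s in sites:
        if s.chrom != focal.chrom or s.matches(focal):
            continue
        if abs(s.pos - focal.pos) <= half and s.alt_frequency < freq_max:
            out.append(s)
    return out


def background_sites(
    matrix: HaplotypeMatrix, carriers: CarrierSet
) -> list[Site]:
    """Site copies whose allele statistics are recomputed over non-carrier
    samples only.

    Rare-site selection thresholds refer to the background population;
    whole-cohort frequencies would be inflated by the very carriers under
    test whenever the cohort is small.
    """
    from dataclasses import replace

    from .haplotype_io import MISSING

    carrier_samples = set(carriers.sample_ids)
    rows = np.array(
        [
            2 * i + k
            for i, s in enumerate(matrix.samples)
            if s not in carrier_samples
            for k in (0, 1)
        ],
        dtype=np.intp,
    )
    out = []
    for j, site in enumerate(matrix.sites):
        col = matrix.alleles[rows, j]
        obs = col != MISSING
        n_obs = int(obs.sum())
        freq = float(col[obs].sum() / n_obs) if n_obs else 0.0
        out.append(
            replace(site, alt_frequency=freq, missing_rate=1.0 - n_obs / col.size)
        )
    return out


@dataclass
class TagAssociation:
    site: Site
    result: ContingencyResult
    p_bonferroni: float


def tag_report(
    matrix: HaplotypeMatrix,
    carriers: CarrierSet,
    rare_sites: list[Site],
    one_per_family: list[str] | None = None,
) -> list[TagAssociation]:
    """One exact-test row per rare site: carriers vs background.

    A sample counts as "with variant" if the rare alt is present on either
    haplotype (genotype-level dosage >= 1).  When ``one_per_family`` is
    given only those carrier representatives are counted in the carrier
    column; all carriers (representatives or not) stay excluded from the
    background.  The Bonferroni column multiplies the two-sided p by the
    number of rare sites tested (raw p values are the primary output).
    """
    counted = (
        carriers.restricted(one_per_family) if one_per_family else carriers
    )
    counted_idx = [matrix.sample_index(s) for s in counted.sample_ids]
    all_carrier = set(carriers.sample_ids)
    background_idx = [
        i for i, s in enumerate(matrix.samples) if s not in all_carrier
    ]

    def dosage_ge1(sample_indices: list[int], j: int) -> int:
        col = matrix.alleles[:, j]
        return sum(
            1
            for i in sample_indices
            if col[2 * i] == 1 or col[2 * i + 1] == 1
        )

    rows = []
    m = len(rare_sites)
    for site in rare_sites:
        j = next(
            k
            for k, s in enumerate(matrix.sites)
            if (s.chrom, s.pos, s.ref, s.alt)
            == (site.chrom, site.pos, site.ref, site.alt)
        )
        a = dosage_ge1(counted_idx, j)
        c = dosage_ge1(background_idx, j)
        table = ContingencyTable(
            a=a, b=len(counted_idx) - a, c=c, d=len(background_idx) - c
        )
        res = fisher_exact_2x2(table)
        rows.append(
            TagAssociation(site, res, min(1.0, res.p_two_sided * max(m, 1)))
        )
    return rows
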