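"""Shared-haplotype core detection around a focal variant.

Carriers of a founder variant inherit, besides the variant itself, a
stretch of the founder's chromosome that recombination has not yet broken
up.  Given phased genotypes and the focal haplotype of each carrier, this
module builds the carrier consensus haplotype, measures how far each
carrier matches it on either side of the focal site, intersects those
extents into the minimal shared core, and counts how often that core
occurs among background (non-carrier) haplotypes — the "<1 in K" evidence
that the sharing is not chance.

Missing alleles never match the consensus (conservative).  All scans are
deterministic: majority-vote ties go to the allele of the first carrier in
sample-ID sort order, and the mismatch tolerance is budgeted per direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .haplotype_io import MISSING, CarrierSet, HaplotypeMatrix, Site


class SharedCoreError(ValueError):
    pass


@dataclass
class ConsensusHaplotype:
    """Per-site majority allele over the carrier focal haplotypes."""

    sites: list[Site]
    alleles: np.ndarray  # one of {0, 1, MISSING} per site
    support: np.ndarray  # carriers matching the consensus allele per site
    n_carriers: int


@dataclass(frozen=True)
class ExtentInterval:
    """Maximal consensus-matching run around the focal site for one carrier.

    ``left_pos``/``right_pos`` are the outermost *matched* site positions;
    within the run the carrier mismatches the consensus at most
    ``tolerance`` sites per direction.
    """

    carrier: str
    left_pos: int
    right_pos: int
    n_sites: int
    left_index: int
    right_index: int

    @property
    def span_bp(self) -> int:
        return self.right_pos - self.left_pos


@dataclass
class SharedCoreResult:
    """Intersection of all carrier extents, with its background frequency."""

    core_left: int
    core_right: int
    core_site_indices: np.ndarray
    core_alleles: np.ndarray
    background_matches: int = 0
    background_total: int = 0
    frequency_text: str = ""

    @property
    def core_interval(self) -> tuple[int, int]:
        return (self.core_left, self.core_right)


def consensus_haplotype(
    matrix: HaplotypeMatrix, carriers: CarrierSet
) -> ConsensusHaplotype:
    """Majority vote across carrier focal haplotypes at every site.

    Ties (equal 0/1 counts, missing alleles abstaining) are broken toward
    the allele of the first carrier in sample-ID sort order, falling back
    through that order past missing alleles so reruns are reproducible.
    """
    if len(carriers) == 0:
        raise SharedCoreError("consensus requires at least one carrier")
    order = sorted(range(len(carriers)), key=lambda i: carriers.carriers[i][0])
    rows = carriers.haplotype_rows(matrix)
    hap = matrix.alleles[rows]  # carriers x sites
    ones = (hap == 1).sum(axis=0)
    zeros = (hap == 0).sum(axis=0)
    # First non-missing allele in sample-ID sort order, for tie-breaking.
    fallback = np.full(matrix.n_sites, MISSING, dtype=np.int8)
    for i in order:
        fallback = np.where(fallback == MISSING, hap[i], fallback)
    alleles = np.where(
        ones > zeros, 1, np.where(zeros > ones, 0, fallback)
    ).astype(np.int8)
    support = ((hap == alleles) & (alleles != MISSING)).sum(axis=0)
    return ConsensusHaplotype(
        sites=list(matrix.sites),
        alleles=alleles,
        support=support.astype(np.int64),
        n_carriers=len(carriers),
    )


def _scan(match: np.ndarray, start: int, step: int, tolerance: int) -> int:
    """Outermost matched index walking from ``start`` by ``step`` with a
    per-direction mismatch budget."""
    budget = tolerance
    last = start
    j = start + step
    while 0 <= j < match.size:
        if match[j]:
            last = j
        else:
            budget -= 1
            if budget < 0:
                break
        j += step
    return last


def carrier_extent(
    matrix: HaplotypeMatrix,
    carrier: tuple[str, int],
    consensus: ConsensusHaplotype,
    focal_index: int,
    mismatch_tolerance: int = 0,
) -> ExtentInterval:
    """Extent of consensus matching around the focal site for one carrier.

    Scans outward from the focal site separately left and right; each
    direction stops just before its (tolerance+1)-th mismatch, and the
    reported boundary is the outermost matched site, so trailing tolerated
    mismatches are not counted into the extent.
    """
    if mismatch_tolerance < 0:
        raise SharedCoreError("mismatch tolerance must be >= 0")
    sample_id, which = carrier
    hap = matrix.haplotype(matrix.sample_index(sample_id), which)
    match = (hap == consensus.alleles) & (consensus.alleles != MISSING)
    left = _scan(match, focal_index, -1, mismatch_tolerance)
    right = _scan(match, focal_index, +1, mismatch_tolerance)
    positions = matrix.positions
    return ExtentInterval(
        carrier=sample_id,
        left_pos=int(positions[left]),
        right_pos=int(positions[right]),
        n_sites=int(match[left : right + 1].sum()),
        left_index=left,
        right_index=right,
    )


def minimal_core(
    extents: list[ExtentInterval], consensus: ConsensusHaplotype
) -> SharedCoreResult:
    """Intersect carrier extents into the minimal shared core.

    The core is ``[max(left_pos), min(right_pos)]``; it contains the focal
    site by construction since every extent does.
    """
    if not extents:
        raise SharedCoreError("minimal core requires at least one extent")
    left = max(e.left_pos for e in extents)
    right = min(e.right_pos for e in extents)
    positions = np.array([s.pos for s in consensus.sites], dtype=np.int64)
    idx = np.flatnonzero((positions >= left) & (positions <= right))
    return SharedCoreResult(
        core_left=left,
        core_right=right,
        core_site_indices=idx,
        core_alleles=consensus.alleles[idx].copy(),
    )


def background_frequency(
    matrix: HaplotypeMatrix, core: SharedCoreResult, exclude: CarrierSet
) -> SharedCoreResult:
    """Count background haplotypes matching the core alleles at every core
    site.

    Background = both haplotypes of every sample outside the carrier set
    (plus any caller-supplied relatives already dropped from the matrix).
    A missing allele counts as a mismatch.  The frequency is formatted
    "1 in K" with K = floor(total / matches).
    """
    carrier_samples = set(exclude.sample_ids)
    rows = np.array(
        [
            2 * i + k
            for i, s in enumerate(matrix.samples)
            if s not in carrier_samples
            for k in (0, 1)
        ],
        dtype=np.intp,
    )
    sub = matrix.alleles[np.ix_(rows, core.core_site_indices)]
    matches = int(np.all(sub == core.core_alleles, axis=1).sum())
    total = rows.size
    if matches == 0:
        text = f"0 matches in {total}"
    else:
        text = f"1 in {total // matches}"
    core.background_matches = matches
    core.background_total = total
    core.frequency_text = text
    return core


def match_matrix(
    matrix: HaplotypeMatrix, carriers: CarrierSet, consensus: ConsensusHaplotype
) -> np.ndarray:
    """Carriers x sites indicator of agreement with the consensus (the text
    analogue of a shared-haplotype heat strip: 1 match, 0 mismatch)."""
    hap = matrix.alleles[carriers.haplotype_rows(matrix)]
    return ((hap == consensus.alleles) & (consensus.alleles != MISSING)).astype(
        np.int8
    )


@dataclass
class SharedCoreAnalysis:
    """Bundle of the full shared-core computation for one cohort."""

    consensus: ConsensusHaplotype
    extents: list[ExtentInterval]
    core: SharedCoreResult
    focal_index: int

    @property
    def extent_span_bp(self) -> tuple[int, int]:
        """(min, max) carrier extent length in bp — the "extends from X Mb
        to Y Mb between individuals" summary."""
        spans = [e.span_bp for e in self.extents]
        return (min(spans), max(spans))


def shared_core_analysis(
    matrix: HaplotypeMatrix,
    carriers: CarrierSet,
    mismatch_tolerance: int = 0,
) -> SharedCoreAnalysis:
    """Consensus -> per-carrier extents -> minimal core -> background count."""
    focal_index = matrix.site_index(carriers.focal)
    consensus = consensus_haplotype(matrix, carriers)
    extents = [
        carrier_extent(matrix, c, consensus, focal_index, mismatch_tolerance)
        for c in carriers.carriers
    ]
    core = minimal_core(extents, consensus)
    core = background_frequency(matrix, core, carriers)
    return SharedCoreAnalysis(consensus, extents, core, focal_index)
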