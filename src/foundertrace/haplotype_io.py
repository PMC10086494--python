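"""Phased genotypes as a haplotype matrix.

A cohort of N samples phased at M biallelic sites is held as a 2N x M
allele matrix (0 = ref, 1 = alt, -1 = missing); haplotype row
``2 * sample_index + k`` is haplotype k of that sample.  Loading applies
the site filters used for haplotype analysis — minor allele frequency
strictly above ``maf_min`` and missing rate strictly below
``missing_max`` — or retains all sites when the frequency filter is
disabled (``maf_min=0``), as rare-variant tagging requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from cyvcf2 import VCF

from .variants import VariantRecord

MISSING = -1


class VcfFormatError(ValueError):
    """Malformed or unsupported VCF content."""


class UnphasedGenotypeError(VcfFormatError):
    """A diploid genotype uses '/' where phased '|' input is required."""


class FocalSiteError(ValueError):
    """Focal variant absent from the matrix, or carrier not heterozygous."""


@dataclass(frozen=True)
class Site:
    """One biallelic site with its cohort allele statistics."""

    chrom: str
    pos: int
    ref: str
    alt: str
    alt_frequency: float
    missing_rate: float

    @property
    def minor_allele_frequency(self) -> float:
        return min(self.alt_frequency, 1.0 - self.alt_frequency)

    @property
    def vcf_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    def matches(self, v: VariantRecord) -> bool:
        return (
            self.chrom == v.chrom
            and self.pos == v.pos
            and self.ref == v.ref
            and self.alt == v.alt
        )


@dataclass
class HaplotypeMatrix:
    """Phased haplotypes of a cohort: ``alleles[2*i + k, j]`` is haplotype k
    of sample i at site j (0 ref / 1 alt / -1 missing)."""

    samples: list[str]
    alleles: np.ndarray
    sites: list[Site]

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape != (2 * len(self.samples), len(self.sites)):
            raise ValueError(
                f"allele matrix shape {self.alleles.shape} does not match "
                f"{len(self.samples)} samples x {len(self.sites)} sites"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    def haplotype(self, sample_index: int, which: int) -> np.ndarray:
        return self.alleles[2 * sample_index + which]

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in matrix") from None

    def site_index(self, v: VariantRecord) -> int:
        for j, s in enumerate(self.sites):
            if s.matches(v):
                return j
        raise FocalSiteError(f"site {v.vcf_id} not present in matrix")

    def filtered(
        self,
        maf_min: float = 0.0,
        missing_max: float = 1.0,
        keep: VariantRecord | None = None,
    ) -> "HaplotypeMatrix":
        """Return a copy restricted to sites passing the filters.

        Strict thresholds: minor allele frequency > ``maf_min`` and missing
        rate < ``missing_max``.  ``maf_min=0`` / ``missing_max=1`` disable
        the respective filter.  A site matching ``keep`` is always retained
        (the focal variant must survive common-variant filtering).
        """
        mask = []
        for s in self.sites:
            ok = True
            if maf_min > 0 and not s.minor_allele_frequency > maf_min:
                ok = False
            if missing_max < 1 and not s.missing_rate < missing_max:
                ok = False
            if keep is not None and s.matches(keep):
                ok = True
            mask.append(ok)
        idx = np.flatnonzero(mask)
        return HaplotypeMatrix(
            samples=list(self.samples),
            alleles=self.alleles[:, idx],
            sites=[self.sites[j] for j in idx],
        )

    def drop_samples(self, sample_ids: set[str]) -> "HaplotypeMatrix":
        keep = [i for i, s in enumerate(self.samples) if s not in sample_ids]
        rows = np.array([2 * i + k for i in keep for k in (0, 1)], dtype=np.intp)
        return HaplotypeMatrix(
            samples=[self.samples[i] for i in keep],
            alleles=self.alleles[rows],
            sites=list(self.sites),
        )


@dataclass
class CarrierSet:
    """Samples heterozygous for the focal variant, with the haplotype
    (0 or 1) that carries it resolved per sample."""

    carriers: list[tuple[str, int]]
    focal: VariantRecord
    one_per_family: list[str] | None = None

    def __len__(self) -> int:
        return len(self.carriers)

    @property
    def sample_ids(self) -> list[str]:
        return [s for s, _ in self.carriers]

    def restricted(self, representatives: list[str]) -> "CarrierSet":
        """Keep one representative per family (Table-2-style counting)."""
        wanted = set(representatives)
        kept = [(s, h) for s, h in self.carriers if s in wanted]
        missing = wanted - {s for s, _ in kept}
        if missing:
            raise KeyError(f"representatives not in carrier set: {sorted(missing)}")
        return CarrierSet(kept, self.focal, one_per_family=list(representatives))

    def haplotype_rows(self, matrix: HaplotypeMatrix) -> np.ndarray:
        """Row indices of each carrier's focal haplotype in the matrix."""
        return np.array(
            [2 * matrix.sample_index(s) + h for s, h in self.carriers],
            dtype=np.intp,
        )


def _site_stats(col: np.ndarray) -> tuple[float, float]:
    observed = col != MISSING
    n_obs = int(observed.sum())
    alt_freq = float(col[observed].sum() / n_obs) if n_obs else 0.0
    return alt_freq, 1.0 - n_obs / col.size


def read_phased_vcf(
    path: str,
    region: tuple[str, int, int] | None = None,
    maf_min: float = 0.0,
    missing_max: float = 1.0,
    assume_phased_hom: bool = False,
    keep: VariantRecord | None = None,
    snv_only: bool | None = None,
) -> HaplotypeMatrix:
    """Load phased GT fields from a VCF into a :class:`HaplotypeMatrix`.

    Parameters
    ----------
    region
        Half-open ``(chrom, start, end)`` interval on 1-based positions;
        ``None`` loads everything.
    maf_min, missing_max
        Strict site filters (see :meth:`HaplotypeMatrix.filtered`); allele
        statistics are computed over the loaded samples before filtering.
    assume_phased_hom
        Accept '/'-separated genotypes when both alleles agree (homozygous
        sites carry no phase information).
    keep
        A variant (typically the focal one) retained regardless of filters.
    snv_only
        Restrict to single-nucleotide sites.  Defaults to True when the
        frequency filter is active (common-variant haplotype mode) and
        False otherwise, so unfiltered loads retain indels such as the
        focal delins.

    Multi-allelic records are skipped (biallelic decomposition is out of
    scope).  Unphased heterozygous genotypes raise
    :class:`UnphasedGenotypeError`.
    """
    if snv_only is None:
        snv_only = maf_min > 0
    vcf = VCF(path)
    samples = list(vcf.samples)
    if not samples:
        raise VcfFormatError(f"{path}: VCF has no sample columns")
    columns: list[np.ndarray] = []
    sites: list[Site] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue
        chrom, pos, ref, alt = rec.CHROM, rec.POS, rec.REF, rec.ALT[0]
        if region is not None:
            rchrom, start, end = region
            if chrom != rchrom or not (start <= pos < end):
                continue
        if snv_only and not (len(ref) == 1 and len(alt) == 1):
            continue
        col = np.full(2 * len(samples), MISSING, dtype=np.int8)
        for i, gt in enumerate(rec.genotypes):
            *alleles_i, phased = gt
            if len(alleles_i) != 2:
                raise VcfFormatError(
                    f"{chrom}:{pos}: sample {samples[i]} is not diploid"
                )
            a, b = alleles_i
            if not phased:
                hom = a == b
                if not (assume_phased_hom and hom):
                    raise UnphasedGenotypeError(
                        f"{chrom}:{pos}: sample {samples[i]} genotype is "
                        "unphased ('/'); phased input required"
                    )
            col[2 * i] = a if a >= 0 else MISSING
            col[2 * i + 1] = b if b >= 0 else MISSING
        alt_freq, miss = _site_stats(col)
        sites.append(Site(chrom, pos, ref, alt, alt_freq, miss))
        columns.append(col)
    alleles = (
        np.stack(columns, axis=1)
        if columns
        else np.empty((2 * len(samples), 0), dtype=np.int8)
    )
    order = np.lexsort(([s.pos for s in sites], [s.chrom for s in sites]))
    matrix = HaplotypeMatrix(
        samples=samples,
        alleles=alleles[:, order],
        sites=[sites[j] for j in order],
    )
    return matrix.filtered(maf_min=maf_min, missing_max=missing_max, keep=keep)


def write_phased_vcf(matrix: HaplotypeMatrix, path: str) -> None:
    """Write the matrix as an uncompressed phased VCF (GT-only).

    The emitter is deliberately plain text with a fixed layout so that a
    fixed simulation seed yields a byte-identical file; reading the file
    back reproduces alleles and site order exactly.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(s.chrom for s in matrix.sites):
            max_pos = max(s.pos + len(s.ref) for s in matrix.sites if s.chrom == chrom)
            fh.write(f"##contig=<ID={chrom},length={max_pos + 1}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        sym = {0: "0", 1: "1", MISSING: "."}
        for j, s in enumerate(matrix.sites):
            col = matrix.alleles[:, j]
            gts = "\t".join(
                f"{sym[int(col[2 * i])]}|{sym[int(col[2 * i + 1])]}"
                for i in range(matrix.n_samples)
            )
            fh.write(f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\t.\t.\tGT\t{gts}\n")


def focal_carriers(matrix: HaplotypeMatrix, focal: VariantRecord) -> CarrierSet:
    """Resolve heterozygous carriers of the focal variant and the haplotype
    bearing it.

    Samples homozygous for the focal alt raise :class:`FocalSiteError`:
    the founder model assumes heterozygous carriers, so a homozygote
    signals either consanguinity or a genotyping artefact that the caller
    must resolve.
    """
    j = matrix.site_index(focal)
    col = matrix.alleles[:, j]
    carriers: list[tuple[str, int]] = []
    for i, sample in enumerate(matrix.samples):
        a, b = int(col[2 * i]), int(col[2 * i + 1])
        n_alt = (a == 1) + (b == 1)
        if n_alt == 2:
            raise FocalSiteError(
                f"sample {sample} is homozygous for focal {focal.vcf_id}; "
                "heterozygous carriers expected"
            )
        if n_alt == 1:
            carriers.append((sample, 0 if a == 1 else 1))
    return CarrierSet(carriers, focal)


def read_sample_list(path: str) -> list[str]:
    """One sample ID per line; blank lines and '#' comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out
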