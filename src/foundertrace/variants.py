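"""Sequence-variant representation, normalization, and equivalence.

A complex delins (delete one sequence, insert another at the same locus)
admits many VCF representations that all edit the reference into the same
product.  Variant callers routinely emit several of them for the same
underlying event — the focal uromodulin delins studied here was emitted as
six distinct records across carriers.  This module provides the canonical
left-aligned form and an edited-product equivalence relation so such calls
can be unified into a single variant class.

Coordinates are 1-based throughout, as in VCF; REF and ALT are anchored,
non-empty A/C/G/T strings.
"""

from __future__ import annotations

from dataclasses import dataclass

_VALID_BASES = frozenset("ACGT")


class VariantError(ValueError):
    """Base class for variant-representation errors."""


class ReferenceMismatchError(VariantError):
    """Window sequence does not carry the variant's REF allele."""


class OutOfWindowError(VariantError):
    """Variant span (or a required left-shift) exits the reference window."""


def _check_allele(name: str, allele: str) -> None:
    if not allele:
        raise VariantError(f"{name} allele must be non-empty")
    if not set(allele) <= _VALID_BASES:
        raise VariantError(f"{name} allele {allele!r} contains non-ACGT characters")


@dataclass(frozen=True, order=True)
class VariantRecord:
    """One sequence change: ``chrom:pos:ref:alt`` with a 1-based position."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VariantError(f"pos must be >= 1, got {self.pos}")
        _check_allele("ref", self.ref)
        _check_allele("alt", self.alt)
        if self.ref == self.alt:
            raise VariantError("ref and alt must differ")

    @property
    def end(self) -> int:
        """1-based inclusive position of the last REF base."""
        return self.pos + len(self.ref) - 1

    @property
    def vcf_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @classmethod
    def from_id(cls, text: str) -> "VariantRecord":
        """Parse a ``chrom:pos:ref:alt`` identifier."""
        parts = text.split(":")
        if len(parts) != 4:
            raise VariantError(f"expected chrom:pos:ref:alt, got {text!r}")
        chrom, pos, ref, alt = parts
        return cls(chrom, int(pos), ref.upper(), alt.upper())


@dataclass(frozen=True)
class ReferenceWindow:
    """A slice of reference sequence: ``sequence`` starts at 1-based ``start``."""

    chrom: str
    start: int
    sequence: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise VariantError(f"window start must be >= 1, got {self.start}")
        if not self.sequence:
            raise VariantError("window sequence must be non-empty")
        if not set(self.sequence) <= _VALID_BASES:
            raise VariantError("window sequence contains non-ACGT characters")

    @property
    def end(self) -> int:
        """1-based inclusive end position."""
        return self.start + len(self.sequence) - 1

    def contains(self, v: VariantRecord) -> bool:
        return v.chrom == self.chrom and v.pos >= self.start and v.end <= self.end

    def base_at(self, pos: int) -> str:
        return self.sequence[pos - self.start]


def apply_edit(window: ReferenceWindow, v: VariantRecord) -> str:
    """Return the window sequence with the variant's REF span replaced by ALT.

    Raises :class:`OutOfWindowError` if the variant does not lie fully inside
    the window and :class:`ReferenceMismatchError` if the window bases under
    the variant differ from its REF allele.
    """
    if not window.contains(v):
        raise OutOfWindowError(
            f"variant {v.vcf_id} not contained in window "
            f"{window.chrom}:{window.start}-{window.end}"
        )
    lo = v.pos - window.start
    hi = lo + len(v.ref)
    observed = window.sequence[lo:hi]
    if observed != v.ref:
        raise ReferenceMismatchError(
            f"window has {observed!r} at {v.chrom}:{v.pos}, variant claims {v.ref!r}"
        )
    return window.sequence[:lo] + v.alt + window.sequence[hi:]


def normalize(v: VariantRecord, window: ReferenceWindow) -> VariantRecord:
    """Canonical minimal left-aligned representation of ``v``.

    The canonical form trims the shared suffix, left-shifts through repeat
    context while the representation stays anchored (each step replaces a
    shared trailing base with the reference base preceding the variant),
    then trims the shared prefix, always leaving at least one base in each
    allele.  This is standard VCF-style left alignment, so round-trips
    ``chrom:pos:ref:alt`` identifiers produced by common tooling.

    Raises :class:`OutOfWindowError` when a left shift would require
    reference context before the window start.
    """
    # Validates containment and REF agreement up front.
    apply_edit(window, v)

    pos, ref, alt = v.pos, v.ref, v.alt
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        elif ref[-1] == alt[-1]:
            # Anchored indel whose alleles still share a trailing base:
            # shift one base left, pulling in the preceding reference base.
            if pos <= window.start:
                raise OutOfWindowError(
                    f"left-aligning {v.vcf_id} needs context before "
                    f"window start {window.start}"
                )
            prev = window.base_at(pos - 1)
            ref, alt, pos = prev + ref[:-1], prev + alt[:-1], pos - 1
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    return VariantRecord(v.chrom, pos, ref, alt)


def equivalent(v1: VariantRecord, v2: VariantRecord, window: ReferenceWindow) -> bool:
    """True iff the two variants edit the window into the same product."""
    return apply_edit(window, v1) == apply_edit(window, v2)


def unify(
    variants: list[VariantRecord], window: ReferenceWindow
) -> list[tuple[VariantRecord, list[VariantRecord]]]:
    """Partition variants into edited-product equivalence classes.

    Returns one ``(canonical_representative, members)`` pair per class, in
    order of first appearance.  The representative is the normalized form of
    the first member; every member of a class normalizes to that same form.
    """
    classes: dict[str, list[VariantRecord]] = {}
    for v in variants:
        classes.setdefault(apply_edit(window, v), []).append(v)
    return [(normalize(members[0], window), members) for members in classes.values()]
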