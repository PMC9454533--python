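"""Domain types for annotated somatic variants and allele normalization.

A variant's *identity* is its normalized ``(chrom, pos, ref, alt)`` key;
everything else (gene, VAF, quality, evidence codes) is an attribute.
This makes "the same variant seen in two body fluids" well defined even
when the two callers emitted different but equivalent representations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

__all__ = [
    "EFFECTS",
    "EVIDENCE_CODES",
    "CLINICAL_EVIDENCE_LEVELS",
    "FLUIDS",
    "InvalidVariantError",
    "AnnotatedVariant",
    "PatientPair",
    "normalize_variant",
]

#: Controlled vocabulary for the predicted molecular consequence of a variant.
EFFECTS = frozenset(
    {
        "frameshift",
        "inframe_indel",
        "start_loss",
        "stop_change",
        "missense",
        "synonymous",
        "splice_region",
        "intronic",
        "copy_number_loss",
        "other",
    }
)

#: ACMG/AMP 2015 evidence-code alphabet.
EVIDENCE_CODES = frozenset(
    {"PVS1"}
    | {f"PS{i}" for i in range(1, 5)}
    | {f"PM{i}" for i in range(1, 7)}
    | {f"PP{i}" for i in range(1, 6)}
    | {"BA1"}
    | {f"BS{i}" for i in range(1, 5)}
    | {f"BP{i}" for i in range(1, 8)}
)

CLINICAL_EVIDENCE_LEVELS = frozenset({"A", "B", "C", "D", "none"})

FLUIDS = ("plasma", "urine")

_BASES = frozenset("ACGT")


class InvalidVariantError(ValueError):
    """Raised when allele strings or coordinates violate the variant contract."""


def _strip_chr(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def normalize_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    reference: Mapping[str, str] | Callable[[str, int], str] | None = None,
) -> tuple[str, int, str, str]:
    """Return the canonical minimal representation of ``(chrom, pos, ref, alt)``.

    Shared trailing bases are trimmed first, then shared leading bases are
    trimmed with ``pos`` advanced, always keeping at least one base on each
    allele.  When a ``reference`` context is supplied (a mapping from
    chromosome to sequence, or a callable ``(chrom, pos) -> base`` with
    1-based ``pos``), indels are additionally shifted left as far as the
    context allows, yielding the unique leftmost minimal representation.

    The operation is idempotent.  Coordinates are 1-based; the chromosome
    name is compared after stripping an optional ``chr`` prefix but returned
    as given (minus that prefix).

    Raises
    ------
    InvalidVariantError
        If an allele is empty, contains a non-ACGT character, ``pos < 1``,
        or ``ref == alt`` (no variant left after trimming).
    """
    if pos < 1:
        raise InvalidVariantError(f"pos must be >= 1, got {pos}")
    ref = ref.upper()
    alt = alt.upper()
    if not ref or not alt:
        raise InvalidVariantError("empty allele string")
    if not set(ref) <= _BASES or not set(alt) <= _BASES:
        raise InvalidVariantError(f"non-ACGT allele: {ref!r}/{alt!r}")
    if ref == alt:
        raise InvalidVariantError(f"ref == alt ({ref!r}): not a variant")
    chrom = _strip_chr(chrom)

    get_base: Callable[[str, int], str] | None
    if reference is None:
        get_base = None
    elif callable(reference):
        get_base = reference
    else:
        seqs = reference
        get_base = lambda c, p: seqs[_strip_chr(c)][p - 1].upper()  # noqa: E731

    while True:
        # Right-trim a shared trailing base (keep >= 1 base per allele);
        # with reference context an exhausted allele is refilled from the
        # left so the indel keeps shifting toward the 5' end.
        if ref[-1] == alt[-1] and (len(ref) > 1 and len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
        elif get_base is not None and ref[-1] == alt[-1] and pos > 1:
            try:
                left = get_base(chrom, pos - 1).upper()
            except (KeyError, IndexError):
                break
            ref, alt = left + ref[:-1], left + alt[:-1]
            pos -= 1
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if ref == alt:  # defensive; cannot be reached after the guards above
        raise InvalidVariantError("alleles identical after trimming")
    return chrom, pos, ref, alt


@dataclass
class AnnotatedVariant:
    """One called somatic variant with its annotations.

    ``vaf`` is in percent (0-100); ``pop_af`` is a fraction in [0, 1] or
    ``None`` when the variant is absent from population databases (treated
    downstream as maximally rare).  ``intron_offset`` is the signed distance
    in bases from the nearest exon boundary, 0 for exonic positions.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    call_quality: float = 0.0
    vaf: float = 0.0
    depth: int = 0
    pop_af: float | None = None
    effect: str = "other"
    intron_offset: int = 0
    splice_pred_flag: bool = False
    gof_flag: bool = False
    lof_flag: bool = False
    evidence_codes: frozenset[str] = field(default_factory=frozenset)
    clinical_evidence_level: str = "none"
    established_pathogenic: bool = False
    sample_id: str = ""
    fluid: str = "plasma"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise InvalidVariantError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise InvalidVariantError("ref == alt")
        if not (0.0 <= self.vaf <= 100.0):
            raise InvalidVariantError(f"vaf out of [0, 100]: {self.vaf}")
        if self.pop_af is not None and not (0.0 <= self.pop_af <= 1.0):
            raise InvalidVariantError(f"pop_af out of [0, 1]: {self.pop_af}")
        if self.effect not in EFFECTS:
            raise InvalidVariantError(f"unknown effect {self.effect!r}")
        if self.fluid not in FLUIDS:
            raise InvalidVariantError(f"fluid must be one of {FLUIDS}")
        unknown = set(self.evidence_codes) - EVIDENCE_CODES
        if unknown:
            raise InvalidVariantError(f"unknown evidence codes: {sorted(unknown)}")
        if self.clinical_evidence_level not in CLINICAL_EVIDENCE_LEVELS:
            raise InvalidVariantError(
                f"unknown clinical evidence level {self.clinical_evidence_level!r}"
            )
        self.evidence_codes = frozenset(self.evidence_codes)

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Normalized identity key ``(chrom, pos, ref, alt)``."""
        return (self.chrom, self.pos, self.ref, self.alt)

    def normalized(self) -> "AnnotatedVariant":
        """Return a copy with the canonical minimal allele representation."""
        chrom, pos, ref, alt = normalize_variant(self.chrom, self.pos, self.ref, self.alt)
        if (chrom, pos, ref, alt) == self.key:
            return self
        return replace(self, chrom=chrom, pos=pos, ref=ref, alt=alt)

    @property
    def label(self) -> str:
        """Human-readable label used in report tables and heatmap rows."""
        core = f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"
        return f"{self.gene} {core}" if self.gene else core


@dataclass(frozen=True)
class PatientPair:
    """A patient's matched plasma and urine samples.

    Concentrations are cfDNA in ng/mL; zero is allowed (below the
    fluorometric detection limit).
    """

    patient_id: str
    plasma_vcf: str
    urine_vcf: str
    plasma_conc: float = 0.0
    urine_conc: float = 0.0

    def __post_init__(self) -> None:
        if self.plasma_vcf == self.urine_vcf:
            raise ValueError("plasma and urine VCF paths must differ")
        if self.plasma_conc < 0 or self.urine_conc < 0:
            raise ValueError("cfDNA concentrations must be >= 0")
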