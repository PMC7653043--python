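"""Null/defective classification of FH pathogenic variants.

LDLR pathogenic variants (PVs) are split by predicted receptor consequence:

* **null** — no functional receptor: premature stop codons (nonsense),
  frameshifting small indels, large rearrangements (exon-level CNVs), and
  missense changes falling in the fifth cysteine-rich repeat (LR5) of the
  ligand-binding domain;
* **defective** — residual receptor function: the remaining in-frame point
  variants and in-frame indels, plus promoter/regulatory variants.

APOB and PCSK9 variants are pathogenic for FH but the null/defective split
does not apply to them.

The LR5 boundary is not standardised across reports; the default residue
interval (195, 232) in mature-protein (legacy) numbering is a config value,
not a claim, and is overridable everywhere it is consumed.  The protein
numbering convention (with or without the 21-residue signal peptide) must
be consistent between the variant table and the configured interval.

A deliberately lightweight HGVS reader (:func:`parse_hgvs_lite`) extracts
the few features classification needs — cDNA position (including negative
promoter offsets), substitution alleles, indel/CNV kind, and stop-gain
detection from the protein notation.  It is not a general HGVS validator.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .errors import ClassificationInputError, HGVSParseError, UnsupportedGenotypeError

logger = logging.getLogger(__name__)

FH_GENES = ("LDLR", "APOB", "PCSK9")

#: Default LR5 residue interval (inclusive), legacy numbering; overridable.
DEFAULT_REPEAT5_RANGE: tuple[int, int] = (195, 232)


class VariantClass(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT_INDEL = "frameshift_indel"
    INFRAME_INDEL = "inframe_indel"
    LARGE_REARRANGEMENT = "large_rearrangement"
    PROMOTER_REGULATORY = "promoter_regulatory"


class PVClass(str, Enum):
    NULL = "null_pv"
    DEFECTIVE = "defective_pv"
    NOT_APPLICABLE = "not_applicable"


class PVGroup(str, Enum):
    PV_NEGATIVE = "pv_negative"
    LDLR_NULL = "ldlr_null"
    LDLR_DEFECTIVE = "ldlr_defective"
    APOB_PCSK9 = "apob_pcsk9"
    COMPOUND_OR_HOMOZYGOUS = "compound_or_homozygous"


class Zygosity(str, Enum):
    HETEROZYGOUS = "heterozygous"
    HOMOZYGOUS = "homozygous"


@dataclass(frozen=True)
class VariantRecord:
    """One pathogenic variant call for one patient."""

    gene: str
    cdna_hgvs: str
    protein_hgvs: str | None = None
    variant_class: VariantClass | None = None
    zygosity: Zygosity = Zygosity.HETEROZYGOUS

    def __post_init__(self) -> None:
        gene = str(self.gene).upper()
        if gene not in FH_GENES:
            raise ClassificationInputError(f"gene must be one of {FH_GENES}, got {self.gene!r}")
        object.__setattr__(self, "gene", gene)
        if self.variant_class is not None:
            object.__setattr__(self, "variant_class", VariantClass(self.variant_class))
        object.__setattr__(self, "zygosity", Zygosity(self.zygosity))


@dataclass(frozen=True)
class ParsedVariant:
    """Minimal descriptor extracted from cDNA/protein HGVS strings."""

    kind: str  # substitution | indel | large_rearrangement
    cdna_position: int | None = None
    ref: str | None = None
    alt: str | None = None
    protein_position: int | None = None
    is_stop_gain: bool = False
    is_frameshift: bool = False


_SUB_RE = re.compile(r"^c\.(?P<pos>-?\d+)(?P<ref>[ACGT])>(?P<alt>[ACGT])$")
_INDEL_RE = re.compile(
    r"^c\.(?P<pos>-?\d+)(?:_(?P<end>-?\d+))?(?P<kind>del|dup|ins|delins)(?P<seq>[ACGT]*)$"
)
_LARGE_RE = re.compile(r"(?i)\bcnv\b|\bexon\b|\bex\d|^c\.\(")
# protein stop-gain: p.E228X, p.W23*, p.Gln12Ter, p.(Arg744Ter)
_STOP_RE = re.compile(r"(?:\*|Ter|(?<=\d)X)\)?$")
_FS_RE = re.compile(r"fs(?:\*|Ter)?\d*\)?$", re.IGNORECASE)
_PROT_POS_RE = re.compile(r"p\.\(?(?:[A-Z][a-z]{2}|[A-Z])(?P<pos>\d+)")


def parse_hgvs_lite(cdna: str, protein: str | None = None) -> ParsedVariant:
    """Parse the subset of HGVS notation the classifier needs.

    Handles simple cDNA substitutions (with negative promoter offsets),
    small del/dup/ins/delins, and free-text exon-level rearrangements
    (e.g. ``"CNV, exon 8-12"``).  Stop-gain and frameshift are detected
    from the protein notation when supplied.
    """
    cdna = (cdna or "").strip()
    if not cdna:
        raise HGVSParseError("empty cDNA HGVS string")

    protein = (protein or "").strip() or None
    protein_position = None
    is_stop = False
    is_fs = False
    if protein:
        m = _PROT_POS_RE.search(protein)
        if m:
            protein_position = int(m.group("pos"))
        is_fs = bool(_FS_RE.search(protein))
        is_stop = bool(_STOP_RE.search(protein)) and not is_fs

    m = _SUB_RE.match(cdna)
    if m:
        return ParsedVariant(
            kind="substitution",
            cdna_position=int(m.group("pos")),
            ref=m.group("ref"),
            alt=m.group("alt"),
            protein_position=protein_position,
            is_stop_gain=is_stop,
            is_frameshift=is_fs,
        )
    m = _INDEL_RE.match(cdna)
    if m:
        return ParsedVariant(
            kind="indel",
            cdna_position=int(m.group("pos")),
            protein_position=protein_position,
            is_stop_gain=is_stop,
            is_frameshift=is_fs,
        )
    if _LARGE_RE.search(cdna):
        return ParsedVariant(
            kind="large_rearrangement",
            protein_position=protein_position,
            is_stop_gain=is_stop,
            is_frameshift=is_fs,
        )
    raise HGVSParseError(f"cannot parse HGVS notation: {cdna!r}")


def infer_variant_class(parsed: ParsedVariant) -> VariantClass:
    """Fallback inference of the variant class from parsed notation only.

    Used when the input table omits ``variant_class``; the inference is
    logged because the table value, when present, is authoritative.
    """
    if parsed.kind == "large_rearrangement":
        return VariantClass.LARGE_REARRANGEMENT
    if parsed.is_frameshift:
        return VariantClass.FRAMESHIFT_INDEL
    if parsed.kind == "substitution":
        if parsed.cdna_position is not None and parsed.cdna_position < 0:
            return VariantClass.PROMOTER_REGULATORY
        if parsed.is_stop_gain:
            return VariantClass.NONSENSE
        return VariantClass.MISSENSE
    # small indel without frameshift annotation: assume in-frame
    return VariantClass.INFRAME_INDEL


def classify_variant(
    variant: VariantRecord,
    repeat5_range: tuple[int, int] = DEFAULT_REPEAT5_RANGE,
) -> PVClass:
    """Assign null/defective to an LDLR variant; APOB/PCSK9 are not applicable.

    Null: nonsense, frameshift indel, large rearrangement, or missense with
    the affected residue inside ``repeat5_range`` (LR5).  Defective: all
    other missense, in-frame indels, promoter/regulatory variants.
    """
    if variant.gene in ("APOB", "PCSK9"):
        return PVClass.NOT_APPLICABLE

    vclass = variant.variant_class
    parsed = None
    if vclass is None:
        parsed = parse_hgvs_lite(variant.cdna_hgvs, variant.protein_hgvs)
        vclass = infer_variant_class(parsed)
        logger.info(
            "variant_class missing for %s %s; inferred %s from notation",
            variant.gene,
            variant.cdna_hgvs,
            vclass.value,
        )

    if vclass in (
        VariantClass.NONSENSE,
        VariantClass.FRAMESHIFT_INDEL,
        VariantClass.LARGE_REARRANGEMENT,
    ):
        return PVClass.NULL
    if vclass is VariantClass.MISSENSE:
        if parsed is None:
            try:
                parsed = parse_hgvs_lite(variant.cdna_hgvs, variant.protein_hgvs)
            except HGVSParseError:
                parsed = None
        pos = parsed.protein_position if parsed is not None else None
        if pos is not None and repeat5_range[0] <= pos <= repeat5_range[1]:
            return PVClass.NULL
        return PVClass.DEFECTIVE
    if vclass in (VariantClass.INFRAME_INDEL, VariantClass.PROMOTER_REGULATORY):
        return PVClass.DEFECTIVE
    raise ClassificationInputError(f"cannot classify variant_class {vclass!r}")


@dataclass(frozen=True)
class PatientGenotype:
    """Patient-level pathogenic-variant group."""

    group: PVGroup
    has_any_null: bool


def _allele_count(v: VariantRecord) -> int:
    return 2 if v.zygosity is Zygosity.HOMOZYGOUS else 1


def classify_patient(
    variants: Sequence[VariantRecord] | Iterable[VariantRecord],
    repeat5_range: tuple[int, int] = DEFAULT_REPEAT5_RANGE,
) -> PatientGenotype:
    """Derive the patient-level PV group from their variant list.

    Zero variants -> PV-negative; one heterozygous variant -> a gene/class
    group; two pathogenic alleles (a homozygous variant or two heterozygous
    ones) -> the combined compound/homozygous group with ``has_any_null``
    recording whether any LDLR allele classifies null.  More than two
    alleles is outside the study design and raises.
    """
    variants = list(variants)
    n_alleles = sum(_allele_count(v) for v in variants)
    if n_alleles > 2:
        raise UnsupportedGenotypeError(f"{n_alleles} pathogenic alleles are not supported")

    classes = [classify_variant(v, repeat5_range) for v in variants]
    has_null = any(
        c is PVClass.NULL for v, c in zip(variants, classes) if v.gene == "LDLR"
    )

    if n_alleles == 0:
        return PatientGenotype(PVGroup.PV_NEGATIVE, False)
    if n_alleles == 1:
        (v,), (c,) = variants, classes
        if v.gene in ("APOB", "PCSK9"):
            return PatientGenotype(PVGroup.APOB_PCSK9, False)
        group = PVGroup.LDLR_NULL if c is PVClass.NULL else PVGroup.LDLR_DEFECTIVE
        return PatientGenotype(group, has_null)
    return PatientGenotype(PVGroup.COMPOUND_OR_HOMOZYGOUS, has_null)
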