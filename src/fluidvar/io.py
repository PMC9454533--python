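"""Reading and writing the pipeline's file formats.

VCF v4.2 is the variant interchange format (read through cyvcf2, written by
a small deterministic text emitter); exclusion windows come as BED3
(0-based half-open); cfDNA concentrations as a three-column CSV; the cohort
manifest as TSV.  All coordinate-system conversion between the 1-based VCF
world and the 0-based BED world lives in :func:`window_contains`.
"""

from __future__ import annotations

import bisect
import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from cyvcf2 import VCF
from pydantic import BaseModel

from .variants import (
    AnnotatedVariant,
    InvalidVariantError,
    PatientPair,
    normalize_variant,
)

__all__ = [
    "TagConfig",
    "WindowSet",
    "read_sample_vcf",
    "write_sample_vcf",
    "read_concentrations",
    "read_window_bed",
    "window_contains",
    "read_manifest",
]


class TagConfig(BaseModel):
    """Names of the VCF tags carrying each annotation field.

    ``quality`` of ``None`` means the QUAL column; otherwise it names an
    INFO tag.  ``vaf`` names an INFO tag holding the VAF in percent; when
    the tag is absent the per-sample AD/DP ratio is used as a fallback.
    """

    gene: str = "GENE"
    vaf: str = "VAFPCT"
    pop_af: str = "POPAF"
    effect: str = "EFFECT"
    intron_offset: str = "INTOFF"
    splice_pred: str = "SPLICEPRED"
    gof: str = "GOF"
    lof: str = "LOF"
    evidence: str = "EVID"
    clinical_evidence: str = "CLINEVID"
    established_pathogenic: str = "ESTPATH"
    quality: str | None = None

    @classmethod
    def from_json(cls, path: str | Path) -> "TagConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))


def _strip_chr(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def _split_per_allele(value: object, n_alt: int) -> list[str]:
    """Expand a Number=A INFO string into one entry per ALT allele."""
    if value is None:
        return [""] * n_alt
    parts = str(value).split(",")
    if len(parts) == n_alt:
        return parts
    if len(parts) == 1:
        return parts * n_alt
    raise InvalidVariantError(
        f"INFO cardinality mismatch: {value!r} for {n_alt} ALT allele(s)"
    )


def _per_allele_floats(value: object, n_alt: int) -> list[float | None]:
    if value is None:
        return [None] * n_alt
    if isinstance(value, (tuple, list)):
        vals = list(value)
    else:
        vals = [value]
    if len(vals) == 1 and n_alt > 1:
        vals = vals * n_alt
    if len(vals) != n_alt:
        raise InvalidVariantError(f"INFO cardinality mismatch: {value!r}")
    return [None if v is None else float(v) for v in vals]


def _parse_evidence(token: str) -> frozenset[str]:
    token = token.strip()
    if token in ("", "."):
        return frozenset()
    return frozenset(code.strip() for code in token.split("|") if code.strip())


def read_sample_vcf(
    path: str | Path,
    tag_config: TagConfig | None = None,
    sample_id: str = "",
    fluid: str = "plasma",
) -> list[AnnotatedVariant]:
    """Read an annotated sample VCF into :class:`AnnotatedVariant` records.

    Multi-allelic records are split into one variant per ALT allele and each
    is normalized (trailing/leading shared bases trimmed).  ``call_quality``
    comes from the QUAL column unless ``tag_config.quality`` names an INFO
    tag.  VAF resolution order: the configured tag, then the first sample's
    AD/DP ratio; if neither is available the record is rejected.
    """
    cfg = tag_config or TagConfig()
    out: list[AnnotatedVariant] = []
    vcf = VCF(str(path))
    try:
        for rec in vcf:
            alts = rec.ALT
            n_alt = len(alts)
            vafs = _per_allele_floats(rec.INFO.get(cfg.vaf), n_alt)
            pop_afs = _per_allele_floats(rec.INFO.get(cfg.pop_af), n_alt)
            effects = _split_per_allele(rec.INFO.get(cfg.effect), n_alt)
            offsets = _per_allele_floats(rec.INFO.get(cfg.intron_offset), n_alt)
            genes = _split_per_allele(rec.INFO.get(cfg.gene), n_alt)
            evid = _split_per_allele(rec.INFO.get(cfg.evidence), n_alt)
            level = str(rec.INFO.get(cfg.clinical_evidence) or "none")
            if cfg.quality is not None:
                qual = float(rec.INFO.get(cfg.quality) or 0.0)
            else:
                qual = float(rec.QUAL) if rec.QUAL is not None else 0.0
            dp = rec.format("DP")
            ad = rec.format("AD")
            depth = int(dp[0][0]) if dp is not None else 0
            for i, alt in enumerate(alts):
                vaf = vafs[i]
                if vaf is None:
                    if ad is not None and dp is not None and depth > 0:
                        vaf = 100.0 * float(ad[0][i + 1]) / depth
                    else:
                        raise InvalidVariantError(
                            f"{path}: record {rec.CHROM}:{rec.POS} has no "
                            f"{cfg.vaf} tag and no AD/DP fallback"
                        )
                chrom, pos, ref, alt_n = normalize_variant(rec.CHROM, rec.POS, rec.REF, alt)
                out.append(
                    AnnotatedVariant(
                        chrom=chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt_n,
                        gene=genes[i] if genes[i] not in ("", ".") else "",
                        call_quality=qual,
                        vaf=vaf,
                        depth=depth,
                        pop_af=pop_afs[i],
                        effect=effects[i] if effects[i] not in ("", ".") else "other",
                        intron_offset=int(offsets[i]) if offsets[i] is not None else 0,
                        splice_pred_flag=bool(rec.INFO.get(cfg.splice_pred)),
                        gof_flag=bool(rec.INFO.get(cfg.gof)),
                        lof_flag=bool(rec.INFO.get(cfg.lof)),
                        evidence_codes=_parse_evidence(evid[i]),
                        clinical_evidence_level=level if level != "." else "none",
                        established_pathogenic=bool(rec.INFO.get(cfg.established_pathogenic)),
                        sample_id=sample_id,
                        fluid=fluid,
                    )
                )
    finally:
        vcf.close()
    return out


_VCF_HEADER_LINES = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=GENE,Number=A,Type=String,Description="HGNC gene symbol">',
    '##INFO=<ID=VAFPCT,Number=A,Type=Float,Description="Variant allele fraction in percent">',
    '##INFO=<ID=POPAF,Number=A,Type=Float,Description="Maximum population allele fraction">',
    '##INFO=<ID=EFFECT,Number=A,Type=String,Description="Predicted molecular consequence">',
    '##INFO=<ID=INTOFF,Number=A,Type=Integer,Description="Signed distance in bases from nearest exon boundary">',
    '##INFO=<ID=SPLICEPRED,Number=0,Type=Flag,Description="External splice-disruption prediction">',
    '##INFO=<ID=GOF,Number=0,Type=Flag,Description="Gain-of-function association">',
    '##INFO=<ID=LOF,Number=0,Type=Flag,Description="Loss-of-function association">',
    '##INFO=<ID=EVID,Number=A,Type=String,Description="ACMG/AMP evidence codes, pipe-separated per allele">',
    '##INFO=<ID=CLINEVID,Number=1,Type=String,Description="Clinical evidence level A/B/C/D/none">',
    '##INFO=<ID=ESTPATH,Number=0,Type=Flag,Description="Established pathogenic variant">',
    '##INFO=<ID=ACMG_CLASS,Number=A,Type=String,Description="Assigned ACMG five-class impact">',
    '##INFO=<ID=TIER,Number=A,Type=String,Description="Assigned AMP/ASCO/CAP tier">',
    '##INFO=<ID=VAFBIN,Number=A,Type=String,Description="VAF abundance bin">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref, alt)">',
]

_CONTIGS = [str(c) for c in range(1, 23)] + ["X"]


def _chrom_sort_key(chrom: str) -> tuple[int, str]:
    c = _strip_chr(chrom)
    return (int(c), "") if c.isdigit() else (99, c)


def write_sample_vcf(
    path: str | Path,
    variants: Sequence[AnnotatedVariant],
    sample_id: str,
    extra_info: dict[tuple[str, int, str, str], dict[str, str]] | None = None,
) -> None:
    """Write variants as a sorted single-sample VCF v4.2 text file.

    ``extra_info`` optionally maps a variant key to additional INFO
    ``tag -> value`` pairs (used to emit ACMG_CLASS / TIER / VAFBIN on
    annotated output).  Output is byte-deterministic for a fixed input.
    """
    lines = list(_VCF_HEADER_LINES)
    lines.extend(f"##contig=<ID={c}>" for c in _CONTIGS)
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id
    )
    for v in sorted(variants, key=lambda v: (_chrom_sort_key(v.chrom), v.pos, v.ref, v.alt)):
        info = [f"GENE={v.gene or '.'}", f"VAFPCT={v.vaf:.4f}"]
        if v.pop_af is not None:
            info.append(f"POPAF={v.pop_af:.6f}")
        info.append(f"EFFECT={v.effect}")
        info.append(f"INTOFF={v.intron_offset}")
        if v.splice_pred_flag:
            info.append("SPLICEPRED")
        if v.gof_flag:
            info.append("GOF")
        if v.lof_flag:
            info.append("LOF")
        if v.evidence_codes:
            info.append("EVID=" + "|".join(sorted(v.evidence_codes)))
        if v.clinical_evidence_level != "none":
            info.append(f"CLINEVID={v.clinical_evidence_level}")
        if v.established_pathogenic:
            info.append("ESTPATH")
        for tag, value in (extra_info or {}).get(v.key, {}).items():
            info.append(f"{tag}={value}")
        alt_depth = int(round(v.depth * v.vaf / 100.0))
        fmt = f"{v.depth}:{max(v.depth - alt_depth, 0)},{alt_depth}"
        lines.append(
            "\t".join(
                [
                    v.chrom,
                    str(v.pos),
                    ".",
                    v.ref,
                    v.alt,
                    f"{v.call_quality:.2f}",
                    "PASS",
                    ";".join(info),
                    "DP:AD",
                    fmt,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_concentrations(path: str | Path) -> dict[str, tuple[float, float]]:
    """Read the per-patient cfDNA concentration CSV.

    Expects a header ``patient_id,plasma_ng_ml,urine_ng_ml``.  Duplicate
    patient ids and negative concentrations are rejected; zero is allowed
    (below the detection limit).
    """
    out: dict[str, tuple[float, float]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"patient_id", "plasma_ng_ml", "urine_ng_ml"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected header columns {sorted(required)}")
        for row in reader:
            pid = row["patient_id"].strip()
            plasma = float(row["plasma_ng_ml"])
            urine = float(row["urine_ng_ml"])
            if plasma < 0 or urine < 0:
                raise ValueError(f"{path}: negative concentration for patient {pid}")
            if pid in out:
                raise ValueError(f"{path}: duplicate patient_id {pid}")
            out[pid] = (plasma, urine)
    return out


@dataclass(frozen=True)
class WindowSet:
    """Exclusion windows as 0-based half-open intervals per chromosome."""

    intervals: dict[str, tuple[tuple[int, int], ...]] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, intervals: Iterable[tuple[str, int, int]]) -> "WindowSet":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if start >= end:
                raise ValueError(f"invalid interval {chrom}:{start}-{end} (start >= end)")
            by_chrom.setdefault(_strip_chr(chrom), []).append((int(start), int(end)))
        return cls({c: tuple(sorted(v)) for c, v in by_chrom.items()})

    def __len__(self) -> int:
        return sum(len(v) for v in self.intervals.values())


def read_window_bed(path: str | Path) -> WindowSet:
    """Read a BED3 file of excluded windows (0-based half-open)."""
    intervals: list[tuple[str, int, int]] = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{line_no}: expected >= 3 BED columns")
        intervals.append((fields[0], int(fields[1]), int(fields[2])))
    return WindowSet.from_intervals(intervals)


def window_contains(windows: WindowSet, chrom: str, pos: int) -> bool:
    """True iff 1-based ``pos`` falls inside any window on ``chrom``.

    BED intervals are 0-based half-open, so a window ``(start, end)``
    contains 1-based positions ``start < pos <= end``.
    """
    ivals = windows.intervals.get(_strip_chr(chrom))
    if not ivals:
        return False
    starts = [s for s, _ in ivals]
    i = bisect.bisect_right(starts, pos - 1)
    # Intervals may overlap: pos is covered iff the running maximum of the
    # interval ends among all windows starting at or before pos-1 reaches it.
    max_end = 0
    for _, e in ivals[:i]:
        if e > max_end:
            max_end = e
    return max_end >= pos


def read_manifest(path: str | Path, concentrations: dict[str, tuple[float, float]] | None = None) -> list[PatientPair]:
    """Read the cohort manifest TSV (patient_id, plasma_vcf, urine_vcf)."""
    pairs: list[PatientPair] = []
    base = Path(path).parent
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("patient_id\t"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{line_no}: expected 3 TSV columns")
        pid, plasma_vcf, urine_vcf = fields[:3]
        plasma = str(base / plasma_vcf) if not Path(plasma_vcf).is_absolute() else plasma_vcf
        urine = str(base / urine_vcf) if not Path(urine_vcf).is_absolute() else urine_vcf
        conc = (concentrations or {}).get(pid, (0.0, 0.0))
        pairs.append(PatientPair(pid, plasma, urine, conc[0], conc[1]))
    return pairs
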