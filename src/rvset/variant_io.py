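"""Genotype and gene-group-file I/O for set-based rare-variant tests.

A *gene group file* maps each gene to its variants and per-variant functional
annotations (``lof`` / ``missense`` / ``synonymous`` / ``other``).  Genotypes
come from a VCF (hard calls via GT, or dosages via DS when present) and are
assembled into per-gene dosage matrices oriented to the minor allele.  Testing
sets are then carved out of a gene by a :class:`MaskSpec` — an annotation
subset crossed with a maximum-MAF cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Default maximum-MAF grid: 1%, 0.1% and 0.01%.
DEFAULT_MAF_CUTOFFS = (0.01, 0.001, 0.0001)


class Annotation(str, Enum):
    """Functional annotation class of a variant within a gene."""

    LOF = "lof"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


ANNOTATION_TOKENS = tuple(a.value for a in Annotation)


class GroupFileError(ValueError):
    """Malformed gene group file."""


class EmptySetError(ValueError):
    """A gene or mask cell ended up with zero qualifying variants."""


@dataclass(frozen=True)
class Variant:
    """A single bi-allelic variant keyed as ``chr:pos:ref:alt`` (1-based)."""

    variant_id: str
    chrom: str
    pos: int
    annotation: Annotation

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")

    @classmethod
    def from_id(cls, variant_id: str, annotation: Annotation | str) -> "Variant":
        parts = variant_id.split(":")
        if len(parts) != 4:
            raise ValueError(f"variant id must be chr:pos:ref:alt, got {variant_id!r}")
        return cls(
            variant_id=variant_id,
            chrom=parts[0],
            pos=int(parts[1]),
            annotation=Annotation(annotation),
        )


@dataclass
class GeneVariantSet:
    """A gene's minor-allele dosage matrix with per-variant MAF/MAC/annotation.

    ``dosage`` is N_samples x M_variants with entries in [0, 2], oriented so
    that each column counts copies of the *minor* allele.  ``mac`` is the
    real-valued sum of minor-allele dosages per column and
    ``maf = mac / (2 * N)``.
    """

    gene_id: str
    dosage: np.ndarray
    variants: list[Variant]
    sample_ids: list[str]
    maf: np.ndarray = field(default=None)  # type: ignore[assignment]
    mac: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be a 2-D matrix (samples x variants)")
        n, m = self.dosage.shape
        if m != len(self.variants):
            raise ValueError("variant list length must match dosage columns")
        if m < 1:
            raise EmptySetError(f"gene {self.gene_id}: no variants")
        if self.mac is None:
            self.mac = self.dosage.sum(axis=0)
        else:
            self.mac = np.asarray(self.mac, dtype=float)
        if self.maf is None:
            self.maf = self.mac / (2.0 * n) if n else np.zeros(m)
        else:
            self.maf = np.asarray(self.maf, dtype=float)
        if np.any(self.maf > 0.5 + 1e-12):
            raise ValueError("maf > 0.5: dosage columns must be minor-allele oriented")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def subset_variants(self, idx: np.ndarray) -> "GeneVariantSet":
        idx = np.asarray(idx)
        return GeneVariantSet(
            gene_id=self.gene_id,
            dosage=self.dosage[:, idx],
            variants=[self.variants[int(i)] for i in idx],
            sample_ids=self.sample_ids,
            maf=self.maf[idx],
            mac=self.mac[idx],
        )


@dataclass(frozen=True)
class MaskSpec:
    """One testing cell: an annotation subset plus a maximum-MAF cutoff."""

    annotations: frozenset
    max_maf: float

    def __post_init__(self) -> None:
        annos = frozenset(Annotation(a) for a in self.annotations)
        object.__setattr__(self, "annotations", annos)
        if not annos:
            raise ValueError("mask must include at least one annotation class")
        if not (0.0 < self.max_maf <= 0.5):
            raise ValueError(f"max_maf must lie in (0, 0.5], got {self.max_maf}")

    def label(self) -> str:
        order = [Annotation.LOF, Annotation.MISSENSE, Annotation.SYNONYMOUS, Annotation.OTHER]
        return ",".join(a.value for a in order if a in self.annotations)


def default_mask_grid(max_mafs: Sequence[float] = DEFAULT_MAF_CUTOFFS) -> list[MaskSpec]:
    """The 3 x 3 grid: {LoF} / {LoF,missense} / {LoF,missense,synonymous}
    crossed with the maximum-MAF cutoffs (default 1%, 0.1%, 0.01%)."""
    anno_sets = [
        frozenset({Annotation.LOF}),
        frozenset({Annotation.LOF, Annotation.MISSENSE}),
        frozenset({Annotation.LOF, Annotation.MISSENSE, Annotation.SYNONYMOUS}),
    ]
    return [MaskSpec(a, m) for a in anno_sets for m in max_mafs]


def parse_group_file(path: str | Path) -> dict[str, list[tuple[str, Annotation]]]:
    """Parse a two-line-per-gene group file.

    Each gene contributes a ``<gene> var <id...>`` line and a
    ``<gene> anno <token...>`` line of equal length.  Returns a mapping
    ``gene_id -> [(variant_id, annotation), ...]`` preserving variant order.
    """
    var_lines: dict[str, list[str]] = {}
    anno_lines: dict[str, list[str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            tokens = raw.split()
            if not tokens:
                continue
            if len(tokens) < 3:
                raise GroupFileError(f"line {lineno}: expected '<gene> var|anno <items...>'")
            gene, kind, items = tokens[0], tokens[1], tokens[2:]
            if kind == "var":
                if gene in var_lines:
                    raise GroupFileError(f"gene {gene}: duplicate 'var' line")
                if len(set(items)) != len(items):
                    raise GroupFileError(f"gene {gene}: duplicate variant id on var line")
                var_lines[gene] = items
                order.append(gene)
            elif kind == "anno":
                if gene in anno_lines:
                    raise GroupFileError(f"gene {gene}: duplicate 'anno' line")
                bad = [t for t in items if t not in ANNOTATION_TOKENS]
                if bad:
                    raise GroupFileError(
                        f"gene {gene}: unknown annotation token(s) {bad}; "
                        f"allowed: {list(ANNOTATION_TOKENS)}"
                    )
                anno_lines[gene] = items
            else:
                raise GroupFileError(f"line {lineno}: unknown record kind {kind!r}")
    out: dict[str, list[tuple[str, Annotation]]] = {}
    for gene in order:
        if gene not in anno_lines:
            raise GroupFileError(f"gene {gene}: missing 'anno' line")
        vids, annos = var_lines[gene], anno_lines[gene]
        if len(vids) != len(annos):
            raise GroupFileError(
                f"gene {gene}: var line has {len(vids)} items but anno line has {len(annos)}"
            )
        out[gene] = [(v, Annotation(a)) for v, a in zip(vids, annos)]
    missing_var = set(anno_lines) - set(var_lines)
    if missing_var:
        raise GroupFileError(f"gene(s) {sorted(missing_var)}: 'anno' line without 'var' line")
    return out


def _dosage_from_record(record, n_samples: int) -> np.ndarray:
    """ALT dosage per sample from a cyvcf2 record; NaN marks missing.

    DS is preferred when present; otherwise hard calls from GT.
    """
    try:
        ds = record.format("DS")
    except KeyError:
        ds = None
    if ds is not None:
        d = np.asarray(ds, dtype=float).reshape(n_samples)
        d[d < 0] = np.nan
        return d
    gt = np.asarray(record.genotype.array())[:, :2]
    d = np.where(gt < 0, np.nan, gt).sum(axis=1).astype(float)
    return d


def load_gene_dosages(
    vcf_path: str | Path,
    sample_ids: Sequence[str],
    variant_ids: Sequence[str],
    annotations: Sequence[Annotation | str] | None = None,
    gene_id: str = "gene",
) -> GeneVariantSet:
    """Build a :class:`GeneVariantSet` from a VCF for the given variant keys.

    Columns whose ALT frequency exceeds 0.5 are flipped (``2 - dosage``) so the
    matrix counts minor alleles; missing genotypes are mean-imputed to
    ``2 * MAF`` computed on the non-missing samples; variants absent from the
    VCF are dropped with a warning.  Multi-allelic records must be pre-split.
    """
    from cyvcf2 import VCF

    sample_ids = list(sample_ids)
    vcf = VCF(str(vcf_path))
    vcf_samples = list(vcf.samples)
    missing = [s for s in sample_ids if s not in set(vcf_samples)]
    if missing:
        raise ValueError(f"samples absent from VCF: {missing[:10]}" + ("..." if len(missing) > 10 else ""))
    sample_idx = np.array([vcf_samples.index(s) for s in sample_ids])

    wanted = {v: i for i, v in enumerate(variant_ids)}
    if len(wanted) != len(variant_ids):
        raise ValueError("duplicate variant ids requested")
    anno_list = list(annotations) if annotations is not None else [Annotation.OTHER] * len(variant_ids)
    if len(anno_list) != len(variant_ids):
        raise ValueError("annotations length must match variant_ids")

    cols: dict[str, np.ndarray] = {}
    for record in vcf:
        if len(record.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {record.CHROM}:{record.POS}; split to one ALT per record first"
            )
        key = f"{record.CHROM}:{record.POS}:{record.REF}:{record.ALT[0]}"
        if key not in wanted:
            continue
        d = _dosage_from_record(record, len(vcf_samples))[sample_idx]
        ok = ~np.isnan(d)
        if not ok.any():
            logger.warning("variant %s: all genotypes missing; dropped", key)
            continue
        alt_freq = d[ok].sum() / (2.0 * ok.sum())
        if alt_freq > 0.5:
            d = 2.0 - d
            logger.info("variant %s: ALT frequency %.4f > 0.5, flipped to minor allele", key, alt_freq)
        maf = np.nansum(d) / (2.0 * ok.sum())
        d[~ok] = 2.0 * maf
        cols[key] = d
    vcf.close()

    found = [v for v in variant_ids if v in cols]
    absent = [v for v in variant_ids if v not in cols]
    if absent:
        logger.warning("gene %s: %d variant(s) not found in VCF and dropped: %s",
                       gene_id, len(absent), absent[:5])
    if not found:
        raise EmptySetError(f"gene {gene_id}: none of the requested variants found in VCF")
    dosage = np.column_stack([cols[v] for v in found])
    variants = [Variant.from_id(v, anno_list[wanted[v]]) for v in found]
    return GeneVariantSet(gene_id=gene_id, dosage=dosage, variants=variants,
                          sample_ids=sample_ids)


def apply_mask(gvs: GeneVariantSet, mask: MaskSpec) -> GeneVariantSet:
    """Restrict a gene to one testing cell.

    Keeps exactly the variants with annotation in ``mask.annotations``,
    ``maf <= mask.max_maf`` and ``mac > 0`` (monomorphic columns never enter a
    test), preserving column order.  Raises :class:`EmptySetError` when no
    variant qualifies — the caller records the cell as *not tested*, never as
    p = 1.
    """
    keep = np.array(
        [
            (v.annotation in mask.annotations)
            and (gvs.maf[j] <= mask.max_maf + 1e-15)
            and (gvs.mac[j] > 0)
            for j, v in enumerate(gvs.variants)
        ]
    )
    if not keep.any():
        raise EmptySetError(
            f"gene {gvs.gene_id}: no qualifying variants for mask "
            f"({mask.label()}, max_maf={mask.max_maf})"
        )
    return gvs.subset_variants(np.flatnonzero(keep))


def write_vcf(gvs: GeneVariantSet, path: str | Path) -> None:
    """Write hard-call/dosage genotypes of a gene as an uncompressed VCF 4.2.

    Integer dosages are emitted as GT hard calls; fractional dosages as DS.
    Intended for fixtures and round-trip checks at desk scale.
    """
    hard = np.allclose(gvs.dosage, np.round(gvs.dosage))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(v.chrom for v in gvs.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if not hard:
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gvs.sample_ids) + "\n")
        for j in sorted(range(gvs.n_variants), key=lambda j: (gvs.variants[j].chrom, gvs.variants[j].pos)):
            v = gvs.variants[j]
            _, _, ref, alt = v.variant_id.split(":")
            if hard:
                gts = []
                for d in np.round(gvs.dosage[:, j]).astype(int):
                    gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[int(d)])
                fmt, fields = "GT", gts
            else:
                fmt = "GT:DS"
                fields = [f"./.:{d:.6g}" for d in gvs.dosage[:, j]]
            fh.write(f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{ref}\t{alt}\t.\t.\t.\t{fmt}\t"
                     + "\t".join(fields) + "\n")


def write_group_file(genes: dict[str, list[tuple[str, Annotation]]], path: str | Path) -> None:
    """Write a mapping of genes to (variant_id, annotation) as a group file."""
    with open(path, "w") as fh:
        for gene, items in genes.items():
            fh.write(f"{gene} var " + " ".join(v for v, _ in items) + "\n")
            fh.write(f"{gene} anno " + " ".join(Annotation(a).value for _, a in items) + "\n")
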