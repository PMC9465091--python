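"""Reading and writing VCF, phenotype and site-list files.

This module is pure plumbing: it maps VCF records onto the package's small
internal data model (:class:`GenotypeCall`, :class:`VariantRecord`,
:class:`PhenotypeMap`) and back, with no analysis logic.  Parsing is done by
:mod:`pysam`; coordinates are 1-based inclusive throughout, following VCF
convention.  Phased (``|``) and unphased (``/``) genotype separators are
treated identically — every downstream analysis is phase-blind.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import pysam

__all__ = [
    "MISSING",
    "GenotypeCall",
    "VariantRecord",
    "PhenotypeMap",
    "VcfReader",
    "read_vcf",
    "read_phenotypes",
    "write_phenotypes",
    "write_sites",
    "read_sites",
]

#: Sentinel for a missing allele / missing rsID.
MISSING = None


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's call at one site.

    ``allele_a``/``allele_b`` are allele indices into ``[ref] + alts``
    (0 = reference) or ``None`` when the genotype is missing (``./.``).
    ``gq`` and ``dp`` are the per-genotype Phred-scaled quality and read
    depth; when absent from the record they are stored as 0 so that they
    fail any positive quality threshold.
    """

    allele_a: Optional[int]
    allele_b: Optional[int]
    gq: int = 0
    dp: int = 0

    @property
    def is_missing(self) -> bool:
        return self.allele_a is None or self.allele_b is None

    @property
    def is_homozygous(self) -> bool:
        return not self.is_missing and self.allele_a == self.allele_b

    @property
    def is_heterozygous(self) -> bool:
        return not self.is_missing and self.allele_a != self.allele_b

    @property
    def alleles(self) -> tuple[Optional[int], Optional[int]]:
        return (self.allele_a, self.allele_b)

    def carries(self, allele: int) -> bool:
        """True if either (non-missing) allele equals ``allele``."""
        return self.allele_a == allele or self.allele_b == allele

    def carries_alt(self) -> bool:
        """True if a non-missing allele is non-reference."""
        return any(a is not None and a > 0 for a in self.alleles)


@dataclass
class VariantRecord:
    """One VCF data line with per-sample calls.

    ``samples`` is the header sample list (shared between records from the
    same file); ``calls`` is ordered to match it.
    """

    chrom: str
    pos: int  # 1-based
    id: Optional[str]
    ref: str
    alts: tuple[str, ...]
    qual: Optional[float]
    info: dict
    calls: list[GenotypeCall]
    samples: tuple[str, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.samples and len(self.calls) != len(self.samples):
            raise ValueError(
                f"{self.chrom}:{self.pos}: {len(self.calls)} calls for "
                f"{len(self.samples)} samples"
            )

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and all(
            len(a) == 1 and a in "ACGTN" for a in self.alts
        )

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    def call_for(self, sample: str) -> GenotypeCall:
        try:
            return self.calls[self.samples.index(sample)]
        except ValueError:
            raise KeyError(
                f"sample {sample!r} not present at {self.chrom}:{self.pos}"
            ) from None


@dataclass
class PhenotypeMap:
    """Sample identifiers partitioned into cases and controls."""

    cases: list[str]
    controls: list[str]

    def __post_init__(self) -> None:
        dup = set(self.cases) & set(self.controls)
        if dup:
            raise ValueError(f"samples listed as both case and control: {sorted(dup)}")

    @property
    def all_samples(self) -> list[str]:
        return list(self.cases) + list(self.controls)

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    @property
    def n_controls(self) -> int:
        return len(self.controls)

    def validate_against(self, samples: Sequence[str]) -> None:
        """Raise if any phenotyped sample is absent from a VCF sample list."""
        missing = [s for s in self.all_samples if s not in samples]
        if missing:
            raise ValueError(f"phenotyped samples not in VCF header: {missing}")


def _convert_call(sample_data) -> GenotypeCall:
    gt = sample_data.get("GT", (None, None))
    if gt is None or len(gt) == 0:
        a, b = None, None
    elif len(gt) == 1:  # haploid call: duplicate, keeping analyses diploid
        a = b = gt[0]
    else:
        a, b = gt[0], gt[1]
    gq = sample_data.get("GQ")
    dp = sample_data.get("DP")
    return GenotypeCall(
        allele_a=a,
        allele_b=b,
        gq=int(gq) if gq is not None else 0,
        dp=int(dp) if dp is not None else 0,
    )


class VcfReader:
    """Iterate a VCF file as :class:`VariantRecord` objects.

    Exposes the header ``samples`` tuple and, when the file is
    VEP-annotated, the ``csq_format`` field layout declared in the
    ``##INFO=<ID=CSQ,...>`` header line.
    """

    def __init__(self, path: str | Path, region: Optional[str] = None):
        self.path = str(path)
        try:
            self._vf = pysam.VariantFile(self.path)
        except (ValueError, OSError) as exc:
            raise ValueError(f"cannot parse VCF {self.path}: {exc}") from exc
        self.samples: tuple[str, ...] = tuple(self._vf.header.samples)
        self.region = region
        self.csq_format: Optional[list[str]] = self._parse_csq_format()

    def _parse_csq_format(self) -> Optional[list[str]]:
        rec = self._vf.header.info.get("CSQ")
        if rec is None:
            return None
        m = re.search(r"Format:\s*([^\"]+)", rec.description or "")
        if not m:
            return None
        return [f.strip() for f in m.group(1).split("|")]

    def __iter__(self) -> Iterator[VariantRecord]:
        for rec in self._vf:
            if self.region is not None and rec.chrom != self.region:
                continue
            try:
                calls = [_convert_call(rec.samples[s]) for s in self.samples]
            except Exception as exc:  # pragma: no cover - defensive
                raise ValueError(
                    f"bad genotype data at {rec.chrom}:{rec.pos}: {exc}"
                ) from exc
            info = dict(rec.info)
            yield VariantRecord(
                chrom=rec.chrom,
                pos=rec.pos,
                id=rec.id,  # pysam maps "." to None
                ref=rec.ref,
                alts=tuple(rec.alts or ()),
                qual=rec.qual,
                info=info,
                calls=calls,
                samples=self.samples,
            )

    def close(self) -> None:
        self._vf.close()

    def __enter__(self) -> "VcfReader":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def read_vcf(
    path: str | Path, region: Optional[str] = None
) -> Iterator[VariantRecord]:
    """Stream :class:`VariantRecord` objects from a VCF 4.x file.

    ``region`` restricts the stream to one chromosome label (string
    comparison; no "chr"-prefix normalisation).
    """
    reader = VcfReader(path, region=region)
    try:
        yield from reader
    finally:
        reader.close()


def read_phenotypes(path: str | Path) -> PhenotypeMap:
    """Read a two-column ``sample<TAB>status`` table (status: case|control)."""
    cases: list[str] = []
    controls: list[str] = []
    seen: set[str] = set()
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = re.split(r"\s+", line)
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            sample, status = parts
            if sample in seen:
                raise ValueError(f"{path}:{lineno}: duplicate sample {sample!r}")
            seen.add(sample)
            status_l = status.lower()
            if status_l == "case":
                cases.append(sample)
            elif status_l == "control":
                controls.append(sample)
            else:
                raise ValueError(
                    f"{path}:{lineno}: unknown status {status!r} (want case|control)"
                )
            n_rows += 1
    if n_rows == 0:
        raise ValueError(f"{path}: empty phenotype file")
    return PhenotypeMap(cases=cases, controls=controls)


def write_phenotypes(phen: PhenotypeMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# sample\tstatus\n")
        for s in phen.cases:
            fh.write(f"{s}\tcase\n")
        for s in phen.controls:
            fh.write(f"{s}\tcontrol\n")


def write_sites(sites, path: str | Path) -> None:
    """Write a named site set as a tab-delimited ``chrom pos label`` list.

    Positions stay 1-based (this is a site list, not BED).  Sorted by
    (chrom, pos) with chromosomes compared as strings.
    """
    with open(path, "w") as fh:
        fh.write("# chrom\tpos\tmethod\n")
        name = getattr(sites, "name", "sites")
        for chrom, pos in sorted(iter(sites), key=lambda k: (str(k[0]), k[1])):
            fh.write(f"{chrom}\t{pos}\t{name}\n")


def read_sites(path: str | Path):
    """Read a site list written by :func:`write_sites` back into a SiteSet."""
    from .intersect import SiteSet

    keys: set[tuple[str, int]] = set()
    name = Path(path).stem
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: malformed site line {line!r}")
            keys.add((parts[0], int(parts[1])))
            if len(parts) >= 3:
                name = parts[2]
    return SiteSet(name=name, sites=frozenset(keys))
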