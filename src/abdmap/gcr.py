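"""Genotype-criteria (GCR) scanning and its closed-form expectation.

At a fully penetrant autosomal recessive site sequenced in affected cases
and their obligate-carrier parents, the Mendelian expectation is that every
case is homozygous for one allele and every carrier is heterozygous and
carries that allele.  Scanning a multi-sample VCF for this pattern — with
per-genotype quality gates (GQ > 12, DP > 11 by default) — yields candidate
positions.  Under the null of independent genotypes each in one of three
states with probability 1/3, the pattern occurs at one site with probability
1/3^(n+m) for n cases and m carriers, so a file of S sites is expected to
contain S / 3^(n+m) qualifying positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .vcfio import GenotypeCall, PhenotypeMap, VariantRecord

__all__ = [
    "GCRConfig",
    "GCRHit",
    "site_meets_gcr",
    "scan_gcr",
    "expected_gcr_count",
    "round_half_away",
    "min_animals_for_unique_site",
]

ALLELE_MODES = ("either_homozygote", "alt_only")


@dataclass(frozen=True)
class GCRConfig:
    """Thresholds and pattern mode for the genotype-criteria scan.

    ``min_gq``/``min_dp`` are strict lower bounds: a genotype qualifies only
    with GQ > min_gq and DP > min_dp (the defaults 12 and 11 gate at
    GQ >= 13 and DP >= 12).  ``allele_mode`` chooses whether cases may be
    homozygous for either allele (the verbatim textual criterion) or for a
    non-reference allele only (the variant matching the single-pattern
    1/3^(n+m) probability model).
    """

    min_gq: int = 12
    min_dp: int = 11
    allele_mode: str = "either_homozygote"

    def __post_init__(self) -> None:
        if self.min_gq < 0 or self.min_dp < 0:
            raise ValueError("quality thresholds must be >= 0")
        if self.allele_mode not in ALLELE_MODES:
            raise ValueError(
                f"allele_mode must be one of {ALLELE_MODES}, got {self.allele_mode!r}"
            )


@dataclass(frozen=True)
class GCRHit:
    """A site matching the genotype criteria."""

    chrom: str
    pos: int
    case_allele: int
    record: VariantRecord = field(compare=False, hash=False)

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


def _passes_quality(call: GenotypeCall, cfg: GCRConfig) -> bool:
    return call.gq > cfg.min_gq and call.dp > cfg.min_dp


def site_meets_gcr(
    record: VariantRecord, phen: PhenotypeMap, cfg: GCRConfig = GCRConfig()
) -> tuple[bool, Optional[int]]:
    """Test one record against the genotype criteria.

    Returns ``(True, case_allele)`` iff every phenotyped genotype passes the
    quality gates, all cases are homozygous for one common allele, and all
    controls are heterozygous carrying that allele.  Missing genotypes never
    qualify.  Raises ``KeyError`` if a phenotyped sample is absent.
    """
    calls = {s: record.call_for(s) for s in phen.all_samples}
    if not all(_passes_quality(c, cfg) for c in calls.values()):
        return False, None

    case_allele: Optional[int] = None
    for s in phen.cases:
        c = calls[s]
        if not c.is_homozygous:
            return False, None
        if case_allele is None:
            case_allele = c.allele_a
        elif c.allele_a != case_allele:
            return False, None
    if case_allele is None:  # no cases configured
        return False, None
    if cfg.allele_mode == "alt_only" and case_allele == 0:
        return False, None

    for s in phen.controls:
        c = calls[s]
        if not (c.is_heterozygous and c.carries(case_allele)):
            return False, None
    return True, case_allele


def scan_gcr(
    records: Iterable[VariantRecord],
    phen: PhenotypeMap,
    cfg: GCRConfig = GCRConfig(),
) -> tuple[list[GCRHit], pd.DataFrame]:
    """Scan a record stream for GCR sites.

    Returns the hits in stream (genome) order plus a per-chromosome summary
    with the scanned-site count, hit count and the closed-form expected hit
    count ``n_sites / 3^(n_cases + n_controls)``.
    """
    hits: list[GCRHit] = []
    scanned: dict[str, int] = {}
    hit_counts: dict[str, int] = {}
    for rec in records:
        scanned[rec.chrom] = scanned.get(rec.chrom, 0) + 1
        ok, allele = site_meets_gcr(rec, phen, cfg)
        if ok:
            assert allele is not None
            hits.append(GCRHit(rec.chrom, rec.pos, allele, rec))
            hit_counts[rec.chrom] = hit_counts.get(rec.chrom, 0) + 1
    rows = []
    for chrom in scanned:
        n_sites = scanned[chrom]
        expected = expected_gcr_count(n_sites, phen.n_cases, phen.n_controls)
        rows.append(
            {
                "chrom": chrom,
                "n_sites_scanned": n_sites,
                "n_hits": hit_counts.get(chrom, 0),
                "expected_hits": expected,
                "expected_hits_rounded": round_half_away(expected),
            }
        )
    summary = pd.DataFrame(
        rows, columns=["chrom", "n_sites_scanned", "n_hits", "expected_hits",
                       "expected_hits_rounded"]
    )
    return hits, summary


def expected_gcr_count(n_sites: int, n_cases: int, n_controls: int) -> float:
    """Expected number of GCR sites: ``n_sites / 3**(n_cases + n_controls)``."""
    if n_sites < 0 or n_cases < 0 or n_controls < 0:
        raise ValueError("counts must be >= 0")
    return n_sites / 3 ** (n_cases + n_controls)


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (table display)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def min_animals_for_unique_site(n_sites: int) -> int:
    """Smallest k such that ``n_sites / 3**k <= 1``.

    This is the minimum number of genotyped animals (cases + carriers
    combined) at which at most one site in a file of ``n_sites`` positions
    is expected to match the genotype criteria by chance.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    k = 0
    power = 1
    while power < n_sites:  # exact integer arithmetic, no float log
        power *= 3
        k += 1
    return k
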