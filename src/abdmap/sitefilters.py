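"""Annotation-driven candidate filters: rsID novelty and VEP impact.

Two independent lines of evidence for a *novel* deleterious variant:

* absence of a dbSNP accession (rs number) in the VCF ID column — a
  previously catalogued variant is unlikely to be the new lethal; the
  stricter variant additionally requires every sequenced animal to carry at
  least one non-reference allele, since cases and obligate carriers all
  harbour the causal allele;
* a HIGH-impact consequence in the VEP ``CSQ`` annotation (splice
  acceptor/donor, stop gained, frameshift, ...), parsed from the field
  layout declared in the VCF header.  SIFT scores, when present in the
  annotation, are parsed and reported but never recomputed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional

from .intersect import SiteSet
from .vcfio import VariantRecord

__all__ = [
    "IMPACT_ORDER",
    "ImpactAnnotation",
    "has_rsid",
    "filter_no_rs",
    "filter_no_rs_all_alt",
    "consequence_impact_table",
    "parse_impact",
    "max_impact",
    "filter_high_impact",
]

log = logging.getLogger(__name__)

#: Severity order, most severe first.
IMPACT_ORDER = ("HIGH", "MODERATE", "LOW", "MODIFIER")
_IMPACT_RANK = {cat: i for i, cat in enumerate(IMPACT_ORDER)}

_RS_RE = re.compile(r"^rs\d+$", re.IGNORECASE)


@dataclass(frozen=True)
class ImpactAnnotation:
    """One transcript's VEP annotation for one record."""

    consequences: tuple[str, ...]
    impact: str
    gene: str = ""
    transcript: str = ""
    sift: Optional[float] = None

    def __post_init__(self) -> None:
        if self.impact not in IMPACT_ORDER:
            raise ValueError(f"unknown impact category {self.impact!r}")


def has_rsid(record_id: Optional[str]) -> bool:
    """True if any semicolon-separated ID token matches rs-number syntax."""
    if record_id is None:
        return False
    return any(_RS_RE.match(tok) for tok in record_id.split(";"))


def filter_no_rs(records: Iterable[VariantRecord], name: str = "NoRS") -> SiteSet:
    """Sites whose ID column carries no rs-number token."""
    keys = {rec.key for rec in records if not has_rsid(rec.id)}
    return SiteSet(name=name, sites=frozenset(keys))


def filter_no_rs_all_alt(
    records: Iterable[VariantRecord], name: Optional[str] = None
) -> SiteSet:
    """No-rsID sites where *every* sample carries >= 1 non-reference allele.

    Missing alleles do not count as alt (a missing call is not evidence of
    the variant), so a site with any fully missing genotype is excluded.
    With nine sequenced animals this is the "NoRS9" candidate set.
    """
    keys: set[tuple[str, int]] = set()
    n_samples = None
    for rec in records:
        n_samples = len(rec.calls)
        if has_rsid(rec.id):
            continue
        if all(c.carries_alt() for c in rec.calls):
            keys.add(rec.key)
    if name is None:
        name = f"NoRS{n_samples}" if n_samples else "NoRS_allalt"
    return SiteSet(name=name, sites=frozenset(keys))


_impact_table_cache: Optional[dict[str, str]] = None


def consequence_impact_table() -> dict[str, str]:
    """Bundled Ensembl mapping of consequence term -> impact category."""
    global _impact_table_cache
    if _impact_table_cache is None:
        table: dict[str, str] = {}
        text = (
            resources.files("abdmap")
            .joinpath("data/consequence_impact.tsv")
            .read_text()
        )
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            term, impact = line.split("\t")
            table[term] = impact
        _impact_table_cache = table
    return _impact_table_cache


def _parse_sift(token: str) -> Optional[float]:
    # VEP writes SIFT as "deleterious(0.01)" or a bare number.
    m = re.search(r"\(([\d.eE+-]+)\)", token)
    if m:
        token = m.group(1)
    try:
        return float(token)
    except ValueError:
        return None


def parse_impact(
    record: VariantRecord, csq_format: Optional[list[str]]
) -> list[ImpactAnnotation]:
    """Parse the CSQ INFO field into per-transcript annotations.

    The IMPACT sub-field is used verbatim when the header declares one;
    otherwise the impact is looked up from the bundled consequence-term
    table (unknown terms fall back to MODIFIER with a warning).  Records
    without a CSQ field yield an empty list.
    """
    csq = record.info.get("CSQ")
    if csq is None:
        return []
    if csq_format is None:
        raise ValueError(
            f"{record.chrom}:{record.pos} carries CSQ but the header declares "
            "no CSQ Format layout"
        )
    entries = csq if isinstance(csq, (tuple, list)) else [csq]
    idx = {fname: i for i, fname in enumerate(csq_format)}
    table = consequence_impact_table()
    out: list[ImpactAnnotation] = []
    for entry in entries:
        fields = str(entry).split("|")

        def get(fname: str) -> str:
            i = idx.get(fname)
            return fields[i] if i is not None and i < len(fields) else ""

        consequences = tuple(t for t in get("Consequence").split("&") if t)
        impact = get("IMPACT")
        if impact not in IMPACT_ORDER:
            impact = ""
        if not impact:
            ranks = []
            for term in consequences:
                if term not in table:
                    log.warning("unknown consequence term %r -> MODIFIER", term)
                ranks.append(_IMPACT_RANK[table.get(term, "MODIFIER")])
            impact = IMPACT_ORDER[min(ranks)] if ranks else "MODIFIER"
        sift_tok = get("SIFT")
        out.append(
            ImpactAnnotation(
                consequences=consequences,
                impact=impact,
                gene=get("SYMBOL") or get("Gene"),
                transcript=get("Feature"),
                sift=_parse_sift(sift_tok) if sift_tok else None,
            )
        )
    return out


def max_impact(annotations: Iterable[ImpactAnnotation]) -> Optional[str]:
    """Most severe impact category among the annotations, None if empty."""
    ranks = [_IMPACT_RANK[a.impact] for a in annotations]
    return IMPACT_ORDER[min(ranks)] if ranks else None


def filter_high_impact(
    records: Iterable[VariantRecord],
    csq_format: Optional[list[str]],
    name: str = "SIFT",
) -> tuple[SiteSet, int, int]:
    """Sites whose maximum VEP impact is HIGH.

    Returns ``(site_set, n_records, n_sites)``: several transcripts can
    annotate one position, so the HIGH-impact record count generally
    exceeds the deduplicated position count and both are reported.
    """
    keys: set[tuple[str, int]] = set()
    n_records = 0
    for rec in records:
        anns = parse_impact(rec, csq_format)
        n_high = sum(1 for a in anns if a.impact == "HIGH")
        if n_high:
            n_records += n_high
            keys.add(rec.key)
    return SiteSet(name=name, sites=frozenset(keys)), n_records, len(keys)
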