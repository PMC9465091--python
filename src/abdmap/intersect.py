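"""Combining the candidate site sets from independent mapping methods.

Each method (genotype criteria, ABD significance, no-rsID novelty, HIGH
impact annotation) yields a named set of genomic positions.  A site found
by all of them is the prime candidate for the causal variant.  Sites are
keyed by (chrom, pos) only — linking on position, not alleles — with an
allele-aware key available behind a flag at set-construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

__all__ = [
    "SiteSet",
    "Region",
    "OverlapReport",
    "abd_site_set",
    "overlap_matrix",
    "report_candidates",
]


@dataclass(frozen=True)
class SiteSet:
    """A named set of genomic positions produced by one mapping method."""

    name: str
    sites: frozenset  # of (chrom, pos) or (chrom, pos, alleles) keys

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("SiteSet name must be non-empty")
        object.__setattr__(self, "sites", frozenset(self.sites))

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator:
        return iter(self.sites)

    def __contains__(self, key) -> bool:
        return key in self.sites

    def restrict(self, region: Optional["Region"]) -> "SiteSet":
        if region is None:
            return self
        return SiteSet(
            name=self.name,
            sites=frozenset(k for k in self.sites if region.contains(k[0], k[1])),
        )


@dataclass(frozen=True)
class Region:
    """A 1-based inclusive chromosomal interval, e.g. ``4:70889821-78684588``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start > end")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    @classmethod
    def parse(cls, text: str) -> "Region":
        chrom, _, span = text.partition(":")
        start, _, end = span.partition("-")
        try:
            return cls(chrom, int(start.replace(",", "")), int(end.replace(",", "")))
        except ValueError as exc:
            raise ValueError(f"cannot parse region {text!r} (want chrom:start-end)") from exc

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def abd_site_set(track, threshold: float, name: str = "ABD") -> SiteSet:
    """Sites of an ABD track whose score meets the threshold."""
    d = track.data
    above = d["abd_kb"] >= threshold
    keys = frozenset(
        zip(d.loc[above, "chrom"].astype(str), d.loc[above, "pos"].astype(int))
    )
    return SiteSet(name=name, sites=keys)


@dataclass
class OverlapReport:
    """All k-way intersection counts between named site sets."""

    set_names: list[str]
    sizes: dict[str, int]
    counts: dict[frozenset, int]  # frozenset of names -> |intersection|
    region: Optional[Region] = None
    region_sizes: dict[str, int] = field(default_factory=dict)
    region_counts: dict[frozenset, int] = field(default_factory=dict)
    candidates: list = field(default_factory=list)

    def count(self, *names: str) -> int:
        return self.counts[frozenset(names)]

    def region_count(self, *names: str) -> int:
        return self.region_counts[frozenset(names)]

    def _cell(self, names: Sequence[str]) -> str:
        key = frozenset(names)
        n = self.sizes[names[0]] if len(names) == 1 else self.counts[key]
        if self.region is None:
            return str(n)
        rn = (
            self.region_sizes[names[0]]
            if len(names) == 1
            else self.region_counts[key]
        )
        return f"{n} ({rn})"

    def to_frame(self) -> pd.DataFrame:
        """Overlap table: per-set rows (lower triangle with sizes on the
        diagonal), then combined-set rows against the remaining sets."""
        names = self.set_names
        columns = names
        rows: list[tuple[str, dict[str, str]]] = []
        for i, ni in enumerate(names):
            cells = {}
            for j, nj in enumerate(names):
                if j < i:
                    cells[nj] = self._cell([ni, nj])
                elif j == i:
                    cells[nj] = self._cell([ni])
            rows.append((ni, cells))
        # combined rows: every combo of >=2 leading sets vs each later set
        for r in range(2, len(names)):
            for combo in combinations(names, r):
                last = max(names.index(n) for n in combo)
                cells = {}
                for nj in names[last + 1 :]:
                    cells[nj] = self._cell(list(combo) + [nj])
                if cells:
                    rows.append(("+".join(combo), cells))
        frame = pd.DataFrame(
            [{"method": label, **{c: cells.get(c, "") for c in columns}}
             for label, cells in rows]
        )
        return frame

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            if self.region is not None:
                fh.write(f"# counts restricted to {self.region} in parentheses\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)


def overlap_matrix(
    sets: Sequence[SiteSet], region: Optional[Region] = None
) -> OverlapReport:
    """Full intersection lattice over >= 2 named site sets.

    When ``region`` is given every count is also computed on the
    region-restricted sets.  ``candidates`` is the sorted intersection of
    all sets.
    """
    if len(sets) < 2:
        raise ValueError("need at least two site sets")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate set names: {names}")
    by_name = {s.name: s.sites for s in sets}

    def lattice(site_map: dict[str, frozenset]) -> dict[frozenset, int]:
        counts: dict[frozenset, int] = {}
        for r in range(2, len(names) + 1):
            for combo in combinations(names, r):
                inter = site_map[combo[0]]
                for n in combo[1:]:
                    inter = inter & site_map[n]
                counts[frozenset(combo)] = len(inter)
        return counts

    counts = lattice(by_name)
    inter_all = by_name[names[0]]
    for n in names[1:]:
        inter_all = inter_all & by_name[n]
    report = OverlapReport(
        set_names=names,
        sizes={n: len(by_name[n]) for n in names},
        counts=counts,
        candidates=sorted(inter_all, key=lambda k: (str(k[0]), k[1])),
    )
    if region is not None:
        restricted = {s.name: s.restrict(region).sites for s in sets}
        report.region = region
        report.region_sizes = {n: len(restricted[n]) for n in names}
        report.region_counts = lattice(restricted)
    return report


def report_candidates(report: OverlapReport, annotations: Optional[dict] = None) -> str:
    """Human-readable verdict on the final candidate list.

    ``annotations`` may map a (chrom, pos) key to extra text (ABD score,
    impact, ...) appended to that candidate's line.
    """
    lines = [f"Methods intersected: {', '.join(report.set_names)}"]
    if report.region is not None:
        lines.append(f"Region restriction: {report.region}")
    if report.candidates:
        lines.append(
            f"{len(report.candidates)} site(s) present in all "
            f"{len(report.set_names)} sets:"
        )
        for key in report.candidates:
            extra = ""
            if annotations and key in annotations:
                extra = f"  [{annotations[key]}]"
            lines.append(f"  {key[0]}:{key[1]}{extra}")
    else:
        lines.append("No site present in all sets.")
        k = len(report.set_names) - 1
        best = {
            combo: n
            for combo, n in report.counts.items()
            if len(combo) == k and n > 0
        }
        if best:
            lines.append(f"Largest {k}-way survivors:")
            for combo, n in sorted(best.items(), key=lambda kv: -kv[1]):
                lines.append(f"  {'+'.join(sorted(combo))}: {n} site(s)")
    return "\n".join(lines)
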