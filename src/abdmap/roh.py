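"""Runs of homozygosity (ROH) from a zygosity matrix, plus site hard-filtering.

A run of homozygosity is a maximal stretch of consecutive homozygous calls
along one chromosome of one individual.  Both homozygote classes extend a
run; a heterozygous call terminates it; chromosome ends terminate it.  Run
length is the inclusive base-pair span (end - start + 1) expressed in Kb.
Missing genotypes are, by default, recoded to homozygous reference before
run detection; a stricter policy treats them as run breakers instead, which
avoids inflating ROH in low-coverage samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .vcfio import GenotypeCall, PhenotypeMap, VariantRecord

__all__ = [
    "HOM_REF",
    "HET",
    "HOM_ALT",
    "MISSING_CODE",
    "GenotypeMatrix",
    "ROHRun",
    "zygosity_code",
    "zygosity_matrix",
    "roh_runs",
    "roh_length_at_site",
    "site_roh_lengths",
    "hard_filter_sites",
]

log = logging.getLogger(__name__)

HOM_REF = 0
HET = 1
HOM_ALT = 2
MISSING_CODE = 3

MISSING_POLICIES = ("hom_ref", "break")


@dataclass
class GenotypeMatrix:
    """Per-chromosome zygosity codes for a fixed sample list.

    ``positions[chrom]`` is a strictly increasing int64 vector of 1-based
    positions; ``codes[chrom]`` is a (n_samples, n_sites) uint8 array of
    zygosity codes.  Built from biallelic SNVs only.
    """

    samples: tuple[str, ...]
    positions: dict[str, np.ndarray]
    codes: dict[str, np.ndarray]
    n_skipped_non_biallelic_snv: int = 0

    @property
    def chroms(self) -> list[str]:
        return list(self.positions)

    @property
    def n_sites(self) -> int:
        return sum(len(p) for p in self.positions.values())

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)


def zygosity_code(call: GenotypeCall, missing_policy: str = "hom_ref") -> int:
    """Map a genotype call to a zygosity code under the missing policy."""
    if call.is_missing:
        # "break" treats a missing call like a heterozygote so that it
        # terminates runs; the default assumes homozygous reference.
        return HOM_REF if missing_policy == "hom_ref" else HET
    if call.is_heterozygous:
        return HET
    return HOM_REF if call.allele_a == 0 else HOM_ALT


def zygosity_matrix(
    records: Iterable[VariantRecord],
    phen: PhenotypeMap,
    missing_policy: str = "hom_ref",
) -> GenotypeMatrix:
    """Build the zygosity matrix for all phenotyped samples.

    Only biallelic SNVs enter the matrix (others are counted and skipped).
    Duplicate positions keep the first record; out-of-order positions on a
    chromosome raise, instructing the caller to sort the VCF.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"missing_policy must be one of {MISSING_POLICIES}")
    samples = tuple(phen.all_samples)
    pos_by_chrom: dict[str, list[int]] = {}
    codes_by_chrom: dict[str, list[list[int]]] = {}
    n_skipped = 0
    n_dup = 0
    for rec in records:
        if not (rec.is_biallelic and rec.is_snv):
            n_skipped += 1
            continue
        plist = pos_by_chrom.setdefault(rec.chrom, [])
        if plist:
            if rec.pos == plist[-1]:
                n_dup += 1
                continue
            if rec.pos < plist[-1]:
                raise ValueError(
                    f"unsorted positions on {rec.chrom}: {rec.pos} after "
                    f"{plist[-1]}; sort the VCF by position first"
                )
        col = [
            zygosity_code(rec.call_for(s), missing_policy) for s in samples
        ]
        plist.append(rec.pos)
        codes_by_chrom.setdefault(rec.chrom, []).append(col)
    if n_skipped:
        log.info("zygosity_matrix: skipped %d non-biallelic-SNV records", n_skipped)
    if n_dup:
        log.warning("zygosity_matrix: %d duplicate positions dropped (first kept)", n_dup)
    positions = {
        c: np.asarray(p, dtype=np.int64) for c, p in pos_by_chrom.items()
    }
    codes = {
        c: np.asarray(cols, dtype=np.uint8).T  # sites x samples -> samples x sites
        for c, cols in codes_by_chrom.items()
    }
    return GenotypeMatrix(
        samples=samples,
        positions=positions,
        codes=codes,
        n_skipped_non_biallelic_snv=n_skipped,
    )


@dataclass(frozen=True)
class ROHRun:
    """A maximal homozygous stretch in one individual on one chromosome."""

    chrom: str
    start_index: int
    end_index: int  # inclusive
    start_pos: int
    end_pos: int

    @property
    def length_kb(self) -> float:
        return (self.end_pos - self.start_pos + 1) / 1000.0

    @property
    def n_sites(self) -> int:
        return self.end_index - self.start_index + 1


def roh_runs(
    row: np.ndarray, positions: np.ndarray, chrom: str = ""
) -> list[ROHRun]:
    """Maximal homozygous runs in one sample's zygosity row.

    HOM_REF and HOM_ALT both extend a run; HET terminates it.  An isolated
    homozygous site is a run spanning 1 bp (0.001 Kb).
    """
    row = np.asarray(row)
    positions = np.asarray(positions)
    if len(row) != len(positions):
        raise ValueError("row and positions length mismatch")
    hom = (row == HOM_REF) | (row == HOM_ALT)
    runs: list[ROHRun] = []
    start: Optional[int] = None
    for i, h in enumerate(hom):
        if h and start is None:
            start = i
        elif not h and start is not None:
            runs.append(
                ROHRun(chrom, start, i - 1, int(positions[start]), int(positions[i - 1]))
            )
            start = None
    if start is not None:
        n = len(row)
        runs.append(
            ROHRun(chrom, start, n - 1, int(positions[start]), int(positions[n - 1]))
        )
    return runs


def roh_length_at_site(runs: Sequence[ROHRun], site_index: int) -> float:
    """Length (Kb) of the run containing ``site_index``; 0 for HET sites."""
    if site_index < 0:
        raise IndexError(f"site_index {site_index} out of range")
    for r in runs:
        if r.start_index <= site_index <= r.end_index:
            return r.length_kb
    return 0.0


def site_roh_lengths(row: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Per-site Kb length of the containing run for one sample (vectorised).

    Equivalent to ``roh_length_at_site(roh_runs(row, positions), i)`` for
    every i, but fills whole runs at once.
    """
    out = np.zeros(len(positions), dtype=np.float64)
    for r in roh_runs(row, positions):
        out[r.start_index : r.end_index + 1] = r.length_kb
    return out


def _metric_value(rec: VariantRecord, var: str) -> Optional[float]:
    if var.upper() == "QUAL":
        return rec.qual
    v = rec.info.get(var)
    if v is None:
        return None
    if isinstance(v, (tuple, list)):
        vals = [float(x) for x in v if x is not None]
        return float(np.mean(vals)) if vals else None
    try:
        return float(v)
    except (TypeError, ValueError):
        return None


def hard_filter_sites(
    records: Iterable[VariantRecord],
    mode: str = "auto_2sd",
    fixed: Optional[dict[str, tuple[Optional[float], Optional[float]]]] = None,
    variables: Sequence[str] = ("QUAL", "DP"),
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Hard-filter sites on per-site metrics before ROH analysis.

    ``mode='fixed'`` drops sites whose metric falls outside the configured
    (min, max) bounds in ``fixed``.  ``mode='auto_2sd'`` computes each
    configured variable's mean and standard deviation over all sites in a
    first pass and keeps sites within mean +/- 2 s.d. in a second pass — a
    generic substitute for recalibration when no truth set exists.  A
    variable whose s.d. is 0 filters nothing; records lacking a metric are
    not filtered on it.  Returns the kept records and a per-variable report.
    """
    recs = list(records)
    if mode not in ("fixed", "auto_2sd"):
        raise ValueError("mode must be 'fixed' or 'auto_2sd'")
    if mode == "fixed":
        bounds = dict(fixed or {})
    else:
        bounds = {}
        for var in variables:
            vals = np.array(
                [v for r in recs if (v := _metric_value(r, var)) is not None],
                dtype=float,
            )
            if len(vals) == 0:
                raise ValueError(f"metric {var!r} absent from all records")
            sd = float(vals.std(ddof=0))
            if sd == 0.0:
                bounds[var] = (None, None)  # degenerate: keep all
            else:
                mu = float(vals.mean())
                bounds[var] = (mu - 2 * sd, mu + 2 * sd)

    dropped_by: dict[str, int] = {v: 0 for v in bounds}
    kept: list[VariantRecord] = []
    for rec in recs:
        ok = True
        for var, (lo, hi) in bounds.items():
            v = _metric_value(rec, var)
            if v is None:
                continue
            if (lo is not None and v < lo) or (hi is not None and v > hi):
                dropped_by[var] += 1
                ok = False
        if ok:
            kept.append(rec)
    report = pd.DataFrame(
        [
            {
                "variable": var,
                "lower": bounds[var][0],
                "upper": bounds[var][1],
                "n_violations": dropped_by[var],
            }
            for var in bounds
        ],
        columns=["variable", "lower", "upper", "n_violations"],
    )
    report.attrs["n_input"] = len(recs)
    report.attrs["n_kept"] = len(kept)
    return kept, report
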