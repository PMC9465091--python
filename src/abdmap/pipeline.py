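"""End-to-end workflow: scan, filter, map, intersect, report.

Wires the stages into the one-command mapping run: genotype-criteria scan,
optional hard filtering, ABD with permutation threshold, the no-rsID /
all-alt novelty filter, the optional HIGH-impact annotation filter, and
the final intersection of the candidate site sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .abd import AutozygosityDifferenceModel, ABDResults
from .gcr import GCRConfig, scan_gcr
from .intersect import (
    Region,
    SiteSet,
    overlap_matrix,
    report_candidates,
)
from .roh import hard_filter_sites, zygosity_matrix
from .sitefilters import filter_high_impact, filter_no_rs_all_alt
from .vcfio import (
    PhenotypeMap,
    VcfReader,
    read_phenotypes,
    write_sites,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for one end-to-end mapping run."""

    vcf: Path
    phenotypes: Path
    out_dir: Path
    gcr: GCRConfig = field(default_factory=GCRConfig)
    n_perm: int = 100
    alpha: float = 0.01
    seed: Optional[int] = None
    missing_policy: str = "hom_ref"
    hard_filter: str = "none"  # none | auto_2sd | fixed
    hard_filter_variables: tuple[str, ...] = ("QUAL", "DP")
    hard_filter_fixed: Optional[dict] = None
    use_impact_filter: bool = True
    region: Optional[Region] = None

    def __post_init__(self) -> None:
        self.vcf = Path(self.vcf)
        self.phenotypes = Path(self.phenotypes)
        self.out_dir = Path(self.out_dir)


@dataclass
class PipelineResult:
    """Outputs of one end-to-end run."""

    candidates: list
    sets: list[SiteSet]
    abd: ABDResults
    gcr_hits: list
    report_text: str
    unique_candidate: Optional[tuple] = None


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    phen = read_phenotypes(cfg.phenotypes)

    log.info("stage gcr: scanning %s", cfg.vcf)
    with VcfReader(cfg.vcf) as reader:
        phen.validate_against(reader.samples)
        csq_format = reader.csq_format
        records = list(reader)
    hits, gcr_summary = scan_gcr(records, phen, cfg.gcr)
    gcr_set = SiteSet(name="GCR", sites=frozenset(h.key for h in hits))
    log.info("stage gcr: %d hits", len(gcr_set))
    gcr_summary.to_csv(cfg.out_dir / "gcr_by_chrom.tsv", sep="\t", index=False)
    write_sites(gcr_set, cfg.out_dir / "gcr_sites.tsv")

    abd_input = records
    if cfg.hard_filter != "none":
        log.info("stage hard-filter: mode=%s", cfg.hard_filter)
        abd_input, hf_report = hard_filter_sites(
            records,
            mode=cfg.hard_filter,
            fixed=cfg.hard_filter_fixed,
            variables=cfg.hard_filter_variables,
        )
        hf_report.to_csv(cfg.out_dir / "hard_filter_report.tsv", sep="\t",
                         index=False)
        log.info(
            "stage hard-filter: kept %d of %d records",
            hf_report.attrs["n_kept"], hf_report.attrs["n_input"],
        )

    log.info("stage abd: %d permutations at alpha=%s", cfg.n_perm, cfg.alpha)
    matrix = zygosity_matrix(abd_input, phen, cfg.missing_policy)
    results = AutozygosityDifferenceModel(matrix, phen).fit(
        n_perm=cfg.n_perm, alpha=cfg.alpha, seed=cfg.seed
    )
    results.to_tsv(cfg.out_dir / "abd_track.tsv")
    results.significant_regions().to_csv(
        cfg.out_dir / "abd_regions.tsv", sep="\t", index=False
    )
    abd_set = results.site_set()
    log.info("stage abd: threshold %.1f Kb, %d significant sites",
             results.threshold_kb, len(abd_set))
    write_sites(abd_set, cfg.out_dir / "abd_sites.tsv")

    nors_set = filter_no_rs_all_alt(records)
    log.info("stage nors: %d sites", len(nors_set))
    write_sites(nors_set, cfg.out_dir / "nors_sites.tsv")

    sets = [gcr_set, abd_set, nors_set]
    if cfg.use_impact_filter:
        if csq_format is None:
            raise ValueError(
                "impact filter requested but the VCF carries no CSQ header; "
                "rerun with the impact filter disabled or annotate the VCF"
            )
        high_set, n_rec, n_sites = filter_high_impact(records, csq_format)
        log.info("stage impact: %d HIGH records at %d sites", n_rec, n_sites)
        write_sites(high_set, cfg.out_dir / "high_impact_sites.tsv")
        sets.append(high_set)

    report = overlap_matrix(sets, region=cfg.region)
    report.to_tsv(cfg.out_dir / "overlap_matrix.tsv")
    ann = {}
    score_by_key = {
        (row.chrom, int(row.pos)): float(row.abd_kb)
        for row in results.data.itertuples()
    }
    for key in report.candidates:
        if key in score_by_key:
            ann[key] = f"ABD={score_by_key[key]:.1f} Kb"
    text = report_candidates(report, annotations=ann)
    (cfg.out_dir / "candidates.txt").write_text(text + "\n")
    log.info("pipeline: %d final candidate(s)", len(report.candidates))

    return PipelineResult(
        candidates=report.candidates,
        sets=sets,
        abd=results,
        gcr_hits=hits,
        report_text=text,
        unique_candidate=report.candidates[0]
        if len(report.candidates) == 1
        else None,
    )
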