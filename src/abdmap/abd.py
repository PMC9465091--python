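"""Autozygosity-by-difference (ABD) mapping with permutation thresholds.

The ABD score at a SNV position is the mean length (Kb) of the run of
homozygosity spanning that position in cases minus the same mean in
controls.  A new fully penetrant recessive variant sits on a long founder
haplotype that is homozygous in affected animals, so the score is large
around the causal site while breed-wide ROH, present in both groups, cancel
out.

Significance is assessed by permutation: animals are reallocated to the
case/control groups at random (group sizes preserved) and the whole track
recomputed.  Permuted scores from all sites are pooled and the empirical
(1 - alpha) quantile of the pool is the genome-wide threshold; pooling is
what lets 100 permutations support a 0.01-level cut-off.  Per-site
empirical p-values against the same pooled null are also reported.

The module exposes the track/threshold primitives as free functions and a
model-style surface on top: ``AutozygosityDifferenceModel(matrix, phen)``
with ``.fit()`` returning an :class:`ABDResults`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .roh import GenotypeMatrix, site_roh_lengths, zygosity_matrix
from .vcfio import PhenotypeMap

__all__ = [
    "ABDTrack",
    "abd_track",
    "permutation_threshold",
    "significant_regions",
    "AutozygosityDifferenceModel",
    "ABDResults",
]

log = logging.getLogger(__name__)


def _roh_length_matrix(matrix: GenotypeMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-sample per-site ROH length (Kb).

    Returns a (chrom, pos) frame and an (n_samples, n_total_sites) array.
    Sample ROH lengths do not depend on phenotype labels, so permutation
    tests only ever re-average the rows of this matrix.
    """
    frames = []
    blocks = []
    for chrom in matrix.chroms:
        pos = matrix.positions[chrom]
        codes = matrix.codes[chrom]
        block = np.vstack(
            [site_roh_lengths(codes[i], pos) for i in range(codes.shape[0])]
        )
        blocks.append(block)
        frames.append(pd.DataFrame({"chrom": chrom, "pos": pos}))
    sites = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "pos"]
    )
    L = np.hstack(blocks) if blocks else np.zeros((len(matrix.samples), 0))
    return sites, L


@dataclass
class ABDTrack:
    """Per-site group means of ROH length and their difference (Kb)."""

    data: pd.DataFrame  # columns: chrom, pos, mean_case_kb, mean_ctrl_kb, abd_kb
    n_cases: int
    n_controls: int

    @property
    def scores(self) -> np.ndarray:
        return self.data["abd_kb"].to_numpy()


def abd_track(matrix: GenotypeMatrix, phen: PhenotypeMap) -> ABDTrack:
    """Compute the observed ABD track (deterministic)."""
    if phen.n_cases < 1 or phen.n_controls < 1:
        raise ValueError("need at least one case and one control")
    sites, L = _roh_length_matrix(matrix)
    case_idx = [matrix.sample_index(s) for s in phen.cases]
    ctrl_idx = [matrix.sample_index(s) for s in phen.controls]
    mean_case = L[case_idx].mean(axis=0)
    mean_ctrl = L[ctrl_idx].mean(axis=0)
    data = sites.assign(
        mean_case_kb=mean_case,
        mean_ctrl_kb=mean_ctrl,
        abd_kb=mean_case - mean_ctrl,
    )
    return ABDTrack(data=data, n_cases=phen.n_cases, n_controls=phen.n_controls)


def permutation_threshold(
    matrix: GenotypeMatrix,
    phen: PhenotypeMap,
    n_perm: int = 100,
    alpha: float = 0.01,
    seed: Optional[int] = None,
) -> tuple[float, np.ndarray]:
    """Genome-wide ABD threshold from label permutations.

    Each permutation reallocates the samples to case/control groups
    uniformly at random without replacement, preserving group sizes, and
    recomputes the full track.  All permuted per-site scores are pooled;
    the empirical (1 - alpha) quantile of the pool is returned as the
    threshold, together with per-site empirical p-values
    ``(1 + #{pooled >= observed}) / (1 + pool size)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if phen.n_cases < 1 or phen.n_controls < 1:
        raise ValueError("need at least one case and one control")
    rng = np.random.default_rng(seed)
    sites, L = _roh_length_matrix(matrix)
    n_samples = len(matrix.samples)
    case_idx = np.array([matrix.sample_index(s) for s in phen.cases])
    ctrl_idx = np.array([matrix.sample_index(s) for s in phen.controls])
    observed = L[case_idx].mean(axis=0) - L[ctrl_idx].mean(axis=0)

    n_distinct = math.comb(n_samples, phen.n_cases)
    if n_perm > n_distinct:
        log.info(
            "n_perm=%d exceeds the %d distinct labelings; permutations are "
            "sampled with replacement over labelings",
            n_perm,
            n_distinct,
        )
    k = phen.n_cases
    pooled = np.empty((n_perm, L.shape[1]), dtype=np.float64)
    for p in range(n_perm):
        perm = rng.permutation(n_samples)
        pooled[p] = L[perm[:k]].mean(axis=0) - L[perm[k:]].mean(axis=0)
    pool = pooled.ravel()
    # "higher" keeps the threshold an actually-attained permuted score.
    threshold = float(np.quantile(pool, 1.0 - alpha, method="higher"))
    pool_sorted = np.sort(pool)
    n_ge = pool_sorted.size - np.searchsorted(pool_sorted, observed, side="left")
    pvalues = (1.0 + n_ge) / (1.0 + pool_sorted.size)
    return threshold, pvalues


def significant_regions(track: ABDTrack, threshold: float) -> pd.DataFrame:
    """Maximal consecutive stretches of sites with score >= threshold.

    Region span is reported as ``end_pos - start_pos + 1`` bp.
    """
    rows = []
    df = track.data
    for chrom, sub in df.groupby("chrom", sort=False):
        above = (sub["abd_kb"] >= threshold).to_numpy()
        pos = sub["pos"].to_numpy()
        scores = sub["abd_kb"].to_numpy()
        start = None
        for i in range(len(above) + 1):
            active = i < len(above) and above[i]
            if active and start is None:
                start = i
            elif not active and start is not None:
                seg = slice(start, i)
                rows.append(
                    {
                        "chrom": chrom,
                        "start_pos": int(pos[start]),
                        "end_pos": int(pos[i - 1]),
                        "length_bp": int(pos[i - 1] - pos[start] + 1),
                        "n_sites": i - start,
                        "max_score_kb": float(scores[seg].max()),
                    }
                )
                start = None
    return pd.DataFrame(
        rows,
        columns=["chrom", "start_pos", "end_pos", "length_bp", "n_sites",
                 "max_score_kb"],
    )


class AutozygosityDifferenceModel:
    """ABD analysis of a case/control zygosity matrix.

    Parameters
    ----------
    matrix:
        Biallelic-SNV zygosity matrix covering every phenotyped sample.
    phen:
        Case/control partition of the matrix's samples.
    """

    def __init__(self, matrix: GenotypeMatrix, phen: PhenotypeMap):
        phen.validate_against(matrix.samples)
        self.matrix = matrix
        self.phen = phen

    @classmethod
    def from_vcf(
        cls,
        path: str | Path,
        phen: PhenotypeMap,
        missing_policy: str = "hom_ref",
    ) -> "AutozygosityDifferenceModel":
        from .vcfio import read_vcf

        matrix = zygosity_matrix(read_vcf(path), phen, missing_policy)
        return cls(matrix, phen)

    def fit(
        self,
        n_perm: int = 100,
        alpha: float = 0.01,
        seed: Optional[int] = None,
    ) -> "ABDResults":
        """Compute the observed track and its permutation threshold."""
        track = abd_track(self.matrix, self.phen)
        threshold, pvalues = permutation_threshold(
            self.matrix, self.phen, n_perm=n_perm, alpha=alpha, seed=seed
        )
        data = track.data.assign(p_emp=pvalues)
        return ABDResults(
            model=self,
            track=ABDTrack(data=data, n_cases=track.n_cases,
                           n_controls=track.n_controls),
            threshold_kb=threshold,
            alpha=alpha,
            n_perm=n_perm,
            seed=seed,
        )


@dataclass
class ABDResults:
    """Fitted ABD track with its permutation threshold."""

    model: AutozygosityDifferenceModel
    track: ABDTrack
    threshold_kb: float
    alpha: float
    n_perm: int
    seed: Optional[int] = None

    @property
    def data(self) -> pd.DataFrame:
        return self.track.data

    def significant_regions(self) -> pd.DataFrame:
        return significant_regions(self.track, self.threshold_kb)

    def site_set(self, name: str = "ABD", threshold: Optional[float] = None):
        from .intersect import abd_site_set

        return abd_site_set(self.track, self.threshold_kb if threshold is None
                            else threshold, name=name)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# ABD track; threshold_kb={self.threshold_kb:.3f} "
                f"(alpha={self.alpha}, n_perm={self.n_perm})\n"
            )
            self.data.to_csv(fh, sep="\t", index=False, float_format="%.4f")

    def summary(self) -> str:
        regions = self.significant_regions()
        d = self.data
        lines = [
            "Autozygosity-by-difference results",
            "==================================",
            f"Samples:            {self.track.n_cases} cases / "
            f"{self.track.n_controls} controls",
            f"Sites (biallelic SNV): {len(d)}",
            f"Permutations:       {self.n_perm} (alpha={self.alpha}, "
            f"seed={self.seed})",
            f"Genome-wide threshold: {self.threshold_kb:.3f} Kb",
            f"Max ABD score:      {d['abd_kb'].max():.3f} Kb"
            if len(d)
            else "Max ABD score:      n/a",
            f"Significant regions: {len(regions)}",
        ]
        if len(regions):
            lines.append("")
            lines.append(regions.to_string(index=False))
        return "\n".join(lines)

    def plot_manhattan(self, out: Optional[str | Path] = None, ax=None):
        """Manhattan-style plot of the ABD score with the threshold line."""
        import matplotlib

        if out is not None:
            matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        offset = 0
        ticks, labels = [], []
        for i, (chrom, sub) in enumerate(self.data.groupby("chrom", sort=False)):
            x = sub["pos"].to_numpy() + offset
            ax.scatter(x, sub["abd_kb"], s=4,
                       color="C0" if i % 2 == 0 else "C1")
            ticks.append(offset + sub["pos"].max() / 2)
            labels.append(str(chrom))
            offset += int(sub["pos"].max())
        ax.axhline(self.threshold_kb, color="red", lw=1,
                   label=f"p<{self.alpha} threshold ({self.threshold_kb:.0f} Kb)")
        ax.set_xticks(ticks, labels)
        ax.set_xlabel("chromosome")
        ax.set_ylabel("ABD score (Kb)")
        ax.legend(loc="upper right", fontsize=8)
        if out is not None:
            ax.figure.savefig(out, dpi=150, bbox_inches="tight")
            plt.close(ax.figure)
        return ax
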