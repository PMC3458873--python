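"""Per-locus clinality screening and marker-class contingency analysis.

A locus is *clinal* when the broken-stick fit beats the horizontal fit in a
likelihood-ratio test at alpha = 0.05.  It is additionally *Co-Co eligible*
when its per-locus pairwise-FST matrix shows significant isolation by
latitudinal distance in a one-sided Mantel test at the same level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .cline import (
    BrokenStickCline,
    ClineFitError,
    HorizontalCline,
    lrt_clinal,
)
from .datasets import ClineDataset
from .focal import FocalAlleleError, focal_series, select_focal_allele
from .stats import latitude_distance_matrix, mantel_test, pairwise_fst_matrix


@dataclass
class ScreenResult:
    """Screening outcome for one locus."""

    locus: str
    focal_allele: str | None
    lrt_stat: float
    lrt_p: float
    mantel_r: float
    mantel_p: float
    is_clinal: bool
    coco_eligible: bool
    midpoint: float | None
    slope: float | None
    flags: tuple[str, ...] = ()


class ClinalScreen(BaseEstimator):
    """Screen every locus of a dataset for clinality and Co-Co eligibility.

    Parameters
    ----------
    alpha
        Significance level for both the LRT and the Mantel test.
    n_permutations
        Mantel permutations (seeded; default 999).
    objective
        Cline-fit objective, "binomial" (default) or "gaussian".
    run_mantel
        Skip the (slow) Mantel test when False; coco_eligible then equals
        is_clinal.
    adjust
        Optional "fdr_bh" to Benjamini-Hochberg-adjust LRT p-values across
        loci before thresholding (off by default; the screen is nominal).
    seed
        Seed for the Mantel permutations.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        n_permutations: int = 999,
        objective: str = "binomial",
        run_mantel: bool = True,
        adjust: str | None = None,
        seed: int | None = None,
    ):
        self.alpha = alpha
        self.n_permutations = n_permutations
        self.objective = objective
        self.run_mantel = run_mantel
        self.adjust = adjust
        self.seed = seed

    def fit(self, ds: ClineDataset, y=None):
        seeds = np.random.SeedSequence(self.seed).spawn(ds.n_loci)
        results = [
            screen_locus(
                ds,
                lid,
                alpha=self.alpha,
                n_permutations=self.n_permutations,
                objective=self.objective,
                run_mantel=self.run_mantel,
                seed=int(s.generate_state(1)[0] % (2**31)),
            )
            for lid, s in zip(ds.locus_ids, seeds)
        ]
        if self.adjust == "fdr_bh":
            ps = np.array([r.lrt_p for r in results])
            ok = np.isfinite(ps)
            adj = np.full(len(ps), np.nan)
            if ok.any():
                adj[ok] = multipletests(ps[ok], method="fdr_bh")[1]
            for r, p in zip(results, adj):
                r.lrt_p = float(p)
                r.is_clinal = bool(p < self.alpha)
                r.coco_eligible = r.is_clinal and (
                    not self.run_mantel or r.mantel_p < self.alpha
                )
        self.results_ = results
        self.frame_ = results_frame(results)
        return self

    def predict(self, ds: ClineDataset | None = None) -> np.ndarray:
        """Boolean clinal flags in locus order (of the fitted dataset)."""
        return self.frame_["is_clinal"].to_numpy()


def screen_locus(
    ds: ClineDataset,
    locus_id: str,
    alpha: float = 0.05,
    n_permutations: int = 999,
    objective: str = "binomial",
    run_mantel: bool = True,
    seed: int | None = None,
) -> ScreenResult:
    """Run focal-allele selection, both cline fits, the LRT and the Mantel test."""
    loc = ds.locus(locus_id)
    flags: list[str] = []
    focal = loc.allele_ids[0]
    if len(loc.allele_ids) > 2:
        try:
            focal = select_focal_allele(ds, locus_id)
        except FocalAlleleError:
            flags.append("no_regions_fallback_first_allele")
    lat, x, n = focal_series(ds, locus_id, focal)

    midpoint = slope = None
    try:
        h = HorizontalCline(objective=objective).fit(lat, x, n)
        bs = BrokenStickCline(objective=objective).fit(lat, x, n)
        stat, _, lrt_p = lrt_clinal(bs.fit_, h.fit_)
        midpoint, slope = bs.midpoint_, bs.slope_
        flags.extend(bs.flags_)
    except ClineFitError as e:
        flags.append(f"fit_failed:{e}")
        stat, lrt_p = np.nan, np.nan

    mantel_r = mantel_p = np.nan
    if run_mantel:
        try:
            g = pairwise_fst_matrix(ds, locus_id)
            d = latitude_distance_matrix(ds, list(g.ids))
            mantel_r, mantel_p = mantel_test(g, d, n_perm=n_permutations, seed=seed)
        except ValueError as e:
            flags.append(f"mantel_failed:{e}")

    is_clinal = bool(np.isfinite(lrt_p) and lrt_p < alpha)
    coco_eligible = is_clinal and (not run_mantel or bool(mantel_p < alpha))
    return ScreenResult(
        locus=locus_id,
        focal_allele=focal,
        lrt_stat=float(stat) if np.isfinite(stat) else np.nan,
        lrt_p=float(lrt_p) if np.isfinite(lrt_p) else np.nan,
        mantel_r=float(mantel_r) if np.isfinite(mantel_r) else np.nan,
        mantel_p=float(mantel_p) if np.isfinite(mantel_p) else np.nan,
        is_clinal=is_clinal,
        coco_eligible=coco_eligible,
        midpoint=midpoint,
        slope=slope,
        flags=tuple(flags),
    )


def results_frame(results: list[ScreenResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "locus": [r.locus for r in results],
            "focal_allele": [r.focal_allele for r in results],
            "lrt_stat": [r.lrt_stat for r in results],
            "lrt_p": [r.lrt_p for r in results],
            "mantel_r": [r.mantel_r for r in results],
            "mantel_p": [r.mantel_p for r in results],
            "is_clinal": [r.is_clinal for r in results],
            "coco_eligible": [r.coco_eligible for r in results],
            "midpoint": [r.midpoint for r in results],
            "slope": [r.slope for r in results],
            "flags": [";".join(r.flags) for r in results],
        }
    )


def clinal_contingency(
    results: list[ScreenResult] | pd.DataFrame,
    marker_classes: dict[str, str],
) -> tuple[pd.DataFrame, float]:
    """Marker-class x clinal contingency table and SNP-vs-rest Fisher p.

    Returns the full class x {clinal, not_clinal} table and the two-sided
    Fisher exact p-value of the 2x2 collapse into SNP vs non-SNP rows.
    Classes with zero loci are omitted.
    """
    df = results if isinstance(results, pd.DataFrame) else results_frame(results)
    df = df.assign(marker_class=[marker_classes[l] for l in df["locus"]])
    table = (
        df.groupby("marker_class")["is_clinal"]
        .agg(clinal="sum", not_clinal=lambda s: int((~s.astype(bool)).sum()))
        .astype(int)
    )
    table = table[(table.sum(axis=1) > 0)]
    if len(table) < 2:
        raise ValueError("need >= 2 marker classes with loci")
    is_snp = table.index == "SNP"
    collapsed = np.array(
        [
            [table.loc[~is_snp, "clinal"].sum(), table.loc[~is_snp, "not_clinal"].sum()],
            [table.loc[is_snp, "clinal"].sum(), table.loc[is_snp, "not_clinal"].sum()],
        ]
    )
    _, p = fisher_exact(collapsed, alternative="two-sided")
    return table, float(p)


def fisher_2x2(table) -> float:
    """Two-sided Fisher exact p for an explicit 2x2 table."""
    _, p = fisher_exact(np.asarray(table), alternative="two-sided")
    return float(p)
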