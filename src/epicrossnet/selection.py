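"""Cancer-associated m6A site selection.

Three labeling procedures:

* high-confidence filtering — keep sites supported by at least
  ``min_studies`` independent studies;
* cancer-specific labels — set differences between one cancer condition's
  sites and its matched normal tissue (positives present only in cancer,
  negatives only in normal);
* pan-cancer selection — per-site Fisher's exact test on the 2x2
  present/absent x cancer/normal condition table, BH-adjusted, with
  positives at log2(OR) > 2 and q < 0.05 and a symmetric negative pool,
  balanced 1:1 by seeded subsampling.

Odds ratios use the Haldane–Anscombe 0.5 correction when any cell is
zero (the correction never touches the p-value).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import EvaluationError, ParameterError, SamplingError, SelectionError
from .simulate import SiteCatalog

log = logging.getLogger(__name__)


@dataclass
class OddsRatioResult:
    """2x2 association of one site's occurrence with condition class."""

    site_id: str
    a: int  # cancer conditions containing the site
    b: int  # cancer conditions lacking it
    c: int  # normal conditions containing it
    d: int  # normal conditions lacking it
    odds_ratio: float
    log2_or: float
    p_value: float
    q_value: float = float("nan")


@dataclass
class LabeledSiteSet:
    positives: set = field(default_factory=set)
    negatives: set = field(default_factory=set)
    provenance: str = "pan_cancer"  # or 'cancer_specific'
    selection_params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.positives & self.negatives:
            raise SelectionError("positives and negatives overlap")


def filter_high_confidence(catalog: SiteCatalog, min_studies: int) -> SiteCatalog:
    """Retain sites reported by at least ``min_studies`` independent studies."""
    if min_studies < 1:
        raise ParameterError("min_studies must be >= 1")
    keep = np.array([s.study_support >= min_studies for s in catalog.sites])
    if not keep.any():
        log.warning("high-confidence filter at min_studies=%d removed every site",
                    min_studies)
    return catalog.subset(keep)


def cancer_specific_labels(cancer_sites: set, normal_sites: set) -> LabeledSiteSet:
    """Positives = cancer-only sites, negatives = normal-only sites."""
    if not cancer_sites or not normal_sites:
        raise ParameterError("both site sets must be nonempty")
    positives = set(cancer_sites) - set(normal_sites)
    negatives = set(normal_sites) - set(cancer_sites)
    if not positives and not negatives:
        raise SelectionError("both set differences are empty (identical catalogs)")
    if not positives:
        raise SelectionError("cancer-only difference is empty (no positives)")
    if not negatives:
        raise SelectionError("normal-only difference is empty (no negatives)")
    return LabeledSiteSet(positives, negatives, provenance="cancer_specific")


def haldane_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """(a·d)/(b·c), adding 0.5 to every cell only when some cell is zero."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def fisher_association(
    occurrence_row: np.ndarray,
    condition_classes: np.ndarray,
    site_id: str = "",
) -> OddsRatioResult:
    """Two-sided Fisher's exact test of one site's occurrence vs class."""
    occurrence_row = np.asarray(occurrence_row)
    condition_classes = np.asarray(condition_classes)
    if occurrence_row.shape != condition_classes.shape:
        raise ParameterError("row and class vectors must align")
    is_cancer = condition_classes == "cancer"
    if not is_cancer.any() or is_cancer.all():
        raise EvaluationError("need at least one cancer and one normal condition")
    a = int(occurrence_row[is_cancer].sum())
    b = int(is_cancer.sum()) - a
    c = int(occurrence_row[~is_cancer].sum())
    d = int((~is_cancer).sum()) - c
    # two-sided probability-mass criterion over the conditional hypergeometric
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    odds = haldane_odds_ratio(a, b, c, d)
    return OddsRatioResult(site_id, a, b, c, d, odds, float(np.log2(odds)), float(p))


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def associate_catalog(catalog: SiteCatalog) -> list[OddsRatioResult]:
    """Fisher association for every site, with BH-adjusted q-values filled in."""
    classes = catalog.condition_classes
    results = [
        fisher_association(row, classes, site_id=sid)
        for sid, row in zip(catalog.site_ids, catalog.occurrence)
    ]
    q = bh_adjust([r.p_value for r in results])
    for r, qi in zip(results, q):
        r.q_value = float(qi)
    return results


def select_pan_cancer(
    results: list[OddsRatioResult],
    lor_cut: float = 2.0,
    q_cut: float = 0.05,
    adjusted: bool = True,
) -> LabeledSiteSet:
    """Pan-cancer positives: log2(OR) > lor_cut and q < q_cut (strict).

    The negative pool mirrors the criterion (log2(OR) < -lor_cut,
    q < q_cut).  ``adjusted=False`` thresholds the raw p-value instead.
    """
    seen = set()
    for r in results:
        if r.site_id in seen:
            raise ParameterError(f"duplicate result for site {r.site_id!r}")
        seen.add(r.site_id)

    def sig(r):
        v = r.q_value if adjusted else r.p_value
        return v < q_cut

    positives = {r.site_id for r in results if r.log2_or > lor_cut and sig(r)}
    negatives = {r.site_id for r in results if r.log2_or < -lor_cut and sig(r)}
    if not positives:
        raise SelectionError("no sites pass the pan-cancer positive criterion")
    return LabeledSiteSet(
        positives, negatives, provenance="pan_cancer",
        selection_params={"lor_cut": lor_cut, "q_cut": q_cut, "adjusted": adjusted},
    )


def balance_sample(labeled: LabeledSiteSet, seed: int) -> LabeledSiteSet:
    """Subsample the negative pool to a 1:1 ratio, uniformly without replacement."""
    n_pos = len(labeled.positives)
    pool = sorted(labeled.negatives)
    if len(pool) < n_pos:
        raise SamplingError(
            f"negative pool ({len(pool)}) smaller than positives ({n_pos})"
        )
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(pool, size=n_pos, replace=False).tolist())
    params = dict(labeled.selection_params)
    params["balance_seed"] = seed
    return LabeledSiteSet(set(labeled.positives), chosen, labeled.provenance, params)
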