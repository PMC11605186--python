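"""Synthetic m6A condition catalogs with planted pan-cancer structure.

The generator fabricates a universe of base-resolution m6A sites observed
across K cancer and K normal conditions.  A tunable fraction of sites is
"pan-cancer positive" (present in cancer conditions with probability
``p_high`` and in normal conditions with ``p_low``), a fraction is the
mirror-image "pan-negative", and the remainder is background occurring at
``p_background`` in both.  Each site carries a 41-nt window centred on the
methylated adenosine of a DRACH motif; by default the flanking sequence is
uniform so sequence alone carries no class signal (``sequence_effect``
raises a class-dependent base-composition bias for positive controls).
Genomic feature tables are drawn class-conditionally so that planted
effects — e.g. elevated ``struct_hybridize``, higher ``isoform_num``,
depleted ``constitutive_exon``, CDS-proximal relative positions — can be
recovered downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .exceptions import ParameterError, SchemaError
from .schema import FeatureSchema, default_schema

PAN_POSITIVE = "pan_positive"
PAN_NEGATIVE = "pan_negative"
BACKGROUND = "background"

_RNA = np.array(list("ACGU"))
_D = list("AGU")  # D = not C
_R = list("AG")  # purine
_H = list("ACU")  # H = not G

WINDOW_LEN = 41
CENTER = 20  # methylated A, 0-based


@dataclass(frozen=True)
class FeatureEffect:
    """Class-conditional distribution for one feature.

    family: 'bernoulli' (param p), 'beta' (a, b), 'poisson_plus1' (lam),
    'normal' (mu, sd).  ``pos`` applies to pan-positive sites, ``neg`` to
    every other site.
    """

    family: str
    pos: tuple
    neg: tuple


DEFAULT_FEATURE_EFFECTS: dict[str, FeatureEffect] = {
    # positives sit deep in the CDS near the stop codon, not in the 3'UTR body
    "rel_pos_cds": FeatureEffect("beta", (5.0, 2.0), (2.0, 2.0)),
    "rel_pos_utr3": FeatureEffect("beta", (2.0, 5.0), (2.0, 2.0)),
    # positives enriched in base-paired structure
    "struct_hybridize": FeatureEffect("bernoulli", (0.7,), (0.3,)),
    # positives on genes with more isoforms
    "isoform_num": FeatureEffect("poisson_plus1", (5.0,), (2.0,)),
    # positives depleted from constitutive exons
    "constitutive_exon": FeatureEffect("bernoulli", (0.3,), (0.7,)),
}


@dataclass
class GeneratorParams:
    n_sites: int = 4000
    n_cancer_conditions: int = 10
    n_normal_conditions: int = 10
    frac_pan_positive: float = 0.25
    frac_pan_negative: float = 0.25
    p_high: float = 0.9
    p_low: float = 0.1
    p_background: float = 0.5
    feature_effects: dict[str, FeatureEffect] = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_EFFECTS)
    )
    sequence_effect: float = 0.0
    study_support_rate: float = 1.0  # support = 1 + Poisson(rate)
    seed: int = 0

    def validate(self) -> None:
        if self.n_sites <= 0:
            raise ParameterError("n_sites must be positive")
        if self.n_cancer_conditions <= 0 or self.n_normal_conditions <= 0:
            raise ParameterError("condition counts must be positive")
        for name in ("frac_pan_positive", "frac_pan_negative",
                     "p_high", "p_low", "p_background"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if self.frac_pan_positive + self.frac_pan_negative > 1.0:
            raise ParameterError("frac_pan_positive + frac_pan_negative > 1")
        planting = self.frac_pan_positive > 0 or self.frac_pan_negative > 0
        if planting and not (self.p_high > self.p_background > self.p_low):
            raise ParameterError(
                "require p_high > p_background > p_low when planting signal"
            )
        if self.sequence_effect < 0:
            raise ParameterError("sequence_effect must be >= 0")
        if self.study_support_rate < 0:
            raise ParameterError("study_support_rate must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["feature_effects"] = {
            k: {"family": v.family, "pos": list(v.pos), "neg": list(v.neg)}
            for k, v in self.feature_effects.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorParams":
        d = dict(d)
        fe = d.get("feature_effects")
        if fe is not None:
            d["feature_effects"] = {
                k: FeatureEffect(v["family"], tuple(v["pos"]), tuple(v["neg"]))
                for k, v in fe.items()
            }
        return cls(**d)


@dataclass
class SiteRecord:
    site_id: str
    chrom: str
    position: int  # 0-based genomic position of the methylated A
    strand: str
    window_seq: str  # 41 nt, RNA alphabet, A at index 20
    study_support: int
    truth_label: str  # synthetic only

    def __post_init__(self):
        if len(self.window_seq) != WINDOW_LEN:
            raise ParameterError(f"window must be {WINDOW_LEN} nt")
        if self.window_seq[CENTER] != "A":
            raise ParameterError("central base must be A")


@dataclass
class SiteCatalog:
    """Per-condition presence of m6A sites plus study-support counts."""

    sites: list[SiteRecord]
    occurrence: np.ndarray  # n_sites x n_conditions, {0,1}
    condition_ids: list[str]
    condition_meta: dict[str, str]  # condition id -> 'cancer' | 'normal'

    def __post_init__(self):
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ParameterError("site ids must be unique")
        if self.occurrence.shape != (len(self.sites), len(self.condition_ids)):
            raise ParameterError("occurrence shape mismatch")
        if not np.isin(self.occurrence, (0, 1)).all():
            raise ParameterError("occurrence entries must be 0/1")
        for cid in self.condition_ids:
            if self.condition_meta.get(cid) not in ("cancer", "normal"):
                raise ParameterError(f"condition {cid!r} lacks a class label")

    @property
    def site_ids(self) -> list[str]:
        return [s.site_id for s in self.sites]

    @property
    def condition_classes(self) -> np.ndarray:
        return np.array([self.condition_meta[c] for c in self.condition_ids])

    def truth_labels(self) -> np.ndarray:
        return np.array([s.truth_label for s in self.sites])

    def subset(self, keep: np.ndarray) -> "SiteCatalog":
        """Row-subset by boolean mask or index array."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return SiteCatalog(
            sites=[self.sites[i] for i in keep],
            occurrence=self.occurrence[keep],
            condition_ids=list(self.condition_ids),
            condition_meta=dict(self.condition_meta),
        )


def _window(rng: np.random.Generator, bias: Optional[np.ndarray]) -> str:
    """One 41-nt window: DRACH core at 19-23, flanks uniform or biased."""
    if bias is None:
        probs = np.full(4, 0.25)
    else:
        probs = bias
    seq = rng.choice(_RNA, size=WINDOW_LEN, p=probs)
    seq[CENTER - 1] = rng.choice(_R)
    seq[CENTER - 2] = rng.choice(_D)
    seq[CENTER] = "A"
    seq[CENTER + 1] = "C"
    seq[CENTER + 2] = rng.choice(_H)
    return "".join(seq)


def _class_bias(effect: float, label: str) -> Optional[np.ndarray]:
    if effect == 0:
        return None
    w = np.ones(4)
    if label == PAN_POSITIVE:
        w += effect * np.array([1.0, 0.0, 1.0, 0.0])  # tilt A/G
    else:
        w += effect * np.array([0.0, 1.0, 0.0, 1.0])  # tilt C/U
    return w / w.sum()


def generate_catalog(params: GeneratorParams) -> SiteCatalog:
    """Draw a site universe and its site-by-condition occurrence matrix."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_sites
    n_pos = int(round(n * params.frac_pan_positive))
    n_neg = int(round(n * params.frac_pan_negative))
    labels = np.array(
        [PAN_POSITIVE] * n_pos
        + [PAN_NEGATIVE] * n_neg
        + [BACKGROUND] * (n - n_pos - n_neg)
    )
    rng.shuffle(labels)

    supports = 1 + rng.poisson(params.study_support_rate, size=n)
    chroms = rng.integers(1, 23, size=n)
    positions = rng.integers(100, 1_000_000, size=n)
    strands = rng.choice(["+", "-"], size=n)

    sites = []
    for i in range(n):
        bias = _class_bias(params.sequence_effect, labels[i])
        sites.append(
            SiteRecord(
                site_id=f"site_{i:06d}",
                chrom=f"chr{chroms[i]}",
                position=int(positions[i]),
                strand=str(strands[i]),
                window_seq=_window(rng, bias),
                study_support=int(supports[i]),
                truth_label=str(labels[i]),
            )
        )

    kc, kn = params.n_cancer_conditions, params.n_normal_conditions
    condition_ids = [f"cancer_{j+1:02d}" for j in range(kc)] + [
        f"normal_{j+1:02d}" for j in range(kn)
    ]
    condition_meta = {c: ("cancer" if c.startswith("cancer") else "normal")
                      for c in condition_ids}

    p_cancer = np.where(
        labels == PAN_POSITIVE, params.p_high,
        np.where(labels == PAN_NEGATIVE, params.p_low, params.p_background),
    )
    p_normal = np.where(
        labels == PAN_POSITIVE, params.p_low,
        np.where(labels == PAN_NEGATIVE, params.p_high, params.p_background),
    )
    occ_c = rng.random((n, kc)) < p_cancer[:, None]
    occ_n = rng.random((n, kn)) < p_normal[:, None]
    occurrence = np.concatenate([occ_c, occ_n], axis=1).astype(np.int8)

    return SiteCatalog(sites, occurrence, condition_ids, condition_meta)


_NULL_DEFAULTS = {
    "binary": FeatureEffect("bernoulli", (0.5,), (0.5,)),
    "count": FeatureEffect("poisson_plus1", (3.0,), (3.0,)),
    "fraction": FeatureEffect("beta", (2.0, 2.0), (2.0, 2.0)),
    "score": FeatureEffect("normal", (0.0, 1.0), (0.0, 1.0)),
}


def _draw(rng: np.random.Generator, family: str, args: tuple, size: int) -> np.ndarray:
    if family == "bernoulli":
        return (rng.random(size) < args[0]).astype(float)
    if family == "beta":
        return rng.beta(args[0], args[1], size)
    if family == "poisson_plus1":
        return 1.0 + rng.poisson(args[0], size)
    if family == "normal":
        return rng.normal(args[0], args[1], size)
    raise ParameterError(f"unknown distribution family {family!r}")


def generate_features(
    catalog: SiteCatalog,
    params: GeneratorParams,
    schema: Optional[FeatureSchema] = None,
):
    """Class-conditional draw of the 52-column genomic feature table.

    Features named in ``params.feature_effects`` use their positive-class
    distribution for pan-positive sites and the negative-class one for all
    other sites; every other feature is drawn identically across classes
    from a kind-appropriate null.
    """
    from .encoding import FeatureMatrix  # local import avoids a cycle

    if schema is None:
        schema = default_schema()
    known = set(schema.names)
    for name in params.feature_effects:
        if name not in known:
            raise SchemaError(f"feature_effects names unknown feature {name!r}")

    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    labels = catalog.truth_labels()
    is_pos = labels == PAN_POSITIVE
    n = len(labels)
    values = np.empty((n, 52))
    for j, desc in enumerate(schema):
        eff = params.feature_effects.get(desc.name, _NULL_DEFAULTS[desc.kind])
        col = np.empty(n)
        col[is_pos] = _draw(rng, eff.family, eff.pos, int(is_pos.sum()))
        col[~is_pos] = _draw(rng, eff.family, eff.neg, int((~is_pos).sum()))
        values[:, j] = col
    return FeatureMatrix(site_ids=list(catalog.site_ids), values=values, schema=schema)
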