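"""The 52-column genome-derived feature schema.

Every m6A site is described by 52 features grouped into eight blocks:
binary region dummies, region lengths, local site-clustering statistics,
evolutionary conservation scores, RNA secondary-structure flags, gene
attributes (including m6A writer/eraser/reader binding), transcript
properties, and metagene relative positions.  Conservation, structure and
gene-attribute columns are consumed from external tables (their upstream
computation is out of scope); the rest are computed from annotation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator

GROUPS = (
    "region_dummy",
    "region_length",
    "clustering",
    "conservation",
    "structure",
    "gene_attribute",
    "transcript_property",
    "relative_position",
)

GROUP_SIZES = {
    "region_dummy": 13,
    "region_length": 6,
    "clustering": 6,
    "conservation": 4,
    "structure": 2,
    "gene_attribute": 13,
    "transcript_property": 4,
    "relative_position": 4,
}

KINDS = ("binary", "count", "fraction", "score")
SOURCES = ("computed", "external_column")


@dataclass(frozen=True)
class FeatureDescriptor:
    name: str
    index: int  # 1-based, 1..52
    group: str
    kind: str
    source: str


@dataclass
class FeatureSchema:
    """Ordered collection of exactly 52 feature descriptors."""

    descriptors: list[FeatureDescriptor] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.descriptors) != 52:
            raise ValueError(f"schema must define exactly 52 features, got {len(self.descriptors)}")
        indices = [d.index for d in self.descriptors]
        if sorted(indices) != list(range(1, 53)):
            raise ValueError("feature indices must be unique and cover 1..52")
        names = [d.name for d in self.descriptors]
        if len(set(names)) != 52:
            raise ValueError("feature names must be unique")
        for group, size in GROUP_SIZES.items():
            n = sum(1 for d in self.descriptors if d.group == group)
            if n != size:
                raise ValueError(f"group {group!r} must contain {size} features, found {n}")
        for d in self.descriptors:
            if d.kind not in KINDS:
                raise ValueError(f"unknown kind {d.kind!r} for {d.name!r}")
            if d.source not in SOURCES:
                raise ValueError(f"unknown source {d.source!r} for {d.name!r}")

    def __iter__(self) -> Iterator[FeatureDescriptor]:
        return iter(sorted(self.descriptors, key=lambda d: d.index))

    def __len__(self) -> int:
        return 52

    @property
    def names(self) -> list[str]:
        return [d.name for d in self]

    def index_of(self, name: str) -> int:
        """0-based column index of a named feature."""
        for i, d in enumerate(self):
            if d.name == name:
                return i
        raise KeyError(name)

    def descriptor(self, name: str) -> FeatureDescriptor:
        for d in self:
            if d.name == name:
                return d
        raise KeyError(name)

    @property
    def binary_mask(self) -> list[bool]:
        return [d.kind == "binary" for d in self]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                [
                    {"name": d.name, "index": d.index, "group": d.group,
                     "kind": d.kind, "source": d.source}
                    for d in self
                ],
                fh, indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "FeatureSchema":
        with open(path) as fh:
            raw = json.load(fh)
        return cls([FeatureDescriptor(**r) for r in raw])


def _spec(name, group, kind, source="computed"):
    return (name, group, kind, source)


_DEFAULT = [
    # 1-13: region dummies
    _spec("utr5", "region_dummy", "binary"),
    _spec("cds", "region_dummy", "binary"),
    _spec("utr3", "region_dummy", "binary"),
    _spec("start_codon", "region_dummy", "binary"),
    _spec("stop_codon", "region_dummy", "binary"),
    _spec("exon", "region_dummy", "binary"),
    _spec("intron", "region_dummy", "binary"),
    _spec("constitutive_exon", "region_dummy", "binary"),
    _spec("alternative_exon", "region_dummy", "binary"),
    _spec("exon_junction_50nt", "region_dummy", "binary"),
    _spec("lncrna_exon", "region_dummy", "binary", "external_column"),
    _spec("sncrna", "region_dummy", "binary", "external_column"),
    _spec("first_exon", "region_dummy", "binary"),
    # 14-19: region lengths
    _spec("len_gene", "region_length", "count"),
    _spec("len_transcript", "region_length", "count"),
    _spec("len_utr5", "region_length", "count"),
    _spec("len_cds", "region_length", "count"),
    _spec("len_utr3", "region_length", "count"),
    _spec("len_containing_exon", "region_length", "count"),
    # 20-25: clustering
    _spec("sites_within_100nt", "clustering", "count"),
    _spec("sites_within_1000nt", "clustering", "count"),
    _spec("dist_nearest_site", "clustering", "count"),
    _spec("a_count_50nt", "clustering", "count"),
    _spec("drach_count_window", "clustering", "count"),
    _spec("log_dist_nearest_site", "clustering", "score"),
    # 26-29: conservation
    _spec("phastcons_site", "conservation", "score", "external_column"),
    _spec("phastcons_window", "conservation", "score", "external_column"),
    _spec("fitcons_site", "conservation", "score", "external_column"),
    _spec("fitcons_window", "conservation", "score", "external_column"),
    # 30-31: secondary structure
    _spec("struct_hybridize", "structure", "binary", "external_column"),
    _spec("struct_loop", "structure", "binary", "external_column"),
    # 32-44: gene attributes
    _spec("housekeeping", "gene_attribute", "binary", "external_column"),
    _spec("sncrna_host", "gene_attribute", "binary", "external_column"),
    _spec("lncrna_gene", "gene_attribute", "binary", "external_column"),
    _spec("bind_mettl3", "gene_attribute", "binary", "external_column"),
    _spec("bind_mettl14", "gene_attribute", "binary", "external_column"),
    _spec("bind_wtap", "gene_attribute", "binary", "external_column"),
    _spec("bind_fto", "gene_attribute", "binary", "external_column"),
    _spec("bind_alkbh5", "gene_attribute", "binary", "external_column"),
    _spec("bind_ythdf1", "gene_attribute", "binary", "external_column"),
    _spec("bind_ythdf2", "gene_attribute", "binary", "external_column"),
    _spec("bind_ythdf3", "gene_attribute", "binary", "external_column"),
    _spec("bind_ythdc1", "gene_attribute", "binary", "external_column"),
    _spec("bind_ythdc2", "gene_attribute", "binary", "external_column"),
    # 45-48: transcript properties
    _spec("isoform_num", "transcript_property", "count"),
    _spec("gc_content", "transcript_property", "fraction"),
    _spec("exon_count", "transcript_property", "count"),
    _spec("coding_transcript", "transcript_property", "binary"),
    # 49-52: relative positions
    _spec("rel_pos_transcript", "relative_position", "fraction"),
    _spec("rel_pos_utr5", "relative_position", "fraction"),
    _spec("rel_pos_cds", "relative_position", "fraction"),
    _spec("rel_pos_utr3", "relative_position", "fraction"),
]


def default_schema() -> FeatureSchema:
    """The package's versioned 52-feature schema."""
    return FeatureSchema(
        [FeatureDescriptor(name, i + 1, group, kind, source)
         for i, (name, group, kind, source) in enumerate(_DEFAULT)]
    )
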