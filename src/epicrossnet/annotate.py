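"""Genome-derived feature annotation against a transcript model.

Real m6A sites are annotated by mapping each site onto the single longest
(primary) transcript of its host gene, then computing region dummies,
region lengths, clustering statistics, transcript properties and metagene
relative positions in strand-aware transcript coordinates.  Conservation,
secondary-structure and gene-attribute columns are copied from an
external auxiliary table — their upstream computation is out of scope.

GFF3 input is parsed with gffutils; its 1-based closed coordinates are
converted to the package's 0-based half-open convention at the boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

import gffutils
import numpy as np
import pandas as pd

from .encoding import FeatureMatrix
from .exceptions import AnnotationError, SchemaError
from .schema import FeatureSchema, default_schema
from .simulate import SiteCatalog, SiteRecord

_DRACH = re.compile(r"(?=[AGU][AG]AC[ACU])")


def gff_to_zero_based(start_1based: int, end_1based: int) -> tuple[int, int]:
    """Convert a 1-based closed GFF interval to 0-based half-open."""
    return start_1based - 1, end_1based


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # 0-based half-open, genomic order
    cds: list[tuple[int, int]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def contains_exonic(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)

    def containing_exon(self, pos: int) -> Optional[tuple[int, int]]:
        for s, e in self.exons:
            if s <= pos < e:
                return (s, e)
        return None

    def genomic_to_tx(self, pos: int) -> Optional[int]:
        """Strand-aware transcript coordinate of a genomic position."""
        if not self.contains_exonic(pos):
            return None
        offset = 0
        if self.strand == "+":
            for s, e in self.exons:
                if pos < e:
                    return offset + (pos - s)
                offset += e - s
        else:
            for s, e in reversed(self.exons):
                if pos >= s:
                    return offset + (e - 1 - pos)
                offset += e - s
        return None

    def cds_tx_interval(self) -> Optional[tuple[int, int]]:
        """CDS extent in transcript coordinates (half-open), if coding."""
        if not self.cds:
            return None
        bounds = []
        for s, e in self.cds:
            bounds.extend([self.genomic_to_tx(s), self.genomic_to_tx(e - 1)])
        bounds = [b for b in bounds if b is not None]
        return min(bounds), max(bounds) + 1

    def junction_tx_positions(self) -> list[int]:
        """Transcript coordinates of internal exon-exon junctions."""
        out = []
        acc = 0
        lengths = [e - s for s, e in
                   (self.exons if self.strand == "+" else self.exons[::-1])]
        for ln in lengths[:-1]:
            acc += ln
            out.append(acc)
        return out

    def first_exon(self) -> tuple[int, int]:
        return self.exons[0] if self.strand == "+" else self.exons[-1]


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    start: int  # 0-based
    end: int  # half-open
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    @property
    def primary(self) -> Transcript:
        """Longest transcript; ties broken by transcript id."""
        return min(self.transcripts.values(),
                   key=lambda t: (-t.length, t.transcript_id))


class TranscriptModel:
    """All genes of an annotation, indexed for site lookup."""

    def __init__(self, genes: dict[str, Gene]):
        self.genes = genes

    @classmethod
    def from_gff(cls, path: str) -> "TranscriptModel":
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique",
            keep_order=True,
        )
        genes: dict[str, Gene] = {}
        for g in db.features_of_type("gene"):
            gs, ge = gff_to_zero_based(g.start, g.end)
            gene = Gene(g.id, g.seqid, g.strand, gs, ge)
            for t in db.children(g, level=1):
                if t.featuretype not in ("mRNA", "transcript", "ncRNA"):
                    continue
                exons, cds = [], []
                for child in db.children(t, level=1):
                    iv = gff_to_zero_based(child.start, child.end)
                    if child.featuretype == "exon":
                        exons.append(iv)
                    elif child.featuretype == "CDS":
                        cds.append(iv)
                if not exons:
                    continue
                gene.transcripts[t.id] = Transcript(
                    t.id, g.id, g.seqid, g.strand,
                    sorted(exons), sorted(cds),
                )
            if gene.transcripts:
                genes[g.id] = gene
        return cls(genes)

    def locate(self, chrom: str, pos: int, strand: str) -> Gene:
        """Host gene of a site (exonic match preferred, then intronic)."""
        exonic, spanning = [], []
        for gene in self.genes.values():
            if gene.chrom != chrom or gene.strand != strand:
                continue
            if not (gene.start <= pos < gene.end):
                continue
            if gene.primary.contains_exonic(pos):
                exonic.append(gene)
            else:
                spanning.append(gene)
        pool = exonic or spanning
        if not pool:
            raise AnnotationError(
                f"site at {chrom}:{pos}({strand}) maps to no annotated gene"
            )
        return min(pool, key=lambda g: g.gene_id)


def _is_constitutive(gene: Gene, exon: tuple[int, int]) -> bool:
    """An exon is constitutive when present (same coords) in every isoform."""
    return all(exon in t.exons for t in gene.transcripts.values())


def _rel(tx_pos, lo, hi):
    """Region-local relative position; (dummy, rel, length)."""
    length = hi - lo
    if tx_pos is None or length <= 0 or not (lo <= tx_pos < hi):
        return 0.0, 0.0, float(max(length, 0))
    return 1.0, (tx_pos - lo) / length, float(length)


def annotate_genomic_features(
    site: SiteRecord,
    model: TranscriptModel,
    aux: pd.DataFrame,
    schema: Optional[FeatureSchema] = None,
    neighbor_positions: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Compute the 52-feature vector for one site.

    ``aux`` is indexed by site_id and must provide every external column
    of the schema.  ``neighbor_positions`` holds the genomic positions of
    the other input sites on the same chromosome and strand (for the
    clustering features).
    """
    if schema is None:
        schema = default_schema()
    try:
        gene = model.locate(site.chrom, site.position, site.strand)
    except AnnotationError as exc:
        raise AnnotationError(f"site {site.site_id!r}: {exc}") from None
    tx = gene.primary
    pos = site.position
    tx_pos = tx.genomic_to_tx(pos)
    exonic = tx_pos is not None
    tx_len = tx.length

    cds_iv = tx.cds_tx_interval()
    if cds_iv is not None:
        cds_lo, cds_hi = cds_iv
        utr5_lo, utr5_hi = 0, cds_lo
        utr3_lo, utr3_hi = cds_hi, tx_len
    else:
        cds_lo = cds_hi = 0
        utr5_lo = utr5_hi = utr3_lo = utr3_hi = 0

    d_utr5, rel_utr5, len_utr5 = _rel(tx_pos, utr5_lo, utr5_hi)
    d_cds, rel_cds, len_cds = _rel(tx_pos, cds_lo, cds_hi)
    d_utr3, rel_utr3, len_utr3 = _rel(tx_pos, utr3_lo, utr3_hi)

    start_codon = stop_codon = 0.0
    if cds_iv is not None and tx_pos is not None:
        # codon regions extended by 1 nt on each side
        if cds_lo - 1 <= tx_pos < cds_lo + 4:
            start_codon = 1.0
        if cds_hi - 4 <= tx_pos < cds_hi + 1:
            stop_codon = 1.0

    exon_iv = tx.containing_exon(pos)
    constitutive = float(exonic and exon_iv is not None
                         and _is_constitutive(gene, exon_iv))
    alternative = float(exonic) - constitutive
    junctions = tx.junction_tx_positions()
    near_junction = 0.0
    if exonic and junctions:
        near_junction = float(min(abs(tx_pos - j) for j in junctions) <= 50)
    fe = tx.first_exon()
    in_first_exon = float(exonic and fe[0] <= pos < fe[1])

    # clustering over the input site list
    if neighbor_positions is None or len(neighbor_positions) == 0:
        n100 = n1000 = 0
        nearest = 1_000_000.0
    else:
        nb = np.asarray(neighbor_positions)
        dist = np.abs(nb - pos)
        dist = dist[dist > 0]  # exclude the site itself
        n100 = int((dist <= 100).sum())
        n1000 = int((dist <= 1000).sum())
        nearest = float(dist.min()) if dist.size else 1_000_000.0

    window = site.window_seq.upper().replace("T", "U")
    a_count = float(window.count("A"))
    drach_count = float(len(_DRACH.findall(window)))
    gc = float((window.count("G") + window.count("C")) / len(window))

    computed = {
        "utr5": d_utr5,
        "cds": d_cds,
        "utr3": d_utr3,
        "start_codon": start_codon,
        "stop_codon": stop_codon,
        "exon": float(exonic),
        "intron": float(not exonic),
        "constitutive_exon": constitutive,
        "alternative_exon": alternative,
        "exon_junction_50nt": near_junction,
        "first_exon": in_first_exon,
        "len_gene": float(gene.end - gene.start),
        "len_transcript": float(tx_len),
        "len_utr5": len_utr5,
        "len_cds": len_cds,
        "len_utr3": len_utr3,
        "len_containing_exon": float(exon_iv[1] - exon_iv[0]) if exon_iv else 0.0,
        "sites_within_100nt": float(n100),
        "sites_within_1000nt": float(n1000),
        "dist_nearest_site": nearest,
        "a_count_50nt": a_count,
        "drach_count_window": drach_count,
        "log_dist_nearest_site": float(np.log10(1.0 + nearest)),
        "isoform_num": float(len(gene.transcripts)),
        "gc_content": gc,
        "exon_count": float(len(tx.exons)),
        "coding_transcript": float(bool(tx.cds)),
        "rel_pos_transcript": (tx_pos / tx_len) if exonic and tx_len else 0.0,
        "rel_pos_utr5": rel_utr5,
        "rel_pos_cds": rel_cds,
        "rel_pos_utr3": rel_utr3,
    }

    vec = np.empty(len(schema))
    for j, desc in enumerate(schema):
        if desc.source == "external_column":
            if desc.name not in aux.columns:
                raise SchemaError(f"auxiliary table lacks column {desc.name!r}")
            vec[j] = float(aux.loc[site.site_id, desc.name])
        else:
            vec[j] = computed[desc.name]
    return vec


def annotate_catalog(
    catalog: SiteCatalog,
    model: TranscriptModel,
    aux: pd.DataFrame,
    schema: Optional[FeatureSchema] = None,
) -> FeatureMatrix:
    """Annotate every site of a catalog; neighbors are the catalog itself."""
    if schema is None:
        schema = default_schema()
    by_key: dict[tuple[str, str], list[int]] = {}
    for s in catalog.sites:
        by_key.setdefault((s.chrom, s.strand), []).append(s.position)
    rows = [
        annotate_genomic_features(
            s, model, aux, schema,
            neighbor_positions=np.array(by_key[(s.chrom, s.strand)]),
        )
        for s in catalog.sites
    ]
    return FeatureMatrix(list(catalog.site_ids), np.vstack(rows), schema)
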