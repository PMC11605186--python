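"""On-disk artifacts: BED6 sites, FASTA windows, TSV tables, JSON params.

Base-resolution sites are stored as BED6 (0-based half-open, one-base
intervals, name = site id, score = study support).  Windows go to FASTA
keyed by site id; the occurrence matrix, condition classes, truth labels
and feature tables are plain TSV.  All readers validate record shape and
report the offending line on failure, and every writer/reader pair
round-trips losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .encoding import FeatureMatrix
from .exceptions import ParseError
from .schema import FeatureSchema
from .simulate import GeneratorParams, SiteCatalog, SiteRecord


def write_catalog(catalog: SiteCatalog, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "bed": outdir / "sites.bed",
        "fasta": outdir / "windows.fasta",
        "occurrence": outdir / "occurrence.tsv",
        "conditions": outdir / "conditions.tsv",
        "meta": outdir / "sites_meta.tsv",
    }
    with open(paths["bed"], "w") as fh:
        for s in catalog.sites:
            fh.write(f"{s.chrom}\t{s.position}\t{s.position + 1}\t"
                     f"{s.site_id}\t{s.study_support}\t{s.strand}\n")
    SeqIO.write(
        (SeqRecord(Seq(s.window_seq), id=s.site_id, description="")
         for s in catalog.sites),
        str(paths["fasta"]), "fasta",
    )
    occ = pd.DataFrame(catalog.occurrence, index=catalog.site_ids,
                       columns=catalog.condition_ids)
    occ.to_csv(paths["occurrence"], sep="\t", index_label="site_id")
    pd.DataFrame(
        {"condition_id": catalog.condition_ids,
         "class": [catalog.condition_meta[c] for c in catalog.condition_ids]}
    ).to_csv(paths["conditions"], sep="\t", index=False)
    pd.DataFrame(
        {"site_id": catalog.site_ids,
         "truth_label": [s.truth_label for s in catalog.sites]}
    ).to_csv(paths["meta"], sep="\t", index=False)
    return paths


def read_catalog(outdir) -> SiteCatalog:
    outdir = Path(outdir)
    bed_rows = {}
    with open(outdir / "sites.bed") as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 6:
                raise ParseError(f"sites.bed line {lineno}: expected 6 fields")
            chrom, start, end, name, score, strand = fields
            try:
                start, end, score = int(start), int(end), int(score)
            except ValueError:
                raise ParseError(
                    f"sites.bed line {lineno}: non-integer coordinate"
                ) from None
            if end - start != 1:
                raise ParseError(
                    f"sites.bed line {lineno}: base-resolution site must have "
                    f"end - start = 1, got {end - start}"
                )
            if strand not in "+-":
                raise ParseError(f"sites.bed line {lineno}: bad strand {strand!r}")
            bed_rows[name] = (chrom, start, score, strand)
    windows = {rec.id: str(rec.seq) for rec in
               SeqIO.parse(str(outdir / "windows.fasta"), "fasta")}
    meta = pd.read_csv(outdir / "sites_meta.tsv", sep="\t").set_index("site_id")
    occ = pd.read_csv(outdir / "occurrence.tsv", sep="\t", index_col="site_id")
    cond = pd.read_csv(outdir / "conditions.tsv", sep="\t")
    sites = []
    for sid in occ.index:
        if sid not in bed_rows or sid not in windows:
            raise ParseError(f"site {sid!r} missing from BED or FASTA")
        chrom, start, score, strand = bed_rows[sid]
        sites.append(SiteRecord(
            site_id=sid, chrom=chrom, position=start, strand=strand,
            window_seq=windows[sid], study_support=score,
            truth_label=str(meta.loc[sid, "truth_label"]),
        ))
    return SiteCatalog(
        sites=sites,
        occurrence=occ.to_numpy().astype(np.int8),
        condition_ids=list(occ.columns),
        condition_meta=dict(zip(cond["condition_id"], cond["class"])),
    )


def write_features(features: FeatureMatrix, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"features": outdir / "features.tsv",
             "schema": outdir / "schema.json"}
    pd.DataFrame(features.values, index=features.site_ids,
                 columns=features.schema.names).to_csv(
        paths["features"], sep="\t", index_label="site_id")
    features.schema.to_json(paths["schema"])
    return paths


def read_features(outdir) -> FeatureMatrix:
    outdir = Path(outdir)
    schema = FeatureSchema.from_json(outdir / "schema.json")
    df = pd.read_csv(outdir / "features.tsv", sep="\t", index_col="site_id")
    if list(df.columns) != schema.names:
        raise ParseError("features.tsv columns do not match schema order")
    return FeatureMatrix(list(df.index), df.to_numpy(), schema)


def write_fixture(catalog: SiteCatalog, features: FeatureMatrix,
                  params: GeneratorParams, outdir) -> dict[str, Path]:
    """Emit the full synthetic fixture (sites, windows, tables, params)."""
    outdir = Path(outdir)
    paths = write_catalog(catalog, outdir)
    paths.update(write_features(features, outdir))
    paths["params"] = outdir / "params.json"
    with open(paths["params"], "w") as fh:
        json.dump(params.to_dict(), fh, indent=1)
    return paths


def read_params(path) -> GeneratorParams:
    with open(path) as fh:
        return GeneratorParams.from_dict(json.load(fh))
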