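"""Transcript-model annotation on a toy two-gene GFF3.

Gene g1 (chr1, +): three single-exon isoforms; the primary (longest)
transcript t1 is 600 nt with CDS at transcript positions 101-400
(1-based), i.e. [100, 400) internally.  Gene g2 (chr2, -): one
three-exon transcript for strand-aware coordinate checks.
"""

import numpy as np
import pytest

from conftest import make_window
from epicrossnet.annotate import annotate_genomic_features, gff_to_zero_based
from epicrossnet.exceptions import AnnotationError, SchemaError
from epicrossnet.simulate import SiteRecord


def _site(site_id, chrom, pos, strand, window=None):
    return SiteRecord(site_id=site_id, chrom=chrom, position=pos,
                      strand=strand, window_seq=window or make_window(),
                      study_support=2, truth_label="background")


def _named(schema, vec):
    return dict(zip(schema.names, vec))


def test_primary_transcript_and_isoform_count(toy_model, toy_aux, schema):
    gene = toy_model.genes["g1"]
    assert gene.primary.transcript_id == "t1"
    assert gene.primary.length == 600
    site = _site("ts0", "chr1", 1250, "+")
    f = _named(schema, annotate_genomic_features(site, toy_model, toy_aux, schema))
    assert f["isoform_num"] == 3.0
    assert f["len_transcript"] == 600.0
    assert f["len_cds"] == 300.0
    assert f["len_utr5"] == 100.0
    assert f["len_utr3"] == 200.0


def test_relative_positions_in_toy_cds(toy_model, toy_aux, schema):
    """Genomic 1250 = transcript position 250: the CDS midpoint."""
    site = _site("ts1", "chr1", 1250, "+")
    f = _named(schema, annotate_genomic_features(site, toy_model, toy_aux, schema))
    assert f["cds"] == 1.0 and f["utr5"] == 0.0 and f["utr3"] == 0.0
    assert f["rel_pos_cds"] == pytest.approx((250 - 100) / 300)
    assert f["rel_pos_transcript"] == pytest.approx(250 / 600)
    assert f["rel_pos_utr5"] == 0.0 and f["rel_pos_utr3"] == 0.0


def test_stop_codon_containment(toy_model, toy_aux, schema):
    """Transcript position 398 sits in the stop codon and the CDS."""
    site = _site("ts2", "chr1", 1398, "+")
    f = _named(schema, annotate_genomic_features(site, toy_model, toy_aux, schema))
    assert f["stop_codon"] == 1.0
    assert f["cds"] == 1.0
    assert f["start_codon"] == 0.0


def test_utr3_site(toy_model, toy_aux, schema):
    site = _site("ts3", "chr1", 1500, "+")  # tx position 500
    f = _named(schema, annotate_genomic_features(site, toy_model, toy_aux, schema))
    assert f["utr3"] == 1.0
    assert f["rel_pos_utr3"] == pytest.approx((500 - 400) / 200)


def test_gc_content_near_extreme(toy_model, toy_aux, schema):
    window = "G" * 20 + "A" + "C" * 20  # maximally GC given the central A
    site = _site("ts4", "chr1", 1250, "+", window=window)
    f = _named(schema, annotate_genomic_features(site, toy_model, toy_aux, schema))
    assert f["gc_content"] == pytest.approx(40 / 41)


def test_minus_strand_transcript_coordinates(toy_model):
    """g2 exons (0-based) [2000,2100)+[2200,2300)+[2400,2500), strand -.
    The 5' end is the highest genomic coordinate: 2499 -> 0."""
    tx = toy_model.genes["g2"].primary
    assert tx.length == 300
    assert tx.genomic_to_tx(2499) == 0
    assert tx.genomic_to_tx(2450) == 49
    assert tx.genomic_to_tx(2250) == 100 + (2299 - 2250)
    assert tx.genomic_to_tx(2000) == 299
    assert tx.genomic_to_tx(2150) is None  # intronic


def test_intronic_site_features(toy_model, toy_aux, schema):
    site = _site("ts5", "chr2", 2150, "-")
    f = _named(schema, annotate_genomic_features(site, toy_model, toy_aux, schema))
    assert f["intron"] == 1.0 and f["exon"] == 0.0
    assert f["len_containing_exon"] == 0.0
    assert f["rel_pos_transcript"] == 0.0


def test_clustering_features(toy_model, toy_aux, schema):
    site = _site("ts6", "chr1", 1250, "+")
    neighbors = np.array([1250, 1260, 1500, 3000])
    f = _named(schema, annotate_genomic_features(
        site, toy_model, toy_aux, schema, neighbor_positions=neighbors))
    assert f["sites_within_100nt"] == 1.0  # 1260 only (self excluded)
    assert f["sites_within_1000nt"] == 2.0  # 1260 and 1500
    assert f["dist_nearest_site"] == 10.0
    assert f["log_dist_nearest_site"] == pytest.approx(np.log10(11.0))


def test_drach_count_in_window(toy_model, toy_aux, schema):
    site = _site("ts7", "chr1", 1250, "+")
    f = _named(schema, annotate_genomic_features(site, toy_model, toy_aux, schema))
    assert f["drach_count_window"] == 1.0  # only the central GGACU core


def test_unmapped_site_raises(toy_model, toy_aux, schema):
    with pytest.raises(AnnotationError, match="ts8"):
        annotate_genomic_features(_site("ts8", "chr9", 50, "+"),
                                  toy_model, toy_aux, schema)


def test_missing_aux_column_raises(toy_model, toy_aux, schema):
    broken = toy_aux.drop(columns=["struct_hybridize"])
    with pytest.raises(SchemaError, match="struct_hybridize"):
        annotate_genomic_features(_site("ts9", "chr1", 1250, "+"),
                                  toy_model, broken, schema)


def test_gff_coordinate_conversion():
    assert gff_to_zero_based(1001, 1600) == (1000, 1600)
    assert gff_to_zero_based(1, 1) == (0, 1)
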