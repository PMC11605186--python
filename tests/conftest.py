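"""Shared fixtures: small synthetic catalogs, a toy GFF3 gene model, and
independent oracles (hypergeometric enumeration, hand BH, O(n^2) AUROC)."""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from epicrossnet.schema import default_schema
from epicrossnet.simulate import GeneratorParams, generate_catalog, generate_features


# ---------------------------------------------------------------------------
# independent oracles


def fisher_enum_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact-rational enumeration of all tables with
    the observed margins (probability-mass criterion)."""
    r1, r2, col1 = a + b, c + d, a + c
    denom = comb(r1 + r2, col1)
    def pmf(x):
        return Fraction(comb(r1, x) * comb(r2, col1 - x), denom)
    p_obs = pmf(a)
    lo, hi = max(0, col1 - r2), min(r1, col1)
    return float(sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs))


def bh_stepup(p: np.ndarray) -> np.ndarray:
    """Hand Benjamini-Hochberg step-up, returned in input order."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0, 1)
    return q


def auroc_bruteforce(scores, labels) -> float:
    """O(n^2) pairwise concordance with half-credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# synthetic fixtures


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def small_params():
    return GeneratorParams(n_sites=400, seed=7)


@pytest.fixture(scope="session")
def small_catalog(small_params):
    return generate_catalog(small_params)


@pytest.fixture(scope="session")
def small_features(small_catalog, small_params):
    return generate_features(small_catalog, small_params)


# ---------------------------------------------------------------------------
# toy transcript annotation


TOY_GFF = """\
##gff-version 3
chr1\ttoy\tgene\t1001\t1600\t.\t+\t.\tID=g1
chr1\ttoy\tmRNA\t1001\t1600\t.\t+\t.\tID=t1;Parent=g1
chr1\ttoy\texon\t1001\t1600\t.\t+\t.\tID=t1e1;Parent=t1
chr1\ttoy\tCDS\t1101\t1400\t.\t+\t0\tID=t1c1;Parent=t1
chr1\ttoy\tmRNA\t1001\t1300\t.\t+\t.\tID=t2;Parent=g1
chr1\ttoy\texon\t1001\t1300\t.\t+\t.\tID=t2e1;Parent=t2
chr1\ttoy\tmRNA\t1001\t1500\t.\t+\t.\tID=t3;Parent=g1
chr1\ttoy\texon\t1001\t1500\t.\t+\t.\tID=t3e1;Parent=t3
chr2\ttoy\tgene\t2001\t2500\t.\t-\t.\tID=g2
chr2\ttoy\tmRNA\t2001\t2500\t.\t-\t.\tID=t4;Parent=g2
chr2\ttoy\texon\t2001\t2100\t.\t-\t.\tID=t4e1;Parent=t4
chr2\ttoy\texon\t2201\t2300\t.\t-\t.\tID=t4e2;Parent=t4
chr2\ttoy\texon\t2401\t2500\t.\t-\t.\tID=t4e3;Parent=t4
"""


@pytest.fixture(scope="session")
def toy_gff(tmp_path_factory):
    path = tmp_path_factory.mktemp("annot") / "toy.gff3"
    path.write_text(TOY_GFF)
    return path


@pytest.fixture(scope="session")
def toy_model(toy_gff):
    from epicrossnet.annotate import TranscriptModel

    return TranscriptModel.from_gff(toy_gff)


@pytest.fixture()
def toy_aux(schema):
    names = [d.name for d in schema if d.source == "external_column"]
    idx = [f"ts{i}" for i in range(10)]
    return pd.DataFrame(0.0, index=idx, columns=names)


def make_window(center_context: str = "GGACU") -> str:
    """41-nt window with the given DRACH 5-mer centred on the A (index 20)."""
    assert len(center_context) == 5 and center_context[2] == "A"
    return "C" * 18 + center_context + "C" * 18
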