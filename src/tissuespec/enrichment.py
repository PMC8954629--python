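"""Over-representation analysis of gene sets against a gene-to-term annotation.

The test is the standard hypergeometric upper tail: for a term annotated to
K of N universe genes, with n set genes in the universe and k of them carrying
the term, p = P(X >= k) for X ~ Hypergeometric(N, K, n).  Benjamini-Hochberg
adjustment is applied within the tested term list, and q-values use the
conservative pi0 = 1 estimate (so q coincides with the BH-adjusted p; chosen
for determinism over power).  A term is significant at the dual cutoff
p < 0.05 and q < 0.2.
"""

from __future__ import annotations

import logging
from typing import Collection

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

NAMESPACES = ("biological_process", "cellular_component", "molecular_function")


def read_annotation_tsv(path) -> pd.DataFrame:
    """Load a gene-to-term annotation table.

    Expected columns: ``gene_id``, ``term_id`` and optionally ``term_name``
    and ``namespace``.  Duplicate (gene, term) pairs are dropped.
    """
    anno = pd.read_csv(path, sep="\t", dtype=str)
    return validate_annotation(anno)


def validate_annotation(anno: pd.DataFrame) -> pd.DataFrame:
    for col in ("gene_id", "term_id"):
        if col not in anno.columns:
            raise ValueError(f"annotation table missing column {col!r}")
    if "term_name" not in anno.columns:
        anno = anno.assign(term_name=anno["term_id"])
    if "namespace" not in anno.columns:
        anno = anno.assign(namespace="biological_process")
    bad_ns = set(anno["namespace"]) - set(NAMESPACES)
    if bad_ns:
        raise ValueError(f"unknown namespace(s) {sorted(bad_ns)}; expected {NAMESPACES}")
    return anno.drop_duplicates(subset=["gene_id", "term_id"])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrich(
    gene_set: Collection[str],
    annotation: pd.DataFrame,
    universe: Collection[str],
    p_cutoff: float = 0.05,
    q_cutoff: float = 0.2,
    min_term_size: int = 3,
) -> pd.DataFrame:
    """Hypergeometric over-representation of annotation terms in a gene set.

    Set genes absent from the universe are dropped (and logged) before
    testing; terms annotated to fewer than ``min_term_size`` universe genes
    are excluded as noise control (set ``min_term_size=0`` to disable).
    Results are sorted by p, then term id.
    """
    genes = set(gene_set)
    universe = set(universe)
    if not genes:
        raise ValueError("gene set is empty")
    if not universe:
        raise ValueError("universe is empty")
    dropped = genes - universe
    if dropped:
        logger.info(
            "dropping %d gene(s) absent from the universe before enrichment", len(dropped)
        )
    genes &= universe
    if not genes:
        raise ValueError("no gene of the set is present in the universe")
    anno = validate_annotation(annotation)
    anno = anno[anno["gene_id"].isin(universe)]
    n_universe = len(universe)
    n_set = len(genes)
    rows = []
    for (term_id, term_name, namespace), sub in anno.groupby(
        ["term_id", "term_name", "namespace"], sort=True
    ):
        term_genes = set(sub["gene_id"])
        big_k = len(term_genes)
        if big_k < max(min_term_size, 1):
            continue
        k = len(term_genes & genes)
        p = float(hypergeom.sf(k - 1, n_universe, big_k, n_set))
        rows.append(
            {
                "term_id": term_id,
                "term_name": term_name,
                "namespace": namespace,
                "k": k,
                "n": n_set,
                "K": big_k,
                "N": n_universe,
                "p": min(p, 1.0),
            }
        )
    result = pd.DataFrame(
        rows, columns=["term_id", "term_name", "namespace", "k", "n", "K", "N", "p"]
    )
    if len(result):
        result["p_adj"] = bh_adjust(result["p"].to_numpy())
        result["q"] = result["p_adj"]  # q-value under pi0 = 1
        result["significant"] = (result["p"] < p_cutoff) & (result["q"] < q_cutoff)
        result = result.sort_values(["p", "term_id"], kind="stable").reset_index(drop=True)
    else:
        result["p_adj"] = []
        result["q"] = []
        result["significant"] = []
    return result
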