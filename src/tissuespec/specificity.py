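"""Tissue-specificity screens: abundance tiers, fold-ratio screens, set algebra.

A gene is called specific to a target tissue when (1) its abundance in the
target is at least ``eg_cutoff`` TPM and (2) the ratio of the target abundance
to the *maximum* abundance over the reference tissues is at least
``fold_threshold`` (default 100, inclusive).  Samples with role ``excluded``
take no part in the comparison — e.g. anthers are excluded from the reference
panel of the pollen screen, and pollen from the anther screen, because late
anthers already contain mature pollen grains.

When every reference sample is silent for a gene, the reference maximum is
floored at ``zero_floor`` (default ``eg_cutoff / fold_threshold``) so that any
target abundance meeting the expression cutoff passes the ratio test: absence
in the references is the strongest possible specificity evidence and must not
be lost to a division by zero.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, ExpressionMatrixError

TIERS = ("notEG", "LEG", "MEG", "HEG", "VHEG")
AGGREGATIONS = ("single", "mean")


@dataclass(frozen=True)
class ScreenConfig:
    """All screen thresholds in one place.

    eg_cutoff:
        Expressed-gene cutoff in TPM (strict ``>`` for tier classification,
        inclusive ``>=`` for the specificity screen's target condition).
    tier_bounds:
        Abundance tier boundaries in TPM: LEG (eg_cutoff, b0), MEG [b0, b1),
        HEG [b1, b2), VHEG [b2, inf).
    fold_threshold:
        Minimum target / reference-max ratio (inclusive).
    abundant_cutoff:
        TPM cutoff (inclusive) for the "abundant gene" screen.
    zero_floor:
        Pseudo-floor applied to the reference maximum; ``None`` means
        ``eg_cutoff / fold_threshold``.
    """

    eg_cutoff: float = 1.0
    tier_bounds: tuple[float, float, float] = (10.0, 30.0, 300.0)
    fold_threshold: float = 100.0
    abundant_cutoff: float = 300.0
    zero_floor: float | None = None

    def __post_init__(self) -> None:
        b0, b1, b2 = self.tier_bounds
        if not (0 < self.eg_cutoff < b0 < b1 < b2):
            raise ValueError(
                f"require 0 < eg_cutoff < tier bounds (ascending); got "
                f"eg_cutoff={self.eg_cutoff}, tier_bounds={self.tier_bounds}"
            )
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must exceed 1")
        if self.zero_floor is not None and self.zero_floor <= 0:
            raise ValueError("zero_floor must be positive")

    @property
    def floor(self) -> float:
        return self.zero_floor if self.zero_floor is not None else self.eg_cutoff / self.fold_threshold


@dataclass(frozen=True)
class GeneSet:
    """Named set of gene identifiers with screen provenance."""

    name: str
    genes: frozenset[str]
    provenance: str

    def __post_init__(self) -> None:
        if not self.provenance:
            raise ValueError("GeneSet provenance must be non-empty")
        object.__setattr__(self, "genes", frozenset(self.genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# provenance: {self.provenance}\n")
            for g in sorted(self.genes):
                fh.write(g + "\n")

    @classmethod
    def from_file(cls, path, name: str | None = None) -> "GeneSet":
        provenance = "loaded from file"
        genes = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    if line.lower().startswith("# provenance:"):
                        provenance = line.split(":", 1)[1].strip()
                    continue
                genes.append(line)
        import os

        return cls(name or os.path.basename(str(path)), frozenset(genes), provenance)


def classify_abundance(tpm_value: float, config: ScreenConfig = ScreenConfig()) -> str:
    """Classify one TPM value into an abundance tier.

    Tiers are half-open: notEG (<= eg_cutoff), LEG (eg_cutoff, b0),
    MEG [b0, b1), HEG [b1, b2), VHEG [b2, inf) — boundary values 10 -> MEG,
    30 -> HEG, 300 -> VHEG with the default bounds.
    """
    if tpm_value < 0 or not np.isfinite(tpm_value):
        raise ValueError(f"TPM value must be non-negative and finite, got {tpm_value!r}")
    b0, b1, b2 = config.tier_bounds
    if tpm_value <= config.eg_cutoff:
        return "notEG"
    if tpm_value < b0:
        return "LEG"
    if tpm_value < b1:
        return "MEG"
    if tpm_value < b2:
        return "HEG"
    return "VHEG"


def classify_abundance_series(tpm: pd.Series, config: ScreenConfig = ScreenConfig()) -> pd.Series:
    """Vectorised tier classification of a TPM vector."""
    x = tpm.to_numpy(dtype=float)
    if (x < 0).any() or not np.isfinite(x).all():
        raise ValueError("TPM values must be non-negative and finite")
    b0, b1, b2 = config.tier_bounds
    tier = np.select(
        [x <= config.eg_cutoff, x < b0, x < b1, x < b2],
        ["notEG", "LEG", "MEG", "HEG"],
        default="VHEG",
    )
    return pd.Series(pd.Categorical(tier, categories=list(TIERS)), index=tpm.index, name="tier")


def tier_counts(tpm: pd.Series, config: ScreenConfig = ScreenConfig()) -> pd.Series:
    """Number of genes per abundance tier (a partition of the gene universe)."""
    return classify_abundance_series(tpm, config).value_counts().reindex(list(TIERS))


def _target_abundance(
    m: ExpressionMatrix, meta: pd.DataFrame, aggregation: str
) -> tuple[pd.Series, str]:
    targets = meta.loc[meta["role"] == "target", "sample_id"].tolist()
    if not targets:
        raise ExpressionMatrixError("no sample has role 'target'")
    missing = [s for s in targets if s not in m.sample_ids]
    if missing:
        raise ExpressionMatrixError(f"target sample(s) {missing} absent from matrix")
    if aggregation == "single":
        if len(targets) != 1:
            raise ExpressionMatrixError(
                f"aggregation 'single' requires exactly one target sample, got {targets}"
            )
        return m.data[targets[0]], targets[0]
    if aggregation == "mean":
        label = "mean(" + ",".join(targets) + ")"
        return m.data[targets].mean(axis=1), label
    raise ValueError(f"unknown aggregation {aggregation!r}; expected one of {AGGREGATIONS}")


def screen_specific(
    m: ExpressionMatrix,
    meta: pd.DataFrame,
    aggregation: str = "single",
    config: ScreenConfig = ScreenConfig(),
    name: str | None = None,
) -> tuple[GeneSet, pd.DataFrame]:
    """Fold-ratio specificity screen.

    Target abundance is the single target sample's TPM (``single``) or the
    unweighted mean over target samples (``mean``, used for the 13-anther
    screen).  The reference abundance is the per-gene maximum over all
    ``reference`` samples; ``excluded`` samples are ignored.  Returns the
    specific :class:`GeneSet` and a per-gene record table (all genes).
    """
    if m.unit != "TPM":
        raise ExpressionMatrixError("screen_specific requires a TPM matrix")
    target, target_label = _target_abundance(m, meta, aggregation)
    refs = meta.loc[meta["role"] == "reference", "sample_id"].tolist()
    if not refs:
        raise ExpressionMatrixError("no sample has role 'reference'")
    missing = [s for s in refs if s not in m.sample_ids]
    if missing:
        raise ExpressionMatrixError(f"reference sample(s) {missing} absent from matrix")
    ref_max = m.data[refs].max(axis=1)
    ratio = target / np.maximum(ref_max, config.floor)
    specific = (target >= config.eg_cutoff) & (ratio >= config.fold_threshold)
    records = pd.DataFrame(
        {
            "target_abundance": target,
            "reference_max": ref_max,
            "ratio": ratio,
            "is_specific": specific,
        }
    )
    records.index.name = "gene_id"
    set_name = name or f"{target_label}-specific"
    provenance = (
        f"specificity screen: target={target_label} ({aggregation}), "
        f"references={refs}, eg_cutoff={config.eg_cutoff}, "
        f"fold_threshold={config.fold_threshold}, zero_floor={config.floor}"
    )
    gene_set = GeneSet(set_name, frozenset(records.index[specific]), provenance)
    return gene_set, records


def abundant_genes(
    m: ExpressionMatrix,
    meta: pd.DataFrame,
    aggregation: str = "single",
    config: ScreenConfig = ScreenConfig(),
    name: str | None = None,
) -> GeneSet:
    """Genes whose target abundance meets the abundant cutoff (>= 300 TPM)."""
    if m.unit != "TPM":
        raise ExpressionMatrixError("abundant_genes requires a TPM matrix")
    target, target_label = _target_abundance(m, meta, aggregation)
    genes = frozenset(target.index[target >= config.abundant_cutoff])
    provenance = (
        f"abundance screen: target={target_label} ({aggregation}), "
        f"abundant_cutoff={config.abundant_cutoff}"
    )
    return GeneSet(name or f"{target_label}-abundant", genes, provenance)


def intersect(sets: Sequence[GeneSet], name: str | None = None) -> tuple[GeneSet, dict[frozenset, int]]:
    """Intersect >= 2 gene sets and tally every exclusive Venn region.

    Returns the full intersection as a :class:`GeneSet` plus a mapping from
    each non-empty membership pattern (frozenset of set names) to the number
    of genes exclusively in that region.
    """
    if len(sets) < 2:
        raise ValueError("intersect requires at least two gene sets")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ValueError(f"gene set names must be unique, got {names}")
    regions: Counter[frozenset] = Counter()
    universe = set().union(*(s.genes for s in sets))
    for gene in universe:
        pattern = frozenset(s.name for s in sets if gene in s.genes)
        regions[pattern] += 1
    common = frozenset.intersection(*(s.genes for s in sets))
    provenance = "intersection of " + " & ".join(names)
    return GeneSet(name or "&".join(names), common, provenance), dict(regions)


def overlap_percentage(subset_size: int, set_size: int) -> float:
    """100 x subset / set, rounded half-up to one decimal place."""
    if set_size <= 0:
        raise ValueError("set_size must be positive")
    if not 0 <= subset_size <= set_size:
        raise ValueError(f"require 0 <= subset_size <= set_size, got {subset_size}/{set_size}")
    pct = Decimal(subset_size * 100) / Decimal(set_size)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def make_roles(
    meta: pd.DataFrame,
    target_labels: Iterable[str],
    exclude_labels: Iterable[str] = (),
) -> pd.DataFrame:
    """Return a copy of the metadata with roles assigned for one screen.

    Samples whose ``tissue_label`` is in ``target_labels`` become targets,
    those in ``exclude_labels`` are excluded, everything else is a reference.
    """
    target_labels = set(target_labels)
    exclude_labels = set(exclude_labels)
    unknown = (target_labels | exclude_labels) - set(meta["tissue_label"])
    if unknown:
        raise ValueError(f"tissue label(s) {sorted(unknown)} not present in metadata")
    out = meta.copy()
    out["role"] = "reference"
    out.loc[out["tissue_label"].isin(exclude_labels), "role"] = "excluded"
    out.loc[out["tissue_label"].isin(target_labels), "role"] = "target"
    return out
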