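"""Expression-matrix I/O, TPM normalisation and per-tissue transcriptome summaries.

The central container is :class:`ExpressionMatrix`, a thin validated wrapper
around a genes x samples :class:`pandas.DataFrame` with a unit flag
(``"counts"`` or ``"TPM"``).  TPM is the within-sample abundance unit
(transcripts per kilobase of exon model per million mapped reads): per sample,
counts are divided by gene length in kb and rescaled so the column sums to 1e6.

Sample metadata is a plain DataFrame with columns ``sample_id``,
``tissue_label``, ``role`` (``target`` / ``reference`` / ``excluded``) and
``condition`` (``NT`` / ``HT`` / ``NA``); the role column encodes which samples
a specificity screen compares (e.g. anthers are excluded from the reference
panel of the pollen screen because late anthers already contain mature pollen).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TPM_TOTAL = 1e6

UNITS = ("counts", "TPM")
ROLES = ("target", "reference", "excluded")
CONDITIONS = ("NT", "HT", "NA")

METADATA_COLUMNS = ["sample_id", "tissue_label", "role", "condition"]


class ExpressionMatrixError(ValueError):
    """Raised when an expression matrix violates its invariants."""


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance matrix with a unit flag.

    Parameters
    ----------
    data:
        DataFrame with gene identifiers as index and sample identifiers as
        columns.  Values must be finite and non-negative.
    unit:
        Either ``"counts"`` or ``"TPM"``.
    strict_tpm:
        When True (the default, used for matrices produced in memory), TPM
        columns must sum to 1e6 within relative tolerance 1e-6; when False
        (used on file load) a violation only raises a warning.
    """

    data: pd.DataFrame
    unit: str
    strict_tpm: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ExpressionMatrixError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        idx = self.data.index
        dup = idx[idx.duplicated()]
        if len(dup):
            raise ExpressionMatrixError(f"duplicate gene identifier(s): {sorted(set(dup))}")
        cols = self.data.columns
        dup = cols[cols.duplicated()]
        if len(dup):
            raise ExpressionMatrixError(f"duplicate sample identifier(s): {sorted(set(dup))}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ExpressionMatrixError("matrix contains non-numeric values")
        bad = ~np.isfinite(values) | (values < 0)
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise ExpressionMatrixError(
                f"negative or non-finite value {values[g, s]!r} at "
                f"gene {idx[g]!r}, sample {cols[s]!r}"
            )
        if self.unit == "TPM" and self.data.shape[0] > 0:
            colsums = values.sum(axis=0)
            off = np.abs(colsums - TPM_TOTAL) > 1e-6 * TPM_TOTAL
            if off.any():
                msg = (
                    f"TPM column(s) {list(cols[off])} sum to {colsums[off]} "
                    f"instead of {TPM_TOTAL:g}"
                )
                if self.strict_tpm:
                    raise ExpressionMatrixError(msg)
                warnings.warn(msg, stacklevel=2)

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene_id")


def read_expression_tsv(path, unit: str) -> ExpressionMatrix:
    """Load a rectangular TSV (header = sample ids, first column = gene ids).

    Duplicated identifiers and negative or non-numeric cells are hard errors
    that name the offending gene/sample.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    raw.index = raw.index.astype(str)
    numeric = raw.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise ExpressionMatrixError(
            f"non-numeric value {raw.iat[g, s]!r} at gene {raw.index[g]!r}, "
            f"sample {raw.columns[s]!r} in {path}"
        )
    if numeric.isna().to_numpy().any():
        raise ExpressionMatrixError(f"missing value(s) in {path}")
    return ExpressionMatrix(numeric.astype(float), unit, strict_tpm=False)


def read_gene_lengths_tsv(path) -> pd.Series:
    """Load effective gene lengths (bp) as a Series indexed by gene id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    lengths = df.iloc[:, 0].astype(float)
    lengths.index = lengths.index.astype(str)
    return validate_gene_lengths(lengths)


def validate_gene_lengths(lengths: pd.Series, matrix: ExpressionMatrix | None = None) -> pd.Series:
    if lengths.index.duplicated().any():
        dup = lengths.index[lengths.index.duplicated()]
        raise ExpressionMatrixError(f"duplicate gene identifier(s) in lengths: {sorted(set(dup))}")
    if (lengths <= 0).any() or not np.isfinite(lengths).all():
        bad = lengths.index[(lengths <= 0) | ~np.isfinite(lengths)]
        raise ExpressionMatrixError(f"non-positive gene length(s) for {list(bad[:5])}")
    if matrix is not None:
        missing = matrix.gene_ids.difference(lengths.index)
        if len(missing):
            raise ExpressionMatrixError(
                f"lengths missing for {len(missing)} gene(s), e.g. {list(missing[:5])}"
            )
    return lengths


def read_sample_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    return validate_sample_metadata(meta)


def validate_sample_metadata(meta: pd.DataFrame, matrix: ExpressionMatrix | None = None) -> pd.DataFrame:
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ExpressionMatrixError(f"sample metadata missing column(s) {missing_cols}")
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"]
        raise ExpressionMatrixError(f"duplicate metadata row(s) for sample(s) {sorted(set(dup))}")
    bad_roles = set(meta["role"]) - set(ROLES)
    if bad_roles:
        raise ExpressionMatrixError(f"unknown role(s) {sorted(bad_roles)}; expected {ROLES}")
    bad_cond = set(meta["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise ExpressionMatrixError(f"unknown condition(s) {sorted(bad_cond)}; expected {CONDITIONS}")
    if matrix is not None:
        unmatched = set(matrix.sample_ids) - set(meta["sample_id"])
        if unmatched:
            raise ExpressionMatrixError(f"no metadata row for sample(s) {sorted(unmatched)}")
    return meta


def counts_to_tpm(counts: ExpressionMatrix, lengths: pd.Series) -> ExpressionMatrix:
    """Convert raw counts to TPM.

    Per sample: ``rate_g = count_g / length_g(kb)``; ``TPM_g = 1e6 * rate_g /
    sum(rates)``.  Every output column sums to 1e6.
    """
    if counts.unit != "counts":
        raise ExpressionMatrixError(f"expected a counts matrix, got unit {counts.unit!r}")
    lengths = validate_gene_lengths(lengths, counts)
    kb = lengths.reindex(counts.gene_ids) / 1000.0
    rates = counts.data.div(kb, axis=0)
    totals = rates.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ExpressionMatrixError(
            f"TPM undefined: sample column(s) {list(zero.index)} are all zero"
        )
    tpm = rates.div(totals, axis=1) * TPM_TOTAL
    return ExpressionMatrix(tpm, "TPM")


def correlation_matrix(m: ExpressionMatrix, log2_transform: bool = False) -> pd.DataFrame:
    """Sample x sample Pearson correlation matrix of abundances.

    By default raw values are correlated; ``log2_transform`` switches to
    log2(x + 1).  Samples with constant abundance across genes have undefined
    correlations; the affected entries (including the diagonal) are reported
    as NaN with a warning rather than silently set to 0.
    """
    if m.shape[1] < 2 or m.shape[0] < 2:
        raise ExpressionMatrixError("correlation requires >= 2 samples and >= 2 genes")
    x = m.data.to_numpy(dtype=float)
    if log2_transform:
        x = np.log2(x + 1.0)
    std = x.std(axis=0)
    constant = std == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    np.fill_diagonal(r, 1.0)
    if constant.any():
        labels = list(m.sample_ids[constant])
        warnings.warn(
            f"correlation undefined for constant sample column(s) {labels}; entries set to NaN",
            stacklevel=2,
        )
        r[constant, :] = np.nan
        r[:, constant] = np.nan
    r = np.clip(r, -1.0, 1.0)
    return pd.DataFrame(r, index=m.sample_ids, columns=m.sample_ids)


def transcriptome_summary(
    m: ExpressionMatrix,
    eg_cutoff: float = 1.0,
    top_ns: tuple[int, ...] = (300, 1000),
) -> pd.DataFrame:
    """Per-sample expressed-gene summary.

    For each sample: the number of expressed genes (TPM strictly above
    ``eg_cutoff``), the mean TPM of those genes, and for each N in ``top_ns``
    the mean TPM of the N most abundant expressed genes and the percentage of
    the transcriptome they occupy (sum of their TPM / 1e6 x 100).  Ties at the
    top-N boundary are broken by gene id (lexicographic) so the summary is
    deterministic and invariant to row order.  If a sample has fewer than N
    expressed genes, all of them are used and ``top{N}_shortfall`` is True.
    """
    if m.unit != "TPM":
        raise ExpressionMatrixError("transcriptome_summary requires a TPM matrix")
    rows = []
    for sample in m.sample_ids:
        col = m.data[sample]
        eg = col[col > eg_cutoff]
        rec = {
            "sample_id": sample,
            "n_EG": int(len(eg)),
            "mean_TPM_EG": float(eg.mean()) if len(eg) else 0.0,
        }
        ordered = eg.sort_index().sort_values(ascending=False, kind="stable")
        for n in top_ns:
            top = ordered.iloc[:n]
            rec[f"mean_top{n}_TPM"] = float(top.mean()) if len(top) else 0.0
            rec[f"pct_top{n}"] = float(100.0 * top.sum() / TPM_TOTAL)
            rec[f"top{n}_shortfall"] = bool(len(eg) < n)
        rows.append(rec)
    return pd.DataFrame(rows).set_index("sample_id")
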