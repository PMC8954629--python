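"""Differential expression between two unreplicated libraries.

With one library per condition the dispersion cannot be estimated from the
data, so it is fixed a priori through the biological coefficient of variation:
``phi = bcv**2`` (default BCV 0.3, hence phi = 0.09).  Counts are modelled as
negative binomial with variance ``mu + phi * mu**2``.

The two-sided test is the classic conditional exact test: both counts are
first rescaled to a common effective library size (the geometric mean of the
two effective sizes, preserving expectations); under the null the conditional
distribution of one count given the total ``n`` is then beta-binomial
``(n, r, r)`` with ``r = 1/phi``, and the p-value is the total conditional
probability of all outcomes no more probable than the observed one.  The
conditional support is enumerated exactly; totals whose support exceeds
``enumeration_cap`` raise an error suggesting the cap be raised.

Non-integer rescaled counts are resolved by bilinear interpolation of the
p-value over the four integer corners (floor/ceil of each rescaled count) —
deterministic and documented.

Library-size normalisation uses TMM (trimmed mean of M-values): per sample, a
doubly-trimmed (30% on M, 5% on A) weighted mean of gene-wise log2 ratios
against a reference sample, weighted by the inverse asymptotic variance of M;
the resulting factors are rescaled to geometric mean 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import rankdata

from .expression import ExpressionMatrix, ExpressionMatrixError
from .specificity import GeneSet, overlap_percentage

DIRECTIONS = ("up", "down", "ns")


@dataclass(frozen=True)
class DiffExprConfig:
    """Parameters of the unreplicated DEG call."""

    bcv: float = 0.3
    p_cutoff: float = 0.05
    min_count: int = 1  # count >= min_count in at least one sample
    tmm: bool = True
    enumeration_cap: int = 100_000

    def __post_init__(self) -> None:
        if self.bcv <= 0:
            raise ValueError("bcv must be positive")
        if not 0 < self.p_cutoff < 1:
            raise ValueError("p_cutoff must lie in (0, 1)")

    @property
    def dispersion(self) -> float:
        return self.bcv**2


def tmm_factors(
    counts: pd.DataFrame,
    ref_column: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """TMM normalisation factors, rescaled to geometric mean 1.

    ``ref_column`` defaults to the sample whose 75th-percentile count fraction
    is closest to the mean over samples.  Genes with a zero count in either
    the sample or the reference are excluded before trimming.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("every library must have a positive total count")
    if ref_column is None:
        q75 = counts.apply(lambda c: np.quantile(c[c > 0], 0.75) if (c > 0).any() else 0.0)
        frac = q75 / lib
        ref_column = (frac - frac.mean()).abs().idxmin()
    if ref_column not in counts.columns:
        raise ValueError(f"reference column {ref_column!r} not in matrix")

    yr = counts[ref_column].to_numpy(dtype=float)
    nr = lib[ref_column]
    factors = {}
    for sample in counts.columns:
        if sample == ref_column:
            factors[sample] = 1.0
            continue
        ys = counts[sample].to_numpy(dtype=float)
        ns = lib[sample]
        keep = (ys > 0) & (yr > 0)
        if not keep.any():
            warnings.warn(f"no genes shared between {sample!r} and reference; factor set to 1")
            factors[sample] = 1.0
            continue
        ps, pr = ys[keep] / ns, yr[keep] / nr
        m = np.log2(ps / pr)
        a = 0.5 * np.log2(ps * pr)
        n = len(m)
        lo_m = math.floor(n * trim_m) + 1
        hi_m = n + 1 - lo_m
        lo_a = math.floor(n * trim_a) + 1
        hi_a = n + 1 - lo_a
        rm, ra = rankdata(m), rankdata(a)
        sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if not sel.any():
            warnings.warn(f"no genes survive TMM trimming for {sample!r}; factor set to 1")
            factors[sample] = 1.0
            continue
        ysel, rsel = ys[keep][sel], yr[keep][sel]
        w = 1.0 / ((ns - ysel) / (ns * ysel) + (nr - rsel) / (nr * rsel))
        factors[sample] = float(2.0 ** (np.sum(w * m[sel]) / np.sum(w)))
    f = pd.Series(factors).reindex(counts.columns)
    return f / np.exp(np.log(f).mean())


def _conditional_logpmf(n: int, r: float) -> np.ndarray:
    """Log pmf of the beta-binomial(n, r, r) conditional null distribution.

    Computed from the identity Gamma(k + r) / Gamma(r) = prod_{j<k} (r + j),
    which stays exact for arbitrarily large r (the Poisson/binomial limit).
    """
    j = np.arange(n, dtype=float)
    c = np.concatenate(([0.0], np.cumsum(np.log(r + j))))
    k = np.arange(n + 1)
    logw = c[k] + c[n - k] - gammaln(k + 1.0) - gammaln(n - k + 1.0)
    return logw - logsumexp(logw)


def _exact_p_integer(a: int, b: int, phi: float, cap: int) -> float:
    n = a + b
    if n == 0:
        return 1.0
    if n + 1 > cap:
        raise ValueError(
            f"conditional support of {n + 1} outcomes exceeds enumeration_cap={cap}; "
            "raise the cap to test this gene"
        )
    logpmf = _conditional_logpmf(n, 1.0 / phi)
    obs = logpmf[a]
    sel = logpmf <= obs + 1e-8  # tolerate float ties (symmetry partners)
    p = math.exp(logsumexp(logpmf[sel]))
    if p >= 1.0 - 1e-9:  # full support selected up to float residue
        return 1.0
    return float(p)


def nb_exact_test(
    y_a: float,
    y_b: float,
    lib_a: float = 1.0,
    lib_b: float = 1.0,
    phi: float = 0.09,
    enumeration_cap: int = 100_000,
) -> float:
    """Two-sided exact NB test of equal means for one gene, two libraries.

    Counts are rescaled to the geometric-mean effective library size; the
    p-value at non-integer rescaled counts is the bilinear interpolation over
    the neighbouring integer pairs.
    """
    if phi <= 0:
        raise ValueError("dispersion phi must be positive")
    if lib_a <= 0 or lib_b <= 0:
        raise ValueError("effective library sizes must be positive")
    if y_a < 0 or y_b < 0:
        raise ValueError("counts must be non-negative")
    common = math.sqrt(lib_a * lib_b)
    za = y_a * common / lib_a
    zb = y_b * common / lib_b
    # snap float residue so equal libraries reduce to the integer test exactly
    if abs(za - round(za)) < 1e-9:
        za = round(za)
    if abs(zb - round(zb)) < 1e-9:
        zb = round(zb)
    fa, fb = math.floor(za), math.floor(zb)
    wa, wb = za - fa, zb - fb
    corners = {}
    p = 0.0
    for da, weight_a in ((0, 1.0 - wa), (1, wa)):
        for db, weight_b in ((0, 1.0 - wb), (1, wb)):
            w = weight_a * weight_b
            if w == 0.0:
                continue
            key = (fa + da, fb + db)
            if key not in corners:
                corners[key] = _exact_p_integer(key[0], key[1], phi, enumeration_cap)
            p += w * corners[key]
    return float(min(1.0, p))


def call_degs(counts: ExpressionMatrix, config: DiffExprConfig = DiffExprConfig()) -> pd.DataFrame:
    """Call DEGs between two unreplicated libraries (second sample vs first).

    Genes failing the count filter (count >= ``min_count`` in at least one
    sample) are dropped before testing.  The log2 fold change is computed on
    normalised counts with a display pseudo-count of 0.5 per cell; the
    pseudo-count never enters the test.  Direction is assigned by the sign of
    the fold change at raw p < ``p_cutoff``; BH-adjusted p-values are emitted
    as an extra column.
    """
    if counts.unit != "counts":
        raise ExpressionMatrixError("call_degs requires a counts matrix")
    if counts.shape[1] != 2:
        raise ExpressionMatrixError("call_degs requires exactly two samples")
    sample_a, sample_b = counts.sample_ids
    data = counts.data
    kept = data[data.max(axis=1) >= config.min_count]
    lib = data.sum(axis=0).astype(float)
    if config.tmm:
        factors = tmm_factors(data, ref_column=sample_a)
    else:
        factors = pd.Series(1.0, index=data.columns)
    eff = lib * factors
    common = float(np.sqrt(eff.prod()))

    ya = kept[sample_a].to_numpy()
    yb = kept[sample_b].to_numpy()
    eff_a, eff_b = float(eff[sample_a]), float(eff[sample_b])
    pvals = np.empty(len(kept))
    for i in range(len(kept)):
        pvals[i] = nb_exact_test(
            ya[i], yb[i], eff_a, eff_b, config.dispersion, config.enumeration_cap
        )
    norm_a = ya / eff_a * common
    norm_b = yb / eff_b * common
    log2_fc = np.log2((norm_b + 0.5) / (norm_a + 0.5))
    from statsmodels.stats.multitest import multipletests

    p_adj = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else np.array([])
    direction = np.where(
        pvals < config.p_cutoff, np.where(log2_fc > 0, "up", np.where(log2_fc < 0, "down", "ns")), "ns"
    )
    out = pd.DataFrame(
        {
            "count_A": ya,
            "count_B": yb,
            "norm_factor_A": factors[sample_a],
            "norm_factor_B": factors[sample_b],
            "log2_fold_change": log2_fc,
            "p_value": pvals,
            "p_adj": p_adj,
            "direction": direction,
        },
        index=kept.index,
    )
    out.index.name = "gene_id"
    return out


def deg_sets(degs: pd.DataFrame, p_cutoff: float = 0.05) -> dict[str, set[str]]:
    """Up/down/all DEG identifier sets from a DEG table."""
    sig = degs[degs["p_value"] < p_cutoff]
    up = set(sig.index[sig["direction"] == "up"])
    down = set(sig.index[sig["direction"] == "down"])
    return {"up": up, "down": down, "all": up | down}


def cross_tabulate_degs(
    degs: pd.DataFrame,
    tiers: pd.Series,
    sets: Mapping[str, GeneSet] | None = None,
) -> dict[str, pd.DataFrame]:
    """Cross-tabulate called DEGs against abundance tiers and gene sets.

    ``tiers`` maps gene id to abundance tier (e.g. the target tissue's tier
    classification).  Returns per-tier and per-set tables of up/down/total
    DEG counts with the percentage of all DEGs they occupy.
    """
    groups = deg_sets(degs)
    total = len(groups["all"])
    tier_rows = []
    for tier in tiers.cat.categories if hasattr(tiers, "cat") else sorted(tiers.unique()):
        tier_genes = set(tiers.index[tiers == tier])
        n_up = len(groups["up"] & tier_genes)
        n_down = len(groups["down"] & tier_genes)
        tier_rows.append(
            {
                "tier": tier,
                "up": n_up,
                "down": n_down,
                "total": n_up + n_down,
                "pct_of_degs": overlap_percentage(n_up + n_down, total) if total else 0.0,
            }
        )
    report = {"by_tier": pd.DataFrame(tier_rows).set_index("tier")}
    if sets:
        set_rows = []
        for name, gene_set in sets.items():
            n_up = len(groups["up"] & gene_set.genes)
            n_down = len(groups["down"] & gene_set.genes)
            set_rows.append(
                {
                    "set": name,
                    "set_size": len(gene_set),
                    "up": n_up,
                    "down": n_down,
                    "total": n_up + n_down,
                    "pct_of_degs": overlap_percentage(n_up + n_down, total) if total else 0.0,
                }
            )
        report["by_set"] = pd.DataFrame(set_rows).set_index("set")
    return report
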