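"""Synthetic multi-tissue expression atlas with known ground truth.

The generator emulates, at reduced scale, a 22-tissue atlas of an
HT-sensitive cotton line: one mature-pollen sample, 13 anther developmental
stages indexed by bud length, and 8 vegetative/reproductive reference tissues
(root, stem, leaf, bract, sepal, petal, stigma, ovule), plus a matched
high-temperature pollen library for the two-condition DEG contrast.

Key features of real data that are emulated:

* counts are negative binomial with variance ``mu + phi * mu**2``
  (``phi = bcv**2``, default BCV 0.3, matching the fixed-dispersion DEG test);
* the pollen transcriptome is sparse (few expressed genes) and top-heavy (a
  small number of very abundant transcripts), so its expressed-gene count is
  far below the reference tissues while its top-300 share is far above;
* planted tissue-specific genes are silent in the reference panel, the way
  real pollen-/anther-specific genes are undetected outside their tissue, so
  their specificity ratio exceeds any finite fold threshold;
* pollen-expressed background genes are drawn from the upper half of the
  baseline abundance distribution, keeping their reference expression well
  above the zero-floor regime and their specificity ratios in the tens;
* a configurable number of planted DEGs overlap the planted pollen-specific
  set (default 10 shared genes).

Everything is reproducible from the single integer seed in the config.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cre import DEFAULT_MOTIFS, Motif, reverse_complement, write_motifs_yaml
from .expression import ExpressionMatrix

POLLEN_LABEL = "NTpollen"
ANTHER_LABELS = (
    "NT3-5", "NT5-6", "NT6-7", "NT7-8", "NT8-9", "NT9-10", "NT10-11",
    "NT11-12", "NT12-13", "NT13-14", "NT14-16", "NT16-19", "NT19-24",
)
REFERENCE_LABELS = (
    "NTroot", "NTstem", "NTleaf", "NTbract", "NTsepal", "NTpetal", "NTstigma", "NTovule",
)
# tetrad, tapetal-degradation, anther-dehiscence stages by bud length
STAGE_SAMPLES = {"TS": "NT6-7", "TDS": "NT11-12", "ADS": "NT19-24"}
HT_POLLEN_LABEL = "HTpollen"

NT_SAMPLES = (POLLEN_LABEL,) + ANTHER_LABELS + REFERENCE_LABELS


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters of the synthetic atlas."""

    n_genes: int = 5000
    n_planted_psg: int = 50
    n_planted_asg: int = 50
    n_planted_stage: int = 50  # per developmental stage
    planted_fold: float = math.inf  # target/reference mean ratio of planted genes
    bcv: float = 0.3
    pollen_sparsity: float = 0.8  # fraction of background genes silent in pollen
    rare_fraction: float = 0.15  # background genes weakly expressed everywhere
    n_deg_up: int = 40
    deg_up_fold: float = 4.0
    n_deg_down: int = 160
    deg_down_fold: float = 0.25
    n_shared_deg_psg: int = 10  # planted DEGs that are also planted PSGs
    min_deg_mean_count: float = 50.0
    lib_size: float = 2.0e6
    lib_size_cv: float = 0.1
    motif_lambda: float = 3.0  # planted copies per promoter per planted motif
    promoter_length: int = 2000
    truncate_fraction: float = 0.05
    n_background_terms: int = 40
    n_planted_terms: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        planted = self.n_planted_psg + self.n_planted_asg + 3 * self.n_planted_stage
        if planted >= self.n_genes:
            raise ValueError(
                f"infeasible plan: {planted} planted genes for {self.n_genes} total genes"
            )
        if not 0 <= self.pollen_sparsity < 1:
            raise ValueError("pollen_sparsity must lie in [0, 1)")
        if self.planted_fold < 200:
            raise ValueError("planted_fold must be at least 200 (or inf for silent references)")
        if self.n_shared_deg_psg > min(self.n_planted_psg, self.n_deg_up + self.n_deg_down):
            raise ValueError("n_shared_deg_psg exceeds the planted PSG or DEG budget")
        if self.bcv <= 0:
            raise ValueError("bcv must be positive")


@dataclass
class GroundTruth:
    """Planted gene sets and true means, consistent with the emitted files."""

    psg: frozenset[str]
    asg: frozenset[str]  # every gene satisfying the anther-mean criterion
    stage: dict[str, frozenset[str]]
    pollen_expressed: frozenset[str]
    deg_up: frozenset[str]
    deg_down: frozenset[str]
    shared_deg_psg: frozenset[str]
    true_tpm: pd.DataFrame  # genes x samples, columns sum to 1e6

    def to_json(self, path) -> None:
        payload = {
            "psg": sorted(self.psg),
            "asg": sorted(self.asg),
            "stage": {k: sorted(v) for k, v in self.stage.items()},
            "pollen_expressed": sorted(self.pollen_expressed),
            "deg_up": sorted(self.deg_up),
            "deg_down": sorted(self.deg_down),
            "shared_deg_psg": sorted(self.shared_deg_psg),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class SyntheticExpression:
    """Bundle of every expression-side input the pipeline consumes."""

    counts: ExpressionMatrix  # 22 NT tissue libraries
    lengths: pd.Series
    metadata: pd.DataFrame  # roles pre-assigned for the pollen screen
    deg_counts: ExpressionMatrix  # NT vs HT pollen
    truth: GroundTruth
    config: SyntheticConfig

    def write(self, outdir) -> None:
        os.makedirs(outdir, exist_ok=True)
        self.counts.to_tsv(os.path.join(outdir, "counts.tsv"))
        self.lengths.rename("effective_length").to_csv(
            os.path.join(outdir, "lengths.tsv"), sep="\t", index_label="gene_id"
        )
        self.metadata.to_csv(os.path.join(outdir, "metadata.tsv"), sep="\t", index=False)
        self.deg_counts.to_tsv(os.path.join(outdir, "deg_counts.tsv"))
        self.truth.to_json(os.path.join(outdir, "truth.json"))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean, variance = mean + phi mean^2) draw; zero mean gives zero."""
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def generate_expression(config: SyntheticConfig = SyntheticConfig()) -> SyntheticExpression:
    """Generate the 22-tissue counts matrix, the HT contrast and ground truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = pd.Index([f"G{i:05d}" for i in range(n)], name="gene_id")
    lengths = pd.Series(
        np.clip(rng.lognormal(math.log(1500.0), 0.45, n), 300, 8000).round(),
        index=gene_ids,
        name="effective_length",
    )

    samples = list(NT_SAMPLES) + [HT_POLLEN_LABEL]
    t = pd.DataFrame(0.0, index=gene_ids, columns=samples)

    # --- planted gene indices (disjoint) ------------------------------------
    n_planted = config.n_planted_psg + config.n_planted_asg + 3 * config.n_planted_stage
    planted_idx = rng.choice(n, size=n_planted, replace=False)
    cursor = 0
    psg_idx = planted_idx[cursor : cursor + config.n_planted_psg]
    cursor += config.n_planted_psg
    asg_idx = planted_idx[cursor : cursor + config.n_planted_asg]
    cursor += config.n_planted_asg
    stage_idx = {}
    for stage in STAGE_SAMPLES:
        stage_idx[stage] = planted_idx[cursor : cursor + config.n_planted_stage]
        cursor += config.n_planted_stage
    background = np.setdiff1d(np.arange(n), planted_idx)

    # --- background genes ----------------------------------------------------
    baseline = rng.lognormal(math.log(30.0), 1.0, n)
    rare = rng.random(n) < config.rare_fraction
    baseline[rare] = rng.lognormal(math.log(0.3), 0.7, int(rare.sum()))
    non_pollen = list(ANTHER_LABELS) + list(REFERENCE_LABELS)
    effects = rng.lognormal(0.0, 0.4, (n, len(non_pollen)))
    t.loc[gene_ids[background], non_pollen] = (
        baseline[background, None] * effects[background, :]
    )

    # pollen expresses a high-abundance subset of the background transcriptome
    bg_base = baseline[background]
    candidates = background[(bg_base >= np.median(bg_base)) & ~rare[background]]
    n_pollen_bg = int(round((1.0 - config.pollen_sparsity) * len(background)))
    n_pollen_bg = min(n_pollen_bg, len(candidates))
    pollen_bg = rng.choice(candidates, size=n_pollen_bg, replace=False)
    pollen_fold = np.exp(rng.uniform(math.log(0.5), math.log(20.0), n_pollen_bg))
    t.loc[gene_ids[pollen_bg], POLLEN_LABEL] = baseline[pollen_bg] * pollen_fold

    # --- planted specific genes ----------------------------------------------
    ref_div = config.planted_fold  # inf -> silent references
    psg_level = rng.lognormal(math.log(300.0), 0.5, len(psg_idx))
    t.loc[gene_ids[psg_idx], POLLEN_LABEL] = psg_level
    if math.isfinite(ref_div):
        t.loc[gene_ids[psg_idx], list(REFERENCE_LABELS)] = (psg_level / ref_div)[:, None]

    asg_level = rng.lognormal(math.log(100.0), 0.5, len(asg_idx))
    anther_effects = rng.lognormal(0.0, 0.1, (len(asg_idx), len(ANTHER_LABELS)))
    t.loc[gene_ids[asg_idx], list(ANTHER_LABELS)] = asg_level[:, None] * anther_effects
    if math.isfinite(ref_div):
        t.loc[gene_ids[asg_idx], list(REFERENCE_LABELS)] = (asg_level / ref_div)[:, None]

    for stage, sample in STAGE_SAMPLES.items():
        level = rng.lognormal(math.log(150.0), 0.5, len(stage_idx[stage]))
        t.loc[gene_ids[stage_idx[stage]], sample] = level
        if math.isfinite(ref_div):
            t.loc[gene_ids[stage_idx[stage]], list(REFERENCE_LABELS)] = (level / ref_div)[:, None]

    # --- DEG planting on the pollen profile ----------------------------------
    kb = lengths.to_numpy() / 1000.0
    pollen_t = t[POLLEN_LABEL].to_numpy()
    share = pollen_t * kb
    share = share / share.sum()
    exp_count = share * config.lib_size
    eligible_bg = np.array(
        [i for i in pollen_bg if exp_count[i] >= config.min_deg_mean_count], dtype=int
    )
    eligible_psg = np.array(
        [i for i in psg_idx if exp_count[i] >= config.min_deg_mean_count], dtype=int
    )
    if len(eligible_psg) < config.n_shared_deg_psg:
        raise ValueError("not enough high-count planted PSGs for the shared DEG quota")
    shared = rng.choice(eligible_psg, size=config.n_shared_deg_psg, replace=False)
    n_shared_up = int(round(config.n_shared_deg_psg * config.n_deg_up / max(1, config.n_deg_up + config.n_deg_down)))
    shared_up, shared_down = shared[:n_shared_up], shared[n_shared_up:]
    n_bg_up = config.n_deg_up - len(shared_up)
    n_bg_down = config.n_deg_down - len(shared_down)
    if len(eligible_bg) < n_bg_up + n_bg_down:
        raise ValueError("not enough high-count pollen-expressed background genes for DEG plan")
    picked = rng.choice(eligible_bg, size=n_bg_up + n_bg_down, replace=False)
    up_idx = np.concatenate([shared_up, picked[:n_bg_up]])
    down_idx = np.concatenate([shared_down, picked[n_bg_up:]])

    t[HT_POLLEN_LABEL] = t[POLLEN_LABEL]
    t.loc[gene_ids[up_idx], HT_POLLEN_LABEL] *= config.deg_up_fold
    t.loc[gene_ids[down_idx], HT_POLLEN_LABEL] *= config.deg_down_fold

    # --- counts ---------------------------------------------------------------
    counts = pd.DataFrame(0, index=gene_ids, columns=samples, dtype=np.int64)
    phi = config.bcv**2
    for sample in samples:
        weights = t[sample].to_numpy() * kb
        total = weights.sum()
        if total == 0:
            raise ValueError(f"sample {sample} has no expressed gene")
        lib = config.lib_size * rng.lognormal(0.0, config.lib_size_cv)
        counts[sample] = _nb_draw(rng, weights / total * lib, phi)

    true_tpm = t.div(t.sum(axis=0), axis=1) * 1e6

    # genes satisfying the anther-mean specificity criterion by construction:
    # planted ASGs plus stage-planted genes (expressed in one of the 13
    # anthers, silent in every reference)
    asg_truth = set(gene_ids[asg_idx])
    if not math.isfinite(ref_div):
        for stage in STAGE_SAMPLES:
            asg_truth |= set(gene_ids[stage_idx[stage]])
    truth = GroundTruth(
        psg=frozenset(gene_ids[psg_idx]),
        asg=frozenset(asg_truth),
        stage={s: frozenset(gene_ids[stage_idx[s]]) for s in STAGE_SAMPLES},
        pollen_expressed=frozenset(gene_ids[np.concatenate([pollen_bg, psg_idx])]),
        deg_up=frozenset(gene_ids[up_idx]),
        deg_down=frozenset(gene_ids[down_idx]),
        shared_deg_psg=frozenset(gene_ids[shared]),
        true_tpm=true_tpm,
    )

    metadata = pd.DataFrame(
        {
            "sample_id": list(NT_SAMPLES),
            "tissue_label": list(NT_SAMPLES),
            "role": [
                "target" if s == POLLEN_LABEL else ("excluded" if s in ANTHER_LABELS else "reference")
                for s in NT_SAMPLES
            ],
            "condition": "NT",
        }
    )

    counts_nt = ExpressionMatrix(counts[list(NT_SAMPLES)].copy(), "counts")
    deg_counts = ExpressionMatrix(
        counts[[POLLEN_LABEL, HT_POLLEN_LABEL]].copy(), "counts"
    )
    return SyntheticExpression(counts_nt, lengths, metadata, deg_counts, truth, config)


# ---------------------------------------------------------------------------
# toy genome, motif planting and annotation
# ---------------------------------------------------------------------------

PLANTED_MOTIFS: tuple[Motif, ...] = (
    Motif("TC-rich repeats", "ATTCTCTAAC", "stress-related"),
    Motif("ABRE3a", "TACGTGTC", "ABA-responsive"),
)

_CDS_LEN = 300
_SPACER = 100
_GENES_PER_CONTIG = 25


@dataclass
class SyntheticGenome:
    """Toy genome with planted promoter motifs and a planted-term annotation."""

    contigs: dict[str, str]
    gff_lines: list[str]
    motifs: list[Motif]
    planted_hits: pd.DataFrame  # gene_id, motif, position (promoter offset), strand
    annotation: pd.DataFrame
    planted_terms: list[str]
    truncated_genes: frozenset[str]

    def write(self, outdir) -> dict[str, str]:
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "genome": os.path.join(outdir, "genome.fa"),
            "gff3": os.path.join(outdir, "models.gff3"),
            "motifs": os.path.join(outdir, "motifs.yaml"),
            "annotation": os.path.join(outdir, "annotation.tsv"),
            "planted_hits": os.path.join(outdir, "planted_hits.tsv"),
        }
        with open(paths["genome"], "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        with open(paths["gff3"], "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write("\n".join(self.gff_lines) + "\n")
        write_motifs_yaml(self.motifs, paths["motifs"])
        self.annotation.to_csv(paths["annotation"], sep="\t", index=False)
        self.planted_hits.to_csv(paths["planted_hits"], sep="\t", index=False)
        return paths


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def _plant_motifs(
    rng: np.random.Generator,
    promoter: str,
    gene_id: str,
    motifs: Sequence[Motif],
    lam: float,
) -> tuple[str, list[dict]]:
    seq = list(promoter)
    occupied: list[tuple[int, int]] = []
    records = []
    for motif in motifs:
        width = len(motif.pattern)
        for _ in range(rng.poisson(lam)):
            for _attempt in range(50):
                pos = int(rng.integers(0, len(seq) - width + 1))
                if all(pos + width <= s or pos >= e for s, e in occupied):
                    break
            else:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            instance = motif.pattern if strand == "+" else reverse_complement(motif.pattern)
            seq[pos : pos + width] = list(instance)
            occupied.append((pos, pos + width))
            records.append(
                {"gene_id": gene_id, "motif": motif.name, "position": pos, "strand": strand}
            )
    return "".join(seq), records


def generate_promoters_and_annotation(
    config: SyntheticConfig,
    gene_ids: Sequence[str],
    motif_target_genes: Sequence[str],
    term_target_genes: Sequence[str],
    all_gene_ids: Sequence[str] | None = None,
) -> SyntheticGenome:
    """Build a toy genome with promoters for ``gene_ids``, planting motifs
    into the promoters of ``motif_target_genes`` and enriched annotation terms
    onto ``term_target_genes``.

    ``all_gene_ids`` (default: ``gene_ids``) is the annotation universe.
    A ``truncate_fraction`` of genes is laid out near the contig edge so their
    promoter windows are clipped, exercising the truncation path.
    """
    rng = np.random.default_rng(config.seed + 1)
    gene_ids = list(gene_ids)
    motif_targets = set(motif_target_genes)
    plen = config.promoter_length

    contigs: dict[str, str] = {}
    gff_lines: list[str] = []
    planted_records: list[dict] = []
    truncated: set[str] = set()

    for c_start in range(0, len(gene_ids), _GENES_PER_CONTIG):
        contig_genes = gene_ids[c_start : c_start + _GENES_PER_CONTIG]
        contig_name = f"chr{c_start // _GENES_PER_CONTIG + 1}"
        parts: list[str] = []
        offset = 0
        for j, gene in enumerate(contig_genes):
            truncate = j == 0 and rng.random() < config.truncate_fraction * _GENES_PER_CONTIG
            # a truncated promoter needs the contig edge upstream, so the
            # truncated gene sits at the contig start on the + strand
            strand = "+" if truncate or rng.random() < 0.5 else "-"
            up_len = int(plen * 0.25) if truncate else plen
            if truncate:
                truncated.add(gene)
            promoter = _random_seq(rng, up_len)
            if gene in motif_targets:
                promoter, recs = _plant_motifs(
                    rng, promoter, gene, PLANTED_MOTIFS, config.motif_lambda
                )
                planted_records.extend(recs)
            cds = _random_seq(rng, _CDS_LEN)
            if strand == "+":
                # [promoter][CDS][spacer]
                cds_start = offset + up_len + 1  # 1-based
                cds_end = cds_start + _CDS_LEN - 1
                parts.append(promoter + cds + _random_seq(rng, _SPACER))
            else:
                # [spacer][CDS][revcomp(promoter)]
                cds_start = offset + _SPACER + 1
                cds_end = cds_start + _CDS_LEN - 1
                parts.append(_random_seq(rng, _SPACER) + cds + reverse_complement(promoter))
            offset += up_len + _CDS_LEN + _SPACER
            for ftype, fid in (("gene", gene), ("mRNA", f"{gene}.t1"), ("CDS", f"{gene}.cds")):
                parent = "" if ftype == "gene" else (
                    f";Parent={gene}" if ftype == "mRNA" else f";Parent={gene}.t1"
                )
                gff_lines.append(
                    f"{contig_name}\tsynthetic\t{ftype}\t{cds_start}\t{cds_end}\t.\t{strand}\t"
                    f"{'0' if ftype == 'CDS' else '.'}\tID={fid}{parent}"
                )
        contigs[contig_name] = "".join(parts)

    motifs = list(DEFAULT_MOTIFS)
    for m in PLANTED_MOTIFS:
        if m.name not in {x.name for x in motifs}:
            motifs.append(m)

    # annotation with planted enriched terms
    universe = list(all_gene_ids) if all_gene_ids is not None else list(gene_ids)
    term_targets = [g for g in term_target_genes if g in set(universe)]
    rows = []
    namespaces = ("biological_process", "cellular_component", "molecular_function")
    for i in range(config.n_background_terms):
        size = int(rng.integers(20, 80))
        members = rng.choice(universe, size=min(size, len(universe)), replace=False)
        for g in members:
            rows.append(
                {
                    "gene_id": g,
                    "term_id": f"SYN:{i:04d}",
                    "term_name": f"background process {i}",
                    "namespace": namespaces[i % 3],
                }
            )
    planted_terms = []
    for i in range(config.n_planted_terms):
        term_id = f"SYN:P{i:03d}"
        planted_terms.append(term_id)
        n_in = min(20, len(term_targets))
        members = list(rng.choice(term_targets, size=n_in, replace=False)) if n_in else []
        others = [g for g in universe if g not in set(members)]
        members += list(rng.choice(others, size=10, replace=False))
        for g in members:
            rows.append(
                {
                    "gene_id": g,
                    "term_id": term_id,
                    "term_name": f"planted process {i}",
                    "namespace": namespaces[i % 3],
                }
            )
    annotation = pd.DataFrame(rows).drop_duplicates(subset=["gene_id", "term_id"])

    return SyntheticGenome(
        contigs=contigs,
        gff_lines=gff_lines,
        motifs=motifs,
        planted_hits=pd.DataFrame(
            planted_records, columns=["gene_id", "motif", "position", "strand"]
        ),
        annotation=annotation,
        planted_terms=planted_terms,
        truncated_genes=frozenset(truncated),
    )
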