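"""Promoter extraction and cis-regulatory element (CRE) scanning.

Promoters are the (up to) 2-kb windows immediately upstream of the annotated
CDS start codon: on the + strand the ``length`` bases ending just before the
first CDS base; on the - strand the ``length`` bases immediately after the
last CDS base, reverse-complemented.  Contig-edge truncation is flagged, a
gene without a resolvable CDS is skipped with a warning.

Motifs are named IUPAC nucleotide patterns assigned to one of 11 functional
groups (common, tissue-specific, light-responsive, stress-related,
temperature-responsive, the five hormone-response classes, other).  Scanning
reports every position where the expanded pattern matches on the forward
strand and every position where its reverse complement matches (a - strand
hit); overlapping occurrences are all counted, and a palindromic pattern
matching both strands at one position counts twice unless
``collapse_palindromes`` is set.

Coordinates are 0-based half-open internally; file output is 1-based
inclusive.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import pandas as pd
import yaml

GROUPS = (
    "common",
    "tissue-specific",
    "light-responsive",
    "stress-related",
    "temperature-responsive",
    "MeJA-responsive",
    "ABA-responsive",
    "SA-responsive",
    "GA-responsive",
    "auxin-responsive",
    "other",
)

IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "[AG]",
    "Y": "[CT]",
    "S": "[CG]",
    "W": "[AT]",
    "K": "[GT]",
    "M": "[AC]",
    "B": "[CGT]",
    "D": "[AGT]",
    "H": "[ACT]",
    "V": "[ACG]",
    "N": "[ACGT]",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a (possibly IUPAC-degenerate) nucleotide string."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


def iupac_to_regex(pattern: str, motif_name: str = "") -> re.Pattern:
    try:
        body = "".join(IUPAC[c] for c in pattern.upper())
    except KeyError as exc:
        raise ValueError(
            f"invalid IUPAC letter {exc.args[0]!r} in motif {motif_name or pattern!r}"
        ) from None
    # lookahead so overlapping occurrences are all reported
    return re.compile(f"(?=({body}))")


@dataclass(frozen=True)
class Motif:
    """A named IUPAC promoter element with its functional group."""

    name: str
    pattern: str
    group: str

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError(f"motif {self.name!r} has an empty pattern")
        iupac_to_regex(self.pattern, self.name)
        if self.group not in GROUPS:
            raise ValueError(f"motif {self.name!r} has unknown group {self.group!r}; expected one of {GROUPS}")


# Representative fixture catalogue of literature-standard consensus elements.
# This is NOT a replica of any screening database; full inventories (e.g. the
# 116-element PlantCARE-style catalogue) are supplied as a user dictionary.
DEFAULT_MOTIFS: tuple[Motif, ...] = (
    Motif("TATA-box", "TATAAA", "common"),
    Motif("CAAT-box", "CCAAT", "common"),
    Motif("POLLEN1LELAT52", "AGAAA", "tissue-specific"),
    Motif("GTGANTG10", "GTGA", "tissue-specific"),
    Motif("Box4", "ATTAAT", "light-responsive"),
    Motif("GT1-motif", "GGTTAA", "light-responsive"),
    Motif("G-box", "CACGTG", "light-responsive"),
    Motif("ARE", "AAACCA", "stress-related"),
    Motif("STRE", "AGGGG", "stress-related"),
    Motif("MBS", "CAACTG", "stress-related"),
    Motif("TC-rich repeats", "ATTCTCTAAC", "stress-related"),
    Motif("LTR", "CCGAAA", "temperature-responsive"),
    Motif("HSE", "AGAAAATTCG", "temperature-responsive"),
    Motif("CGTCA-motif", "CGTCA", "MeJA-responsive"),
    Motif("TGACG-motif", "TGACG", "MeJA-responsive"),
    Motif("ABRE", "ACGTGGC", "ABA-responsive"),
    Motif("ABRE3a", "TACGTGTC", "ABA-responsive"),
    Motif("TCA-element", "CCATCTTTTT", "SA-responsive"),
    Motif("GARE-motif", "TCTGTTG", "GA-responsive"),
    Motif("P-box", "CCTTTTG", "GA-responsive"),
    Motif("TGA-element", "AACGAC", "auxin-responsive"),
    Motif("AuxRR-core", "GGTCCAT", "auxin-responsive"),
    Motif("O2-site", "GATGACATGG", "other"),
    Motif("circadian", "CAANNNNATC", "other"),
)


def load_motifs_yaml(path) -> list[Motif]:
    """Load a motif dictionary from YAML: a list of {name, pattern, group}."""
    with open(path) as fh:
        records = yaml.safe_load(fh)
    if not isinstance(records, list):
        raise ValueError("motif file must contain a list of {name, pattern, group} records")
    return [Motif(r["name"], r["pattern"], r["group"]) for r in records]


def write_motifs_yaml(motifs, path) -> None:
    records = [{"name": m.name, "pattern": m.pattern, "group": m.group} for m in motifs]
    with open(path, "w") as fh:
        yaml.safe_dump(records, fh, sort_keys=False)


@dataclass(frozen=True)
class Promoter:
    """Strand-corrected upstream sequence ending just before the start codon."""

    gene_id: str
    contig: str
    start: int  # 0-based half-open genomic interval
    end: int
    strand: str
    sequence: str
    truncated: bool

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"promoter {self.gene_id!r}: sequence length {len(self.sequence)} "
                f"!= interval length {self.end - self.start}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def extract_promoters(genome_fasta, gff3, length: int = 2000) -> list[Promoter]:
    """Extract promoters for every gene in a GFF3 against an indexed FASTA.

    The start codon is resolved from the gene's CDS features (minimum CDS
    start on +, maximum CDS end on -).  Windows overhanging the contig edge
    are clipped and flagged ``truncated``; genes with no CDS or a fully
    off-contig window are skipped with a warning.
    """
    import gffutils
    from pyfaidx import Fasta

    db = gffutils.create_db(
        str(gff3), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    fasta = Fasta(str(genome_fasta), as_raw=True, sequence_always_upper=True)
    promoters = []
    for gene in db.features_of_type("gene"):
        cds = list(db.children(gene, featuretype="CDS"))
        if not cds:
            warnings.warn(f"gene {gene.id!r} has no CDS feature; skipped")
            continue
        contig_len = len(fasta[gene.seqid])
        if gene.strand == "+":
            atg = min(c.start for c in cds)  # 1-based first CDS base
            end0 = atg - 1  # 0-based half-open end
            start0 = max(0, end0 - length)
        elif gene.strand == "-":
            atg = max(c.end for c in cds)
            start0 = atg  # 0-based start just past the CDS end
            end0 = min(contig_len, start0 + length)
        else:
            warnings.warn(f"gene {gene.id!r} has no strand; skipped")
            continue
        if end0 <= start0:
            warnings.warn(f"promoter of gene {gene.id!r} lies fully off the contig; skipped")
            continue
        seq = str(fasta[gene.seqid][start0:end0])
        if gene.strand == "-":
            seq = reverse_complement(seq)
        promoters.append(
            Promoter(
                gene_id=gene.id,
                contig=gene.seqid,
                start=start0,
                end=end0,
                strand=gene.strand,
                sequence=seq,
                truncated=(end0 - start0) < length,
            )
        )
    return promoters


def scan_motifs(
    promoters,
    motifs=DEFAULT_MOTIFS,
    strands: str = "both",
    collapse_palindromes: bool = False,
) -> pd.DataFrame:
    """Scan promoters for every motif occurrence on the requested strands.

    Returns a hit table with one row per (gene, motif, promoter offset,
    matched strand).  Offsets are 0-based positions within the promoter
    sequence.  With ``collapse_palindromes`` a +/- pair at the same offset for
    the same motif is reported once (as a + hit).
    """
    if strands not in ("both", "forward", "reverse"):
        raise ValueError("strands must be 'both', 'forward' or 'reverse'")
    rows = []
    compiled = []
    for m in motifs:
        fwd = iupac_to_regex(m.pattern, m.name)
        rev = iupac_to_regex(reverse_complement(m.pattern), m.name)
        compiled.append((m, fwd, rev))
    for prom in promoters:
        seq = prom.sequence.upper()
        for m, fwd, rev in compiled:
            hits = {}
            if strands in ("both", "forward"):
                for match in fwd.finditer(seq):
                    hits[(match.start(), "+")] = True
            if strands in ("both", "reverse"):
                for match in rev.finditer(seq):
                    key = (match.start(), "-")
                    if collapse_palindromes and (match.start(), "+") in hits:
                        continue
                    hits[key] = True
            for (pos, strand) in hits:
                rows.append(
                    {
                        "gene_id": prom.gene_id,
                        "motif": m.name,
                        "group": m.group,
                        "position": pos,
                        "strand": strand,
                    }
                )
    return pd.DataFrame(rows, columns=["gene_id", "motif", "group", "position", "strand"])


def group_frequencies(hits: pd.DataFrame, promoters) -> pd.Series:
    """Average motif sites per promoter, by functional group.

    ``promoters`` defines the denominator (every promoter counts, including
    those with zero hits); hits for genes outside the promoter set are
    ignored.
    """
    gene_ids = {p.gene_id for p in promoters}
    if not gene_ids:
        raise ValueError("promoter set is empty")
    counts = pd.Series(0.0, index=list(GROUPS))
    if len(hits):
        sub = hits[hits["gene_id"].isin(gene_ids)]
        per_group = sub.groupby("group").size()
        counts.loc[per_group.index] = per_group.to_numpy(dtype=float)
    return counts / len(gene_ids)


def write_hits_tsv(hits: pd.DataFrame, promoters, path) -> None:
    """Write a BED-like hit table (1-based inclusive promoter coordinates)."""
    by_gene = {p.gene_id: p for p in promoters}
    out = hits.copy()
    out["promoter_start_1based"] = out["position"] + 1
    out["contig"] = [by_gene[g].contig if g in by_gene else "." for g in out["gene_id"]]
    out.to_csv(path, sep="\t", index=False)
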