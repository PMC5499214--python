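"""Simplified functional classification of variants against a gene model.

Each SNP receives exactly one class from::

    intergenic, intronic, upstream, downstream, 5'-UTR, 3'-UTR,
    exonic, non-coding exonic, splicing, stop

When a position satisfies several definitions (e.g. overlapping genes),
the most specific annotation wins:

    splicing > stop > 5'-UTR > 3'-UTR > exonic / non-coding exonic
             > intronic > upstream > downstream > intergenic

Windows: upstream/downstream extend 5 kb from the gene ends (strand-aware:
"upstream" is 5' of the TSS); "splicing" means an intronic position within
2 bp of an exon/intron junction; "stop" is the last 3 coding base pairs.
All three are configurable — they are pragmatic defaults, not an attempt
to reproduce any particular annotator's internals.

Gene models are held in memory (coordinates 0-based half-open) and can be
read from a minimal GFF3 subset (gene / exon / CDS / UTR features with
ID / Parent attributes, one transcript per gene) or built directly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Gene",
    "GeneModel",
    "FUNCTIONAL_CLASSES",
    "classify_variant",
    "classify_variants",
    "class_composition",
    "read_gff3",
    "write_gff3",
]

FUNCTIONAL_CLASSES = (
    "splicing",
    "stop",
    "5'-UTR",
    "3'-UTR",
    "exonic",
    "non-coding exonic",
    "intronic",
    "upstream",
    "downstream",
    "intergenic",
)
_PRIORITY = {c: i for i, c in enumerate(FUNCTIONAL_CLASSES)}


@dataclass
class Gene:
    """One gene with a single transcript's exon/CDS structure.

    Coordinates are 0-based half-open; ``exons`` must be sorted,
    non-overlapping and contained in ``[start, end)``.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        prev_end = self.start
        for s, e in self.exons:
            if s < self.start or e > self.end or s >= e:
                raise ValueError(f"gene {self.gene_id}: exon ({s},{e}) outside gene span")
            if s < prev_end:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
            prev_end = e

    @property
    def coding(self) -> bool:
        return bool(self.cds)

    def stop_codon_span(self) -> tuple[int, int] | None:
        """The last 3 coding bp in transcription order, or None."""
        if not self.cds:
            return None
        total = sum(e - s for s, e in self.cds)
        if total < 3:
            return None
        if self.strand == "+":
            s, e = self.cds[-1]
            if e - s >= 3:
                return (e - 3, e)
            # stop codon split across CDS segments: fall back to last segment
            return (s, e)
        s, e = self.cds[0]
        if e - s >= 3:
            return (s, s + 3)
        return (s, e)


class GeneModel:
    """A collection of genes indexed by chromosome."""

    def __init__(self, genes: Iterable[Gene]):
        self.genes = list(genes)
        self._by_chrom: dict[str, list[Gene]] = {}
        for g in self.genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for glist in self._by_chrom.values():
            glist.sort(key=lambda g: g.start)

    def __len__(self) -> int:
        return len(self.genes)

    def genes_on(self, chrom: str) -> list[Gene]:
        return self._by_chrom.get(chrom, [])

    @property
    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)


def _classify_against_gene(
    p0: int,
    gene: Gene,
    window: int,
    splice_window: int,
) -> str | None:
    """Best class this gene can assign to 0-based position p0, or None."""
    if gene.start <= p0 < gene.end:
        in_exon = any(s <= p0 < e for s, e in gene.exons)
        if not in_exon:
            # splice site: intronic position close to an exon boundary
            for s, e in gene.exons:
                if 0 < s - p0 <= splice_window or 0 < p0 - (e - 1) <= splice_window:
                    return "splicing"
            return "intronic"
        stop = gene.stop_codon_span()
        if stop and stop[0] <= p0 < stop[1]:
            return "stop"
        if any(s <= p0 < e for s, e in gene.utr5):
            return "5'-UTR"
        if any(s <= p0 < e for s, e in gene.utr3):
            return "3'-UTR"
        return "exonic" if gene.coding else "non-coding exonic"
    # flanks, strand-aware
    if gene.strand == "+":
        if gene.start - window <= p0 < gene.start:
            return "upstream"
        if gene.end <= p0 < gene.end + window:
            return "downstream"
    else:
        if gene.end <= p0 < gene.end + window:
            return "upstream"
        if gene.start - window <= p0 < gene.start:
            return "downstream"
    return None


def classify_variant(
    chrom: str,
    pos: int,
    model: GeneModel,
    window: int = 5000,
    splice_window: int = 2,
) -> str:
    """Functional class of a SNP at a 1-based position; always returns one
    class ("intergenic" when nothing applies, including unknown
    chromosomes)."""
    if pos < 1:
        raise ValueError(f"SNP position {pos} < 1; positions are 1-based")
    p0 = pos - 1
    best: str | None = None
    for gene in model.genes_on(chrom):
        if gene.start - window > p0:
            break
        if gene.end + window <= p0:
            continue
        cls = _classify_against_gene(p0, gene, window, splice_window)
        if cls is not None and (best is None or _PRIORITY[cls] < _PRIORITY[best]):
            best = cls
    return best if best is not None else "intergenic"


def classify_variants(
    chroms: Sequence[str],
    positions: Sequence[int],
    model: GeneModel,
    window: int = 5000,
    splice_window: int = 2,
) -> list[str]:
    return [
        classify_variant(c, int(p), model, window, splice_window)
        for c, p in zip(chroms, positions)
    ]


def class_composition(classes: Sequence[str]) -> dict[str, Fraction]:
    """Proportion of SNPs per functional class, as exact fractions.

    Every known class appears in the output (0 when absent); proportions
    sum to exactly 1.
    """
    classes = list(classes)
    if not classes:
        raise ValueError("class_composition needs at least one classified SNP")
    unknown = set(classes) - set(FUNCTIONAL_CLASSES)
    if unknown:
        raise ValueError(f"unknown functional class(es): {sorted(unknown)}")
    counts = Counter(classes)
    total = len(classes)
    return {c: Fraction(counts.get(c, 0), total) for c in FUNCTIONAL_CLASSES}


def composition_table(classes: Sequence[str]) -> pd.DataFrame:
    comp = class_composition(classes)
    return pd.DataFrame(
        {
            "class": list(comp),
            "count": [int(f * len(list(classes))) for f in comp.values()],
            "proportion": [float(f) for f in comp.values()],
        }
    )


# ---------------------------------------------------------------------------
# Minimal GFF3 subset I/O

_FEATURE_KEYS = {
    "exon": "exons",
    "CDS": "cds",
    "five_prime_UTR": "utr5",
    "three_prime_UTR": "utr3",
}


def _attributes(col: str) -> dict[str, str]:
    out = {}
    for item in col.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff3(path: str | Path) -> GeneModel:
    """Read a minimal GFF3 subset: gene features with ID, child exon / CDS /
    UTR features with Parent. GFF3 is 1-based inclusive; converted to
    0-based half-open internally."""
    path = Path(path)
    genes: dict[str, Gene] = {}
    children: dict[str, dict[str, list[tuple[int, int]]]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = fields
            span = (int(start) - 1, int(end))
            adict = _attributes(attrs)
            if ftype == "gene":
                gid = adict.get("ID")
                if gid is None:
                    raise ValueError(f"{path}:{lineno}: gene feature without ID")
                genes[gid] = Gene(gid, chrom, strand, span[0], span[1], exons=[])
            elif ftype in _FEATURE_KEYS:
                parent = adict.get("Parent")
                if parent is None:
                    raise ValueError(f"{path}:{lineno}: {ftype} feature without Parent")
                children.setdefault(parent, {}).setdefault(_FEATURE_KEYS[ftype], []).append(span)
    out = []
    for gid, gene in genes.items():
        kid = children.get(gid, {})
        out.append(
            Gene(
                gid,
                gene.chrom,
                gene.strand,
                gene.start,
                gene.end,
                exons=kid.get("exons", [(gene.start, gene.end)]),
                cds=kid.get("cds", []),
                utr5=kid.get("utr5", []),
                utr3=kid.get("utr3", []),
            )
        )
    return GeneModel(out)


def write_gff3(model: GeneModel, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for gene in sorted(model.genes, key=lambda g: (g.chrom, g.start)):
            fh.write(
                f"{gene.chrom}\tenhancerenrich\tgene\t{gene.start + 1}\t{gene.end}\t.\t"
                f"{gene.strand}\t.\tID={gene.gene_id}\n"
            )
            rows = [("exon", span) for span in gene.exons]
            rows += [("CDS", span) for span in gene.cds]
            rows += [("five_prime_UTR", span) for span in gene.utr5]
            rows += [("three_prime_UTR", span) for span in gene.utr3]
            for ftype, (s, e) in rows:
                fh.write(
                    f"{gene.chrom}\tenhancerenrich\t{ftype}\t{s + 1}\t{e}\t.\t"
                    f"{gene.strand}\t.\tParent={gene.gene_id}\n"
                )
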