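"""Strand-aware extraction of proximal promoter windows from a genome.

The promoter window is [-1000, +100] relative to the TSS by biological
convention: there is no position 0, so the window covers 1000 upstream and
100 downstream bases, 1100 nt in total.  Sequences are emitted 5'->3' on
the transcribed strand; soft-masked repeats (lowercase in the genome FASTA)
are carried through as lowercase and only hardened to N in `masked_view`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio.Seq import Seq
from pyfaidx import Fasta

DEFAULT_WINDOW = (-1000, 100)


@dataclass(frozen=True)
class TSSRecord:
    chrom: str
    position: int  # 1-based TSS coordinate
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"{self.gene_id}: TSS position must be >= 1")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")


@dataclass
class PromoterSeq:
    """TSS-oriented promoter sequence with per-base repeat-mask flags."""

    gene_id: str
    sequence: str  # soft-masked: repeats lowercase
    chrom: str
    tss: int
    strand: str
    window: tuple[int, int] = DEFAULT_WINDOW
    clipped: bool = False

    @property
    def mask_flags(self) -> list[bool]:
        return [c.islower() for c in self.sequence]

    def __len__(self) -> int:
        return len(self.sequence)


def read_tss(bed_path, unique: bool = False) -> list[TSSRecord]:
    """Read TSSs from a BED6 file (0-based half-open intervals).

    The TSS is the 5' end of the feature: chromStart+1 on the + strand and
    chromEnd (1-based) on the - strand.  With ``unique=True`` a duplicated
    gene id is an error (background promoter sets must be one-per-gene).
    """
    records: list[TSSRecord] = []
    seen: set[str] = set()
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{bed_path}:{lineno}: expected BED6, got {len(parts)} fields")
            chrom, start, end, name, _score, strand = parts[:6]
            if strand not in "+-":
                raise ValueError(f"{bed_path}:{lineno}: malformed strand {strand!r}")
            if unique and name in seen:
                raise ValueError(f"{bed_path}:{lineno}: duplicate gene id {name!r}")
            seen.add(name)
            tss = int(start) + 1 if strand == "+" else int(end)
            records.append(TSSRecord(chrom, tss, strand, name))
    return records


def load_genome(fasta_path) -> dict[str, str]:
    """Load a (small) genome FASTA preserving case (soft masks)."""
    fa = Fasta(str(fasta_path), rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def extract_promoter(
    genome: dict[str, str],
    rec: TSSRecord,
    window: tuple[int, int] = DEFAULT_WINDOW,
) -> PromoterSeq:
    """Extract the promoter window around a TSS, strand-aware.

    With the default window, + strand yields genomic [TSS-1000, TSS+99]
    (1-based inclusive) and - strand the reverse complement of
    [TSS-99, TSS+1000]; both are 1100 nt.  A window running past a contig
    end is clipped and flagged, never silently padded.
    """
    up, down = window
    if up >= 0 or down <= 0:
        raise ValueError(f"window must span upstream and downstream, got {window}")
    if rec.chrom not in genome:
        raise KeyError(f"{rec.gene_id}: contig {rec.chrom!r} not in genome")
    contig = genome[rec.chrom]
    # no position 0: -1 abuts +1, so a window (-1000, +100) is 1100 nt
    if rec.strand == "+":
        lo = rec.position + up  # 1-based
        hi = rec.position + down - 1
    else:
        lo = rec.position - down + 1
        hi = rec.position - up
    clipped = lo < 1 or hi > len(contig)
    lo_c, hi_c = max(lo, 1), min(hi, len(contig))
    seq = contig[lo_c - 1 : hi_c]
    if rec.strand == "-":
        seq = reverse_complement(seq)
    return PromoterSeq(
        gene_id=rec.gene_id,
        sequence=seq,
        chrom=rec.chrom,
        tss=rec.position,
        strand=rec.strand,
        window=window,
        clipped=clipped,
    )


def reverse_complement(seq: str) -> str:
    """Case-preserving reverse complement (soft masks stay lowercase)."""
    return str(Seq(seq).reverse_complement())


def masked_view(p: PromoterSeq) -> tuple[str, str]:
    """(hard-masked, unmasked) uppercase views of a promoter.

    The hard-masked view replaces repeat-flagged (lowercase) bases by N;
    the unmasked view simply uppercases everything.
    """
    masked = "".join("N" if c.islower() else c for c in p.sequence)
    return masked, p.sequence.upper()


def build_background(
    records: list[TSSRecord],
    genome: dict[str, str],
    window: tuple[int, int] = DEFAULT_WINDOW,
    exclude: set[str] | None = None,
) -> dict[str, PromoterSeq]:
    """One promoter per unique gene id; duplicates dropped with a warning.

    Genes listed in ``exclude`` (e.g. cluster genes, for de novo discovery
    backgrounds) are removed; by default cluster genes stay in the
    background.
    """
    out: dict[str, PromoterSeq] = {}
    for rec in records:
        if exclude and rec.gene_id in exclude:
            continue
        if rec.gene_id in out:
            warnings.warn(f"duplicate gene id {rec.gene_id!r} in background; keeping first")
            continue
        out[rec.gene_id] = extract_promoter(genome, rec, window)
    return out


def write_promoters_fasta(promoters: dict[str, PromoterSeq], path) -> None:
    """FASTA with headers `>geneid|chrom|tss|strand|clipflag`."""
    with open(path, "w") as fh:
        for gid in promoters:
            p = promoters[gid]
            flag = "clipped" if p.clipped else "full"
            fh.write(f">{p.gene_id}|{p.chrom}|{p.tss}|{p.strand}|{flag}\n")
            for i in range(0, len(p.sequence), 70):
                fh.write(p.sequence[i : i + 70] + "\n")


def read_promoters_fasta(path) -> dict[str, str]:
    """Read any promoter FASTA to an id -> sequence map (case preserved).

    Headers written by `write_promoters_fasta` keep only the gene id part.
    """
    out: dict[str, str] = {}
    gid = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if gid is not None:
                    out[gid] = "".join(chunks)
                gid = line[1:].split("|")[0].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if gid is not None:
        out[gid] = "".join(chunks)
    return out
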