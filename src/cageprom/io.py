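"""Readers/writers for external formats and the internal coordinate convention.

All internal coordinates are 0-based half-open on both strands ([start, end),
matching BED). GTF input (1-based inclusive) is converted on read; this is the
only conversion site. A minus-strand "TSS position" is ``end - 1`` of the
5'-most exon.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

STRANDS = ("+", "-", ".")
BASES = "ACGT"


class ParseError(ValueError):
    """Malformed record in an external file."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def gap_to(self, other: "GenomicInterval") -> int:
        """bp gap between two intervals; overlapping or touching gives 0."""
        if self.chrom != other.chrom:
            raise ValueError("intervals on different chromosomes")
        return max(0, max(self.start, other.start) - min(self.end, other.end))


@dataclass
class Transcript:
    transcript_id: str
    tss: int
    exons: list[tuple[int, int]]
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    start_codon: int | None = None  # genomic position of the codon's first base

    @property
    def coding(self) -> bool:
        return bool(self.cds)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)


@dataclass
class PWMRecord:
    """A position count matrix (rows = positions, columns = A,C,G,T)."""

    matrix_id: str
    tf_name: str
    counts: np.ndarray  # shape (length, 4), nonnegative

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must have shape (length, 4)")
        if self.counts.shape[0] < 4:
            raise ValueError("matrix must have at least 4 positions")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if np.any(self.counts.sum(axis=1) == 0):
            raise ValueError("per-position counts must not all be zero")

    @property
    def length(self) -> int:
        return self.counts.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=1))


# ---------------------------------------------------------------------------
# BED

def read_bed(path) -> list[GenomicInterval]:
    """Read BED (>=3 columns); strand from column 6 when present.

    ``track``/``browser`` header lines and blank lines are skipped.  BED's
    native 0-based half-open coordinates are kept unchanged.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from None
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            out.append(GenomicInterval(fields[0], start, end, strand, name))
    return out


def write_bed(intervals, path, scores=None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            score = 0 if scores is None else scores[i]
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# GTF

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _subtract(intervals, others):
    """Subtract a set of intervals from another (both lists of (start, end))."""
    result = []
    for a, b in intervals:
        pieces = [(a, b)]
        for c, d in others:
            nxt = []
            for s, e in pieces:
                if d <= s or c >= e:
                    nxt.append((s, e))
                else:
                    if s < c:
                        nxt.append((s, c))
                    if d < e:
                        nxt.append((d, e))
            pieces = nxt
        result.extend(pieces)
    return sorted(result)


def read_gtf(path) -> list[GeneModel]:
    """Read gene models from GTF (1-based inclusive -> internal half-open).

    Uses exon/CDS/five_prime_utr/three_prime_utr/start_codon features.  When
    UTR features are absent they are derived as exonic sequence outside the
    CDS span (5' vs 3' by strand).  The TSS is the 5'-most exon boundary in
    strand orientation.  Transcripts without exons are skipped with a warning.
    """
    tx_feats: dict[tuple[str, str], dict] = {}
    order: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ParseError(f"{path}:{lineno}: fewer than 9 columns")
            feat = f[2]
            if feat not in (
                "exon", "CDS", "five_prime_utr", "three_prime_utr", "start_codon",
            ):
                continue
            try:
                start, end = int(f[3]) - 1, int(f[4])  # to 0-based half-open
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            attrs = dict(_ATTR_RE.findall(f[8]))
            gid, tid = attrs.get("gene_id"), attrs.get("transcript_id")
            if gid is None or tid is None:
                raise ParseError(f"{path}:{lineno}: missing gene_id/transcript_id")
            key = (gid, tid)
            if key not in tx_feats:
                tx_feats[key] = {
                    "chrom": f[0], "strand": f[6], "exon": [], "CDS": [],
                    "five_prime_utr": [], "three_prime_utr": [], "start_codon": [],
                }
                order.append(key)
            tx_feats[key][feat].append((start, end))

    genes: dict[str, GeneModel] = {}
    for gid, tid in order:
        d = tx_feats[(gid, tid)]
        strand = d["strand"]
        exons = sorted(d["exon"])
        if not exons:
            warnings.warn(f"transcript {tid} has no exons; skipped")
            continue
        tss = exons[0][0] if strand == "+" else exons[-1][1] - 1
        cds = sorted(d["CDS"])
        utr5, utr3 = sorted(d["five_prime_utr"]), sorted(d["three_prime_utr"])
        if cds and not (utr5 or utr3):
            cds_lo, cds_hi = cds[0][0], cds[-1][1]
            before = _subtract(exons, [(cds_lo, exons[-1][1])])
            after = _subtract(exons, [(exons[0][0], cds_hi)])
            utr5, utr3 = (before, after) if strand == "+" else (after, before)
        start_codon = None
        if d["start_codon"]:
            sc = sorted(d["start_codon"])
            start_codon = sc[0][0] if strand == "+" else sc[-1][1] - 1
        elif cds:
            start_codon = cds[0][0] if strand == "+" else cds[-1][1] - 1
        tx = Transcript(tid, tss, exons, utr5, utr3, cds, start_codon)
        if gid not in genes:
            genes[gid] = GeneModel(gid, d["chrom"], strand)
        genes[gid].transcripts.append(tx)
    return list(genes.values())


def write_gtf(genes: list[GeneModel], path) -> None:
    """Write gene models as GTF (internal half-open -> 1-based inclusive)."""
    with open(path, "w") as fh:
        for g in genes:
            attr = lambda t: f'gene_id "{g.gene_id}"; transcript_id "{t}";'
            for tx in g.transcripts:
                rows = [("exon", s, e) for s, e in tx.exons]
                rows += [("CDS", s, e) for s, e in tx.cds]
                rows += [("five_prime_utr", s, e) for s, e in tx.utr5]
                rows += [("three_prime_utr", s, e) for s, e in tx.utr3]
                if tx.start_codon is not None:
                    if g.strand == "+":
                        rows.append(("start_codon", tx.start_codon, tx.start_codon + 3))
                    else:
                        rows.append(("start_codon", tx.start_codon - 2, tx.start_codon + 1))
                for feat, s, e in rows:
                    fh.write(
                        f"{g.chrom}\tcageprom\t{feat}\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                        f"{attr(tx.transcript_id)}\n"
                    )


# ---------------------------------------------------------------------------
# FASTA (via Biopython)

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# TRANSFAC matrices

_ROW_RE = re.compile(r"^\d\d")


def read_transfac(path) -> list[PWMRecord]:
    """Read PWMs from TRANSFAC-format text.

    Minimal dialect: blocks delimited by ``//``; ``ID``/``AC`` give the matrix
    id, ``NA`` the factor name; lines beginning with two digits are matrix
    rows of 4 counts (followed optionally by a consensus letter); all other
    tags (XX, CC, P0, ...) are ignored.
    """
    records: list[PWMRecord] = []
    matrix_id = tf_name = None
    rows: list[list[float]] = []

    def flush(lineno):
        nonlocal matrix_id, tf_name, rows
        if rows:
            rec = PWMRecord(matrix_id or "", tf_name or "", np.array(rows))
            records.append(rec)
        elif matrix_id or tf_name:
            warnings.warn(f"block ending at line {lineno} has no matrix rows; skipped")
        matrix_id = tf_name = None
        rows = []

    with open(path) as fh:
        lineno = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("//"):
                flush(lineno)
                continue
            if line.startswith(("ID", "AC")) and matrix_id is None:
                parts = line.split()
                matrix_id = parts[1] if len(parts) > 1 else None
            elif line.startswith("ID"):
                parts = line.split()
                matrix_id = parts[1] if len(parts) > 1 else matrix_id
            elif line.startswith("NA"):
                parts = line.split(None, 1)
                tf_name = parts[1].strip() if len(parts) > 1 else None
            elif _ROW_RE.match(line):
                fields = line.split()[1:]
                vals = []
                for tok in fields:
                    try:
                        vals.append(float(tok))
                    except ValueError:
                        break
                if len(vals) != 4:
                    raise ParseError(
                        f"{path}:{lineno}: matrix row must have 4 numeric fields, "
                        f"got {len(vals)}"
                    )
                rows.append(vals)
        flush(lineno)
    return records


def write_transfac(pwms: list[PWMRecord], path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f"ID {pwm.matrix_id}\nNA {pwm.tf_name}\nP0 A C G T\n")
            for j, row in enumerate(pwm.counts, start=1):
                vals = " ".join(f"{v:g}" for v in row)
                cons = BASES[int(np.argmax(row))]
                fh.write(f"{j:02d} {vals} {cons}\n")
            fh.write("//\n")


# ---------------------------------------------------------------------------
# Tabular stage outputs and CAGE tag tables

def write_table(df: pd.DataFrame, path) -> None:
    """Write a stage-output table as TSV (header, >=10 significant digits)."""
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_tag_table(path) -> pd.DataFrame:
    """Read a CAGE tag table: chrom, pos, strand, then one count column per sample."""
    df = pd.read_csv(path, sep="\t")
    required = ["chrom", "pos", "strand"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    return df
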