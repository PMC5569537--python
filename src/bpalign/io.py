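"""Readers and writers: FASTA, annotation tables, gene orders, alignments.

Alignments are serialized either as Stockholm 1.0 (machine readable, with a
``#=GC region`` line carrying the per-column region tags and ``#=GF SC`` /
``#=GF OV`` metadata) or as a fixed-width annotated text rendering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .breakpoints import GeneAnnotation
from .engine import TAG_CHAR, TriAlignment
from .measure import BreakpointGeometry
from .scoring import GAP, IUPAC_EXTRA, LETTERS, NucSeq

log = logging.getLogger("bpalign")

_TEXT_WIDTH = 60


@dataclass(frozen=True)
class AlignmentDocument:
    """A serialized three-row alignment: gapped rows, region tags, metadata."""

    names: tuple[str, str, str]
    rows: tuple[str, str, str]
    region: str
    score: float
    signed_overlap: int

    def __post_init__(self) -> None:
        n = {len(r) for r in self.rows} | {len(self.region)}
        if len(n) != 1:
            raise ValueError("alignment rows and region line must have equal length")

    @classmethod
    def from_alignment(
        cls, aln: TriAlignment, geometry: BreakpointGeometry
    ) -> "AlignmentDocument":
        return cls(
            names=(aln.F.id or "F", aln.L.id or "L", aln.R.id or "R"),
            rows=aln.gapped_rows(),
            region=aln.region_string(),
            score=aln.score,
            signed_overlap=geometry.signed_value,
        )


# ---------------------------------------------------------------------------
# FASTA


def normalize_residues(seq: str, ident: str = "?") -> str:
    """Uppercase and map IUPAC ambiguity codes to N (with a logged warning)."""
    s = seq.upper().replace(".", GAP)
    extra = set(s) & IUPAC_EXTRA
    if extra:
        log.warning(
            "sequence %s: IUPAC ambiguity codes %s normalized to N",
            ident,
            "".join(sorted(extra)),
        )
        s = "".join("N" if c in IUPAC_EXTRA else c for c in s)
    bad = set(s) - set(LETTERS) - {GAP}
    if bad:
        raise ValueError(f"sequence {ident}: unsupported symbols {sorted(bad)}")
    return s


def read_fasta(path: str | Path) -> list[NucSeq]:
    """Read a FASTA file into normalized NucSeq records (file order kept)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate record identifiers")
    return [
        NucSeq(r.id, normalize_residues(str(r.seq), r.id).replace(GAP, ""))
        for r in records
    ]


def write_fasta(seqs: list[NucSeq], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for off in range(0, len(s.seq), 70):
                fh.write(s.seq[off : off + 70] + "\n")


# ---------------------------------------------------------------------------
# annotations and gene orders


def read_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Read a gene annotation table.

    Accepts a simple 1-based inclusive TSV (gene, start, end, strand) or
    BED (0-based half-open, detected by the .bed suffix and converted at
    this boundary).
    """
    path = Path(path)
    is_bed = path.suffix.lower() == ".bed"
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if is_bed:
                if len(parts) < 4:
                    raise ValueError(f"{path}: BED needs chrom,start,end,name")
                _, start, end, gene = parts[:4]
                strand = parts[5] if len(parts) > 5 else "+"
                out.append(GeneAnnotation(gene, int(start) + 1, int(end), strand))
            else:
                if len(parts) < 4:
                    raise ValueError(f"{path}: TSV needs gene,start,end,strand")
                gene, start, end, strand = parts[:4]
                out.append(GeneAnnotation(gene, int(start), int(end), strand))
    if not out:
        raise ValueError(f"{path}: no annotations found")
    return out


def read_gene_order(path: str | Path) -> list[str]:
    """Read a signed gene order: whitespace-separated tokens, '#' comments."""
    tokens: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0]
            tokens.extend(line.split())
    if not tokens:
        raise ValueError(f"{path}: no gene tokens found")
    return tokens


# ---------------------------------------------------------------------------
# Stockholm


def write_stockholm(doc: AlignmentDocument, path: str | Path) -> None:
    """Write one alignment as Stockholm 1.0."""
    width = max(len(n) for n in doc.names + ("#=GC region",)) + 2
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        fh.write(f"#=GF SC {doc.score:g}\n")
        fh.write(f"#=GF OV {doc.signed_overlap:d}\n")
        for name, row in zip(doc.names, doc.rows):
            fh.write(f"{name:<{width}}{row}\n")
        fh.write(f"{'#=GC region':<{width}}{doc.region}\n")
        fh.write("//\n")


def read_stockholm(path: str | Path) -> AlignmentDocument:
    """Read one alignment written by :func:`write_stockholm`."""
    names: list[str] = []
    rows: list[str] = []
    region = ""
    score = 0.0
    overlap = 0
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# STOCKHOLM"):
            raise ValueError(f"{path}: not a Stockholm file")
        for line in fh:
            line = line.rstrip("\n")
            if not line or line == "//":
                continue
            if line.startswith("#=GF SC"):
                score = float(line.split()[2])
            elif line.startswith("#=GF OV"):
                overlap = int(line.split()[2])
            elif line.startswith("#=GC region"):
                region = line.split()[2]
            elif line.startswith("#"):
                continue
            else:
                name, row = line.split()
                names.append(name)
                rows.append(row)
    if len(names) != 3:
        raise ValueError(f"{path}: expected exactly three sequence rows")
    return AlignmentDocument(
        names=tuple(names), rows=tuple(rows), region=region,
        score=score, signed_overlap=overlap,
    )


# ---------------------------------------------------------------------------
# text rendering


def write_text_alignment(doc: AlignmentDocument, path: str | Path) -> None:
    """Fixed-width human-readable rendering, 60 columns per block.

    The annotation line repeats the per-column region tag characters
    (L = F-L region, O = three-way overlap region, R = F-R region,
    f/l/r = unaligned free stretches).
    """
    width = max(len(n) for n in doc.names + ("region",)) + 2
    total = len(doc.region)
    with open(path, "w") as fh:
        fh.write(
            f"# score {doc.score:g}  signed_overlap {doc.signed_overlap:d}\n"
        )
        for off in range(0, total, _TEXT_WIDTH):
            hi = min(off + _TEXT_WIDTH, total)
            for name, row in zip(doc.names, doc.rows):
                fh.write(f"{name:<{width}}{row[off:hi]}\n")
            fh.write(f"{'region':<{width}}{doc.region[off:hi]}\n")
            if hi < total:
                fh.write("\n")
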