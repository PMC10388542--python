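"""Reading, writing and canonicalizing circular organelle genomes.

Chloroplast genomes are circular molecules conventionally linearized in the
order LSC - IRb - SSC - IRa.  This module parses FASTA / GenBank / GFF3 into
:class:`CircularGenome`, writes the same formats back, and rotates (and, if
needed, reverse-complements) a genome into that canonical linear order so
coordinates are comparable across genomes.

Internal coordinates are 0-based half-open throughout; 1-based coordinates
appear only in emitted VCF/GFF3 files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FEATURE_KINDS = ("gene", "tRNA", "rRNA", "other")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AnnotationFeature:
    """A named feature on the canonical linearization.

    A feature wrapping the circular origin is stored as two sub-intervals,
    i.e. two ``AnnotationFeature`` entries sharing the same ``name``.
    """

    name: str
    kind: str  # one of FEATURE_KINDS
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.name!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in "+-":
            raise ValueError(f"feature {self.name!r}: strand must be '+' or '-'")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass
class CircularGenome:
    """A circular DNA sequence with optional annotation features."""

    id: str
    sequence: str
    circular: bool = True
    features: list[AnnotationFeature] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome {self.id!r}: empty sequence")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise ValueError(
                f"genome {self.id!r}: sequence contains non-ACGTN symbols {sorted(bad)}"
            )
        for f in self.features:
            if f.end > len(self.sequence):
                raise ValueError(
                    f"feature {f.name!r} extends past genome end "
                    f"({f.end} > {len(self.sequence)})"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def subseq(self, start: int, end: int) -> str:
        """Sequence of [start, end); indices taken modulo length if circular."""
        n = len(self.sequence)
        if 0 <= start <= end <= n:
            return self.sequence[start:end]
        if not self.circular:
            raise IndexError(f"interval [{start}, {end}) outside linear genome")
        start %= n
        length = end - start if end >= start else (end % n) - start
        if length < 0:
            length += n
        doubled = self.sequence + self.sequence
        return doubled[start : start + length]

    def genes(self) -> list[AnnotationFeature]:
        return [f for f in self.features if f.kind == "gene"]


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def _clean_seq(raw: str, where: str) -> str:
    seq = raw.upper().replace("U", "T")
    if not seq:
        raise ValueError(f"{where}: empty sequence")
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(f"{where}: unsupported symbols {sorted(bad)}")
    return seq


def _kind_of(ftype: str) -> str | None:
    if ftype == "gene":
        return "gene"
    if ftype == "tRNA":
        return "tRNA"
    if ftype == "rRNA":
        return "rRNA"
    if ftype in ("CDS", "exon", "intron", "misc_feature", "repeat_region"):
        return "other"
    return None


def _features_from_record(record: SeqRecord) -> list[AnnotationFeature]:
    feats: list[AnnotationFeature] = []
    n = len(record.seq)
    for sf in record.features:
        kind = _kind_of(sf.type)
        if kind is None:
            continue
        name = (
            sf.qualifiers.get("gene", [None])[0]
            or sf.qualifiers.get("locus_tag", [None])[0]
            or sf.type
        )
        strand = "-" if sf.location.strand == -1 else "+"
        for part in sf.location.parts:
            start, end = int(part.start), int(part.end)
            if start < end <= n:
                feats.append(AnnotationFeature(name, kind, start, end, strand))
    feats.sort(key=lambda f: (f.start, f.end, f.name))
    return feats


def infer_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext in (".gb", ".gbk", ".gbff", ".genbank"):
        return "genbank"
    return "fasta"


def read_genome(
    path: str, format: str | None = None, circular: bool = True
) -> CircularGenome:
    """Read one genome record from a FASTA or GenBank file.

    GenBank features of type gene/tRNA/rRNA are carried over; FASTA files are
    assumed circular unless ``circular=False``.
    """
    fmt = format or infer_format(path)
    if fmt not in ("fasta", "genbank"):
        raise ValueError(f"unsupported format {fmt!r}")
    try:
        records = list(SeqIO.parse(path, fmt))
    except Exception as exc:  # Biopython raises assorted parse errors
        raise ValueError(f"cannot parse {path} as {fmt}: {exc}") from exc
    if not records:
        raise ValueError(f"{path}: no {fmt} records found")
    record = records[0]
    seq = _clean_seq(str(record.seq), path)
    feats = _features_from_record(record) if fmt == "genbank" else []
    if fmt == "genbank":
        topology = record.annotations.get("topology", "circular")
        circular = topology != "linear"
    return CircularGenome(
        id=record.id, sequence=seq, circular=circular, features=feats, source=path
    )


def read_gff3(path: str) -> list[AnnotationFeature]:
    """Parse a minimal GFF3 file into annotation features (gene/tRNA/rRNA/other)."""
    feats: list[AnnotationFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            _, _, ftype, start, end, _, strand, _, attrs = cols
            kind = _kind_of(ftype)
            if kind is None:
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            name = attr.get("Name") or attr.get("gene") or attr.get("ID") or ftype
            feats.append(
                AnnotationFeature(
                    name, kind, int(start) - 1, int(end), strand if strand in "+-" else "+"
                )
            )
    feats.sort(key=lambda f: (f.start, f.end, f.name))
    return feats


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def write_fasta(genome: CircularGenome, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.id}\n")
        for i in range(0, len(genome.sequence), width):
            fh.write(genome.sequence[i : i + width] + "\n")


def write_gff3(genome: CircularGenome, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome)}\n")
        for i, f in enumerate(genome.features, 1):
            fh.write(
                "\t".join(
                    [
                        genome.id,
                        "chlorotype",
                        f.kind if f.kind != "other" else "misc_feature",
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        f"ID={f.kind}-{i};Name={f.name}",
                    ]
                )
                + "\n"
            )


def write_genbank(genome: CircularGenome, path: str) -> None:
    """Write a minimal GenBank flat file (used for round-trip fixtures)."""
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.id,
        name=genome.id[:16],
        description="",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.circular else "linear",
        },
    )
    for f in genome.features:
        record.features.append(
            SeqFeature(
                FeatureLocation(f.start, f.end, strand=1 if f.strand == "+" else -1),
                type=f.kind if f.kind != "other" else "misc_feature",
                qualifiers={"gene": [f.name]},
            )
        )
    SeqIO.write(record, path, "genbank")


# ---------------------------------------------------------------------------
# Canonical rotation
# ---------------------------------------------------------------------------


def _remap_rotation(
    feats: list[AnnotationFeature], offset: int, n: int
) -> list[AnnotationFeature]:
    out: list[AnnotationFeature] = []
    for f in feats:
        start = (f.start - offset) % n
        end = start + len(f)
        if end <= n:
            out.append(replace(f, start=start, end=end))
        else:  # wraps the new origin: store as two sub-intervals
            out.append(replace(f, start=start, end=n))
            out.append(replace(f, start=0, end=end - n))
    out.sort(key=lambda f: (f.start, f.end, f.name))
    return out


def _remap_revcomp(
    feats: list[AnnotationFeature], n: int
) -> list[AnnotationFeature]:
    out = [
        replace(f, start=n - f.end, end=n - f.start, strand="-" if f.strand == "+" else "+")
        for f in feats
    ]
    out.sort(key=lambda f: (f.start, f.end, f.name))
    return out


def canonical_rotation(genome: CircularGenome, structure) -> CircularGenome:
    """Rotate (and reverse-complement if needed) to LSC-IRb-SSC-IRa order.

    Position 0 of the result is the first base of the LSC.  Both strands give
    a valid LSC-IR-SSC-IR order, so the strand is fixed deterministically by
    choosing the lexicographically smaller of the two candidate
    linearizations; this makes canonicalization idempotent and invariant to
    reverse-complementing the input.

    ``structure`` is a :class:`~chlorotype.quadripartite.QuadripartiteStructure`
    computed on this genome.
    """
    n = len(genome)
    if structure.genome_length != n:
        raise ValueError(
            f"structure computed on a genome of length {structure.genome_length}, "
            f"got {n}"
        )
    lsc_start = structure.lsc[0] % n

    fwd_seq = genome.subseq(lsc_start, lsc_start + n)
    fwd_feats = _remap_rotation(genome.features, lsc_start, n)

    # Reverse-complement candidate: LSC maps to [n - end, n - start) on the
    # other strand; rotate that strand so its LSC starts at 0.
    rc = revcomp(genome.sequence)
    rc_lsc_start = (n - structure.lsc[1]) % n
    rc_doubled = rc + rc
    rev_seq = rc_doubled[rc_lsc_start : rc_lsc_start + n]
    rev_feats = _remap_rotation(_remap_revcomp(genome.features, n), rc_lsc_start, n)

    if rev_seq < fwd_seq:
        seq, feats = rev_seq, rev_feats
    else:
        seq, feats = fwd_seq, fwd_feats
    return CircularGenome(
        id=genome.id,
        sequence=seq,
        circular=genome.circular,
        features=feats,
        source=genome.source,
    )
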