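"""Quadripartite structure detection for chloroplast genomes.

A typical chloroplast genome carries two identical inverted-repeat copies
(IRa/IRb) separating a large and a small single-copy region (LSC/SSC).  This
module finds the maximal pair of disjoint exact reverse-complement repeats on
the circle, partitions the genome into LSC/IRb/SSC/IRa, reports the gene
context of the four junctions, and tabulates structures across genomes.

Intervals are (start, end) pairs, 0-based half-open on the circle; ``end``
may exceed the genome length when a segment wraps the origin.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field

import pandas as pd

from .genome_io import AnnotationFeature, CircularGenome, revcomp


class StructureNotFoundError(ValueError):
    """No inverted-repeat pair of the required length exists."""


@dataclass(frozen=True)
class QuadripartiteStructure:
    """LSC/IRb/SSC/IRa intervals on a genome's current coordinates.

    IRb is, by convention, the inverted-repeat copy adjacent to the right end
    of the LSC, so in canonical order segments read LSC, IRb, SSC, IRa.
    """

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    genome_length: int
    gc_percent: float

    @property
    def lengths(self) -> dict[str, int]:
        return {
            "lsc": self.lsc[1] - self.lsc[0],
            "irb": self.irb[1] - self.irb[0],
            "ssc": self.ssc[1] - self.ssc[0],
            "ira": self.ira[1] - self.ira[0],
        }

    def __post_init__(self) -> None:
        L = self.lengths
        total = L["lsc"] + L["irb"] + L["ssc"] + L["ira"]
        if total != self.genome_length:
            raise ValueError(
                f"segment lengths sum to {total}, genome is {self.genome_length} bp"
            )
        if L["irb"] != L["ira"]:
            raise ValueError("IR copies differ in length")
        if L["lsc"] < L["ssc"]:
            raise ValueError("LSC shorter than SSC")


def gc_content_percent(sequence: str) -> float:
    """G+C percentage over the whole sequence, rounded half-up to 2 decimals."""
    gc = sequence.count("G") + sequence.count("C")
    frac = decimal.Decimal(gc * 100) / decimal.Decimal(len(sequence))
    return float(frac.quantize(decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Maximal inverted-repeat search
# ---------------------------------------------------------------------------


def _maximal_inverted_matches(seq: str, min_len: int) -> list[tuple[int, int, int]]:
    """All maximal pairs (a, b, L): circle intervals [a,a+L) and [b,b+L) with
    seq[b..] = revcomp(seq[a..]), L >= min_len, disjoint on the circle, a <= b.

    Seeds of length k stepped so that any match of length >= min_len contains
    an aligned seed; each hit is extended maximally on the doubled sequence.
    """
    n = len(seq)
    s2 = seq + seq
    t2 = revcomp(s2)  # match in s2 vs t2 <=> inverted match within the circle
    k = min(24, min_len)
    step = max(1, min_len - k + 1)

    index: dict[str, list[int]] = {}
    for j in range(len(t2) - k + 1):
        index.setdefault(t2[j : j + k], []).append(j)

    seen_runs: dict[int, list[tuple[int, int]]] = {}  # diag -> [(i_start, i_end)]
    results: set[tuple[int, int, int]] = set()
    two_n = 2 * n
    for i in range(0, two_n - k + 1, step):
        hits = index.get(s2[i : i + k])
        if not hits:
            continue
        for j in hits:
            diag = i - j
            covered = False
            for a0, a1 in seen_runs.get(diag, ()):
                if a0 <= i < a1:
                    covered = True
                    break
            if covered:
                continue
            # extend maximally
            i0, j0 = i, j
            while i0 > 0 and j0 > 0 and s2[i0 - 1] == t2[j0 - 1]:
                i0 -= 1
                j0 -= 1
            i1, j1 = i + k, j + k
            while i1 < two_n and j1 < len(t2) and s2[i1] == t2[j1]:
                i1 += 1
                j1 += 1
            seen_runs.setdefault(diag, []).append((i0, i1))
            L = i1 - i0
            if L < min_len:
                continue
            L = min(L, n)
            # matched segment in s2 coordinates on the reverse strand:
            # t2[j0:j0+L] corresponds to s2[2n - j0 - L : 2n - j0]
            a = i0 % n
            b = (two_n - j0 - L) % n
            if a > b:
                a, b = b, a
            # disjoint on the circle: [a,a+L) and [b,b+L), a <= b < n
            if b < a + L:  # overlap going forward
                continue
            if a + n < b + L:  # overlap wrapping the origin
                continue
            results.add((a, b, L))
    return sorted(results)


def detect_structure(
    genome: CircularGenome, min_ir_len: int = 1000
) -> QuadripartiteStructure:
    """Partition a circular genome into LSC/IRb/SSC/IRa.

    Finds the maximal-length pair of disjoint exact reverse-complement
    repeats of at least ``min_ir_len`` bp (searching across the circular
    origin).  The shorter gap between the copies is the SSC, the longer the
    LSC.  Ties between equally long repeat pairs are broken by smallest SSC,
    then by lowest start coordinate.
    """
    n = len(genome)
    if n <= 2 * min_ir_len:
        raise ValueError(
            f"genome of {n} bp cannot contain two inverted repeats of {min_ir_len} bp"
        )
    matches = _maximal_inverted_matches(genome.sequence, min_ir_len)
    if not matches:
        raise StructureNotFoundError(
            f"no quadripartite structure: no inverted repeat >= {min_ir_len} bp "
            f"in genome {genome.id!r}"
        )

    def keyfun(m: tuple[int, int, int]) -> tuple[int, int, int]:
        a, b, L = m
        gap1 = b - (a + L)  # between copy A end and copy B start
        gap2 = n - b - L + a  # wrapping gap
        ssc = min(gap1, gap2)
        return (-L, ssc, a)

    a, b, L = min(matches, key=keyfun)

    def norm(iv: tuple[int, int]) -> tuple[int, int]:
        s, e = iv
        return (s % n, s % n + (e - s))

    gap1 = norm((a + L, b))  # forward gap
    gap2 = norm((b + L, a + n))  # wrapping gap (end beyond n)
    if gap1[1] - gap1[0] >= gap2[1] - gap2[0]:
        lsc, ssc = gap1, gap2
        # LSC's right end is b => IRb is copy B
        irb, ira = (b, b + L), (a, a + L)
    else:
        lsc, ssc = gap2, gap1
        # LSC wraps and ends at a => IRb is copy A
        irb, ira = (a, a + L), (b, b + L)
    return QuadripartiteStructure(
        lsc=lsc,
        irb=irb,
        ssc=ssc,
        ira=ira,
        genome_length=n,
        gc_percent=gc_content_percent(genome.sequence),
    )


# ---------------------------------------------------------------------------
# Junction context
# ---------------------------------------------------------------------------

JUNCTION_NAMES = ("LSC-IRb", "IRb-SSC", "SSC-IRa", "IRa-LSC")


@dataclass
class JunctionContext:
    junction: str
    position: int
    spanning: list[dict] = field(default_factory=list)
    left_neighbor: str | None = None
    right_neighbor: str | None = None


@dataclass
class JunctionReport:
    genome_id: str
    junctions: list[JunctionContext]
    warning: str | None = None


def junction_report(
    genome: CircularGenome, structure: QuadripartiteStructure
) -> JunctionReport:
    """Features spanning or flanking the four LSC/IR/SSC junctions.

    Expects a canonically rotated genome (LSC starting at position 0).  For a
    feature crossing a junction the report gives the fragment length on each
    side; fragments sum to the feature length.
    """
    n = len(genome)
    L = structure.lengths
    positions = {
        "LSC-IRb": L["lsc"],
        "IRb-SSC": L["lsc"] + L["irb"],
        "SSC-IRa": L["lsc"] + L["irb"] + L["ssc"],
        "IRa-LSC": n,  # == position 0 on the circle
    }
    contexts: list[JunctionContext] = []
    for name in JUNCTION_NAMES:
        p = positions[name]
        ctx = JunctionContext(junction=name, position=p % n)
        for f in genome.features:
            if f.start < p < f.end:
                ctx.spanning.append(
                    {
                        "name": f.name,
                        "kind": f.kind,
                        "left_bp": p - f.start,
                        "right_bp": f.end - p,
                    }
                )
        left = [f for f in genome.features if f.end <= p]
        right = [f for f in genome.features if f.start >= (p % n)]
        if left:
            ctx.left_neighbor = max(left, key=lambda f: f.end).name
        if right:
            ctx.right_neighbor = min(right, key=lambda f: f.start).name
        contexts.append(ctx)
    warning = "genome has no annotation features" if not genome.features else None
    return JunctionReport(genome_id=genome.id, junctions=contexts, warning=warning)


# ---------------------------------------------------------------------------
# Cross-genome comparison
# ---------------------------------------------------------------------------


def compare_structures(
    structures: dict[str, QuadripartiteStructure]
) -> pd.DataFrame:
    """Tabulate segment lengths and GC% per genome, with deltas vs the first.

    ``structures`` maps genome id -> structure; requires at least two.
    """
    if len(structures) < 2:
        raise ValueError("need at least two structures to compare")
    rows = []
    for gid, st in structures.items():
        L = st.lengths
        rows.append(
            {
                "genome": gid,
                "total_bp": st.genome_length,
                "lsc_bp": L["lsc"],
                "ssc_bp": L["ssc"],
                "ira_bp": L["ira"],
                "irb_bp": L["irb"],
                "gc_percent": st.gc_percent,
            }
        )
    df = pd.DataFrame(rows).set_index("genome")
    first = df.iloc[0]
    for col in list(df.columns):
        delta = df[col] - first[col]
        df[f"delta_{col}"] = delta.round(2) if col == "gc_percent" else delta.astype(int)
    return df
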