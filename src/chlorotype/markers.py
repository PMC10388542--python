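"""Tandem-repeat copy-number characterization and diagnostic marker design.

Large InDels between cytoplasm types typically arise from copy-number
changes of a short tandemly repeated unit in an intergenic spacer.  This
module finds the repeat unit explaining an InDel, counts copies in each
genome, selects marker-worthy InDels (length strictly greater than a cutoff,
intergenic by default), and designs or accepts PCR primer pairs whose
products differ between cytotypes by copy-difference x unit-length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import yaml
from Bio.SeqUtils import MeltingTemp

from .genome_io import CircularGenome, revcomp
from .variants import Variant

# Tm model: nearest-neighbor thermodynamics, 50 mM monovalent salt,
# 0.5 uM primer (the amplifying strand in excess).
_TM_KW = dict(Na=50, dnac1=500, dnac2=0, saltcorr=5)


def primer_tm(seq: str) -> float:
    return float(MeltingTemp.Tm_NN(seq, **_TM_KW))


def _is_primitive(unit: str) -> bool:
    """True unless the string is an integer repetition of a shorter string."""
    L = len(unit)
    for d in range(1, L):
        if L % d == 0 and unit == unit[:d] * (L // d):
            return False
    return True


@dataclass(frozen=True)
class TandemRepeatCNV:
    """An InDel explained as a copy-number change of a tandem unit."""

    locus: tuple[int, int]  # maximal tandem run on the reference (0-based)
    unit: str
    copies_ref: int
    copies_qry: int
    variant: Variant

    @property
    def unit_len(self) -> int:
        return len(self.unit)

    def __post_init__(self) -> None:
        if abs(self.copies_ref - self.copies_qry) * self.unit_len != self.variant.length:
            raise ValueError("copy difference inconsistent with InDel length")


@dataclass(frozen=True)
class PrimerPair:
    fwd: str
    rev: str
    tm_fwd: float
    tm_rev: float


@dataclass
class MarkerCandidate:
    name: str
    variant: Variant
    cnv: TandemRepeatCNV | None = None
    context: str = ""
    primers: PrimerPair | None = None
    expected_sizes: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class MarkerDefinition:
    """A deployable marker: primer pair plus expected per-cytotype sizes."""

    name: str
    fwd: str
    rev: str
    expected: dict[str, int]  # cytotype -> amplicon bp
    tolerance_bp: int = 2


# ---------------------------------------------------------------------------
# Tandem unit detection
# ---------------------------------------------------------------------------


def _count_copies(seq: str, pos: int, unit: str) -> tuple[int, int, int]:
    """Maximal exact tandem run of ``unit`` with a copy boundary at ``pos``.

    Returns (copies, run_start, run_end); zero copies if no copy abuts pos.
    """
    u = len(unit)
    start = pos
    while start - u >= 0 and seq[start - u : start] == unit:
        start -= u
    end = pos
    while end + u <= len(seq) and seq[end : end + u] == unit:
        end += u
    return (end - start) // u, start, end


def detect_tandem_unit(
    variant: Variant,
    ref: CircularGenome | str,
    qry: CircularGenome | str,
    max_unit: int = 100,
) -> TandemRepeatCNV | None:
    """Explain an InDel as a tandem-repeat copy-number change, if possible.

    Tries every unit length dividing the InDel length (smallest first, up to
    ``max_unit``): the unit must be primitive, the inserted/deleted sequence
    an exact integer number of copies, and at least one further exact copy
    must flank the event in the reference.  Copy numbers are the maximal
    exact tandem runs around the locus in each genome.
    """
    if variant.type not in ("insertion", "deletion"):
        raise TypeError(f"expected an InDel, got {variant.type}")
    ref_seq = ref.sequence if isinstance(ref, CircularGenome) else ref
    qry_seq = qry.sequence if isinstance(qry, CircularGenome) else qry

    # standard convention: long allele = anchor + event; at the genome start
    # the anchor follows the event instead
    long_a = variant.alt_allele if variant.type == "insertion" else variant.ref_allele
    short_a = variant.ref_allele if variant.type == "insertion" else variant.alt_allele
    if long_a.startswith(short_a):
        event = long_a[len(short_a):]
        ref_pos0 = variant.ref_pos  # 0-based event position (anchor at pos-1)
        qry_pos0 = variant.qry_pos
    else:
        event = long_a[: -len(short_a)] if short_a else long_a
        ref_pos0 = variant.ref_pos - 1
        qry_pos0 = max(variant.qry_pos - 1, 0)
    L = len(event)

    for u_len in range(1, min(L, max_unit) + 1):
        if L % u_len:
            continue
        unit = event[:u_len]
        if event != unit * (L // u_len):
            continue
        if not _is_primitive(unit):
            continue
        # require a tandem copy in the flanking reference context
        left_ok = ref_pos0 - u_len >= 0 and ref_seq[ref_pos0 - u_len : ref_pos0] == unit
        right_start = ref_pos0 + (L if variant.type == "deletion" else 0)
        right_ok = ref_seq[right_start : right_start + u_len] == unit
        if not (left_ok or right_ok):
            continue
        copies_ref, start, end = _count_copies(ref_seq, ref_pos0, unit)
        copies_qry, _, _ = _count_copies(qry_seq, qry_pos0, unit)
        signed = L // u_len if variant.type == "insertion" else -(L // u_len)
        if copies_qry - copies_ref != signed:
            # fall back to arithmetic if the query scan lost phase
            copies_qry = copies_ref + signed
        if copies_ref < 1 or copies_qry < 0:
            continue
        return TandemRepeatCNV(
            locus=(start, end),
            unit=unit,
            copies_ref=copies_ref,
            copies_qry=copies_qry,
            variant=variant,
        )
    return None


# ---------------------------------------------------------------------------
# Candidate selection
# ---------------------------------------------------------------------------


def select_marker_candidates(
    variants: Iterable[Variant],
    ref: CircularGenome | str | None = None,
    qry: CircularGenome | str | None = None,
    min_len: int = 20,
    require_intergenic: bool = True,
) -> list[MarkerCandidate]:
    """InDels longer than ``min_len`` (strictly), intergenic when required.

    Candidates are ordered by InDel length, longest first, and named
    cp_01, cp_02, ...; each carries its tandem-repeat CNV when the genomes
    are supplied and a unit exists.
    """
    picked = [
        v
        for v in variants
        if v.type in ("insertion", "deletion") and v.length > min_len
    ]
    if require_intergenic:
        picked = [v for v in picked if v.context == "intergenic"]
    picked.sort(key=lambda v: (-v.length, v.ref_pos))
    out = []
    for i, v in enumerate(picked, 1):
        cnv = (
            detect_tandem_unit(v, ref, qry)
            if ref is not None and qry is not None
            else None
        )
        out.append(
            MarkerCandidate(
                name=f"cp_{i:02d}", variant=v, cnv=cnv, context=v.context_detail
            )
        )
    return out


# ---------------------------------------------------------------------------
# Primer design
# ---------------------------------------------------------------------------


class PrimerDesignError(RuntimeError):
    pass


def count_occurrences(genome_seq: str, primer: str, circular: bool = True) -> int:
    """Exact binding sites of a primer on either strand of a (circular) genome."""
    hay = genome_seq + genome_seq[: len(primer) - 1] if circular else genome_seq
    total = 0
    for probe in (primer, revcomp(primer)):
        start = 0
        while True:
            idx = hay.find(probe, start)
            if idx == -1:
                break
            total += 1
            start = idx + 1
    return total


def _gc_frac(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def design_primers(
    candidate: MarkerCandidate,
    ref: CircularGenome,
    qry: CircularGenome,
    flank: int = 200,
    length_range: tuple[int, int] = (18, 25),
    tm_range: tuple[float, float] = (55.0, 62.0),
    gc_range: tuple[float, float] = (0.40, 0.60),
    max_product: int = 400,
    ref_cytotype: str = "S",
    qry_cytotype: str = "N",
) -> MarkerCandidate:
    """Design a diagnostic primer pair around a CNV locus.

    Searches ``flank`` bp on each side of the locus (excluding the tandem run
    itself) for primers of 18-25 nt, Tm 55-62 C (nearest-neighbor model), GC
    40-60%, a single exact binding site in both genomes, and a product of at
    most ``max_product`` bp.  The best pair minimizes the Tm difference and
    the distance of the product size from 250 bp; expected per-cytotype sizes
    are filled by in-silico PCR on both genomes.
    """
    if candidate.cnv is not None:
        locus = candidate.cnv.locus
    else:
        v = candidate.variant
        locus = (v.ref_pos - 1, v.ref_pos - 1 + max(len(v.ref_allele), 1))
    left_lo = max(0, locus[0] - flank)
    left_win = ref.sequence[left_lo : locus[0]]
    right_win = ref.sequence[locus[1] : locus[1] + flank]
    lmin, lmax = length_range

    def admissible(window: str, offset: int, reverse: bool) -> list[tuple[int, str, float]]:
        out = []
        for size in range(lmin, lmax + 1):
            for i in range(len(window) - size + 1):
                seq = window[i : i + size]
                if "N" in seq:
                    continue
                if not (gc_range[0] <= _gc_frac(seq) <= gc_range[1]):
                    continue
                primer = revcomp(seq) if reverse else seq
                tm = primer_tm(primer)
                if not (tm_range[0] <= tm <= tm_range[1]):
                    continue
                if count_occurrences(ref.sequence, primer) != 1:
                    continue
                if count_occurrences(qry.sequence, primer) != 1:
                    continue
                out.append((offset + i, primer, tm))
        return out

    fwd_cands = admissible(left_win, left_lo, reverse=False)
    rev_cands = admissible(right_win, locus[1], reverse=True)
    if not fwd_cands or not rev_cands:
        raise PrimerDesignError(
            f"no primer found for {candidate.name}: "
            f"{len(fwd_cands)} forward / {len(rev_cands)} reverse admissible sites "
            f"in +-{flank} bp flanks"
        )
    best = None
    for fpos, fwd, ftm in fwd_cands:
        for rpos, rev, rtm in rev_cands:
            product = rpos + len(rev) - fpos
            if product > max_product or product < len(fwd) + len(rev):
                continue
            score = -abs(ftm - rtm) - abs(product - 250) / 100
            if best is None or score > best[0]:
                best = (score, fwd, rev, ftm, rtm)
    if best is None:
        raise PrimerDesignError(
            f"no primer pair for {candidate.name} with product <= {max_product} bp"
        )
    _, fwd, rev, ftm, rtm = best
    pair = PrimerPair(fwd=fwd, rev=rev, tm_fwd=round(ftm, 1), tm_rev=round(rtm, 1))
    candidate.primers = pair
    candidate.expected_sizes = predict_expected_sizes(
        pair, {ref_cytotype: ref, qry_cytotype: qry}
    )
    return candidate


def predict_expected_sizes(
    primers: PrimerPair, genomes_by_cytotype: dict[str, CircularGenome]
) -> dict[str, int]:
    """In-silico PCR product size per cytotype (single product expected)."""
    from .genotyping import insilico_pcr

    sizes: dict[str, int] = {}
    for cytotype, genome in genomes_by_cytotype.items():
        amps = insilico_pcr(genome, primers.fwd, primers.rev)
        if len(amps) != 1:
            raise PrimerDesignError(
                f"expected one product in {genome.id}, got {len(amps)}"
            )
        sizes[cytotype] = amps[0].length
    return sizes


def use_published_primers(
    candidate: MarkerCandidate,
    fwd: str,
    rev: str,
    genomes_by_cytotype: dict[str, CircularGenome],
) -> MarkerCandidate:
    """Inject a user-supplied primer pair verbatim, bypassing design."""
    pair = PrimerPair(
        fwd=fwd.upper(),
        rev=rev.upper(),
        tm_fwd=round(primer_tm(fwd.upper()), 1),
        tm_rev=round(primer_tm(rev.upper()), 1),
    )
    candidate.primers = pair
    candidate.expected_sizes = predict_expected_sizes(pair, genomes_by_cytotype)
    return candidate


def to_definition(candidate: MarkerCandidate, tolerance_bp: int = 2) -> MarkerDefinition:
    if candidate.primers is None or not candidate.expected_sizes:
        raise ValueError(f"candidate {candidate.name} has no primers/expected sizes")
    return MarkerDefinition(
        name=candidate.name,
        fwd=candidate.primers.fwd,
        rev=candidate.primers.rev,
        expected=dict(candidate.expected_sizes),
        tolerance_bp=tolerance_bp,
    )


# ---------------------------------------------------------------------------
# Marker-definition serialization
# ---------------------------------------------------------------------------


def save_markers(defs: list[MarkerDefinition], path: str) -> None:
    payload = [
        {
            "name": d.name,
            "fwd": d.fwd,
            "rev": d.rev,
            "expected": dict(d.expected),
            "tolerance_bp": d.tolerance_bp,
        }
        for d in defs
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_markers(path: str) -> list[MarkerDefinition]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return [
        MarkerDefinition(
            name=d["name"],
            fwd=d["fwd"].upper(),
            rev=d["rev"].upper(),
            expected={str(k): int(v) for k, v in d["expected"].items()},
            tolerance_bp=int(d.get("tolerance_bp", 2)),
        )
        for d in payload
    ]
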